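"""The 62-criterion assessment: category stats and correctness diagnostics."""

import numpy as np
import pytest

import swathqc as sq
from swathqc import assess as qa
from swathqc import masses
from swathqc.model import Assay, Fragment, SpectralLibrary, SwathScheme


def make_assay(seq="ELVISLIVESK", charge=2, rt=30.0, proteins=("sp|P1|X",),
               frag_mzs=None, series="y", decoy=None, modseq=None):
    pep = masses.parse_modified_sequence(modseq or seq)
    frags = []
    if frag_mzs is None:
        frags = [
            Fragment(masses.fragment_mz(pep, "y", o, 1), 100.0 - o, "y", o, 1)
            for o in range(1, 7)
        ]
    else:
        frags = [Fragment(mz, 100.0, series, None, 1) for mz in frag_mzs]
    return Assay(
        stripped_sequence=pep.stripped_sequence,
        modified_sequence=masses.canonical_notation(pep),
        precursor_charge=charge,
        precursor_mz=masses.precursor_mz(pep, charge),
        rt=rt,
        protein_ids=list(proteins),
        fragments=frags,
        is_decoy_annotated=decoy,
    )


class TestComplexity:
    def test_counting(self):
        lib = SpectralLibrary(
            [make_assay("ELVISLIVESK", z) for z in (2, 3)]
            + [make_assay("PEPTIDEK", z) for z in (2, 3)]
        )
        cx = sq.complexity_stats(lib)
        assert cx["cx_n_peptides"] == 2
        assert cx["cx_n_precursors"] == 4
        assert cx["cx_n_fragments"] == 24
        assert cx["cx_n_assays"] == 4

    def test_redundancy_multiplies_average_fragments(self, conflict_free_library):
        raw = sq.make_redundant(conflict_free_library, 7, seed=3)
        merged = sq.merge_redundant(raw, n_top=6)
        mean = lambda lib: lib.n_fragments / len({a.precursor_key for a in lib.assays})
        assert mean(raw) / mean(merged) == pytest.approx(7.0, rel=0.01)


class TestCharacteristics:
    def test_pure_y_series_composition(self):
        lib = SpectralLibrary([make_assay()])
        ch = sq.characteristics_stats(lib)
        assert ch["ch_pct_series_y"] == 100.0
        assert ch["ch_pct_series_b"] == 0.0

    def test_charge_percentages_sum_to_100(self, clean_library):
        ch = sq.characteristics_stats(clean_library)
        total = sum(
            ch[k]
            for k in (
                "ch_pct_charge_1", "ch_pct_charge_2", "ch_pct_charge_3",
                "ch_pct_charge_4", "ch_pct_charge_ge5",
            )
        )
        assert total == pytest.approx(100.0, abs=1e-9)
        # tryptic generator: only protein C-terminal tail peptides may lack K/R
        assert ch["ch_pct_tryptic_cterm"] > 85.0


class TestModifications:
    def test_unmodified_library(self):
        lib = SpectralLibrary([make_assay("ELVISLIVESK"), make_assay("PEPTIDEK")])
        m = sq.modification_stats(lib)
        assert m["mod_n_types"] == 0 and m["mod_pct_modified"] == 0.0

    def test_modified_fraction(self):
        assays = [make_assay(f"PEPTIDEK{'A' * i}R".replace("KA", "KA")) for i in range(7)]
        assays += [
            make_assay("MSSSSSSR", modseq="M(UniMod:35)SSSSSSR"),
            make_assay("MTTTTTTR", modseq="M(UniMod:35)TTTTTTR"),
            make_assay("MVVVVVVR", modseq="M(UniMod:35)VVVVVVR"),
        ]
        m = sq.modification_stats(SpectralLibrary(assays))
        assert m["mod_pct_modified"] == pytest.approx(30.0)
        assert m["mod_n_oxidation"] == 3
        assert m["mod_n_types"] == 1

    def test_notation_dialects_count_as_one_type(self):
        lib = SpectralLibrary(
            [
                make_assay("PEPTICK", modseq="PEPTIC[CAM]K"),
                make_assay("SSSTICK", modseq="SSSTIC(UniMod:4)K"),
            ]
        )
        assert sq.modification_stats(lib)["mod_n_types"] == 1


class TestCompleteness:
    def test_coverage_and_proteotypicity(self):
        letters = "CDEFGHILMN"
        recs = [(f"T{i}", "AAAK" + letters[i] * 7 + "K") for i in range(10)]
        index = sq.index_records(recs, sq.DigestParams(0, 4, 50))
        # AAAK is shared by all ten proteins; CCCCCCCK is proteotypic for T0
        lib = SpectralLibrary(
            [
                make_assay("AAAK", proteins=("T0",), frag_mzs=[300.0]),
                make_assay("CCCCCCCK", proteins=("T0",), frag_mzs=[300.0]),
            ]
        )
        cp = sq.completeness_stats(lib, index)
        assert cp["cp_proteome_size"] == 10
        assert cp["cp_pct_coverage"] == 100.0
        assert cp["cp_pct_proteotypic"] == 50.0
        assert cp["cp_pct_shared"] == 50.0
        assert cp["cp_n_single_peptide_proteins"] == 9
        assert cp["cp_mean_peptides_per_protein"] == pytest.approx(1.1)

    def test_unmapped_peptide_counted(self, proteome_index):
        lib = SpectralLibrary([make_assay("WWWWWWWWWWK")])
        cp = sq.completeness_stats(lib, proteome_index)
        assert cp["cp_n_unmapped_peptides"] == 1

    def test_synthetic_library_maps_into_its_proteome(
        self, clean_library, proteome_index
    ):
        cp = sq.completeness_stats(clean_library, proteome_index)
        assert cp["cp_n_unmapped_peptides"] == 0
        assert cp["cp_pct_proteotypic"] + cp["cp_pct_shared"] == pytest.approx(100.0)
        assert 0 < cp["cp_pct_coverage"] <= 100.0


class TestTargetDecoy:
    def test_prefix_rules(self):
        lib = SpectralLibrary(
            [
                make_assay(proteins=("DECOY_sp|P1|X",)),
                make_assay(proteins=("sp|P1|X", "DECOY_sp|P2|Y")),
                make_assay(proteins=("sp|P3|Z",)),
                make_assay(decoy=True),
            ]
        )
        td = sq.classify_target_decoy(lib)
        assert td.classes == ["decoy", "mixed", "target", "decoy"]
        assert td.pct_target + td.pct_decoy + td.pct_mixed == pytest.approx(
            100.0, abs=1e-9
        )

    def test_injected_fraction_recovered(self, conflict_free_library, proteome_index):
        lib = sq.inject_decoys(conflict_free_library, 0.05, proteome_index, seed=9)
        td = sq.classify_target_decoy(lib, proteome_index)
        n_injected = len(lib) - len(conflict_free_library)
        assert td.pct_decoy == pytest.approx(100.0 * n_injected / len(lib), abs=1e-9)


class TestDeltaMass:
    def test_theoretical_library_has_zero_delta(self, clean_library):
        dm = sq.delta_mass_stats(clean_library)
        assert dm.avg_fragment_delta == pytest.approx(0.0, abs=1e-9)
        assert dm.avg_precursor_delta == pytest.approx(0.0, abs=1e-9)
        assert dm.n_problem_assays == 0

    @pytest.mark.parametrize("delta", [0.01, 0.02, 0.05])
    def test_constant_offset_recovered(self, clean_library, delta):
        bad = sq.perturb_fragment_mz(clean_library, delta)
        dm = sq.delta_mass_stats(bad)
        assert dm.avg_fragment_delta == pytest.approx(delta, abs=1e-6)
        assert dm.avg_precursor_delta == pytest.approx(0.0, abs=1e-9)

    def test_half_perturbed_mean(self):
        a = make_assay("ELVISLIVESK")
        b = make_assay("PEPTIDEK")
        for f in a.fragments:
            f.mz += 0.02
        dm = sq.delta_mass_stats(SpectralLibrary([a, b]))
        assert dm.avg_fragment_delta == pytest.approx(0.01, abs=1e-9)
        assert dm.n_mass_error_assays == 1  # only the shifted assay

    def test_unverifiable_assay_routed_to_problems(self):
        bad = make_assay("ELVISLIVESK")
        bad.modified_sequence = "ELVIS[Wizardry]LIVESK"
        lib = SpectralLibrary([bad, make_assay("PEPTIDEK")])
        dm = sq.delta_mass_stats(lib)
        assert dm.n_unverifiable == 1
        assert dm.n_problem_assays == dm.n_mass_error_assays + dm.n_unverifiable


class TestRtFit:
    def test_collinear_points(self):
        assays = []
        for i, seq in enumerate(["ELVISLIVESK", "PEPTIDEK", "SSSSSSSK"]):
            for z in (2, 3):
                assays.append(make_assay(seq, z, rt=10.0 * (i + 1)))
        fit = sq.rt_correlation_fit(SpectralLibrary(assays))
        assert fit.n_pairs == 3
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)

    def test_shared_rt_library_is_perfect(self, clean_library):
        fit = sq.rt_correlation_fit(clean_library)
        assert fit.n_pairs >= 3
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_closed_form_ols_oracle(self):
        rng = np.random.default_rng(42)
        seqs = ["".join(rng.choice(list("ACDEFGHILMNQSTVWY"), 8)) + "K" for _ in range(40)]
        assays = []
        x, y = [], []
        for seq in seqs:
            rt2 = float(rng.uniform(0, 100))
            rt3 = rt2 + float(rng.normal(0, 2.0))
            x.append(rt2)
            y.append(rt3)
            assays.append(make_assay(seq, 2, rt=rt2))
            assays.append(make_assay(seq, 3, rt=rt3))
        fit = sq.rt_correlation_fit(SpectralLibrary(assays))
        x, y = np.array(x), np.array(y)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert fit.n_pairs == 40
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)
        assert fit.r_squared == pytest.approx(r2, abs=1e-9)

    def test_too_few_pairs_not_evaluated(self):
        lib = SpectralLibrary([make_assay("ELVISLIVESK", 2), make_assay("ELVISLIVESK", 3)])
        fit = sq.rt_correlation_fit(lib)
        assert fit.n_pairs == 1 and fit.r_squared is None


class TestConflicts:
    def test_interval_membership(self):
        a = make_assay(frag_mzs=[495.3, 600.2])
        a.precursor_mz = 500.0
        stats = sq.detect_conflicts(
            SpectralLibrary([a]), SwathScheme([(490.0, 505.0), (505.0, 700.0)])
        )
        assert stats.n_conflict_precursors == 1
        assert stats.n_conflict_fragments == 1

    def test_overlapping_windows_both_count(self):
        a = make_assay(frag_mzs=[499.8])
        a.precursor_mz = 500.0
        scheme = SwathScheme([(490.0, 500.5), (499.5, 510.0)])
        stats = sq.detect_conflicts(SpectralLibrary([a]), scheme)
        assert stats.n_conflict_fragments == 1

    def test_window_end_is_exclusive(self):
        a = make_assay(frag_mzs=[505.0])
        a.precursor_mz = 500.0
        stats = sq.detect_conflicts(SpectralLibrary([a]), SwathScheme([(490.0, 505.0)]))
        assert stats.n_conflict_fragments == 0
        start_hit = make_assay(frag_mzs=[490.0])
        start_hit.precursor_mz = 500.0
        stats = sq.detect_conflicts(
            SpectralLibrary([start_hit]), SwathScheme([(490.0, 505.0)])
        )
        assert stats.n_conflict_fragments == 1  # start is inclusive

    def test_precursor_outside_all_windows_is_unverifiable(self):
        a = make_assay(frag_mzs=[495.0])
        a.precursor_mz = 1900.0
        stats = sq.detect_conflicts(SpectralLibrary([a]), SwathScheme([(490.0, 505.0)]))
        assert stats.n_unverifiable_precursors == 1
        assert stats.n_conflict_precursors == 0

    def test_agrees_with_exhaustive_scan(self, clean_library, covering_scheme):
        stats = sq.detect_conflicts(clean_library, covering_scheme)
        # brute force: triple loop over assay x window x fragment
        expect_prec = 0
        expect_frag = 0
        for assay in clean_library.assays:
            containing = [
                w
                for w in covering_scheme.windows
                if w[0] <= assay.precursor_mz < w[1]
            ]
            if not containing:
                continue
            hits = 0
            for frag in assay.fragments:
                if any(s <= frag.mz < e for s, e in containing):
                    hits += 1
            if hits:
                expect_prec += 1
                expect_frag += hits
        assert stats.n_conflict_precursors == expect_prec
        assert stats.n_conflict_fragments == expect_frag


class TestAssessReport:
    def test_exactly_62_criteria_in_five_categories(self, clean_library):
        report = sq.assess(clean_library)
        assert len(report.criteria) == 62
        by_cat = {}
        for c in report.criteria:
            by_cat[c.category] = by_cat.get(c.category, 0) + 1
        assert by_cat == {
            "complexity": 6,
            "characteristics": 28,
            "modifications": 6,
            "completeness": 8,
            "correctness": 14,
        }

    def test_missing_inputs_degrade_to_not_evaluated(self, clean_library):
        report = sq.assess(clean_library)  # no scheme, no proteome
        assert report.get("co_n_conflict_precursors").status == "not_evaluated"
        assert report.get("cp_pct_coverage").status == "not_evaluated"
        assert len(report.criteria) == 62

    def test_full_inputs_evaluate_everything(
        self, clean_library, covering_scheme, proteome_index
    ):
        report = sq.assess(clean_library, covering_scheme, proteome_index)
        assert all(c.status == "evaluated" for c in report.criteria)

    def test_determinism_byte_identical_report(self, clean_library, tmp_path):
        p1, p2 = tmp_path / "r1.tsv", tmp_path / "r2.tsv"
        sq.assess(clean_library).write_tsv(p1)
        sq.assess(clean_library).write_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            sq.assess(SpectralLibrary([]))

    def test_problem_assay_accounting_is_disjoint(self, clean_library, covering_scheme):
        report = sq.assess(clean_library, covering_scheme)
        n_err = report.value("co_n_mass_error_assays")
        n_unv = report.value("co_n_unverifiable_assays")
        assert report.value("co_n_problem_assays") == n_err + n_unv
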