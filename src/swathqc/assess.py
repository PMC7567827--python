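"""Library assessment: the 62-criterion compliance report.

The report is organised in five categories:

* **complexity** (6)      — library size: peptides, precursor ions, fragments
* **characteristics** (28)— physical attributes of precursors (charge, m/z,
  RT, digestion) and fragments (count, ion series, intensity)
* **modifications** (6)   — number and kinds of post-translational mods
* **completeness** (8)    — coverage of the target proteome, proteotypic vs
  shared assays (requires a proteome mapping file)
* **correctness** (14)    — the diagnostics that most influence DIA results:
  target/decoy/mixed accounting, precursor and fragment mass accuracy
  against theory, the cross-charge retention-time fit, and DIA-bin
  (isolation window) conflicts (requires a SWATH definition file)

Criteria whose optional input is absent are reported with status
``not_evaluated`` — never omitted — so every report has exactly 62 rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as _scipy_stats

from . import masses
from .digest import count_missed_cleavages, has_tryptic_cterm
from .model import (
    Assay,
    DEFAULT_DECOY_PREFIXES,
    DigestParams,
    ProteomeIndex,
    SpectralLibrary,
    SwathScheme,
)

CATEGORIES = ("complexity", "characteristics", "modifications", "completeness", "correctness")

#: The criterion registry: (id, category, label, unit).
CRITERIA: list[tuple[str, str, str, str]] = [
    # -- complexity (6)
    ("cx_n_assays", "complexity", "Assays (precursor occurrences)", "count"),
    ("cx_n_peptides", "complexity", "Distinct stripped peptides", "count"),
    ("cx_n_modified_peptides", "complexity", "Distinct modified peptides", "count"),
    ("cx_n_precursors", "complexity", "Distinct precursor ions", "count"),
    ("cx_n_fragments", "complexity", "Fragment ions (transitions)", "count"),
    ("cx_n_proteins", "complexity", "Distinct protein accessions", "count"),
    # -- characteristics (28)
    ("ch_pct_charge_1", "characteristics", "Precursors at charge 1+", "%"),
    ("ch_pct_charge_2", "characteristics", "Precursors at charge 2+", "%"),
    ("ch_pct_charge_3", "characteristics", "Precursors at charge 3+", "%"),
    ("ch_pct_charge_4", "characteristics", "Precursors at charge 4+", "%"),
    ("ch_pct_charge_ge5", "characteristics", "Precursors at charge >=5+", "%"),
    ("ch_precursor_mz_min", "characteristics", "Precursor m/z minimum", "Th"),
    ("ch_precursor_mz_mean", "characteristics", "Precursor m/z mean", "Th"),
    ("ch_precursor_mz_max", "characteristics", "Precursor m/z maximum", "Th"),
    ("ch_pct_with_rt", "characteristics", "Assays with retention time", "%"),
    ("ch_rt_min", "characteristics", "Retention time minimum", "RT"),
    ("ch_rt_max", "characteristics", "Retention time maximum", "RT"),
    ("ch_peptide_length_min", "characteristics", "Peptide length minimum", "aa"),
    ("ch_peptide_length_mean", "characteristics", "Peptide length mean", "aa"),
    ("ch_peptide_length_max", "characteristics", "Peptide length maximum", "aa"),
    ("ch_pct_missed_cleavage_0", "characteristics", "Peptides with 0 missed cleavages", "%"),
    ("ch_pct_missed_cleavage_1", "characteristics", "Peptides with 1 missed cleavage", "%"),
    ("ch_pct_missed_cleavage_ge2", "characteristics", "Peptides with >=2 missed cleavages", "%"),
    ("ch_pct_tryptic_cterm", "characteristics", "Peptides ending in K/R", "%"),
    ("ch_frags_per_precursor_min", "characteristics", "Fragments per precursor minimum", "count"),
    ("ch_frags_per_precursor_mean", "characteristics", "Fragments per precursor mean", "count"),
    ("ch_frags_per_precursor_max", "characteristics", "Fragments per precursor maximum", "count"),
    ("ch_pct_series_b", "characteristics", "Fragments in b series", "%"),
    ("ch_pct_series_y", "characteristics", "Fragments in y series", "%"),
    ("ch_pct_series_other", "characteristics", "Fragments in other/unknown series", "%"),
    ("ch_pct_frag_charge_1", "characteristics", "Fragments at charge 1+", "%"),
    ("ch_pct_frag_charge_ge2", "characteristics", "Fragments at charge >=2+", "%"),
    ("ch_top_fragment_mean_intensity", "characteristics", "Mean relative intensity of top fragment", "a.u."),
    ("ch_pct_positive_intensity", "characteristics", "Assays with all-positive fragment intensities", "%"),
    # -- modifications (6)
    ("mod_n_types", "modifications", "Distinct modification types", "count"),
    ("mod_n_modified_precursors", "modifications", "Modified precursor ions", "count"),
    ("mod_pct_modified", "modifications", "Modified precursor ions", "%"),
    ("mod_n_carbamidomethyl", "modifications", "Precursors with carbamidomethyl (C)", "count"),
    ("mod_n_oxidation", "modifications", "Precursors with oxidation (M)", "count"),
    ("mod_n_other", "modifications", "Precursors with other modifications", "count"),
    # -- completeness (8)
    ("cp_proteome_size", "completeness", "Target proteome size", "count"),
    ("cp_covered_proteins", "completeness", "Proteins covered by the library", "count"),
    ("cp_pct_coverage", "completeness", "Proteome coverage", "%"),
    ("cp_pct_proteotypic", "completeness", "Proteotypic peptides (single protein)", "%"),
    ("cp_pct_shared", "completeness", "Shared peptides (multiple proteins)", "%"),
    ("cp_mean_peptides_per_protein", "completeness", "Mean peptides per covered protein", "count"),
    ("cp_n_single_peptide_proteins", "completeness", "Proteins covered by a single peptide", "count"),
    ("cp_n_unmapped_peptides", "completeness", "Library peptides absent from the proteome", "count"),
    # -- correctness (14)
    ("co_pct_target", "correctness", "Target assays", "%"),
    ("co_pct_decoy", "correctness", "Decoy assays", "%"),
    ("co_pct_mixed", "correctness", "Mixed (target+decoy) assays", "%"),
    ("co_avg_precursor_delta", "correctness", "Average precursor delta mass (library - theoretical)", "Da"),
    ("co_avg_fragment_delta", "correctness", "Average fragment delta mass (library - theoretical)", "Da"),
    ("co_n_mass_error_assays", "correctness", "Assays with >=1 mass error beyond tolerance", "count"),
    ("co_n_unverifiable_assays", "correctness", "Assays that cannot be verified against theory", "count"),
    ("co_n_problem_assays", "correctness", "Problem assays (mass errors + unverifiable)", "count"),
    ("co_rt_n_pairs", "correctness", "Peptides with both 2+ and 3+ assays", "count"),
    ("co_rt_slope", "correctness", "RT fit slope (3+ vs 2+)", ""),
    ("co_rt_intercept", "correctness", "RT fit intercept (3+ vs 2+)", "RT"),
    ("co_rt_r_squared", "correctness", "RT fit R-squared (3+ vs 2+)", ""),
    ("co_n_conflict_precursors", "correctness", "Precursors with >=1 conflict fragment", "count"),
    ("co_n_conflict_fragments", "correctness", "Fragment ions inside their precursor's DIA bin", "count"),
]

assert len(CRITERIA) == 62

EVALUATED = "evaluated"
NOT_EVALUATED = "not_evaluated"


@dataclass
class CriterionResult:
    id: str
    category: str
    label: str
    value: Optional[float]
    unit: str
    status: str = EVALUATED


@dataclass
class AssessParams:
    """Tolerances and conventions used by the assessment."""

    tol_precursor: float = 0.01  # Da beyond which a precursor counts as erroneous
    tol_fragment: float = 0.01
    annotate_tol: float = 0.1  # Da window for annotating unlabelled fragments
    annotate_charge_max: int = 2
    decoy_prefixes: tuple[str, ...] = DEFAULT_DECOY_PREFIXES
    digest_params: DigestParams = field(default_factory=DigestParams)


@dataclass
class DeltaMassStats:
    """Mass-accuracy roll-up: library vs theoretical m/z (signed deltas)."""

    avg_precursor_delta: Optional[float]
    avg_fragment_delta: Optional[float]
    n_precursor_errors: int
    n_fragment_errors: int
    n_mass_error_assays: int
    n_unverifiable: int
    precursor_deltas: list[float] = field(default_factory=list)
    fragment_deltas: list[float] = field(default_factory=list)
    error_assay_indices: list[int] = field(default_factory=list)
    unverifiable_assay_indices: list[int] = field(default_factory=list)

    @property
    def n_problem_assays(self) -> int:
        return self.n_mass_error_assays + self.n_unverifiable


@dataclass
class RtFit:
    n_pairs: int
    slope: Optional[float]
    intercept: Optional[float]
    r_squared: Optional[float]
    pairs: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class ConflictStats:
    n_conflict_precursors: int
    n_conflict_fragments: int
    conflict_index: dict[int, list[int]]
    n_unverifiable_precursors: int = 0
    unverifiable_indices: list[int] = field(default_factory=list)


@dataclass
class TargetDecoyStats:
    pct_target: float
    pct_decoy: float
    pct_mixed: float
    classes: list[str]


@dataclass
class AssessmentReport:
    """Exactly 62 criterion results plus per-assay detail payloads."""

    criteria: list[CriterionResult]
    library_dialect: Optional[str]
    n_assays: int
    scheme_provided: bool
    proteome_provided: bool
    details: dict = field(default_factory=dict)

    def get(self, criterion_id: str) -> CriterionResult:
        for c in self.criteria:
            if c.id == criterion_id:
                return c
        raise KeyError(criterion_id)

    def value(self, criterion_id: str) -> Optional[float]:
        return self.get(criterion_id).value

    def to_rows(self) -> list[dict]:
        return [
            dict(
                id=c.id,
                category=c.category,
                label=c.label,
                value="" if c.value is None else f"{c.value:.6g}",
                unit=c.unit,
                status=c.status,
            )
            for c in self.criteria
        ]

    def write_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.to_rows()).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# shared helpers

def _parse_cache(lib: SpectralLibrary) -> dict[str, Optional[masses.ModifiedPeptide]]:
    """Parse each distinct modified sequence once; None marks unparseable."""
    cache: dict[str, Optional[masses.ModifiedPeptide]] = {}
    for assay in lib.assays:
        seq = assay.modified_sequence
        if seq in cache:
            continue
        try:
            cache[seq] = masses.parse_modified_sequence(seq)
        except ValueError:
            cache[seq] = None
    return cache


def _distinct_precursors(lib: SpectralLibrary) -> dict[tuple[str, int], Assay]:
    out: dict[tuple[str, int], Assay] = {}
    for assay in lib.assays:
        out.setdefault(assay.precursor_key, assay)
    return out


# ---------------------------------------------------------------------------
# category computations

def complexity_stats(lib: SpectralLibrary) -> dict[str, float]:
    precursors = {a.precursor_key for a in lib.assays}
    proteins = {p for a in lib.assays for p in a.protein_ids}
    return {
        "cx_n_assays": len(lib.assays),
        "cx_n_peptides": len({a.stripped_sequence for a in lib.assays}),
        "cx_n_modified_peptides": len({a.modified_sequence for a in lib.assays}),
        "cx_n_precursors": len(precursors),
        "cx_n_fragments": lib.n_fragments,
        "cx_n_proteins": len(proteins),
    }


def characteristics_stats(
    lib: SpectralLibrary, digest_params: DigestParams = DigestParams()
) -> dict[str, Optional[float]]:
    assays = lib.assays
    n = len(assays)
    charges = np.array([a.precursor_charge for a in assays])
    prec_mz = np.array([a.precursor_mz for a in assays])
    rts = [a.rt for a in assays if a.rt is not None]
    peptides = sorted({a.stripped_sequence for a in assays})
    lengths = np.array([len(p) for p in peptides])
    missed = np.array(
        [count_missed_cleavages(p, digest_params.suppress_proline) for p in peptides]
    )
    nfrag = np.array([len(a.fragments) for a in assays])
    series = [f.series for a in assays for f in a.fragments]
    fz = np.array([f.charge for a in assays for f in a.fragments])
    n_series = len(series)
    top_int = [max(f.intensity for f in a.fragments) for a in assays]
    all_pos = [all(f.intensity > 0 for f in a.fragments) for a in assays]
    pct = lambda x: 100.0 * x / n
    return {
        "ch_pct_charge_1": pct(int((charges == 1).sum())),
        "ch_pct_charge_2": pct(int((charges == 2).sum())),
        "ch_pct_charge_3": pct(int((charges == 3).sum())),
        "ch_pct_charge_4": pct(int((charges == 4).sum())),
        "ch_pct_charge_ge5": pct(int((charges >= 5).sum())),
        "ch_precursor_mz_min": float(prec_mz.min()),
        "ch_precursor_mz_mean": float(prec_mz.mean()),
        "ch_precursor_mz_max": float(prec_mz.max()),
        "ch_pct_with_rt": pct(len(rts)),
        "ch_rt_min": float(min(rts)) if rts else None,
        "ch_rt_max": float(max(rts)) if rts else None,
        "ch_peptide_length_min": float(lengths.min()),
        "ch_peptide_length_mean": float(lengths.mean()),
        "ch_peptide_length_max": float(lengths.max()),
        "ch_pct_missed_cleavage_0": 100.0 * int((missed == 0).sum()) / len(peptides),
        "ch_pct_missed_cleavage_1": 100.0 * int((missed == 1).sum()) / len(peptides),
        "ch_pct_missed_cleavage_ge2": 100.0 * int((missed >= 2).sum()) / len(peptides),
        "ch_pct_tryptic_cterm": 100.0
        * sum(has_tryptic_cterm(p) for p in peptides)
        / len(peptides),
        "ch_frags_per_precursor_min": float(nfrag.min()),
        "ch_frags_per_precursor_mean": float(nfrag.mean()),
        "ch_frags_per_precursor_max": float(nfrag.max()),
        "ch_pct_series_b": 100.0 * sum(s == "b" for s in series) / n_series,
        "ch_pct_series_y": 100.0 * sum(s == "y" for s in series) / n_series,
        "ch_pct_series_other": 100.0
        * sum(s not in ("b", "y") for s in series)
        / n_series,
        "ch_pct_frag_charge_1": 100.0 * int((fz == 1).sum()) / n_series,
        "ch_pct_frag_charge_ge2": 100.0 * int((fz >= 2).sum()) / n_series,
        "ch_top_fragment_mean_intensity": float(np.mean(top_int)),
        "ch_pct_positive_intensity": pct(sum(all_pos)),
    }


def modification_stats(lib: SpectralLibrary) -> dict[str, float]:
    """Modification accounting over distinct precursor ions."""
    cache = _parse_cache(lib)
    precursors = _distinct_precursors(lib)
    n_prec = len(precursors)
    types: set[str] = set()
    n_modified = n_cam = n_ox = n_other = 0
    for (modseq, _z), _assay in precursors.items():
        pep = cache.get(modseq)
        if pep is None:
            continue
        mods = pep.modifications
        if not mods:
            continue
        n_modified += 1
        names = {m.name for m in mods}
        types |= names
        if "Carbamidomethyl" in names:
            n_cam += 1
        if "Oxidation" in names:
            n_ox += 1
        if names - {"Carbamidomethyl", "Oxidation"}:
            n_other += 1
    return {
        "mod_n_types": len(types),
        "mod_n_modified_precursors": n_modified,
        "mod_pct_modified": 100.0 * n_modified / n_prec if n_prec else 0.0,
        "mod_n_carbamidomethyl": n_cam,
        "mod_n_oxidation": n_ox,
        "mod_n_other": n_other,
    }


def completeness_stats(
    lib: SpectralLibrary, proteome: ProteomeIndex
) -> dict[str, float]:
    peptides = sorted({a.stripped_sequence for a in lib.assays})
    per_protein: dict[str, set[str]] = {}
    n_proteotypic = n_shared = n_unmapped = 0
    for pep in peptides:
        targets = proteome.target_proteins_for(pep)
        if not targets:
            n_unmapped += 1
            continue
        if len(targets) == 1:
            n_proteotypic += 1
        else:
            n_shared += 1
        for acc in targets:
            per_protein.setdefault(acc, set()).add(pep)
    n_mapped = n_proteotypic + n_shared
    covered = len(per_protein)
    size = proteome.proteome_size
    return {
        "cp_proteome_size": size,
        "cp_covered_proteins": covered,
        "cp_pct_coverage": 100.0 * covered / size if size else 0.0,
        "cp_pct_proteotypic": 100.0 * n_proteotypic / n_mapped if n_mapped else 0.0,
        "cp_pct_shared": 100.0 * n_shared / n_mapped if n_mapped else 0.0,
        "cp_mean_peptides_per_protein": (
            float(np.mean([len(v) for v in per_protein.values()])) if covered else 0.0
        ),
        "cp_n_single_peptide_proteins": sum(
            1 for v in per_protein.values() if len(v) == 1
        ),
        "cp_n_unmapped_peptides": n_unmapped,
    }


def classify_target_decoy(
    lib: SpectralLibrary,
    proteome: Optional[ProteomeIndex] = None,
    decoy_prefixes: tuple[str, ...] = DEFAULT_DECOY_PREFIXES,
) -> TargetDecoyStats:
    """Class every assay as target / decoy / mixed.

    The dialect's decoy flag wins when set; otherwise protein accessions are
    classed by decoy prefix (falling back to the proteome index's accession
    classes when available) and an assay mapping to both classes is mixed.
    """

    def class_of_accession(acc: str) -> str:
        if any(acc.startswith(p) for p in decoy_prefixes):
            return "decoy"
        if proteome is not None:
            return proteome.accession_class.get(acc, "target")
        return "target"

    classes: list[str] = []
    for assay in lib.assays:
        if assay.is_decoy_annotated is True:
            classes.append("decoy")
            continue
        acc_classes = {class_of_accession(acc) for acc in assay.protein_ids}
        if acc_classes == {"decoy"}:
            classes.append("decoy")
        elif "decoy" in acc_classes:
            classes.append("mixed")
        else:
            classes.append("target")
    n = len(classes)
    return TargetDecoyStats(
        pct_target=100.0 * classes.count("target") / n,
        pct_decoy=100.0 * classes.count("decoy") / n,
        pct_mixed=100.0 * classes.count("mixed") / n,
        classes=classes,
    )


def theoretical_fragment_mz(
    pep: masses.ModifiedPeptide,
    fragment,
    annotate_tol: float = 0.1,
    annotate_charge_max: int = 2,
) -> Optional[float]:
    """Theoretical m/z for a fragment, or None when it cannot be verified.

    Annotated b/y fragments (no neutral loss) are computed directly; an
    unannotated fragment is matched to the nearest theoretical b/y ion
    within ``annotate_tol``.  Other series and neutral-loss fragments are
    not verified against theory.
    """
    if fragment.loss:
        return None
    if fragment.series in ("b", "y") and fragment.ordinal:
        if not 1 <= fragment.ordinal <= len(pep) - 1:
            return None
        return masses.fragment_mz(pep, fragment.series, fragment.ordinal, fragment.charge)
    if fragment.series is None:
        hit = masses.annotate_fragment(
            fragment.mz, pep, charge_max=annotate_charge_max, tol=annotate_tol
        )
        if hit is None:
            return None
        series, ordinal, z = hit
        return masses.fragment_mz(pep, series, ordinal, z)
    return None


def delta_mass_stats(
    lib: SpectralLibrary, params: AssessParams = AssessParams()
) -> DeltaMassStats:
    """Signed library-minus-theoretical mass deltas and the problem roll-up.

    An assay is *unverifiable* when its modified sequence cannot be parsed
    or contains non-standard residues/modifications; it is then excluded
    from the averages but counted into the problem assays.
    """
    cache = _parse_cache(lib)
    prec_deltas: list[float] = []
    frag_deltas: list[float] = []
    n_prec_err = n_frag_err = 0
    error_idx: list[int] = []
    unverifiable_idx: list[int] = []
    for i, assay in enumerate(lib.assays):
        pep = cache.get(assay.modified_sequence)
        if pep is None:
            unverifiable_idx.append(i)
            continue
        try:
            theo_prec = masses.precursor_mz(pep, assay.precursor_charge)
        except ValueError:
            unverifiable_idx.append(i)
            continue
        has_error = False
        d = assay.precursor_mz - theo_prec
        prec_deltas.append(d)
        if abs(d) > params.tol_precursor:
            n_prec_err += 1
            has_error = True
        for frag in assay.fragments:
            theo = theoretical_fragment_mz(
                pep, frag, params.annotate_tol, params.annotate_charge_max
            )
            if theo is None:
                continue
            df = frag.mz - theo
            frag_deltas.append(df)
            if abs(df) > params.tol_fragment:
                n_frag_err += 1
                has_error = True
        if has_error:
            error_idx.append(i)
    return DeltaMassStats(
        avg_precursor_delta=float(np.mean(prec_deltas)) if prec_deltas else None,
        avg_fragment_delta=float(np.mean(frag_deltas)) if frag_deltas else None,
        n_precursor_errors=n_prec_err,
        n_fragment_errors=n_frag_err,
        n_mass_error_assays=len(error_idx),
        n_unverifiable=len(unverifiable_idx),
        precursor_deltas=prec_deltas,
        fragment_deltas=frag_deltas,
        error_assay_indices=error_idx,
        unverifiable_assay_indices=unverifiable_idx,
    )


def rt_correlation_fit(lib: SpectralLibrary) -> RtFit:
    """Least-squares fit of RT(3+) against RT(2+) over shared peptides.

    Peptides are paired by modified sequence; duplicate occurrences
    contribute their first observation.  A fit needs at least three pairs
    and non-degenerate 2+ RT spread.
    """
    rt_by_charge: dict[str, dict[int, float]] = {}
    for assay in lib.assays:
        if assay.rt is None or assay.precursor_charge not in (2, 3):
            continue
        slot = rt_by_charge.setdefault(assay.modified_sequence, {})
        slot.setdefault(assay.precursor_charge, assay.rt)
    pairs = [
        (v[2], v[3]) for v in rt_by_charge.values() if 2 in v and 3 in v
    ]
    if len(pairs) < 3:
        return RtFit(len(pairs), None, None, None, pairs)
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0:
        return RtFit(len(pairs), None, None, None, pairs)
    fit = _scipy_stats.linregress(x, y)
    return RtFit(
        n_pairs=len(pairs),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        pairs=pairs,
    )


def detect_conflicts(lib: SpectralLibrary, scheme: SwathScheme) -> ConflictStats:
    """Find fragments falling into a DIA bin that contains their precursor.

    A precursor may sit in several (overlapping) windows; a fragment
    conflicts when its m/z lies in *any* of those windows (half-open
    [start, end) intervals).  Precursors outside every window cannot be
    verified and are counted separately.
    """
    conflict_index: dict[int, list[int]] = {}
    n_frag = 0
    unverifiable: list[int] = []
    for i, assay in enumerate(lib.assays):
        win_idx = scheme.windows_containing(assay.precursor_mz)
        if not win_idx:
            unverifiable.append(i)
            continue
        windows = [scheme.windows[w] for w in win_idx]
        hits = [
            j
            for j, frag in enumerate(assay.fragments)
            if any(start <= frag.mz < end for start, end in windows)
        ]
        if hits:
            conflict_index[i] = hits
            n_frag += len(hits)
    return ConflictStats(
        n_conflict_precursors=len(conflict_index),
        n_conflict_fragments=n_frag,
        conflict_index=conflict_index,
        n_unverifiable_precursors=len(unverifiable),
        unverifiable_indices=unverifiable,
    )


# ---------------------------------------------------------------------------

def assess(
    lib: SpectralLibrary,
    scheme: Optional[SwathScheme] = None,
    proteome: Optional[ProteomeIndex] = None,
    params: AssessParams = AssessParams(),
) -> AssessmentReport:
    """Evaluate all 62 compliance criteria for a library.

    The SWATH scheme and proteome index are optional; criteria that need
    them degrade to ``not_evaluated``.  The result is deterministic for
    fixed inputs.
    """
    if not lib.assays:
        raise ValueError("cannot assess an empty library")
    values: dict[str, Optional[float]] = {}
    status: dict[str, str] = {}

    values.update(complexity_stats(lib))
    ch = characteristics_stats(lib, params.digest_params)
    for k, v in ch.items():
        values[k] = v
        if v is None:
            status[k] = NOT_EVALUATED
    values.update(modification_stats(lib))

    if proteome is not None:
        values.update(completeness_stats(lib, proteome))
    else:
        for cid, cat, _l, _u in CRITERIA:
            if cat == "completeness":
                values[cid] = None
                status[cid] = NOT_EVALUATED

    td = classify_target_decoy(lib, proteome, params.decoy_prefixes)
    values["co_pct_target"] = td.pct_target
    values["co_pct_decoy"] = td.pct_decoy
    values["co_pct_mixed"] = td.pct_mixed

    dm = delta_mass_stats(lib, params)
    values["co_avg_precursor_delta"] = dm.avg_precursor_delta
    values["co_avg_fragment_delta"] = dm.avg_fragment_delta
    if dm.avg_precursor_delta is None:
        status["co_avg_precursor_delta"] = NOT_EVALUATED
    if dm.avg_fragment_delta is None:
        status["co_avg_fragment_delta"] = NOT_EVALUATED
    values["co_n_mass_error_assays"] = dm.n_mass_error_assays
    values["co_n_unverifiable_assays"] = dm.n_unverifiable
    values["co_n_problem_assays"] = dm.n_problem_assays

    fit = rt_correlation_fit(lib)
    values["co_rt_n_pairs"] = fit.n_pairs
    values["co_rt_slope"] = fit.slope
    values["co_rt_intercept"] = fit.intercept
    values["co_rt_r_squared"] = fit.r_squared
    if fit.r_squared is None:
        for cid in ("co_rt_slope", "co_rt_intercept", "co_rt_r_squared"):
            status[cid] = NOT_EVALUATED

    conflicts: Optional[ConflictStats] = None
    if scheme is not None:
        conflicts = detect_conflicts(lib, scheme)
        values["co_n_conflict_precursors"] = conflicts.n_conflict_precursors
        values["co_n_conflict_fragments"] = conflicts.n_conflict_fragments
        # precursors outside every window cannot be verified for this
        # criterion and join the problem-assay roll-up (each assay once)
        already = set(dm.error_assay_indices) | set(dm.unverifiable_assay_indices)
        extra_unverifiable = sum(
            1 for i in conflicts.unverifiable_indices if i not in already
        )
        values["co_n_unverifiable_assays"] = dm.n_unverifiable + extra_unverifiable
        values["co_n_problem_assays"] = dm.n_problem_assays + extra_unverifiable
    else:
        for cid in ("co_n_conflict_precursors", "co_n_conflict_fragments"):
            values[cid] = None
            status[cid] = NOT_EVALUATED

    criteria = [
        CriterionResult(
            id=cid,
            category=cat,
            label=label,
            value=values.get(cid),
            unit=unit,
            status=status.get(cid, EVALUATED),
        )
        for cid, cat, label, unit in CRITERIA
    ]
    charge_hist = {z: 0 for z in (1, 2, 3, 4, 5)}
    for a in lib.assays:
        charge_hist[min(a.precursor_charge, 5)] += 1
    return AssessmentReport(
        criteria=criteria,
        library_dialect=lib.dialect,
        n_assays=len(lib.assays),
        scheme_provided=scheme is not None,
        proteome_provided=proteome is not None,
        details={
            "charge_hist": charge_hist,
            "frags_per_precursor": [len(a.fragments) for a in lib.assays],
            "fragment_deltas": dm.fragment_deltas,
            "rt_pairs": fit.pairs,
            "delta_mass": dm,
            "rt_fit": fit,
            "conflicts": conflicts,
            "target_decoy": td,
        },
    )
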