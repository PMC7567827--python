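"""Synthetic proteomes, SWATH schemes and defect-injected libraries.

The generator emulates a consensus tryptic library built with theoretical
fragment m/z: fully tryptic peptides at 2+ and 3+, carbamidomethylated
cysteines, top-6 b/y fragments per precursor and one iRT per peptide shared
across charge states.  On top of that clean baseline, each defect class
seen in practice can be injected independently:

* a constant q3 m/z offset (libraries built from observed masses),
* decoy assays left over from the DDA search,
* DIA-bin conflict fragments,
* replicate redundancy (non-consensus "raw" libraries).

Every generator is a pure function of its configuration: a fixed seed
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import masses
from .digest import digest
from .model import (
    Assay,
    DigestParams,
    Fragment,
    ProteomeIndex,
    SpectralLibrary,
    SwathScheme,
)

#: Kyte-Doolittle hydropathy, used as an iRT proxy (only cross-charge
#: equality of the assigned value matters for the RT-fit diagnostic).
_KD = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic library generator."""

    seed: int = 0
    n_proteins: int = 30
    protein_length: tuple[int, int] = (150, 400)
    peptides_per_protein: int = 10
    charge_states: tuple[int, ...] = (2, 3)
    fragments_per_precursor: int = 6
    irt_range: tuple[float, float] = (-50.0, 100.0)
    fragment_mz_range: tuple[float, float] = (200.0, 1800.0)
    peptide_length: tuple[int, int] = (7, 25)
    max_assays: Optional[int] = None
    digest_params: DigestParams = field(
        default_factory=lambda: DigestParams(missed_cleavages=0, min_length=7, max_length=25)
    )


def generate_proteome(cfg: SimulationConfig) -> list[tuple[str, str]]:
    """Random protein records as (accession, sequence) pairs.

    Residues are drawn uniformly from the 20 standard amino acids, which
    yields K/R at ~10% and hence realistic tryptic peptide lengths.
    """
    if cfg.n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = cfg.protein_length
    if not 1 <= lo <= hi:
        raise ValueError(f"degenerate protein length range {cfg.protein_length}")
    rng = np.random.default_rng(cfg.seed)
    records = []
    for i in range(cfg.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(_RESIDUES[j] for j in rng.integers(0, 20, size=length))
        records.append((f"sp|P{i:05d}|SYN{i}", seq))
    return records


def index_records(
    records: list[tuple[str, str]], params: DigestParams = DigestParams()
) -> ProteomeIndex:
    """Build a ProteomeIndex directly from in-memory records."""
    peptide_map: dict[str, set[str]] = {}
    accession_class = {}
    for acc, seq in records:
        accession_class[acc] = "decoy" if acc.startswith("DECOY_") else "target"
        for pep in digest(seq, params):
            peptide_map.setdefault(pep, set()).add(acc)
    return ProteomeIndex(peptide_map, accession_class, params)


def _peptide_irt(peptide: str, irt_range: tuple[float, float]) -> float:
    """Hydropathy-proxy iRT, identical across charge states of a peptide."""
    h = sum(_KD[aa] for aa in peptide) / len(peptide)
    lo, hi = irt_range
    return lo + (h + 4.5) / 9.0 * (hi - lo)


def _modified(peptide: str) -> masses.ModifiedPeptide:
    """Apply the fixed carbamidomethyl modification to every cysteine."""
    mods = {
        i: masses.CARBAMIDOMETHYL for i, aa in enumerate(peptide) if aa == "C"
    }
    return masses.ModifiedPeptide(peptide, mods)


def generate_library(
    cfg: SimulationConfig, records: list[tuple[str, str]]
) -> SpectralLibrary:
    """A clean consensus-style library over a (synthetic) proteome.

    All precursor and fragment m/z are theoretical monoisotopic values, so
    the assessment reports zero average delta mass; iRT is shared across
    the 2+/3+ charge states of a peptide, so the RT fit is exact.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    # peptide -> accessions over the whole proteome (for protein_ids)
    index = index_records(records, cfg.digest_params)
    assays: list[Assay] = []
    lo_mz, hi_mz = cfg.fragment_mz_range
    for acc, seq in records:
        peptides = [
            p
            for p in dict.fromkeys(digest(seq, cfg.digest_params))
            if cfg.peptide_length[0] <= len(p) <= cfg.peptide_length[1]
        ]
        for peptide in peptides[: cfg.peptides_per_protein]:
            pep = _modified(peptide)
            modseq = masses.canonical_notation(pep)
            irt = _peptide_irt(peptide, cfg.irt_range)
            n = len(peptide)
            candidates = [
                (series, ordinal)
                for series in ("y", "b")
                for ordinal in range(2 if series == "b" else 1, n)
            ]
            ions = [
                (s, o, masses.fragment_mz(pep, s, o, 1))
                for s, o in candidates
            ]
            ions = [(s, o, mz) for s, o, mz in ions if lo_mz <= mz <= hi_mz]
            if not ions:
                continue
            order = rng.permutation(len(ions))
            chosen = [ions[j] for j in order[: cfg.fragments_per_precursor]]
            intensities = [
                10000.0 * (0.7**k) * float(rng.uniform(0.9, 1.1))
                for k in range(len(chosen))
            ]
            proteins = sorted(index.proteins_for(peptide)) or [acc]
            for charge in cfg.charge_states:
                if cfg.max_assays is not None and len(assays) >= cfg.max_assays:
                    break
                assays.append(
                    Assay(
                        stripped_sequence=peptide,
                        modified_sequence=modseq,
                        precursor_charge=charge,
                        precursor_mz=masses.precursor_mz(pep, charge),
                        rt=irt,
                        protein_ids=list(proteins),
                        fragments=[
                            Fragment(mz, inten, series=s, ordinal=o, charge=1)
                            for (s, o, mz), inten in zip(chosen, intensities)
                        ],
                    )
                )
    if not assays:
        raise ValueError("proteome too small for the requested library")
    if cfg.max_assays is not None:
        assays = assays[: cfg.max_assays]
    return SpectralLibrary(assays, dialect=None)


def perturb_fragment_mz(lib: SpectralLibrary, delta: float) -> SpectralLibrary:
    """Add a constant offset (Da) to every fragment m/z; precursors untouched."""
    out = lib.copy()
    for assay in out.assays:
        for frag in assay.fragments:
            frag.mz += delta
    return out


def inject_decoys(
    lib: SpectralLibrary,
    fraction: float,
    proteome: Optional[ProteomeIndex] = None,
    seed: int = 0,
) -> SpectralLibrary:
    """Append decoy assays built from shuffled peptide sequences.

    ``round(fraction * n_assays)`` source assays are sampled; each decoy
    shuffles the source peptide's internal residues (keeping the tryptic
    C-terminal residue) and is re-drawn until the sequence is absent from
    the proteome index, then rebuilt with theoretical masses under a
    DECOY_-prefixed accession.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    n_new = round(fraction * len(lib.assays))
    out = lib.copy()
    if n_new == 0:
        return out
    rng = np.random.default_rng(seed)
    source_idx = rng.choice(len(lib.assays), size=n_new, replace=False)
    for i in sorted(int(j) for j in source_idx):
        src = lib.assays[i]
        seq = src.stripped_sequence
        decoy_seq = seq
        for _ in range(100):
            body = list(seq[:-1])
            rng.shuffle(body)
            decoy_seq = "".join(body) + seq[-1]
            if decoy_seq != seq and (
                proteome is None or decoy_seq not in proteome.peptide_map
            ):
                break
        pep = _modified(decoy_seq)
        out.assays.append(
            Assay(
                stripped_sequence=decoy_seq,
                modified_sequence=masses.canonical_notation(pep),
                precursor_charge=src.precursor_charge,
                precursor_mz=masses.precursor_mz(pep, src.precursor_charge),
                rt=src.rt,
                protein_ids=[f"DECOY_{p}" for p in src.protein_ids],
                fragments=[
                    Fragment(
                        masses.fragment_mz(pep, f.series, f.ordinal, f.charge),
                        f.intensity,
                        series=f.series,
                        ordinal=f.ordinal,
                        charge=f.charge,
                    )
                    for f in src.fragments
                    if f.series in ("b", "y") and f.ordinal
                ],
            )
        )
    return out


def inject_conflicts(
    lib: SpectralLibrary,
    scheme: SwathScheme,
    fraction: float,
    seed: int = 0,
) -> SpectralLibrary:
    """Rewrite one fragment per selected assay into its precursor's DIA bin.

    Applied to a conflict-free library, the conflict detector recovers
    exactly the altered assays.  Assays whose precursor lies outside every
    window are never selected.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    out = lib.copy()
    eligible = [
        i
        for i, a in enumerate(out.assays)
        if scheme.windows_containing(a.precursor_mz)
    ]
    k = round(fraction * len(out.assays))
    k = min(k, len(eligible))
    if k == 0:
        return out
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=k, replace=False)
    for j in sorted(int(c) for c in chosen):
        assay = out.assays[eligible[j]]
        widx = scheme.windows_containing(assay.precursor_mz)[0]
        start, end = scheme.windows[widx]
        frag = assay.fragments[0]
        frag.mz = (start + end) / 2.0
        frag.series = None  # no longer a theoretical b/y ion
        frag.ordinal = None
    return out


def make_redundant(
    lib: SpectralLibrary, factor: int, seed: int = 0, jitter: float = 0.05
) -> SpectralLibrary:
    """Duplicate every assay ``factor`` times with intensity jitter,
    emulating a raw (non-consensus) library of replicate observations."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return lib.copy()
    rng = np.random.default_rng(seed)
    assays: list[Assay] = []
    for assay in lib.assays:
        for _ in range(factor):
            dup = assay.copy()
            for frag in dup.fragments:
                frag.intensity *= float(rng.uniform(1 - jitter, 1 + jitter))
            assays.append(dup)
    return SpectralLibrary(assays, dialect=lib.dialect)


def generate_swath_scheme(
    n_windows: int,
    mz_start: float,
    mz_end: float,
    overlap: float = 1.0,
    variable: bool = False,
    seed: int = 0,
) -> SwathScheme:
    """An acquisition scheme of ``n_windows`` isolation windows covering
    [mz_start, mz_end], consecutive windows overlapping by ``overlap`` Th.

    Widths are equal by default; with ``variable`` they are drawn from a
    Dirichlet profile seeded deterministically (every width > overlap).
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if not mz_start < mz_end:
        raise ValueError("mz_start must be < mz_end")
    span = mz_end - mz_start
    total = span + (n_windows - 1) * overlap  # sum of window widths
    if n_windows > 1 and total <= n_windows * overlap:
        raise ValueError("overlap too large for the requested window count")
    if variable and n_windows > 1:
        rng = np.random.default_rng(seed)
        extra = (total - n_windows * overlap) * rng.dirichlet(
            np.full(n_windows, 5.0)
        )
        widths = overlap + extra
    else:
        widths = np.full(n_windows, total / n_windows)
    windows = []
    start = mz_start
    for w in widths:
        windows.append((float(start), float(start + w)))
        start += w - overlap
    # pin the final edge against accumulated float error
    last_start, _ = windows[-1]
    windows[-1] = (last_start, float(mz_end))
    return SwathScheme(windows)
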