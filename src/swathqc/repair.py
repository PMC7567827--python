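"""Library repair: mass correction, conflict filtering and hygiene ops.

The canonical repair sequence mirrors DIA practice: rewrite fragment m/z to
their theoretical values, then split the library into a *clean* part (used
for DIA extraction) and a *problem* part (conflict assays kept for
inspection).  All edits and removals are recorded in a change log so the
repair is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import masses
from .assess import (
    AssessParams,
    classify_target_decoy,
    detect_conflicts,
    theoretical_fragment_mz,
)
from .model import Assay, Fragment, ProteomeIndex, SpectralLibrary, SwathScheme


@dataclass
class ChangeRecord:
    assay_index: int
    precursor: str
    action: str  # edited | removed | kept | skipped
    reason: str


@dataclass
class RepairOutcome:
    """Result of a filtering repair: clean + problem partition of the input."""

    clean_library: SpectralLibrary
    problem_library: SpectralLibrary
    change_log: list[ChangeRecord] = field(default_factory=list)


def _assay_id(assay: Assay) -> str:
    return f"{assay.modified_sequence}/{assay.precursor_charge}"


def correct_masses(
    lib: SpectralLibrary,
    scope: str = "fragments",
    params: AssessParams = AssessParams(),
    change_log: Optional[list[ChangeRecord]] = None,
) -> SpectralLibrary:
    """Rewrite m/z values to their theoretical monoisotopic values.

    ``scope`` is ``"fragments"`` (default), ``"precursors"`` or ``"both"``.
    Assays whose sequence cannot be parsed, and fragments that cannot be
    matched to a theoretical b/y ion, pass through unchanged and are
    logged.  The operation is idempotent.
    """
    if scope not in ("fragments", "precursors", "both"):
        raise ValueError(f"unknown scope {scope!r}")
    out = lib.copy()
    log = change_log if change_log is not None else []
    for i, assay in enumerate(out.assays):
        try:
            pep = masses.parse_modified_sequence(assay.modified_sequence)
            theo_prec = masses.precursor_mz(pep, assay.precursor_charge)
        except ValueError as exc:
            log.append(ChangeRecord(i, _assay_id(assay), "skipped", f"unverifiable: {exc}"))
            continue
        edited = False
        if scope in ("precursors", "both") and assay.precursor_mz != theo_prec:
            assay.precursor_mz = theo_prec
            edited = True
        if scope in ("fragments", "both"):
            for frag in assay.fragments:
                theo = theoretical_fragment_mz(
                    pep, frag, params.annotate_tol, params.annotate_charge_max
                )
                if theo is None:
                    log.append(
                        ChangeRecord(
                            i, _assay_id(assay), "kept",
                            f"fragment {frag.mz:.4f} not matched to a b/y ion",
                        )
                    )
                    continue
                if frag.series is None:
                    # persist the annotation so a re-run recomputes the
                    # same theoretical value (idempotence)
                    hit = masses.annotate_fragment(
                        frag.mz, pep, params.annotate_charge_max, params.annotate_tol
                    )
                    if hit is not None:
                        frag.series, frag.ordinal, frag.charge = hit
                if frag.mz != theo:
                    frag.mz = theo
                    edited = True
        if edited:
            log.append(ChangeRecord(i, _assay_id(assay), "edited", "m/z set to theoretical"))
    return out


def filter_conflicts(
    lib: SpectralLibrary,
    scheme: SwathScheme,
    drop_fragments_only: bool = False,
) -> RepairOutcome:
    """Partition a library into clean and problem (conflict) parts.

    By default whole assays with at least one conflict fragment move to the
    problem library.  With ``drop_fragments_only`` the offending fragments
    are removed instead and only assays left with no fragments move.
    """
    stats = detect_conflicts(lib, scheme)
    clean: list[Assay] = []
    problem: list[Assay] = []
    log: list[ChangeRecord] = []
    for i, assay in enumerate(lib.assays):
        hits = stats.conflict_index.get(i)
        if not hits:
            clean.append(assay.copy())
            continue
        if drop_fragments_only:
            kept = [f for j, f in enumerate(assay.fragments) if j not in set(hits)]
            if kept:
                trimmed = assay.copy()
                trimmed.fragments = [f for j, f in enumerate(trimmed.fragments)
                                     if j not in set(hits)]
                clean.append(trimmed)
                log.append(
                    ChangeRecord(i, _assay_id(assay), "edited",
                                 f"removed {len(hits)} conflict fragment(s)")
                )
                continue
        problem.append(assay.copy())
        log.append(
            ChangeRecord(i, _assay_id(assay), "removed",
                         f"{len(hits)} fragment(s) in the precursor's DIA bin")
        )
    return RepairOutcome(
        clean_library=SpectralLibrary(clean, dialect=lib.dialect),
        problem_library=SpectralLibrary(problem, dialect=lib.dialect),
        change_log=log,
    )


def limit_top_n_fragments(lib: SpectralLibrary, n: int) -> SpectralLibrary:
    """Keep the n most intense fragments per assay (ties: lower m/z wins)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = lib.copy()
    for assay in out.assays:
        if len(assay.fragments) > n:
            assay.fragments = sorted(
                assay.fragments, key=lambda f: (-f.intensity, f.mz)
            )[:n]
    return out


def remove_decoys(
    lib: SpectralLibrary,
    proteome: Optional[ProteomeIndex] = None,
    change_log: Optional[list[ChangeRecord]] = None,
) -> SpectralLibrary:
    """Drop decoy-classed assays; mixed assays are retained and logged."""
    td = classify_target_decoy(lib, proteome)
    log = change_log if change_log is not None else []
    kept: list[Assay] = []
    for i, (assay, cls) in enumerate(zip(lib.assays, td.classes)):
        if cls == "decoy":
            log.append(ChangeRecord(i, _assay_id(assay), "removed", "decoy assay"))
            continue
        if cls == "mixed":
            log.append(
                ChangeRecord(i, _assay_id(assay), "kept", "maps to both target and decoy")
            )
        kept.append(assay.copy())
    return SpectralLibrary(kept, dialect=lib.dialect)


def merge_redundant(lib: SpectralLibrary, n_top: int = 6) -> SpectralLibrary:
    """Collapse replicate occurrences of each precursor into one assay.

    Fragment intensities are summed over occurrences by fragment identity
    (series, ordinal, charge, loss); the merged assay then keeps its
    ``n_top`` most intense fragments.  Precursor-level fields come from the
    first occurrence.
    """
    merged: dict[tuple[str, int], Assay] = {}
    order: list[tuple[str, int]] = []
    for assay in lib.assays:
        key = assay.precursor_key
        if key not in merged:
            merged[key] = assay.copy()
            order.append(key)
            continue
        target = merged[key]
        by_key = {f.key(): f for f in target.fragments}
        for frag in assay.fragments:
            fk = frag.key()
            if fk in by_key and fk[1] is not None:
                by_key[fk].intensity += frag.intensity
            else:
                new = Fragment(frag.mz, frag.intensity, frag.series,
                               frag.ordinal, frag.charge, frag.loss)
                target.fragments.append(new)
                by_key[fk] = new
    out = SpectralLibrary([merged[k] for k in order], dialect=lib.dialect)
    return limit_top_n_fragments(out, n_top)


def shift_rt(lib: SpectralLibrary, offset: float) -> SpectralLibrary:
    """Add a constant to every assay's retention time (e.g. to make iRT
    values positive before import into tools that reject negatives)."""
    out = lib.copy()
    for assay in out.assays:
        if assay.rt is not None:
            assay.rt += offset
    return out
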