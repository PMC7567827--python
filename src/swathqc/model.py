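"""Core in-memory containers for spectral assay libraries.

A spectral (assay) library is a table of *transitions*: each row pairs a
precursor ion (modified peptide + charge, "q1") with one of its fragment
ions ("q3").  In memory we group transitions under their precursor into
:class:`Assay` records, the library's atomic unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Accession prefixes recognised as decoy markers (case-sensitive).
DEFAULT_DECOY_PREFIXES = ("DECOY_", "decoy_", "rev_", "reverse_")


@dataclass
class Fragment:
    """One fragment (q3) ion of an assay.

    ``series``/``ordinal``/``charge`` describe the ion annotation when the
    source dialect provides one (e.g. y7 at 1+); ``series`` is ``None`` for
    unannotated fragments and may hold vendor labels other than b/y.
    """

    mz: float
    intensity: float
    series: Optional[str] = None
    ordinal: Optional[int] = None
    charge: int = 1
    loss: Optional[str] = None

    def key(self) -> tuple:
        """Identity key used when merging replicate observations."""
        return (self.series, self.ordinal, self.charge, self.loss)


@dataclass
class Assay:
    """One precursor ion together with its selected fragment ions."""

    stripped_sequence: str
    modified_sequence: str
    precursor_charge: int
    precursor_mz: float
    rt: Optional[float]
    protein_ids: list[str]
    fragments: list[Fragment]
    is_decoy_annotated: Optional[bool] = None
    extra: dict = field(default_factory=dict)

    @property
    def precursor_key(self) -> tuple[str, int]:
        return (self.modified_sequence, self.precursor_charge)

    def copy(self) -> "Assay":
        return replace(
            self,
            protein_ids=list(self.protein_ids),
            fragments=[replace(f) for f in self.fragments],
            extra=dict(self.extra),
        )


@dataclass
class RejectedRow:
    """A source row that could not be parsed into a Fragment/Assay."""

    row_index: int
    reason: str


@dataclass
class SpectralLibrary:
    """Ordered collection of assays plus source-format metadata.

    Duplicate precursors (redundant libraries) are kept as separate
    occurrences; only explicit repair operations merge them.
    """

    assays: list[Assay]
    dialect: Optional[str] = None
    source_columns: Optional[list[str]] = None
    rejected_rows: list[RejectedRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.assays)

    def __iter__(self) -> Iterator[Assay]:
        return iter(self.assays)

    @property
    def n_fragments(self) -> int:
        return sum(len(a.fragments) for a in self.assays)

    def copy(self) -> "SpectralLibrary":
        return SpectralLibrary(
            assays=[a.copy() for a in self.assays],
            dialect=self.dialect,
            source_columns=list(self.source_columns) if self.source_columns else None,
            rejected_rows=list(self.rejected_rows),
        )


class SwathSchemeError(ValueError):
    pass


@dataclass
class SwathScheme:
    """Ordered precursor isolation windows defining the DIA bins.

    Windows are half-open ``[start, end)`` so that acquisition schemes with
    1 Th overlaps do not double-assign boundary m/z values.  Windows may
    overlap; a precursor can therefore sit in more than one bin.
    """

    windows: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.windows:
            raise SwathSchemeError("scheme must contain at least one window")
        for i, (start, end) in enumerate(self.windows):
            if not start < end:
                raise SwathSchemeError(
                    f"window {i}: start {start} must be < end {end}"
                )

    def __len__(self) -> int:
        return len(self.windows)

    def windows_containing(self, mz: float) -> list[int]:
        """Indices of all windows whose [start, end) interval contains mz."""
        return [
            i for i, (start, end) in enumerate(self.windows) if start <= mz < end
        ]


@dataclass(frozen=True)
class DigestParams:
    """In-silico digestion parameters (trypsin by default).

    ``suppress_proline`` keeps the conventional rule that trypsin does not
    cleave K/R-P bonds; switch it off for strict K/R cleavage.
    """

    missed_cleavages: int = 2
    min_length: int = 7
    max_length: int = 50
    suppress_proline: bool = True


@dataclass
class ProteomeIndex:
    """Peptide -> protein map from in-silico digestion of a FASTA proteome.

    ``accession_class`` tags every accession as ``"target"`` or ``"decoy"``
    (decided by accession prefix at build time); ``proteome_size`` counts
    target proteins only.
    """

    peptide_map: dict[str, set[str]]
    accession_class: dict[str, str]
    digest_params: DigestParams

    @property
    def proteome_size(self) -> int:
        return sum(1 for c in self.accession_class.values() if c == "target")

    def proteins_for(self, peptide: str) -> set[str]:
        return self.peptide_map.get(peptide, set())

    def target_proteins_for(self, peptide: str) -> set[str]:
        return {
            acc
            for acc in self.proteins_for(peptide)
            if self.accession_class.get(acc) == "target"
        }
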