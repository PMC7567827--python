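"""In-silico tryptic digestion and digestion-related peptide properties."""

from __future__ import annotations

from typing import Iterable

from .model import DigestParams


def cleavage_sites(sequence: str, suppress_proline: bool = True) -> list[int]:
    """Positions *after which* trypsin cleaves (C-terminal to K/R).

    With ``suppress_proline`` (the convention), K/R followed by P is not
    cleaved.  Returned positions are indices into ``sequence`` such that a
    cut falls between ``pos`` and ``pos + 1``; the C-terminus is excluded.
    """
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR":
            if suppress_proline and sequence[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def digest(sequence: str, params: DigestParams = DigestParams()) -> list[str]:
    """Tryptic peptides of a protein, with up to ``missed_cleavages`` skips.

    Returns peptides within the configured length range, in N->C order
    (duplicates possible when a protein repeats a peptide).
    """
    sites = cleavage_sites(sequence, params.suppress_proline)
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    peptides = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for skip in range(params.missed_cleavages + 1):
            j = i + skip + 1
            if j > n_frag:
                break
            pep = sequence[bounds[i] : bounds[j]]
            if params.min_length <= len(pep) <= params.max_length:
                peptides.append(pep)
    return peptides


def count_missed_cleavages(peptide: str, suppress_proline: bool = True) -> int:
    """Internal uncut K/R sites in a peptide (terminal residue excluded)."""
    return len(cleavage_sites(peptide, suppress_proline))


def has_tryptic_cterm(peptide: str) -> bool:
    """Whether the peptide ends in K or R (canonical tryptic terminus)."""
    return bool(peptide) and peptide[-1] in "KR"


def unique_peptides(sequences: Iterable[str], params: DigestParams) -> set[str]:
    """Union of digests over several protein sequences."""
    out: set[str] = set()
    for seq in sequences:
        out.update(digest(seq, params))
    return out
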