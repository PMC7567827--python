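"""Monoisotopic peptide and fragment mass calculus.

Computes theoretical precursor and b/y fragment m/z for (modified)
peptides, and parses the modified-sequence notations used by the supported
library dialects:

* UniMod accession:      ``PEPTIC(UniMod:4)K``
* bracketed name:        ``PEPTIC[Carbamidomethyl (C)]K``
* bracketed mass delta:  ``PEPTIC[+57.0214]K``
* short vendor labels:   ``PEPTIC[CAM]K``

Only the b and y ion series are generated for theoretical comparison;
fragments carrying any other annotation are classed "other" and excluded
from mass-accuracy averaging.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from pyteomics import mass as _pymass

from .model import STANDARD_RESIDUES

#: Proton mass (Da), CODATA-consistent.
PROTON_MASS = 1.007276466
#: Monoisotopic mass of H2O (Da).
WATER_MASS = 18.010565

#: Monoisotopic residue masses for the 20 standard amino acids.
RESIDUE_MASSES: dict[str, float] = {
    aa: _pymass.std_aa_mass[aa] for aa in sorted(STANDARD_RESIDUES)
}


@dataclass(frozen=True)
class ResidueMassTable:
    """Residue monoisotopic masses plus the water/proton constants."""

    residues: dict[str, float] = field(default_factory=lambda: dict(RESIDUE_MASSES))
    water_mass: float = WATER_MASS
    proton_mass: float = PROTON_MASS


DEFAULT_TABLE = ResidueMassTable()


class SequenceParseError(ValueError):
    """Malformed modified-sequence notation (e.g. unbalanced brackets)."""


class UnknownModificationError(ValueError):
    """Modification label that cannot be resolved to a mass delta."""

    def __init__(self, label: str):
        super().__init__(f"unknown modification label: {label!r}")
        self.label = label


class UnknownResidueError(ValueError):
    """Residue outside the 20 standard amino acids (B, Z, X, U, ...)."""

    def __init__(self, residue: str):
        super().__init__(f"unknown residue: {residue!r}")
        self.residue = residue


class IncompatibleSiteError(ValueError):
    """Known modification placed on a residue it cannot occur on."""


@dataclass(frozen=True)
class Modification:
    """A post-translational modification as a mass delta on a site."""

    name: str
    delta_mass: float
    site: Optional[str] = None  # residue letter, or None = any site
    unimod_id: Optional[int] = None
    fixed: bool = False


CARBAMIDOMETHYL = Modification("Carbamidomethyl", 57.021464, "C", unimod_id=4, fixed=True)
OXIDATION = Modification("Oxidation", 15.994915, "M", unimod_id=35)

#: Built-in modifications, keyed by canonical name.
KNOWN_MODIFICATIONS: dict[str, Modification] = {
    m.name: m for m in (CARBAMIDOMETHYL, OXIDATION)
}

#: Case-insensitive label aliases -> canonical modification name.
_MOD_ALIASES: dict[str, str] = {
    "carbamidomethyl": "Carbamidomethyl",
    "carbamidomethyl (c)": "Carbamidomethyl",
    "cam": "Carbamidomethyl",
    "unimod:4": "Carbamidomethyl",
    "oxidation": "Oxidation",
    "oxidation (m)": "Oxidation",
    "oxi": "Oxidation",
    "ox": "Oxidation",
    "unimod:35": "Oxidation",
}

#: Tolerance for resolving a bracketed mass delta to a known modification.
DELTA_MATCH_TOL = 0.001


@dataclass
class ModifiedPeptide:
    """A stripped sequence with per-position modifications.

    ``mods`` maps 0-based residue position -> Modification.  Terminal
    modifications are stored separately (positions are residue sites only).
    """

    stripped_sequence: str
    mods: dict[int, Modification] = field(default_factory=dict)
    n_term: Optional[Modification] = None
    c_term: Optional[Modification] = None

    def __len__(self) -> int:
        return len(self.stripped_sequence)

    @property
    def modifications(self) -> list[Modification]:
        out = list(self.mods.values())
        if self.n_term:
            out.append(self.n_term)
        if self.c_term:
            out.append(self.c_term)
        return out


def _resolve_label(label: str, residue: Optional[str]) -> Modification:
    """Resolve a modification label (name, UniMod id or mass delta)."""
    text = label.strip()
    # numeric delta, e.g. "+57.0214" or "-17.0265"
    if re.fullmatch(r"[+-]?\d+(\.\d+)?", text):
        delta = float(text)
        for mod in KNOWN_MODIFICATIONS.values():
            if abs(mod.delta_mass - delta) <= DELTA_MATCH_TOL:
                return mod
        return Modification(f"Delta:{delta:+.4f}", delta, residue)
    canonical = _MOD_ALIASES.get(text.lower())
    if canonical is not None:
        return KNOWN_MODIFICATIONS[canonical]
    raise UnknownModificationError(label)


def parse_modified_sequence(text: str, dialect: Optional[str] = None) -> ModifiedPeptide:
    """Parse a modified-sequence string into a normalized ModifiedPeptide.

    Handles all supported notation dialects in one pass; the ``dialect``
    hint is accepted for symmetry with the readers but is not required,
    since the notations are unambiguous.  Raises
    :class:`SequenceParseError` on malformed text,
    :class:`UnknownModificationError` on unresolvable labels and
    :class:`IncompatibleSiteError` when a known site-specific modification
    sits on the wrong residue.
    """
    s = text.strip().strip("_")  # Spectronaut wraps sequences in underscores
    if not s:
        raise SequenceParseError("empty sequence")
    residues: list[str] = []
    mods: dict[int, Modification] = {}
    n_term: Optional[Modification] = None
    i = 0
    while i < len(s):
        ch = s[i]
        if ch in "([":
            closer = ")" if ch == "(" else "]"
            j = s.find(closer, i + 1)
            if j < 0:
                raise SequenceParseError(f"unbalanced {ch!r} in {text!r}")
            label = s[i + 1 : j]
            if not residues:
                mod = _resolve_label(label, None)
                n_term = mod
            else:
                pos = len(residues) - 1
                residue = residues[pos]
                mod = _resolve_label(label, residue)
                if mod.site is not None and mod.site != residue:
                    raise IncompatibleSiteError(
                        f"{mod.name} expects {mod.site}, found on {residue} "
                        f"at position {pos + 1} of {text!r}"
                    )
                mods[pos] = mod
            i = j + 1
        elif ch in ")]":
            raise SequenceParseError(f"unbalanced {ch!r} in {text!r}")
        elif ch.isalpha():
            residues.append(ch.upper())
            i += 1
        elif ch in ".-":  # terminal separators in some vendor notations
            i += 1
        else:
            raise SequenceParseError(f"unexpected character {ch!r} in {text!r}")
    if not residues:
        raise SequenceParseError(f"no residues in {text!r}")
    return ModifiedPeptide("".join(residues), mods, n_term=n_term)


def to_notation(pep: ModifiedPeptide, dialect: str) -> str:
    """Render a ModifiedPeptide in a dialect's modification notation."""

    def token(mod: Modification) -> str:
        if dialect == "openswath":
            if mod.unimod_id is not None:
                return f"(UniMod:{mod.unimod_id})"
            return f"[{mod.delta_mass:+.4f}]"
        if dialect == "peakview":
            short = {"Carbamidomethyl": "CAM", "Oxidation": "Oxi"}.get(mod.name)
            return f"[{short}]" if short else f"[{mod.delta_mass:+.4f}]"
        # spectronaut bracket-name form
        if mod.site is not None and mod.unimod_id is not None:
            return f"[{mod.name} ({mod.site})]"
        return f"[{mod.delta_mass:+.4f}]"

    parts: list[str] = []
    if pep.n_term is not None:
        parts.append(token(pep.n_term))
    for i, aa in enumerate(pep.stripped_sequence):
        parts.append(aa)
        if i in pep.mods:
            parts.append(token(pep.mods[i]))
    body = "".join(parts)
    if dialect == "spectronaut":
        return f"_{body}_"
    return body


def canonical_notation(pep: ModifiedPeptide) -> str:
    """Dialect-independent normal form (UniMod-style) used as assay identity."""
    return to_notation(pep, "openswath")


def _residue_masses(pep: ModifiedPeptide, table: ResidueMassTable) -> list[float]:
    """Per-position residue mass including its modification delta."""
    out = []
    for i, aa in enumerate(pep.stripped_sequence):
        try:
            m = table.residues[aa]
        except KeyError:
            raise UnknownResidueError(aa) from None
        mod = pep.mods.get(i)
        if mod is not None:
            m += mod.delta_mass
        out.append(m)
    return out


def peptide_neutral_mass(pep: ModifiedPeptide, table: ResidueMassTable = DEFAULT_TABLE) -> float:
    """Monoisotopic neutral mass: residue sum + water + terminal mods."""
    mass = sum(_residue_masses(pep, table)) + table.water_mass
    if pep.n_term is not None:
        mass += pep.n_term.delta_mass
    if pep.c_term is not None:
        mass += pep.c_term.delta_mass
    return mass


def precursor_mz(
    pep: ModifiedPeptide, charge: int, table: ResidueMassTable = DEFAULT_TABLE
) -> float:
    """m/z of [M + zH]z+."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (peptide_neutral_mass(pep, table) + charge * table.proton_mass) / charge


def fragment_mz(
    pep: ModifiedPeptide,
    series: str,
    ordinal: int,
    charge: int = 1,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> float:
    """Theoretical m/z of a b- or y-series fragment ion.

    b_i carries the first ``i`` residues; y_i the last ``i`` residues plus
    water.  Terminal modifications ride with their terminus.
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    n = len(pep)
    if not 1 <= ordinal <= n - 1 and not (series == "y" and ordinal == n):
        raise ValueError(f"ordinal {ordinal} out of range for length-{n} peptide")
    masses = _residue_masses(pep, table)
    if series == "b":
        neutral = sum(masses[:ordinal])
        if pep.n_term is not None:
            neutral += pep.n_term.delta_mass
    elif series == "y":
        neutral = sum(masses[n - ordinal :]) + table.water_mass
        if pep.c_term is not None:
            neutral += pep.c_term.delta_mass
        if ordinal == n and pep.n_term is not None:
            neutral += pep.n_term.delta_mass
    else:
        raise ValueError(f"unsupported ion series {series!r}")
    return (neutral + charge * table.proton_mass) / charge


def theoretical_ions(
    pep: ModifiedPeptide,
    charge_max: int = 1,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> list[tuple[str, int, int, float]]:
    """All theoretical b/y ions as (series, ordinal, charge, mz) tuples."""
    out = []
    n = len(pep)
    for series in ("b", "y"):
        for ordinal in range(1, n):
            for z in range(1, charge_max + 1):
                out.append((series, ordinal, z, fragment_mz(pep, series, ordinal, z, table)))
    return out


def annotate_fragment(
    obs_mz: float,
    pep: ModifiedPeptide,
    charge_max: int = 2,
    tol: float = 0.05,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> Optional[tuple[str, int, int]]:
    """Nearest theoretical b/y ion within ``tol`` Da of an observed m/z.

    Ties are broken by smaller absolute error, then y over b, then lower
    charge.  Returns None when nothing matches.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    best = None
    best_rank = None
    for series, ordinal, z, mz in theoretical_ions(pep, charge_max, table):
        err = abs(obs_mz - mz)
        if err > tol:
            continue
        rank = (err, 0 if series == "y" else 1, z)
        if best_rank is None or rank < best_rank:
            best_rank = rank
            best = (series, ordinal, z)
    return best
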