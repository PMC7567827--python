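"""Reading and writing spectral libraries, SWATH schemes and proteomes.

Three tab-separated transition-list dialects are supported, identified by
required-column fingerprints:

* ``openswath``    — PrecursorMz / ProductMz / transition_group_id
* ``peakview``     — Q1 / Q3 / prec_z / frg_type
* ``spectronaut``  — PrecursorMz / FragmentMz / ModifiedPeptide
  (Prosit generic text exports are Spectronaut-compatible and read as this
  dialect)

Rows that cannot be parsed (blank or non-numeric m/z) are collected on the
returned library as rejected rows, never silently dropped, so that
``input rows == stored fragments + rejected rows`` always holds.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional

import pandas as pd
from pyteomics import fasta as _pyfasta

from . import masses
from .digest import digest
from .model import (
    Assay,
    DEFAULT_DECOY_PREFIXES,
    DigestParams,
    Fragment,
    ProteomeIndex,
    RejectedRow,
    SpectralLibrary,
    SwathScheme,
    SwathSchemeError,
)

DIALECTS = ("openswath", "peakview", "spectronaut")

#: Required-column fingerprints, checked in order.
_FINGERPRINTS: dict[str, set[str]] = {
    "peakview": {"Q1", "Q3", "prec_z", "frg_type"},
    "openswath": {"PrecursorMz", "ProductMz", "transition_group_id"},
    "spectronaut": {"PrecursorMz", "FragmentMz", "ModifiedPeptide"},
}

_TRUTHY = {"1", "true", "yes", "decoy"}
_FALSY = {"0", "false", "no", "", "nan", "target"}


class UnknownFormatError(ValueError):
    pass


class LibraryFormatError(ValueError):
    pass


class EmptyLibraryError(ValueError):
    pass


def detect_dialect(path: str | Path) -> str:
    """Identify a library file's dialect from its header line."""
    with open(path) as fh:
        header = fh.readline()
    columns = set(h.strip() for h in header.rstrip("\n").split("\t"))
    for dialect in ("peakview", "openswath", "spectronaut"):
        if _FINGERPRINTS[dialect] <= columns:
            return dialect
    missing = {
        d: sorted(_FINGERPRINTS[d] - columns) for d in _FINGERPRINTS
    }
    raise UnknownFormatError(
        "header matches no supported dialect; missing columns per dialect: "
        + "; ".join(f"{d}: {m}" for d, m in missing.items())
    )


def _split_proteins(text: str) -> list[str]:
    if not text or text.lower() == "nan":
        return []
    if ";" in text:
        return [p.strip() for p in text.split(";") if p.strip()]
    m = re.match(r"^(\d+)/(.+)$", text)
    if m:  # OpenSWATH n/acc1/acc2 convention
        return [p for p in m.group(2).split("/") if p]
    return [text.strip()]


def _parse_decoy(value) -> Optional[bool]:
    if value is None:
        return None
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    return None


def _parse_annotation(text: str) -> tuple[Optional[str], Optional[int], int]:
    """Parse an OpenSWATH-style fragment annotation like ``y7``/``y7^2``."""
    m = re.match(r"^([aby])(\d+)(?:\^(\d+))?", str(text).strip())
    if not m:
        return None, None, 1
    return m.group(1), int(m.group(2)), int(m.group(3) or 1)


def _norm_series(value) -> tuple[Optional[str], Optional[str]]:
    """Normalize a frg_type cell -> (series, neutral-loss label)."""
    s = str(value).strip()
    if not s or s.lower() == "nan":
        return None, None
    loss = None
    if "-" in s:
        s, loss = s.split("-", 1)
    s = s.lower()
    return (s if s else None), loss


def _canonicalize(raw_modseq: str, stripped: str) -> tuple[str, str]:
    """Return (canonical modified sequence, stripped sequence).

    Falls back to the raw text when the notation cannot be parsed; the
    assessment layer re-parses and classifies such assays as unverifiable.
    """
    try:
        pep = masses.parse_modified_sequence(raw_modseq)
    except ValueError:
        return raw_modseq, stripped or raw_modseq
    return masses.canonical_notation(pep), pep.stripped_sequence


# ---------------------------------------------------------------------------
# per-dialect column descriptions

def _col(row, frame_columns, *names):
    for n in names:
        if n in frame_columns:
            return row[n]
    return None


def read_library(path: str | Path, dialect: Optional[str] = None) -> SpectralLibrary:
    """Read a transition-list TSV into a :class:`SpectralLibrary`.

    One assay is produced per contiguous run of rows sharing the same
    precursor identity (transition group id where the dialect has one,
    otherwise modified sequence x charge), so replicate occurrences in
    redundant libraries stay separate.
    """
    if dialect is None:
        dialect = detect_dialect(path)
    if dialect not in DIALECTS:
        raise UnknownFormatError(f"unsupported dialect {dialect!r}")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = _FINGERPRINTS[dialect] - set(frame.columns)
    if missing:
        raise LibraryFormatError(
            f"{dialect} library missing required columns: {sorted(missing)}"
        )
    if frame.empty:
        raise EmptyLibraryError(f"no transition rows in {path}")
    cols = set(frame.columns)

    if dialect == "openswath":
        group_cols = ["transition_group_id"]
        prec_mz_c, frag_mz_c = "PrecursorMz", "ProductMz"
    elif dialect == "peakview":
        group_cols = ["modification_sequence", "prec_z"]
        prec_mz_c, frag_mz_c = "Q1", "Q3"
    else:
        group_cols = ["ModifiedPeptide", "PrecursorCharge"]
        prec_mz_c, frag_mz_c = "PrecursorMz", "FragmentMz"

    key = frame[group_cols].agg("\x00".join, axis=1)
    block = (key != key.shift()).cumsum()

    assays: list[Assay] = []
    rejected: list[RejectedRow] = []
    for _, sub in frame.groupby(block, sort=False):
        first = sub.iloc[0]
        if dialect == "openswath":
            raw_modseq = _col(first, cols, "FullUniModPeptideName", "PeptideSequence") or ""
            stripped = str(_col(first, cols, "PeptideSequence") or "")
            charge_txt = _col(first, cols, "PrecursorCharge")
            rt_txt = _col(first, cols, "Tr_recalibrated", "RetentionTime")
            prot_txt = str(_col(first, cols, "ProteinName") or "")
        elif dialect == "peakview":
            raw_modseq = str(first["modification_sequence"])
            stripped = str(_col(first, cols, "stripped_sequence") or "")
            charge_txt = first["prec_z"]
            rt_txt = _col(first, cols, "iRT", "RT_detected")
            prot_txt = str(
                _col(first, cols, "uniprot_id", "protein_name") or ""
            )
        else:
            raw_modseq = str(first["ModifiedPeptide"])
            stripped = str(_col(first, cols, "StrippedPeptide") or "")
            charge_txt = _col(first, cols, "PrecursorCharge")
            rt_txt = _col(first, cols, "iRT", "RT")
            prot_txt = str(_col(first, cols, "ProteinGroups", "UniprotId") or "")

        prec_mz = pd.to_numeric(first[prec_mz_c], errors="coerce")
        charge = pd.to_numeric(charge_txt, errors="coerce")
        if pd.isna(prec_mz) or pd.isna(charge) or int(charge) < 1:
            for ridx in sub.index:
                rejected.append(RejectedRow(int(ridx), "unparseable precursor m/z or charge"))
            continue
        rt = pd.to_numeric(rt_txt, errors="coerce") if rt_txt is not None else None
        rt = None if rt is None or pd.isna(rt) else float(rt)
        modseq, stripped = _canonicalize(raw_modseq, stripped)

        fragments: list[Fragment] = []
        for ridx, row in sub.iterrows():
            fmz = pd.to_numeric(row[frag_mz_c], errors="coerce")
            if pd.isna(fmz) or fmz <= 0:
                rejected.append(RejectedRow(int(ridx), "unparseable fragment m/z"))
                continue
            if dialect == "openswath":
                ftype = _col(row, cols, "FragmentType")
                if ftype is not None and str(ftype).strip():
                    series, loss = _norm_series(ftype)
                    ordinal = pd.to_numeric(
                        _col(row, cols, "FragmentSeriesNumber"), errors="coerce"
                    )
                    fz = pd.to_numeric(_col(row, cols, "FragmentCharge"), errors="coerce")
                    ordinal = None if pd.isna(ordinal) else int(ordinal)
                    fz = 1 if pd.isna(fz) else int(fz)
                else:
                    ann = _col(row, cols, "Annotation")
                    series, ordinal, fz = (
                        _parse_annotation(ann) if ann is not None else (None, None, 1)
                    )
                    loss = None
                inten = pd.to_numeric(_col(row, cols, "LibraryIntensity"), errors="coerce")
            elif dialect == "peakview":
                series, loss = _norm_series(row["frg_type"])
                ordinal = pd.to_numeric(_col(row, cols, "frg_nr"), errors="coerce")
                ordinal = None if pd.isna(ordinal) else int(ordinal)
                fz = pd.to_numeric(_col(row, cols, "frg_z"), errors="coerce")
                fz = 1 if pd.isna(fz) else int(fz)
                inten = pd.to_numeric(
                    _col(row, cols, "relative_intensity"), errors="coerce"
                )
            else:
                series, loss = _norm_series(_col(row, cols, "FragmentType"))
                ordinal = pd.to_numeric(_col(row, cols, "FragmentNumber"), errors="coerce")
                ordinal = None if pd.isna(ordinal) else int(ordinal)
                fz = pd.to_numeric(_col(row, cols, "FragmentCharge"), errors="coerce")
                fz = 1 if pd.isna(fz) else int(fz)
                inten = pd.to_numeric(
                    _col(row, cols, "RelativeIntensity", "RelativeFragmentIntensity"),
                    errors="coerce",
                )
            fragments.append(
                Fragment(
                    mz=float(fmz),
                    intensity=0.0 if pd.isna(inten) else float(inten),
                    series=series,
                    ordinal=ordinal,
                    charge=max(int(fz), 1),
                    loss=loss,
                )
            )
        if not fragments:
            continue
        assays.append(
            Assay(
                stripped_sequence=stripped,
                modified_sequence=modseq,
                precursor_charge=int(charge),
                precursor_mz=float(prec_mz),
                rt=rt,
                protein_ids=_split_proteins(prot_txt),
                fragments=fragments,
                is_decoy_annotated=_parse_decoy(_col(first, cols, "decoy")),
            )
        )
    if not assays:
        raise EmptyLibraryError(f"no parseable assays in {path}")
    return SpectralLibrary(
        assays=assays,
        dialect=dialect,
        source_columns=list(frame.columns),
        rejected_rows=rejected,
    )


def _render_modseq(assay: Assay, dialect: str) -> str:
    try:
        pep = masses.parse_modified_sequence(assay.modified_sequence)
    except ValueError:
        return assay.modified_sequence
    return masses.to_notation(pep, dialect)


def write_library(lib: SpectralLibrary, path: str | Path, dialect: str) -> None:
    """Write a library as a TSV in the given dialect's column order.

    m/z values keep six decimal places; the decoy column is emitted only
    when at least one assay carries a decoy annotation.
    """
    if dialect not in DIALECTS:
        raise UnknownFormatError(f"unsupported dialect {dialect!r}")
    with_decoy = any(a.is_decoy_annotated is not None for a in lib.assays)
    rows: list[dict] = []
    for idx, assay in enumerate(lib.assays):
        modseq = _render_modseq(assay, dialect)
        proteins = ";".join(assay.protein_ids)
        rt = "" if assay.rt is None else f"{assay.rt:.4f}"
        decoy_val = "" if assay.is_decoy_annotated is None else int(assay.is_decoy_annotated)
        for frag in assay.fragments:
            series = frag.series or ""
            if frag.loss:
                series = f"{series}-{frag.loss}"
            common = dict(
                _prec=f"{assay.precursor_mz:.6f}",
                _frag=f"{frag.mz:.6f}",
                _int=f"{frag.intensity:.4f}",
            )
            if dialect == "openswath":
                row = {
                    "PrecursorMz": common["_prec"],
                    "ProductMz": common["_frag"],
                    "LibraryIntensity": common["_int"],
                    "Tr_recalibrated": rt,
                    "transition_group_id": f"{idx}_{modseq}_{assay.precursor_charge}",
                    "PeptideSequence": assay.stripped_sequence,
                    "FullUniModPeptideName": modseq,
                    "PrecursorCharge": assay.precursor_charge,
                    "ProteinName": proteins,
                    "FragmentType": series,
                    "FragmentCharge": frag.charge if frag.series else "",
                    "FragmentSeriesNumber": frag.ordinal if frag.ordinal else "",
                }
            elif dialect == "peakview":
                row = {
                    "Q1": common["_prec"],
                    "Q3": common["_frag"],
                    "RT_detected": rt,
                    "protein_name": proteins,
                    "relative_intensity": common["_int"],
                    "stripped_sequence": assay.stripped_sequence,
                    "modification_sequence": modseq,
                    "prec_z": assay.precursor_charge,
                    "frg_type": series,
                    "frg_z": frag.charge,
                    "frg_nr": frag.ordinal if frag.ordinal else "",
                    "iRT": rt,
                    "uniprot_id": proteins,
                }
            else:
                row = {
                    "PrecursorMz": common["_prec"],
                    "FragmentMz": common["_frag"],
                    "iRT": rt,
                    "ModifiedPeptide": modseq,
                    "StrippedPeptide": assay.stripped_sequence,
                    "PrecursorCharge": assay.precursor_charge,
                    "FragmentType": series,
                    "FragmentNumber": frag.ordinal if frag.ordinal else "",
                    "FragmentCharge": frag.charge,
                    "RelativeIntensity": common["_int"],
                    "ProteinGroups": proteins,
                }
            if with_decoy:
                row["decoy"] = decoy_val
            rows.append(row)
    if rows:
        frame = pd.DataFrame(rows)
    else:  # header-only file for an empty library
        header = {
            "openswath": [
                "PrecursorMz", "ProductMz", "LibraryIntensity", "Tr_recalibrated",
                "transition_group_id", "PeptideSequence", "FullUniModPeptideName",
                "PrecursorCharge", "ProteinName", "FragmentType", "FragmentCharge",
                "FragmentSeriesNumber",
            ],
            "peakview": [
                "Q1", "Q3", "RT_detected", "protein_name", "relative_intensity",
                "stripped_sequence", "modification_sequence", "prec_z", "frg_type",
                "frg_z", "frg_nr", "iRT", "uniprot_id",
            ],
            "spectronaut": [
                "PrecursorMz", "FragmentMz", "iRT", "ModifiedPeptide",
                "StrippedPeptide", "PrecursorCharge", "FragmentType",
                "FragmentNumber", "FragmentCharge", "RelativeIntensity",
                "ProteinGroups",
            ],
        }[dialect]
        frame = pd.DataFrame(columns=header)
    frame.to_csv(path, sep="\t", index=False)


def read_swath_scheme(path: str | Path) -> SwathScheme:
    """Read a SWATH definition file (one ``start end`` m/z pair per line)."""
    windows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.replace(",", "\t").split()
            if not parts:
                continue
            try:
                start, end = float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                if lineno == 1 and not windows:
                    continue  # optional header line
                raise SwathSchemeError(
                    f"line {lineno}: expected two numeric columns, got {line!r}"
                ) from None
            if start >= end:
                raise SwathSchemeError(
                    f"line {lineno}: window start {start} must be < end {end}"
                )
            windows.append((start, end))
    if not windows:
        raise SwathSchemeError(f"no isolation windows found in {path}")
    return SwathScheme(windows)


def write_swath_scheme(scheme: SwathScheme, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("start_mz\tend_mz\n")
        for start, end in scheme.windows:
            fh.write(f"{start:.4f}\t{end:.4f}\n")


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    """Write (accession-or-header, sequence) records as FASTA."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def build_proteome_index(
    fasta_path: str | Path,
    digest_params: DigestParams = DigestParams(),
    decoy_prefixes: tuple[str, ...] = DEFAULT_DECOY_PREFIXES,
) -> ProteomeIndex:
    """Digest a FASTA proteome into a peptide -> protein-accession map.

    Accessions are the first whitespace-delimited token of each header and
    carry a target/decoy class decided by prefix.  I and L are treated as
    distinct residues throughout.
    """
    peptide_map: dict[str, set[str]] = {}
    accession_class: dict[str, str] = {}
    with open(fasta_path) as fh:
        for header, sequence in _pyfasta.read(fh):
            accession = header.split()[0]
            cls = (
                "decoy"
                if any(accession.startswith(p) for p in decoy_prefixes)
                else "target"
            )
            accession_class[accession] = cls
            for pep in digest(sequence.upper(), digest_params):
                peptide_map.setdefault(pep, set()).add(accession)
    if not accession_class:
        raise ValueError(f"no protein records in {fasta_path}")
    return ProteomeIndex(
        peptide_map=peptide_map,
        accession_class=accession_class,
        digest_params=digest_params,
    )
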