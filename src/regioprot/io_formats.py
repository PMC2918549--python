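"""Readers and writers for every file dialect the pipeline touches.

Dialects (all UTF-8, text only):

* **PSM CSV** -- RFC-4180 comma-separated with the mandatory header
  :data:`PSM_HEADER`.  Modifications are serialized ``pos:Name`` joined by
  ``;`` (empty string = unmodified); candidate accessions are
  semicolon-separated.
* **FASTA** -- standard; the accession is the first whitespace-delimited
  token of the header line.
* **Annotation TSV** -- columns ``accession`` and ``localization``
  (semicolon-separated compartment labels, order-preserving; empty means
  undetermined, stored as ``ND``).
* **GMT** -- tab-separated ``name<TAB>description<TAB>member...``.
* **Protein summary TSV** -- one row per protein with per-region peptide
  counts, the layout used to re-count a published identification table
  (see :func:`read_protein_summary`).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from regioprot.errors import FormatError, ValidationError

# 20 standard one-letter residue codes
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

# variable modification -> residue it may sit on
VALID_MODIFICATIONS: Mapping[str, str] = {
    "Oxidation": "M",
    "Carbamidomethyl": "C",
    "Propionamide": "C",
}

MIN_SLICE = 1
MAX_SLICE = 24

PSM_HEADER = [
    "region",
    "replicate_id",
    "slice_index",
    "spectrum_id",
    "peptide_sequence",
    "modifications",
    "charge",
    "precursor_mz",
    "ion_score",
    "threshold_score",
    "n_b_matched",
    "n_y_matched",
    "candidate_accessions",
]


@dataclass(frozen=True)
class PsmRecord:
    """One candidate peptide identification from one spectrum."""

    region: str
    replicate_id: str
    slice_index: int
    spectrum_id: str
    peptide_sequence: str
    modifications: tuple[tuple[int, str], ...]
    charge: int
    precursor_mz: float
    ion_score: float
    threshold_score: float
    n_b_matched: int
    n_y_matched: int
    candidate_accessions: tuple[str, ...]

    def validate(self) -> None:
        """Raise :class:`ValidationError` on the first violated invariant."""
        if not (MIN_SLICE <= self.slice_index <= MAX_SLICE):
            raise ValidationError(
                f"slice_index {self.slice_index} outside "
                f"{MIN_SLICE}..{MAX_SLICE}"
            )
        if not self.peptide_sequence:
            raise ValidationError("peptide_sequence is empty")
        bad = set(self.peptide_sequence) - STANDARD_RESIDUES
        if bad:
            raise ValidationError(
                f"peptide_sequence contains non-standard residues "
                f"{sorted(bad)}"
            )
        n = len(self.peptide_sequence)
        for pos, name in self.modifications:
            if name not in VALID_MODIFICATIONS:
                raise ValidationError(f"unknown modification {name!r}")
            if not (1 <= pos <= n):
                raise ValidationError(
                    f"modification position {pos} outside peptide of "
                    f"length {n}"
                )
            expected = VALID_MODIFICATIONS[name]
            residue = self.peptide_sequence[pos - 1]
            if residue != expected:
                raise ValidationError(
                    f"{name} requires {expected} but position {pos} "
                    f"is {residue}"
                )
        if self.charge < 1:
            raise ValidationError(f"charge {self.charge} must be positive")
        if self.precursor_mz <= 0:
            raise ValidationError("precursor_mz must be positive")
        if self.ion_score < 0 or self.threshold_score < 0:
            raise ValidationError("scores must be non-negative")
        if self.n_b_matched < 0 or self.n_y_matched < 0:
            raise ValidationError("matched ion counts must be non-negative")
        if not self.candidate_accessions:
            raise ValidationError("candidate_accessions is empty")
        if len(set(self.candidate_accessions)) != len(
            self.candidate_accessions
        ):
            raise ValidationError("candidate_accessions has duplicates")


@dataclass(frozen=True)
class ProteinEntry:
    """A database protein: accession plus amino-acid sequence."""

    accession: str
    sequence: str
    gene_symbol: str | None = None
    localization: tuple[str, ...] | None = None


def parse_modifications(text: str) -> tuple[tuple[int, str], ...]:
    """Parse the ``pos:Name;pos:Name`` serialization ('' = none)."""
    if not text:
        return ()
    mods = []
    for token in text.split(";"):
        pos_str, sep, name = token.partition(":")
        if not sep or not name:
            raise FormatError(f"malformed modification token {token!r}")
        try:
            pos = int(pos_str)
        except ValueError as exc:
            raise FormatError(
                f"malformed modification position {pos_str!r}"
            ) from exc
        mods.append((pos, name))
    return tuple(mods)


def format_modifications(mods: Sequence[tuple[int, str]]) -> str:
    return ";".join(f"{pos}:{name}" for pos, name in mods)


def _parse_int(value: str, column: str, row: int) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise FormatError(
            f"row {row}: column {column!r} is not an integer: {value!r}"
        ) from exc


def _parse_float(value: str, column: str, row: int) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise FormatError(
            f"row {row}: column {column!r} is not a number: {value!r}"
        ) from exc


def read_psm_table(path: str | Path) -> list[PsmRecord]:
    """Read a PSM CSV into validated records, preserving row order.

    Raises :class:`FormatError` naming any missing column and
    :class:`ValidationError` naming the data row (1-based, excluding the
    header) and rule for any invariant violation.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        missing = [col for col in PSM_HEADER if col not in header]
        if missing:
            raise FormatError(
                f"{path}: header is missing column(s) "
                f"{', '.join(repr(c) for c in missing)}"
            )
        if header != PSM_HEADER:
            raise FormatError(
                f"{path}: header must be exactly {','.join(PSM_HEADER)}"
            )
        records: list[PsmRecord] = []
        for row_no, row in enumerate(reader, start=1):
            if len(row) != len(PSM_HEADER):
                raise FormatError(
                    f"{path}: row {row_no} has {len(row)} fields, "
                    f"expected {len(PSM_HEADER)}"
                )
            fields = dict(zip(PSM_HEADER, row))
            record = PsmRecord(
                region=fields["region"],
                replicate_id=fields["replicate_id"],
                slice_index=_parse_int(
                    fields["slice_index"], "slice_index", row_no
                ),
                spectrum_id=fields["spectrum_id"],
                peptide_sequence=fields["peptide_sequence"],
                modifications=parse_modifications(fields["modifications"]),
                charge=_parse_int(fields["charge"], "charge", row_no),
                precursor_mz=_parse_float(
                    fields["precursor_mz"], "precursor_mz", row_no
                ),
                ion_score=_parse_float(
                    fields["ion_score"], "ion_score", row_no
                ),
                threshold_score=_parse_float(
                    fields["threshold_score"], "threshold_score", row_no
                ),
                n_b_matched=_parse_int(
                    fields["n_b_matched"], "n_b_matched", row_no
                ),
                n_y_matched=_parse_int(
                    fields["n_y_matched"], "n_y_matched", row_no
                ),
                candidate_accessions=tuple(
                    acc
                    for acc in fields["candidate_accessions"].split(";")
                    if acc
                ),
            )
            try:
                record.validate()
            except ValidationError as exc:
                raise ValidationError(f"{path}: row {row_no}: {exc}") from exc
            records.append(record)
    return records


def _format_number(value: float) -> str:
    """Canonical numeric formatting: integral floats lose the fraction."""
    if value == int(value):
        return str(int(value))
    return repr(value)


def write_psm_table(records: Iterable[PsmRecord], path: str | Path) -> None:
    """Write records in the canonical PSM CSV dialect (LF line endings)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(PSM_HEADER)
        for rec in records:
            writer.writerow(
                [
                    rec.region,
                    rec.replicate_id,
                    str(rec.slice_index),
                    rec.spectrum_id,
                    rec.peptide_sequence,
                    format_modifications(rec.modifications),
                    str(rec.charge),
                    _format_number(rec.precursor_mz),
                    _format_number(rec.ion_score),
                    _format_number(rec.threshold_score),
                    str(rec.n_b_matched),
                    str(rec.n_y_matched),
                    ";".join(rec.candidate_accessions),
                ]
            )


def read_fasta(path: str | Path) -> list[ProteinEntry]:
    """Read a protein FASTA; accession = first token of the header line.

    Sequences are uppercased with line breaks removed.  Duplicate
    accessions, non-amino-acid characters and empty files are errors.
    """
    path = Path(path)
    entries: list[ProteinEntry] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        accession = record.id
        sequence = str(record.seq).upper()
        if accession in seen:
            raise FormatError(f"{path}: duplicate accession {accession!r}")
        bad = set(sequence) - STANDARD_RESIDUES
        if bad:
            raise ValidationError(
                f"{path}: {accession}: non-amino-acid characters "
                f"{sorted(bad)}"
            )
        if not sequence:
            raise ValidationError(f"{path}: {accession}: empty sequence")
        seen.add(accession)
        entries.append(ProteinEntry(accession=accession, sequence=sequence))
    if not entries:
        raise FormatError(f"{path}: no FASTA records found")
    return entries


def write_fasta(
    entries: Iterable[ProteinEntry], path: str | Path, width: int = 60
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for entry in entries:
            handle.write(f">{entry.accession}\n")
            seq = entry.sequence
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_annotations(path: str | Path) -> dict[str, list[str]]:
    """Read the accession -> compartment-list TSV.

    The listed order is preserved (first label = primary compartment);
    an empty localization field maps to the single label ``ND``.
    """
    path = Path(path)
    mapping: dict[str, list[str]] = {}
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if header[:2] != ["accession", "localization"]:
            raise FormatError(
                f"{path}: header must start with accession<TAB>localization"
            )
        for row_no, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValidationError(
                    f"{path}: row {row_no}: expected 2 fields, got {len(row)}"
                )
            accession = row[0].strip()
            if not accession:
                raise ValidationError(
                    f"{path}: row {row_no}: empty accession"
                )
            labels = [
                label.strip()
                for label in row[1].split(";")
                if label.strip()
            ]
            mapping[accession] = labels if labels else ["ND"]
    return mapping


def write_annotations(
    mapping: Mapping[str, Sequence[str]], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "localization"])
        for accession, labels in mapping.items():
            writer.writerow([accession, ";".join(labels)])


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into ``{set_name: member set}``.

    Member duplicates are collapsed; a line with fewer than three fields
    (i.e. an empty set) is a :class:`FormatError`.
    """
    path = Path(path)
    gene_sets: dict[str, set[str]] = {}
    with path.open(encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            members = {m for m in parts[2:] if m}
            if len(parts) < 3 or not members:
                raise FormatError(
                    f"{path}: line {line_no}: gene set needs a name, "
                    f"description and at least one member"
                )
            gene_sets[parts[0]] = members
    return gene_sets


# ---------------------------------------------------------------------------
# Protein summary table (re-count of a published identification list)

SUMMARY_FIXED_COLUMNS = ["accession", "gene_symbol", "localization"]


def read_protein_summary(path: str | Path):
    """Read a protein-level summary TSV into a pandas DataFrame.

    Layout: ``accession``, ``gene_symbol``, ``localization`` then one
    ``<region>_peptides`` integer column per region (number of peptides
    assigned to that protein in that region; 0 = not detected).  Region
    order follows the column order.  Returns the DataFrame with a
    ``regions`` attribute listing the region names.
    """
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    missing = [c for c in SUMMARY_FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: summary table missing column(s) {missing}"
        )
    region_cols = [c for c in df.columns if c.endswith("_peptides")]
    if not region_cols:
        raise FormatError(f"{path}: no <region>_peptides columns found")
    if df["accession"].duplicated().any():
        dup = df.loc[df["accession"].duplicated(), "accession"].iloc[0]
        raise ValidationError(f"{path}: duplicate accession {dup!r}")
    for col in region_cols:
        if (df[col].fillna(0) < 0).any():
            raise ValidationError(f"{path}: negative count in {col}")
        df[col] = df[col].fillna(0).astype(int)
    df.attrs["regions"] = [c[: -len("_peptides")] for c in region_cols]
    return df
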