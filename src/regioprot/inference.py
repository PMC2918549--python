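"""PSM screening and parsimonious protein inference.

The post-processing chain is: screen PSMs (score above its per-spectrum
significance threshold and more than 3 matched b+y ions), collapse
redundant peptide sequences keeping the best-scoring observation, then
assign every retained peptide to the single candidate protein with the
maximal number of peptide assignments (ties broken by lexicographically
smallest accession).

The protein-level semi-quantitative score is the sum over assigned
peptides of (ion score - threshold score), i.e. the cutoff-subtracted
search-engine score.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from regioprot.errors import ValidationError
from regioprot.io_formats import PsmRecord

IonRule = Literal["total", "per_series"]

#: more than this many matched fragment ions are required to keep a PSM
MIN_MATCHED_IONS = 3


@dataclass
class InferenceResult:
    """Per-(region, replicate) protein inference output."""

    region: str
    replicate_id: str
    assignments: dict[str, list[PsmRecord]] = field(default_factory=dict)
    protein_score: dict[str, float] = field(default_factory=dict)
    single_peptide_flag: dict[str, bool] = field(default_factory=dict)

    @property
    def n_proteins(self) -> int:
        return len(self.assignments)

    @property
    def n_peptides(self) -> int:
        return sum(len(peps) for peps in self.assignments.values())


def _passes_ion_rule(record: PsmRecord, ion_rule: IonRule) -> bool:
    if ion_rule == "total":
        return record.n_b_matched + record.n_y_matched > MIN_MATCHED_IONS
    if ion_rule == "per_series":
        return (
            record.n_b_matched > MIN_MATCHED_IONS
            or record.n_y_matched > MIN_MATCHED_IONS
        )
    raise ValidationError(f"unknown ion rule {ion_rule!r}")


def filter_psms(
    psms: Sequence[PsmRecord], ion_rule: IonRule = "total"
) -> list[PsmRecord]:
    """Keep PSMs whose score strictly exceeds the threshold and whose
    matched-ion count strictly exceeds :data:`MIN_MATCHED_IONS`.

    With ``ion_rule="total"`` (default) the b and y counts are summed;
    with ``"per_series"`` either series alone must exceed the bound.
    Order is preserved.
    """
    return [
        rec
        for rec in psms
        if rec.ion_score > rec.threshold_score
        and _passes_ion_rule(rec, ion_rule)
    ]


def _mod_key(record: PsmRecord) -> tuple[tuple[int, str], ...]:
    return tuple(sorted(record.modifications))


def deduplicate_peptides(psms: Sequence[PsmRecord]) -> list[PsmRecord]:
    """One record per distinct (sequence, modifications) key.

    Keeps the highest ion score; ties keep the earliest record in file
    order.  Output preserves the order of first appearance.
    """
    best: dict[tuple[str, tuple[tuple[int, str], ...]], PsmRecord] = {}
    for rec in psms:
        key = (rec.peptide_sequence, _mod_key(rec))
        kept = best.get(key)
        if kept is None or rec.ion_score > kept.ion_score:
            best[key] = rec
    return list(best.values())


def candidate_counts(unique_peptides: Sequence[PsmRecord]) -> Counter:
    """Number of unique peptides listing each accession as a candidate."""
    counts: Counter = Counter()
    for rec in unique_peptides:
        counts.update(rec.candidate_accessions)
    return counts


def assign_peptides(
    unique_peptides: Sequence[PsmRecord],
    region: str = "",
    replicate_id: str = "",
) -> InferenceResult:
    """Assign each peptide to its maximal-candidate-count protein.

    candidate_count(P) is computed once over the whole unique-peptide
    set; each peptide goes to the candidate maximizing it, ties broken
    by lexicographically smallest accession.  Proteins receiving no
    peptide are absent from the result.
    """
    for rec in unique_peptides:
        if not rec.candidate_accessions:
            raise ValidationError(
                f"peptide {rec.peptide_sequence!r} has no candidate "
                f"accessions"
            )
    counts = candidate_counts(unique_peptides)
    result = InferenceResult(region=region, replicate_id=replicate_id)
    for rec in unique_peptides:
        winner = min(
            rec.candidate_accessions, key=lambda acc: (-counts[acc], acc)
        )
        result.assignments.setdefault(winner, []).append(rec)
    for accession, peptides in result.assignments.items():
        result.protein_score[accession] = sum(
            rec.ion_score - rec.threshold_score for rec in peptides
        )
        result.single_peptide_flag[accession] = len(peptides) == 1
    return result


def infer_region(
    psms: Sequence[PsmRecord],
    ion_rule: IonRule = "total",
    region: str | None = None,
    replicate_id: str | None = None,
) -> InferenceResult:
    """filter -> deduplicate -> assign for one (region, replicate).

    All records must share region and replicate_id; for empty input the
    labels may be supplied explicitly (default empty strings).
    """
    if psms:
        regions = {rec.region for rec in psms}
        replicates = {rec.replicate_id for rec in psms}
        if len(regions) > 1:
            raise ValidationError(
                f"mixed regions in one inference run: {sorted(regions)}"
            )
        if len(replicates) > 1:
            raise ValidationError(
                f"mixed replicates in one inference run: "
                f"{sorted(replicates)}"
            )
        region = regions.pop()
        replicate_id = replicates.pop()
    retained = filter_psms(psms, ion_rule=ion_rule)
    unique = deduplicate_peptides(retained)
    return assign_peptides(
        unique, region=region or "", replicate_id=replicate_id or ""
    )


def write_inference_report(
    result: InferenceResult, path: str | Path
) -> None:
    """TSV report: accession, n_peptides, protein_score,
    single_peptide_flag, assigned peptide list."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write(
            "accession\tn_peptides\tprotein_score\t"
            "single_peptide_flag\tpeptides\n"
        )
        for accession in sorted(result.assignments):
            peptides = result.assignments[accession]
            handle.write(
                "\t".join(
                    [
                        accession,
                        str(len(peptides)),
                        f"{result.protein_score[accession]:.4f}",
                        str(result.single_peptide_flag[accession]).lower(),
                        ";".join(
                            rec.peptide_sequence for rec in peptides
                        ),
                    ]
                )
                + "\n"
            )
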