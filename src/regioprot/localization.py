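"""Subcellular-compartment classification of identified proteins.

Each protein is counted once, under its primary (first-listed)
compartment, mapped onto a fixed eight-way vocabulary; proteins without
an annotation fall into ``ND``.  A fractional mode that splits a protein
evenly across all its listed compartments is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

CATEGORIES = [
    "membrane",
    "cytoplasm",
    "mitochondrion",
    "cytoskeleton",
    "nucleus",
    "extracellular region",
    "other",
    "ND",
]

# common abbreviations seen in annotation tables -> canonical category
_LABEL_ALIASES = {
    "m": "membrane",
    "mem": "membrane",
    "membrane": "membrane",
    "cy": "cytoplasm",
    "cyt": "cytoplasm",
    "cytoplasm": "cytoplasm",
    "mt": "mitochondrion",
    "mito": "mitochondrion",
    "mitochondrion": "mitochondrion",
    "mitochondria": "mitochondrion",
    "cs": "cytoskeleton",
    "csk": "cytoskeleton",
    "cytoskeleton": "cytoskeleton",
    "n": "nucleus",
    "nu": "nucleus",
    "nucleus": "nucleus",
    "ex": "extracellular region",
    "extracellular": "extracellular region",
    "extracellular region": "extracellular region",
    "nd": "ND",
    "other": "other",
}


@dataclass
class LocalizationBreakdown:
    counts: dict[str, int]
    percents: dict[str, float]
    unannotated_count: int
    total: int


def canonical_label(label: str) -> str:
    """Map a raw compartment label onto the canonical vocabulary.

    Unrecognized labels map to ``other``.
    """
    return _LABEL_ALIASES.get(label.strip().lower(), "other")


def classify(
    proteins: Iterable[str],
    annotations: Mapping[str, Sequence[str]],
    fractional: bool = False,
) -> LocalizationBreakdown:
    """Compartment breakdown over a protein set.

    Primary mode (default): each protein contributes 1 to the canonical
    category of its first-listed compartment; unannotated proteins go to
    ``ND``.  Fractional mode splits each protein's unit weight evenly
    over all its listed compartments.  Percentages are count/total*100
    to one decimal.
    """
    protein_list = sorted(set(proteins))
    total = len(protein_list)
    weights: dict[str, float] = {c: 0.0 for c in CATEGORIES}
    unannotated = 0
    for accession in protein_list:
        labels = annotations.get(accession)
        if not labels:
            unannotated += 1
            weights["ND"] += 1.0
            continue
        if fractional:
            share = 1.0 / len(labels)
            for label in labels:
                weights[canonical_label(label)] += share
        else:
            weights[canonical_label(labels[0])] += 1.0

    counts = {c: int(round(w)) for c, w in weights.items()}
    if total:
        percents = {
            c: round(w / total * 100, 1) for c, w in weights.items()
        }
    else:
        percents = {c: 0.0 for c in CATEGORIES}
    return LocalizationBreakdown(
        counts=counts,
        percents=percents,
        unannotated_count=unannotated,
        total=total,
    )


def write_breakdown(
    breakdown: LocalizationBreakdown, path: str | Path
) -> None:
    """TSV: category, count, percent."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("category\tcount\tpercent\n")
        for category in CATEGORIES:
            handle.write(
                f"{category}\t{breakdown.counts[category]}\t"
                f"{breakdown.percents[category]:.1f}\n"
            )
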