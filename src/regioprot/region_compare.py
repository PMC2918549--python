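"""Protein x region landscape: detection calls, region-unique proteins
and cross-region score statistics.

Detection is "any replicate nonzero" by default (a ``min_replicates``
knob tightens it).  A region-unique protein is detected in exactly one
region.  Cross-region statistics are a one-way fixed-effects ANOVA on
replicate scores followed by pairwise two-sample t tests with Bonferroni
multiplication over the comparison family (all region pairs).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from regioprot.errors import ValidationError
from regioprot.inference import InferenceResult

#: the six dissected brain regions, in reporting order
DEFAULT_REGIONS = [
    "thalamus",
    "hippocampus",
    "frontal cortex",
    "parietal cortex",
    "occipital cortex",
    "amygdala",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class RegionMatrix:
    """Adjusted-score tensor: protein x region x replicate (0 = absent)."""

    proteins: list[str]
    regions: list[str]
    replicates: list[str]
    score: np.ndarray  # shape (n_proteins, n_regions, n_replicates)
    peptide_count: np.ndarray  # same shape, integer

    def protein_index(self, accession: str) -> int:
        try:
            return self.proteins.index(accession)
        except ValueError:
            raise KeyError(accession) from None

    def region_scores(self, accession: str) -> dict[str, np.ndarray]:
        """Replicate score vectors per region for one protein."""
        i = self.protein_index(accession)
        return {
            region: self.score[i, j, :].copy()
            for j, region in enumerate(self.regions)
        }


@dataclass
class RegionCallSet:
    """Detection and uniqueness calls derived from a RegionMatrix."""

    detected_per_region: dict[str, set[str]]
    unique_per_region: dict[str, set[str]]
    total_proteins: int
    total_peptides: int


@dataclass
class ScoreComparison:
    """ANOVA + Bonferroni pairwise results for one protein."""

    accession: str
    computable: bool
    reason: str = ""
    anova_f: float = float("nan")
    anova_p: float = float("nan")
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)


def build_matrix(
    results: Sequence[InferenceResult],
    regions: Sequence[str] | None = None,
) -> RegionMatrix:
    """Stack per-(region, replicate) inference results into a matrix.

    Protein order is lexicographic; a protein row exists only if it was
    detected in at least one cell.  Duplicate (region, replicate) pairs
    are an error.
    """
    if not results:
        raise ValidationError("no inference results supplied")
    seen_pairs: set[tuple[str, str]] = set()
    for res in results:
        pair = (res.region, res.replicate_id)
        if pair in seen_pairs:
            raise ValidationError(f"duplicate (region, replicate) {pair}")
        seen_pairs.add(pair)

    if regions is None:
        region_list = sorted({res.region for res in results})
    else:
        region_list = list(regions)
        unknown = {res.region for res in results} - set(region_list)
        if unknown:
            raise ValidationError(
                f"results contain undeclared region(s) {sorted(unknown)}"
            )
    replicate_list = sorted({res.replicate_id for res in results})
    protein_list = sorted(
        {acc for res in results for acc in res.assignments}
    )

    shape = (len(protein_list), len(region_list), len(replicate_list))
    score = np.zeros(shape)
    peptide_count = np.zeros(shape, dtype=int)
    protein_idx = {acc: i for i, acc in enumerate(protein_list)}
    region_idx = {r: j for j, r in enumerate(region_list)}
    replicate_idx = {r: k for k, r in enumerate(replicate_list)}
    for res in results:
        j = region_idx[res.region]
        k = replicate_idx[res.replicate_id]
        for accession, peptides in res.assignments.items():
            i = protein_idx[accession]
            score[i, j, k] = res.protein_score[accession]
            peptide_count[i, j, k] = len(peptides)
    return RegionMatrix(
        proteins=protein_list,
        regions=region_list,
        replicates=replicate_list,
        score=score,
        peptide_count=peptide_count,
    )


def call_regions(
    matrix: RegionMatrix, min_replicates: int = 1
) -> RegionCallSet:
    """Detection and region-unique calls.

    A protein is detected in a region when at least ``min_replicates``
    replicate cells are nonzero; unique when detected in exactly one
    region.  ``total_peptides`` counts assigned peptides with redundancy
    across regions (summed over all cells).
    """
    if min_replicates < 1:
        raise ValidationError("min_replicates must be >= 1")
    detected_per_region: dict[str, set[str]] = {
        r: set() for r in matrix.regions
    }
    nonzero = matrix.score > 0
    n_detected_reps = nonzero.sum(axis=2)  # protein x region
    for i, accession in enumerate(matrix.proteins):
        for j, region in enumerate(matrix.regions):
            if n_detected_reps[i, j] >= min_replicates:
                detected_per_region[region].add(accession)
    unique_per_region: dict[str, set[str]] = {}
    for region in matrix.regions:
        others: set[str] = set()
        for other in matrix.regions:
            if other != region:
                others |= detected_per_region[other]
        unique_per_region[region] = detected_per_region[region] - others
    all_proteins = set().union(*detected_per_region.values())
    return RegionCallSet(
        detected_per_region=detected_per_region,
        unique_per_region=unique_per_region,
        total_proteins=len(all_proteins),
        total_peptides=int(matrix.peptide_count.sum()),
    )


def recount_summary(df) -> RegionCallSet:
    """Re-count a protein-level summary table (see
    :func:`regioprot.io_formats.read_protein_summary`).

    Detection in a region = a positive peptide count in that region's
    column; total peptides are summed with redundancy across regions.
    """
    regions = df.attrs.get("regions")
    if not regions:
        regions = [
            c[: -len("_peptides")]
            for c in df.columns
            if c.endswith("_peptides")
        ]
    detected_per_region: dict[str, set[str]] = {}
    for region in regions:
        col = f"{region}_peptides"
        detected_per_region[region] = set(
            df.loc[df[col] > 0, "accession"]
        )
    unique_per_region: dict[str, set[str]] = {}
    for region in regions:
        others: set[str] = set()
        for other in regions:
            if other != region:
                others |= detected_per_region[other]
        unique_per_region[region] = detected_per_region[region] - others
    all_proteins = set().union(*detected_per_region.values())
    total_peptides = int(
        sum(df[f"{region}_peptides"].sum() for region in regions)
    )
    return RegionCallSet(
        detected_per_region=detected_per_region,
        unique_per_region=unique_per_region,
        total_proteins=len(all_proteins),
        total_peptides=total_peptides,
    )


def _one_way_anova(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Direct sum-of-squares one-way ANOVA.

    Returns (F, p).  Zero between-group variance gives F = 0, p = 1;
    zero within-group variance with nonzero between gives F = inf,
    p = 0.
    """
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand_mean = sum(g.sum() for g in groups) / n_total
    ss_between = sum(
        len(g) * (g.mean() - grand_mean) ** 2 for g in groups
    )
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = k - 1
    df_within = n_total - k
    if ss_between == 0:
        return 0.0, 1.0
    if ss_within == 0:
        return float("inf"), 0.0
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p


def compare_scores(
    matrix: RegionMatrix, accession: str
) -> ScoreComparison:
    """One-way ANOVA across regions plus Bonferroni pairwise t tests.

    Requires >= 2 regions with >= 2 replicates each; otherwise the
    result carries ``computable=False`` and a reason, never a silent
    NaN.  Pairwise p values are raw t-test p times the number of region
    pairs, capped at 1.
    """
    scores = matrix.region_scores(accession)
    groups = {r: v for r, v in scores.items() if len(v) >= 2}
    if len(groups) < 2:
        return ScoreComparison(
            accession=accession,
            computable=False,
            reason="need >= 2 regions with >= 2 replicates",
        )
    region_names = list(groups)
    f_stat, p = _one_way_anova([groups[r] for r in region_names])
    pairs = list(itertools.combinations(region_names, 2))
    n_pairs = len(pairs)
    pairwise: dict[tuple[str, str], float] = {}
    for r1, r2 in pairs:
        g1, g2 = groups[r1], groups[r2]
        if np.all(g1 == g1[0]) and np.all(g2 == g2[0]):
            raw = 1.0 if g1[0] == g2[0] else 0.0
        else:
            raw = float(stats.ttest_ind(g1, g2).pvalue)
        pairwise[(r1, r2)] = min(1.0, raw * n_pairs)
    return ScoreComparison(
        accession=accession,
        computable=True,
        anova_f=f_stat,
        anova_p=p,
        pairwise=pairwise,
    )


def summarize(
    matrix: RegionMatrix,
    callset: RegionCallSet,
    stats_by_protein: Mapping[str, ScoreComparison] | None = None,
):
    """Per-region and per-protein summary tables.

    Returns (region_df, protein_df): region_df has detected/unique
    counts plus the region-abundant total; protein_df has per-region
    mean +/- SE scores and, when supplied, the ANOVA p value and a
    significantly-elevated flag.  Region-abundant = region-unique.
    """
    import pandas as pd

    region_rows = []
    for region in matrix.regions:
        region_rows.append(
            {
                "region": region,
                "n_detected": len(callset.detected_per_region[region]),
                "n_unique": len(callset.unique_per_region[region]),
            }
        )
    region_df = pd.DataFrame(region_rows)
    region_df.attrs["region_abundant_total"] = int(
        region_df["n_unique"].sum()
    )
    region_df.attrs["total_proteins"] = callset.total_proteins
    region_df.attrs["total_peptides"] = callset.total_peptides

    protein_rows = []
    n_reps = len(matrix.replicates)
    for i, accession in enumerate(matrix.proteins):
        row: dict = {"accession": accession}
        for j, region in enumerate(matrix.regions):
            values = matrix.score[i, j, :]
            row[f"{region}_mean"] = float(values.mean())
            row[f"{region}_se"] = (
                float(values.std(ddof=1) / np.sqrt(n_reps))
                if n_reps > 1
                else float("nan")
            )
        if stats_by_protein is not None and accession in stats_by_protein:
            comp = stats_by_protein[accession]
            row["anova_p"] = comp.anova_p if comp.computable else float("nan")
            row["significant"] = bool(
                comp.computable and comp.anova_p < SIGNIFICANCE_LEVEL
            )
        protein_rows.append(row)
    protein_df = pd.DataFrame(protein_rows)
    return region_df, protein_df


def write_matrix_long(matrix: RegionMatrix, path: str | Path) -> None:
    """Long-format TSV: accession, region, replicate, score, n_peptides."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("accession\tregion\treplicate\tscore\tn_peptides\n")
        for i, accession in enumerate(matrix.proteins):
            for j, region in enumerate(matrix.regions):
                for k, replicate in enumerate(matrix.replicates):
                    handle.write(
                        f"{accession}\t{region}\t{replicate}\t"
                        f"{matrix.score[i, j, k]:.4f}\t"
                        f"{matrix.peptide_count[i, j, k]}\n"
                    )


def write_calls(callset: RegionCallSet, path: str | Path) -> None:
    """TSV of per-region detected/unique membership."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("region\taccession\tunique\n")
        for region in callset.detected_per_region:
            unique = callset.unique_per_region[region]
            for accession in sorted(callset.detected_per_region[region]):
                handle.write(
                    f"{region}\t{accession}\t"
                    f"{str(accession in unique).lower()}\n"
                )
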