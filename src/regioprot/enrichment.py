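"""Gene-set over-representation by one-sided Fisher's exact test.

For each gene set S (intersected with the universe U), a query Q in U
and overlap k = |Q & S|, the p value is the upper hypergeometric tail
P[X >= k] with X ~ Hypergeom(|U|, |S|, |Q|).  Optional Benjamini-
Hochberg adjustment (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy import stats

from regioprot.errors import ValidationError


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    p_adj: float | None = None


def fisher_enrichment(
    query: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    adjust: bool = False,
) -> list[EnrichmentRow]:
    """One-sided over-representation test per gene set.

    The query must be a subset of the universe; each gene set is
    intersected with the universe before testing.  Results are sorted
    ascending by p (ties by set name).  ``adjust=True`` adds a
    Benjamini-Hochberg column.
    """
    query_set = set(query)
    universe_set = set(universe)
    if not query_set:
        raise ValidationError("empty query")
    if not universe_set:
        raise ValidationError("empty universe")
    stray = query_set - universe_set
    if stray:
        raise ValidationError(
            f"query contains genes outside the universe: "
            f"{sorted(stray)[:5]}"
        )
    m = len(universe_set)
    n_query = len(query_set)
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe_set
        overlap = len(query_set & in_universe)
        n_set = len(in_universe)
        # P[X >= overlap], X ~ Hypergeom(M=m, n=n_set, N=n_query)
        p = float(stats.hypergeom.sf(overlap - 1, m, n_set, n_query))
        p = min(1.0, max(0.0, p))
        rows.append(
            EnrichmentRow(
                set_name=name,
                overlap=overlap,
                set_size=n_set,
                query_size=n_query,
                universe_size=m,
                p=p,
            )
        )
    rows.sort(key=lambda r: (r.p, r.set_name))
    if adjust and rows:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(
            [r.p for r in rows], method="fdr_bh"
        )
        rows = [
            EnrichmentRow(
                set_name=r.set_name,
                overlap=r.overlap,
                set_size=r.set_size,
                query_size=r.query_size,
                universe_size=r.universe_size,
                p=r.p,
                p_adj=float(q),
            )
            for r, q in zip(rows, p_adj)
        ]
    return rows


def write_enrichment(
    rows: Sequence[EnrichmentRow], path: str | Path
) -> None:
    """TSV: set_name, overlap, set_size, p, p_adj."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("set_name\toverlap\tset_size\tp\tp_adj\n")
        for row in rows:
            p_adj = "" if row.p_adj is None else f"{row.p_adj:.6g}"
            handle.write(
                f"{row.set_name}\t{row.overlap}\t{row.set_size}\t"
                f"{row.p:.6g}\t{p_adj}\n"
            )
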