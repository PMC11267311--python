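"""Fate-alignment statistics across differential-expression comparisons.

Three operators quantify whether two comparisons (e.g. graft PFC-vs-HIP and
host PFC-vs-HIP) regulate the same genes in the same direction:

* :func:`quadrant_analysis` — classify genes by the signs of their log2 fold
  changes in the two comparisons; dominance of quadrants I and III (same
  sign in both) indicates concordant regulation, summarized alongside the
  Pearson correlation of the two fold-change vectors.
* :func:`alignment_score` — the signed sum of log2 fold changes of a
  region-characteristic gene set in a target comparison; a positive sum says
  the graft shifted toward that region's expression program.
* :func:`ora_hypergeometric` — gene-set over-representation by the
  upper-tail hypergeometric test with BH correction across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .deg import bh_adjust

QUADRANTS = ("I", "II", "III", "IV", "axis")


@dataclass
class QuadrantSummary:
    table: pd.DataFrame  # gene, fc_x, fc_y, quadrant
    counts: dict[str, int]
    pearson_r: float

    def genes_in(self, *quadrants: str) -> list[str]:
        mask = self.table["quadrant"].isin(quadrants)
        return self.table.loc[mask, "gene"].tolist()


def comparison_pair(
    deg_x: pd.DataFrame, deg_y: pd.DataFrame, genes: str = "union"
) -> pd.DataFrame:
    """Align two DEG tables on shared genes for quadrant analysis.

    ``genes`` selects which genes enter: "union" (passing in either
    comparison, the default), "intersection" (passing in both) or "all"
    (every shared gene). Tables without a ``passes`` column are treated as
    all-passing.
    """
    if genes not in {"union", "intersection", "all"}:
        raise ValueError("genes must be union, intersection or all")
    x = deg_x.set_index("gene")
    y = deg_y.set_index("gene")
    shared = x.index.intersection(y.index)
    px = x["passes"].reindex(shared) if "passes" in x else pd.Series(True, index=shared)
    py = y["passes"].reindex(shared) if "passes" in y else pd.Series(True, index=shared)
    if genes == "union":
        keep = shared[(px | py).to_numpy()]
    elif genes == "intersection":
        keep = shared[(px & py).to_numpy()]
    else:
        keep = shared
    return pd.DataFrame(
        {
            "gene": keep,
            "fc_x": x.loc[keep, "log2fc"].to_numpy(),
            "fc_y": y.loc[keep, "log2fc"].to_numpy(),
        }
    ).reset_index(drop=True)


def quadrant_analysis(pair: pd.DataFrame, method: str = "pearson") -> QuadrantSummary:
    """Assign each gene a fold-change quadrant and correlate the two axes.

    Quadrants follow the scatterplot convention: I (+,+), II (-,+),
    III (-,-), IV (+,-); genes with either coordinate exactly 0 go to the
    explicit "axis" category rather than being tie-broken into a quadrant.
    """
    fx = np.asarray(pair["fc_x"], dtype=float)
    fy = np.asarray(pair["fc_y"], dtype=float)
    if len(fx) != len(fy):
        raise ValueError("fold-change vectors differ in length")
    if len(fx) < 2:
        raise ValueError("need at least two genes")
    quad = np.where(
        (fx == 0) | (fy == 0),
        "axis",
        np.where(
            fx > 0,
            np.where(fy > 0, "I", "IV"),
            np.where(fy > 0, "II", "III"),
        ),
    )
    if method == "pearson":
        r = scipy.stats.pearsonr(fx, fy).statistic
    elif method == "spearman":
        r = scipy.stats.spearmanr(fx, fy).statistic
    else:
        raise ValueError("method must be pearson or spearman")
    table = pd.DataFrame(
        {"gene": pair["gene"], "fc_x": fx, "fc_y": fy, "quadrant": quad}
    )
    counts = {q: int((quad == q).sum()) for q in QUADRANTS}
    return QuadrantSummary(table=table, counts=counts, pearson_r=float(r))


@dataclass
class AlignmentScore:
    score: float
    sign: str  # "+", "-" or "0"
    n_used: int
    n_missing: int

    @staticmethod
    def _sign(s: float) -> str:
        return "+" if s > 0 else "-" if s < 0 else "0"


def alignment_score(
    gene_set: list[str],
    fold_changes: pd.Series,
    per_gene_mean: bool = False,
) -> AlignmentScore:
    """Signed sum of log2 fold changes over a gene set.

    ``fold_changes`` is indexed by gene (e.g. the log2fc column of a DEG
    table). Genes absent from the comparison are counted as missing.
    ``per_gene_mean`` divides the sum by the number of genes used.
    """
    genes = [g for g in gene_set if g in fold_changes.index]
    if not genes:
        raise ValueError("gene set does not intersect the comparison's genes")
    s = float(fold_changes.loc[genes].sum())
    if per_gene_mean:
        s /= len(genes)
    return AlignmentScore(
        score=s,
        sign=AlignmentScore._sign(s),
        n_used=len(genes),
        n_missing=len(gene_set) - len(genes),
    )


def ora_hypergeometric(
    query: set[str] | list[str],
    collection: dict[str, set[str]],
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """Over-representation of each gene set in the query list.

    With universe size N, query size n, set size K (after intersection with
    the universe) and overlap k, p = P(X >= k) for X hypergeometric. BH
    correction is applied across the collection's sets.
    """
    universe = set(universe)
    query = set(query)
    if not universe or not query:
        raise ValueError("universe and query must be nonempty")
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query genes outside universe, e.g. {extra}")
    N, n = len(universe), len(query)
    rows = []
    for name, genes in collection.items():
        in_universe = set(genes) & universe
        K = len(in_universe)
        k = len(in_universe & query)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {"set": name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out
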