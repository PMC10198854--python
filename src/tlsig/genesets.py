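"""Single-sample gene-set scoring: ssGSEA and marker-mean scores, plus
score-table correlation.

ssGSEA here is the rank-based running-sum enrichment score computed
independently per sample: genes are ranked by expression (average rank for
ties), ordered from highest to lowest, and the enrichment score is the sum of
the gap between the weighted in-set cumulative distribution (weights =
rank^alpha, Barbie-style alpha = 0.25 by default) and the unweighted
out-of-set cumulative distribution. Because only ranks enter, the score is
invariant under any strictly monotone transform of a sample's expression
vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import ExpressionMatrix, GeneSetCollection
from .scoring import ScoreTable, _mean_log2_scores

__all__ = [
    "CorrelationMatrix",
    "ssgsea_score",
    "marker_mean_score",
    "score_correlation",
]


@dataclass
class CorrelationMatrix:
    coefficients: pd.DataFrame  # rows = columns of table_a, cols = of table_b
    p_values: pd.DataFrame
    method: str
    n_shared: int


def _as_sets(gene_sets) -> dict[str, list[str]]:
    if isinstance(gene_sets, GeneSetCollection):
        return gene_sets.sets
    return dict(gene_sets)


def ssgsea_score(
    expr: ExpressionMatrix,
    gene_sets,
    alpha: float = 0.25,
    normalize: bool = False,
) -> ScoreTable:
    """Per-sample ssGSEA enrichment scores.

    ``normalize=True`` divides every set's scores by the max-min ES range
    across samples; it is off by default because it couples samples and
    breaks single-sample semantics.
    """
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    sets = _as_sets(gene_sets)
    values = expr.values
    gene_index = {g: i for i, g in enumerate(values.index)}
    G = len(gene_index)
    masks = {}
    for name, genes in sets.items():
        idx = [gene_index[g] for g in genes if g in gene_index]
        if not idx:
            raise ValidationError(f"gene set {name!r} shares no genes with "
                                  "the expression matrix")
        if len(idx) == G:
            raise ValidationError(
                f"gene set {name!r} covers every expressed gene; the "
                "out-of-set complement is empty"
            )
        mask = np.zeros(G, bool)
        mask[idx] = True
        masks[name] = mask

    mat = values.to_numpy(float)
    out = {name: np.empty(mat.shape[1]) for name in masks}
    for j in range(mat.shape[1]):
        ranks = stats.rankdata(mat[:, j])  # 1..G, average ties
        order = np.argsort(-ranks, kind="mergesort")  # decreasing expression
        r_sorted = ranks[order]
        for name, mask in masks.items():
            m = mask[order]
            w = np.where(m, r_sorted**alpha, 0.0)
            cum_in = np.cumsum(w) / w.sum()
            n_out = G - m.sum()
            cum_out = np.cumsum(~m) / n_out
            out[name][j] = float(np.sum(cum_in - cum_out))

    scores = pd.DataFrame(out, index=values.columns)
    if normalize:
        rng_ = scores.max(axis=0) - scores.min(axis=0)
        rng_ = rng_.replace(0.0, 1.0)
        scores = scores / rng_
    meta = {
        name: {
            "method": "ssgsea",
            "alpha": alpha,
            "normalized": normalize,
            "genes_used": [g for g in sets[name] if g in gene_index],
            "genes_missing": [g for g in sets[name] if g not in gene_index],
        }
        for name in masks
    }
    return ScoreTable(scores, meta)


def marker_mean_score(expr: ExpressionMatrix, gene_sets) -> ScoreTable:
    """Marker-mean score: per sample and set, the arithmetic mean of
    log2(v + 1) over the set's genes present in the matrix. For the 13-gene
    TLS set this is identical to the TLS score (same convention)."""
    return _mean_log2_scores(expr, _as_sets(gene_sets), method="marker_mean")


def score_correlation(
    table_a: ScoreTable | pd.DataFrame,
    table_b: ScoreTable | pd.DataFrame,
    method: str = "spearman",
    min_samples: int = 5,
) -> CorrelationMatrix:
    """Pairwise correlation between two score tables over shared samples.

    Coefficients for pairs with fewer than ``min_samples`` shared samples are
    reported as NaN. P-values use the t approximation.
    """
    if method not in ("spearman", "pearson"):
        raise ValidationError(f"unknown correlation method: {method!r}")
    a = table_a.scores if isinstance(table_a, ScoreTable) else table_a
    b = table_b.scores if isinstance(table_b, ScoreTable) else table_b
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise ValidationError("no shared samples between score tables")
    a, b = a.loc[shared], b.loc[shared]
    n = len(shared)
    coef = pd.DataFrame(np.nan, index=a.columns, columns=b.columns)
    pval = pd.DataFrame(np.nan, index=a.columns, columns=b.columns)
    for ca in a.columns:
        for cb in b.columns:
            if n < min_samples:
                continue
            x, y = a[ca].to_numpy(), b[cb].to_numpy()
            if method == "spearman":
                res = stats.spearmanr(x, y)
            else:
                res = stats.pearsonr(x, y)
            coef.loc[ca, cb] = float(res.statistic)
            pval.loc[ca, cb] = float(res.pvalue)
    return CorrelationMatrix(coef, pval, method=method, n_shared=n)
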