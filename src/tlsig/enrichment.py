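"""Differential expression and over-representation analysis.

Differential expression between two sample groups uses a per-gene Wilcoxon
rank-sum test (Welch t optional) on log2 values; the fold change is the
ratio of linear-scale group means, and a gene is called up/down only when
both |FC| > fc_threshold (default 1.5) and p < p_threshold (default 0.05)
hold.

Over-representation is the hypergeometric upper tail P(X >= k) of the
query/set overlap against a user-supplied universe, BH-corrected across
sets, with the keep rule requiring at least ``min_overlap`` query genes in
the set (default 5) and either FDR < 0.05 ("go" mode) or raw p < 0.05
("pathway" mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import ExpressionMatrix, GeneSetCollection
from .survival import bh_adjust

__all__ = [
    "DEGResult",
    "EnrichmentResult",
    "differential_expression",
    "ora_enrichment",
]

LOG2_FC_15 = float(np.log2(1.5))


@dataclass
class DEGResult:
    """Per-gene differential-expression table.

    ``table`` columns: log2_fc, statistic, p, q, direction (up/down/ns).
    Direction is relative to group A (first group in sorted label order).
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    fc_threshold: float
    p_threshold: float
    test: str

    def genes(self, direction: str) -> list[str]:
        return self.table.index[self.table["direction"] == direction].tolist()

    @property
    def n_pass(self) -> int:
        return int((self.table["direction"] != "ns").sum())


def differential_expression(
    expr: ExpressionMatrix,
    group_labels: pd.Series,
    test: str = "ranksum",
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> DEGResult:
    if test not in ("ranksum", "t"):
        raise ValidationError(f"unknown test: {test!r}")
    if fc_threshold < 1:
        raise ValidationError("fc_threshold must be >= 1")
    labels = pd.Series(group_labels).reindex(expr.values.columns)
    names = sorted(labels.dropna().unique())
    if len(names) != 2:
        raise ValidationError(f"need exactly 2 groups, got {names}")
    mask_a = (labels == names[0]).to_numpy()
    mask_b = (labels == names[1]).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValidationError("each group needs >= 2 samples")

    log2 = expr.to_log2p1().values.to_numpy(float)
    linear = np.power(2.0, log2) - 1.0
    mean_a = linear[:, mask_a].mean(axis=1)
    mean_b = linear[:, mask_b].mean(axis=1)
    # pseudocount keeps the ratio finite for silent genes
    log2_fc = np.log2((mean_a + 1e-9) / (mean_b + 1e-9))

    A = log2[:, mask_a]
    B = log2[:, mask_b]
    pvals = np.ones(log2.shape[0])
    statv = np.zeros(log2.shape[0])
    for i in range(log2.shape[0]):
        if np.ptp(np.concatenate([A[i], B[i]])) == 0:
            continue  # constant gene: p = 1 by convention
        if test == "ranksum":
            res = stats.mannwhitneyu(A[i], B[i], alternative="two-sided",
                                     method="asymptotic")
        else:
            res = stats.ttest_ind(A[i], B[i], equal_var=False)
        statv[i], pvals[i] = float(res.statistic), float(res.pvalue)

    q = bh_adjust(pvals)
    log_thr = np.log2(fc_threshold)
    direction = np.full(log2.shape[0], "ns", dtype=object)
    passing = (np.abs(log2_fc) > log_thr) & (pvals < p_threshold)
    direction[passing & (log2_fc > 0)] = "up"
    direction[passing & (log2_fc < 0)] = "down"
    table = pd.DataFrame(
        {"log2_fc": log2_fc, "statistic": statv, "p": pvals, "q": q,
         "direction": direction},
        index=expr.values.index,
    )
    return DEGResult(table=table, group_a=names[0], group_b=names[1],
                     fc_threshold=fc_threshold, p_threshold=p_threshold,
                     test=test)


@dataclass
class EnrichmentResult:
    """Per-set hypergeometric enrichment table.

    ``table`` columns: k (overlap), K (set size in universe), n (query
    size), N (universe size), p, q, kept, overlap_genes.
    """

    table: pd.DataFrame
    mode: str
    min_overlap: int


def ora_enrichment(
    query_genes,
    universe_genes,
    gene_sets,
    min_overlap: int = 5,
    mode: str = "pathway",
) -> EnrichmentResult:
    """Hypergeometric over-representation of a query list in each gene set.

    Query genes outside the universe are dropped with a warning; sets are
    intersected with the universe. ``kept`` requires k >= min_overlap plus
    q < 0.05 in "go" mode or p < 0.05 in "pathway" mode.
    """
    if mode not in ("go", "pathway"):
        raise ValidationError(f"unknown ORA mode: {mode!r}")
    universe = list(dict.fromkeys(universe_genes))
    if not universe:
        raise ValidationError("empty universe")
    uni = set(universe)
    query = list(dict.fromkeys(query_genes))
    outside = [g for g in query if g not in uni]
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe dropped"
        )
        query = [g for g in query if g in uni]
    sets = gene_sets.sets if isinstance(gene_sets, GeneSetCollection) else dict(gene_sets)

    N = len(universe)
    n = len(query)
    qset = set(query)
    rows = []
    for name, genes in sets.items():
        in_uni = [g for g in genes if g in uni]
        K = len(in_uni)
        overlap = sorted(qset.intersection(in_uni))
        k = len(overlap)
        # upper tail P(X >= k); empty query gives p = 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N, "p": p,
                     "overlap_genes": ",".join(overlap)})
    table = pd.DataFrame(rows).set_index("set")
    table["q"] = bh_adjust(table["p"].to_numpy())
    if mode == "go":
        sig = table["q"] < 0.05
    else:
        sig = table["p"] < 0.05
    table["kept"] = (table["k"] >= min_overlap) & sig
    table = table[["k", "K", "n", "N", "p", "q", "kept", "overlap_genes"]]
    return EnrichmentResult(table=table, mode=mode, min_overlap=min_overlap)
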