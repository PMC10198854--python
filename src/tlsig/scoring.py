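"""TLS signature scoring and quartile stratification.

The TLS score is the geometric mean of the signature chemokines' linear-scale
abundances, computed as the arithmetic mean of log2(v + 1) values and
reported in log2 units (the +1 shift keeps zero TPMs finite). Samples are
stratified by score quartiles: the literal two-class rule (hi = score > Q3)
and the three-class variant (hi > Q3, low < Q1, inter otherwise) are both
available because published TLS-hi/inter/low survival stratifications use the
three-way split while the stated rule is two-way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import TLS_SIGNATURE_GENES
from .errors import ValidationError
from .io import ExpressionMatrix

__all__ = [
    "ScoreTable",
    "StratifiedCohort",
    "TLS_SIGNATURE_GENES",
    "compute_tls_score",
    "stratify_by_quartile",
    "compare_score_by_group",
    "check_signature_coherence",
]


@dataclass
class ScoreTable:
    """Per-sample signature scores (samples x signatures) plus per-signature
    metadata: method, genes_used, genes_missing."""

    scores: pd.DataFrame
    metadata: dict[str, dict]

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValidationError("score table contains non-finite values")

    @property
    def sample_ids(self) -> list[str]:
        return self.scores.index.tolist()

    def series(self, signature: str) -> pd.Series:
        return self.scores[signature]


@dataclass
class StratifiedCohort:
    """Quartile-based class labels with the thresholds that produced them."""

    labels: pd.Series  # sample_id -> class
    q1: float
    q3: float
    mode: str

    @property
    def classes(self) -> list[str]:
        return sorted(self.labels.unique())

    def samples_in(self, cls: str) -> list[str]:
        return self.labels.index[self.labels == cls].tolist()


def _mean_log2_scores(
    expr: ExpressionMatrix,
    gene_sets: dict[str, list[str]],
    method: str,
    min_fraction: float = 0.0,
) -> ScoreTable:
    """Shared kernel: per sample, arithmetic mean of log2(v+1) over the set
    genes present in the matrix."""
    log2 = expr.to_log2p1().values
    cols = {}
    meta = {}
    for name, genes in gene_sets.items():
        present = [g for g in genes if g in log2.index]
        missing = [g for g in genes if g not in log2.index]
        if not present:
            raise ValidationError(f"no genes of signature {name!r} in matrix")
        if len(present) < min_fraction * len(genes):
            raise ValidationError(
                f"signature {name!r}: only {len(present)}/{len(genes)} genes "
                f"present (< {min_fraction:.0%} required)"
            )
        if missing:
            warnings.warn(
                f"signature {name!r}: {len(missing)} genes missing from the "
                f"matrix: {missing}"
            )
        cols[name] = log2.loc[present].mean(axis=0)
        meta[name] = {
            "method": method,
            "genes_used": present,
            "genes_missing": missing,
        }
    return ScoreTable(pd.DataFrame(cols), meta)


def compute_tls_score(
    expr: ExpressionMatrix,
    signature: list[str] | tuple[str, ...] = TLS_SIGNATURE_GENES,
    name: str = "TLS",
    min_fraction: float = 0.7,
) -> ScoreTable:
    """Geometric-mean TLS score per sample, in log2 units.

    Computed as mean(log2(v + 1)) over the signature genes present; errors
    if fewer than ``min_fraction`` of the signature is found.
    """
    return _mean_log2_scores(
        expr, {name: list(signature)}, method="geometric_mean",
        min_fraction=min_fraction,
    )


def stratify_by_quartile(
    scores: pd.Series, mode: str = "three_class"
) -> StratifiedCohort:
    """Assign TLS classes from score quartiles (type-7 / linear
    interpolation).

    ``three_class``: score > Q3 -> TLS-hi, score < Q1 -> TLS-low, otherwise
    TLS-inter. ``two_class_q3`` (the literal published rule): score > Q3 ->
    hi, else low.
    """
    if mode not in ("three_class", "two_class_q3"):
        raise ValidationError(f"unknown stratification mode: {mode!r}")
    scores = pd.Series(scores).astype(float)
    if len(scores) < 4:
        raise ValidationError("need >= 4 scored samples to take quartiles")
    q1 = float(np.quantile(scores, 0.25))  # numpy default = type-7
    q3 = float(np.quantile(scores, 0.75))
    if scores.nunique() == 1:
        warnings.warn("constant scores: all samples fall in one class")
    if mode == "two_class_q3":
        labels = pd.Series(
            np.where(scores > q3, "hi", "low"), index=scores.index
        )
    else:
        labels = pd.Series("TLS-inter", index=scores.index)
        labels[scores > q3] = "TLS-hi"
        labels[scores < q1] = "TLS-low"
    return StratifiedCohort(labels=labels, q1=q1, q3=q3, mode=mode)


def compare_score_by_group(
    scores: pd.Series,
    group_labels: pd.Series,
    test: str = "ranksum",
    sidedness: str = "two-sided",
) -> dict:
    """Two-group score comparison: Wilcoxon rank-sum (exact for small
    tie-free groups, tie-corrected normal approximation otherwise) or Welch
    t-test.

    ``sidedness``: 'two-sided', 'less' or 'greater' (alternative of group A,
    the first group in sorted label order, relative to group B).
    """
    scores = pd.Series(scores).astype(float)
    labels = pd.Series(group_labels).reindex(scores.index)
    names = sorted(labels.dropna().unique())
    if len(names) != 2:
        raise ValidationError(
            f"compare_score_by_group needs exactly 2 groups, got {names}"
        )
    a = scores[labels == names[0]].to_numpy()
    b = scores[labels == names[1]].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("constant pooled scores; p = 1")
        stat, p = 0.0, 1.0
    elif test == "ranksum":
        res = stats.mannwhitneyu(a, b, alternative=sidedness)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "t":
        res = stats.ttest_ind(a, b, equal_var=False, alternative=sidedness)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValidationError(f"unknown test: {test!r}")
    return {
        "groups": names,
        "n": {names[0]: len(a), names[1]: len(b)},
        "medians": {names[0]: float(np.median(a)),
                    names[1]: float(np.median(b))},
        "test": test,
        "sidedness": sidedness,
        "statistic": stat,
        "p_value": p,
    }


def check_signature_coherence(
    expr: ExpressionMatrix, signature: list[str] | tuple[str, ...]
) -> pd.DataFrame:
    """Flag signature genes whose expression opposes the rest of the set.

    For each gene, the Pearson correlation between its log2(v+1) expression
    and the leave-one-out signature score is reported; genes with r < 0 are
    flagged. This reproduces the kind of pruning that removed BCL6 from the
    candidate chemokine list when its expression disagreed with the other
    genes.
    """
    log2 = expr.to_log2p1().values
    present = [g for g in signature if g in log2.index]
    if len(present) < 3:
        raise ValidationError("coherence check needs >= 3 signature genes")
    rows = []
    for g in present:
        others = [x for x in present if x != g]
        loo = log2.loc[others].mean(axis=0)
        v = log2.loc[g]
        r = float(np.corrcoef(v, loo)[0, 1]) if v.std() > 0 else np.nan
        rows.append({"gene": g, "r_leave_one_out": r,
                     "flagged": bool(r < 0) if np.isfinite(r) else True})
    return pd.DataFrame(rows).set_index("gene")
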