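"""Tumor mutational burden and group-wise mutation frequencies from
MAF-like tables.

TMB is the raw count of nonsynonymous mutation records per sample (no
exome-size normalization); per-gene mutation status within a group is
binary — a sample counts as mutated if it carries at least one
nonsynonymous record for the gene — and two-group frequency differences are
tested by Fisher's exact test with BH correction across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import MAFTable, NONSYNONYMOUS_CLASSES
from .scoring import StratifiedCohort
from .survival import bh_adjust

__all__ = [
    "TMBTable",
    "MutationFrequencyTable",
    "compute_tmb",
    "mutation_frequency_by_group",
    "tmb_survival_groups",
]


@dataclass
class TMBTable:
    """Per-sample nonsynonymous mutation counts."""

    counts: pd.Series  # sample_id -> count
    nonsyn_classes: tuple[str, ...]


@dataclass
class MutationFrequencyTable:
    """Per-gene mutation counts/frequencies per group with Fisher tests.

    ``table`` columns (two-group case): count_<g>, size_<g>, freq_<g> per
    group plus fisher_p and q.
    """

    table: pd.DataFrame
    groups: list[str]


def compute_tmb(
    maf: MAFTable,
    cohort_samples,
    nonsyn_classes=NONSYNONYMOUS_CLASSES,
) -> TMBTable:
    """Count nonsynonymous mutations per sample over a cohort roster.

    Roster samples with no MAF records get count 0; duplicate
    (sample, gene, class) records count once.
    """
    roster = list(cohort_samples)
    if not roster:
        raise ValidationError("empty cohort roster")
    if not nonsyn_classes:
        raise ValidationError("nonsyn_classes must be non-empty")
    rec = maf.records.drop_duplicates()
    rec = rec[rec["variant_classification"].isin(set(nonsyn_classes))]
    counts = rec.groupby("sample_id").size()
    counts = counts.reindex(roster, fill_value=0).astype(int)
    counts.name = "tmb"
    return TMBTable(counts=counts, nonsyn_classes=tuple(nonsyn_classes))


def mutation_frequency_by_group(
    maf: MAFTable,
    group_labels: pd.Series,
    nonsyn_classes=NONSYNONYMOUS_CLASSES,
) -> MutationFrequencyTable:
    """Per-gene mutated-sample frequency per group, with a 2x2 Fisher exact
    test when exactly two groups are present."""
    labels = pd.Series(group_labels).dropna()
    names = sorted(labels.unique())
    sizes = labels.value_counts()
    if (sizes.reindex(names).fillna(0) == 0).any():
        raise ValidationError("every group must be non-empty")
    rec = maf.records[
        maf.records["variant_classification"].isin(set(nonsyn_classes))
    ]
    rec = rec[rec["sample_id"].isin(labels.index)]
    # binary status: one hit per (gene, sample)
    status = rec[["gene_id", "sample_id"]].drop_duplicates()
    status["group"] = labels.reindex(status["sample_id"]).to_numpy()
    counts = (
        status.groupby(["gene_id", "group"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=names, fill_value=0)
    out = pd.DataFrame(index=counts.index)
    for g in names:
        size = int(sizes[g])
        out[f"count_{g}"] = counts[g]
        out[f"size_{g}"] = size
        out[f"freq_{g}"] = counts[g] / size
    if len(names) == 2:
        g1, g2 = names
        n1, n2 = int(sizes[g1]), int(sizes[g2])
        pvals = []
        for gene in out.index:
            k1 = int(out.loc[gene, f"count_{g1}"])
            k2 = int(out.loc[gene, f"count_{g2}"])
            _, p = stats.fisher_exact(
                [[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided"
            )
            pvals.append(float(p))
        out["fisher_p"] = pvals
        out["q"] = bh_adjust(np.asarray(pvals))
    return MutationFrequencyTable(table=out, groups=names)


def tmb_survival_groups(
    tmb: TMBTable, split: str = "median"
) -> StratifiedCohort:
    """TMB-high/low (or quartile-class) labels for survival comparison.

    ``median`` split: TMB-high = count strictly greater than the median
    (type-7 quantile), consistent with the score stratification convention.
    ``quartile`` produces high (> Q3) / low (< Q1) / inter.
    """
    if split not in ("median", "quartile"):
        raise ValidationError(f"unknown split: {split!r}")
    counts = tmb.counts.astype(float)
    q1 = float(np.quantile(counts, 0.25))
    q3 = float(np.quantile(counts, 0.75))
    if counts.nunique() == 1:
        warnings.warn("constant TMB: all samples fall in one class")
    if split == "median":
        med = float(np.quantile(counts, 0.5))
        labels = pd.Series(
            np.where(counts > med, "TMB-high", "TMB-low"), index=counts.index
        )
    else:
        labels = pd.Series("TMB-inter", index=counts.index)
        labels[counts > q3] = "TMB-high"
        labels[counts < q1] = "TMB-low"
    return StratifiedCohort(labels=labels, q1=q1, q3=q3, mode=split)
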