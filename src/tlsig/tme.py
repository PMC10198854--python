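"""Multi-parameter tumor-microenvironment classification.

Assembles a panel of per-sample microenvironment parameters (signature
scores, immune/stromal scores, TMB, ...), z-scores each parameter, clusters
samples by complete-linkage hierarchical clustering on Euclidean distance,
and cuts the tree into k classes (k = 5 by default, matching the five
published HNSCC tumor classes). Cluster labels are renumbered by ascending
mean TLS z-score so the highest label is always the TLS-highest class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError
from .io import ClinicalTable
from .mutation import TMBTable
from .scoring import ScoreTable
from .survival import LogRankResult, km_estimate, logrank_test

__all__ = [
    "TMEPanel",
    "ClusterAssignment",
    "build_tme_panel",
    "hierarchical_clusters",
    "characterize_clusters",
    "match_cluster_profiles",
]


@dataclass
class TMEPanel:
    """Z-scored microenvironment parameter matrix (samples x parameters);
    the raw values are retained alongside."""

    z: pd.DataFrame
    raw: pd.DataFrame
    excluded: list[str]

    @property
    def sample_ids(self) -> list[str]:
        return self.z.index.tolist()

    @property
    def parameters(self) -> list[str]:
        return self.z.columns.tolist()


@dataclass
class ClusterAssignment:
    labels: pd.Series  # sample_id -> 1..k
    k: int
    linkage_method: str
    metric: str
    merge_history: pd.DataFrame  # child1, child2, height, size


def build_tme_panel(
    tables,
    tmb: TMBTable | None = None,
    imputation: str = "drop_sample",
    min_shared: float = 0.9,
) -> TMEPanel:
    """Inner-join score tables (and optionally TMB) into one z-scored panel.

    ``tables`` is an iterable of ScoreTables or DataFrames. Constant
    parameters are excluded with a warning. ``imputation``: 'drop_sample'
    removes samples with any missing cell; 'mean' fills with the column mean.
    """
    frames = []
    for t in tables:
        frames.append(t.scores if isinstance(t, ScoreTable) else pd.DataFrame(t))
    if tmb is not None:
        frames.append(tmb.counts.astype(float).rename("TMB").to_frame())
    if not frames:
        raise ValidationError("no input tables")
    union = set()
    shared = None
    for f in frames:
        union |= set(f.index)
        shared = set(f.index) if shared is None else shared & set(f.index)
    if union and len(shared) < min_shared * len(union):
        raise ValidationError(
            f"inputs share only {len(shared)}/{len(union)} samples "
            f"(< {min_shared:.0%} required)"
        )
    raw = pd.concat(frames, axis=1, join="inner")
    if raw.columns.has_duplicates:
        raise ValidationError("duplicate parameter names across input tables")
    if imputation == "drop_sample":
        raw = raw.dropna(axis=0)
    elif imputation == "mean":
        raw = raw.fillna(raw.mean())
    else:
        raise ValidationError(f"unknown imputation policy: {imputation!r}")
    excluded = raw.columns[raw.std(ddof=0) < 1e-12].tolist()
    if excluded:
        warnings.warn(f"constant parameters excluded: {excluded}")
        raw = raw.drop(columns=excluded)
    if raw.shape[1] < 2:
        raise ValidationError("panel needs >= 2 non-constant parameters")
    z = (raw - raw.mean()) / raw.std(ddof=0)
    return TMEPanel(z=z, raw=raw, excluded=excluded)


def hierarchical_clusters(
    panel: TMEPanel | pd.DataFrame,
    k: int = 5,
    linkage_method: str = "complete",
    metric: str = "euclidean",
    order_by: str | None = "TLS",
) -> ClusterAssignment:
    """Complete-linkage hierarchical clustering of panel rows cut at k.

    Labels are renumbered so cluster k has the highest mean of the
    ``order_by`` column (default the TLS score) — stable, interpretable
    numbering across runs. Falls back to ordering by descending cluster size
    when the column is absent.
    """
    z = panel.z if isinstance(panel, TMEPanel) else pd.DataFrame(panel)
    n = len(z)
    if k > n:
        raise ValidationError(f"k = {k} exceeds n = {n}")
    if k < 1:
        raise ValidationError("k must be >= 1")
    Z = linkage(z.to_numpy(float), method=linkage_method, metric=metric)
    raw_labels = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw_labels, index=z.index)
    # renumber for stable interpretation
    groups = sorted(labels.unique())
    if order_by is not None and order_by in z.columns:
        key = {g: z.loc[labels == g, order_by].mean() for g in groups}
        ordered = sorted(groups, key=lambda g: key[g])  # ascending TLS
    else:
        key = {g: (labels == g).sum() for g in groups}
        ordered = sorted(groups, key=lambda g: -key[g])
    remap = {g: i + 1 for i, g in enumerate(ordered)}
    labels = labels.map(remap)
    merge = pd.DataFrame(
        Z, columns=["child1", "child2", "height", "size"]
    )
    return ClusterAssignment(
        labels=labels, k=len(groups), linkage_method=linkage_method,
        metric=metric, merge_history=merge,
    )


def characterize_clusters(
    panel: TMEPanel,
    assignment: ClusterAssignment,
    clinical: ClinicalTable | None = None,
):
    """Per-cluster parameter profile (mean z, n) and, when clinical data is
    supplied, the k-group log-rank test plus KM curves per cluster.

    Returns (profile DataFrame indexed by cluster, LogRankResult | None,
    KMEstimate | None).
    """
    labels = assignment.labels.reindex(panel.z.index)
    if labels.isna().any():
        raise ValidationError("assignment does not cover the panel samples")
    profile = panel.z.groupby(labels).mean()
    profile.index.name = "cluster"
    profile["n"] = labels.value_counts().reindex(profile.index)
    logrank: LogRankResult | None = None
    km = None
    if clinical is not None:
        shared = clinical.data.index.intersection(labels.index)
        if shared.empty:
            raise ValidationError("no samples shared with the clinical table")
        clin = clinical.subset(shared)
        lab = labels.reindex(shared)
        if lab.nunique() > 1:
            logrank = logrank_test(clin, lab)
        km = km_estimate(clin, lab)
    return profile, logrank, km


def match_cluster_profiles(
    profile: pd.DataFrame, archetype_centers: pd.DataFrame
) -> pd.DataFrame:
    """Hungarian matching of recovered cluster profiles to planted archetype
    centers on Pearson profile correlation.

    Returns a frame with cluster, matched archetype, and the correlation of
    the matched pair. Used to validate planted-archetype recovery.
    """
    params = [c for c in profile.columns
              if c != "n" and c in archetype_centers.columns]
    P = profile[params].to_numpy(float)
    A = archetype_centers[params].to_numpy(float)
    corr = np.corrcoef(P, A)[: len(P), len(P):]
    rows_idx, cols_idx = linear_sum_assignment(-corr)
    rows = [
        {
            "cluster": profile.index[i],
            "archetype": archetype_centers.index[j],
            "profile_correlation": float(corr[i, j]),
        }
        for i, j in zip(rows_idx, cols_idx)
    ]
    return pd.DataFrame(rows).set_index("cluster")
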