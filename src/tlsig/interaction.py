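"""Per-gene Cox interaction screen.

For a focal per-sample score F (the TLS score, generalizing the cytotoxic-T
level) and each candidate gene's expression V, fit the linear log-hazard
model

    h = a*F + b*V + d*F*V + c

with Cox proportional-hazards regression. On cohorts where F is protective,
``a`` is negative; the slope of the hazard in F is ``a + d*V``, so a
negative ``d`` means higher expression of the gene strengthens (sharpens)
the protective association — an "enhancer" — while a positive ``d`` weakens
it — a "reducer". The intercept ``c`` is absorbed into the Cox baseline
hazard and is not estimated. F and V are z-standardized before fitting so
``d`` is comparable across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CollinearityError, ValidationError
from .io import ClinicalTable, ExpressionMatrix
from .scoring import ScoreTable
from .survival import bh_adjust, cox_fit

__all__ = [
    "InteractionFit",
    "ScreenResult",
    "fit_interaction_model",
    "screen_genes",
    "modulator_score",
]


@dataclass
class InteractionFit:
    """Coefficients of the three-covariate Cox fit for one gene."""

    gene_id: str
    a: float
    b: float
    d: float
    se_a: float
    se_b: float
    se_d: float
    p_a: float
    p_b: float
    p_d: float
    converged: bool


@dataclass
class ScreenResult:
    """Per-gene interaction fits plus the classification into enhancer
    (d < 0), reducer (d > 0) and null genes.

    ``table`` columns: gene, a, b, d, se_d, p_d, q_d, class, converged.
    """

    table: pd.DataFrame
    p_threshold: float
    fdr_threshold: float
    counts: dict[str, int] = field(default_factory=dict)

    def genes_in(self, cls: str) -> list[str]:
        return self.table.loc[self.table["class"] == cls, "gene"].tolist()


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd < 1e-12:
        raise ValidationError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def fit_interaction_model(
    clinical: ClinicalTable,
    focal_scores: pd.Series,
    gene_expression: pd.Series,
    gene_id: str = "",
) -> InteractionFit:
    """Fit h = a*F + b*V + d*F*V + c for one gene by Cox regression.

    F and V are z-standardized; the product term is formed after
    standardization. Raises :class:`CollinearityError` when V duplicates F.
    """
    samples = clinical.data.index
    F = _zscore(focal_scores.reindex(samples).to_numpy(float))
    V = _zscore(gene_expression.reindex(samples).to_numpy(float))
    design = pd.DataFrame(
        {"F": F, "V": V, "FxV": F * V}, index=samples
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-gene convergence noise
        fit = cox_fit(clinical, design)
    coef = dict(zip(fit.names, fit.beta))
    se = dict(zip(fit.names, fit.se))
    pv = dict(zip(fit.names, fit.p))
    return InteractionFit(
        gene_id=gene_id or str(gene_expression.name),
        a=coef["F"], b=coef["V"], d=coef["FxV"],
        se_a=se["F"], se_b=se["V"], se_d=se["FxV"],
        p_a=pv["F"], p_b=pv["V"], p_d=pv["FxV"],
        converged=fit.converged,
    )


def screen_genes(
    clinical: ClinicalTable,
    focal_scores: pd.Series | ScoreTable,
    expr: ExpressionMatrix,
    p_threshold: float = 0.05,
    fdr_threshold: float = 1.0,
    signature_name: str | None = None,
) -> ScreenResult:
    """Run the interaction model over every gene and classify by the sign
    and significance of d.

    A gene is classified ``enhancer`` (d < 0) or ``reducer`` (d > 0) when its
    raw interaction p-value passes ``p_threshold`` AND its BH-adjusted q
    passes ``fdr_threshold``; otherwise ``null``. The default
    ``fdr_threshold=1.0`` disables the FDR gate, matching raw-p filtering.
    Near-constant genes (SD < 1e-8) are skipped with a warning;
    non-convergent or collinear fits are flagged and excluded from
    classification.
    """
    if not (0 < p_threshold <= 1 and 0 < fdr_threshold <= 1):
        raise ValidationError("thresholds must lie in (0, 1]")
    if isinstance(focal_scores, ScoreTable):
        name = signature_name or focal_scores.scores.columns[0]
        focal_scores = focal_scores.series(name)
    log2 = expr.to_log2p1().values
    rows = []
    skipped = []
    for gene in log2.index:
        v = log2.loc[gene]
        if v.std() < 1e-8:
            skipped.append(gene)
            continue
        try:
            fit = fit_interaction_model(clinical, focal_scores, v,
                                        gene_id=gene)
        except (CollinearityError, ValidationError):
            rows.append({"gene": gene, "a": np.nan, "b": np.nan,
                         "d": np.nan, "se_d": np.nan, "p_d": np.nan,
                         "converged": False})
            continue
        rows.append({"gene": gene, "a": fit.a, "b": fit.b, "d": fit.d,
                     "se_d": fit.se_d, "p_d": fit.p_d,
                     "converged": fit.converged})
    if skipped:
        warnings.warn(
            f"{len(skipped)} near-constant genes skipped: "
            f"{skipped[:5]}{'...' if len(skipped) > 5 else ''}"
        )
    if not rows:
        raise ValidationError("no genes could be fit")
    table = pd.DataFrame(rows)
    if not table["converged"].any():
        raise ValidationError("every interaction fit failed to converge")
    ok = table["converged"] & table["p_d"].notna()
    table["q_d"] = np.nan
    table.loc[ok, "q_d"] = bh_adjust(table.loc[ok, "p_d"].to_numpy())
    cls = np.full(len(table), "null", dtype=object)
    passing = (
        ok.to_numpy()
        & (table["p_d"].to_numpy() <= p_threshold)
        & (table["q_d"].to_numpy() <= fdr_threshold)
    )
    cls[passing & (table["d"].to_numpy() < 0)] = "enhancer"
    cls[passing & (table["d"].to_numpy() > 0)] = "reducer"
    table["class"] = cls
    counts = table["class"].value_counts().to_dict()
    for k in ("enhancer", "reducer", "null"):
        counts.setdefault(k, 0)
    return ScreenResult(
        table=table, p_threshold=p_threshold, fdr_threshold=fdr_threshold,
        counts=counts,
    )


def modulator_score(
    expr: ExpressionMatrix, screen: ScreenResult, direction: str
) -> ScoreTable:
    """Aggregate score over a screened gene class: per sample, the mean
    z-standardized log2 expression of the class's genes."""
    if direction not in ("enhancer", "reducer"):
        raise ValidationError(f"unknown direction: {direction!r}")
    genes = [g for g in screen.genes_in(direction)
             if g in expr.to_log2p1().values.index]
    if not genes:
        raise ValidationError(f"no {direction} genes available to score")
    log2 = expr.to_log2p1().values.loc[genes]
    z = log2.sub(log2.mean(axis=1), axis=0).div(
        log2.std(axis=1).replace(0.0, 1.0), axis=0
    )
    scores = pd.DataFrame({direction: z.mean(axis=0)})
    meta = {direction: {"method": "marker_mean", "genes_used": genes,
                        "genes_missing": []}}
    return ScoreTable(scores, meta)
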