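"""Synthetic cohort generation.

Builds expression + clinical + mutation + ICB-response cohorts whose
statistical structure matches what the downstream analysis assumes:

* a latent per-sample TLS factor F ~ N(0, 1) drives correlated
  over-expression of the 13 signature chemokines on the log2 scale;
* survival times are exponential with log-hazard
  ``c + a*F + sum_g b_g*V_g + sum_g d_g*F*V_g`` where ``V_g`` is centered
  expression, plus independent exponential right-censoring tuned to a target
  censoring fraction;
* per-gene mutation frequencies depend on a TLS-hi/low group split;
* ordinal ICB response labels (PD < SD < PR < CR) follow a cumulative-logit
  model shifted toward CR by F.

One global seed expands into fixed per-stage child seeds so each stage can
be re-run in isolation and reproduce the orchestrated run exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import SpecError
from .io import ClinicalTable, ExpressionMatrix, MAFTable, RESPONSE_LEVELS

__all__ = [
    "HazardCoeffs",
    "CohortSpec",
    "SyntheticCohort",
    "TLS_SIGNATURE_GENES",
    "default_cohort_spec",
    "simulate_expression",
    "simulate_survival",
    "simulate_mutations",
    "simulate_response",
    "simulate_cohort",
    "simulate_tme_archetypes",
]

#: The 13-chemokine TLS signature for head & neck squamous cell carcinoma.
TLS_SIGNATURE_GENES = (
    "CCL2", "CCL3", "CCL4", "CCL5", "CCL18", "CCL19", "CCL21",
    "CXCL9", "CXCL10", "CXCL11", "CXCL13", "CXCR4", "LAMP3",
)

# fixed child-seed offsets per simulation stage
_STAGE = {"expression": 1, "survival": 2, "mutation": 3, "response": 4,
          "covariates": 5}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STAGE[stage]])


@dataclass
class HazardCoeffs:
    """Linear log-hazard model h = a*F + sum b_g*V_g + sum d_g*F*V_g + c.

    ``a`` multiplies the focal (latent TLS) factor, ``b_map``/``d_map`` give
    per-gene main and interaction effects, and ``c`` is the baseline
    log-hazard (absorbed into the Cox baseline when estimating, but real in
    the generator).
    """

    a: float = -0.7
    b_map: dict[str, float] = field(default_factory=dict)
    d_map: dict[str, float] = field(default_factory=dict)
    c: float = -2.5


@dataclass
class CohortSpec:
    n_samples: int = 600
    n_genes: int = 500
    signature_genes: tuple[str, ...] = TLS_SIGNATURE_GENES
    tls_effect: float = 1.0
    noise_sd: float = 0.5
    hazard: HazardCoeffs = field(default_factory=HazardCoeffs)
    censoring_rate: float = 0.3
    # gene -> {group label -> mutation frequency}
    mutation_freqs: dict[str, dict[str, float]] = field(default_factory=dict)
    response_shift: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise SpecError("n_samples and n_genes must be positive")
        if self.n_genes < len(self.signature_genes):
            raise SpecError(
                f"n_genes ({self.n_genes}) < signature size "
                f"({len(self.signature_genes)})"
            )
        if not 0 <= self.censoring_rate < 1:
            raise SpecError("censoring_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise SpecError("noise_sd must be positive")
        if self.response_shift < 0:
            raise SpecError("response_shift must be >= 0")
        genes = set(self.gene_ids())
        for name, mapping in (("b_map", self.hazard.b_map),
                              ("d_map", self.hazard.d_map),
                              ("mutation_freqs", self.mutation_freqs)):
            missing = set(mapping) - genes
            if missing:
                raise SpecError(f"{name} names unknown genes: {sorted(missing)}")
        for gene, per_group in self.mutation_freqs.items():
            for grp, f in per_group.items():
                if not 0 <= f <= 1:
                    raise SpecError(
                        f"mutation frequency for {gene}/{grp} outside [0,1]"
                    )

    def gene_ids(self) -> list[str]:
        """Signature genes first, then named effect genes, then filler."""
        named = list(self.signature_genes)
        for extra in (*self.hazard.b_map, *self.hazard.d_map,
                      *self.mutation_freqs):
            if extra not in named:
                named.append(extra)
        n_fill = self.n_genes - len(named)
        if n_fill < 0:
            raise SpecError("n_genes smaller than the number of named genes")
        return named + [f"G{i:04d}" for i in range(1, n_fill + 1)]

    def sample_ids(self) -> list[str]:
        return [f"S{i:04d}" for i in range(1, self.n_samples + 1)]


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix  # scale = log2p1
    latent_tls: pd.Series
    clinical: ClinicalTable
    maf: MAFTable
    truth: CohortSpec


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The default test-bed cohort: 600 samples, 500 genes, 13 signature
    genes, 20 interaction enhancers (d = -0.5), 20 reducers (d = +0.5),
    protective focal effect a = -0.7, and two planted mutation genes with
    group-dependent frequencies.
    """
    d_map = {f"ENH{i:03d}": -0.5 for i in range(1, 21)}
    d_map.update({f"RED{i:03d}": +0.5 for i in range(1, 21)})
    mutation_freqs = {
        "MUC16L": {"TLS-hi": 0.22, "TLS-low": 0.17},
        "CASP8L": {"TLS-hi": 0.10, "TLS-low": 0.22},
    }
    # background mutations so TMB is non-trivial
    for i in range(1, 41):
        mutation_freqs[f"BG{i:03d}"] = {"TLS-hi": 0.08, "TLS-low": 0.08}
    return CohortSpec(
        hazard=HazardCoeffs(a=-0.7, d_map=d_map, c=-2.5),
        mutation_freqs=mutation_freqs,
        seed=seed,
    )


def simulate_expression(spec: CohortSpec) -> tuple[ExpressionMatrix, pd.Series]:
    """Draw the latent TLS factor and a log2(TPM+1)-scale expression matrix.

    Signature genes: baseline + tls_effect * F + N(0, noise_sd).
    All other genes: baseline + N(0, noise_sd). Per-gene baselines are drawn
    once from U(2, 6), a realistic log2-TPM range for expressed genes.
    Values are clipped at 0 so the log2p1 matrix maps back to non-negative
    linear abundances.
    """
    spec.validate()
    rng = _rng(spec.seed, "expression")
    genes = spec.gene_ids()
    samples = spec.sample_ids()
    n_g, n_s = len(genes), len(samples)
    latent = rng.standard_normal(n_s)
    baseline = rng.uniform(2.0, 6.0, size=n_g)
    mat = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(n_g, n_s))
    sig_idx = [genes.index(g) for g in spec.signature_genes]
    mat[sig_idx, :] += spec.tls_effect * latent[None, :]
    mat = np.clip(mat, 0.0, None)
    em = ExpressionMatrix(
        pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"),
                     columns=samples),
        scale="log2p1",
    )
    return em, pd.Series(latent, index=samples, name="latent_tls")


def _tune_censoring_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate mu with mean P(censor) = target, where
    P(censor | lambda_i) = mu / (lambda_i + mu)."""
    def mean_censored(mu):
        return float(np.mean(mu / (hazards + mu))) - target

    lo, hi = 1e-12, float(hazards.max()) * 1e6 + 1.0
    return brentq(mean_censored, lo, hi)


def simulate_survival(
    latent_tls: pd.Series,
    expression: ExpressionMatrix,
    hazard: HazardCoeffs,
    censoring_rate: float,
    seed: int,
) -> ClinicalTable:
    """Exponential event times from the linear log-hazard model, with
    independent exponential censoring tuned to the target censoring fraction.
    """
    if not 0 <= censoring_rate < 1:
        raise SpecError("censoring_rate must lie in [0, 1)")
    missing = (set(hazard.b_map) | set(hazard.d_map)) - set(
        expression.gene_ids
    )
    if missing:
        raise SpecError(f"hazard coefficients name unknown genes: {sorted(missing)}")
    rng = _rng(seed, "survival")
    log2 = expression.to_log2p1().values
    samples = log2.columns
    F = latent_tls.reindex(samples).to_numpy(float)
    eta = hazard.c + hazard.a * F
    for gene, b in hazard.b_map.items():
        v = log2.loc[gene].to_numpy(float)
        eta = eta + b * (v - v.mean())
    for gene, d in hazard.d_map.items():
        v = log2.loc[gene].to_numpy(float)
        eta = eta + d * F * (v - v.mean())
    rate = np.exp(eta)
    t_event = rng.exponential(1.0 / rate)
    if censoring_rate == 0:
        time, event = t_event, np.ones(len(t_event), int)
    else:
        mu = _tune_censoring_rate(rate, censoring_rate)
        t_cens = rng.exponential(1.0 / mu, size=len(t_event))
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    df = pd.DataFrame({"time": time, "event": event}, index=samples)
    df.index.name = "sample_id"
    return ClinicalTable(df)


def simulate_mutations(
    sample_groups: pd.Series,
    mutation_freqs: dict[str, dict[str, float]],
    seed: int,
) -> MAFTable:
    """Independent per-(sample, gene) Bernoulli mutations at group-specific
    frequencies; mutated records are emitted as Missense_Mutation."""
    rng = _rng(seed, "mutation")
    records = []
    samples = sample_groups.index.tolist()
    groups = sample_groups.to_numpy()
    for gene in mutation_freqs:
        per_group = mutation_freqs[gene]
        for f in per_group.values():
            if not 0 <= f <= 1:
                raise SpecError(f"mutation frequency outside [0,1] for {gene}")
        probs = np.array([per_group.get(g, 0.0) for g in groups])
        hits = rng.random(len(samples)) < probs
        for s in np.asarray(samples)[hits]:
            records.append((s, gene, "Missense_Mutation"))
    df = pd.DataFrame(
        records, columns=["sample_id", "gene_id", "variant_classification"]
    )
    return MAFTable(df)


# baseline ICB response mix (PD, SD, PR, CR) at latent factor 0; chosen to
# mirror typical checkpoint-blockade trial response distributions
_RESPONSE_BASELINE = {"PD": 0.40, "SD": 0.30, "PR": 0.18, "CR": 0.12}


def simulate_response(
    latent_tls: pd.Series, response_shift: float, seed: int
) -> pd.Series:
    """Ordinal CR/PR/SD/PD labels from a cumulative-logit model.

    P(Y <= level_j | F) = sigmoid(theta_j - response_shift * F) with cutpoints
    theta_j set by the baseline mix, so larger latent TLS shifts mass toward
    CR.
    """
    if response_shift < 0:
        raise SpecError("response_shift must be >= 0")
    rng = _rng(seed, "response")
    base = np.array([_RESPONSE_BASELINE[l] for l in RESPONSE_LEVELS])
    cum = np.cumsum(base)[:-1]  # cutpoints between the 4 ordered levels
    theta = np.log(cum / (1 - cum))
    F = latent_tls.to_numpy(float)
    # P(Y <= j) per sample per cutpoint
    cdf = 1.0 / (1.0 + np.exp(-(theta[None, :] - response_shift * F[:, None])))
    u = rng.random(len(F))
    level_idx = (u[:, None] > cdf).sum(axis=1)  # 0..3 (PD..CR)
    labels = np.array(RESPONSE_LEVELS)[level_idx]
    return pd.Series(labels, index=latent_tls.index, name="response")


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate the full cohort: expression, survival, covariates, mutations
    and ICB response, all sharing the same sample ids and fully determined by
    ``spec.seed``."""
    spec.validate()
    expression, latent = simulate_expression(spec)
    clinical = simulate_survival(
        latent, expression, spec.hazard, spec.censoring_rate, spec.seed
    )
    # independent demographic covariates for the survival screens
    rng = _rng(spec.seed, "covariates")
    n = spec.n_samples
    df = clinical.data.copy()
    df["age"] = np.round(rng.normal(60.0, 10.0, n), 1)
    df["gender"] = rng.choice(["female", "male"], size=n)
    df["stage"] = rng.choice(["I", "II", "III", "IV"], size=n,
                             p=[0.15, 0.25, 0.3, 0.3])
    df["hpv_status"] = rng.choice(["negative", "positive"], size=n,
                                  p=[0.7, 0.3])
    df["response"] = simulate_response(latent, spec.response_shift, spec.seed)
    clinical = ClinicalTable(df)

    groups = pd.Series(
        np.where(latent > latent.median(), "TLS-hi", "TLS-low"),
        index=latent.index,
    )
    maf = simulate_mutations(groups, spec.mutation_freqs, spec.seed)
    return SyntheticCohort(
        expression=expression,
        latent_tls=latent,
        clinical=clinical,
        maf=maf,
        truth=spec,
    )


# ---------------------------------------------------------------------------
# planted TME archetypes

#: z-scale archetype centers over 8 microenvironment parameters, one row per
#: planted class, following the published five-class HNSCC TME profiles:
#: an immune desert with many malignant cells; an immune-low but TMB-high
#: class; an immune- and stroma-rich TLS-high class with exhausted T cells;
#: a stromal-high immune desert (the worst-prognosis class); and an
#: immune-hot TLS-highest class with only moderate stroma (the best
#: prognosis). TLS level is ordered hot > immune-stromal > TMB-high >
#: stromal-desert > desert.
TME_ARCHETYPE_PARAMS = (
    "TLS", "immune_score", "stromal_score", "CAF", "exhausted_T",
    "cytotoxic_T", "TMB", "malignant",
)
TME_ARCHETYPE_CENTERS = {
    "immune-desert": (-1.5, -1.5, -1.2, -1.2, -1.2, -1.5, -1.0, 1.5),
    "immune-low-TMB-high": (-0.5, -1.0, -0.8, -0.8, -0.8, -1.0, 1.5, 1.2),
    "immune-stromal-rich": (1.2, 1.2, 1.5, 1.5, 1.3, 1.0, -1.0, -0.5),
    "stromal-immune-desert": (-1.2, -1.3, 1.5, 1.3, -0.5, -1.2, -1.2, 0.8),
    "immune-hot-TLS": (1.8, 1.5, 0.2, 0.0, 0.5, 1.5, 1.2, -1.2),
}
#: per-archetype baseline log-hazard; the stromal immune-desert class is
#: planted with the largest hazard (worst survival), the plain immune
#: desert next, and the immune-hot TLS class with the smallest
TME_ARCHETYPE_LOG_HAZARD = {
    "immune-desert": -1.8,
    "immune-low-TMB-high": -2.4,
    "immune-stromal-rich": -2.4,
    "stromal-immune-desert": -1.2,
    "immune-hot-TLS": -3.4,
}


def simulate_tme_archetypes(
    n_per_class: int = 50,
    within_sd: float = 0.5,
    censoring_rate: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, ClinicalTable]:
    """Planted-archetype microenvironment panel for clustering validation.

    Returns (raw panel DataFrame samples x parameters, planted labels,
    clinical table with exponential survival whose baseline hazard depends on
    the archetype).
    """
    rng = np.random.default_rng([int(seed), 7])
    names = list(TME_ARCHETYPE_CENTERS)
    rows, labels, loghaz = [], [], []
    for arch in names:
        center = np.array(TME_ARCHETYPE_CENTERS[arch])
        rows.append(center[None, :]
                    + rng.normal(0, within_sd, (n_per_class, len(center))))
        labels.extend([arch] * n_per_class)
        loghaz.extend([TME_ARCHETYPE_LOG_HAZARD[arch]] * n_per_class)
    X = np.vstack(rows)
    samples = [f"A{i:04d}" for i in range(1, len(labels) + 1)]
    panel = pd.DataFrame(X, index=samples, columns=TME_ARCHETYPE_PARAMS)
    planted = pd.Series(labels, index=samples, name="archetype")
    rate = np.exp(np.array(loghaz))
    t_event = rng.exponential(1.0 / rate)
    if censoring_rate > 0:
        mu = _tune_censoring_rate(rate, censoring_rate)
        t_cens = rng.exponential(1.0 / mu, size=len(t_event))
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        time, event = t_event, np.ones(len(t_event), int)
    clin = ClinicalTable(
        pd.DataFrame({"time": time, "event": event},
                     index=pd.Index(samples, name="sample_id"))
    )
    return panel, planted, clin
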