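"""End-to-end pipeline: simulate/ingest -> score -> stratify -> survival ->
interaction screen -> DEG/ORA -> mutation -> TME classification.

Configuration is a flat YAML/dict; every stage writes deterministic TSV
outputs (provenance header, no timestamps), and the run manifest records the
ordered stage list, parameters, and a SHA-256 hash of every output so two
runs from the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import default_cohort_spec, simulate_cohort
from .enrichment import differential_expression, ora_enrichment
from .errors import ValidationError
from .genesets import marker_mean_score
from .interaction import modulator_score, screen_genes
from .io import (read_clinical, read_expression_matrix, read_gmt, read_maf,
                 write_clinical, write_expression_matrix, write_maf)
from .mutation import compute_tmb, mutation_frequency_by_group
from .scoring import compute_tls_score, stratify_by_quartile
from .survival import km_estimate, logrank_test, survival_screen
from .tme import build_tme_panel, characterize_clusters, hierarchical_clusters

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

log = logging.getLogger("tlsig.pipeline")

DEFAULT_CONFIG: dict = {
    "simulate": True,
    "seed": 0,
    "expression": None,            # TSV path when simulate is false
    "expression_scale": "log2p1",
    "clinical": None,
    "maf": None,
    "gene_sets": None,             # optional GMT for ssGSEA / ORA
    "signature_name": "TLS",
    "stratify_mode": "three_class",
    "screen_p": 0.05,
    "screen_fdr": 1.0,
    "deg_fc": 1.5,
    "deg_p": 0.05,
    "ora_mode": "pathway",
    "ora_min_overlap": 5,
    "cluster_k": 5,
    "out_dir": "tlsig_run",
}

STAGES = (
    "ingest", "score", "stratify", "survival", "screen",
    "differential", "mutation", "classify",
)


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**DEFAULT_CONFIG, **user}
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, what: str, index_label) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tlsig {__version__} {what}\n")
        df.to_csv(fh, sep="\t", index_label=index_label, na_rep="NA")


def run_pipeline(config: dict) -> dict:
    """Execute the full analysis; returns the run manifest dict.

    Raises at the failing stage with the stage name in the log; outputs of a
    partial run are left on disk but not listed in a manifest.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    if not cfg["simulate"]:
        for key in ("expression", "clinical", "maf"):
            if cfg[key] and not Path(cfg[key]).exists():
                raise ValidationError(f"input file missing: {cfg[key]}")
        if not cfg["expression"] or not cfg["clinical"]:
            raise ValidationError(
                "expression and clinical inputs are required when "
                "simulate is false"
            )

    manifest: dict = {
        "version": __version__,
        "config": {k: cfg[k] for k in sorted(cfg)},
        "stages": [],
        "outputs": {},
    }
    outputs: dict[str, Path] = {}

    def done(stage: str) -> None:
        log.info("[%s] complete", stage)
        manifest["stages"].append(stage)

    # ingest -----------------------------------------------------------
    if cfg["simulate"]:
        spec = default_cohort_spec(seed=int(cfg["seed"]))
        cohort = simulate_cohort(spec)
        expr, clinical, maf = cohort.expression, cohort.clinical, cohort.maf
        write_expression_matrix(expr, out_dir / "expression.tsv")
        write_clinical(clinical, out_dir / "clinical.tsv")
        write_maf(maf, out_dir / "maf.tsv")
        truth = asdict(spec)
        truth["hazard"] = asdict(spec.hazard)
        truth["signature_genes"] = list(spec.signature_genes)
        with open(out_dir / "truth.yaml", "w") as fh:
            yaml.safe_dump(truth, fh, sort_keys=True)
        outputs.update(
            expression=out_dir / "expression.tsv",
            clinical=out_dir / "clinical.tsv",
            maf=out_dir / "maf.tsv",
            truth=out_dir / "truth.yaml",
        )
    else:
        expr = read_expression_matrix(cfg["expression"],
                                      scale=cfg["expression_scale"])
        clinical = read_clinical(cfg["clinical"])
        maf = read_maf(cfg["maf"]) if cfg["maf"] else None
    gene_sets = read_gmt(cfg["gene_sets"]) if cfg["gene_sets"] else None
    done("ingest")

    # score ------------------------------------------------------------
    sig_name = cfg["signature_name"]
    if gene_sets is not None and sig_name in gene_sets:
        scores = compute_tls_score(expr, gene_sets[sig_name], name=sig_name)
    else:
        scores = compute_tls_score(expr, name=sig_name)
    if gene_sets is not None:
        extra = {n: g for n, g in gene_sets.sets.items() if n != sig_name}
        if extra:
            mm = marker_mean_score(expr, extra)
            scores.scores = scores.scores.join(mm.scores)
            scores.metadata.update(mm.metadata)
    _write_tsv(scores.scores, out_dir / "scores.tsv", "scores", "sample_id")
    outputs["scores"] = out_dir / "scores.tsv"
    done("score")

    # stratify ---------------------------------------------------------
    strata = stratify_by_quartile(scores.series(sig_name),
                                  mode=cfg["stratify_mode"])
    _write_tsv(strata.labels.rename("tls_class").to_frame(),
               out_dir / "strata.tsv", "strata", "sample_id")
    outputs["strata"] = out_dir / "strata.tsv"
    done("stratify")

    # survival ---------------------------------------------------------
    km = km_estimate(clinical, strata.labels)
    km_rows = []
    for g, tab in km.groups.items():
        t = tab.copy()
        t.insert(0, "group", g)
        km_rows.append(t)
    _write_tsv(pd.concat(km_rows, ignore_index=True), out_dir / "km.tsv",
               "kaplan-meier", "row")
    lr = logrank_test(clinical, strata.labels)
    covars = strata.labels.rename("tls_class").to_frame()
    screen_tab = survival_screen(clinical, covars, mode="both")
    screen_tab.insert(0, "logrank_chi2", lr.chi2)
    screen_tab.insert(1, "logrank_p", lr.p_value)
    _write_tsv(screen_tab, out_dir / "survival.tsv", "survival", "row")
    outputs["km"] = out_dir / "km.tsv"
    outputs["survival"] = out_dir / "survival.tsv"
    done("survival")

    # interaction screen -----------------------------------------------
    screen = screen_genes(
        clinical, scores.series(sig_name), expr,
        p_threshold=float(cfg["screen_p"]),
        fdr_threshold=float(cfg["screen_fdr"]),
    )
    _write_tsv(screen.table.set_index("gene"), out_dir / "screen.tsv",
               "interaction-screen", "gene")
    outputs["screen"] = out_dir / "screen.tsv"
    done("screen")

    # differential expression + ORA ------------------------------------
    two_class = (strata.labels if cfg["stratify_mode"] == "two_class_q3"
                 else stratify_by_quartile(scores.series(sig_name),
                                           mode="two_class_q3").labels)
    deg = differential_expression(
        expr, two_class, fc_threshold=float(cfg["deg_fc"]),
        p_threshold=float(cfg["deg_p"]),
    )
    _write_tsv(deg.table, out_dir / "deg.tsv", "differential-expression",
               "gene")
    outputs["deg"] = out_dir / "deg.tsv"
    if gene_sets is not None:
        query = deg.genes("up") + deg.genes("down")
        ora = ora_enrichment(
            query, expr.gene_ids, gene_sets,
            min_overlap=int(cfg["ora_min_overlap"]), mode=cfg["ora_mode"],
        )
        _write_tsv(ora.table, out_dir / "ora.tsv", "ora", "set")
        outputs["ora"] = out_dir / "ora.tsv"
    done("differential")

    # mutation ----------------------------------------------------------
    tmb = None
    if maf is not None:
        tmb = compute_tmb(maf, clinical.sample_ids)
        _write_tsv(tmb.counts.to_frame(), out_dir / "tmb.tsv", "tmb",
                   "sample_id")
        mfreq = mutation_frequency_by_group(maf, two_class)
        _write_tsv(mfreq.table, out_dir / "mutfreq.tsv",
                   "mutation-frequency", "gene_id")
        outputs["tmb"] = out_dir / "tmb.tsv"
        outputs["mutfreq"] = out_dir / "mutfreq.tsv"
    done("mutation")

    # TME classification ------------------------------------------------
    panel_tables = [scores]
    for direction in ("enhancer", "reducer"):
        if screen.counts.get(direction):
            panel_tables.append(modulator_score(expr, screen, direction))
    panel = build_tme_panel(panel_tables, tmb=tmb)
    assignment = hierarchical_clusters(
        panel, k=min(int(cfg["cluster_k"]), len(panel.sample_ids)),
        order_by=sig_name,
    )
    profile, cluster_lr, _ = characterize_clusters(panel, assignment, clinical)
    _write_tsv(assignment.labels.rename("cluster").to_frame(),
               out_dir / "clusters.tsv", "tme-clusters", "sample_id")
    _write_tsv(assignment.merge_history, out_dir / "dendrogram.tsv",
               "dendrogram", "merge")
    _write_tsv(profile, out_dir / "cluster_profiles.tsv",
               "cluster-profiles", "cluster")
    outputs["clusters"] = out_dir / "clusters.tsv"
    outputs["dendrogram"] = out_dir / "dendrogram.tsv"
    outputs["cluster_profiles"] = out_dir / "cluster_profiles.tsv"
    manifest["cluster_logrank_p"] = (
        cluster_lr.p_value if cluster_lr is not None else None
    )
    done("classify")

    manifest["outputs"] = {
        name: {"path": str(path), "sha256": _sha256(path)}
        for name, path in sorted(outputs.items())
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _setup_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    root = logging.getLogger("tlsig")
    root.handlers[:] = [handler]
    root.setLevel(logging.DEBUG if verbose else logging.INFO)
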