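"""End-to-end orchestration: config handling, robustness sweeps, cross-dataset runs.

Robustness experiments re-run the full CV pipeline while varying one thing at
a time: the right-censoring cutoff used to define prognosis labels (k from 3
to 14 years by default), or the completeness of the interactome (replicate
networks with 5/10/15/20% of edges randomly deleted). Cross-dataset
prediction fits class statistics and the model on one cohort and scores a
second cohort on the shared gene/module universe.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .evaluation import EvaluationReport, make_cv_plan, roc_auc, run_cv, derive_seeds
from .features import build_features, fit_class_statistics
from .model import ModelConfig, fit_elastic_net, predict_scores
from .modules import delete_edges, filter_modules
from .io import InteractomeNetwork, ModuleSet

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_config",
    "run_evaluation",
    "run_cutoff_sweep",
    "run_network_robustness",
    "run_cross_dataset",
]


@dataclass
class RunConfig:
    """Serializable run configuration (validated before any computation)."""

    expression: str = ""
    modules: str = ""
    network: str = ""
    outcomes: str = ""
    clinical: str = ""
    event_type: str = ""
    cutoff_years: float = 5.0
    n_folds: int = 5
    n_repeats: int = 50
    master_seed: int = 0
    feature_mode: str = "averaged"
    biomarker_q: float = 2.0
    cutoff_sweep: tuple = (3, 14)
    deletion_fractions: tuple = (0.05, 0.10, 0.15, 0.20)
    deletion_replicates: int = 50
    output_dir: str = "netprog_out"
    model: dict = field(default_factory=dict)  # overrides for ModelConfig

    def model_config(self) -> ModelConfig:
        cfg = ModelConfig(mode=self.feature_mode)
        for key, val in self.model.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown model option {key!r}")
            setattr(cfg, key, tuple(val) if isinstance(val, list) else val)
        return cfg

    def validate(self) -> None:
        if self.n_folds < 2 or self.n_repeats < 1:
            raise ValueError("need n_folds >= 2 and n_repeats >= 1")
        if self.feature_mode not in ("averaged", "expanded", "auto"):
            raise ValueError(f"unknown feature mode {self.feature_mode!r}")
        if not 0 < self.biomarker_q < 50:
            raise ValueError("biomarker_q must lie in (0, 50)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cutoff_sweep"] = list(self.cutoff_sweep)
        d["deletion_fractions"] = list(self.deletion_fractions)
        return d


def load_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**doc)
    cfg.validate()
    return cfg


def _content_hash(paths) -> str:
    h = hashlib.sha1()
    for p in paths:
        if p and Path(p).exists():
            h.update(Path(p).read_bytes())
    return h.hexdigest()[:12]


def _load_inputs(cfg: RunConfig):
    expr = io.read_expression(cfg.expression)
    mods = io.read_modules(cfg.modules)
    outcomes = io.read_outcomes(cfg.outcomes)
    clinical = io.read_clinical(cfg.clinical) if cfg.clinical else None
    return expr, mods, outcomes, clinical


def run_evaluation(cfg: RunConfig, outdir: str | Path | None = None) -> EvaluationReport:
    """Full repeated-CV evaluation from a RunConfig; writes report + provenance."""
    cfg.validate()
    expr, mods, outcomes, clinical = _load_inputs(cfg)
    labels, excluded = io.derive_labels(outcomes, cfg.cutoff_years,
                                        cfg.event_type or None)
    labels = labels.loc[[p for p in labels.index if p in expr.columns]]
    plan = make_cv_plan(labels, cfg.n_folds, cfg.n_repeats, cfg.master_seed)
    report = run_cv(expr, mods, labels, clinical=clinical, plan=plan,
                    config=cfg.model_config())
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_json(outdir / "evaluation.json")
        report.to_tsv(outdir / "evaluation.tsv")
        provenance = {
            "config": cfg.to_dict(),
            "input_hash": _content_hash([cfg.expression, cfg.modules,
                                         cfg.outcomes, cfg.clinical]),
            "n_excluded_censored": len(excluded),
            "summary": report.summary(),
        }
        (outdir / "run.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    return report


def run_cutoff_sweep(
    expr: pd.DataFrame,
    modules: ModuleSet,
    outcomes: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    k_range=range(3, 15),
    event_type: str | None = None,
    n_folds: int = 5,
    n_repeats: int = 10,
    master_seed: int = 0,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Median AUC as a function of the right-censoring cutoff k.

    Labels are re-derived per k (patients censored before k are re-excluded)
    and the full CV pipeline re-run. Cutoffs that leave a single class, or a
    class smaller than the fold count, are skipped with a warning.
    """
    rows = []
    for k in k_range:
        try:
            labels, excluded = io.derive_labels(outcomes, float(k), event_type)
        except ValueError as exc:
            logger.warning("cutoff k=%s skipped: %s", k, exc)
            continue
        labels = labels.loc[[p for p in labels.index if p in expr.columns]]
        if labels.nunique() < 2 or labels.value_counts().min() < n_folds:
            logger.warning("cutoff k=%s skipped: class too small", k)
            continue
        plan = make_cv_plan(labels, n_folds, n_repeats, master_seed)
        report = run_cv(expr, modules, labels, clinical=clinical, plan=plan,
                        config=config)
        summ = report.summary()
        rows.append({"k": k, "n_patients": len(labels),
                     "n_excluded": len(excluded),
                     "median_auc": summ["median_auc"],
                     "ci_low": summ["ci_low"], "ci_high": summ["ci_high"]})
    return pd.DataFrame(rows)


def run_network_robustness(
    expr: pd.DataFrame,
    modules: ModuleSet,
    network: InteractomeNetwork,
    labels: pd.Series,
    clinical: pd.DataFrame | None = None,
    fractions=(0.05, 0.10, 0.15, 0.20),
    n_replicates: int = 50,
    n_folds: int = 5,
    n_repeats: int = 5,
    master_seed: int = 0,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """AUC distributions under random edge deletion.

    Per replicate, the stated fraction of edges is removed, module membership
    is restricted to nodes still incident to an edge, the 1/3-coverage filter
    re-applied, and the CV pipeline re-run. Returns one row per
    (fraction, replicate, repeat-AUC) — boxplot-ready.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate per fraction")
    seeds = derive_seeds(master_seed, len(fractions) * n_replicates)
    plan = make_cv_plan(labels, n_folds, n_repeats, master_seed)
    rows = []
    i = 0
    for frac in fractions:
        for rep in range(n_replicates):
            perturbed = delete_edges(network, frac, seeds[i])
            i += 1
            alive = {n for n in perturbed.graph.nodes
                     if perturbed.graph.degree[n] > 0}
            restricted = []
            for mid, members in modules:
                kept = members & alive
                if kept:
                    restricted.append((mid, frozenset(kept)))
            if not restricted:
                logger.warning("fraction %.2f replicate %d: no modules survive", frac, rep)
                continue
            report = run_cv(expr, ModuleSet(restricted), labels,
                            clinical=clinical, plan=plan, config=config)
            for r, auc in enumerate(report.per_repeat_aucs()):
                rows.append({"fraction": frac, "replicate": rep,
                             "repeat": r, "auc": auc})
    return pd.DataFrame(rows)


def run_cross_dataset(
    train: dict,
    test: dict,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> dict:
    """Train on one cohort, score another on the shared gene/module universe.

    ``train`` and ``test`` are dicts with keys ``expression``, ``labels`` and
    (train only) ``modules``. Gene universes are intersected first, the
    1/3-coverage module filter re-applied on the intersection, then class
    statistics and the model come exclusively from the training cohort.
    Returns the test-cohort ROC/AUC and the fitted hyperparameters.
    """
    cfg = config or ModelConfig()
    expr_tr, labels_tr = train["expression"], train["labels"]
    expr_te, labels_te = test["expression"], test["labels"]
    modules = train["modules"]

    shared_genes = sorted(set(expr_tr.index) & set(expr_te.index))
    if not shared_genes:
        raise ValueError("train and test gene universes are disjoint")
    expr_tr = expr_tr.loc[shared_genes]
    expr_te = expr_te.loc[shared_genes]
    try:
        fmods = filter_modules(modules, expr_tr)
    except ValueError as exc:
        raise ValueError(f"no shared modules after harmonization: {exc}") from exc

    labels_tr = labels_tr.loc[[p for p in labels_tr.index if p in expr_tr.columns]]
    labels_te = labels_te.loc[[p for p in labels_te.index if p in expr_te.columns]]
    stats = fit_class_statistics(expr_tr, labels_tr, list(labels_tr.index))
    mode = cfg.mode if cfg.mode != "auto" else "averaged"
    feats_tr = build_features(expr_tr[list(labels_tr.index)], fmods, stats, mode)
    model = fit_elastic_net(feats_tr.data, labels_tr, alpha_grid=cfg.alpha_grid,
                            inner_folds=cfg.inner_folds, seed=seed,
                            max_iter=cfg.max_iter, family=cfg.family)
    feats_te = build_features(expr_te[list(labels_te.index)], fmods, stats, mode)
    x_te = feats_te.data.reindex(columns=list(model.coef.index), fill_value=0.0)
    scores = predict_scores(model, x_te)
    points, auc = roc_auc(scores, labels_te)
    return {
        "auc": auc,
        "roc": points,
        "scores": scores,
        "alpha": model.alpha,
        "lambda": model.lam,
        "n_train": len(labels_tr),
        "n_test": len(labels_te),
        "n_shared_genes": len(shared_genes),
        "n_shared_modules": len(fmods.kept),
    }
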