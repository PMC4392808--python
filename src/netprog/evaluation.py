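"""Repeated stratified cross-validation and performance metrics.

The evaluation protocol is 5-fold cross-validation repeated 50 times with a
deterministic set of derived seeds, so competing configurations can be run on
identical fold splits. Class statistics, features and the model are fitted on
the four training folds only; the held-out fold is scored with those frozen
statistics. One AUC is reported per repeat by pooling the five test folds'
scores; per-fold AUCs and coefficient vectors are retained for biomarker
stability analysis.

AUC uses the midrank (tie-aware) formulation. Classification accuracy is
reported at the accuracy-optimal ROC operating point (with symmetric error
costs the optimal slope S = N/P point minimises FP + FN) and at a fixed
sensitivity of 90%. AUC distributions are compared with a two-sided
Mann-Whitney U test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .biomarker import collapse_module_coefficients
from .features import build_features, fit_class_statistics
from .io import ModuleSet
from .model import ModelConfig, fit_combined, fit_elastic_net
from .modules import FilteredModuleSet, filter_modules

logger = logging.getLogger(__name__)

__all__ = [
    "CVPlan",
    "FoldRecord",
    "EvaluationReport",
    "make_cv_plan",
    "run_cv",
    "roc_auc",
    "accuracy_at_optimum",
    "accuracy_at_sensitivity",
    "summarize_auc",
    "compare_auc_sets",
]


# ---------------------------------------------------------------------------
# CV plan


@dataclass
class CVPlan:
    n_folds: int
    n_repeats: int
    master_seed: int
    seeds: tuple
    assignments: list  # per repeat: pd.Series patient_id -> fold index

    @property
    def patients(self) -> pd.Index:
        return self.assignments[0].index


def derive_seeds(master_seed: int, n: int) -> tuple:
    """Deterministic child seeds (< 2^31) from one master seed."""
    return tuple(int(s) for s in
                 np.random.SeedSequence(master_seed).generate_state(n) % (2**31))


def make_cv_plan(labels: pd.Series, n_folds: int = 5, n_repeats: int = 50,
                 master_seed: int = 0) -> CVPlan:
    """Stratified fold assignments, one set per repeat, all derived from one seed."""
    counts = labels.value_counts()
    small = counts[counts < n_folds]
    if not small.empty:
        raise ValueError(
            f"class(es) {list(small.index)} have fewer than n_folds={n_folds} members")
    seeds = derive_seeds(master_seed, n_repeats)
    assignments = []
    y = labels.to_numpy()
    for seed in seeds:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        fold_of = np.empty(len(labels), dtype=int)
        for f, (_, te) in enumerate(skf.split(np.zeros(len(labels)), y)):
            fold_of[te] = f
        assignments.append(pd.Series(fold_of, index=labels.index))
    return CVPlan(n_folds, n_repeats, master_seed, seeds, assignments)


# ---------------------------------------------------------------------------
# metrics


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(pd.Series(scores), dtype=float)
    y = np.asarray(pd.Series(labels), dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return s, y


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve points and the tie-aware (midrank) AUC.

    AUC is the probability that a random bad-prognosis patient outranks a
    random good-prognosis patient, ties counting one half.
    """
    s, y = _split_scores(scores, labels)
    ranks = sps.rankdata(s)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(y, s)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return points, float(auc)


def accuracy_at_optimum(scores, labels) -> tuple[float, float]:
    """Accuracy at the accuracy-optimal ROC operating point.

    With zero cost for correct calls and symmetric misclassification costs the
    optimal ROC slope is S = N/P, i.e. the point minimising FP + FN —
    equivalently maximising accuracy. Scans every threshold (score >= t is
    called positive); ties prefer the higher-sensitivity point.
    """
    s, y = _split_scores(scores, labels)
    thresholds = np.concatenate([np.unique(s), [np.inf]])
    best = None  # (acc, sens, threshold)
    for t in thresholds:
        pred = s >= t
        acc = float(np.mean(pred == (y == 1)))
        sens = float(pred[y == 1].mean())
        if best is None or acc > best[0] + 1e-15 or (
                abs(acc - best[0]) <= 1e-15 and sens > best[1] + 1e-15):
            best = (acc, sens, float(t))
    return best[2], best[0]


def accuracy_at_sensitivity(scores, labels, target_sens: float = 0.90) -> float:
    """Accuracy at the strictest threshold reaching the target sensitivity."""
    s, y = _split_scores(scores, labels)
    for t in np.sort(np.unique(s))[::-1]:
        pred = s >= t
        if pred[y == 1].mean() >= target_sens:
            return float(np.mean(pred == (y == 1)))
    # all-positive call always reaches sensitivity 1
    return float(np.mean(y == 1))


def summarize_auc(aucs) -> dict:
    """Median and 95% percentile interval of a set of per-repeat AUCs."""
    a = np.asarray(list(aucs), dtype=float)
    if a.size < 2:
        raise ValueError("need at least two AUC values")
    return {
        "median_auc": float(np.median(a)),
        "ci_low": float(np.percentile(a, 2.5)),
        "ci_high": float(np.percentile(a, 97.5)),
        "n": int(a.size),
    }


def compare_auc_sets(aucs_a, aucs_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two AUC sets.

    Exact null distribution when both sets are small (min n <= 8) and tie-free;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(list(aucs_a), dtype=float)
    b = np.asarray(list(aucs_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both AUC sets must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# the CV harness


@dataclass
class FoldRecord:
    repeat: int
    fold: int
    test_ids: list
    scores: list
    labels: list
    auc: float
    alpha: float
    lam: float
    k: float
    mode: str
    module_coefs: dict


@dataclass
class EvaluationReport:
    records: list  # of FoldRecord
    n_folds: int
    n_repeats: int
    master_seed: int
    config: dict = field(default_factory=dict)

    def per_repeat_aucs(self) -> list[float]:
        """One AUC per repeat, pooling the repeat's test-fold scores."""
        out = []
        for r in range(self.n_repeats):
            recs = [rec for rec in self.records if rec.repeat == r]
            scores = np.concatenate([rec.scores for rec in recs])
            labels = np.concatenate([rec.labels for rec in recs])
            _, auc = roc_auc(scores, labels)
            out.append(auc)
        return out

    def per_fold_aucs(self) -> list[float]:
        return [rec.auc for rec in self.records]

    def coefficient_maps(self) -> list[dict]:
        return [rec.module_coefs for rec in self.records]

    def summary(self) -> dict:
        aucs = self.per_repeat_aucs()
        out = summarize_auc(aucs)
        acc_opt, acc_sens = [], []
        for r in range(self.n_repeats):
            recs = [rec for rec in self.records if rec.repeat == r]
            scores = np.concatenate([rec.scores for rec in recs])
            labels = np.concatenate([rec.labels for rec in recs])
            acc_opt.append(accuracy_at_optimum(scores, labels)[1])
            acc_sens.append(accuracy_at_sensitivity(scores, labels, 0.90))
        out["median_accuracy_at_optimum"] = float(np.median(acc_opt))
        out["median_accuracy_at_90_sensitivity"] = float(np.median(acc_sens))
        return out

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "version": 1,
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
            "master_seed": self.master_seed,
            "config": self.config,
            "records": [
                {
                    "repeat": r.repeat, "fold": r.fold,
                    "test_ids": list(map(str, r.test_ids)),
                    "scores": [float(x) for x in r.scores],
                    "labels": [int(x) for x in r.labels],
                    "auc": r.auc, "alpha": r.alpha, "lambda": r.lam,
                    "k": r.k, "mode": r.mode,
                    "module_coefs": {k: float(v) for k, v in r.module_coefs.items()},
                }
                for r in self.records
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "EvaluationReport":
        doc = json.loads(Path(path).read_text())
        records = [
            FoldRecord(d["repeat"], d["fold"], d["test_ids"], d["scores"],
                       d["labels"], d["auc"], d["alpha"], d["lambda"], d["k"],
                       d["mode"], d["module_coefs"])
            for d in doc["records"]
        ]
        return cls(records, doc["n_folds"], doc["n_repeats"], doc["master_seed"],
                   doc.get("config", {}))

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"repeat": r.repeat, "fold": r.fold, "auc": r.auc, "alpha": r.alpha,
             "lambda": r.lam, "k": r.k, "mode": r.mode, "n_test": len(r.test_ids)}
            for r in self.records
        ]
        pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def _select_mode(features_by_mode: dict, labels: pd.Series, train_ids,
                 config: ModelConfig, seed: int) -> str:
    """Pick averaged vs expanded by inner-CV AUC on the training patients."""
    cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    y = labels.loc[train_ids]
    best = None
    for mode in ("averaged", "expanded"):
        df = features_by_mode[mode].data.loc[train_ids]
        oof = pd.Series(index=df.index, dtype=float)
        for i, (tr, te) in enumerate(cv.split(df, y)):
            enet = fit_elastic_net(df.iloc[tr], y.iloc[tr],
                                   alpha_grid=config.alpha_grid,
                                   inner_folds=config.inner_folds,
                                   seed=seed + i, max_iter=config.max_iter)
            oof.iloc[te] = enet.predict(df.iloc[te])
        _, auc = roc_auc(oof, y)
        if best is None or auc > best[0] + 1e-15:
            best = (auc, mode)
    return best[1]


def run_cv(
    expr: pd.DataFrame,
    modules: ModuleSet | FilteredModuleSet,
    labels: pd.Series,
    clinical: pd.DataFrame | None = None,
    plan: CVPlan | None = None,
    config: ModelConfig | None = None,
) -> EvaluationReport:
    """Run the full repeated-CV pipeline and collect an EvaluationReport.

    Per fold: class statistics are fitted on the training patients only,
    features built for everyone with those statistics, the model fitted on the
    training rows and the held-out fold scored. ``clinical`` (raw, encoded
    internally) activates the combined model with its grid-searched weight k.
    """
    cfg = config or ModelConfig()
    if plan is None:
        plan = make_cv_plan(labels)
    missing = [p for p in plan.patients if p not in expr.columns]
    if missing:
        raise ValueError(f"patients in plan but not in expression: {missing[:5]}")
    fmods = (modules if isinstance(modules, FilteredModuleSet)
             else filter_modules(modules, expr))
    clin_enc = None
    if clinical is not None:
        from .io import encode_clinical
        clin_enc = encode_clinical(clinical.loc[plan.patients])

    records: list[FoldRecord] = []
    fit_seeds = derive_seeds(plan.master_seed + 1, plan.n_repeats * plan.n_folds)
    for rep, fold_of in enumerate(plan.assignments):
        for fold in range(plan.n_folds):
            seed = fit_seeds[rep * plan.n_folds + fold]
            test_ids = fold_of.index[fold_of == fold]
            train_ids = fold_of.index[fold_of != fold]
            try:
                stats = fit_class_statistics(expr, labels, train_ids)
                if cfg.mode == "auto":
                    by_mode = {m: build_features(expr[list(plan.patients)], fmods,
                                                 stats, m)
                               for m in ("averaged", "expanded")}
                    mode = _select_mode(by_mode, labels, train_ids, cfg, seed)
                    feats = by_mode[mode]
                else:
                    mode = cfg.mode
                    feats = build_features(expr[list(plan.patients)], fmods, stats, mode)
                ftrain = feats.data.loc[train_ids]
                ftest = feats.data.loc[test_ids]
                if clin_enc is not None:
                    model = fit_combined(ftrain, clin_enc.loc[train_ids],
                                         labels, k_grid=cfg.k_grid,
                                         seed=seed, config=cfg)
                    scores = model.predict(ftest, clin_enc.loc[test_ids])
                    alpha, lam, k = (model.elastic.alpha, model.elastic.lam, model.k)
                    coef = model.elastic.coef
                else:
                    model = fit_elastic_net(ftrain, labels,
                                            alpha_grid=cfg.alpha_grid,
                                            inner_folds=cfg.inner_folds,
                                            seed=seed, max_iter=cfg.max_iter,
                                            family=cfg.family)
                    scores = model.predict(ftest)
                    alpha, lam, k = model.alpha, model.lam, 1.0
                    coef = model.coef
            except Exception as exc:
                raise RuntimeError(f"CV failure at repeat={rep} fold={fold}: {exc}") from exc
            _, auc = roc_auc(scores, labels.loc[test_ids])
            records.append(FoldRecord(
                repeat=rep, fold=fold, test_ids=list(test_ids),
                scores=[float(x) for x in scores],
                labels=[int(x) for x in labels.loc[test_ids]],
                auc=auc, alpha=float(alpha), lam=float(lam), k=float(k),
                mode=mode,
                module_coefs=collapse_module_coefficients(coef, mode),
            ))
    cfg_doc = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in vars(cfg).items()}
    return EvaluationReport(records, plan.n_folds, plan.n_repeats,
                            plan.master_seed, cfg_doc)
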