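"""Model-object interface: build a prognosis model from data, fit it, inspect results.

    >>> model = PrognosisModel(expression, modules, labels, clinical=clinical)
    >>> res = model.fit(seed=0)
    >>> print(res.summary())
    >>> res.predict(new_expression)

`PrognosisModel` holds the data and configuration; `fit()` performs module
filtering, training-set class standardization, feature construction, the
elastic-net fit (optionally combined with the logistic clinical arm) and
returns a `PrognosisResults` carrying the estimates, chosen hyperparameters
and everything needed to score new patients.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .biomarker import collapse_module_coefficients, select_significant
from .features import (
    ClassStatistics,
    build_features,
    fit_class_statistics,
)
from .model import (
    CombinedModel,
    ElasticNetModel,
    ModelConfig,
    fit_combined,
    fit_elastic_net,
    predict_scores,
)
from .modules import FilteredModuleSet, filter_modules

logger = logging.getLogger(__name__)

__all__ = ["PrognosisModel", "PrognosisResults"]


class PrognosisModel:
    """Prognosis regression on network-module expression features.

    Parameters
    ----------
    expression : DataFrame, genes x patients (normalized, may contain NaN)
    modules : ModuleSet (overlapping membership allowed)
    labels : Series patient -> {0 good, 1 bad}
    clinical : optional raw clinical DataFrame (encoded internally)
    config : ModelConfig with grids, feature mode and family
    """

    def __init__(self, expression: pd.DataFrame, modules: io.ModuleSet,
                 labels: pd.Series, clinical: pd.DataFrame | None = None,
                 config: ModelConfig | None = None):
        self.expression = expression
        self.modules = modules
        self.labels = labels.loc[[p for p in labels.index if p in expression.columns]]
        if self.labels.empty:
            raise ValueError("no labeled patients present in the expression matrix")
        self.clinical = clinical
        self.config = config or ModelConfig()
        self.filtered_modules: FilteredModuleSet = filter_modules(modules, expression)

    @classmethod
    def from_files(cls, expression_path, modules_path, outcomes_path,
                   cutoff_years: float = 5.0, event_type: str | None = None,
                   clinical_path=None, config: ModelConfig | None = None
                   ) -> "PrognosisModel":
        expr = io.read_expression(expression_path)
        mods = io.read_modules(modules_path)
        outcomes = io.read_outcomes(outcomes_path)
        labels, excluded = io.derive_labels(outcomes, cutoff_years, event_type)
        if excluded:
            logger.info("excluded %d patients censored before the %.1f-year cutoff",
                        len(excluded), cutoff_years)
        clinical = io.read_clinical(clinical_path) if clinical_path else None
        return cls(expr, mods, labels, clinical, config)

    def fit(self, training_ids=None, seed: int = 0) -> "PrognosisResults":
        """Fit on ``training_ids`` (default: all labeled patients)."""
        cfg = self.config
        train = list(training_ids) if training_ids is not None else list(self.labels.index)
        stats = fit_class_statistics(self.expression, self.labels, train)

        if cfg.mode == "auto":
            from .evaluation import _select_mode
            by_mode = {m: build_features(self.expression[train], self.filtered_modules,
                                         stats, m) for m in ("averaged", "expanded")}
            mode = _select_mode(by_mode, self.labels, train, cfg, seed)
        else:
            mode = cfg.mode
        feats = build_features(self.expression[train], self.filtered_modules,
                               stats, mode)
        clin_enc = None
        if self.clinical is not None:
            clin_enc = io.encode_clinical(self.clinical.loc[train])
            fitted = fit_combined(feats.data, clin_enc, self.labels,
                                  k_grid=cfg.k_grid, seed=seed, config=cfg)
        else:
            fitted = fit_elastic_net(feats.data, self.labels,
                                     alpha_grid=cfg.alpha_grid,
                                     inner_folds=cfg.inner_folds, seed=seed,
                                     max_iter=cfg.max_iter, family=cfg.family)
        return PrognosisResults(model=self, stats=stats, mode=mode,
                                fitted=fitted, training_ids=tuple(train))


@dataclass
class PrognosisResults:
    """Fitted prognosis model: coefficients, hyperparameters, scoring, summary."""

    model: PrognosisModel
    stats: ClassStatistics
    mode: str
    fitted: ElasticNetModel | CombinedModel
    training_ids: tuple

    # -- parameter access ---------------------------------------------------

    @property
    def elastic(self) -> ElasticNetModel:
        return self.fitted.elastic if isinstance(self.fitted, CombinedModel) else self.fitted

    @property
    def params(self) -> pd.Series:
        """Per-feature elastic-net coefficients."""
        return self.elastic.coef

    @property
    def alpha(self) -> float:
        return self.elastic.alpha

    @property
    def lam(self) -> float:
        return self.elastic.lam

    @property
    def k(self) -> float:
        return self.fitted.k if isinstance(self.fitted, CombinedModel) else 1.0

    def module_coefficients(self) -> dict:
        return collapse_module_coefficients(self.params, self.mode)

    def significant_modules(self, q: float = 2.0):
        return select_significant(self.module_coefficients(), q, source="full-fit")

    # -- prediction ---------------------------------------------------------

    def predict(self, expression: pd.DataFrame | None = None,
                clinical: pd.DataFrame | None = None) -> pd.Series:
        """Risk scores for patients in ``expression`` (default: training data).

        Features are rebuilt with the frozen training-class statistics, so new
        patients influence only their own scores. Features absent from the new
        data (e.g. unmeasured genes in a cross-dataset setting) are scored at
        the class mean (0).
        """
        expr = expression if expression is not None else \
            self.model.expression[list(self.training_ids)]
        feats = build_features(expr, self.model.filtered_modules, self.stats, self.mode)
        names = list(self.params.index)
        x = feats.data.reindex(columns=names, fill_value=0.0)
        clin_enc = None
        if (isinstance(self.fitted, CombinedModel)
                and self.fitted.clinical is not None and self.k < 1.0):
            if clinical is None:
                raise ValueError("fitted model has a clinical arm; pass clinical data")
            clin_enc = io.encode_clinical(clinical).reindex(
                columns=list(self.fitted.clinical.coef.index), fill_value=0.0)
        return predict_scores(self.fitted, x, clin_enc)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        coefs = self.module_coefficients()
        nonzero = {m: c for m, c in coefs.items() if c != 0.0}
        top = sorted(nonzero.items(), key=lambda kv: -abs(kv[1]))[:10]
        lines = [
            "Prognosis regression on network-module expression features",
            "=" * 60,
            f"patients (training): {len(self.training_ids)}",
            f"modules (post-filter): {len(self.model.filtered_modules.kept)}",
            f"feature mode: {self.mode}   features: {len(self.params)}",
            f"family: {self.elastic.family}   scaling: {self.elastic.scaling}",
            f"alpha: {self.alpha:.3f}   lambda: {self.lam:.5g}   k (module arm weight): {self.k:.2f}",
            f"nonzero module coefficients: {len(nonzero)}/{len(coefs)}",
            "-" * 60,
            "top module coefficients (largest |coef|):",
        ]
        for mid, c in top:
            lines.append(f"  {mid:<12s} {c:+.5f}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        doc = {
            "version": 1,
            "mode": self.mode,
            "k": self.k,
            "model": (self.fitted.to_dict() if isinstance(self.fitted, CombinedModel)
                      else {"k": 1.0, "elastic": self.fitted.to_dict(), "clinical": None}),
            "training_ids": list(map(str, self.training_ids)),
            "class_statistics": {
                "mean_good": {g: float(v) for g, v in self.stats.mean_good.items()},
                "mean_bad": {g: float(v) for g, v in self.stats.mean_bad.items()},
                "sd_good": {g: float(v) for g, v in self.stats.sd_good.items()},
                "sd_bad": {g: float(v) for g, v in self.stats.sd_bad.items()},
                "flagged": sorted(self.stats.flagged),
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @staticmethod
    def load_model(path: str | Path) -> CombinedModel:
        """Reload the fitted coefficient document (scores FeatureMatrix inputs)."""
        doc = json.loads(Path(path).read_text())
        return CombinedModel.from_dict(doc["model"])
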