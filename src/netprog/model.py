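"""Elastic-net prognosis regression, the logistic clinical arm, and their combination.

The penalized objective is the unscaled form

    min_{b0, b}  sum_i (y_i - b0 - x_i'b)^2  +  lambda * P_alpha(b),
    P_alpha(b) = sum_j [ ((1-alpha)/2) b_j^2 + alpha |b_j| ]

with alpha in [0, 1] trading ridge (alpha=0) against lasso (alpha=1) and the
0/1 prognosis label regressed with Gaussian least squares. Optimisation is
delegated to scikit-learn's coordinate descent, which minimises
1/(2N)*RSS + a*(l1_ratio*|b|_1 + (1-l1_ratio)/2*|b|_2^2); the conversion
a = lambda/(2N), l1_ratio = alpha is exact and recorded in each model's
``scaling`` tag.

(alpha, lambda) are chosen by inner cross-validation minimising mean squared
prediction error; ties prefer the sparser model (smallest alpha, then largest
lambda). Features arrive already class-standardized, so no further internal
standardization is applied.

When clinical covariates are available a logistic model is fitted to them
separately (they are low-dimensional, so the elastic net is not appropriate)
and the final score is the weighted combination Y = k*Y1 + (1-k)*Y2 with the
weight k chosen by grid search on inner-CV AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, LogisticRegression, enet_path
from sklearn.model_selection import KFold, StratifiedKFold

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

SCALING_TAG = "rss+lambda*P_alpha; sklearn_alpha=lambda/(2N), l1_ratio=alpha"

__all__ = [
    "ModelConfig",
    "ElasticNetModel",
    "ClinicalModel",
    "CombinedModel",
    "default_alpha_grid",
    "default_lambda_grid",
    "fit_elastic_net",
    "fit_clinical",
    "fit_combined",
    "predict_scores",
]


def default_alpha_grid() -> np.ndarray:
    """alpha in {0.05, 0.10, ..., 1.0}."""
    return np.round(np.arange(0.05, 1.0001, 0.05), 2)


@dataclass
class ModelConfig:
    """Grids and policies for model fitting.

    ``mode`` is the feature representation: "averaged" (G/B per module),
    "expanded" (per-gene P/Q) or "auto" (pick the better of the two by
    inner-CV AUC).
    """

    alpha_grid: tuple = tuple(default_alpha_grid())
    n_lambda: int = 50
    lambda_decades: float = 4.0
    inner_folds: int = 3
    k_grid: tuple = tuple(np.round(np.arange(0.0, 1.0001, 0.01), 2))
    mode: str = "averaged"
    family: str = "gaussian"  # "binomial" optional alternative
    clinical_ridge_guard: float = 0.01
    max_iter: int = 50_000


def default_lambda_grid(X: np.ndarray, y: np.ndarray, alpha: float,
                        n_lambda: int = 50, decades: float = 4.0) -> np.ndarray:
    """Log-spaced lambda path from lambda_max (all-zero solution) down ``decades``.

    In the unscaled objective the smallest all-zeroing lambda at mixing alpha
    is 2*max|X_c' y_c| / alpha (centered X and y).
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    lam_max = 2.0 * np.max(np.abs(Xc.T @ yc)) / max(alpha, 1e-3)
    lam_max = max(lam_max, 1e-8)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_lambda)


@dataclass
class ElasticNetModel:
    intercept: float
    coef: pd.Series
    alpha: float
    lam: float
    n_train: int
    scaling: str = SCALING_TAG
    family: str = "gaussian"

    def predict(self, features: FeatureMatrix | pd.DataFrame) -> pd.Series:
        df = features.data if isinstance(features, FeatureMatrix) else features
        missing = [c for c in self.coef.index if c not in df.columns]
        if missing:
            raise ValueError(f"feature-name mismatch; missing: {missing[:10]}")
        x = df[list(self.coef.index)].to_numpy(dtype=float)
        return pd.Series(self.intercept + x @ self.coef.to_numpy(), index=df.index)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": {k: float(v) for k, v in self.coef.items()},
            "alpha": self.alpha,
            "lambda": self.lam,
            "n_train": self.n_train,
            "scaling": self.scaling,
            "family": self.family,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElasticNetModel":
        return cls(
            intercept=float(d["intercept"]),
            coef=pd.Series(d["coefficients"], dtype=float),
            alpha=float(d["alpha"]),
            lam=float(d["lambda"]),
            n_train=int(d["n_train"]),
            scaling=d.get("scaling", SCALING_TAG),
            family=d.get("family", "gaussian"),
        )


def _check_features(X: np.ndarray) -> None:
    if X.shape[1] == 0:
        raise ValueError("no features")
    if np.all(X.std(axis=0) == 0):
        raise ValueError("all features are constant")


def _fit_at(X: np.ndarray, y: np.ndarray, alpha: float, lam: float,
            max_iter: int) -> tuple[float, np.ndarray]:
    """Single elastic-net fit at fixed (alpha, lambda) in the unscaled convention.

    Tight tolerance, intended for small instances / explicit single-point
    grids; grid-searched refits go through the warm-started path instead.
    """
    n = X.shape[0]
    skl_alpha = lam / (2.0 * n)
    est = ElasticNet(alpha=skl_alpha, l1_ratio=alpha, fit_intercept=True,
                     max_iter=max_iter, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            est.fit(X, y)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                f"elastic net did not converge at (alpha={alpha}, lambda={lam})"
            ) from exc
    return float(est.intercept_), est.coef_.copy()


def _fit_via_path(X: np.ndarray, y: np.ndarray, alpha: float, lam: float,
                  lams: np.ndarray, max_iter: int, tol: float = 1e-4
                  ) -> tuple[float, np.ndarray]:
    """Refit at (alpha, lambda) by a warm-started path down the lambda grid."""
    n = X.shape[0]
    mu_x, mu_y = X.mean(axis=0), y.mean()
    Xc, yc = X - mu_x, y - mu_y
    path_lams = np.concatenate([lams[lams > lam], [lam]])
    skl_alphas = path_lams / (2.0 * n)
    gap_limit = tol * float(yc @ yc)
    for trial_iter in (max_iter, 10 * max_iter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, coefs, gaps = enet_path(Xc, yc, l1_ratio=max(alpha, 1e-3),
                                       alphas=skl_alphas, max_iter=trial_iter,
                                       tol=tol)
        if gaps[-1] <= gap_limit or not np.isfinite(gap_limit):
            coef = coefs[:, -1]
            return float(mu_y - mu_x @ coef), coef.copy()
    raise RuntimeError(
        f"elastic net did not converge at (alpha={alpha}, lambda={lam})")


def fit_elastic_net(
    features: FeatureMatrix | pd.DataFrame,
    labels: pd.Series,
    alpha_grid=None,
    lambda_grid=None,
    inner_folds: int = 3,
    seed: int = 0,
    max_iter: int = 50_000,
    family: str = "gaussian",
) -> ElasticNetModel:
    """Fit the elastic net with (alpha, lambda) chosen by inner CV on MSE.

    ``lambda_grid`` may be None (per-alpha path from lambda_max down four
    decades, 50 points), a 1-D array shared across alphas, or ignored when the
    total grid has a single point (fit directly, no CV). The refit at the
    selected pair uses all supplied patients. Deterministic for a given seed.
    """
    df = features.data if isinstance(features, FeatureMatrix) else features
    y = labels.loc[df.index].to_numpy(dtype=float)
    X = df.to_numpy(dtype=float)
    _check_features(X)
    if family == "binomial":
        return _fit_binomial(df, y, alpha_grid, inner_folds, seed, max_iter)

    alphas = np.sort(np.asarray(
        alpha_grid if alpha_grid is not None else default_alpha_grid(), dtype=float))
    if alphas.size == 0:
        raise ValueError("empty alpha grid")

    fixed_lams = None
    if lambda_grid is not None:
        fixed_lams = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
        if fixed_lams.size == 0:
            raise ValueError("empty lambda grid")

    # degenerate grid: nothing to select
    if alphas.size == 1 and fixed_lams is not None and fixed_lams.size == 1:
        b0, b = _fit_at(X, y, float(alphas[0]), float(fixed_lams[0]), max_iter)
        return ElasticNetModel(b0, pd.Series(b, index=df.columns),
                               float(alphas[0]), float(fixed_lams[0]), len(y),
                               family=family)

    n = len(y)
    n_splits = min(inner_folds, n)
    cv = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(cv.split(X))
    # per-fold centered data + Gram matrices, shared across the alpha grid
    fold_data = []
    for tr, te in splits:
        Xtr, ytr = X[tr], y[tr]
        mu_x, mu_y = Xtr.mean(axis=0), ytr.mean()
        Xc, yc = Xtr - mu_x, ytr - mu_y
        fold_data.append((Xc, yc, np.dot(Xc.T, Xc), X[te] - mu_x,
                          y[te] - mu_y, len(tr)))

    best = None  # (mse, alpha, lam)
    sel_iter = min(max_iter, 500)  # selection paths need only ranking accuracy
    for alpha in alphas:
        lams = fixed_lams if fixed_lams is not None else default_lambda_grid(X, y, alpha)
        sq_err = np.zeros(lams.size)
        for Xc, yc, gram, Xte_c, yte_c, n_tr in fold_data:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                _, coefs, _ = enet_path(Xc, yc, l1_ratio=max(alpha, 1e-3),
                                        alphas=lams / (2.0 * n_tr),
                                        precompute=gram, max_iter=sel_iter)
            pred = Xte_c @ coefs  # (n_te, n_lambda)
            sq_err += ((pred - yte_c[:, None]) ** 2).sum(axis=0)
        mse = sq_err / n
        # preference order: smallest alpha, then largest lambda (lams descend)
        for j in range(lams.size):
            cand = (mse[j], float(alpha), float(lams[j]), lams)
            if best is None or cand[0] < best[0] - 1e-15:
                best = cand
    _, alpha_star, lam_star, lams_star = best
    b0, b = _fit_via_path(X, y, alpha_star, lam_star, lams_star, max_iter)
    return ElasticNetModel(b0, pd.Series(b, index=df.columns), alpha_star,
                           lam_star, n, family=family)


def _fit_binomial(df: pd.DataFrame, y: np.ndarray, alpha_grid, inner_folds: int,
                  seed: int, max_iter: int) -> ElasticNetModel:
    """Optional logistic-family elastic net (off by default)."""
    alphas = np.asarray(alpha_grid if alpha_grid is not None else default_alpha_grid(),
                        dtype=float)
    best = None
    cv = StratifiedKFold(n_splits=min(inner_folds, 3), shuffle=True, random_state=seed)
    Cs = np.logspace(-2, 2, 10)
    for alpha in alphas:
        for C in Cs:
            accs = []
            for tr, te in cv.split(df, y):
                est = LogisticRegression(solver="saga", C=C,
                                         l1_ratio=max(alpha, 1e-3),
                                         max_iter=max_iter)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    est.fit(df.iloc[tr], y[tr])
                p = est.predict_proba(df.iloc[te])[:, 1]
                accs.append(np.mean((p - y[te]) ** 2))
            score = float(np.mean(accs))
            if best is None or score < best[0] - 1e-15:
                best = (score, float(alpha), float(C))
    _, alpha_star, C_star = best
    est = LogisticRegression(solver="saga", C=C_star,
                             l1_ratio=max(alpha_star, 1e-3), max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(df, y)
    lam = 1.0 / C_star
    return ElasticNetModel(float(est.intercept_[0]),
                           pd.Series(est.coef_[0], index=df.columns),
                           alpha_star, lam, len(y), family="binomial",
                           scaling="binomial deviance + (1/C)*P_alpha")


@dataclass
class ClinicalModel:
    """Logistic-regression arm over encoded clinical covariates."""

    intercept: float
    coef: pd.Series
    dropped: list = field(default_factory=list)

    def predict_proba(self, clinical: pd.DataFrame) -> pd.Series:
        missing = [c for c in self.coef.index if c not in clinical.columns]
        if missing:
            raise ValueError(f"clinical covariates missing: {missing}")
        if len(self.coef):
            eta = self.intercept + clinical[list(self.coef.index)].to_numpy(float) @ self.coef.to_numpy()
        else:
            eta = np.full(len(clinical), self.intercept)
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=clinical.index)

    def to_dict(self) -> dict:
        return {"intercept": self.intercept,
                "coefficients": {k: float(v) for k, v in self.coef.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "ClinicalModel":
        return cls(float(d["intercept"]), pd.Series(d["coefficients"], dtype=float))


def fit_clinical(clinical: pd.DataFrame, labels: pd.Series,
                 ridge_guard: float = 0.01) -> ClinicalModel:
    """Maximum-likelihood logistic fit with a small L2 guard against separation.

    Constant covariates are dropped with a warning; if nothing remains the
    model is intercept-only (predicted probability = class prevalence). The
    guard penalises coefficients only, never the intercept.
    """
    y = labels.loc[clinical.index].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit the clinical model")
    keep = [c for c in clinical.columns if clinical[c].nunique(dropna=False) > 1]
    dropped = [c for c in clinical.columns if c not in keep]
    if dropped:
        logger.warning("fit_clinical: dropping constant covariates %s", dropped)
    if not keep:
        prev = float(np.mean(y))
        return ClinicalModel(float(np.log(prev / (1 - prev))), pd.Series(dtype=float),
                             dropped)
    est = LogisticRegression(C=1.0 / ridge_guard, max_iter=5000)
    est.fit(clinical[keep].to_numpy(dtype=float), y)
    return ClinicalModel(float(est.intercept_[0]),
                         pd.Series(est.coef_[0], index=keep), dropped)


@dataclass
class CombinedModel:
    """Weighted combination Y = k*Y1 + (1-k)*Y2 of the module and clinical arms."""

    elastic: ElasticNetModel
    clinical: ClinicalModel | None
    k: float

    def predict(self, features: FeatureMatrix | pd.DataFrame,
                clinical: pd.DataFrame | None = None) -> pd.Series:
        y1 = self.elastic.predict(features)
        if self.clinical is None or self.k == 1.0:
            if self.k != 1.0 and self.clinical is None:
                raise ValueError("combined model has no clinical arm but k < 1")
            return y1 if self.k == 1.0 else self.k * y1
        if clinical is None:
            raise ValueError("clinical covariates required for combined prediction")
        y2 = self.clinical.predict_proba(clinical).loc[y1.index]
        return self.k * y1 + (1.0 - self.k) * y2

    def to_dict(self) -> dict:
        return {"k": self.k, "elastic": self.elastic.to_dict(),
                "clinical": None if self.clinical is None else self.clinical.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "CombinedModel":
        clin = None if d["clinical"] is None else ClinicalModel.from_dict(d["clinical"])
        return cls(ElasticNetModel.from_dict(d["elastic"]), clin, float(d["k"]))


def fit_combined(
    features: FeatureMatrix | pd.DataFrame,
    clinical: pd.DataFrame | None,
    labels: pd.Series,
    k_grid=None,
    inner_folds: int = 3,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> CombinedModel:
    """Fit both arms and choose the weight k by inner-CV AUC of the combined score.

    With no clinical table (or no usable covariates) the model degenerates to
    k = 1 with a warning. Ties in AUC prefer the smallest k.
    """
    from .evaluation import roc_auc  # local import: avoids module cycle

    cfg = config or ModelConfig()
    k_grid = np.asarray(cfg.k_grid if k_grid is None else k_grid, dtype=float)
    if np.any((k_grid < 0) | (k_grid > 1)):
        raise ValueError("k_grid must lie in [0, 1]")
    df = features.data if isinstance(features, FeatureMatrix) else features
    y = labels.loc[df.index]

    def _fit_enet(sub_df, sub_y, fold_seed):
        return fit_elastic_net(sub_df, sub_y, alpha_grid=cfg.alpha_grid,
                               inner_folds=cfg.inner_folds, seed=fold_seed,
                               max_iter=cfg.max_iter, family=cfg.family)

    if clinical is None or clinical.shape[1] == 0:
        logger.warning("fit_combined: no clinical covariates; using k = 1")
        return CombinedModel(_fit_enet(df, y, seed), None, 1.0)

    clin = clinical.loc[df.index]
    if k_grid.size > 1:
        cv = StratifiedKFold(n_splits=min(inner_folds, 3), shuffle=True, random_state=seed)
        oof1 = pd.Series(index=df.index, dtype=float)
        oof2 = pd.Series(index=df.index, dtype=float)
        for i, (tr, te) in enumerate(cv.split(df, y)):
            tr_idx, te_idx = df.index[tr], df.index[te]
            enet = _fit_enet(df.loc[tr_idx], y.loc[tr_idx], seed + i + 1)
            cmod = fit_clinical(clin.loc[tr_idx], y.loc[tr_idx],
                                ridge_guard=cfg.clinical_ridge_guard)
            oof1.loc[te_idx] = enet.predict(df.loc[te_idx])
            oof2.loc[te_idx] = cmod.predict_proba(clin.loc[te_idx])
        best = None
        for k in np.sort(k_grid):
            _, auc = roc_auc(k * oof1 + (1 - k) * oof2, y)
            if best is None or auc > best[0] + 1e-15:
                best = (auc, float(k))
        k_star = best[1]
    else:
        k_star = float(k_grid[0])

    return CombinedModel(_fit_enet(df, y, seed),
                         fit_clinical(clin, y, ridge_guard=cfg.clinical_ridge_guard),
                         k_star)


def predict_scores(model, features: FeatureMatrix | pd.DataFrame,
                   clinical: pd.DataFrame | None = None) -> pd.Series:
    """Per-patient real-valued risk scores; higher means predicted bad prognosis."""
    if isinstance(model, CombinedModel):
        return model.predict(features, clinical)
    return model.predict(features)
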