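"""Class-conditional standardization features and module-averaged features.

Every feature is built from training-set statistics only. For gene *k* and
patient *i* with expression E_ik, the good- and bad-class standardized values
are

    P_ik = (E_ik - <E_kg>) / sigma_kg
    Q_ik = (E_ik - <E_kb>) / sigma_kb

where the class means and SDs come exclusively from the training patients of
each prognosis class. A module *m* with s_m usable genes contributes the two
averaged features G_im = mean_k P_ik and B_im = mean_k Q_ik ("averaged" mode),
or all of its per-gene P/Q values ("expanded" mode).

Standard deviations use the sample (n-1) convention. Genes with fewer than two
observations in a class, or zero variance in a class, are flagged and excluded
from feature construction rather than epsilon-floored — flooring a zero SD
manufactures arbitrarily large standardized signal.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ModuleSet
from .modules import FilteredModuleSet

logger = logging.getLogger(__name__)

MODES = ("averaged", "expanded")

__all__ = [
    "ClassStatistics",
    "FeatureMatrix",
    "fit_class_statistics",
    "standardize",
    "build_features",
    "write_features",
    "read_features",
]


@dataclass
class ClassStatistics:
    """Per-gene class-conditional means and SDs from training patients only."""

    mean_good: pd.Series
    mean_bad: pd.Series
    sd_good: pd.Series
    sd_bad: pd.Series
    flagged: frozenset
    training_ids: tuple

    @property
    def fingerprint(self) -> str:
        """Hash of the sorted training-ID list — makes leakage auditable."""
        h = hashlib.sha1("\x1f".join(sorted(map(str, self.training_ids))).encode())
        return h.hexdigest()[:12]

    def usable_genes(self) -> pd.Index:
        return self.mean_good.index[~self.mean_good.index.isin(self.flagged)]


@dataclass
class FeatureMatrix:
    """Patient x feature matrix with a mode tag and training-stats fingerprint."""

    data: pd.DataFrame  # patients x features
    mode: str
    stats_fingerprint: str
    dropped_modules: list[str] = field(default_factory=list)

    @property
    def patients(self) -> pd.Index:
        return self.data.index

    @property
    def feature_names(self) -> pd.Index:
        return self.data.columns


def fit_class_statistics(
    expr: pd.DataFrame, labels: pd.Series, training_ids
) -> ClassStatistics:
    """Compute per-gene class means/SDs over the given training patients.

    Missing expression entries are skipped. Genes that cannot be standardized
    against either class (sd = 0, or fewer than 2 class observations) are
    flagged.
    """
    training_ids = list(training_ids)
    unknown = [p for p in training_ids if p not in expr.columns]
    if unknown:
        raise ValueError(f"training patients absent from expression matrix: {unknown[:5]}")
    lab = labels.loc[training_ids]
    good_ids = lab.index[lab == 0]
    bad_ids = lab.index[lab == 1]
    if len(good_ids) == 0 or len(bad_ids) == 0:
        raise ValueError("both prognosis classes must be present in the training set")

    good = expr[list(good_ids)]
    bad = expr[list(bad_ids)]
    mean_g = good.mean(axis=1, skipna=True)
    mean_b = bad.mean(axis=1, skipna=True)
    sd_g = good.std(axis=1, ddof=1, skipna=True)
    sd_b = bad.std(axis=1, ddof=1, skipna=True)
    n_g = good.notna().sum(axis=1)
    n_b = bad.notna().sum(axis=1)

    bad_mask = (n_g < 2) | (n_b < 2) | (sd_g <= 0) | (sd_b <= 0) | sd_g.isna() | sd_b.isna()
    flagged = frozenset(expr.index[bad_mask])
    if flagged:
        logger.info("fit_class_statistics: flagged %d/%d genes", len(flagged), len(expr.index))
    return ClassStatistics(
        mean_good=mean_g, mean_bad=mean_b, sd_good=sd_g, sd_bad=sd_b,
        flagged=flagged, training_ids=tuple(training_ids),
    )


def standardize(expr_value: float, stats: ClassStatistics, gene: str) -> tuple[float, float]:
    """Return (P, Q) for one expression value of one gene."""
    if gene in stats.flagged:
        raise ValueError(f"gene {gene!r} is flagged (degenerate class statistics)")
    p = (expr_value - stats.mean_good[gene]) / stats.sd_good[gene]
    q = (expr_value - stats.mean_bad[gene]) / stats.sd_bad[gene]
    return float(p), float(q)


def _standardize_frame(expr: pd.DataFrame, stats: ClassStatistics) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorized P/Q for all unflagged genes (rows) and all patients (cols)."""
    genes = [g for g in expr.index if g not in stats.flagged]
    sub = expr.loc[genes]
    p = sub.sub(stats.mean_good[genes], axis=0).div(stats.sd_good[genes], axis=0)
    q = sub.sub(stats.mean_bad[genes], axis=0).div(stats.sd_bad[genes], axis=0)
    return p, q


def build_features(
    expr: pd.DataFrame,
    filtered_modules: FilteredModuleSet | ModuleSet,
    stats: ClassStatistics,
    mode: str = "averaged",
) -> FeatureMatrix:
    """Build the per-patient module feature matrix.

    ``averaged``: two features per usable module — ``<id>.G`` and ``<id>.B``,
    the per-patient mean of P/Q over the module's measured, unflagged genes
    (missing entries are skipped patient-wise; the denominator is each
    patient's observed-gene count). ``expanded``: two features per
    (module, gene) pair — ``<id>.<gene>.P`` / ``<id>.<gene>.Q``.

    Modules with no usable genes are dropped with a warning. A feature whose
    underlying expression value is missing for a patient (expanded mode, or an
    averaged module where the patient observes no member gene) is set to 0 —
    the class mean on the standardized scale.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    mset = filtered_modules.kept if isinstance(filtered_modules, FilteredModuleSet) else filtered_modules
    if len(mset) == 0:
        raise ValueError("no modules to build features from")

    p_all, q_all = _standardize_frame(expr, stats)
    usable_index = set(p_all.index)
    patients = expr.columns

    cols: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for mid, members in mset:
        genes = sorted(g for g in members if g in usable_index)
        if not genes:
            dropped.append(mid)
            continue
        if mode == "averaged":
            cols[f"{mid}.G"] = p_all.loc[genes].mean(axis=0, skipna=True).to_numpy()
            cols[f"{mid}.B"] = q_all.loc[genes].mean(axis=0, skipna=True).to_numpy()
        else:
            for g in genes:
                cols[f"{mid}.{g}.P"] = p_all.loc[g].to_numpy()
                cols[f"{mid}.{g}.Q"] = q_all.loc[g].to_numpy()
    if dropped:
        logger.warning("build_features: dropped %d modules with no usable genes: %s",
                       len(dropped), dropped[:10])
    if not cols:
        raise ValueError("every module lost all usable genes; no features built")
    data = pd.DataFrame(cols, index=patients).fillna(0.0)
    data.index.name = "patient_id"
    return FeatureMatrix(data=data, mode=mode,
                         stats_fingerprint=stats.fingerprint,
                         dropped_modules=dropped)


def write_features(features: FeatureMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"#mode={features.mode}\tstats={features.stats_fingerprint}\n")
        features.data.to_csv(fh, sep="\t", index_label="patient_id")


def read_features(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("#mode="):
            raise ValueError(f"{path}: missing feature-matrix header line")
        fields = dict(part.split("=", 1) for part in header[1:].split("\t"))
        data = pd.read_csv(fh, sep="\t", index_col="patient_id")
    return FeatureMatrix(data=data, mode=fields["mode"],
                         stats_fingerprint=fields.get("stats", ""))
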