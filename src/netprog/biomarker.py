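"""Significant-module selection, stability, cancer-gene enrichment and degree summaries.

A fitted model assigns each module a coefficient (in averaged mode the
larger-magnitude of its G/B coefficients; in expanded mode the
largest-magnitude over its per-gene P/Q coefficients). Modules in the extreme
tails of the coefficient distribution — the highest and lowest q percent,
q = 2 by default with q = 10 as a common alternative — are the candidate
prognostic biomarker modules.

Enrichment of known cancer genes among significant-module genes is measured as

    Ef = C / T   (expected fraction: cancer genes over all module genes)
    Of = X / N   (observed fraction among unique significant-module genes)
    En = Of / Ef

with an upper cumulative binomial test P[Binomial(N, Ef) >= X].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import InteractomeNetwork, ModuleSet
from .modules import FilteredModuleSet

logger = logging.getLogger(__name__)

__all__ = [
    "SignificantModuleSet",
    "EnrichmentResult",
    "StabilityResult",
    "collapse_module_coefficients",
    "select_significant",
    "consensus_significant",
    "stability",
    "enrichment",
    "degree_summary",
]


def collapse_module_coefficients(coef: pd.Series, mode: str) -> dict:
    """Collapse per-feature coefficients to one value per module.

    Averaged-mode features are ``<module>.G`` / ``<module>.B``; expanded-mode
    features ``<module>.<gene>.P`` / ``<module>.<gene>.Q``. Each module gets
    its largest-magnitude coefficient (first occurrence wins exact-magnitude
    ties, so the result is deterministic in feature order).
    """
    out: dict[str, float] = {}
    for name, value in coef.items():
        if mode == "averaged":
            mid, _ = name.rsplit(".", 1)
        else:
            mid, _, _ = name.rsplit(".", 2)
        v = float(value)
        if mid not in out or abs(v) > abs(out[mid]):
            out[mid] = v
    return out


@dataclass
class SignificantModuleSet:
    """Modules in the coefficient-distribution tails, with their coefficients."""

    coefficients: dict  # selected module_id -> coefficient
    q: float
    source: str = ""

    @property
    def ids(self) -> list[str]:
        return sorted(self.coefficients)

    def __len__(self) -> int:
        return len(self.coefficients)


def select_significant(coefficients: dict | pd.Series, q: float = 2.0,
                       source: str = "") -> SignificantModuleSet:
    """Select modules whose coefficients fall in the top-q% or bottom-q% tails.

    Each tail holds ``round(q/100 * n)`` modules (at least one). Ties are
    broken lexicographically by module id, so the selection is deterministic
    even on a degenerate all-equal coefficient vector. Invariant to adding a
    constant to every coefficient.
    """
    if not 0 < q < 50:
        raise ValueError("q must lie in (0, 50)")
    items = list(pd.Series(coefficients).items())
    if not items:
        raise ValueError("empty coefficient map")
    n = len(items)
    n_tail = max(1, int(np.floor(q / 100.0 * n + 0.5)))
    ordered = sorted(items, key=lambda kv: (kv[1], kv[0]))
    selected = {k: float(v) for k, v in ordered[:n_tail]}
    selected.update({k: float(v) for k, v in ordered[-n_tail:]})
    return SignificantModuleSet(selected, q, source)


def consensus_significant(coefficient_maps: list[dict], q: float = 2.0,
                          min_fraction: float = 0.5) -> tuple[list, dict]:
    """Modules significant in at least ``min_fraction`` of the per-fit maps.

    ``coefficient_maps`` is typically one module-coefficient dict per
    (repeat, fold) fit of a CV run. Returns ``(consensus_ids, counts)``.
    """
    if not coefficient_maps:
        raise ValueError("no coefficient maps")
    counts: dict[str, int] = {}
    for cmap in coefficient_maps:
        for mid in select_significant(cmap, q).coefficients:
            counts[mid] = counts.get(mid, 0) + 1
    need = min_fraction * len(coefficient_maps)
    consensus = sorted(m for m, c in counts.items() if c >= need)
    return consensus, counts


@dataclass
class StabilityResult:
    rhos: list = field(default_factory=list)  # (i, j, rho)
    n_pairs: int = 0
    n_skipped: int = 0

    def fraction_at_least(self, threshold: float = 0.98) -> float:
        vals = [r for _, _, r in self.rhos]
        if not vals:
            return float("nan")
        return float(np.mean([r >= threshold for r in vals]))


def stability(significant_sets: list[SignificantModuleSet]) -> StabilityResult:
    """Spearman rank correlation of significant-module coefficients over all pairs.

    For every pair of fits the correlation is computed on the modules
    significant in both; pairs sharing fewer than two modules (or with a
    degenerate constant vector) are skipped and counted.
    """
    if len(significant_sets) < 2:
        raise ValueError("need at least two significant-module sets")
    result = StabilityResult()
    for i, j in combinations(range(len(significant_sets)), 2):
        a, b = significant_sets[i], significant_sets[j]
        shared = sorted(set(a.coefficients) & set(b.coefficients))
        if len(shared) < 2:
            result.n_skipped += 1
            continue
        va = [a.coefficients[m] for m in shared]
        vb = [b.coefficients[m] for m in shared]
        rho = sps.spearmanr(va, vb).statistic
        if np.isnan(rho):
            result.n_skipped += 1
            continue
        result.rhos.append((i, j, float(rho)))
    result.n_pairs = len(result.rhos)
    return result


@dataclass
class EnrichmentResult:
    n_cancer_total: int      # C: cancer genes among all module genes
    n_genes_total: int       # T: unique genes across all modules
    n_cancer_significant: int  # X: cancer genes among significant-module genes
    n_genes_significant: int   # N: unique genes across significant modules
    expected_fraction: float   # Ef = C/T
    observed_fraction: float   # Of = X/N
    enrichment: float          # En = Of/Ef
    p_value: float


def enrichment(
    significant: SignificantModuleSet,
    all_modules: FilteredModuleSet | ModuleSet,
    cancer_genes: set,
) -> EnrichmentResult:
    """Cancer-gene enrichment of significant modules, on unique gene sets.

    ``p = P[Binomial(N, Ef) >= X]`` (upper cumulative binomial).
    """
    if not cancer_genes:
        raise ValueError("empty cancer gene list")
    mset = all_modules.kept if isinstance(all_modules, FilteredModuleSet) else all_modules
    membership = dict(mset.modules)
    genes_total = set().union(*membership.values())
    t_i = len(genes_total)
    c_i = len(genes_total & set(cancer_genes))
    sig_genes: set = set()
    for mid in significant.coefficients:
        if mid not in membership:
            raise KeyError(f"significant module {mid!r} not in module set")
        sig_genes |= membership[mid]
    n_i = len(sig_genes)
    if n_i == 0:
        raise ValueError("significant modules contain no genes")
    x_i = len(sig_genes & set(cancer_genes))
    ef = c_i / t_i
    if ef == 0:
        raise ValueError("no known cancer genes among module genes; enrichment undefined")
    of = x_i / n_i
    p = float(sps.binom.sf(x_i - 1, n_i, ef))
    return EnrichmentResult(c_i, t_i, x_i, n_i, ef, of, of / ef, min(p, 1.0))


def degree_summary(network: InteractomeNetwork, gene_sets: dict) -> dict:
    """Mean network degree over each named gene set (absent genes excluded).

    Returns ``{name: {"mean_degree", "n_present", "n_absent"}}``; a set with
    no member in the network is an error.
    """
    out = {}
    nodes = network.nodes
    for name, genes in gene_sets.items():
        present = sorted(set(genes) & nodes)
        if not present:
            raise ValueError(f"gene set {name!r} has no members in the network")
        degs = [network.degree(g) for g in present]
        out[name] = {
            "mean_degree": float(np.mean(degs)),
            "n_present": len(present),
            "n_absent": len(set(genes)) - len(present),
        }
    return out
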