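"""Module filtering against measured genes, module-set sweeps and network perturbation.

Module detection itself (ClusterONE-style overlapping clustering, hierarchical
or affinity-propagation alternatives) is consumed as precomputed files; this
layer only reconciles those modules with an expression matrix and perturbs
networks for robustness experiments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import InteractomeNetwork, ModuleSet

logger = logging.getLogger(__name__)

#: minimum fraction of a module's genes that must have expression rows
COVERAGE_MIN = 1.0 / 3.0

__all__ = [
    "FilteredModuleSet",
    "filter_modules",
    "delete_edges",
    "make_random_network_suite",
    "sweep_module_sets",
]


@dataclass
class FilteredModuleSet:
    """Modules restricted to measured genes, with per-module coverage bookkeeping."""

    kept: ModuleSet
    dropped_ids: list[str] = field(default_factory=list)
    coverage: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.kept)


def filter_modules(modules: ModuleSet, expr: pd.DataFrame) -> FilteredModuleSet:
    """Keep modules where at least 1/3 of member genes have expression rows.

    The boundary is inclusive (a 1-of-3 module is kept), and kept modules are
    restricted to their measured members — unmeasured genes cannot contribute
    to a module average, so the downstream module size ``s_m`` is the measured
    member count. Idempotent.
    """
    measured = set(expr.index)
    kept: list[tuple[str, frozenset]] = []
    dropped: list[str] = []
    coverage: dict[str, float] = {}
    for mid, members in modules:
        present = members & measured
        frac = len(present) / len(members)
        coverage[mid] = frac
        # integer comparison avoids float trouble exactly at 1/3
        if 3 * len(present) >= len(members) and present:
            kept.append((mid, frozenset(present)))
        else:
            dropped.append(mid)
    if not kept:
        raise ValueError("no modules pass the 1/3 expression-coverage filter")
    return FilteredModuleSet(ModuleSet(kept), dropped, coverage)


def delete_edges(
    network: InteractomeNetwork, fraction: float, seed: int
) -> InteractomeNetwork:
    """Remove ``round(fraction * |E|)`` edges uniformly at random.

    The node set is unchanged (nodes may become isolated). Rounding is
    half-up. Reproducible for a given seed; a fraction that rounds to zero
    removals returns the network unchanged with a warning.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    edges = sorted(tuple(sorted(e)) for e in network.graph.edges)
    n_remove = math.floor(fraction * len(edges) + 0.5)
    if n_remove == 0:
        logger.warning("delete_edges: fraction %.3f removes no edges on %d-edge graph",
                       fraction, len(edges))
        return InteractomeNetwork(network.graph.copy())
    rng = np.random.default_rng(seed)
    drop_idx = set(rng.choice(len(edges), size=n_remove, replace=False).tolist())
    g = network.graph.copy()
    g.remove_edges_from(e for i, e in enumerate(edges) if i in drop_idx)
    return InteractomeNetwork(g)


def make_random_network_suite(
    network: InteractomeNetwork,
    fractions: list[float] = (0.05, 0.10, 0.15, 0.20),
    n_per_fraction: int = 50,
    seed: int = 0,
) -> list[tuple[float, int, InteractomeNetwork]]:
    """Generate replicate edge-deleted networks per deletion fraction.

    Returns ``(fraction, replicate_index, network)`` triples — 4 x 50 = 200
    networks at the defaults. Per-replicate seeds are derived from ``seed``.
    """
    if n_per_fraction < 1:
        raise ValueError("n_per_fraction must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(fractions) * n_per_fraction
    ) % (2**31)
    out = []
    i = 0
    for frac in fractions:
        for rep in range(n_per_fraction):
            out.append((frac, rep, delete_edges(network, frac, int(child_seeds[i]))))
            i += 1
    return out


def sweep_module_sets(
    candidates: list[tuple[object, ModuleSet]],
    expr: pd.DataFrame,
    labels: pd.Series,
    clinical: pd.DataFrame | None = None,
    config=None,
    n_folds: int = 5,
    n_repeats: int = 5,
    master_seed: int = 0,
):
    """Run the CV pipeline on each candidate module set; keep the best.

    Candidates are ``(params, ModuleSet)`` pairs — typically one per point of
    a clustering-parameter sweep (e.g. ClusterONE's size/density grid). The
    winner maximises the median per-repeat AUC; ties go to the earliest
    candidate. Every candidate sees the identical CV plan, so differences are
    attributable to the module sets alone.

    Returns ``(best_params, best_module_set, per_candidate)`` where
    ``per_candidate`` is a list of ``(params, median_auc)``.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    from .evaluation import make_cv_plan, run_cv  # local import: avoids cycle

    plan = make_cv_plan(labels, n_folds=n_folds, n_repeats=n_repeats,
                        master_seed=master_seed)
    per_candidate: list[tuple[object, float]] = []
    best = None
    for params, mset in candidates:
        report = run_cv(expr, mset, labels, clinical=clinical, plan=plan,
                        config=config)
        med = float(np.median(report.per_repeat_aucs()))
        per_candidate.append((params, med))
        if best is None or med > best[2]:
            best = (params, mset, med)
    return best[0], best[1], per_candidate
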