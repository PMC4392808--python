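"""Readers/writers for the pipeline's external formats and prognosis-label derivation.

All tabular files are UTF-8 text. Lines starting with ``#`` are comments.
Network and module files accept any whitespace as a separator; matrices and
tables are tab-separated. Every writer here produces a file its reader
round-trips.

Gene identifiers are plain case-sensitive symbols; identifier mapping is the
caller's concern. Missing expression values stay missing (``NaN``) — they are
never imputed at this layer.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_NA_STRINGS = {"", "NA", "NaN", "nan", "na", "NULL"}

__all__ = [
    "InteractomeNetwork",
    "ModuleSet",
    "read_network",
    "write_network",
    "read_modules",
    "write_modules",
    "read_expression",
    "write_expression",
    "read_outcomes",
    "write_outcomes",
    "read_clinical",
    "write_clinical",
    "encode_clinical",
    "read_gene_list",
    "write_gene_list",
    "derive_labels",
]


@dataclass(frozen=True)
class InteractomeNetwork:
    """Undirected protein-interaction network: no self-loops, no duplicate edges."""

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
    ) -> "InteractomeNetwork":
        g = nx.Graph()
        g.add_nodes_from(extra_nodes)
        for a, b in edges:
            if a == b:
                continue
            g.add_edge(a, b)
        return cls(g)


@dataclass
class ModuleSet:
    """Ordered, possibly overlapping gene-membership modules.

    The same gene may belong to several modules (pleiotropy is the point of
    overlapping module detection); module ids are unique.
    """

    modules: list[tuple[str, frozenset]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [mid for mid, _ in self.modules]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate module ids")
        for mid, members in self.modules:
            if len(members) == 0:
                raise ValueError(f"module {mid!r} has no members")

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    @property
    def ids(self) -> list[str]:
        return [mid for mid, _ in self.modules]

    def members(self, module_id: str) -> frozenset:
        for mid, mem in self.modules:
            if mid == module_id:
                return mem
        raise KeyError(module_id)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, mem in self.modules:
            out |= mem
        return out


# ---------------------------------------------------------------------------
# network edge lists


def read_network(path: str | Path) -> InteractomeNetwork:
    """Read a whitespace-separated two-column edge list.

    Self-loops are dropped and duplicate edges collapsed (counts logged).
    """
    path = Path(path)
    g = nx.Graph()
    n_self, n_dup, n_lines = 0, 0, 0
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#node"):
                tokens = line.split()
                if len(tokens) >= 2:
                    g.add_node(tokens[1])
                continue
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns, got {line!r}")
            a, b = tokens[0], tokens[1]
            n_lines += 1
            if a == b:
                n_self += 1
                g.add_node(a)
                continue
            if g.has_edge(a, b):
                n_dup += 1
                continue
            g.add_edge(a, b)
    if n_lines == 0:
        raise ValueError(f"{path}: empty network file")
    if n_self or n_dup:
        logger.info(
            "read_network(%s): dropped %d self-loops, collapsed %d duplicates",
            path, n_self, n_dup,
        )
    return InteractomeNetwork(g)


def write_network(network: InteractomeNetwork, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{a}\t{b}\n")
        # isolated nodes are kept as degenerate comment records so the node
        # set survives a round trip through delete_edges output
        isolated = sorted(n for n in network.graph.nodes if network.graph.degree[n] == 0)
        for n in isolated:
            fh.write(f"#node\t{n}\n")


# ---------------------------------------------------------------------------
# module membership files


def read_modules(path: str | Path) -> ModuleSet:
    """Read one module per line (whitespace-separated member symbols).

    A leading ``<id>:`` token names the module; otherwise ids are assigned
    ``M1..Mn`` in line order. Empty lines are skipped with a warning.
    """
    path = Path(path)
    modules: list[tuple[str, frozenset]] = []
    idx = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                continue
            if not line:
                logger.warning("read_modules(%s): skipping empty line %d", path, lineno)
                continue
            tokens = line.split()
            idx += 1
            if tokens[0].endswith(":"):
                mid = tokens[0][:-1]
                members = tokens[1:]
            else:
                mid = f"M{idx}"
                members = tokens
            if not members:
                raise ValueError(f"{path}:{lineno}: module {mid!r} has no members")
            modules.append((mid, frozenset(members)))
    if not modules:
        raise ValueError(f"{path}: no modules found")
    return ModuleSet(modules)


def write_modules(modules: ModuleSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for mid, members in modules:
            fh.write(f"{mid}: " + " ".join(sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x patients TSV (header row = patient IDs, first column = gene).

    Blank/NA cells become ``NaN``. Ragged rows and duplicate gene or patient
    IDs are errors.
    """
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")
                if r and not (r[0].startswith("#"))]
    if not rows:
        raise ValueError(f"{path}: empty expression file")
    header = rows[0]
    patients = header[1:]
    if len(set(patients)) != len(patients):
        raise ValueError(f"{path}: duplicate patient IDs in header")
    ncol = len(header)
    genes: list[str] = []
    data: list[list[float]] = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise ValueError(
                f"{path}: row {i} has {len(row)} columns, expected {ncol}"
            )
        genes.append(row[0])
        data.append(
            [np.nan if c.strip() in _NA_STRINGS else float(c) for c in row[1:]]
        )
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"{path}: duplicate gene rows {dupes}")
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=patients, dtype=float)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(Path(path), sep="\t", na_rep="NA", index_label="gene")


# ---------------------------------------------------------------------------
# outcome, clinical and gene-list tables


def read_outcomes(path: str | Path) -> pd.DataFrame:
    """Outcome TSV: patient_id, time_years, event (0/1), event_type."""
    df = pd.read_csv(Path(path), sep="\t", comment="#", dtype={"patient_id": str})
    required = {"patient_id", "time_years", "event", "event_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: outcome table missing columns {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate patient IDs")
    if (df["time_years"] < 0).any():
        raise ValueError(f"{path}: negative follow-up times")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event indicator must be 0/1")
    return df.set_index("patient_id")


def write_outcomes(outcomes: pd.DataFrame, path: str | Path) -> None:
    outcomes.to_csv(Path(path), sep="\t", index_label="patient_id")


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", comment="#", dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise ValueError(f"{path}: clinical table needs a patient_id column")
    if df["patient_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate patient IDs")
    return df.set_index("patient_id")


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(Path(path), sep="\t", index_label="patient_id")


def encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Encode a mixed clinical table to numeric covariates.

    Numeric columns pass through; categorical columns are one-hot encoded with
    deterministic ``col=value`` names in sorted category order.
    """
    parts: list[pd.DataFrame] = []
    for col in clinical.columns:
        s = clinical[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float).to_frame(col))
        else:
            cats = sorted(s.dropna().astype(str).unique())
            onehot = pd.DataFrame(
                {f"{col}={c}": (s.astype(str) == c).astype(float) for c in cats},
                index=s.index,
            )
            parts.append(onehot)
    if not parts:
        return pd.DataFrame(index=clinical.index)
    return pd.concat(parts, axis=1)


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line (Cancer Gene Census export style)."""
    out: set[str] = set()
    with Path(path).open(encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.add(line.split()[0])
    if not out:
        raise ValueError(f"{path}: empty gene list")
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# label derivation


def derive_labels(
    outcomes: pd.DataFrame,
    cutoff_k: float,
    event_type: str | None = None,
) -> tuple[pd.Series, list[str]]:
    """Derive binary prognosis labels from right-censored follow-up records.

    A patient is *bad* (1) if the event occurred within ``cutoff_k`` years and
    *good* (0) if followed event-free for at least ``cutoff_k`` years. Patients
    censored before the cutoff carry no usable outcome and are excluded.

    Returns ``(labels, excluded_ids)``; ``labels`` is an int Series indexed by
    patient ID. Raising the cutoff can only keep a good-at-k patient good at
    every smaller cutoff (monotone by construction).
    """
    if cutoff_k <= 0:
        raise ValueError("cutoff_k must be positive")
    table = outcomes
    if event_type is not None:
        table = table[table["event_type"] == event_type]
        if table.empty:
            raise ValueError(f"no outcome rows with event_type={event_type!r}")
    labels: dict[str, int] = {}
    excluded: list[str] = []
    for pid, row in table.iterrows():
        t, ev = float(row["time_years"]), int(row["event"])
        if t >= cutoff_k:
            labels[pid] = 0
        elif ev == 1:
            labels[pid] = 1
        else:
            excluded.append(pid)
    if not labels:
        raise ValueError("no patients remain after excluding those censored before the cutoff")
    return pd.Series(labels, name="label", dtype=int), excluded
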