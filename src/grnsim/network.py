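"""Synthetic regulatory-network geometry.

Networks are grown as d-dimensional simplicial complexes (growth with an
energy/flavor attachment rule), merged into a single graph by random
edge insertion, and finally partitioned into activator and repressor
subnetworks ``A`` and ``R`` with full adjacency ``N = A + R``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np

from .powerlaw import PowerLawFit, fit_discrete_powerlaw

__all__ = [
    "AdjacencyFormatError",
    "BasalGeometrySpec",
    "RegulatoryNetwork",
    "ConnectivityReport",
    "grow_simplicial_complex",
    "merge_basal_networks",
    "partition_regulators",
    "read_adjacency",
    "write_adjacency",
    "connectivity_report",
    "generate_network",
]

_VALID_FLAVORS = (-1, 0, 1)
_N_ENERGY_LEVELS = 10  # node energies drawn uniformly from 0..9


class AdjacencyFormatError(ValueError):
    """Raised when an adjacency file cannot be parsed."""


@dataclass(frozen=True)
class BasalGeometrySpec:
    """Configuration of one basal network geometry.

    ``shape_params`` is ``(flavor, inverse_temperature)``: the flavor
    (an integer in {-1, 0, 1}) selects the attachment rule and the
    inverse temperature weights faces by random node energies.
    """

    dimension: int
    gene_fraction: float
    shape_params: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.dimension not in (1, 2, 3):
            raise ValueError(f"dimension must be 1, 2 or 3, got {self.dimension}")
        if not (0.0 <= self.gene_fraction <= 1.0):
            raise ValueError(f"gene_fraction must be in [0, 1], got {self.gene_fraction}")
        if len(self.shape_params) != 2 or not all(
            math.isfinite(p) for p in self.shape_params
        ):
            raise ValueError(f"shape_params must be two finite reals, got {self.shape_params}")
        if int(round(self.shape_params[0])) not in _VALID_FLAVORS:
            raise ValueError(f"flavor (first shape param) must be in {_VALID_FLAVORS}")

    @property
    def flavor(self) -> int:
        return int(round(self.shape_params[0]))

    @property
    def inverse_temperature(self) -> float:
        return float(self.shape_params[1])


@dataclass(eq=False)
class RegulatoryNetwork:
    """Directed regulatory network split into activation and repression.

    Entry ``A[j, i] == 1`` means gene ``j`` activates gene ``i``;
    ``R[j, i] == 1`` means gene ``j`` represses gene ``i``.
    """

    A: np.ndarray
    R: np.ndarray
    core_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    core_weights: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.int8)
        self.R = np.asarray(self.R, dtype=np.int8)
        self.core_indices = np.asarray(self.core_indices, dtype=np.int64)
        self.core_weights = np.asarray(self.core_weights, dtype=float)
        n = self.A.shape[0]
        for name, m in (("A", self.A), ("R", self.R)):
            if m.ndim != 2 or m.shape != (n, n):
                raise ValueError(f"{name} must be square of shape ({n}, {n})")
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"{name} must be binary")
            if np.any(np.diag(m) != 0):
                raise ValueError(f"{name} must have a zero diagonal (no self-regulation)")
        if np.any((self.A == 1) & (self.R == 1)):
            raise ValueError("A and R must have disjoint supports")
        if self.core_indices.size != self.core_weights.size:
            raise ValueError("core_indices and core_weights must have equal length")
        if self.core_indices.size:
            if self.core_indices.min() < 0 or self.core_indices.max() >= n:
                raise ValueError("core gene index out of range")
            if np.unique(self.core_indices).size != self.core_indices.size:
                raise ValueError("core gene indices must be unique")
            if not np.all(np.isfinite(self.core_weights)) or np.any(self.core_weights < 0):
                raise ValueError("core weights must be finite and nonnegative")

    @property
    def n_genes(self) -> int:
        return int(self.A.shape[0])

    @property
    def N(self) -> np.ndarray:
        """Full adjacency, N = A + R."""
        return (self.A + self.R).astype(np.int8)

    @property
    def core_genes(self) -> list[tuple[int, float]]:
        return [(int(i), float(w)) for i, w in zip(self.core_indices, self.core_weights)]


@dataclass
class ConnectivityReport:
    in_degree_histogram: dict[int, int]
    out_degree_histogram: dict[int, int]
    powerlaw_exponent_in: float | None
    powerlaw_exponent_out: float | None
    fit_xmin_in: int | None
    fit_xmin_out: int | None
    fit_method: str = "discrete-mle-ks"


def grow_simplicial_complex(
    spec: BasalGeometrySpec, n_nodes: int, seed=None
) -> nx.Graph:
    """Grow a connected graph by gluing d-simplexes onto (d-1)-faces.

    Growth starts from a single d-simplex; each step attaches one new node
    by gluing a fresh d-simplex onto an existing (d-1)-face selected with
    probability proportional to ``exp(-beta * energy) * (1 + flavor * n)``
    where ``n`` counts how many extra simplexes already share the face.
    """
    d = spec.dimension
    if n_nodes < d + 1:
        raise ValueError(f"n_nodes must be >= {d + 1} for dimension {d}, got {n_nodes}")
    flavor = spec.flavor
    beta = spec.inverse_temperature
    rng = np.random.default_rng(seed)
    energies = rng.integers(0, _N_ENERGY_LEVELS, size=n_nodes)

    edges: list[tuple[int, int]] = []
    # parallel arrays over (d-1)-faces: member nodes, saturation count, energy weight
    face_nodes: list[tuple[int, ...]] = []
    face_count: list[int] = []
    face_wt: list[float] = []

    def _add_face(nodes: tuple[int, ...]) -> None:
        face_nodes.append(nodes)
        face_count.append(0)
        face_wt.append(math.exp(-beta * float(energies[list(nodes)].sum())))

    base = tuple(range(d + 1))
    edges.extend(combinations(base, 2))
    for f in combinations(base, d):
        _add_face(f)

    for new in range(d + 1, n_nodes):
        weights = np.asarray(face_wt) * (1.0 + flavor * np.asarray(face_count))
        np.maximum(weights, 0.0, out=weights)
        total = weights.sum()
        if total <= 0:
            raise RuntimeError("no attachable faces left (saturated growth)")
        idx = int(rng.choice(len(face_nodes), p=weights / total))
        chosen = face_nodes[idx]
        face_count[idx] += 1
        edges.extend((u, new) for u in chosen)
        for f in combinations(chosen + (new,), d):
            if new in f:
                _add_face(f)

    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    g.add_edges_from(edges)
    return g


def merge_basal_networks(
    graphs, edge_rate: float, iterations: int, seed=None
) -> nx.Graph:
    """Disjoint union of ``graphs`` plus random bridging edges.

    Each iteration inserts exactly ``max(1, round(edge_rate * |V|))`` new
    distinct edges between uniformly chosen non-adjacent node pairs
    (collisions are resampled so the count is exact).
    """
    graphs = list(graphs)
    if not graphs:
        raise ValueError("at least one graph is required")
    if not edge_rate > 0:
        raise ValueError(f"edge_rate must be > 0, got {edge_rate}")
    if iterations < 0:
        raise ValueError(f"iterations must be >= 0, got {iterations}")
    g = nx.disjoint_union_all(graphs) if len(graphs) > 1 else nx.convert_node_labels_to_integers(graphs[0])
    rng = np.random.default_rng(seed)
    n = g.number_of_nodes()
    for _ in range(iterations):
        k = max(1, int(round(edge_rate * n)))
        available = n * (n - 1) // 2 - g.number_of_edges()
        if k > available:
            raise ValueError(
                f"cannot add {k} edges: merged graph with {n} nodes has only "
                f"{available} free node pairs (saturated)"
            )
        added = 0
        while added < k:
            u, v = (int(x) for x in rng.integers(0, n, size=2))
            if u == v or g.has_edge(u, v):
                continue
            g.add_edge(u, v)
            added += 1
    return g


def partition_regulators(
    graph: nx.Graph, activation_fraction: float = 0.5, seed=None
) -> RegulatoryNetwork:
    """Orient and label each undirected edge as activation or repression.

    Direction is chosen uniformly at random per edge; the edge becomes an
    activation with probability ``activation_fraction``, else a repression.
    """
    if not (0.0 <= activation_fraction <= 1.0):
        raise ValueError(f"activation_fraction must be in [0, 1], got {activation_fraction}")
    nodes = sorted(graph.nodes())
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n), dtype=np.int8)
    R = np.zeros((n, n), dtype=np.int8)
    rng = np.random.default_rng(seed)
    for u, v in sorted(tuple(sorted((index[a], index[b]))) for a, b in graph.edges()):
        if u == v:
            continue  # self-loops are never regulatory
        src, tgt = (u, v) if rng.random() < 0.5 else (v, u)
        if rng.random() < activation_fraction:
            A[src, tgt] = 1
        else:
            R[src, tgt] = 1
    return RegulatoryNetwork(A=A, R=R)


def write_adjacency(matrix: np.ndarray, path) -> None:
    """Write a square binary matrix as whitespace-delimited 0/1 text."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"adjacency matrix must be square, got shape {m.shape}")
    if not np.isin(m, (0, 1)).all():
        raise ValueError("adjacency matrix must be binary")
    with open(path, "w") as fh:
        for row in m.astype(np.int8):
            fh.write(" ".join(str(int(v)) for v in row))
            fh.write("\n")


def read_adjacency(path) -> np.ndarray:
    """Read a matrix written by :func:`write_adjacency` (bit-exact roundtrip)."""
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tokens = line.split()
            row = []
            for tok in tokens:
                if tok not in ("0", "1"):
                    raise AdjacencyFormatError(
                        f"{path}: line {lineno}: non-binary token {tok!r}"
                    )
                row.append(int(tok))
            if rows and len(row) != len(rows[0]):
                raise AdjacencyFormatError(
                    f"{path}: line {lineno}: expected {len(rows[0])} columns, got {len(row)}"
                )
            rows.append(row)
    if not rows:
        raise AdjacencyFormatError(f"{path}: empty adjacency file")
    m = np.asarray(rows, dtype=np.int8)
    if m.shape[0] != m.shape[1]:
        raise AdjacencyFormatError(
            f"{path}: matrix is {m.shape[0]}x{m.shape[1]}, expected square"
        )
    return m


def connectivity_report(network: RegulatoryNetwork) -> ConnectivityReport:
    """Degree histograms of N plus discrete power-law tail fits."""
    if network.n_genes == 0:
        raise ValueError("network is empty")
    N = network.N
    in_deg = np.asarray(N.sum(axis=0)).ravel()
    out_deg = np.asarray(N.sum(axis=1)).ravel()

    def _hist(deg: np.ndarray) -> dict[int, int]:
        counts = np.bincount(deg)
        return {int(k): int(c) for k, c in enumerate(counts) if c > 0}

    fit_in = fit_discrete_powerlaw(in_deg)
    fit_out = fit_discrete_powerlaw(out_deg)

    def _exp(fit: PowerLawFit):
        return (float(fit.alpha), int(fit.xmin)) if fit.converged else (None, None)

    alpha_in, xmin_in = _exp(fit_in)
    alpha_out, xmin_out = _exp(fit_out)
    return ConnectivityReport(
        in_degree_histogram=_hist(in_deg),
        out_degree_histogram=_hist(out_deg),
        powerlaw_exponent_in=alpha_in,
        powerlaw_exponent_out=alpha_out,
        fit_xmin_in=xmin_in,
        fit_xmin_out=xmin_out,
    )


def _allocate_nodes(specs, n_genes: int) -> list[int]:
    fractions = np.array([s.gene_fraction for s in specs], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"gene fractions must sum to 1, got {fractions.sum()}")
    raw = fractions * n_genes
    counts = np.floor(raw).astype(int)
    # largest-remainder rounding so counts sum exactly to n_genes
    for i in np.argsort(raw - counts)[::-1][: n_genes - counts.sum()]:
        counts[i] += 1
    for spec, c in zip(specs, counts):
        if c > 0 and c < spec.dimension + 1:
            raise ValueError(
                f"basal geometry d={spec.dimension} needs >= {spec.dimension + 1} "
                f"nodes, allocated {c}"
            )
    return [int(c) for c in counts]


def generate_network(
    n_genes: int,
    specs,
    edge_rate: float = 0.02,
    iterations: int = 1,
    activation_fraction: float = 0.5,
    seed=None,
    core_indices=None,
    core_weights=None,
    n_core: int = 0,
) -> RegulatoryNetwork:
    """Full geometry pipeline: grow basal complexes, merge, partition.

    Core genes are taken from ``core_indices`` when given, otherwise
    ``n_core`` genes are picked uniformly at random with equal weights.
    """
    specs = list(specs)
    root = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    children = root.spawn(len(specs) + 3)
    counts = _allocate_nodes(specs, n_genes)
    graphs = [
        grow_simplicial_complex(spec, c, child)
        for spec, c, child in zip(specs, counts, children)
        if c > 0
    ]
    merged = merge_basal_networks(graphs, edge_rate, iterations, children[-3])
    net = partition_regulators(merged, activation_fraction, children[-2])
    if core_indices is not None:
        idx = np.asarray(core_indices, dtype=np.int64)
        if core_weights is None:
            w = np.full(idx.size, 1.0 / idx.size) if idx.size else np.empty(0)
        else:
            w = np.asarray(core_weights, dtype=float)
    elif n_core > 0:
        rng = np.random.default_rng(children[-1])
        idx = np.sort(rng.choice(n_genes, size=n_core, replace=False))
        w = np.full(n_core, 1.0 / n_core)
    else:
        idx = np.empty(0, dtype=np.int64)
        w = np.empty(0, dtype=float)
    return RegulatoryNetwork(A=net.A, R=net.R, core_indices=idx, core_weights=w)
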