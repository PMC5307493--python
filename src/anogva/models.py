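"""Graph containers and the five random-graph models used in the simulation study.

All generators return a :class:`Graph` with a symmetric, zero-diagonal binary
adjacency matrix and are deterministic for a fixed seed.  Model parameters in
the simulations are drawn per graph from a truncated normal law and linearly
normalized to [0, 1] by the upper truncation bound.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

logger = logging.getLogger("anogva")

RngLike = "int | np.random.Generator | np.random.SeedSequence | None"


def as_rng(seed) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Graph:
    """Undirected graph stored as a dense symmetric adjacency matrix.

    The adjacency is binary for simulated graphs and real-valued for
    connectivity graphs; the diagonal is always zero.
    """

    adjacency: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if a.shape[0] < 1:
            raise ValueError("graph needs at least one vertex")
        if not np.allclose(a, a.T, atol=1e-8):
            raise ValueError("adjacency must be symmetric")
        a = (a + a.T) / 2.0  # exact symmetry for the eigensolver
        np.fill_diagonal(a, 0.0)
        self.adjacency = a

    @property
    def n_vertices(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    def degrees(self) -> np.ndarray:
        return np.count_nonzero(self.adjacency, axis=1)


@dataclass
class GraphPopulation:
    """Named, ordered sample of graphs assumed to come from one random process.

    All members must share the vertex count so their spectra can be compared
    on a common grid.
    """

    name: str
    graphs: list[Graph] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.graphs:
            raise ValueError(f"population {self.name!r} is empty")
        n0 = self.graphs[0].n_vertices
        if any(g.n_vertices != n0 for g in self.graphs):
            raise ValueError(
                f"population {self.name!r}: all graphs must have the same vertex count"
            )

    def __len__(self) -> int:
        return len(self.graphs)

    @property
    def n_vertices(self) -> int:
        return self.graphs[0].n_vertices


@dataclass(frozen=True)
class ParameterLaw:
    """Truncated normal law for per-graph model parameters.

    Draws live in [lower, upper] and are normalized to [0, 1] by dividing by
    ``upper``, matching the convention that the normalized value is fed to a
    generator whose natural parameter lives on the unit interval.
    """

    lower: float = 0.0
    upper: float = 10.0
    mean: float = 1.0
    variance: float = 1.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("invalid law: lower must be < upper")
        if not self.variance > 0:
            raise ValueError("invalid law: variance must be positive")


def sample_parameters(law: ParameterLaw, count: int, rng=None) -> np.ndarray:
    """Draw ``count`` normalized parameters from a truncated normal law.

    Sampling is by inverse CDF on the truncated interval, so a fixed seed
    gives a fixed sample with no rejection-loop drift.  Returned values are
    the raw draws divided by ``law.upper`` and therefore lie in [0, 1].
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    sd = math.sqrt(law.variance)
    a = (law.lower - law.mean) / sd
    b = (law.upper - law.mean) / sd
    rng = as_rng(rng)
    u = rng.uniform(size=count)
    draws = stats.truncnorm.ppf(u, a, b, loc=law.mean, scale=sd)
    return draws / law.upper


def truncated_normal_mean(law: ParameterLaw) -> float:
    """Closed-form mean of the normalized truncated normal law."""
    sd = math.sqrt(law.variance)
    a = (law.lower - law.mean) / sd
    b = (law.upper - law.mean) / sd
    return float(stats.truncnorm.mean(a, b, loc=law.mean, scale=sd) / law.upper)


def integer_parameter(theta: float) -> int:
    """Map a normalized parameter in [0, 1] to an integer: floor(10 * theta).

    Used for generators whose natural parameter is an integer (vertex degree
    of the regular model, preferential-attachment exponent).  May return 0;
    callers that cannot accept 0 must resample.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must lie in [0, 1], got {theta}")
    return int(math.floor(10.0 * theta))


# ---------------------------------------------------------------------------
# random-graph generators
# ---------------------------------------------------------------------------

def _graph_from_edges(n: int, edges: np.ndarray, label: str | None) -> Graph:
    a = np.zeros((n, n))
    if len(edges):
        e = np.asarray(edges)
        a[e[:, 0], e[:, 1]] = 1.0
        a[e[:, 1], e[:, 0]] = 1.0
    return Graph(a, label=label)


def erdos_renyi(n: int, p: float, rng=None, label: str | None = None) -> Graph:
    """Erdős–Rényi G(n, p): each unordered vertex pair is an edge w.p. ``p``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"edge probability must lie in [0, 1], got {p}")
    rng = as_rng(rng)
    iu = np.triu_indices(n, k=1)
    mask = rng.uniform(size=len(iu[0])) < p
    a = np.zeros((n, n))
    a[iu[0][mask], iu[1][mask]] = 1.0
    return Graph(a + a.T, label=label)


def geometric_graph(n: int, radius: float, dim: int = 2, rng=None,
                    label: str | None = None) -> Graph:
    """Random geometric graph: uniform points in the unit hypercube, edge iff
    Euclidean distance strictly below ``radius`` (no torus wrap)."""
    if n < 1 or dim < 1:
        raise ValueError("n and dim must be >= 1")
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    rng = as_rng(rng)
    pts = rng.uniform(size=(n, dim))
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    a = (d2 < radius * radius).astype(float)
    np.fill_diagonal(a, 0.0)
    return Graph(a, label=label)


def k_regular(n: int, deg: int, rng=None, label: str | None = None) -> Graph:
    """Random simple graph with every vertex of degree ``deg`` (pairing model)."""
    if not 0 <= deg < n:
        raise ValueError(f"degree must satisfy 0 <= deg < n, got deg={deg}, n={n}")
    if (n * deg) % 2 != 0:
        raise ValueError(f"infeasible degree sequence: n*deg = {n * deg} is odd")
    rng = as_rng(rng)
    g = nx.random_regular_graph(deg, n, seed=rng)
    a = nx.to_numpy_array(g, nodelist=range(n))
    return Graph(a, label=label)


def watts_strogatz(n: int, nei: int, p_w: float, rng=None, dim: int = 1,
                   label: str | None = None) -> Graph:
    """Watts–Strogatz small-world graph on a one-dimensional ring lattice.

    Starts from a ring where each vertex connects to its ``nei`` nearest
    neighbours on either side, then walks the lattice edges lap by lap
    (distance 1 first, then 2, ...), rewiring each edge independently with
    probability ``p_w``.  Rewiring keeps the lattice-order endpoint and
    re-targets the other end uniformly, redrawing on self-loops and duplicate
    edges, so the edge count ``n * nei`` is conserved exactly.
    """
    if dim != 1:
        raise ValueError("only one-dimensional ring lattices are supported")
    if n <= 2 * nei:
        raise ValueError(f"invalid lattice: need n > 2*nei, got n={n}, nei={nei}")
    if not 0.0 <= p_w <= 1.0:
        raise ValueError(f"rewiring probability must lie in [0, 1], got {p_w}")
    rng = as_rng(rng)
    adj: list[set[int]] = [set() for _ in range(n)]
    for d in range(1, nei + 1):
        for v in range(n):
            adj[v].add((v + d) % n)
            adj[(v + d) % n].add(v)
    for d in range(1, nei + 1):          # one lap per neighbour distance
        for v in range(n):
            w = (v + d) % n
            if rng.uniform() >= p_w:
                continue
            if w not in adj[v]:          # already rewired away earlier this lap
                continue
            # re-target the clockwise endpoint, keeping v
            candidates = [u for u in range(n) if u != v and u not in adj[v]]
            if not candidates:
                continue                 # v saturated; leave the edge alone
            u = candidates[rng.integers(len(candidates))]
            adj[v].discard(w)
            adj[w].discard(v)
            adj[v].add(u)
            adj[u].add(v)
    a = np.zeros((n, n))
    for v in range(n):
        for u in adj[v]:
            a[v, u] = 1.0
    return Graph(a, label=label)


def barabasi_albert(n: int, power: float = 1.0, m1: int = 1, n0: int = 1,
                    rng=None, label: str | None = None) -> Graph:
    """Preferential attachment with attachment probability ∝ degree**power.

    Starts from ``n0`` isolated seed vertices; each arriving vertex connects
    to ``m1`` distinct existing vertices.  ``0**0`` is taken as 1, and when
    every existing vertex has zero attachment weight targets are chosen
    uniformly (this covers the start-up steps of the default seed graph).
    """
    if power < 0:
        raise ValueError("power must be nonnegative")
    if not 1 <= m1 <= n0:
        raise ValueError(f"need 1 <= m1 <= n0, got m1={m1}, n0={n0}")
    if n0 >= n:
        raise ValueError("n0 must be smaller than n")
    rng = as_rng(rng)
    deg = np.zeros(n)
    a = np.zeros((n, n))
    for v in range(n0, n):
        d = deg[:v]
        with np.errstate(divide="ignore"):
            w = np.where(d > 0, d ** power, 1.0 if power == 0 else 0.0)
        total = w.sum()
        if total <= 0:
            w = np.ones(v)
            total = float(v)
        targets = rng.choice(v, size=m1, replace=False, p=w / total)
        for t in targets:
            a[v, t] = a[t, v] = 1.0
            deg[t] += 1
            deg[v] += 1
    return Graph(a, label=label)
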