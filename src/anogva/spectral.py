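"""Adjacency spectra, kernel spectral-density estimation, KL divergence, Δ.

The spectral density of a random graph is estimated in three steps: compute
the eigenvalues of the adjacency matrix, smooth them with a Gaussian kernel
(Nadaraya–Watson estimator), and renormalize so the curve integrates to one.
The kernel bandwidth is (λ1 − λn) / bins with the bin count from Sturges'
rule.  Population densities are averages of per-graph densities; the test
statistic Δ sums the KL divergences of the k population densities to their
pointwise mean, a k-group generalization of the Jensen–Shannon divergence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .models import Graph, GraphPopulation

logger = logging.getLogger("anogva")

_KL_TOL = 1e-12          # mass below this is treated as zero in the KL integrand
_INTEGRAL_TOL = 1e-6

_SCALE_MODES = ("none", "n", "sqrt_n")


@dataclass
class Spectrum:
    """Eigenvalues of one graph's adjacency matrix, sorted descending.

    ``scale_mode`` divides each eigenvalue by 1, n or sqrt(n).  When every
    graph in an analysis has the same vertex count the choice is immaterial:
    Δ and the permutation p-value are invariant under a common affine
    rescaling of all spectra (the grid rescales with them).
    """

    eigenvalues: np.ndarray
    scale_mode: str = "none"

    def __post_init__(self) -> None:
        ev = np.sort(np.asarray(self.eigenvalues, dtype=float))[::-1]
        self.eigenvalues = ev

    @property
    def n(self) -> int:
        return len(self.eigenvalues)


@dataclass
class SpectralDensity:
    """Density values on a shared, strictly increasing grid; trapezoid
    integral equal to one."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have the same length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.values < -1e-12):
            raise ValueError("density values must be nonnegative")
        total = np.trapezoid(self.values, self.grid)
        if abs(total - 1.0) > _INTEGRAL_TOL:
            raise ValueError(f"density must integrate to 1, got {total!r}")

    def integral(self) -> float:
        return float(np.trapezoid(self.values, self.grid))


@dataclass(frozen=True)
class DensityEstimationConfig:
    """Plumbing knobs for density estimation (grid size, margin, scaling)."""

    grid_points: int = 512
    grid_margin: float = 3.0       # in units of the largest per-graph bandwidth
    scale_mode: str = "none"

    def __post_init__(self) -> None:
        if self.grid_points < 16:
            raise ValueError("grid_points must be >= 16")
        if self.grid_margin < 0:
            raise ValueError("grid_margin must be nonnegative")
        if self.scale_mode not in _SCALE_MODES:
            raise ValueError(f"scale_mode must be one of {_SCALE_MODES}")


def compute_spectrum(graph: Graph, scale_mode: str = "none") -> Spectrum:
    """Eigenvalues of the (possibly weighted) adjacency, scaled and sorted."""
    if scale_mode not in _SCALE_MODES:
        raise ValueError(f"scale_mode must be one of {_SCALE_MODES}")
    a = graph.adjacency
    if not np.allclose(a, a.T, atol=1e-8):
        raise ValueError("adjacency must be symmetric")
    ev = np.linalg.eigvalsh(a)
    if scale_mode == "n":
        ev = ev / graph.n_vertices
    elif scale_mode == "sqrt_n":
        ev = ev / math.sqrt(graph.n_vertices)
    return Spectrum(ev, scale_mode=scale_mode)


def sturges_bins(count: int) -> int:
    """Sturges' rule: ceil(log2(count) + 1) histogram bins for ``count`` points."""
    if count < 1:
        raise ValueError("count must be >= 1")
    return max(1, math.ceil(math.log2(count) + 1.0))


def bandwidth(spectrum: Spectrum) -> float:
    """Kernel bandwidth (λ1 − λn) / Sturges-bins, with a degenerate fallback.

    When all eigenvalues coincide (edgeless or complete-regular graphs) the
    spread is zero and the bandwidth falls back to a small positive value so
    the kernel stays proper.
    """
    ev = spectrum.eigenvalues
    if len(ev) == 0:
        raise ValueError("empty spectrum")
    spread = float(ev[0] - ev[-1])
    if spread <= 0.0:
        fallback = max(1e-3, abs(float(ev[0])) * 1e-3)
        logger.warning("degenerate spectrum spread; falling back to bandwidth %g",
                       fallback)
        return fallback
    return spread / sturges_bins(len(ev))


def make_grid(spectra: list[Spectrum],
              config: DensityEstimationConfig = DensityEstimationConfig()) -> np.ndarray:
    """Shared evaluation grid covering every spectrum plus a kernel margin.

    The grid spans [min λ − margin·h_max, max λ + margin·h_max] over all
    spectra, so every density entering a KL computation sits on identical
    support and the average density is a valid reference measure.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    lo = min(float(s.eigenvalues[-1]) for s in spectra)
    hi = max(float(s.eigenvalues[0]) for s in spectra)
    h = max(bandwidth(s) for s in spectra)
    pad = config.grid_margin * h
    if hi + pad <= lo - pad:
        pad = max(pad, 0.5)
    return np.linspace(lo - pad, hi + pad, config.grid_points)


def estimate_density(spectrum: Spectrum, grid: np.ndarray,
                     config: DensityEstimationConfig = DensityEstimationConfig(),
                     bw: float | None = None) -> SpectralDensity:
    """Gaussian-kernel density of the eigenvalues on ``grid``, renormalized.

    Each eigenvalue contributes a Gaussian bump of width ``bw`` (default: the
    Sturges-based bandwidth of this spectrum); the curve is then rescaled so
    its trapezoid integral over the grid is exactly one.  The effective
    width is floored at the grid spacing — a narrower kernel cannot be
    resolved on the grid and can drop all its mass between grid points.
    """
    grid = np.asarray(grid, dtype=float)
    ev = spectrum.eigenvalues
    if ev[-1] < grid[0] or ev[0] > grid[-1]:
        raise ValueError("grid does not span the eigenvalue range")
    h = bandwidth(spectrum) if bw is None else float(bw)
    h = max(h, float(grid[1] - grid[0]))
    z = (grid[:, None] - ev[None, :]) / h
    vals = np.exp(-0.5 * z * z).mean(axis=1) / (h * math.sqrt(2.0 * math.pi))
    total = np.trapezoid(vals, grid)
    if total <= 0:
        raise ValueError("degenerate density: zero mass on the grid")
    return SpectralDensity(grid, vals / total)


def graph_densities(graphs: list[Graph],
                    config: DensityEstimationConfig = DensityEstimationConfig(),
                    grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-graph densities on a common grid.

    Returns ``(grid, D)`` where row ``D[i]`` is the estimated density of
    ``graphs[i]``.  This is the cached building block of the permutation
    test: population densities are row-averages of ``D``.
    """
    spectra = [compute_spectrum(g, config.scale_mode) for g in graphs]
    if grid is None:
        grid = make_grid(spectra, config)
    d = np.empty((len(graphs), len(grid)))
    for i, s in enumerate(spectra):
        d[i] = estimate_density(s, grid, config).values
    return grid, d


def population_density(population: GraphPopulation,
                       grid: np.ndarray,
                       config: DensityEstimationConfig = DensityEstimationConfig(),
                       ) -> SpectralDensity:
    """Average of the per-graph spectral densities of one population."""
    _, d = graph_densities(population.graphs, config, grid=grid)
    return SpectralDensity(grid, d.mean(axis=0))


def _check_shared_grid(densities: list[SpectralDensity]) -> np.ndarray:
    g0 = densities[0].grid
    for d in densities[1:]:
        if d.grid is not g0 and not np.array_equal(d.grid, g0):
            raise ValueError("grid mismatch: densities must share one grid")
    return g0


def reference_density(densities: list[SpectralDensity]) -> SpectralDensity:
    """Pointwise mean of k population densities (the reference measure).

    Wherever any population density is positive the reference is at least
    that value divided by k, so KL of each population to the reference is
    finite.
    """
    if len(densities) < 2:
        raise ValueError("need at least two densities")
    grid = _check_shared_grid(densities)
    vals = np.mean([d.values for d in densities], axis=0)
    return SpectralDensity(grid, vals)


def kl_divergence(p: SpectralDensity, q: SpectralDensity) -> float:
    """KL(p || q) = ∫ p log(p/q) by the trapezoid rule on the shared grid.

    Uses the 0·log(0/·) = 0 convention; if p carries mass where q has none
    the divergence is +inf (the support of q must contain that of p).
    """
    grid = _check_shared_grid([p, q])
    return _kl_on_grid(p.values, q.values, grid)


def _kl_on_grid(pv: np.ndarray, qv: np.ndarray, grid: np.ndarray) -> float:
    p_pos = pv > _KL_TOL
    if np.any(p_pos & (qv <= _KL_TOL)):
        return math.inf
    integrand = np.zeros_like(pv)
    integrand[p_pos] = pv[p_pos] * np.log(pv[p_pos] / qv[p_pos])
    return float(np.trapezoid(integrand, grid))


def delta_statistic(densities: list[SpectralDensity]) -> float:
    """Δ = Σ_i KL(ρ̂_i, ρ̂_M), the spread of k densities around their mean."""
    return float(np.sum(per_population_kl(densities)))


def per_population_kl(densities: list[SpectralDensity]) -> np.ndarray:
    """KL divergence of each population density to the pointwise mean."""
    if len(densities) < 2:
        raise ValueError("need at least two densities")
    ref = reference_density(densities)
    return np.array([kl_divergence(d, ref) for d in densities])


def delta_from_rows(rows: np.ndarray, group_slices: list[np.ndarray],
                    grid: np.ndarray) -> tuple[float, np.ndarray]:
    """Δ from cached per-graph density rows and index groups (fast path).

    ``rows`` is the (n_graphs × grid) matrix of per-graph densities;
    ``group_slices`` lists the row indices of each population.  Used by the
    permutation test, where only the group assignment changes.
    """
    means = np.stack([rows[ix].mean(axis=0) for ix in group_slices])
    ref = means.mean(axis=0)
    kls = np.array([_kl_on_grid(m, ref, grid) for m in means])
    return float(kls.sum()), kls
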