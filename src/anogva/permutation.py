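"""The ANOGVA permutation test.

Null hypothesis: all k populations of graphs were generated by the same
random-graph process, i.e. their spectral densities coincide.  The observed
statistic Δ̂ sums the KL divergences of the k estimated population densities
to their average.  The null distribution is built by permuting the
graph-to-population assignment (preserving group sizes |g_i|), recomputing
Δ̂* each time; the p-value is the fraction of permuted statistics at least
as large as the observed one.

Per-graph densities do not depend on group labels, so they are estimated
once and the permutation loop only re-averages rows — mathematically
identical to re-estimating everything, and asserted to be so in the tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .models import GraphPopulation
from .spectral import DensityEstimationConfig, delta_from_rows, graph_densities

logger = logging.getLogger("anogva")


@dataclass
class AnogvaResult:
    """Outcome of one ANOGVA run.

    ``p_value`` is the plain permutation fraction #{Δ̂* ≥ Δ̂} / B; with
    ``add_one`` it becomes (1 + #{Δ̂* ≥ Δ̂}) / (B + 1) and can never be
    exactly zero.  A plain-fraction zero should be read as "< 1/B".
    """

    delta_observed: float
    delta_permuted: np.ndarray
    p_value: float
    per_population_kl: np.ndarray
    population_names: list[str]
    n_permutations: int
    seed: int | None
    add_one: bool = False
    config: DensityEstimationConfig = field(default_factory=DensityEstimationConfig)

    @property
    def k(self) -> int:
        return len(self.per_population_kl)

    def summary(self) -> str:
        p = (f"p = {self.p_value:.6g}" if self.p_value > 0
             else f"p < {1.0 / self.n_permutations:.4g}")
        return (f"ANOGVA: k={self.k} populations "
                f"({', '.join(self.population_names)}), "
                f"delta = {self.delta_observed:.6g}, B = {self.n_permutations}, {p}")

    def to_dict(self) -> dict:
        return {
            "delta_observed": self.delta_observed,
            "delta_permuted": [float(x) for x in self.delta_permuted],
            "p_value": self.p_value,
            "per_population_kl": [float(x) for x in self.per_population_kl],
            "population_names": list(self.population_names),
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "add_one": self.add_one,
            "grid_points": self.config.grid_points,
            "scale_mode": self.config.scale_mode,
        }


def _group_slices(sizes: list[int]) -> list[np.ndarray]:
    bounds = np.cumsum([0] + sizes)
    return [np.arange(bounds[i], bounds[i + 1]) for i in range(len(sizes))]


def anogva(populations: list[GraphPopulation],
           n_permutations: int = 1000,
           seed: int | None = None,
           config: DensityEstimationConfig = DensityEstimationConfig(),
           add_one: bool = False) -> AnogvaResult:
    """Test whether k ≥ 2 populations of graphs share one generating process.

    Parameters
    ----------
    populations
        Populations of graphs, all with the same vertex count.
    n_permutations
        Number of label permutations B used for the null distribution.
    seed
        Seeds the permutation stream; per-permutation substreams are derived
        from it so results do not depend on evaluation order.
    config
        Density-estimation settings (grid size, eigenvalue scaling).
    add_one
        Apply the (1 + x) / (B + 1) correction to the p-value.
    """
    if len(populations) < 2:
        raise ValueError("need at least two populations")
    n0 = populations[0].n_vertices
    if any(p.n_vertices != n0 for p in populations):
        raise ValueError("incompatible populations: vertex counts differ")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")

    graphs = list(itertools.chain.from_iterable(p.graphs for p in populations))
    sizes = [len(p) for p in populations]
    grid, rows = graph_densities(graphs, config)
    slices = _group_slices(sizes)

    delta_obs, kls = delta_from_rows(rows, slices, grid)

    n_total = len(graphs)
    streams = np.random.SeedSequence(seed).spawn(n_permutations)
    delta_perm = np.empty(n_permutations)
    for b, ss in enumerate(streams):
        perm = np.random.default_rng(ss).permutation(n_total)
        perm_slices = [perm[ix] for ix in slices]
        delta_perm[b], _ = delta_from_rows(rows, perm_slices, grid)

    exceed = int(np.count_nonzero(delta_perm >= delta_obs))
    if add_one:
        p_value = (1 + exceed) / (n_permutations + 1)
    else:
        p_value = exceed / n_permutations
    return AnogvaResult(
        delta_observed=delta_obs,
        delta_permuted=delta_perm,
        p_value=float(p_value),
        per_population_kl=kls,
        population_names=[p.name for p in populations],
        n_permutations=n_permutations,
        seed=seed,
        add_one=add_one,
        config=config,
    )


def pairwise_anogva(populations: list[GraphPopulation],
                    n_permutations: int = 1000,
                    seed: int | None = None,
                    config: DensityEstimationConfig = DensityEstimationConfig(),
                    add_one: bool = False,
                    bh_adjust: bool = False) -> dict[tuple[str, str], float]:
    """Post-hoc pairwise ANOGVA over all C(k, 2) population pairs.

    Returns raw pairwise p-values by default; ``bh_adjust`` applies a
    Benjamini–Hochberg correction across the pairs.
    """
    if len(populations) < 2:
        raise ValueError("need at least two populations")
    names = [p.name for p in populations]
    if len(set(names)) != len(names):
        raise ValueError("population names must be unique for pairwise results")
    pairs = list(itertools.combinations(range(len(populations)), 2))
    streams = np.random.SeedSequence(seed).spawn(len(pairs))
    out: dict[tuple[str, str], float] = {}
    for (i, j), ss in zip(pairs, streams):
        res = anogva([populations[i], populations[j]], n_permutations,
                     seed=int(ss.generate_state(1)[0] % (2 ** 31)),
                     config=config, add_one=add_one)
        out[(names[i], names[j])] = res.p_value
    if bh_adjust:
        keys = list(out)
        _, adj, _, _ = multipletests([out[k] for k in keys], method="fdr_bh")
        out = dict(zip(keys, adj.tolist()))
    return out
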