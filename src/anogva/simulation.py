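"""Simulation study: type-I error / power scenarios and the feature benchmark.

Four scenarios probe the test on populations of random graphs whose
parameters are drawn per graph from a truncated normal law normalized to
[0, 1]:

1. null — three Erdős–Rényi populations share one parameter law;
2. shifted parameter — the middle population's law has a larger mean;
3. unbalanced — as scenario 2 with unequal group sizes;
4. cross-model — the middle population is Watts–Strogatz instead of
   Erdős–Rényi, optionally with a fraction of graphs mislabeled between
   the models.

Each scenario is replicated; the p-values yield an ROC-style curve of
rejection proportion against nominal threshold.  The feature benchmark runs
the same three-population design for each of five graph models and compares
the spectral permutation test against one-way ANOVA applied to classical
graph features (edge count, betweenness, closeness, assortativity,
transitivity, global efficiency).

Default problem sizes are scaled down (60-vertex graphs, groups of 20,
200 replicates, 100 permutations) so a full scenario runs on a desk machine;
the original study sizes (300 vertices, groups of 50–125, 1,000 replicates
and permutations) are available through the same configuration fields.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import igraph as ig
import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .models import (Graph, GraphPopulation, ParameterLaw, as_rng,
                     barabasi_albert, erdos_renyi, geometric_graph,
                     integer_parameter, k_regular, sample_parameters,
                     watts_strogatz)
from .permutation import anogva
from .spectral import DensityEstimationConfig

logger = logging.getLogger("anogva")

MODELS = ("er", "grg", "kreg", "ws", "ba")

#: parameter law shared by all populations under the null
BASE_LAW = ParameterLaw(lower=0.0, upper=10.0, mean=1.0, variance=1.0)
#: law of the middle population under the shifted-parameter alternatives
SHIFTED_LAW = ParameterLaw(lower=0.0, upper=10.0, mean=1.5, variance=1.0)

WS_NEI = 4           # lattice neighbourhood of the Watts-Strogatz population
GRG_DIM = 2          # embedding dimension of the geometric model


# ---------------------------------------------------------------------------
# model adapters: normalized parameter theta in [0, 1] -> graph
# ---------------------------------------------------------------------------

def parameter_feasible(model: str, theta: float, n_vertices: int) -> bool:
    """Whether the integer-mapped parameter yields a constructible graph."""
    if model == "kreg":
        deg = integer_parameter(theta)
        return 1 <= deg < n_vertices and (n_vertices * deg) % 2 == 0
    return True


def graph_from_theta(model: str, theta: float, n_vertices: int, rng) -> Graph:
    """Generate one graph of ``model`` with normalized parameter ``theta``."""
    if model == "er":
        return erdos_renyi(n_vertices, theta, rng)
    if model == "grg":
        return geometric_graph(n_vertices, theta, GRG_DIM, rng)
    if model == "kreg":
        return k_regular(n_vertices, integer_parameter(theta), rng)
    if model == "ws":
        return watts_strogatz(n_vertices, WS_NEI, theta, rng)
    if model == "ba":
        return barabasi_albert(n_vertices, power=float(integer_parameter(theta)),
                               rng=rng)
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


def _draw_feasible_theta(law: ParameterLaw, model: str, n_vertices: int,
                         rng, counter: dict) -> float:
    """One normalized parameter, resampled until the generator accepts it."""
    for _ in range(10_000):
        theta = float(sample_parameters(law, 1, rng)[0])
        if parameter_feasible(model, theta, n_vertices):
            return theta
        counter["resampled"] = counter.get("resampled", 0) + 1
    raise RuntimeError(f"could not draw a feasible parameter for {model}")


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario run: models, laws, sizes, replication and seeding."""

    scenario_id: int
    group_sizes: tuple[int, int, int] = (20, 20, 20)
    n_vertices: int = 60
    mislabel_rate: float = 0.0
    mislabel_direction: str = "both"     # "both" | "to_g2" | "from_g2"
    replications: int = 200
    permutations: int = 100
    seed: int | None = None
    density_config: DensityEstimationConfig = field(
        default_factory=DensityEstimationConfig)

    def __post_init__(self) -> None:
        if self.scenario_id not in (1, 2, 3, 4):
            raise ValueError("scenario_id must be 1..4")
        if any(s < 1 for s in self.group_sizes):
            raise ValueError("group sizes must be >= 1")
        if not 0.0 <= self.mislabel_rate < 0.5:
            raise ValueError("mislabel_rate must lie in [0, 0.5)")
        if self.mislabel_rate > 0 and self.scenario_id != 4:
            raise ValueError("mislabeling only applies to scenario 4")

    def population_specs(self) -> list[tuple[str, ParameterLaw]]:
        """(model, parameter law) for each of the three populations."""
        if self.scenario_id == 1:
            return [("er", BASE_LAW)] * 3
        if self.scenario_id in (2, 3):
            return [("er", BASE_LAW), ("er", SHIFTED_LAW), ("er", BASE_LAW)]
        return [("er", BASE_LAW), ("ws", BASE_LAW), ("er", BASE_LAW)]


@dataclass
class RocCurve:
    """Empirical rejection proportion as a function of the nominal p-value
    threshold; nondecreasing by construction."""

    thresholds: np.ndarray
    rejection_proportions: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.rejection_proportions = np.asarray(self.rejection_proportions,
                                                dtype=float)
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if np.any(np.diff(self.rejection_proportions) < -1e-12):
            raise ValueError("rejection proportions must be nondecreasing")

    @classmethod
    def from_p_values(cls, p_values: np.ndarray,
                      thresholds: np.ndarray | None = None) -> "RocCurve":
        if thresholds is None:
            thresholds = np.linspace(0.0, 1.0, 101)[1:]
        p = np.asarray(p_values, dtype=float)
        rej = np.array([np.mean(p <= t) for t in thresholds])
        return cls(thresholds, rej)


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    p_values: np.ndarray
    roc: RocCurve
    infeasible_resamples: int = 0

    def power(self, alpha: float = 0.05) -> float:
        """Rejection proportion at nominal level ``alpha``."""
        return float(np.mean(self.p_values <= alpha))


def _generate_scenario_populations(config: ScenarioConfig, rng) -> tuple[list, dict]:
    counter: dict = {}
    specs = config.population_specs()
    pops = []
    for pop_ix, ((model, law), size) in enumerate(zip(specs, config.group_sizes)):
        graphs = []
        for _ in range(size):
            actual_model = model
            if config.scenario_id == 4 and config.mislabel_rate > 0:
                swap = rng.uniform() < config.mislabel_rate
                if swap and pop_ix == 1 and config.mislabel_direction in ("both", "from_g2"):
                    actual_model = "er"
                elif swap and pop_ix != 1 and config.mislabel_direction in ("both", "to_g2"):
                    actual_model = "ws"
            theta = _draw_feasible_theta(law, actual_model, config.n_vertices,
                                         rng, counter)
            graphs.append(graph_from_theta(actual_model, theta,
                                           config.n_vertices, rng))
        pops.append(GraphPopulation(f"g{pop_ix + 1}", graphs))
    return pops, counter


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Replicate one scenario and collect the permutation p-values.

    Each replicate draws fresh per-graph parameters, generates the three
    populations, and runs the spectral permutation test.  Infeasible
    integer parameters are resampled and counted.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.replications)
    p_values = np.empty(config.replications)
    resampled = 0
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pops, counter = _generate_scenario_populations(config, rng)
        resampled += counter.get("resampled", 0)
        res = anogva(pops, n_permutations=config.permutations,
                     seed=int(ss.generate_state(1)[0] % (2 ** 31)),
                     config=config.density_config)
        p_values[r] = res.p_value
    if resampled:
        logger.info("scenario %d: %d infeasible parameters resampled",
                    config.scenario_id, resampled)
    return ScenarioResult(config, p_values,
                          RocCurve.from_p_values(p_values), resampled)


# ---------------------------------------------------------------------------
# graph features + one-way ANOVA benchmark
# ---------------------------------------------------------------------------

FEATURES = ("NE", "BC", "CC", "AS", "TR", "GE")


def _to_igraph(graph: Graph) -> ig.Graph:
    i, j = np.nonzero(np.triu(graph.adjacency, k=1))
    return ig.Graph(n=graph.n_vertices, edges=list(zip(i.tolist(), j.tolist())))


def graph_features(graph: Graph) -> dict[str, float]:
    """Classical whole-graph summary features.

    NE — number of edges; BC — mean betweenness centrality (shortest-path
    pass-through counts); CC — mean closeness, 1 / sum of distances with
    unreachable pairs contributing infinite distance (closeness 0); AS —
    degree assortativity (NaN when degrees have zero variance); TR —
    transitivity, 3 · triangles / connected triples; GE — global efficiency,
    the mean of 1/distance over ordered pairs with 1/inf = 0.
    """
    g = _to_igraph(graph)
    n = g.vcount()
    out: dict[str, float] = {"NE": float(g.ecount())}
    out["BC"] = float(np.mean(g.betweenness())) if n > 1 else 0.0
    dmat = np.asarray(g.distances(), dtype=float)
    np.fill_diagonal(dmat, np.nan)
    with np.errstate(divide="ignore"):
        row_sums = np.nansum(dmat, axis=1) + np.where(
            np.isinf(dmat).any(axis=1), np.inf, 0.0)
        closeness = np.where(np.isfinite(row_sums) & (row_sums > 0),
                             1.0 / row_sums, 0.0)
        inv_d = np.where(np.isfinite(dmat) & (dmat > 0), 1.0 / dmat, 0.0)
    out["CC"] = float(np.mean(closeness)) if n > 1 else 0.0
    out["GE"] = float(np.nansum(inv_d) / (n * (n - 1))) if n > 1 else 0.0
    deg = graph.degrees()
    out["AS"] = (float(g.assortativity_degree()) if np.ptp(deg) > 0
                 and g.ecount() > 0 else float("nan"))
    tr = g.transitivity_undirected(mode="zero")
    out["TR"] = float(tr)
    return out


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA; returns (F, p).

    Degenerate inputs with no variability at all (within or between groups)
    return F = 0, p = 1 by convention.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    if all(np.ptp(a) == 0 for a in arrays):
        # between-group signal with zero within-group noise
        return math.inf, 0.0
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


@dataclass
class MethodOutcome:
    """Rejection proportion at one nominal level, with a Wilson 95% CI."""

    proportion: float
    ci_low: float
    ci_high: float
    n_replicates: int
    n_skipped: int = 0


@dataclass
class FeatureBenchmarkResult:
    """Per (model × method) rejection proportions at the nominal level."""

    alpha: float
    outcomes: dict[str, dict[str, MethodOutcome]]

    def proportion(self, model: str, method: str) -> float:
        return self.outcomes[model][method].proportion


def wilson_ci(successes: int, trials: int) -> tuple[float, float]:
    lo, hi = proportion_confint(successes, trials, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def feature_benchmark(models: list[str] | tuple[str, ...] = MODELS,
                      group_sizes: tuple[int, int, int] = (30, 30, 30),
                      n_vertices: int = 100,
                      replications: int = 200,
                      permutations: int = 100,
                      features: tuple[str, ...] = FEATURES,
                      laws: tuple[ParameterLaw, ParameterLaw, ParameterLaw] = (
                          BASE_LAW, SHIFTED_LAW, BASE_LAW),
                      alpha: float = 0.05,
                      seed: int | None = None,
                      density_config: DensityEstimationConfig = DensityEstimationConfig(),
                      ) -> FeatureBenchmarkResult:
    """Compare the spectral test with feature-wise ANOVA across graph models.

    For each model and replicate, three populations are generated with the
    given parameter laws (middle population shifted by default); the
    spectral permutation test and a one-way ANOVA on each requested feature
    are applied and their rejections at ``alpha`` tabulated with Wilson 95%
    confidence intervals.  Replicates where a feature is undefined (e.g.
    assortativity of a regular graph) are skipped for that feature and
    counted.
    """
    unknown = set(features) - set(FEATURES)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    outcomes: dict[str, dict[str, MethodOutcome]] = {}
    root = np.random.SeedSequence(seed)
    for model, model_ss in zip(models, root.spawn(len(models))):
        rej = {m: 0 for m in ("ANOGVA", *features)}
        used = {m: 0 for m in ("ANOGVA", *features)}
        counter: dict = {}
        for ss in model_ss.spawn(replications):
            rng = np.random.default_rng(ss)
            pops = []
            feats: list[dict[str, np.ndarray]] = []
            for pop_ix, (law, size) in enumerate(zip(laws, group_sizes)):
                graphs = []
                for _ in range(size):
                    theta = _draw_feasible_theta(law, model, n_vertices, rng,
                                                 counter)
                    graphs.append(graph_from_theta(model, theta, n_vertices, rng))
                pops.append(GraphPopulation(f"g{pop_ix + 1}", graphs))
                if features:
                    fvals = [graph_features(g) for g in graphs]
                    feats.append({f: np.array([fv[f] for fv in fvals])
                                  for f in features})
            res = anogva(pops, n_permutations=permutations,
                         seed=int(ss.generate_state(1)[0] % (2 ** 31)),
                         config=density_config)
            used["ANOGVA"] += 1
            rej["ANOGVA"] += res.p_value <= alpha
            for f in features:
                groups = [fg[f] for fg in feats]
                if any(np.isnan(g).any() for g in groups):
                    continue
                _, p = one_way_anova(groups)
                used[f] += 1
                rej[f] += p <= alpha
        outcomes[model] = {}
        for m in ("ANOGVA", *features):
            if used[m] == 0:
                outcomes[model][m] = MethodOutcome(float("nan"), float("nan"),
                                                   float("nan"), 0,
                                                   replications)
                continue
            lo, hi = wilson_ci(rej[m], used[m])
            outcomes[model][m] = MethodOutcome(rej[m] / used[m], lo, hi,
                                               used[m],
                                               replications - used[m])
        if counter.get("resampled"):
            logger.info("benchmark %s: %d infeasible parameters resampled",
                        model, counter["resampled"])
    return FeatureBenchmarkResult(alpha=alpha, outcomes=outcomes)
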