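# anogva

Statistical comparison of **populations of graphs**: a permutation test
(ANOGVA — analysis of graph structure variability) that decides whether
k ≥ 2 groups of undirected graphs were generated by the same random-graph
process.

## The problem

Real interaction networks — functional brain networks above all — are noisy:
two subjects from the same group have visibly different graphs, and graphs
from different groups may come from the same stochastic process.
Isomorphism-style comparisons therefore misfire.  A better framing treats
each observed graph as a *sample from a random-graph model* and asks whether
several groups of graphs share one generating process.

## The method

The spectrum of a graph's adjacency matrix (its eigenvalues
λ₁ ≥ … ≥ λₙ) acts as a fingerprint of the generating model.  For each graph
the spectral density is estimated by Gaussian-kernel smoothing of the
eigenvalues (bandwidth (λ₁ − λₙ)/bins with the bin count from Sturges'
rule), renormalized to unit integral.  Each group's density ρ̂\_gᵢ is the
average of its graphs' densities, and the test statistic is

    Δ = Σᵢ KL(ρ̂_gᵢ ‖ ρ̂_gM),     ρ̂_gM = (1/k) Σᵢ ρ̂_gᵢ

— a k-group generalization of the Jensen–Shannon divergence, zero exactly
when all group densities coincide.  Since Δ's null distribution is unknown,
group labels are permuted (preserving group sizes) B times and the p-value
is the fraction of permuted statistics Δ\* at least as large as the
observed one.

The package also ships:

* the five random-graph models used to study the test (Erdős–Rényi,
  geometric, k-regular, Watts–Strogatz, Barabási–Albert) with per-graph
  parameters drawn from a normalized truncated-normal law,
* the type-I-error / power simulation scenarios with ROC summaries and a
  benchmark against one-way ANOVA on classical graph features,
* a functional-connectivity pipeline (Spearman correlation → Fisher z →
  OLS covariate residualization → BH-FDR → sub-network graphs) plus a
  synthetic multi-subject cohort generator so the pipeline is testable
  without imaging data.

## Worked example

```python
import numpy as np
from anogva import GraphPopulation, anogva, erdos_renyi, watts_strogatz

rng = np.random.default_rng(0)
controls = GraphPopulation(
    "controls", [erdos_renyi(100, 0.16, rng) for _ in range(20)])
patients = GraphPopulation(
    "patients", [watts_strogatz(100, 8, 0.16, rng) for _ in range(20)])
null_twin = GraphPopulation(
    "null_twin", [erdos_renyi(100, 0.16, rng) for _ in range(20)])

result = anogva([controls, patients, null_twin],
                n_permutations=1000, seed=42)
print(result.summary())
print("per-population KL:",
      dict(zip(result.population_names,
               np.round(result.per_population_kl, 4))))
```

prints

```
ANOGVA: k=3 populations (controls, patients, null_twin), delta = 0.0364542, B = 1000, p < 0.001
per-population KL: {'controls': 0.0065, 'patients': 0.0243, 'null_twin': 0.0057}
```

All three populations have (almost exactly) the same expected edge count,
so edge-count comparisons cannot separate them; the spectral densities can.
Δ̂ = 0.036 exceeded every one of the 1,000 permuted Δ̂\*, so the plain
permutation fraction is reported as p < 0.001.  The per-population KL terms
localize the discrepancy: the small-world group sits 4× further from the
reference density than either Erdős–Rényi group.

A command-line interface mirrors the library
(`anogva generate | spectrum | test | simulate | benchmark | connectivity`);
run `anogva --help`.

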