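"""Functional-connectivity networks from ROI time series.

Pipeline: per subject, pairwise Spearman correlation between ROI time
series; Fisher z-transform of the correlations; ordinary-least-squares
residualization of every edge against nuisance covariates (site, gender,
age, scrubbing proportion); Benjamini–Hochberg FDR correction of the
edgewise p-values; and extraction of labeled sub-network graphs
(somatomotor, visual, default-mode, cerebellar, fronto-parietal) for the
group-level spectral permutation test.

Because the real resting-state cohort cannot ship with the package, a
synthetic cohort generator emulates multi-subject ROI series with
group-dependent block covariance structure and known covariate effects, so
the whole pipeline — including confound removal and planted-effect
recovery — is testable end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import Graph, GraphPopulation, as_rng

logger = logging.getLogger("anogva")

SUBNETWORKS = ("somatomotor", "visual", "default-mode", "cerebellar",
               "fronto-parietal")

_CLIP = 1.0 - 1e-7


@dataclass
class SubjectTimeSeries:
    """One subject's ROI time series (timepoints × ROIs) plus covariates."""

    subject_id: str
    group: str
    series: np.ndarray
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.series, dtype=float)
        if s.ndim != 2 or s.shape[0] < 3:
            raise ValueError("series must be a T x R matrix with T >= 3")
        if np.isnan(s).any():
            raise ValueError(f"subject {self.subject_id}: series has missing values")
        self.series = s

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[0]

    @property
    def n_rois(self) -> int:
        return self.series.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI × ROI association matrix with companion p-values.

    ``stage`` records what the entries are: Spearman rho, Fisher z, or
    covariate-residualized z.  The diagonal is ignored.
    """

    values: np.ndarray
    p_values: np.ndarray | None = None
    stage: str = "rho"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")
        if self.stage == "rho":
            finite = np.isfinite(v)
            if np.any(np.abs(v[finite]) > 1 + 1e-12):
                raise ValueError("Spearman correlations must lie in [-1, 1]")
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def spearman_connectivity(ts: SubjectTimeSeries) -> ConnectivityMatrix:
    """Pairwise Spearman correlation between all ROI pairs of one subject.

    Ties are handled by average ranks; two-sided p-values come from the t
    approximation.  Constant ROI series yield undefined (NaN) correlations
    for their pairs, with a warning.
    """
    x = ts.series
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints")
    constant = np.ptp(x, axis=0) == 0
    if constant.any():
        logger.warning("subject %s: %d constant ROI series; correlations NaN",
                       ts.subject_id, int(constant.sum()))
    rho, p = stats.spearmanr(x)
    if np.ndim(rho) == 0:          # scipy collapses the two-ROI case
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    rho = np.asarray(rho, dtype=float)
    p = np.asarray(p, dtype=float)
    np.fill_diagonal(rho, 0.0)
    np.fill_diagonal(p, 1.0)
    return ConnectivityMatrix(rho, p, stage="rho")


def fisher_z(rho):
    """Fisher z-transform atanh(rho); |rho| = 1 is clipped with a warning."""
    r = np.asarray(rho, dtype=float)
    clipped = np.abs(r) >= 1.0
    if np.any(clipped & np.isfinite(r)):
        logger.warning("fisher_z: %d correlations at +-1 clipped",
                       int(np.count_nonzero(clipped & np.isfinite(r))))
    out = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    if np.isscalar(rho):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# covariate residualization
# ---------------------------------------------------------------------------

def design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    """Intercept + one-hot categoricals (reference level dropped) + numerics."""
    cols = [np.ones(len(covariates))]
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            cols.extend(dummies[c].to_numpy() for c in dummies.columns)
        else:
            cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols)


def residualize_edges(z_stack: np.ndarray,
                      covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of every edge's z-values against the covariates.

    ``z_stack`` is (subjects × edges); each edge (column) is regressed on
    [intercept, covariates] and replaced by its residuals.  Collinear
    design columns are tolerated (minimum-norm fit); the residuals are
    orthogonal to the design either way.
    """
    z = np.asarray(z_stack, dtype=float)
    if z.ndim != 2:
        raise ValueError("z_stack must be (subjects x edges)")
    x = design_matrix(covariates)
    if len(covariates) != z.shape[0]:
        raise ValueError("covariate table and z_stack disagree on subjects")
    if z.shape[0] < x.shape[1] + 1:
        raise ValueError("need more subjects than design columns")
    beta, _, rank, _ = np.linalg.lstsq(x, z, rcond=None)
    if rank < x.shape[1]:
        logger.warning("residualize_edges: rank-deficient design "
                       "(rank %d of %d columns)", rank, x.shape[1])
    return z - x @ beta


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flat = p.ravel()
    _, adj, _, _ = multipletests(flat, method="fdr_bh")
    return adj.reshape(p.shape)


# ---------------------------------------------------------------------------
# edge vectorization and sub-network graphs
# ---------------------------------------------------------------------------

def upper_triangle(matrix: np.ndarray) -> np.ndarray:
    """Vectorize the strict upper triangle (R(R-1)/2 edges) of a symmetric matrix."""
    m = np.asarray(matrix, dtype=float)
    return m[np.triu_indices(m.shape[0], k=1)]


def from_upper_triangle(vector: np.ndarray, n_rois: int) -> np.ndarray:
    """Inverse of :func:`upper_triangle`: symmetric matrix with zero diagonal."""
    out = np.zeros((n_rois, n_rois))
    iu = np.triu_indices(n_rois, k=1)
    out[iu] = vector
    return out + out.T


def read_subnetwork_labels(mapping) -> dict[int, str]:
    """Normalize an ROI → sub-network mapping (0-based ROI indices)."""
    return {int(k): str(v) for k, v in dict(mapping).items()}


def extract_subnetwork(matrix: ConnectivityMatrix,
                       labels: dict[int, str],
                       name: str,
                       binarize_alpha: float | None = None,
                       adjusted_p: np.ndarray | None = None,
                       label: str | None = None) -> Graph:
    """Principal submatrix over the ROIs carrying ``name``, as a Graph.

    By default the sub-network graph is weighted by the (residual) values;
    with ``binarize_alpha`` the edges are 1 where the FDR-adjusted p-value
    is below the cutoff and 0 elsewhere.
    """
    rois = sorted(i for i, lab in labels.items() if lab == name)
    if not rois:
        raise KeyError(f"no ROIs labeled {name!r}")
    if max(rois) >= matrix.n_rois:
        raise ValueError("sub-network label index outside the matrix")
    sub = matrix.values[np.ix_(rois, rois)].copy()
    if binarize_alpha is not None:
        if adjusted_p is None:
            if matrix.p_values is None:
                raise ValueError("binarization needs p-values")
            adjusted_p = fdr_bh(upper_triangle(matrix.p_values))
            adjusted_p = from_upper_triangle(adjusted_p, matrix.n_rois)
        sub = (adjusted_p[np.ix_(rois, rois)] < binarize_alpha).astype(float)
    np.fill_diagonal(sub, 0.0)
    sub = np.nan_to_num(sub, nan=0.0)
    return Graph(sub, label=label)


def subject_connectivity_graphs(subjects: list[SubjectTimeSeries],
                                labels: dict[int, str],
                                subnetwork: str,
                                residualize: bool = True,
                                binarize_alpha: float | None = None,
                                ) -> list[GraphPopulation]:
    """Full per-subject pipeline → one GraphPopulation per subject group.

    Spearman correlations are Fisher z-transformed, optionally residualized
    against the subjects' covariate table, reassembled into symmetric
    matrices, and sliced to the requested sub-network.
    """
    if not subjects:
        raise ValueError("no subjects")
    n_rois = subjects[0].n_rois
    mats = [spearman_connectivity(s) for s in subjects]
    z_stack = np.stack([fisher_z(np.nan_to_num(upper_triangle(m.values)))
                        for m in mats])
    if residualize:
        cov = pd.DataFrame([s.covariates for s in subjects])
        z_stack = residualize_edges(z_stack, cov)
    groups: dict[str, list[Graph]] = {}
    for s, m, z in zip(subjects, mats, z_stack):
        conn = ConnectivityMatrix(from_upper_triangle(z, n_rois),
                                  m.p_values, stage="residual_z" if residualize
                                  else "z")
        g = extract_subnetwork(conn, labels, subnetwork,
                               binarize_alpha=binarize_alpha,
                               label=s.subject_id)
        groups.setdefault(s.group, []).append(g)
    return [GraphPopulation(name, graphs) for name, graphs in groups.items()]


# ---------------------------------------------------------------------------
# synthetic cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovarianceEffect:
    """Planted group effect: raise the within-block correlation of one
    sub-network in one group by ``delta``."""

    group: str
    subnetwork: str
    delta: float = 0.25


def default_labels(n_rois: int) -> dict[int, str]:
    """Contiguous equal blocks of ROIs, one per canonical sub-network."""
    if n_rois < len(SUBNETWORKS):
        raise ValueError("need at least one ROI per sub-network")
    block = n_rois // len(SUBNETWORKS)
    labels = {}
    for i in range(n_rois):
        labels[i] = SUBNETWORKS[min(i // block, len(SUBNETWORKS) - 1)]
    return labels


def _nearest_pd_correlation(c: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(c)
    if w.min() > 1e-8:
        return c
    logger.warning("template not positive definite (min eig %g); repairing",
                   w.min())
    w = np.clip(w, 1e-6, None)
    c = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    return (c + c.T) / 2


def _template(labels: dict[int, str], within: float, between: float,
              boosted: str | None, delta: float) -> np.ndarray:
    n = len(labels)
    names = np.array([labels[i] for i in range(n)])
    same = names[:, None] == names[None, :]
    c = np.where(same, within, between).astype(float)
    if boosted is not None:
        block = names == boosted
        c[np.ix_(block, block)] = within + delta
    np.fill_diagonal(c, 1.0)
    return _nearest_pd_correlation(c)


#: known covariate effects on every edge's Fisher z, used to make
#: residualization testable by construction
DEFAULT_COVARIATE_BETAS = {"site": 0.15, "gender": 0.08, "age": 0.012,
                           "scrub_proportion": 0.4}


def synthesize_cohort(groups: list[tuple[str, int]],
                      n_rois: int = 40,
                      n_timepoints: int = 120,
                      effect: CovarianceEffect | None = None,
                      labels: dict[int, str] | None = None,
                      within: float = 0.3,
                      between: float = 0.05,
                      covariate_betas: dict | None = None,
                      seed=None) -> list[SubjectTimeSeries]:
    """Synthetic multi-subject ROI time series with block covariance.

    Each subject's series is drawn from a multivariate normal whose
    correlation template has one block per sub-network (``within`` inside a
    block, ``between`` elsewhere).  ``effect`` raises one group's named
    block by ``delta``.  Nuisance covariates (site, gender, age, scrubbing
    proportion) shift every edge's correlation on the Fisher-z scale by
    known coefficients, so confound removal can be verified exactly.
    """
    if n_rois < 4 or n_timepoints < 20:
        raise ValueError("need n_rois >= 4 and n_timepoints >= 20")
    rng = as_rng(seed)
    if labels is None:
        labels = default_labels(n_rois)
    betas = DEFAULT_COVARIATE_BETAS if covariate_betas is None else covariate_betas
    subjects = []
    for group, n_subj in groups:
        boosted = effect.subnetwork if effect and effect.group == group else None
        delta = effect.delta if effect else 0.0
        base = _template(labels, within, between, boosted, delta)
        base_z = fisher_z(upper_triangle(base))
        for s in range(n_subj):
            cov = {
                "site": "A" if rng.uniform() < 0.5 else "B",
                "gender": "M" if rng.uniform() < 0.5 else "F",
                "age": float(rng.uniform(8.0, 30.0)),
                "scrub_proportion": float(rng.uniform(0.0, 0.3)),
            }
            shift = (betas.get("site", 0.0) * (cov["site"] == "B")
                     + betas.get("gender", 0.0) * (cov["gender"] == "M")
                     + betas.get("age", 0.0) * (cov["age"] - 19.0)
                     + betas.get("scrub_proportion", 0.0)
                     * cov["scrub_proportion"])
            z = base_z + shift
            c = from_upper_triangle(np.tanh(z), n_rois)
            np.fill_diagonal(c, 1.0)
            c = _nearest_pd_correlation(c)
            chol = np.linalg.cholesky(c)
            series = rng.standard_normal((n_timepoints, n_rois)) @ chol.T
            subjects.append(SubjectTimeSeries(
                subject_id=f"{group}_{s:03d}", group=group,
                series=series, covariates={"group": group, **cov}))
    return subjects


def subnetwork_screen(subjects: list[SubjectTimeSeries],
                      labels: dict[int, str],
                      n_permutations: int = 100,
                      seed: int | None = None,
                      residualize: bool = True,
                      covariate_columns: tuple[str, ...] = (
                          "site", "gender", "age", "scrub_proportion"),
                      ) -> dict[str, float]:
    """Run the group comparison on every sub-network; returns name → p-value.

    This is the screening step of the connectivity analysis: for each
    labeled sub-network, subject-level (residualized) connectivity graphs
    are compared across groups with the spectral permutation test.
    """
    from .permutation import anogva

    names = sorted(set(labels.values()))
    # residualize once over the full matrix, then slice per sub-network
    n_rois = subjects[0].n_rois
    mats = [spearman_connectivity(s) for s in subjects]
    z_stack = np.stack([fisher_z(np.nan_to_num(upper_triangle(m.values)))
                        for m in mats])
    if residualize:
        cov = pd.DataFrame([{k: s.covariates[k] for k in covariate_columns}
                            for s in subjects])
        z_stack = residualize_edges(z_stack, cov)
    out: dict[str, float] = {}
    streams = np.random.SeedSequence(seed).spawn(len(names))
    for name, ss in zip(names, streams):
        groups: dict[str, list[Graph]] = {}
        for s, z in zip(subjects, z_stack):
            conn = ConnectivityMatrix(from_upper_triangle(z, n_rois),
                                      stage="residual_z")
            g = extract_subnetwork(conn, labels, name, label=s.subject_id)
            groups.setdefault(s.group, []).append(g)
        pops = [GraphPopulation(n, g) for n, g in sorted(groups.items())]
        res = anogva(pops, n_permutations=n_permutations,
                     seed=int(ss.generate_state(1)[0] % (2 ** 31)))
        out[name] = res.p_value
    return out
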