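"""Synthetic panel-count generation with controlled spatio-temporal correlation.

A replication emulates a panel of ``n_units`` areal units observed at
``n_times`` consecutive time points (the motivating study uses 54 countries
over 20 years).  The generating process:

1. draw per-unit 2-D coordinates iid N(0, 1);
2. draw spatial noise from MVN(0, equicorrelation(n_units, sp)) and temporal
   noise from MVN(0, equicorrelation(n_times, tm)) — ``sp`` and ``tm`` are the
   scenario's target correlations;
3. the spatial term of unit i is its x-coordinate plus its spatial noise,
   constant over time; the temporal term of time t is its temporal noise,
   shared by all units;
4. the latent intensity is ``lambda[i, t] = exp(scale * (s_i + t_t - mean))``,
   centred and mildly scaled so counts stay moderate;
5. counts are zero-truncated Poisson draws with mean parameter lambda, so
   every observed count is at least 1.

Ten mutually orthogonal standardized covariates accompany each panel (they
mimic varimax-rotated principal components, hence all variance inflation
factors are exactly 1) but do not enter the latent intensity: the true fixed
effect vector is zero, and fitted models estimate null covariate effects.
A symmetrized k-nearest-neighbour graph over the coordinates supplies the
spatial adjacency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .graphs import SpatialGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation design: a (spatial, temporal) correlation pair.

    The study grid takes ``sp`` and ``tm`` in {0.05, 0.15, ..., 0.95}; any
    value in the open unit interval is accepted.
    """

    sp: float
    tm: float
    n_units: int = 54
    n_times: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.sp < 1.0:
            raise ValueError(f"sp must lie in (0, 1), got {self.sp}")
        if not 0.0 < self.tm < 1.0:
            raise ValueError(f"tm must lie in (0, 1), got {self.tm}")
        if self.n_units < 2 or self.n_times < 1:
            raise ValueError("need n_units >= 2 and n_times >= 1")


@dataclass
class SimulatedPanel:
    """One replication's data: counts, latent intensities, covariates, graph."""

    y: np.ndarray          # (n_units, n_times) integer counts, all >= 1
    lam: np.ndarray        # (n_units, n_times) latent intensities
    X: np.ndarray          # (n_units, n_times, p) standardized covariates
    offset: np.ndarray     # (n_units, n_times) log-exposure, default zero
    coords: np.ndarray     # (n_units, 2)
    graph: SpatialGraph
    scenario: Scenario
    spatial_term: np.ndarray = field(default=None)   # (n_units,)
    temporal_term: np.ndarray = field(default=None)  # (n_times,)

    @property
    def n_records(self) -> int:
        return self.y.size


@dataclass(frozen=True)
class SplitPanel:
    """Record-level train/test partition of a panel (records = unit-time cells)."""

    train_index: np.ndarray
    test_index: np.ndarray
    train_fraction: float

    def __post_init__(self) -> None:
        joint = np.sort(np.concatenate([self.train_index, self.test_index]))
        if not np.array_equal(joint, np.arange(joint.size)):
            raise ValueError("train and test indices must partition the records")


def equicorrelation_matrix(dim: int, r: float) -> np.ndarray:
    """Compound-symmetry correlation matrix: unit diagonal, all off-diagonals r.

    Positive definite for 0 <= r < 1 with eigenvalues ``1 - r`` (multiplicity
    dim - 1) and ``1 + (dim - 1) r``.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if not 0.0 <= r < 1.0:
        raise ValueError(f"r must lie in [0, 1), got {r}")
    return np.full((dim, dim), r) + (1.0 - r) * np.eye(dim)


def generate_noise(
    scenario: Scenario, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the spatial and temporal noise vectors for one replication.

    Returns ``(spatial_noise, temporal_noise)`` sampled from zero-mean
    multivariate normals with equicorrelation covariance at the scenario's
    ``sp`` and ``tm`` values.  Sampling goes through an explicit Cholesky
    factor so the output is bit-reproducible for a fixed generator state.
    """
    cov_s = equicorrelation_matrix(scenario.n_units, scenario.sp)
    cov_t = equicorrelation_matrix(scenario.n_times, scenario.tm)
    ls = np.linalg.cholesky(cov_s)
    lt = np.linalg.cholesky(cov_t)
    spatial = ls @ rng.standard_normal(scenario.n_units)
    temporal = lt @ rng.standard_normal(scenario.n_times)
    return spatial, temporal


def generate_covariates(
    n_units: int, n_times: int, p: int = 10, rng: np.random.Generator | None = None
) -> np.ndarray:
    """``p`` exactly orthogonal, standardized covariates over the panel records.

    Columns of iid normal draws are orthogonalized (QR after projecting out
    the constant) and rescaled to mean 0 and sd 1, so every pairwise sample
    correlation is zero to round-off and every VIF equals 1.
    Returns an array of shape (n_units, n_times, p).
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    n = n_units * n_times
    if p >= n:
        raise ValueError(f"need p < n_units * n_times, got p={p}, records={n}")
    if rng is None:
        rng = np.random.default_rng()
    raw = rng.standard_normal((n, p))
    basis = np.column_stack([np.ones(n), raw])
    Q, _ = np.linalg.qr(basis)
    cols = Q[:, 1 : p + 1]                      # orthogonal to 1 and each other
    cols = cols / cols.std(axis=0, ddof=0)      # exact mean 0 by construction
    return cols.reshape(n_units, n_times, p)


def compute_vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factor ``1 / (1 - R^2_j)`` per covariate column.

    ``X`` may be (records, p) or (units, times, p).  Computed as the diagonal
    of the inverse correlation matrix, the closed form of the regression
    definition.  Exact collinearity is reported as ``inf`` with a warning.
    """
    X2 = np.asarray(X, dtype=float)
    if X2.ndim == 3:
        X2 = X2.reshape(-1, X2.shape[-1])
    p = X2.shape[1]
    if p < 1:
        raise ValueError("need at least one column")
    if np.any(X2.std(axis=0) == 0):
        raise ValueError("constant covariate column; VIF undefined")
    if p == 1:
        return np.ones(1)
    corr = np.corrcoef(X2, rowvar=False)
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0 or logdet < -30:
        logger.warning("exactly collinear covariates: VIF reported as inf")
        vif = np.full(p, np.inf)
        # salvage finite entries for columns not in the collinear set
        for j in range(p):
            others = np.delete(np.arange(p), j)
            sub = corr[np.ix_(others, others)]
            r2 = float(corr[j, others] @ np.linalg.pinv(sub) @ corr[others, j])
            if r2 < 1.0 - 1e-12:
                vif[j] = 1.0 / (1.0 - r2)
        return vif
    return np.diag(np.linalg.inv(corr)).copy()


def build_knn_adjacency(coords: np.ndarray, k: int = 4) -> SpatialGraph:
    """Symmetrized k-nearest-neighbour adjacency over unit coordinates.

    Units i and j are neighbours if either is among the other's ``k`` nearest
    points (Euclidean distance), which guarantees a symmetric binary graph
    with no isolated construction artefacts beyond genuine outliers.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if not 0 < k < n:
        raise ValueError(f"need 0 < k < n_units, got k={k}, n_units={n}")
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)        # first hit is the point itself
    W = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    W[rows, idx[:, 1:].ravel()] = 1.0
    W = np.maximum(W, W.T)
    np.fill_diagonal(W, 0.0)
    return SpatialGraph(W)


def _zero_truncated_poisson(
    lam: np.ndarray, rng: np.random.Generator, small: float = 0.1
) -> np.ndarray:
    """Sample y >= 1 with P(y = k) ∝ Poisson(k; lam), k >= 1.

    Rejection of zeros for moderate lam; inverse-CDF through the truncated
    uniform slice for small lam, where rejection would stall.
    """
    lam = np.asarray(lam, dtype=float)
    y = np.zeros(lam.shape, dtype=np.int64)
    big = lam >= small
    if big.any():
        lam_b = lam[big]
        draws = rng.poisson(lam_b)
        while True:
            zero = draws == 0
            if not zero.any():
                break
            draws[zero] = rng.poisson(lam_b[zero])
        y[big] = draws
    if (~big).any():
        lam_s = lam[~big]
        p0 = np.exp(-lam_s)
        u = p0 + rng.uniform(size=lam_s.shape) * (1.0 - p0)
        y[~big] = stats.poisson.ppf(np.clip(u, None, 1.0 - 1e-16), lam_s).astype(
            np.int64
        )
    return np.maximum(y, 1)


def generate_panel(
    scenario: Scenario,
    rng: np.random.Generator | None = None,
    *,
    p: int = 10,
    knn_k: int = 4,
    latent_scale: float = 0.5,
    latent_bound: float = 10.0,
    fresh_spatial_noise_per_time: bool = False,
) -> SimulatedPanel:
    """Generate one replication of the panel-count data.

    The latent field is the sum of a per-unit spatial term (x-coordinate plus
    correlated spatial noise, constant over time) and a per-time temporal term
    (correlated temporal noise, shared across units).  It is centred and
    multiplied by ``latent_scale`` before exponentiation; if its magnitude
    still exceeds ``latent_bound`` the replication is rescaled with a warning,
    guarding against overflow at extreme correlations.

    ``fresh_spatial_noise_per_time`` redraws the spatial noise at every time
    point instead of once per replication; it is off by default (the default
    decomposition is the one in which the temporal noise is replicated across
    units and the spatial term is constant over time).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    coords = rng.standard_normal((scenario.n_units, 2))
    spatial_noise, temporal_noise = generate_noise(scenario, rng)

    if fresh_spatial_noise_per_time:
        cov_s = equicorrelation_matrix(scenario.n_units, scenario.sp)
        ls = np.linalg.cholesky(cov_s)
        extra = ls @ rng.standard_normal((scenario.n_units, scenario.n_times - 1))
        s_field = np.column_stack([spatial_noise, extra]) + coords[:, [0]]
    else:
        s_field = (coords[:, 0] + spatial_noise)[:, None]

    g = s_field + temporal_noise[None, :]
    g = latent_scale * (g - g.mean())
    m = np.abs(g).max()
    if m > latent_bound:
        logger.warning(
            "latent field magnitude %.2f exceeds bound %.2f; rescaling", m, latent_bound
        )
        g = g * (latent_bound / m)
    lam = np.exp(np.broadcast_to(g, (scenario.n_units, scenario.n_times)).copy())

    y = _zero_truncated_poisson(lam, rng)
    X = generate_covariates(scenario.n_units, scenario.n_times, p=p, rng=rng)
    graph = build_knn_adjacency(coords, k=min(knn_k, scenario.n_units - 1))
    spatial_term = None if fresh_spatial_noise_per_time else (
        coords[:, 0] + spatial_noise
    )
    return SimulatedPanel(
        y=y,
        lam=lam,
        X=X,
        offset=np.zeros_like(lam),
        coords=coords,
        graph=graph,
        scenario=scenario,
        spatial_term=spatial_term,
        temporal_term=temporal_noise,
    )


def train_test_split(
    panel: SimulatedPanel,
    fraction: float = 0.7,
    rng: np.random.Generator | None = None,
) -> SplitPanel:
    """Uniform record-level partition into train (``fraction``) and test sets."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    if rng is None:
        rng = np.random.default_rng(panel.scenario.seed)
    n = panel.n_records
    perm = rng.permutation(n)
    n_train = int(round(fraction * n))
    return SplitPanel(
        train_index=np.sort(perm[:n_train]),
        test_index=np.sort(perm[n_train:]),
        train_fraction=fraction,
    )
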