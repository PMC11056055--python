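"""The four Bayesian spatio-temporal Poisson models.

All four share the Poisson observation layer with log link and offset,

    y_it ~ Poisson(mu_it),   log mu_it = eta_it + v_it,
    eta_it = x_it' beta + offset_it,

and differ in how the spatio-temporal random effect v_it is decomposed:

SPLTM (spatio-temporal Poisson linear trend model)
    v_it = omega1 + a_i + (omega2 + b_i) * (t - tbar) / T,  tbar = (T + 1) / 2;
    a ~ CAR(rho_int, k2_int, W), b ~ CAR(rho_slo, k2_slo, W); omega1, omega2 flat.
SPAM (spatio-temporal Poisson ANOVA model)
    v_it = a_i + b_t + c_it;  a ~ CAR(rho_s, k2_s, W), b ~ CAR(rho_T, k2_T, Z),
    c_it iid N(0, k2_I).
STSM (spatio-temporal Poisson separable model)
    v_it = a_it + b_t;  a_.t ~ CAR(rho_s, k2_t, W) independently per t,
    b ~ CAR(rho_T, k2, Z).
TMS (Poisson temporal model)
    v_it = a_it;  a_.1 ~ N(0, k2 Q(W, rho_s)^{-1}),
    a_.t | a_.(t-1) ~ N(rho_T a_.(t-1), k2 Q(W, rho_s)^{-1}).

Priors: every correlation rho is uniform on (0, 1); every variance k2 is
inverse-gamma; beta and the omegas are flat.  Each model exposes the joint
log posterior with its analytic gradient on an unconstrained scale (logit for
rho, log for k2, with Jacobian corrections), which is what the Hamiltonian
sampler consumes.  The CAR terms are evaluated through the cached Laplacian
eigendecomposition of the graphs, so one gradient costs a handful of small
dense matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.special import expit, gammaln

from .graphs import SpatialGraph, TemporalGraph, CarParams, car_log_density

MODEL_NAMES = ("SPLTM", "SPAM", "STSM", "TMS")
LOG2PI = float(np.log(2.0 * np.pi))
_ETA_BOUND = 200.0  # |log mu| beyond this is treated as a divergent state


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters shared by all variance components.

    Every variance k2 gets an inverse-gamma IG(ig_shape, ig_scale) prior
    (weakly informative default IG(1, 0.01)); every rho a uniform(0, 1);
    beta and the overall intercept/slope improper flat priors.
    """

    ig_shape: float = 1.0
    ig_scale: float = 0.01

    def __post_init__(self) -> None:
        if self.ig_shape <= 0 or self.ig_scale <= 0:
            raise ValueError("inverse-gamma hyperparameters must be positive")


@dataclass(eq=False)
class PanelData:
    """Observed panel plus graph structures, as consumed by the models.

    ``mask`` flags the unit-time cells that enter the likelihood; cells left
    out (the test set in validation runs) still have random effects, which are
    then constrained only by their priors.
    """

    y: np.ndarray
    offset: np.ndarray
    X: np.ndarray
    graph: SpatialGraph
    tgraph: TemporalGraph
    mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        N, T = self.y.shape
        if self.offset.shape != (N, T) or self.X.shape[:2] != (N, T):
            raise ValueError("y, offset and X dimensions are inconsistent")
        if self.graph.N != N or self.tgraph.T != T:
            raise ValueError("graph dimensions do not match the panel")
        if not np.all(np.isfinite(self.offset)):
            raise ValueError("offset must be finite")
        if self.mask is None:
            self.mask = np.ones((N, T), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.y.shape

    @property
    def p(self) -> int:
        return self.X.shape[2]


@dataclass
class ParameterState:
    """Constrained-scale parameter values of one model, keyed by symbol."""

    model: str
    params: dict[str, Any]

    def __getitem__(self, key: str):
        return self.params[key]


def _ig_logpdf(k2: float, shape: float, scale: float) -> float:
    return (
        shape * np.log(scale)
        - gammaln(shape)
        - (shape + 1.0) * np.log(k2)
        - scale / k2
    )


class STModel:
    """Base class: likelihood plumbing and the unconstrained-scale posterior.

    Subclasses define the parameter layout and the random-effect structure.
    The unconstrained vector theta stacks beta, the random effects, logit(rho)
    for each correlation and log(k2) for each variance, in the order given by
    ``flat_names``.
    """

    name: str

    def __init__(
        self,
        data: PanelData,
        priors: PriorConfig | None = None,
        centered: bool = True,
    ) -> None:
        self.data = data
        self.priors = priors or PriorConfig()
        self.centered = centered
        N, T = data.shape
        self.N, self.T, self.p = N, T, data.p
        self._Xf = np.ascontiguousarray(data.X.reshape(N * T, data.p))
        self._maskf = data.mask.astype(float)
        self._ymask = data.y * self._maskf
        self._lgam = float((gammaln(data.y + 1.0) * self._maskf).sum())
        self._Ls = np.ascontiguousarray(data.graph.laplacian)
        self._ds = np.ascontiguousarray(data.graph.laplacian_eigh[0])
        self._Lt = np.ascontiguousarray(data.tgraph.laplacian)
        self._dt = np.ascontiguousarray(data.tgraph.laplacian_eigh[0])
        self._build_layout()
        self._yf = np.ascontiguousarray(data.y, dtype=np.float64)
        self._off64 = np.ascontiguousarray(data.offset, dtype=np.float64)
        self._ig_const = float(
            self.priors.ig_shape * np.log(self.priors.ig_scale)
            - gammaln(self.priors.ig_shape)
        )
        self._kernel = None
        self._setup_kernel()

    # ---- layout ------------------------------------------------------
    def _build_layout(self) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    def _register(self, blocks: list[tuple[str, int]]) -> None:
        self._blocks = blocks
        self._slices: dict[str, slice] = {}
        off = 0
        for name, size in blocks:
            self._slices[name] = slice(off, off + size)
            off += size
        self.dim = off

    @property
    def flat_names(self) -> list[str]:
        out = []
        for name, size in self._blocks:
            if size == 1:
                out.append(name)
            else:
                out.extend(f"{name}[{k}]" for k in range(size))
        return out

    # names of the blocks holding logit(rho) / log(k2) in theta
    _rho_blocks: tuple[str, ...] = ()
    _var_blocks: tuple[str, ...] = ()

    # ---- constrained <-> unconstrained ------------------------------
    # With centered=False the effect blocks of theta hold phi_raw with
    # phi = sqrt(k2) * phi_raw, which decorrelates each effect from its
    # variance in the sampler (useful when the prior dominates, e.g.
    # prior-only sampling); with centered=True (default) theta holds the
    # natural-scale effects, which mixes faster on fully observed panels.
    _scaled_effects: tuple[tuple[str, str], ...] = ()

    def _scale_effects(self, params: dict) -> None:
        for eff, var in self._scaled_effects:
            params[eff] = params[eff] * np.sqrt(params[var])

    def _unscale_effects(self, params: dict) -> None:
        for eff, var in self._scaled_effects:
            params[eff] = np.asarray(params[eff], dtype=float) / np.sqrt(params[var])

    def unpack(self, theta: np.ndarray) -> ParameterState:
        """Map an unconstrained vector to a constrained, natural-scale state."""
        params: dict[str, Any] = {}
        for name, size in self._blocks:
            v = theta[self._slices[name]]
            if name in self._rho_blocks:
                v = expit(v)
            elif name in self._var_blocks:
                v = np.exp(v)
            params[name] = float(v[0]) if size == 1 else v.copy()
        if not self.centered:
            self._scale_effects(params)
        return ParameterState(self.name, self._reshape_params(params))

    def pack(self, state: ParameterState) -> np.ndarray:
        """Inverse of :meth:`unpack`."""
        theta = np.empty(self.dim)
        flat = self._flatten_params(dict(state.params))
        if not self.centered:
            self._unscale_effects(flat)
        for name, size in self._blocks:
            v = np.atleast_1d(np.asarray(flat[name], dtype=float)).ravel()
            if name in self._rho_blocks:
                v = np.log(v) - np.log1p(-v)
            elif name in self._var_blocks:
                v = np.log(v)
            theta[self._slices[name]] = v
        return theta

    def _reshape_params(self, params: dict) -> dict:
        return params

    def _flatten_params(self, params: dict) -> dict:
        return params

    # ---- likelihood --------------------------------------------------
    def _eta_base(self, beta: np.ndarray) -> np.ndarray:
        return self.data.offset + (self._Xf @ beta).reshape(self.N, self.T)

    def _loglik_and_resid(self, eta: np.ndarray):
        """Masked Poisson log likelihood and (y - mu) * mask, or (-inf, None)."""
        if np.abs(eta).max() > _ETA_BOUND:
            return -np.inf, None
        mu = np.exp(eta)
        ll = float((self._ymask * eta).sum() - (mu * self._maskf).sum()) - self._lgam
        if not np.isfinite(ll):
            return -np.inf, None
        return ll, (self.data.y - mu) * self._maskf

    def linear_predictor(self, state: ParameterState) -> np.ndarray:
        """log mu_it on the full panel (intercept key honoured if present)."""
        eta = self._eta_base(np.asarray(state["beta"], dtype=float))
        eta = eta + self._effects(state)
        return eta + state.params.get("intercept", 0.0)

    def _effects(self, state: ParameterState) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def pointwise_loglik(self, state: ParameterState) -> np.ndarray:
        """Per-cell Poisson log likelihood matrix (all cells, unmasked).

        A vanishing intensity (mu underflows to 0) with a positive count has
        zero likelihood, reported as -inf.
        """
        eta = self.linear_predictor(state)
        mu = np.exp(eta)
        pw = self.data.y * eta - mu - gammaln(self.data.y + 1.0)
        pw[(mu == 0.0) & (self.data.y >= 1)] = -np.inf
        return pw

    def log_likelihood(self, state: ParameterState) -> tuple[float, np.ndarray]:
        """Masked total log likelihood plus the full pointwise matrix."""
        pw = self.pointwise_loglik(state)
        total = float((pw * self._maskf).sum())
        if not np.isfinite(total):
            total = -np.inf
        return total, pw

    # ---- priors on the constrained scale ----------------------------
    def log_prior(self, state: ParameterState) -> float:
        """Joint log prior density at a constrained state (no Jacobians)."""
        rhos = [float(state[n]) for n in self._rho_state_names()]
        if any(not 0.0 < r < 1.0 for r in rhos):
            return -np.inf
        k2s = np.concatenate(
            [np.atleast_1d(state[n]) for n in self._var_state_names()]
        ).astype(float)
        if np.any(k2s <= 0.0):
            return -np.inf
        lp = float(
            sum(_ig_logpdf(v, self.priors.ig_shape, self.priors.ig_scale) for v in k2s)
        )
        return lp + self._effect_log_prior(state)

    def _rho_state_names(self) -> tuple[str, ...]:
        return self._rho_blocks

    def _var_state_names(self) -> tuple[str, ...]:
        return self._var_blocks

    def _effect_log_prior(self, state: ParameterState) -> float:  # pragma: no cover
        raise NotImplementedError

    # ---- the sampler target ------------------------------------------
    def _setup_kernel(self) -> None:
        """Attach the compiled gradient kernel for the centered path, if any."""

    def logp_and_grad(
        self, theta: np.ndarray, include_likelihood: bool = True
    ) -> tuple[float, np.ndarray]:
        """Unnormalised log posterior (plus transform Jacobians) and gradient.

        Dispatches to the compiled kernel on the centered parameterization;
        the numpy implementation (``_logp_and_grad_py``) is the reference and
        the only path for the non-centered parameterization.
        """
        if self.centered and self._kernel is not None:
            return self._kernel(theta, *self._kernel_args, include_likelihood)
        return self._logp_and_grad_py(theta, include_likelihood)

    def _logp_and_grad_py(
        self, theta: np.ndarray, include_likelihood: bool = True
    ) -> tuple[float, np.ndarray]:  # pragma: no cover - abstract
        raise NotImplementedError

    # ---- initialisation ---------------------------------------------
    def initial_theta(self, rng: np.random.Generator) -> np.ndarray:
        """Moment-matched starting point: beta from a log-scale least-squares
        fit, random effects at zero plus jitter, rho at 0.5, k2 at 0.1."""
        N, T = self.N, self.T
        z = (np.log(self.data.y + 0.5) - self.data.offset).ravel()
        w = self._maskf.ravel() > 0
        beta, *_ = np.linalg.lstsq(self._Xf[w], z[w], rcond=None)
        for attempt in range(100):
            theta = np.zeros(self.dim)
            scale = 0.01 * (1.0 + attempt)
            theta += scale * rng.standard_normal(self.dim)
            sl = self._slices["beta"]
            theta[sl] = beta + scale * rng.standard_normal(self.p)
            for name in self._var_blocks:
                theta[self._slices[name]] = np.log(0.1) + scale * rng.standard_normal(
                    self._slices[name].stop - self._slices[name].start
                )
            for name in self._rho_blocks:
                theta[self._slices[name]] = scale * rng.standard_normal(
                    self._slices[name].stop - self._slices[name].start
                )
            lp, _ = self.logp_and_grad(theta)
            if np.isfinite(lp):
                return theta
        raise RuntimeError("could not find a finite starting point")

    # ---- shared pieces for subclasses --------------------------------
    def _transform_tail(self, theta: np.ndarray):
        """Decode rho/k2 blocks; return (rhos, k2s, tail log prior, tail grads).

        tail log prior = uniform-with-logit Jacobian for each rho plus
        IG-with-log Jacobian for each k2; the gradients returned are with
        respect to the *unconstrained* coordinates.
        """
        a, b = self.priors.ig_shape, self.priors.ig_scale
        try:
            ig_const = self._ig_const
        except AttributeError:
            ig_const = self._ig_const = float(a * np.log(b) - gammaln(a))
        rhos: dict[str, np.ndarray] = {}
        k2s: dict[str, np.ndarray] = {}
        lp = 0.0
        with np.errstate(divide="ignore", over="ignore"):
            for name in self._rho_blocks:
                t = theta[self._slices[name]]
                r = expit(t)
                rhos[name] = r
                lp += float((np.log(r) + np.log1p(-r)).sum())
            for name in self._var_blocks:
                s = theta[self._slices[name]]
                k2 = np.exp(s)
                k2s[name] = k2
                lp += s.size * ig_const - a * float(s.sum()) - b * float(
                    (1.0 / k2).sum()
                )
        return rhos, k2s, lp

    @staticmethod
    def _car_block(phi: np.ndarray, rho: float, k2: float, L: np.ndarray,
                   d: np.ndarray):
        """Log density, grad wrt phi, and d/drho, d/dk2 of one CAR term."""
        n = phi.shape[0]
        u = L @ phi
        pl = float(phi @ u)
        pp = float(phi @ phi)
        q = rho * d + (1.0 - rho)
        qf = rho * pl + (1.0 - rho) * pp
        logp = (
            0.5 * float(np.log(q).sum())
            - 0.5 * n * (LOG2PI + np.log(k2))
            - 0.5 * qf / k2
        )
        gphi = -(rho * u + (1.0 - rho) * phi) / k2
        grho = 0.5 * float(((d - 1.0) / q).sum()) - 0.5 * (pl - pp) / k2
        gk2 = -0.5 * n / k2 + 0.5 * qf / (k2 * k2)
        return logp, gphi, grho, gk2


# ----------------------------------------------------------------------
class SPLTM(STModel):
    """Linear-trend model: CAR intercepts and CAR slopes over a centred time score."""

    name = "SPLTM"

    def _build_layout(self) -> None:
        N, T, p = self.N, self.T, self.p
        self._register(
            [
                ("beta", p), ("omega1", 1), ("omega2", 1),
                ("a", N), ("b", N),
                ("rho_int", 1), ("rho_slo", 1), ("k2_int", 1), ("k2_slo", 1),
            ]
        )
        t = np.arange(1, T + 1, dtype=float)
        self._score = (t - (T + 1) / 2.0) / T  # (t - tbar)/T, tbar = (T+1)/2

    _rho_blocks = ("rho_int", "rho_slo")
    _var_blocks = ("k2_int", "k2_slo")
    _scaled_effects = (("a", "k2_int"), ("b", "k2_slo"))

    def _setup_kernel(self) -> None:
        try:
            from . import _kernels
        except ImportError:
            return
        self._kernel = _kernels.spltm_kernel
        self._kernel_args = (
            self.N, self.T, self.p, self._Xf, self._yf, self._off64,
            self._maskf, self._lgam, self._Ls, self._ds, self._score,
            self.priors.ig_shape, self.priors.ig_scale, self._ig_const,
        )

    def _effects(self, state: ParameterState) -> np.ndarray:
        a = np.asarray(state["a"])
        b = np.asarray(state["b"])
        return (
            state["omega1"]
            + a[:, None]
            + (state["omega2"] + b[:, None]) * self._score[None, :]
        )

    def _effect_log_prior(self, state: ParameterState) -> float:
        lp = car_log_density(
            np.asarray(state["a"]), CarParams(state["rho_int"], state["k2_int"]),
            self.data.graph,
        )
        lp += car_log_density(
            np.asarray(state["b"]), CarParams(state["rho_slo"], state["k2_slo"]),
            self.data.graph,
        )
        return lp

    def _logp_and_grad_py(self, theta, include_likelihood=True):
        sl = self._slices
        cen = self.centered
        beta = theta[sl["beta"]]
        om1 = theta[sl["omega1"]][0]
        om2 = theta[sl["omega2"]][0]
        a_th = theta[sl["a"]]
        b_th = theta[sl["b"]]
        rhos, k2s, lp_tail = self._transform_tail(theta)
        r_int = float(rhos["rho_int"][0]); r_slo = float(rhos["rho_slo"][0])
        v_int = float(k2s["k2_int"][0]); v_slo = float(k2s["k2_slo"][0])
        shp, scl = self.priors.ig_shape, self.priors.ig_scale

        grad = np.zeros(self.dim)
        logp = lp_tail

        if cen:
            a, b = a_th, b_th
            lpa, ga, gra, gva = self._car_block(a, r_int, v_int, self._Ls, self._ds)
            lpb, gb, grb, gvb = self._car_block(b, r_slo, v_slo, self._Ls, self._ds)
            grad[sl["k2_int"]] += gva * v_int
            grad[sl["k2_slo"]] += gvb * v_slo
        else:
            s_int = np.sqrt(v_int); s_slo = np.sqrt(v_slo)
            a, b = s_int * a_th, s_slo * b_th
            lpa, ga, gra, _ = self._car_block(a_th, r_int, 1.0, self._Ls, self._ds)
            lpb, gb, grb, _ = self._car_block(b_th, r_slo, 1.0, self._Ls, self._ds)
        logp += lpa + lpb
        grad[sl["a"]] += ga
        grad[sl["b"]] += gb
        grad[sl["rho_int"]] += gra * r_int * (1 - r_int) + (1 - 2 * r_int)
        grad[sl["rho_slo"]] += grb * r_slo * (1 - r_slo) + (1 - 2 * r_slo)
        grad[sl["k2_int"]] += -shp + scl / v_int
        grad[sl["k2_slo"]] += -shp + scl / v_slo

        if include_likelihood:
            eta = (
                self._eta_base(beta)
                + om1
                + a[:, None]
                + (om2 + b[:, None]) * self._score[None, :]
            )
            ll, resid = self._loglik_and_resid(eta)
            if not np.isfinite(ll):
                return -np.inf, np.zeros(self.dim)
            logp += ll
            grad[sl["beta"]] += self._Xf.T @ resid.ravel()
            grad[sl["omega1"]] += resid.sum()
            rs = resid @ self._score
            grad[sl["omega2"]] += rs.sum()
            gla = resid.sum(axis=1)
            if cen:
                grad[sl["a"]] += gla
                grad[sl["b"]] += rs
            else:
                grad[sl["a"]] += s_int * gla
                grad[sl["b"]] += s_slo * rs
                grad[sl["k2_int"]] += 0.5 * float(a @ gla)
                grad[sl["k2_slo"]] += 0.5 * float(b @ rs)
        return logp, grad


# ----------------------------------------------------------------------
class SPAM(STModel):
    """ANOVA-type model: spatial main effect + temporal main effect + iid interaction."""

    name = "SPAM"

    def _build_layout(self) -> None:
        N, T, p = self.N, self.T, self.p
        self._register(
            [
                ("beta", p), ("a", N), ("b", T), ("c", N * T),
                ("rho_s", 1), ("rho_T", 1),
                ("k2_s", 1), ("k2_T", 1), ("k2_I", 1),
            ]
        )

    _rho_blocks = ("rho_s", "rho_T")
    _var_blocks = ("k2_s", "k2_T", "k2_I")
    _scaled_effects = (("a", "k2_s"), ("b", "k2_T"), ("c", "k2_I"))

    def _setup_kernel(self) -> None:
        try:
            from . import _kernels
        except ImportError:
            return
        self._kernel = _kernels.spam_kernel
        self._kernel_args = (
            self.N, self.T, self.p, self._Xf, self._yf, self._off64,
            self._maskf, self._lgam, self._Ls, self._ds, self._Lt, self._dt,
            self.priors.ig_shape, self.priors.ig_scale, self._ig_const,
        )

    def _reshape_params(self, params: dict) -> dict:
        params["c"] = params["c"].reshape(self.N, self.T)
        return params

    def _flatten_params(self, params: dict) -> dict:
        params = dict(params)
        params["c"] = np.asarray(params["c"]).reshape(-1)
        return params

    def _effects(self, state: ParameterState) -> np.ndarray:
        return (
            np.asarray(state["a"])[:, None]
            + np.asarray(state["b"])[None, :]
            + np.asarray(state["c"])
        )

    def _effect_log_prior(self, state: ParameterState) -> float:
        lp = car_log_density(
            np.asarray(state["a"]), CarParams(state["rho_s"], state["k2_s"]),
            self.data.graph,
        )
        lp += car_log_density(
            np.asarray(state["b"]), CarParams(state["rho_T"], state["k2_T"]),
            self.data.tgraph,
        )
        c = np.asarray(state["c"])
        k2I = float(state["k2_I"])
        lp += -0.5 * c.size * (LOG2PI + np.log(k2I)) - 0.5 * float(
            (c * c).sum()
        ) / k2I
        return lp

    def _logp_and_grad_py(self, theta, include_likelihood=True):
        sl = self._slices
        cen = self.centered
        N, T = self.N, self.T
        beta = theta[sl["beta"]]
        a_th = theta[sl["a"]]
        b_th = theta[sl["b"]]
        c_th = theta[sl["c"]]
        rhos, k2s, lp_tail = self._transform_tail(theta)
        r_s = float(rhos["rho_s"][0]); r_T = float(rhos["rho_T"][0])
        v_s = float(k2s["k2_s"][0]); v_T = float(k2s["k2_T"][0])
        v_I = float(k2s["k2_I"][0])

        grad = np.zeros(self.dim)
        logp = lp_tail
        shp, scl = self.priors.ig_shape, self.priors.ig_scale

        if cen:
            a, b, c = a_th, b_th, c_th
            lpa, ga, gra, gva = self._car_block(a, r_s, v_s, self._Ls, self._ds)
            lpb, gb, grb, gvb = self._car_block(b, r_T, v_T, self._Lt, self._dt)
            cc = float(c @ c)
            lpc = -0.5 * c.size * (LOG2PI + np.log(v_I)) - 0.5 * cc / v_I
            gc = -c / v_I
            grad[sl["k2_s"]] += gva * v_s
            grad[sl["k2_T"]] += gvb * v_T
            grad[sl["k2_I"]] += -0.5 * c.size + 0.5 * cc / v_I
        else:
            s_s = np.sqrt(v_s); s_T = np.sqrt(v_T); s_I = np.sqrt(v_I)
            a, b, c = s_s * a_th, s_T * b_th, s_I * c_th
            lpa, ga, gra, _ = self._car_block(a_th, r_s, 1.0, self._Ls, self._ds)
            lpb, gb, grb, _ = self._car_block(b_th, r_T, 1.0, self._Lt, self._dt)
            lpc = -0.5 * c_th.size * LOG2PI - 0.5 * float(c_th @ c_th)
            gc = -c_th
        logp += lpa + lpb + lpc
        grad[sl["a"]] += ga
        grad[sl["b"]] += gb
        grad[sl["c"]] += gc
        grad[sl["rho_s"]] += gra * r_s * (1 - r_s) + (1 - 2 * r_s)
        grad[sl["rho_T"]] += grb * r_T * (1 - r_T) + (1 - 2 * r_T)
        grad[sl["k2_s"]] += -shp + scl / v_s
        grad[sl["k2_T"]] += -shp + scl / v_T
        grad[sl["k2_I"]] += -shp + scl / v_I

        if include_likelihood:
            eta = (
                self._eta_base(beta)
                + a[:, None]
                + b[None, :]
                + c.reshape(N, T)
            )
            ll, resid = self._loglik_and_resid(eta)
            if not np.isfinite(ll):
                return -np.inf, np.zeros(self.dim)
            logp += ll
            rf = resid.ravel()
            gla = resid.sum(axis=1)
            glb = resid.sum(axis=0)
            grad[sl["beta"]] += self._Xf.T @ rf
            if cen:
                grad[sl["a"]] += gla
                grad[sl["b"]] += glb
                grad[sl["c"]] += rf
            else:
                grad[sl["a"]] += s_s * gla
                grad[sl["b"]] += s_T * glb
                grad[sl["c"]] += s_I * rf
                grad[sl["k2_s"]] += 0.5 * float(a @ gla)
                grad[sl["k2_T"]] += 0.5 * float(b @ glb)
                grad[sl["k2_I"]] += 0.5 * float(c @ rf)
        return logp, grad


# ----------------------------------------------------------------------
class STSM(STModel):
    """Separable model: per-time spatial CAR fields plus a temporal CAR trend."""

    name = "STSM"

    def _build_layout(self) -> None:
        N, T, p = self.N, self.T, self.p
        self._register(
            [
                ("beta", p), ("a", N * T), ("b", T),
                ("rho_s", 1), ("rho_T", 1),
                ("k2_t", T), ("k2", 1),
            ]
        )

    _rho_blocks = ("rho_s", "rho_T")
    _var_blocks = ("k2_t", "k2")

    def _setup_kernel(self) -> None:
        try:
            from . import _kernels
        except ImportError:
            return
        self._kernel = _kernels.stsm_kernel
        self._kernel_args = (
            self.N, self.T, self.p, self._Xf, self._yf, self._off64,
            self._maskf, self._lgam, self._Ls, self._ds, self._Lt, self._dt,
            self.priors.ig_shape, self.priors.ig_scale, self._ig_const,
        )

    def _scale_effects(self, params: dict) -> None:
        scale_t = np.sqrt(np.atleast_1d(params["k2_t"]))
        params["a"] = (
            params["a"].reshape(self.N, self.T) * scale_t[None, :]
        ).ravel()
        params["b"] = params["b"] * np.sqrt(params["k2"])

    def _unscale_effects(self, params: dict) -> None:
        scale_t = np.sqrt(np.atleast_1d(params["k2_t"]))
        params["a"] = (
            np.asarray(params["a"], dtype=float).reshape(self.N, self.T)
            / scale_t[None, :]
        ).ravel()
        params["b"] = np.asarray(params["b"], dtype=float) / np.sqrt(params["k2"])

    def _reshape_params(self, params: dict) -> dict:
        params["a"] = params["a"].reshape(self.N, self.T)
        return params

    def _flatten_params(self, params: dict) -> dict:
        params = dict(params)
        params["a"] = np.asarray(params["a"]).reshape(-1)
        return params

    def _effects(self, state: ParameterState) -> np.ndarray:
        return np.asarray(state["a"]) + np.asarray(state["b"])[None, :]

    def _effect_log_prior(self, state: ParameterState) -> float:
        A = np.asarray(state["a"])
        k2_t = np.atleast_1d(state["k2_t"])
        lp = sum(
            car_log_density(
                A[:, t], CarParams(state["rho_s"], float(k2_t[t])), self.data.graph
            )
            for t in range(self.T)
        )
        lp += car_log_density(
            np.asarray(state["b"]), CarParams(state["rho_T"], float(state["k2"])),
            self.data.tgraph,
        )
        return lp

    def _logp_and_grad_py(self, theta, include_likelihood=True):
        sl = self._slices
        cen = self.centered
        N, T = self.N, self.T
        beta = theta[sl["beta"]]
        A_th = theta[sl["a"]].reshape(N, T)
        b_th = theta[sl["b"]]
        rhos, k2s, lp_tail = self._transform_tail(theta)
        r_s = float(rhos["rho_s"][0]); r_T = float(rhos["rho_T"][0])
        v_t = k2s["k2_t"]
        v_b = float(k2s["k2"][0])

        grad = np.zeros(self.dim)
        logp = lp_tail
        shp, scl = self.priors.ig_shape, self.priors.ig_scale

        # T spatial CAR fields sharing rho_s, one variance per time point
        U = self._Ls @ A_th                    # (N, T)
        pl = np.einsum("nt,nt->t", A_th, U)
        pp = np.einsum("nt,nt->t", A_th, A_th)
        q = r_s * self._ds + (1.0 - r_s)
        qf = r_s * pl + (1.0 - r_s) * pp
        if cen:
            A, b = A_th, b_th
            logp += float(
                T * 0.5 * np.log(q).sum()
                - 0.5 * N * T * LOG2PI
                - 0.5 * N * np.log(v_t).sum()
                - 0.5 * (qf / v_t).sum()
            )
            grad[sl["a"]] += (-(r_s * U + (1.0 - r_s) * A_th) / v_t[None, :]).ravel()
            gr_s = T * 0.5 * float(((self._ds - 1.0) / q).sum()) - 0.5 * float(
                ((pl - pp) / v_t).sum()
            )
            grad[sl["k2_t"]] += -0.5 * N + 0.5 * qf / v_t
            lpb, gb, grb, gvb = self._car_block(b, r_T, v_b, self._Lt, self._dt)
            grad[sl["k2"]] += gvb * v_b
        else:
            scale_t = np.sqrt(v_t)
            s_b = np.sqrt(v_b)
            A = A_th * scale_t[None, :]
            b = s_b * b_th
            logp += float(
                T * 0.5 * np.log(q).sum() - 0.5 * N * T * LOG2PI - 0.5 * qf.sum()
            )
            grad[sl["a"]] += (-(r_s * U + (1.0 - r_s) * A_th)).ravel()
            gr_s = T * 0.5 * float(((self._ds - 1.0) / q).sum()) - 0.5 * float(
                (pl - pp).sum()
            )
            lpb, gb, grb, _ = self._car_block(b_th, r_T, 1.0, self._Lt, self._dt)
        logp += lpb
        grad[sl["b"]] += gb
        grad[sl["rho_s"]] += gr_s * r_s * (1 - r_s) + (1 - 2 * r_s)
        grad[sl["rho_T"]] += grb * r_T * (1 - r_T) + (1 - 2 * r_T)
        grad[sl["k2_t"]] += -shp + scl / v_t
        grad[sl["k2"]] += -shp + scl / v_b

        if include_likelihood:
            eta = self._eta_base(beta) + A + b[None, :]
            ll, resid = self._loglik_and_resid(eta)
            if not np.isfinite(ll):
                return -np.inf, np.zeros(self.dim)
            logp += ll
            glb = resid.sum(axis=0)
            grad[sl["beta"]] += self._Xf.T @ resid.ravel()
            grad[sl["b"]] += glb if cen else s_b * glb
            if cen:
                grad[sl["a"]] += resid.ravel()
            else:
                grad[sl["a"]] += (resid * scale_t[None, :]).ravel()
                grad[sl["k2_t"]] += 0.5 * np.einsum("nt,nt->t", A, resid)
                grad[sl["k2"]] += 0.5 * float(b @ glb)
        return logp, grad


# ----------------------------------------------------------------------
class TMS(STModel):
    """Lag-one temporal autoregression of spatial CAR fields."""

    name = "TMS"

    def _build_layout(self) -> None:
        N, T, p = self.N, self.T, self.p
        self._register(
            [
                ("beta", p), ("a", N * T),
                ("rho_s", 1), ("rho_T", 1), ("k2", 1),
            ]
        )

    _rho_blocks = ("rho_s", "rho_T")
    _var_blocks = ("k2",)
    _scaled_effects = (("a", "k2"),)

    def _setup_kernel(self) -> None:
        try:
            from . import _kernels
        except ImportError:
            return
        self._kernel = _kernels.tms_kernel
        self._kernel_args = (
            self.N, self.T, self.p, self._Xf, self._yf, self._off64,
            self._maskf, self._lgam, self._Ls, self._ds,
            self.priors.ig_shape, self.priors.ig_scale, self._ig_const,
        )

    def _reshape_params(self, params: dict) -> dict:
        params["a"] = params["a"].reshape(self.N, self.T)
        return params

    def _flatten_params(self, params: dict) -> dict:
        params = dict(params)
        params["a"] = np.asarray(params["a"]).reshape(-1)
        return params

    def _effects(self, state: ParameterState) -> np.ndarray:
        return np.asarray(state["a"])

    def _effect_log_prior(self, state: ParameterState) -> float:
        A = np.asarray(state["a"])
        r_s = float(state["rho_s"]); r_T = float(state["rho_T"])
        k2 = float(state["k2"])
        if not (0 < r_s < 1 and 0 < r_T < 1) or k2 <= 0:
            return -np.inf
        E = A.copy()
        E[:, 1:] -= r_T * A[:, :-1]
        d = self._ds
        q = r_s * d + (1.0 - r_s)
        U = self._Ls @ E
        qf = r_s * np.einsum("nt,nt->", E, U) + (1.0 - r_s) * np.einsum(
            "nt,nt->", E, E
        )
        return float(
            self.T * 0.5 * np.sum(np.log(q))
            - 0.5 * self.N * self.T * (LOG2PI + np.log(k2))
            - 0.5 * qf / k2
        )

    def _logp_and_grad_py(self, theta, include_likelihood=True):
        sl = self._slices
        cen = self.centered
        N, T = self.N, self.T
        beta = theta[sl["beta"]]
        A_th = theta[sl["a"]].reshape(N, T)
        rhos, k2s, lp_tail = self._transform_tail(theta)
        r_s = float(rhos["rho_s"][0]); r_T = float(rhos["rho_T"][0])
        k2 = float(k2s["k2"][0])

        grad = np.zeros(self.dim)
        logp = lp_tail
        shp, scl = self.priors.ig_shape, self.priors.ig_scale

        # lag-one autoregression of spatial CAR innovations
        vv = k2 if cen else 1.0
        E = A_th.copy()
        E[:, 1:] -= r_T * A_th[:, :-1]
        U = self._Ls @ E
        QE = r_s * U + (1.0 - r_s) * E           # Q(W, rho_s) e_t per column
        q = r_s * self._ds + (1.0 - r_s)
        pl = float(np.einsum("nt,nt->", E, U))
        pp = float(np.einsum("nt,nt->", E, E))
        qf = r_s * pl + (1.0 - r_s) * pp
        logp += (
            T * 0.5 * float(np.log(q).sum())
            - 0.5 * N * T * (LOG2PI + np.log(vv))
            - 0.5 * qf / vv
        )
        gA = -QE / vv
        gA[:, :-1] += r_T * QE[:, 1:] / vv
        grad[sl["a"]] += gA.ravel()
        gr_T = float(np.einsum("nt,nt->", QE[:, 1:], A_th[:, :-1])) / vv
        grad[sl["rho_T"]] += gr_T * r_T * (1 - r_T) + (1 - 2 * r_T)
        gr_s = T * 0.5 * float(((self._ds - 1.0) / q).sum()) - 0.5 * (pl - pp) / vv
        grad[sl["rho_s"]] += gr_s * r_s * (1 - r_s) + (1 - 2 * r_s)
        grad[sl["k2"]] += -shp + scl / k2
        if cen:
            grad[sl["k2"]] += -0.5 * N * T + 0.5 * qf / k2

        if include_likelihood:
            sk = 1.0 if cen else np.sqrt(k2)
            A = A_th if cen else sk * A_th
            eta = self._eta_base(beta) + A
            ll, resid = self._loglik_and_resid(eta)
            if not np.isfinite(ll):
                return -np.inf, np.zeros(self.dim)
            logp += ll
            grad[sl["beta"]] += self._Xf.T @ resid.ravel()
            if cen:
                grad[sl["a"]] += resid.ravel()
            else:
                grad[sl["a"]] += sk * resid.ravel()
                grad[sl["k2"]] += 0.5 * float(np.einsum("nt,nt->", A, resid))
        return logp, grad


_MODEL_CLASSES = {"SPLTM": SPLTM, "SPAM": SPAM, "STSM": STSM, "TMS": TMS}


def build_model(
    name: str,
    data: PanelData,
    priors: PriorConfig | None = None,
    centered: bool = True,
) -> STModel:
    """Instantiate one of the four models by its enum name.

    ``centered`` selects the sampling parameterization of the random effects
    (natural scale vs. unit-scale effects multiplied by sqrt(k2)); both target
    the same posterior.
    """
    try:
        cls = _MODEL_CLASSES[name.upper()]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    return cls(data, priors, centered=centered)


# ---- module-level operation surface ----------------------------------
def linear_predictor(model: STModel, state: ParameterState) -> np.ndarray:
    if state.model != model.name:
        raise ValueError(f"state is for {state.model}, model is {model.name}")
    return model.linear_predictor(state)


def log_likelihood(state: ParameterState, model: STModel) -> tuple[float, np.ndarray]:
    if state.model != model.name:
        raise ValueError(f"state is for {state.model}, model is {model.name}")
    return model.log_likelihood(state)


def log_prior(state: ParameterState, model: STModel) -> float:
    if state.model != model.name:
        raise ValueError(f"state is for {state.model}, model is {model.name}")
    return model.log_prior(state)


def log_posterior(state: ParameterState, model: STModel) -> float:
    lp = log_prior(state, model)
    if not np.isfinite(lp):
        return -np.inf
    ll, _ = log_likelihood(state, model)
    return ll + lp


def recenter_effects(state: ParameterState) -> ParameterState:
    """Sum-to-zero post-processing of main random effects.

    Recentres the spatial (and temporal) main effects and folds the removed
    means into the intercept terms (omega1/omega2 for SPLTM, an explicit
    ``intercept`` entry for SPAM), leaving the fitted log mu unchanged.
    Models whose effects are cell-level (STSM, TMS) are returned unchanged.
    """
    p = dict(state.params)
    if state.model == "SPLTM":
        abar = float(np.mean(p["a"]))
        bbar = float(np.mean(p["b"]))
        p["a"] = p["a"] - abar
        p["b"] = p["b"] - bbar
        p["omega1"] = p["omega1"] + abar
        p["omega2"] = p["omega2"] + bbar
    elif state.model == "SPAM":
        abar = float(np.mean(p["a"]))
        bbar = float(np.mean(p["b"]))
        p["a"] = p["a"] - abar
        p["b"] = p["b"] - bbar
        p["intercept"] = p.get("intercept", 0.0) + abar + bbar
    return ParameterState(state.model, p)
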