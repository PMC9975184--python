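"""Bayesian state-space model of the treatment effect.

Observation model, per session s and 1-min bin t (normalized amplitude or
convulsion-rate scale)::

    y[s,t] = yhat[t] + u[s]*d_M + v[s]*d_T[t] + eps,   eps ~ Normal(0, sigma^2)

with subject coding u = -1/+1 (exactly two subjects), treatment coding
v = 0 (vehicle) / 1 (DCZ), and process models

* basic trend ``yhat``: second-order random walk — its increments follow a
  Normal random walk with innovation scale ``sigma_y``;
* treatment effect ``d_T``: Cauchy-increment random walk with scale
  ``sigma_T`` (heavy tails permit abrupt onsets);
* subject effect ``d_M`` ~ Normal(0, sigma_M^2), a single scalar.

Inference is by a Gibbs sampler.  Each Cauchy increment is represented as a
scale mixture of normals (Student-t with one degree of freedom:
``delta | lam ~ Normal(0, scale^2/lam)``, ``lam ~ Gamma(1/2, 1/2)``), which
makes the joint latent block (yhat, d_M, d_T) exactly Gaussian given the
scales and mixing variables; it is drawn in one shot from its banded-
precision conditional via Cholesky factorization.  The four scale parameters
get weakly-informative half-Cauchy(0, 2.5) priors and are updated by 1-D
slice sampling.  The MAP estimate is the stored draw maximizing the joint
log posterior (with the Cauchy terms evaluated exactly, mixing variables
marginalized out), optionally refined by local optimization.

The headline summary mirrors the study's evaluation: posterior draws of the
window mean of ``yhat + v*d_T`` over the 3 min before ([-3, 0)) and after
([0, 3)) treatment, per treatment group, reported as MAP point plus central
99 % credible interval, with significance declared when the two post-
treatment intervals are disjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.stats

from .ecog import NormalizedSeries

DEFAULT_BIN_RANGE = (-15, 15)
PRE_WINDOW_MIN = (-3.0, 0.0)
POST_WINDOW_MIN = (0.0, 3.0)


class DesignError(ValueError):
    """Raised when session metadata cannot be coded into the model design."""


@dataclass
class StateSpaceData:
    """Aligned observation matrix and session codings.

    ``y`` is (n_sessions, n_bins) with NaN marking missing cells; ``u`` in
    {-1, +1} codes the two subjects; ``v`` in {0, 1} codes vehicle/DCZ.
    """

    bin_start_min: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    session_ids: tuple[str, ...] = ()
    subjects: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.bin_start_min = np.asarray(self.bin_start_min, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        S, T = self.y.shape
        if self.bin_start_min.shape != (T,) or self.u.shape != (S,) or self.v.shape != (S,):
            raise DesignError("inconsistent design dimensions")
        if not set(np.unique(self.u)).issubset({-1.0, 1.0}):
            raise DesignError("u must be coded -1/+1")
        if not set(np.unique(self.v)).issubset({0.0, 1.0}):
            raise DesignError("v must be coded 0/1")
        obs = ~np.isnan(self.y)
        pre = self.bin_start_min < 0
        for s in range(S):
            if not obs[s, pre].any() or not obs[s, ~pre].any():
                raise DesignError(
                    f"session {s} lacks an observed pre- or post-treatment bin"
                )

    @property
    def n_sessions(self) -> int:
        return self.y.shape[0]

    @property
    def n_bins(self) -> int:
        return self.y.shape[1]

    def window_mask(self, start_min: float, end_min: float) -> np.ndarray:
        return (self.bin_start_min >= start_min - 1e-9) & (
            self.bin_start_min < end_min - 1e-9
        )


@dataclass
class StateSpaceParams:
    """One point in parameter space (trend, effects, noise scales)."""

    yhat: np.ndarray
    d_M: float
    d_T: np.ndarray
    sigma: float
    sigma_M: float
    sigma_y: float
    sigma_T: float


@dataclass
class Priors:
    """Hyperpriors: half-Cauchy(0, scale) on all four scales; diffuse
    Normal(0, init_sd^2) on the first two trend bins and the first
    treatment-effect bin.  ``cauchy_square_scale`` reads the treatment-walk
    dispersion as sigma_T^2 instead of sigma_T."""

    scale_prior_scale: float = 2.5
    init_sd: float = 10.0
    cauchy_square_scale: bool = False

    def cauchy_scale(self, sigma_T: float) -> float:
        return sigma_T**2 if self.cauchy_square_scale else sigma_T


# ---------------------------------------------------------------------------
# design assembly


def assemble_design(
    sessions: list[tuple[NormalizedSeries, str, str, str]],
    bin_range_min: tuple[int, int] = DEFAULT_BIN_RANGE,
) -> StateSpaceData:
    """Align normalized series on a common bin grid and code u/v.

    ``sessions`` holds (series, subject, treatment, session_id) tuples.
    Subjects are sorted lexicographically: the first maps to u = -1, the
    second to u = +1; more or fewer than two subjects is an error because
    the model's subject coding is defined for exactly two.  Sessions are
    sorted by id so the fitted posterior is invariant to input order.
    """
    if not sessions:
        raise DesignError("no sessions")
    items = sorted(sessions, key=lambda it: it[3])
    subjects = sorted({subj for _, subj, _, _ in items})
    if len(subjects) != 2:
        raise DesignError(
            f"subject coding u is defined for exactly two subjects; got {subjects}"
        )
    lo, hi = bin_range_min
    grid = np.arange(lo, hi, dtype=float)
    S = len(items)
    y = np.full((S, grid.size), np.nan)
    u = np.empty(S)
    v = np.empty(S)
    ids = []
    for s, (series, subject, treatment, sid) in enumerate(items):
        if treatment not in ("DCZ", "vehicle"):
            raise DesignError(f"unknown treatment {treatment!r} for session {sid}")
        u[s] = -1.0 if subject == subjects[0] else 1.0
        v[s] = 1.0 if treatment == "DCZ" else 0.0
        idx = np.round(series.bin_start_min - lo).astype(int)
        ok = (idx >= 0) & (idx < grid.size) & np.isclose(
            series.bin_start_min, lo + idx, atol=1e-6
        )
        y[s, idx[ok]] = series.values[ok]
        ids.append(sid)
    return StateSpaceData(
        bin_start_min=grid, y=y, u=u, v=v,
        session_ids=tuple(ids), subjects=tuple(subjects),
    )


def observed_window_means(data: StateSpaceData, window_min: tuple[float, float]) -> np.ndarray:
    """Per-session mean of observed y over a window (NaN if nothing observed)."""
    mask = data.window_mask(*window_min)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(data.y[:, mask], axis=1)


# ---------------------------------------------------------------------------
# joint log posterior


def _half_cauchy_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return float(np.log(2.0 / (np.pi * scale * (1.0 + (x / scale) ** 2))))


def log_posterior(
    params: StateSpaceParams, data: StateSpaceData, priors: Priors | None = None
) -> float:
    """Joint log posterior density (unnormalized only by the evidence).

    Terms: Normal observation density per observed cell; Normal(0, sigma_M^2)
    for d_M; Normal second-order random-walk terms on the trend increments;
    Cauchy terms on the treatment-effect increments; half-Cauchy priors on
    the four scales and diffuse Normal priors on the initial states.
    """
    priors = priors or Priors()
    yhat, d_T = np.asarray(params.yhat), np.asarray(params.d_T)
    T = yhat.size
    if d_T.size != T or T != data.n_bins:
        raise ValueError("parameter trajectories must span the bin grid")
    for name, s in (("sigma", params.sigma), ("sigma_M", params.sigma_M),
                    ("sigma_y", params.sigma_y), ("sigma_T", params.sigma_T)):
        if s <= 0:
            raise ValueError(f"{name} must be positive")

    obs = ~np.isnan(data.y)
    mu = yhat[None, :] + data.u[:, None] * params.d_M + data.v[:, None] * d_T[None, :]
    resid = (data.y - mu)[obs]
    lp = float(np.sum(scipy.stats.norm.logpdf(resid, scale=params.sigma)))

    lp += float(scipy.stats.norm.logpdf(params.d_M, scale=params.sigma_M))

    if T >= 3:
        inc = np.diff(yhat)
        lp += float(np.sum(scipy.stats.norm.logpdf(np.diff(inc), scale=params.sigma_y)))
    c_scale = priors.cauchy_scale(params.sigma_T)
    if T >= 2:
        lp += float(np.sum(scipy.stats.cauchy.logpdf(np.diff(d_T), scale=c_scale)))

    lp += float(scipy.stats.norm.logpdf(yhat[0], scale=priors.init_sd))
    if T > 1:
        lp += float(scipy.stats.norm.logpdf(yhat[1], scale=priors.init_sd))
    lp += float(scipy.stats.norm.logpdf(d_T[0], scale=priors.init_sd))

    for s in (params.sigma, params.sigma_M, params.sigma_y, params.sigma_T):
        lp += _half_cauchy_logpdf(s, priors.scale_prior_scale)
    return lp


# ---------------------------------------------------------------------------
# Gibbs sampler internals


def _slice_sample_log(logf, x0: float, rng: np.random.Generator, w: float = 1.0,
                      max_steps: int = 50) -> float:
    """Univariate slice sampler (stepping out + shrinkage) on the real line."""
    f0 = logf(x0)
    log_u = f0 + np.log(rng.uniform())
    lo = x0 - w * rng.uniform()
    hi = lo + w
    for _ in range(max_steps):
        if logf(lo) < log_u:
            break
        lo -= w
    for _ in range(max_steps):
        if logf(hi) < log_u:
            break
        hi += w
    for _ in range(max_steps):
        x1 = rng.uniform(lo, hi)
        if logf(x1) >= log_u:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


class _GibbsModel:
    """Precomputed sufficient statistics and one-iteration updates."""

    def __init__(self, data: StateSpaceData, priors: Priors):
        self.data = data
        self.priors = priors
        S, T = data.y.shape
        self.T = T
        self.D = 2 * T + 1  # yhat[0:T], d_M, d_T[0:T]
        obs = ~np.isnan(data.y)
        y0 = np.where(obs, data.y, 0.0)
        u, v = data.u[:, None], data.v[:, None]
        self.n_t = obs.sum(axis=0).astype(float)
        self.su_t = (u * obs).sum(axis=0)
        self.sv_t = (v * obs).sum(axis=0)
        self.suv_t = (u * v * obs).sum(axis=0)
        self.svv_t = (v * v * obs).sum(axis=0)
        self.sy_t = y0.sum(axis=0)
        self.suy_t = (u * y0).sum(axis=0)
        self.svy_t = (v * y0).sum(axis=0)
        self.n_obs = int(obs.sum())
        self.obs = obs
        # second-difference penalty matrix for the trend
        if T >= 3:
            D2 = np.zeros((T - 2, T))
            for k in range(T - 2):
                D2[k, k : k + 3] = (1.0, -2.0, 1.0)
            self.D2tD2 = D2.T @ D2
        else:
            self.D2tD2 = np.zeros((T, T))

    def sample_latents(self, scales: dict[str, float], lam: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
        """Draw (yhat, d_M, d_T) jointly from the Gaussian full conditional."""
        T, D = self.T, self.D
        pr = self.priors
        w_obs = 1.0 / scales["sigma"] ** 2
        w_y = 1.0 / scales["sigma_y"] ** 2
        c = pr.cauchy_scale(scales["sigma_T"])
        w_T = lam / c**2  # per-increment precision weights (length T-1)

        iy = np.arange(T)
        iT = T + 1 + np.arange(T)
        iM = T
        Q = np.zeros((D, D))
        b = np.zeros(D)
        # observation block
        Q[iy, iy] += w_obs * self.n_t
        Q[iM, iM] += w_obs * self.n_t.sum()
        Q[iT, iT] += w_obs * self.svv_t
        Q[iy, iM] += w_obs * self.su_t
        Q[iM, iy] += w_obs * self.su_t
        Q[iy, iT] += w_obs * self.sv_t
        Q[iT, iy] += w_obs * self.sv_t
        Q[iM, iT] += w_obs * self.suv_t
        Q[iT, iM] += w_obs * self.suv_t
        b[iy] = w_obs * self.sy_t
        b[iM] = w_obs * self.suy_t.sum()
        b[iT] = w_obs * self.svy_t
        # process priors
        Q[:T, :T] += w_y * self.D2tD2
        Q[0, 0] += 1.0 / pr.init_sd**2
        if T > 1:
            Q[1, 1] += 1.0 / pr.init_sd**2
        Q[iM, iM] += 1.0 / scales["sigma_M"] ** 2
        if T >= 2:
            a = iT[:-1]
            bidx = iT[1:]
            Q[a, a] += w_T
            Q[bidx, bidx] += w_T
            Q[a, bidx] -= w_T
            Q[bidx, a] -= w_T
        Q[iT[0], iT[0]] += 1.0 / pr.init_sd**2

        L = scipy.linalg.cholesky(Q, lower=True)
        mu = scipy.linalg.cho_solve((L, True), b)
        z = mu + scipy.linalg.solve_triangular(
            L.T, rng.standard_normal(D), lower=False
        )
        return z

    def split(self, z: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
        T = self.T
        return z[:T], float(z[T]), z[T + 1 :]

    def sample_lambda(self, d_T: np.ndarray, sigma_T: float,
                      rng: np.random.Generator) -> np.ndarray:
        """Mixing variables: lam_t | delta_t ~ Gamma(1, 1/2 + delta^2/(2c^2))."""
        c = self.priors.cauchy_scale(sigma_T)
        delta = np.diff(d_T)
        rate = 0.5 + delta**2 / (2.0 * c**2)
        return rng.gamma(shape=1.0, scale=1.0 / rate)

    def sample_scales(self, z: np.ndarray, lam: np.ndarray,
                      scales: dict[str, float], rng: np.random.Generator) -> dict[str, float]:
        yhat, d_M, d_T = self.split(z)
        pr = self.priors
        mu = yhat[None, :] + self.data.u[:, None] * d_M + self.data.v[:, None] * d_T[None, :]
        sse = float(np.sum(((self.data.y - mu)[self.obs]) ** 2))
        n = self.n_obs
        ss_y = float(np.sum((self.D2tD2 @ yhat) * yhat)) if self.T >= 3 else 0.0
        delta2 = np.diff(d_T) ** 2
        sum_lam_d2 = float(np.sum(lam * delta2))
        m = self.T - 1

        def make_logf(count, ss):
            def logf(log_s):
                s = np.exp(log_s)
                return (
                    -count * log_s
                    - ss / (2.0 * s**2)
                    + _half_cauchy_logpdf(s, pr.scale_prior_scale)
                    + log_s  # Jacobian of the log transform
                )
            return logf

        new = {}
        new["sigma"] = float(np.exp(_slice_sample_log(
            make_logf(n, sse), np.log(scales["sigma"]), rng)))
        new["sigma_M"] = float(np.exp(_slice_sample_log(
            make_logf(1, d_M**2), np.log(scales["sigma_M"]), rng)))
        new["sigma_y"] = float(np.exp(_slice_sample_log(
            make_logf(self.T - 2 if self.T >= 3 else 0, ss_y),
            np.log(scales["sigma_y"]), rng)))

        if pr.cauchy_square_scale:
            def logf_T(log_s):
                s = np.exp(log_s)
                c = s**2
                return (
                    -m * np.log(c) - sum_lam_d2 / (2.0 * c**2)
                    + _half_cauchy_logpdf(s, pr.scale_prior_scale) + log_s
                )
            new["sigma_T"] = float(np.exp(_slice_sample_log(
                logf_T, np.log(scales["sigma_T"]), rng)))
        else:
            new["sigma_T"] = float(np.exp(_slice_sample_log(
                make_logf(m, sum_lam_d2), np.log(scales["sigma_T"]), rng)))
        return new


# ---------------------------------------------------------------------------
# posterior container and fitting


@dataclass
class WindowSummary:
    """Posterior summary of mean(yhat + v*d_T) over one window, one group."""

    group: str  # "DCZ" | "vehicle"
    window_min: tuple[float, float]
    map_value: float
    ci_low: float
    ci_high: float
    posterior_mean: float

    @property
    def interval(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


@dataclass
class SeparationReport:
    separated: bool
    gap: float
    interval_a: tuple[float, float]
    interval_b: tuple[float, float]


@dataclass
class StateSpacePosterior:
    """MCMC draws (chains x draws) plus the data they were fitted to."""

    data: StateSpaceData
    priors: Priors
    yhat: np.ndarray  # (C, N, T)
    d_M: np.ndarray  # (C, N)
    d_T: np.ndarray  # (C, N, T)
    sigma: np.ndarray
    sigma_M: np.ndarray
    sigma_y: np.ndarray
    sigma_T: np.ndarray
    log_post: np.ndarray  # (C, N)
    map_params: StateSpaceParams = None  # type: ignore[assignment]
    rhat: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.log_post.size

    def flat(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape(-1, *arr.shape[2:])

    def window_effect_draws(self, v: int, window_min: tuple[float, float]) -> np.ndarray:
        """Draws of mean over window of yhat + v*d_T."""
        mask = self.data.window_mask(*window_min)
        if not mask.any():
            raise ValueError(f"empty window {window_min}")
        traj = self.flat(self.yhat) + v * self.flat(self.d_T)
        return traj[:, mask].mean(axis=1)

    def map_window_effect(self, v: int, window_min: tuple[float, float]) -> float:
        mask = self.data.window_mask(*window_min)
        traj = self.map_params.yhat + v * self.map_params.d_T
        return float(traj[mask].mean())


def _init_state(model: _GibbsModel) -> tuple[np.ndarray, dict[str, float], np.ndarray]:
    data = model.data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ybar = np.nanmean(data.y, axis=0)
    if np.isnan(ybar).any():
        idx = np.arange(ybar.size)
        good = ~np.isnan(ybar)
        ybar = np.interp(idx, idx[good], ybar[good])
    z = np.concatenate([ybar, [0.0], np.zeros(model.T)])
    scales = {"sigma": 0.1, "sigma_M": 0.1, "sigma_y": 0.1, "sigma_T": 0.1}
    lam = np.ones(max(model.T - 1, 1))
    return z, scales, lam


def fit_posterior(
    data: StateSpaceData,
    priors: Priors | None = None,
    chains: int = 4,
    draws: int = 1000,
    warmup: int = 500,
    thin: int = 1,
    seed: int = 0,
    refine_map: bool = False,
    rhat_warn: float = 1.05,
) -> StateSpacePosterior:
    """Fit the model by Gibbs sampling; deterministic given (seed, config).

    ``draws`` post-warmup draws are kept per chain.  Split-R-hat is computed
    (via arviz) for the scales and the pre/post window effects; values above
    ``rhat_warn`` raise a warning.  The MAP estimate is the stored draw with
    the highest joint log posterior; ``refine_map`` polishes it by local
    optimization of the joint density.
    """
    priors = priors or Priors()
    model = _GibbsModel(data, priors)
    T = model.T
    C = chains
    yhat_d = np.empty((C, draws, T))
    dM_d = np.empty((C, draws))
    dT_d = np.empty((C, draws, T))
    sig_d = {k: np.empty((C, draws)) for k in ("sigma", "sigma_M", "sigma_y", "sigma_T")}
    lp_d = np.empty((C, draws))

    for c in range(C):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), c]))
        z, scales, lam = _init_state(model)
        # overdisperse chain starts slightly
        z = z + 0.05 * rng.standard_normal(z.size)
        for it in range(warmup + draws * thin):
            z = model.sample_latents(scales, lam, rng)
            yhat, d_M, d_T = model.split(z)
            lam = model.sample_lambda(d_T, scales["sigma_T"], rng)
            scales = model.sample_scales(z, lam, scales, rng)
            if it >= warmup and (it - warmup) % thin == 0:
                k = (it - warmup) // thin
                yhat_d[c, k] = yhat
                dM_d[c, k] = d_M
                dT_d[c, k] = d_T
                for name in sig_d:
                    sig_d[name][c, k] = scales[name]
                lp_d[c, k] = log_posterior(
                    StateSpaceParams(yhat, d_M, d_T, scales["sigma"],
                                     scales["sigma_M"], scales["sigma_y"],
                                     scales["sigma_T"]),
                    data, priors,
                )

    post = StateSpacePosterior(
        data=data, priors=priors, yhat=yhat_d, d_M=dM_d, d_T=dT_d,
        sigma=sig_d["sigma"], sigma_M=sig_d["sigma_M"],
        sigma_y=sig_d["sigma_y"], sigma_T=sig_d["sigma_T"], log_post=lp_d,
    )

    # MAP: highest-density stored draw, optionally refined
    ci, ki = np.unravel_index(np.argmax(lp_d), lp_d.shape)
    map_params = StateSpaceParams(
        yhat=yhat_d[ci, ki].copy(), d_M=float(dM_d[ci, ki]), d_T=dT_d[ci, ki].copy(),
        sigma=float(sig_d["sigma"][ci, ki]), sigma_M=float(sig_d["sigma_M"][ci, ki]),
        sigma_y=float(sig_d["sigma_y"][ci, ki]), sigma_T=float(sig_d["sigma_T"][ci, ki]),
    )
    if refine_map:
        map_params = _refine_map(map_params, data, priors)
    post.map_params = map_params

    post.rhat = _convergence_check(post, rhat_warn)
    return post


def _refine_map(params: StateSpaceParams, data: StateSpaceData, priors: Priors) -> StateSpaceParams:
    T = params.yhat.size

    def pack(p: StateSpaceParams) -> np.ndarray:
        return np.concatenate(
            [p.yhat, [p.d_M], p.d_T,
             np.log([p.sigma, p.sigma_M, p.sigma_y, p.sigma_T])]
        )

    def unpack(x: np.ndarray) -> StateSpaceParams:
        s = np.exp(x[2 * T + 1 :])
        return StateSpaceParams(x[:T], float(x[T]), x[T + 1 : 2 * T + 1],
                                float(s[0]), float(s[1]), float(s[2]), float(s[3]))

    def neg(x: np.ndarray) -> float:
        return -log_posterior(unpack(x), data, priors)

    res = scipy.optimize.minimize(neg, pack(params), method="Nelder-Mead",
                                  options={"maxiter": 20000, "xatol": 1e-6, "fatol": 1e-8})
    refined = unpack(res.x)
    if log_posterior(refined, data, priors) > log_posterior(params, data, priors):
        return refined
    return params


def _convergence_check(post: StateSpacePosterior, threshold: float) -> dict:
    import arviz as az

    monitored = {
        "sigma": post.sigma, "sigma_M": post.sigma_M,
        "sigma_y": post.sigma_y, "sigma_T": post.sigma_T,
    }
    mask_pre = post.data.window_mask(*PRE_WINDOW_MIN)
    mask_post = post.data.window_mask(*POST_WINDOW_MIN)
    for v, name in ((0, "vehicle"), (1, "dcz")):
        traj = post.yhat + v * post.d_T
        if mask_pre.any():
            monitored[f"{name}_pre"] = traj[:, :, mask_pre].mean(axis=2)
        if mask_post.any():
            monitored[f"{name}_post"] = traj[:, :, mask_post].mean(axis=2)
    rhat = {}
    for name, arr in monitored.items():
        r = float(np.asarray(az.rhat(az.convert_to_dataset(arr[:, :, None]))["x"].values).ravel()[0])
        rhat[name] = r
        if np.isfinite(r) and r > threshold:
            warnings.warn(
                f"split-R-hat for {name} is {r:.3f} > {threshold}; "
                "increase draws/warmup", RuntimeWarning,
            )
    return rhat


# ---------------------------------------------------------------------------
# summaries and decision


def summarize_effect(
    post: StateSpacePosterior,
    pre_window_min: tuple[float, float] = PRE_WINDOW_MIN,
    post_window_min: tuple[float, float] = POST_WINDOW_MIN,
    ci: float = 0.99,
) -> dict[str, WindowSummary]:
    """MAP + central 99 % credible interval of mean(yhat + v*d_T) per group
    and window.  Keys: '<group>_pre', '<group>_post'."""
    out = {}
    alpha = (1.0 - ci) / 2.0
    for v, group in ((0, "vehicle"), (1, "DCZ")):
        for window, tag in ((pre_window_min, "pre"), (post_window_min, "post")):
            draws = post.window_effect_draws(v, window)
            out[f"{group}_{tag}"] = WindowSummary(
                group=group,
                window_min=tuple(window),
                map_value=post.map_window_effect(v, window),
                ci_low=float(np.quantile(draws, alpha)),
                ci_high=float(np.quantile(draws, 1.0 - alpha)),
                posterior_mean=float(draws.mean()),
            )
    return out


def decide_separation(
    summary_a: WindowSummary | tuple[float, float],
    summary_b: WindowSummary | tuple[float, float],
) -> SeparationReport:
    """True iff the two credible intervals are disjoint (touching endpoints
    count as overlap); the report carries the gap between them."""
    a = summary_a.interval if isinstance(summary_a, WindowSummary) else tuple(summary_a)
    b = summary_b.interval if isinstance(summary_b, WindowSummary) else tuple(summary_b)
    for lo, hi in (a, b):
        if not (np.isfinite(lo) and np.isfinite(hi)) or hi < lo:
            raise ValueError("intervals must be finite and ordered")
    if a[1] < b[0]:
        separated, gap = True, b[0] - a[1]
    elif b[1] < a[0]:
        separated, gap = True, a[0] - b[1]
    else:
        separated = False
        gap = -min(a[1], b[1]) + max(a[0], b[0])  # negative overlap extent
        gap = min(gap, 0.0)
    return SeparationReport(separated=separated, gap=float(gap),
                            interval_a=a, interval_b=b)
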