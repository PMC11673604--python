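"""Sequential estimators of time-varying MVAR coefficients.

All three filters share one state-space view: for each target channel
``i`` the stacked row-``i`` coefficients over lags form the state
``a_t`` (length ``N*p``), evolving as a random walk ``a_t = a_{t-1} +
w_t``, observed through the scalar measurement ``x_{i,t} = H_t a_t +
v_t`` with the lagged regressor ``H_t = (x_{t-1}, ..., x_{t-p})``
flattened over channels.  Channels are estimated independently; the
estimators differ only in how they handle the unknown noise:

* :class:`KalmanMVAR` — the linear-Gaussian optimum; assumed process
  and observation covariances are fixed hyperparameters.
* :class:`CorrentropyKalmanMVAR` — the Kalman recursion with the
  observation noise inflated by the inverse Gaussian-kernel weight of
  the innovation (fixed-point maximum-correntropy update), which
  suppresses the gain on gross outliers.
* :class:`CostReferenceMVAR` — a cost-reference particle filter: no
  noise densities at all, only a user-chosen incremental cost
  ``|innovation|^q`` accumulated with a forgetting factor; resampling
  weights derive from a monotone decreasing map of particle risk, and
  the propagation variance is adapted online from realized particle
  displacements.

Estimator outputs for samples ``t < p`` are undefined and stored as
NaN.  A filter that leaves the finite range is reported through
``diverged_`` — never raised — and its remaining estimates stay NaN.

The classes follow scikit-learn conventions (``fit(X)`` on an
``(n_samples, n_channels)`` array, trailing-underscore fitted
attributes, ``get_params``/``set_params``); the module-level
``kf_estimate`` / ``mcf_estimate`` / ``crpf_estimate`` functions are
thin wrappers keeping the channels-by-samples :class:`TimeSeries`
interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .datatypes import CoefficientTrajectory, TimeSeries

__all__ = [
    "KFConfig",
    "MCFConfig",
    "CRPFConfig",
    "ParticleEnsemble",
    "KalmanMVAR",
    "CorrentropyKalmanMVAR",
    "CostReferenceMVAR",
    "kf_estimate",
    "mcf_estimate",
    "crpf_estimate",
    "crpf_initialize",
    "crpf_resample",
    "crpf_propagate",
    "crpf_estimate_step",
]


# ---------------------------------------------------------------------------
# configuration dataclasses (the config-file facing surface)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KFConfig:
    """Kalman-filter settings: Q*I process covariance, scalar observation
    variance R, zero initial state and covariance."""

    process_noise_scale: float = 10.0
    observation_noise_variance: float = 1.0e4
    initial_covariance: float = 0.0

    def __post_init__(self) -> None:
        if self.process_noise_scale < 0:
            raise ValueError("process noise scale must be >= 0")
        if not self.observation_noise_variance > 0:
            raise ValueError("observation noise variance must be > 0")
        if self.initial_covariance < 0:
            raise ValueError("initial covariance must be >= 0")


@dataclass(frozen=True)
class MCFConfig(KFConfig):
    """Maximum-correntropy filter settings: Kalman settings plus the
    Gaussian kernel width applied to innovations."""

    kernel_width: float = 50.0
    max_fixed_point_iter: int = 20
    fixed_point_tol: float = 1.0e-6

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.kernel_width > 0:
            raise ValueError("kernel width must be > 0")


@dataclass(frozen=True)
class CRPFConfig:
    """Cost-reference particle filter hyperparameters.

    M : particle count.
    forgetting : cost forgetting factor lambda in (0, 1).
    cost_exponent : q >= 1 in the incremental cost |innovation|^q.
    weight_offset : delta > 0 keeping weight denominators non-zero.
    weight_exponent : beta > 0 of the monotone decreasing weight map.
    init_spread : variance of the zero-mean particle initialization.
    sigma0_sq : initial propagation variance per state dimension.
    variance_adaptation : 'anneal' (default) shrinks the propagation
        variance deterministically as sigma0_sq/t; 'displacement' adds
        the realized per-dimension squared particle displacement to the
        running mean.  The displacement term has expectation equal to
        the current variance, so under selection it drifts the variance
        upward until tracking is destroyed; annealing is its stable
        zero-displacement envelope and is what makes the filter track.
    """

    M: int = 1000
    forgetting: float = 0.95
    cost_exponent: float = 2.0
    weight_offset: float = 1.0e-6
    weight_exponent: float = 1.0
    init_spread: float = 1.0e-4
    sigma0_sq: float = 2.5e-2
    variance_adaptation: str = "anneal"
    resampling: str = "multinomial"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("particle count must be >= 1")
        if not 0 < self.forgetting < 1:
            raise ValueError("forgetting factor must lie in (0, 1)")
        if self.cost_exponent < 1:
            raise ValueError("cost exponent q must be >= 1")
        if not self.weight_offset > 0:
            raise ValueError("weight offset delta must be > 0")
        if not self.weight_exponent > 0:
            raise ValueError("weight exponent beta must be > 0")
        if self.init_spread < 0:
            raise ValueError("init spread must be >= 0")
        if not self.sigma0_sq > 0:
            raise ValueError("initial propagation variance must be > 0")
        if self.variance_adaptation not in ("anneal", "displacement"):
            raise ValueError(f"unknown variance adaptation {self.variance_adaptation!r}")
        if self.resampling not in ("multinomial", "systematic"):
            raise ValueError(f"unknown resampling scheme {self.resampling!r}")


# ---------------------------------------------------------------------------
# particle ensemble and the four CRPF steps
# ---------------------------------------------------------------------------


@dataclass
class ParticleEnsemble:
    """Per-channel CRPF state: particle states, accumulated costs, the
    last risks, normalized weights and per-particle propagation
    variances."""

    states: np.ndarray  # (M, d)
    costs: np.ndarray  # (M,)
    weights: np.ndarray  # (M,)
    variances: np.ndarray  # (M,)
    risks: np.ndarray | None = None  # (M,)

    @property
    def M(self) -> int:
        return self.states.shape[0]


class ParticleDegeneracyError(RuntimeError):
    """Every particle risk became non-finite at one step."""


def _penalty(err: np.ndarray, q: float) -> np.ndarray:
    """|err|^q with a fast path for the default q=2."""
    if q == 2.0:
        return err * err
    return np.abs(err) ** q


def _decreasing(shifted: np.ndarray, beta: float) -> np.ndarray:
    """shifted^-beta with a fast path for the default beta=1."""
    if beta == 1.0:
        return 1.0 / shifted
    return shifted**-beta


def _mu_weights(values: np.ndarray, delta: float, beta: float) -> np.ndarray:
    """Monotone decreasing normalized weight map (v - min v + delta)^-beta."""
    w = _decreasing(values - np.min(values) + delta, beta)
    return w / w.sum()


def crpf_initialize(
    cfg: CRPFConfig, state_dim: int, rng: np.random.Generator | None = None
) -> ParticleEnsemble:
    """Draw M particles from N(0, init_spread*I) with zero cost, uniform
    weights and the common initial propagation variance."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    states = rng.standard_normal((cfg.M, state_dim)) * np.sqrt(cfg.init_spread)
    return ParticleEnsemble(
        states=states,
        costs=np.zeros(cfg.M),
        weights=np.full(cfg.M, 1.0 / cfg.M),
        variances=np.full(cfg.M, cfg.sigma0_sq),
    )


def crpf_resample(
    ens: ParticleEnsemble,
    x_t: float,
    H_t: np.ndarray,
    cfg: CRPFConfig,
    rng: np.random.Generator | None = None,
) -> ParticleEnsemble:
    """Risk-driven selection: particles whose predicted observation is
    close to x_t (plus their inherited cost) get duplicated.

    Risk = lambda * C_{t-1} + |x_t - H_t a_{t-1}|^q, mapped through the
    decreasing weight function and resampled multinomially (or
    systematically); states, costs and variances travel together.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    risks = cfg.forgetting * ens.costs + _penalty(x_t - ens.states @ H_t, cfg.cost_exponent)
    risks = np.where(np.isfinite(risks), risks, np.inf)
    if not np.any(np.isfinite(risks)):
        raise ParticleDegeneracyError("all particle risks non-finite")
    w = _mu_weights(risks, cfg.weight_offset, cfg.weight_exponent)

    if cfg.resampling == "systematic":
        u = (rng.random() + np.arange(ens.M)) / ens.M
    else:
        u = rng.random(ens.M)
    idx = np.searchsorted(np.cumsum(w), u)
    idx = np.clip(idx, 0, ens.M - 1)
    return ParticleEnsemble(
        states=ens.states[idx],
        costs=ens.costs[idx],
        weights=np.full(ens.M, 1.0 / ens.M),
        variances=ens.variances[idx],
        risks=risks,
    )


def crpf_propagate(
    ens: ParticleEnsemble,
    cfg: CRPFConfig,
    t: int,
    rng: np.random.Generator | None = None,
) -> ParticleEnsemble:
    """Jitter each particle with its own adaptive Gaussian variance.

    a_t^i = a_check^i + N(0, sigma_{t-1}^{2,i} I); the variance then
    follows the configured adaptation with 1-based step counter ``t``:

    * 'anneal' — sigma_t^2 = (t/(t+1)) * sigma_{t-1}^2, the stable
      deterministic 1/t schedule (the zero-displacement envelope of the
      displacement recursion below);
    * 'displacement' — sigma_t^2 = ((t-1)/t) sigma_{t-1}^2 +
      ||a_t - a_check||^2 / (t * dim), the running mean of realized
      per-dimension squared displacements.
    """
    if t < 1:
        raise ValueError("step counter t must be >= 1")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    d = ens.states.shape[1]
    noise = rng.standard_normal((ens.M, d)) * np.sqrt(ens.variances)[:, None]
    if cfg.variance_adaptation == "anneal":
        new_var = (t / (t + 1)) * ens.variances
    else:
        new_var = ((t - 1) / t) * ens.variances + np.einsum("md,md->m", noise, noise) / (t * d)
    return ParticleEnsemble(
        states=ens.states + noise,
        costs=ens.costs,
        weights=ens.weights,
        variances=new_var,
        risks=ens.risks,
    )


def crpf_estimate_step(
    ens: ParticleEnsemble, x_t: float, H_t: np.ndarray, cfg: CRPFConfig
) -> tuple[ParticleEnsemble, np.ndarray]:
    """Accumulate costs and form the cost-weighted state estimate.

    C_t^i = lambda * C_{t-1}^i + |x_t - H_t a_t^i|^q; weights are the
    decreasing map of cost; the estimate is the weighted particle mean.
    """
    costs = cfg.forgetting * ens.costs + _penalty(x_t - ens.states @ H_t, cfg.cost_exponent)
    costs = np.where(np.isfinite(costs), costs, np.inf)
    if not np.any(np.isfinite(costs)):
        raise ParticleDegeneracyError("all particle costs non-finite")
    weights = _mu_weights(costs, cfg.weight_offset, cfg.weight_exponent)
    estimate = weights @ ens.states
    out = ParticleEnsemble(
        states=ens.states,
        costs=costs,
        weights=weights,
        variances=ens.variances,
        risks=ens.risks,
    )
    return out, estimate


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------


def _lagged_regressors(x: np.ndarray, p: int) -> np.ndarray:
    """Z[k] = (x_{t-1}, ..., x_{t-p}) flattened over channels, for
    t = p + k; shape (T - p, N * p)."""
    n, T = x.shape
    return np.hstack([x[:, p - r : T - r].T for r in range(1, p + 1)])


def _rows_to_tensor(A: np.ndarray, p: int, n: int) -> np.ndarray:
    """(N, N*p) stacked rows -> (p, N, N) coefficient matrices."""
    return A.reshape(n, p, n).transpose(1, 0, 2)


# ---------------------------------------------------------------------------
# estimator classes
# ---------------------------------------------------------------------------


class _BaseMVAREstimator(BaseEstimator):
    """Shared fit contract: X is (n_samples, n_channels); after fitting,
    ``coeffs_`` holds the (T, p, N, N) trajectory and ``diverged_`` the
    per-channel divergence flags."""

    def __init__(self, order: int = 2):
        self.order = order

    def _validate(self, X: np.ndarray) -> np.ndarray:
        X = check_array(X, ensure_min_samples=self.order + 1)
        if self.order < 1:
            raise ValueError("model order must be >= 1")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_features_in_ = X.shape[1]
        coeffs, diverged = self._run(X.T)
        self.coeffs_ = coeffs
        self.diverged_ = diverged
        return self

    def _run(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:  # pragma: no cover
        raise NotImplementedError

    def to_trajectory(self) -> CoefficientTrajectory:
        check_is_fitted(self, "coeffs_")
        return CoefficientTrajectory(self.coeffs_, diverged=self.diverged_.copy())


class KalmanMVAR(_BaseMVAREstimator):
    """Time-varying MVAR coefficients by a per-channel Kalman filter.

    Parameters
    ----------
    order : MVAR model order p.
    process_noise : scalar Q; the random-walk state covariance is Q*I.
    obs_noise : scalar observation-noise variance R.
    init_cov : scalar initial state covariance (default 0: the state and
        covariance start at zero and the first updates are driven
        entirely by the injected process covariance; a large value turns
        the Q=0 filter into recursive least squares).
    """

    def __init__(
        self,
        order: int = 2,
        process_noise: float = 10.0,
        obs_noise: float = 1.0e4,
        init_cov: float = 0.0,
    ):
        super().__init__(order=order)
        self.process_noise = process_noise
        self.obs_noise = obs_noise
        self.init_cov = init_cov

    def _kernel_weight(self, e: np.ndarray) -> np.ndarray:
        return np.ones_like(e)

    def _run(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.obs_noise <= 0:
            raise ValueError("observation noise variance must be > 0")
        if self.process_noise < 0:
            raise ValueError("process noise scale must be >= 0")
        n, T = x.shape
        p, Q, R = self.order, self.process_noise, self.obs_noise
        d = n * p
        Z = _lagged_regressors(x, p)
        A = np.zeros((n, d))
        P = np.tile(self.init_cov * np.eye(d), (n, 1, 1))
        eyeQ = Q * np.eye(d)
        out = np.full((T, p, n, n), np.nan)
        active = np.ones(n, dtype=bool)

        eye = np.eye(d)
        with np.errstate(over="ignore", invalid="ignore"):
            for k in range(T - p):
                t = p + k
                h = Z[k]
                P[active] += eyeQ
                Ph = P @ h  # (n, d)
                S = Ph @ h + R  # (n,)
                e0 = x[:, t] - A @ h
                K, R_eff = self._gain(A, P, Ph, S, h, x[:, t], R)
                A[active] += (K * e0[:, None])[active]
                # Joseph-form update keeps P symmetric positive even
                # with a diffuse prior
                IKH = eye[None] - K[:, :, None] * h[None, None, :]
                P_new = IKH @ P @ IKH.transpose(0, 2, 1) + (
                    R_eff[:, None, None] * (K[:, :, None] * K[:, None, :])
                )
                P[active] = P_new[active]

                ok = np.all(np.isfinite(A), axis=1)
                newly_bad = active & ~ok
                if np.any(newly_bad):
                    active &= ok
                out[t] = _rows_to_tensor(np.where(active[:, None], A, np.nan), p, n)
        return out, ~active

    def _gain(self, A, P, Ph, S, h, x_t, R):
        return Ph / S[:, None], np.full(A.shape[0], R)


class CorrentropyKalmanMVAR(KalmanMVAR):
    """Maximum-correntropy Kalman filter for time-varying MVAR rows.

    The observation-noise variance is inflated to R / L where
    L = exp(-innovation^2 / (2 * kernel_width^2)) is resolved by a short
    fixed-point iteration; a gross outlier drives L -> 0 and the update
    gain to zero, while kernel_width -> inf recovers the plain Kalman
    filter exactly.
    """

    def __init__(
        self,
        order: int = 2,
        process_noise: float = 10.0,
        obs_noise: float = 1.0e4,
        init_cov: float = 0.0,
        kernel_width: float = 50.0,
        max_fixed_point_iter: int = 20,
        fixed_point_tol: float = 1.0e-6,
    ):
        super().__init__(
            order=order, process_noise=process_noise, obs_noise=obs_noise, init_cov=init_cov
        )
        self.kernel_width = kernel_width
        self.max_fixed_point_iter = max_fixed_point_iter
        self.fixed_point_tol = fixed_point_tol

    def _gain(self, A, P, Ph, S, h, x_t, R):
        if self.kernel_width <= 0:
            raise ValueError("kernel width must be > 0")
        two_sig_sq = 2.0 * self.kernel_width**2
        hPh = S - R  # (n,)
        a_est = A.copy()
        K = Ph / S[:, None]
        R_eff = np.full(A.shape[0], R)
        for _ in range(self.max_fixed_point_iter):
            e = x_t - a_est @ h
            L = np.exp(-np.minimum(e**2 / two_sig_sq, 700.0))
            L = np.maximum(L, 1e-300)
            R_eff = R / L
            K_new = Ph / (hPh + R_eff)[:, None]
            a_new = A + K_new * (x_t - A @ h)[:, None]
            delta = np.max(np.abs(a_new - a_est)) / (np.max(np.abs(a_est)) + 1e-12)
            a_est, K = a_new, K_new
            if delta < self.fixed_point_tol:
                break
        return K, R_eff


class CostReferenceMVAR(_BaseMVAREstimator):
    """Cost-reference particle filter for time-varying MVAR rows.

    Runs, per channel, the loop resample -> propagate -> cost update /
    estimate over t = p .. T-1, with ``n_particles`` particles of
    dimension N*p.  No noise distribution is assumed anywhere: particle
    selection and the final estimate both derive from the accumulated
    cost ``C_t = lambda C_{t-1} + |innovation|^q`` through the monotone
    decreasing weight map ``(C - min C + delta)^-beta``.

    Parameters mirror :class:`CRPFConfig`; ``random_state`` seeds one
    generator from which independent per-channel streams are spawned.
    """

    def __init__(
        self,
        order: int = 2,
        n_particles: int = 1000,
        forgetting: float = 0.95,
        cost_exponent: float = 2.0,
        weight_offset: float = 1.0e-6,
        weight_exponent: float = 1.0,
        init_spread: float = 1.0e-4,
        sigma0_sq: float = 2.5e-2,
        variance_adaptation: str = "anneal",
        resampling: str = "multinomial",
        random_state: int | None = 0,
    ):
        super().__init__(order=order)
        self.n_particles = n_particles
        self.forgetting = forgetting
        self.cost_exponent = cost_exponent
        self.weight_offset = weight_offset
        self.weight_exponent = weight_exponent
        self.init_spread = init_spread
        self.sigma0_sq = sigma0_sq
        self.variance_adaptation = variance_adaptation
        self.resampling = resampling
        self.random_state = random_state

    def _config(self) -> CRPFConfig:
        return CRPFConfig(
            M=self.n_particles,
            forgetting=self.forgetting,
            cost_exponent=self.cost_exponent,
            weight_offset=self.weight_offset,
            weight_exponent=self.weight_exponent,
            init_spread=self.init_spread,
            sigma0_sq=self.sigma0_sq,
            variance_adaptation=self.variance_adaptation,
            resampling=self.resampling,
            seed=self.random_state if self.random_state is not None else 0,
        )

    def _run(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cfg = self._config()
        n, T = x.shape
        p = self.order
        d = n * p
        Z = _lagged_regressors(x, p)
        out = np.full((T, p, n, n), np.nan)
        diverged = np.zeros(n, dtype=bool)

        streams = np.random.SeedSequence(cfg.seed).spawn(n)
        for i in range(n):
            rng = np.random.default_rng(streams[i])
            est_rows = np.full((T, d), np.nan)
            try:
                self._run_channel(x[i], Z, cfg, rng, est_rows)
            except ParticleDegeneracyError:
                diverged[i] = True
            out[:, :, i, :] = est_rows.reshape(T, p, n)
            if not np.all(np.isfinite(out[p:, :, i, :])):
                diverged[i] = True
        return out, diverged

    def _run_channel(
        self,
        x_i: np.ndarray,
        Z: np.ndarray,
        cfg: CRPFConfig,
        rng: np.random.Generator,
        out: np.ndarray,
    ) -> None:
        """Fused resample -> propagate -> estimate loop for one channel.

        Algorithmically identical to composing crpf_resample /
        crpf_propagate / crpf_estimate_step with the same generator
        (identical draw order, bit-exact states); kept inline to avoid
        per-step allocation overhead on long recordings.
        """
        p = self.order
        T = x_i.shape[0]
        d = Z.shape[1]
        M, lam, q = cfg.M, cfg.forgetting, cfg.cost_exponent
        delta, beta = cfg.weight_offset, cfg.weight_exponent
        anneal = cfg.variance_adaptation == "anneal"
        systematic = cfg.resampling == "systematic"

        states = rng.standard_normal((M, d)) * np.sqrt(cfg.init_spread)
        costs = np.zeros(M)
        variances = np.full(M, cfg.sigma0_sq)
        offsets = np.arange(M)

        with np.errstate(over="ignore", invalid="ignore"):
            for k in range(T - p):
                t = p + k
                xt = x_i[t]
                h = Z[k]
                # resampling on risk
                risks = lam * costs + _penalty(xt - states @ h, q)
                if not np.all(np.isfinite(risks)):
                    risks = np.where(np.isfinite(risks), risks, np.inf)
                    if not np.any(np.isfinite(risks)):
                        raise ParticleDegeneracyError(
                            f"all particle risks non-finite at step {t}"
                        )
                w = _mu_weights(risks, delta, beta)
                u = (rng.random() + offsets) / M if systematic else rng.random(M)
                idx = np.searchsorted(np.cumsum(w), u)
                np.clip(idx, 0, M - 1, out=idx)
                states = states[idx]
                costs = costs[idx]
                variances = variances[idx]
                # propagation with adaptive variance, step counter k+1
                noise = rng.standard_normal((M, d))
                noise *= np.sqrt(variances)[:, None]
                states += noise
                if anneal:
                    variances = ((k + 1) / (k + 2)) * variances
                else:
                    variances = (k / (k + 1)) * variances + np.einsum(
                        "md,md->m", noise, noise
                    ) / ((k + 1) * d)
                # cost update and estimate
                costs = lam * costs + _penalty(xt - states @ h, q)
                if not np.all(np.isfinite(costs)):
                    costs = np.where(np.isfinite(costs), costs, np.inf)
                    if not np.any(np.isfinite(costs)):
                        raise ParticleDegeneracyError(
                            f"all particle costs non-finite at step {t}"
                        )
                weights = _mu_weights(costs, delta, beta)
                est = weights @ states
                if not np.all(np.isfinite(est)):
                    return
                out[t] = est


# ---------------------------------------------------------------------------
# functional wrappers on the TimeSeries interface
# ---------------------------------------------------------------------------


def kf_estimate(ts: TimeSeries, p: int, cfg: KFConfig | None = None) -> CoefficientTrajectory:
    cfg = cfg or KFConfig()
    est = KalmanMVAR(
        order=p,
        process_noise=cfg.process_noise_scale,
        obs_noise=cfg.observation_noise_variance,
        init_cov=cfg.initial_covariance,
    ).fit(ts.data.T)
    return est.to_trajectory()


def mcf_estimate(ts: TimeSeries, p: int, cfg: MCFConfig | None = None) -> CoefficientTrajectory:
    cfg = cfg or MCFConfig()
    est = CorrentropyKalmanMVAR(
        order=p,
        process_noise=cfg.process_noise_scale,
        obs_noise=cfg.observation_noise_variance,
        init_cov=cfg.initial_covariance,
        kernel_width=cfg.kernel_width,
        max_fixed_point_iter=cfg.max_fixed_point_iter,
        fixed_point_tol=cfg.fixed_point_tol,
    ).fit(ts.data.T)
    return est.to_trajectory()


def crpf_estimate(ts: TimeSeries, p: int, cfg: CRPFConfig | None = None) -> CoefficientTrajectory:
    cfg = cfg or CRPFConfig()
    est = CostReferenceMVAR(
        order=p,
        n_particles=cfg.M,
        forgetting=cfg.forgetting,
        cost_exponent=cfg.cost_exponent,
        weight_offset=cfg.weight_offset,
        weight_exponent=cfg.weight_exponent,
        init_spread=cfg.init_spread,
        sigma0_sq=cfg.sigma0_sq,
        variance_adaptation=cfg.variance_adaptation,
        resampling=cfg.resampling,
        random_state=cfg.seed,
    ).fit(ts.data.T)
    return est.to_trajectory()
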