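"""Time-varying MVAR processes: simulation, the 3-channel benchmark
system, and autoregressive order selection.

The benchmark is a 3-channel order-2 system with three time-varying
cross couplings:

    s1_t = 0.59 s1_{t-1} - 0.20 s1_{t-2} + c_t s2_{t-1} + d_t s3_{t-1} + v1_t
    s2_t = 1.58 s2_{t-1} - 0.96 s2_{t-2}                              + v2_t
    s3_t = b_t s1_{t-1} + 0.60 s3_{t-1} - 0.91 s3_{t-2}               + v3_t

where b_t steps from 0 to a constant, c_t oscillates, and d_t ramps
linearly.  Channel 2 is a sharply resonant AR(2) (poles at radius
sqrt(0.96), ~100.7 Hz at fs=1000) driving the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import CoefficientTrajectory, TimeSeries
from .noise import NoiseSource


class InstabilityError(RuntimeError):
    """A trajectory (or the series it generated) left the stable region."""


@dataclass(frozen=True)
class TrajectorySpec:
    """One scalar coefficient's evolution over time.

    kinds
    -----
    constant : value
    step     : start -> value at onset_s seconds
    sinusoid : offset + amplitude * sin(2*pi*freq_hz*t)
    ramp     : start -> value linearly over [0, end_s] (end_s=None: full span)
    """

    kind: str = "constant"
    value: float = 0.0
    start: float = 0.0
    onset_s: float = 0.0
    offset: float = 0.0
    amplitude: float = 0.0
    freq_hz: float = 0.0
    end_s: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "step", "sinusoid", "ramp"):
            raise ValueError(f"unknown trajectory kind {self.kind!r}")

    def evaluate(self, n_samples: int, fs: float) -> np.ndarray:
        t = np.arange(n_samples) / fs
        if self.kind == "constant":
            return np.full(n_samples, self.value)
        if self.kind == "step":
            return np.where(t >= self.onset_s, self.value, self.start)
        if self.kind == "sinusoid":
            return self.offset + self.amplitude * np.sin(2 * np.pi * self.freq_hz * t)
        end = self.end_s if self.end_s is not None else n_samples / fs
        frac = np.clip(t / end, 0.0, 1.0)
        return self.start + (self.value - self.start) * frac


# fixed (self-lag) entries of the benchmark system: (lag, i, j) -> value
_BENCH_FIXED = {
    (1, 0, 0): 0.59,
    (2, 0, 0): -0.20,
    (1, 1, 1): 1.58,
    (2, 1, 1): -0.96,
    (1, 2, 2): 0.60,
    (2, 2, 2): -0.91,
}


def default_benchmark_specs(duration_s: float) -> tuple[TrajectorySpec, TrajectorySpec, TrajectorySpec]:
    """Default b/c/d evolutions, scaled to the simulated duration.

    b steps 0 -> 0.5 at mid-run, c oscillates 0.25 +/- 0.25 at 0.05 Hz,
    d ramps 0 -> 0.5 over the full run.  At the reference 50 s duration
    the step lands at 25 s.
    """
    b = TrajectorySpec(kind="step", start=0.0, value=0.5, onset_s=duration_s / 2)
    c = TrajectorySpec(kind="sinusoid", offset=0.25, amplitude=0.25, freq_hz=0.05)
    d = TrajectorySpec(kind="ramp", start=0.0, value=0.5, end_s=duration_s)
    return b, c, d


def benchmark_trajectory(
    spec_b: TrajectorySpec | None = None,
    spec_c: TrajectorySpec | None = None,
    spec_d: TrajectorySpec | None = None,
    n_samples: int = 50_000,
    fs: float = 1000.0,
    check_stability: bool = True,
) -> CoefficientTrajectory:
    """Build the full (T, 2, 3, 3) coefficient tensor of the benchmark.

    The time-varying entries sit at (3<-1, lag 1) = b, (1<-2, lag 1) = c
    and (1<-3, lag 1) = d; every entry not named by the system is zero.
    """
    duration_s = n_samples / fs
    if spec_b is None or spec_c is None or spec_d is None:
        db, dc, dd = default_benchmark_specs(duration_s)
        spec_b = spec_b or db
        spec_c = spec_c or dc
        spec_d = spec_d or dd

    coeffs = np.zeros((n_samples, 2, 3, 3))
    for (lag, i, j), v in _BENCH_FIXED.items():
        coeffs[:, lag - 1, i, j] = v
    coeffs[:, 0, 2, 0] = spec_b.evaluate(n_samples, fs)  # b: 3 <- 1
    coeffs[:, 0, 0, 1] = spec_c.evaluate(n_samples, fs)  # c: 1 <- 2
    coeffs[:, 0, 0, 2] = spec_d.evaluate(n_samples, fs)  # d: 1 <- 3

    traj = CoefficientTrajectory(coeffs)
    if check_stability:
        # coefficients vary slowly; a decimated scan plus the endpoints
        # covers the whole span
        step = max(1, n_samples // 200)
        radii = traj.spectral_radii(step=step)
        if radii.max() >= 1.0:
            raise InstabilityError(
                f"benchmark trajectory unstable: max companion spectral radius {radii.max():.4f}"
            )
    return traj


def simulate_mvar(
    traj: CoefficientTrajectory,
    noise: NoiseSource | np.ndarray,
    fs: float = 1000.0,
    seed: int = 0,
) -> TimeSeries:
    """Run the MVAR recursion X_t = sum_r A_{r,t} X_{t-r} + E_t.

    The first ``p`` samples are zeros (and are excluded from error
    scoring downstream).  ``noise`` is either a NoiseSource — drawn per
    channel with sub-seeds spawned from ``seed`` — or a pre-drawn
    (N, T) array.

    Raises
    ------
    InstabilityError
        If a non-finite sample appears, naming the first bad index.
    """
    T, p, n, _ = traj.coeffs.shape
    if isinstance(noise, np.ndarray):
        e = np.asarray(noise, dtype=float)
        if e.shape != (n, T):
            raise ValueError(f"noise array must have shape {(n, T)}, got {e.shape}")
    else:
        ss = np.random.SeedSequence(seed)
        e = np.stack(
            [noise.draw(T, np.random.default_rng(child)) for child in ss.spawn(n)]
        )

    x = np.zeros((n, T))
    coeffs = traj.coeffs
    # overflow is detected via the finiteness check, not a warning
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(p, T):
            acc = e[:, t].copy()
            for r in range(1, p + 1):
                acc += coeffs[t, r - 1] @ x[:, t - r]
            x[:, t] = acc
            if not np.all(np.isfinite(acc)):
                raise InstabilityError(f"non-finite sample at index {t}: unstable system")
    return TimeSeries(x, fs=fs)


def _lagged_design(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack lagged regressors: returns (Y, Z) with Y (T-p, N) targets and
    Z (T-p, N*p) regressors ordered lag-1 channels, lag-2 channels, ..."""
    n, T = x.shape
    Y = x[:, p:].T
    Z = np.hstack([x[:, p - r : T - r].T for r in range(1, p + 1)])
    return Y, Z


def ls_fit(ts: TimeSeries, p: int) -> np.ndarray:
    """Stationary least-squares MVAR fit; returns (p, N, N) coefficients."""
    n = ts.n_channels
    Y, Z = _lagged_design(ts.data, p)
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient regressor matrix in MVAR fit")
    B, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    # B is (N*p, N): column i holds row i of [A_1 ... A_p]
    return B.T.reshape(n, p, n).transpose(1, 0, 2)


def fpe_order(ts: TimeSeries, p_max: int) -> int:
    """Select MVAR order by the multivariate final prediction error.

    FPE(p) = det(Sigma_p) * ((T + N*p + 1) / (T - N*p - 1))^N with
    Sigma_p the residual covariance of the stationary LS fit on the
    common sample span; ties break toward smaller p.
    """
    n, T = ts.data.shape
    if T <= n * p_max + 1:
        raise ValueError(f"need T > N*p_max + 1 = {n * p_max + 1}, got T={T}")
    best_p, best_score = 1, None
    for p in range(1, p_max + 1):
        # common span so that scores are comparable across p
        Y = ts.data[:, p_max:].T
        Z = np.hstack(
            [ts.data[:, p_max - r : T - r].T for r in range(1, p + 1)]
        )
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise np.linalg.LinAlgError(f"rank-deficient regressors at order {p}")
        B, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        resid = Y - Z @ B
        t_eff = Y.shape[0]
        sigma = resid.T @ resid / t_eff
        score = np.linalg.det(sigma) * ((t_eff + n * p + 1) / (t_eff - n * p - 1)) ** n
        # ties (within relative 1e-12) break toward the smaller order
        if best_score is None or score < best_score * (1 - 1e-12):
            best_p, best_score = p, score
    return best_p
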