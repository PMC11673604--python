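"""Observation-noise generators for the simulation study.

Three processes drive the benchmark: white Gaussian noise, heavy-tailed
alpha-stable noise, and pink (1/f) noise.  All samplers are pure
functions of their parameters and a seed.

The alpha-stable family is parameterized by the characteristic function

    phi(t) = exp( j*a*t - gamma*|t|^alpha * [1 + j*beta*sgn(t)*omega(t, alpha)] )

with omega(t, alpha) = tan(pi*alpha/2) for alpha != 1 and
(2/pi)*log|t| for alpha = 1.  Sampling uses the Chambers–Mallows–Stuck
transformation; the characteristic function itself is used only by the
numerical-inversion validation oracle (:func:`stable_cdf_numeric`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate


@dataclass(frozen=True)
class AlphaStableParams:
    """Parameters of an alpha-stable law.

    alpha : stability exponent in (0, 2]; alpha=2 is Gaussian with
        variance 2*gamma, alpha=1 with beta=0 is Cauchy.
    beta : skewness in [-1, 1].
    gamma : scale, > 0 (exponent-alpha scale: the characteristic function
        carries gamma*|t|^alpha).
    a : location shift.
    """

    alpha: float = 1.0
    beta: float = 0.0
    gamma: float = 1.0
    a: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 2:
            raise ValueError(f"alpha must be in (0, 2], got {self.alpha}")
        if not -1 <= self.beta <= 1:
            raise ValueError(f"beta must be in [-1, 1], got {self.beta}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")


def sample_gaussian(n: int, variance: float = 1.0, seed: int | np.random.Generator = 0) -> np.ndarray:
    """I.i.d. zero-mean normal draws with the given variance."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if variance < 0:
        raise ValueError(f"variance must be non-negative, got {variance}")
    rng = np.random.default_rng(seed)
    return rng.standard_normal(n) * np.sqrt(variance)


def sample_alpha_stable(
    n: int,
    params: AlphaStableParams | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Alpha-stable draws via the Chambers–Mallows–Stuck transformation.

    Generates a standard stable variate from a uniform angle U on
    (-pi/2, pi/2) and an independent unit exponential W, then applies the
    scale gamma^(1/alpha) (gamma itself on the alpha=1 branch, where the
    scale enters the characteristic function linearly) and the location
    shift a.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if params is None:
        params = AlphaStableParams()
    alpha, beta, gamma, a = params.alpha, params.beta, params.gamma, params.a
    rng = np.random.default_rng(seed)
    u = rng.uniform(-np.pi / 2, np.pi / 2, size=n)
    w = rng.exponential(1.0, size=n)

    if alpha == 1.0:
        x = (2 / np.pi) * (
            (np.pi / 2 + beta * u) * np.tan(u)
            - beta * np.log((np.pi / 2) * w * np.cos(u) / (np.pi / 2 + beta * u))
        )
        # scale enters linearly at alpha=1 (log form of the CMS map)
        return gamma * x + (2 / np.pi) * beta * gamma * np.log(gamma) + a

    b = np.arctan(beta * np.tan(np.pi * alpha / 2)) / alpha
    s = (1 + beta**2 * np.tan(np.pi * alpha / 2) ** 2) ** (1 / (2 * alpha))
    x = (
        s
        * np.sin(alpha * (u + b))
        / np.cos(u) ** (1 / alpha)
        * (np.cos(u - alpha * (u + b)) / w) ** ((1 - alpha) / alpha)
    )
    return gamma ** (1 / alpha) * x + a


def sample_pink(n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Unit-variance pink noise by 1/sqrt(f) spectral shaping of white noise.

    The rFFT of a white Gaussian sequence is multiplied by f^(-1/2)
    (power spectral density proportional to 1/f), the DC bin is zeroed,
    and the inverse transform is de-meaned and normalized to unit sample
    variance.
    """
    if n < 16:
        raise ValueError("pink noise needs n >= 16")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** -0.5
    x = np.fft.irfft(spec * shaping, n=n)
    x -= x.mean()
    return x / x.std()


@dataclass(frozen=True)
class NoiseSource:
    """Config stanza describing one of the three observation-noise kinds.

    ``draw(n, seed)`` materializes a stream; the stored seed acts as a
    default stream offset so that independent channels can be generated
    from one source with distinct seeds.
    """

    kind: str = "gaussian"  # gaussian | alpha_stable | pink
    variance: float = 1.0
    stable: AlphaStableParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "alpha_stable", "pink"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind == "alpha_stable" and self.stable is None:
            object.__setattr__(self, "stable", AlphaStableParams())

    def draw(self, n: int, seed: int | np.random.Generator | None = None) -> np.ndarray:
        s = self.seed if seed is None else seed
        if self.kind == "gaussian":
            return sample_gaussian(n, self.variance, s)
        if self.kind == "alpha_stable":
            return sample_alpha_stable(n, self.stable, s)
        return sample_pink(n, s)


def stable_characteristic_function(t: np.ndarray, params: AlphaStableParams) -> np.ndarray:
    """Evaluate the alpha-stable characteristic function phi(t)."""
    t = np.asarray(t, dtype=float)
    alpha, beta, gamma, a = params.alpha, params.beta, params.gamma, params.a
    with np.errstate(divide="ignore", invalid="ignore"):
        if alpha == 1.0:
            omega = (2 / np.pi) * np.log(np.abs(t))
            omega = np.where(t == 0, 0.0, omega)
        else:
            omega = np.tan(np.pi * alpha / 2)
    return np.exp(
        1j * a * t - gamma * np.abs(t) ** alpha * (1 + 1j * beta * np.sign(t) * omega)
    )


def stable_cdf_numeric(x: np.ndarray, params: AlphaStableParams) -> np.ndarray:
    """CDF by Gil-Pelaez inversion of the characteristic function.

    Independent validation oracle for the CMS sampler:

        F(x) = 1/2 - (1/pi) * integral_0^inf Im( exp(-i t x) phi(t) ) / t dt

    Quadrature is over (0, T] with T chosen so the integrand's stable
    envelope exp(-gamma t^alpha) is negligible; intended for test-scale
    grids, not bulk use.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    alpha, gamma = params.alpha, params.gamma
    # envelope exp(-gamma t^alpha) < 1e-12  =>  t > (12 ln10 / gamma)^(1/alpha)
    t_max = (12 * np.log(10) / gamma) ** (1 / alpha)

    out = np.empty_like(x)
    for k, xv in enumerate(x):
        def integrand(t: float) -> float:
            phi = stable_characteristic_function(np.array([t]), params)[0]
            return float(np.imag(np.exp(-1j * t * xv) * phi) / t)

        val, _ = integrate.quad(integrand, 1e-12, t_max, limit=400)
        out[k] = 0.5 - val / np.pi
    return np.clip(out, 0.0, 1.0)
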