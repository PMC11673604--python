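"""Core containers shared by the simulator, the estimators and the
connectivity layer.

Conventions
-----------
* A multichannel recording is stored channels-by-samples (``N x T``).
* A coefficient trajectory is a ``(T, p, N, N)`` tensor where entry
  ``[t, r-1, i, j]`` is the influence of channel ``j`` at lag ``r`` on
  channel ``i`` at time ``t`` — i.e. row ``i`` of the lag-``r`` MVAR
  coefficient matrix ``A_r`` at sample ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TimeSeries:
    """A channels-by-samples recording with its sampling rate.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        The signal matrix, channels as rows.
    fs : float
        Sampling rate in Hz, strictly positive.
    channel_names : list of str, optional
        Labels; defaults to ``ch0 .. ch{N-1}``.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[None, :]
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got ndim={self.data.ndim}")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError(f"need at least one channel and one sample, got shape {self.data.shape}")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        elif len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.fs


@dataclass
class CoefficientTrajectory:
    """Time-indexed MVAR coefficients.

    ``coeffs[t, r-1, i, j]`` is the effect of channel ``j`` at lag ``r``
    on channel ``i`` at sample ``t``.  Estimators additionally attach a
    per-channel ``diverged`` flag: a filter that left the finite range is
    reported, never raised.
    """

    coeffs: np.ndarray  # (T, p, N, N)
    diverged: np.ndarray | None = None  # (N,) bool, estimator output only

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 4:
            raise ValueError(f"coeffs must be (T, p, N, N), got shape {self.coeffs.shape}")
        if self.coeffs.shape[2] != self.coeffs.shape[3]:
            raise ValueError("coefficient matrices must be square")
        if self.diverged is None:
            self.diverged = np.zeros(self.coeffs.shape[2], dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.coeffs.shape[0]

    @property
    def order(self) -> int:
        return self.coeffs.shape[1]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[2]

    def companion(self, t: int) -> np.ndarray:
        """Companion matrix of the order-p system frozen at sample t."""
        p, n = self.order, self.n_channels
        top = self.coeffs[t].transpose(1, 0, 2).reshape(n, n * p)
        comp = np.zeros((n * p, n * p))
        comp[:n] = top
        if p > 1:
            comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
        return comp

    def spectral_radii(self, step: int = 1) -> np.ndarray:
        """Companion spectral radius at every ``step``-th sample."""
        idx = np.arange(0, self.n_samples, step)
        return np.array(
            [np.abs(np.linalg.eigvals(self.companion(t))).max() for t in idx]
        )
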