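"""Time–frequency directed connectivity from MVAR coefficient
trajectories: squared partial directed coherence (sPDC) and directed
flow summaries.

At each evaluated sample the frozen coefficient matrices define the
spectral transfer structure

    Abar(f) = I - sum_{r=1..p} A_r exp(-i 2 pi f r / fs)

and the sPDC from source channel j to target i is the column-normalized
squared magnitude

    sPDC_ij(f) = |Abar_ij(f)|^2 / sum_m |Abar_mj(f)|^2 ,

so every column sums to one over targets (diagonal included): the
measure ranks where channel j's outflow goes at frequency f.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import CoefficientTrajectory

logger = logging.getLogger(__name__)


@dataclass
class SPDCGrid:
    """sPDC values over (target, source, frequency, time).

    values : (N, N, F, K) array in [0, 1]; entry [i, j, f, k] is the
        influence of source j on target i at freqs[f], times[k].
    freqs : evaluated frequencies in Hz.
    times : evaluated sample indices.
    fs : sampling rate in Hz.
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    fs: float


@dataclass
class FlowSummary:
    """Per-node directed flow over time: (N, K) array of band-summed
    outflow or inflow, self-terms excluded, optionally z-scored over the
    time axis."""

    values: np.ndarray  # (N, K)
    times: np.ndarray
    direction: str  # "in" | "out"
    zscored: bool


def spdc(
    traj: CoefficientTrajectory,
    fs: float,
    freqs: np.ndarray,
    times: np.ndarray | None = None,
) -> SPDCGrid:
    """Evaluate the sPDC grid of a coefficient trajectory.

    ``freqs`` must lie strictly inside (0, fs/2); ``times`` (sample
    indices, default every sample from p on) must be >= the model order.
    A degenerate zero column of Abar yields NaN for that column with a
    logged warning.
    """
    T, p, n, _ = traj.coeffs.shape
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise ValueError("frequencies must lie strictly inside (0, fs/2)")
    if times is None:
        times = np.arange(p, T)
    times = np.atleast_1d(np.asarray(times, dtype=int))
    if np.any(times < p) or np.any(times >= T):
        raise ValueError(f"evaluation times must lie in [{p}, {T})")

    # phase factors: (F, p)
    r = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, r) / fs)
    eye = np.eye(n)

    A_t = traj.coeffs[times]  # (K, p, n, n)
    # Abar: (K, F, n, n)
    abar = eye[None, None] - np.einsum("fr,krij->kfij", phase, A_t)
    power = np.abs(abar) ** 2
    denom = power.sum(axis=2, keepdims=True)  # sum over targets m, per column j
    bad = denom == 0
    if np.any(bad):
        logger.warning("degenerate zero column in transfer matrix: NaN sPDC emitted")
        denom = np.where(bad, np.nan, denom)
    vals = power / denom  # (K, F, n, n)
    return SPDCGrid(values=vals.transpose(2, 3, 1, 0), freqs=freqs, times=times, fs=fs)


def flow_summary(
    grid: SPDCGrid,
    direction: str = "out",
    band: tuple[float, float] | None = None,
    zscore: bool = False,
) -> FlowSummary:
    """Band-summed total outflow or inflow per node over time.

    Outflow of node j sums sPDC over targets i != j; inflow of node i
    sums over sources j != i.  With ``zscore`` each node's time course
    is standardized (a zero-variance course returns zeros with a logged
    warning).
    """
    if direction not in ("in", "out"):
        raise ValueError("direction must be 'in' or 'out'")
    n = grid.values.shape[0]
    if band is None:
        fmask = np.ones_like(grid.freqs, dtype=bool)
    else:
        lo, hi = band
        fmask = (grid.freqs >= lo) & (grid.freqs <= hi)
        if not np.any(fmask):
            raise ValueError(f"band {band} contains no grid frequencies")

    v = grid.values[:, :, fmask, :]  # (N, N, Fb, K)
    offdiag = ~np.eye(n, dtype=bool)
    masked = v * offdiag[:, :, None, None]
    if direction == "out":
        flow = masked.sum(axis=(0, 2))  # per source j
    else:
        flow = masked.sum(axis=(1, 2))  # per target i
    if zscore:
        mu = flow.mean(axis=1, keepdims=True)
        sd = flow.std(axis=1, keepdims=True)
        zero_var = sd[:, 0] == 0
        if np.any(zero_var):
            logger.warning("zero-variance flow series: z-scores set to 0")
        sd = np.where(sd == 0, 1.0, sd)
        flow = (flow - mu) / sd
        flow[zero_var] = 0.0
    return FlowSummary(values=flow, times=grid.times, direction=direction, zscored=zscore)
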