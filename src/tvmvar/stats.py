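"""Condition contrasts on sPDC grids: bootstrap difference testing with
false-discovery-rate control.

Given per-trial sPDC grids from two conditions, the observed statistic
per (target, source, frequency, time) cell is the absolute difference
of condition means.  The null is built by pooling trials and redrawing
both pseudo-conditions with replacement (label resampling), giving an
add-one corrected p-value per cell, followed by Benjamini–Hochberg
correction applied within each directed pair (over its frequency-time
cells; diagonal pairs excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .connectivity import SPDCGrid


@dataclass
class ContrastResult:
    """observed |delta sPDC|, p-values and the FDR-significance mask,
    all shaped (N, N, F, K); diagonal cells carry NaN p-values and are
    never significant."""

    observed: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    alpha: float
    n_resamples: int


def _stack(grids: list[SPDCGrid] | np.ndarray) -> np.ndarray:
    if isinstance(grids, np.ndarray):
        return grids
    return np.stack([g.values for g in grids])


def bootstrap_spdc_contrast(
    grids_a: list[SPDCGrid] | np.ndarray,
    grids_b: list[SPDCGrid] | np.ndarray,
    n_resamples: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> ContrastResult:
    """Bootstrap test of per-cell sPDC differences between conditions.

    Parameters
    ----------
    grids_a, grids_b : per-trial grids (lists of SPDCGrid or arrays of
        shape (trials, N, N, F, K)); shapes must match across
        conditions, >= 2 trials each.
    n_resamples : bootstrap resamples B (>= 100).
    alpha : FDR level.
    seed : seeds the label resampling.

    p = (1 + #{null >= observed}) / (1 + B) per cell, so p is never 0
    and the result is deterministic given the seed.
    """
    a = _stack(grids_a)
    b = _stack(grids_b)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError(f"condition grid shapes differ: {a.shape[1:]} vs {b.shape[1:]}")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 trials per condition")
    if n_resamples < 100:
        raise ValueError("need at least 100 bootstrap resamples")

    n_a, n_b = a.shape[0], b.shape[0]
    observed = np.abs(a.mean(axis=0) - b.mean(axis=0))

    pooled = np.concatenate([a, b], axis=0)
    n_pool = n_a + n_b
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed, dtype=np.int64)
    for _ in range(n_resamples):
        ia = rng.integers(n_pool, size=n_a)
        ib = rng.integers(n_pool, size=n_b)
        null = np.abs(pooled[ia].mean(axis=0) - pooled[ib].mean(axis=0))
        exceed += null >= observed
    p = (1.0 + exceed) / (1.0 + n_resamples)

    n = observed.shape[0]
    significant = np.zeros_like(observed, dtype=bool)
    p_out = p.copy()
    for i in range(n):
        for j in range(n):
            if i == j:
                p_out[i, j] = np.nan
                continue
            cell_p = p[i, j].ravel()
            rej, *_ = multipletests(cell_p, alpha=alpha, method="fdr_bh")
            significant[i, j] = rej.reshape(p[i, j].shape)
    return ContrastResult(
        observed=observed,
        p_values=p_out,
        significant=significant,
        alpha=alpha,
        n_resamples=n_resamples,
    )
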