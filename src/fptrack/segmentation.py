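"""Penalised-contrast segmentation of FPT series into homogeneous bouts.

A track's FPT series at the ARS scale is partitioned into K contiguous
segments by minimising a Gaussian contrast — the sum over segments of
``n_seg * ln(sigma^2_seg)``, sensitive to changes in both mean and variance.
For each K up to K_max the optimal breakpoints are found exactly by dynamic
programming over a precomputed segment-cost matrix; the optimal number of
segments K_opt is then the last K at which the second derivative of the
standardised contrast J_std(K) exceeds a threshold S (default 0.75).

J is standardised affinely onto [1, K_max] (J_std(1) = K_max,
J_std(K_max) = 1) so that the curvature D(K) = J_std(K-1) - 2 J_std(K)
+ J_std(K+1) is dimensionless and comparable to S.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fpt import FPTProfile

logger = logging.getLogger("fptrack")

DEFAULT_S = 0.75
DEFAULT_L_MIN = 10
DEFAULT_K_MAX = 20


@dataclass
class ContrastTable:
    """Contrast J(K), standardised contrast and curvature for K = 1..K_max."""

    K_values: np.ndarray
    J: np.ndarray
    J_std: np.ndarray
    D: np.ndarray  # second derivative; NaN at K = 1 and K = K_max
    L_min: int
    S: float
    breakpoints_per_K: list[list[int]]  # right bounds (exclusive) of each segment but the last


@dataclass
class Segmentation:
    """Optimal partition of one track's analysed fixes."""

    track_label: str
    breakpoints: list[int]  # segment starts within the analysed series, excluding 0
    K_opt: int
    segment_id: np.ndarray  # per original fix; -1 never assigned
    contrast: ContrastTable | None = None


def _cost_matrix(series: np.ndarray, L_min: int, eps_rel: float = 1e-9) -> np.ndarray:
    """cost[i, j] = (j-i+1) * ln(max(var(series[i..j]), eps)) for feasible
    segments (length >= L_min), +inf elsewhere.  Variance is the population
    variance about the segment mean; eps floors zero-variance segments."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    length = (j - i + 1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        seg_sum = s1[j + 1] - s1[i]
        seg_sq = s2[j + 1] - s2[i]
        var = seg_sq / length - (seg_sum / length) ** 2
    eps = max(float(np.var(x)), 1.0) * eps_rel
    var = np.maximum(var, eps)
    cost = length * np.log(var)
    cost[length < L_min] = np.inf
    return cost


def segment_cost(series: np.ndarray, i: int, j: int, L_min: int = 1) -> float:
    """Gaussian contrast of the inclusive segment ``series[i..j]``.

    cost = n * ln(max(sigma^2, eps)) with sigma^2 the within-segment
    (population) variance and eps a floor of 1e-9 x the series variance.
    """
    x = np.asarray(series, dtype=float)
    if j - i + 1 < L_min:
        raise ValueError(f"segment [{i}, {j}] shorter than L_min={L_min}")
    seg = x[i : j + 1]
    var = float(np.var(seg))
    eps = max(float(np.var(x)), 1.0) * 1e-9
    return len(seg) * float(np.log(max(var, eps)))


def optimal_segmentation(
    series: np.ndarray, K_max: int, L_min: int
) -> tuple[np.ndarray, list[list[int]]]:
    """Exact minimum-contrast breakpoints for every K = 1..K_max.

    Returns ``(J, breakpoints_per_K)`` where ``J[K-1]`` is the minimal total
    contrast with K segments and ``breakpoints_per_K[K-1]`` lists the start
    indices of segments 2..K (empty for K = 1).

    Raises
    ------
    ValueError
        if ``len(series) < K_max * L_min`` (names the maximal feasible K).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if K_max < 1 or L_min < 1:
        raise ValueError("K_max and L_min must be >= 1")
    if n < K_max * L_min:
        raise ValueError(
            f"series of length {n} cannot hold {K_max} segments of >= {L_min} fixes; "
            f"maximal feasible K is {n // L_min}"
        )
    C = _cost_matrix(x, L_min)
    # dp[k][j] = min cost of splitting x[0..j] into k+1 segments
    dp = np.full((K_max, n), np.inf)
    arg = np.full((K_max, n), -1, dtype=int)
    dp[0] = C[0]
    for k in range(1, K_max):
        # candidate: dp[k-1][i-1] + C[i, j] over split points i
        cand = dp[k - 1][:-1, None] + C[1:, :]  # i-1 in [0, n-2] => i in [1, n-1]
        best = np.argmin(cand, axis=0)
        dp[k] = cand[best, np.arange(n)]
        arg[k] = best + 1  # start index of the last segment
    J = dp[:, n - 1].copy()
    breakpoints: list[list[int]] = []
    for k in range(K_max):
        bps: list[int] = []
        j, kk = n - 1, k
        while kk > 0:
            i = int(arg[kk, j])
            bps.append(i)
            j, kk = i - 1, kk - 1
        breakpoints.append(sorted(bps))
    return J, breakpoints


def contrast_table(
    series: np.ndarray,
    K_max: int = DEFAULT_K_MAX,
    L_min: int = DEFAULT_L_MIN,
    S: float = DEFAULT_S,
) -> ContrastTable:
    """Run the DP sweep and assemble the standardised contrast table."""
    J, bps = optimal_segmentation(series, K_max, L_min)
    K_values = np.arange(1, K_max + 1)
    span = J[0] - J[-1]
    if span <= 0 or not np.isfinite(span):
        logger.warning("flat contrast function; standardisation degenerate")
        J_std = np.full_like(J, 1.0)
    else:
        J_std = (J[-1] - J) / (J[-1] - J[0]) * (K_max - 1) + 1
    D = np.full_like(J, np.nan)
    if K_max >= 3:
        D[1:-1] = J_std[:-2] - 2 * J_std[1:-1] + J_std[2:]
    return ContrastTable(
        K_values=K_values, J=J, J_std=J_std, D=D, L_min=L_min, S=S, breakpoints_per_K=bps
    )


def choose_kopt(table: ContrastTable, S: float | None = None) -> int:
    """K_opt = the last K whose standardised-contrast curvature D(K) exceeds S.

    Returns 1 (with a warning already logged for flat contrasts) when no K
    qualifies.
    """
    S = table.S if S is None else S
    D = table.D
    qualifying = np.flatnonzero(np.nan_to_num(D, nan=-np.inf) > S)
    if qualifying.size == 0:
        return 1
    return int(table.K_values[qualifying[-1]])


def segment_track(
    profile: FPTProfile,
    r_max: float,
    K_max: int = DEFAULT_K_MAX,
    L_min: int = DEFAULT_L_MIN,
    S: float = DEFAULT_S,
) -> Segmentation | None:
    """Segment one track's FPT series at the ARS scale r_max.

    Fixes with missing FPT at r_max are dropped before segmentation (the
    index mapping is retained); dropped fixes inherit the nearest analysed
    fix's segment label.  Tracks with fewer than ``2 * L_min`` defined values
    are skipped (returns None, reason logged).
    """
    series_full = profile.fpt_at(r_max)
    defined = np.isfinite(series_full)
    idx = np.flatnonzero(defined)
    if idx.size < 2 * L_min:
        logger.info(
            "track %s: skipped, only %d defined FPT values at r_max", profile.track_label, idx.size
        )
        return None
    series = series_full[idx]
    k_cap = min(K_max, len(series) // L_min)
    table = contrast_table(series, K_max=k_cap, L_min=L_min, S=S)
    K_opt = choose_kopt(table)
    bps = table.breakpoints_per_K[K_opt - 1]
    labels_analysed = np.zeros(len(series), dtype=int)
    for s_id, start in enumerate(bps, start=1):
        labels_analysed[start:] = s_id
    # map back: every original fix takes the label of the nearest analysed fix
    seg_id = np.empty(len(series_full), dtype=int)
    nearest = np.searchsorted(idx, np.arange(len(series_full)))
    nearest = np.clip(nearest, 0, len(idx) - 1)
    left = np.clip(nearest - 1, 0, len(idx) - 1)
    use_left = np.abs(idx[left] - np.arange(len(series_full))) <= np.abs(
        idx[nearest] - np.arange(len(series_full))
    )
    chosen = np.where(use_left, left, nearest)
    seg_id = labels_analysed[chosen]
    return Segmentation(
        track_label=profile.track_label,
        breakpoints=list(bps),
        K_opt=K_opt,
        segment_id=seg_id,
        contrast=table,
    )
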