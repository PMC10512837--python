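"""Independent brute-force reference implementations used only by tests.

These deliberately mirror none of the production code paths: correlation
surfaces are computed with explicit Python loops over lags and block
elements, and the permutation null of the rank test is enumerated over
explicit group labelings with direct pair counting.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from cardiomotion.frames import RFFrame
from cardiomotion.tracking import TrackingConfig


def zncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-normalized cross-correlation of two equal-shape patches."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0.0:
        return 0.0
    return float((a * b).sum() / denom)


def brute_force_surface(block: np.ndarray, region: np.ndarray) -> np.ndarray:
    """NCC surface by an explicit double loop over candidate offsets."""
    ba, bl = block.shape
    n_i = region.shape[0] - ba + 1
    n_j = region.shape[1] - bl + 1
    out = np.zeros((n_i, n_j))
    for i in range(n_i):
        for j in range(n_j):
            out[i, j] = zncc(block, region[i : i + ba, j : j + bl])
    return out


def naive_block_matcher(
    f_pre: RFFrame, f_post: RFFrame, config: TrackingConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-node triple-loop NCC matcher (nodes x axial lags x lateral lags).

    Returns integer-lag (d_axial, d_lateral, peak_ncc) on the same node
    grid as the production tracker.  Ties are resolved by the documented
    deterministic preference (smallest lag magnitude, then |axial|, then
    |lateral|, then non-negative sign).
    """
    ba = config.block_axial_samples(f_pre)
    bl = config.block_lateral_pitches
    ma, ml = config.search_margin_axial, config.search_margin_lateral
    shift_a, shift_l = config.shifts(f_pre)
    n_axial, n_lines = f_pre.shape
    n_nodes_a = (n_axial - ba - 2 * ma) // shift_a + 1
    n_nodes_l = (n_lines - bl - 2 * ml) // shift_l + 1

    d_axial = np.zeros((n_nodes_a, n_nodes_l))
    d_lateral = np.zeros((n_nodes_a, n_nodes_l))
    peak = np.zeros((n_nodes_a, n_nodes_l))
    for ia in range(n_nodes_a):
        sa = ma + ia * shift_a
        for jl in range(n_nodes_l):
            sl = ml + jl * shift_l
            block = f_pre.samples[sa : sa + ba, sl : sl + bl]
            best: list[tuple[float, tuple]] = []
            for di in range(-ma, ma + 1):
                for dj in range(-ml, ml + 1):
                    cand = f_post.samples[sa + di : sa + di + ba, sl + dj : sl + dj + bl]
                    best.append((zncc(block, cand), (di, dj)))
            values = np.array([v for v, _ in best])
            top = values.max()
            ties = [lag for v, lag in best if v >= top - 1e-12]
            ties.sort(key=lambda l: (l[0] ** 2 + l[1] ** 2, abs(l[0]), abs(l[1]), l[0] < 0, l[1] < 0))
            d_axial[ia, jl], d_lateral[ia, jl] = ties[0]
            peak[ia, jl] = top
    return d_axial, d_lateral, peak


def permutation_mwu_two_sided(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating group labelings.

    U is computed by direct pair counting (ties count one half); the
    p-value is the fraction of labelings whose U deviates from the null
    mean at least as much as the observed U.
    """

    def u_stat(x: np.ndarray, y: np.ndarray) -> float:
        return float(sum(1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in x for yi in y))

    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n = len(pooled)
    n_a = len(a)
    u_obs = u_stat(a, b)
    mu = n_a * (n - n_a) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(n), n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return u_obs, count / total
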