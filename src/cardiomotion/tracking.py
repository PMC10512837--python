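"""NCC/VNCC block-matching displacement estimation on RF frames.

For every node of a regular grid over the pre-frame, a matching block (MB)
is compared against all equally sized candidate blocks (CBs) inside a
search region of the post-frame; the lag of the maximum zero-normalized
cross-correlation (ZNCC) is the displacement estimate, optionally refined
to sub-sample precision by a 1-D parabolic fit through the correlation
peak.  The vectorized implementation (VNCC) evaluates all nodes
simultaneously per lag and is numerically equivalent to the per-block
loop — vectorization is an efficiency contract only.

Grid semantics: the block size is ``block_axial_wavelengths`` carrier
wavelengths axially by ``block_lateral_pitches`` beam lines laterally; the
stride between adjacent nodes is ``max(1, round(block * (1 - overlap/100)))``
in each axis, so 99.9 % overlap yields a stride of one RF sample.
Incremental per-pair displacements are accumulated on a fixed pixel grid
(Eulerian summation) into the cumulative axial displacement map CD_A, in
mm with positive values pointing away from the probe (downward).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import RegularGridInterpolator

from .frames import RFFrame

# node flag bits
FLAG_ZERO_VARIANCE = 1
FLAG_BORDER_PEAK = 2
FLAG_TIE = 4
FLAG_LOW_SIGNAL = 8

_NCC_TIE_TOL = 1e-12


@dataclass(frozen=True)
class TrackingConfig:
    """Block-matching parameters.

    ``block_axial_wavelengths`` and ``block_lateral_pitches`` default to the
    4-wavelength x 7-pitch block established for hybrid deformation
    scenarios.  ``overlap_percent`` controls the node-grid stride (see
    module docstring); search margins must exceed the per-frame motion.

    ``median_filter_size`` post-filters the per-node displacement map with
    a small spatial median (nearest-edge handling).  Raw-RF correlation
    surfaces carry carrier side-lobes one wavelength from the true lag;
    near half-sample offsets speckle fluctuation occasionally lets a
    side-lobe win ("peak hopping"), and the median removes these isolated
    one-wavelength outliers — the standard remedy in elastography.  Set to
    ``None`` to obtain the unfiltered argmax estimates.

    ``min_block_rms_ratio`` rejects echo-free matching blocks: a node whose
    pre-frame block RMS falls below this fraction (default 0.1, i.e.
    -20 dB) of the strongest block is considered to carry no displacement
    information and is replaced by its nearest informative neighbor.  The
    threshold is set to exceed the point-spread-function leakage level
    found adjacent to bright boundaries (cavity, shadow), whose smooth
    tails otherwise correlate deceptively well at near-zero lag; lower it
    for acquisitions with a genuinely large tissue dynamic range, or set
    ``None`` to disable.
    """

    block_axial_wavelengths: float = 4.0
    block_lateral_pitches: int = 7
    overlap_percent: float = 80.0
    search_margin_axial: int = 8
    search_margin_lateral: int = 2
    subsample_refinement: bool = True
    median_filter_size: int | None = 3
    min_block_rms_ratio: float | None = 0.1

    def __post_init__(self) -> None:
        if not 10.0 <= self.overlap_percent <= 99.9:
            raise ValueError("overlap_percent must be in [10, 99.9]")
        if self.block_axial_wavelengths <= 0 or self.block_lateral_pitches < 1:
            raise ValueError("block dimensions must be positive")
        if self.search_margin_axial < 1 or self.search_margin_lateral < 1:
            raise ValueError("search margins must be >= 1")
        if self.median_filter_size is not None and self.median_filter_size < 2:
            raise ValueError("median_filter_size must be >= 2 or None")

    def block_axial_samples(self, frame: RFFrame) -> int:
        n = int(round(self.block_axial_wavelengths * frame.wavelength_samples))
        if n < 3:
            raise ValueError("axial block smaller than 3 samples; raise block size or fs/f0")
        return n

    def shifts(self, frame: RFFrame) -> tuple[int, int]:
        """Node-grid strides (axial samples, lateral lines)."""
        frac = 1.0 - self.overlap_percent / 100.0
        shift_a = max(1, int(round(self.block_axial_samples(frame) * frac)))
        shift_l = max(1, int(round(self.block_lateral_pitches * frac)))
        return shift_a, shift_l


@dataclass
class DisplacementField:
    """Per-node displacement estimates on a regular block-center grid.

    ``node_axial`` / ``node_lateral`` are the block-center coordinates in
    sample / line indices (half-integer for even block sizes); ``d_axial``
    and ``d_lateral`` are in RF samples and beam lines respectively.
    ``flags`` is a per-node bitmask (zero-variance, border peak, NCC tie).
    """

    node_axial: np.ndarray
    node_lateral: np.ndarray
    d_axial: np.ndarray
    d_lateral: np.ndarray
    peak_ncc: np.ndarray
    flags: np.ndarray
    search_margin_axial: int
    search_margin_lateral: int

    def __post_init__(self) -> None:
        shape = (len(self.node_axial), len(self.node_lateral))
        for name in ("d_axial", "d_lateral", "peak_ncc", "flags"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} must have shape (n_axial_nodes, n_lateral_nodes)")
        if np.any(np.diff(self.node_axial) <= 0) or np.any(np.diff(self.node_lateral) <= 0):
            raise ValueError("node grids must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.d_axial.shape


@dataclass
class CdaMap:
    """Dense cumulative axial displacement over the image, in mm.

    Positive values are movement away from the probe (downward).
    """

    values: np.ndarray
    mm_per_sample: float

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# Correlation primitives
# ---------------------------------------------------------------------------


def _zncc_norm(block: np.ndarray) -> tuple[np.ndarray, float]:
    zm = block - block.mean()
    return zm, float(np.sqrt((zm**2).sum()))


def ncc_surface(matching_block: np.ndarray, search_region: np.ndarray) -> np.ndarray:
    """ZNCC of ``matching_block`` against every candidate in ``search_region``.

    The surface is indexed by the candidate's top-left offset within the
    search region: ``surface[i, j]`` correlates the block with
    ``search_region[i:i+ba, j:j+bl]``.  Values lie in [-1, 1] up to
    rounding; a zero-variance block or candidate yields 0 at that lag.
    """
    mb = np.asarray(matching_block, dtype=float)
    sr = np.asarray(search_region, dtype=float)
    if mb.ndim != 2 or sr.ndim != 2:
        raise ValueError("block and search region must be 2-D")
    if sr.shape[0] <= mb.shape[0] or sr.shape[1] <= mb.shape[1]:
        raise ValueError("search region must be strictly larger than the block in both dims")
    ba, bl = mb.shape
    mb_zm, mb_norm = _zncc_norm(mb)
    n_i = sr.shape[0] - ba + 1
    n_j = sr.shape[1] - bl + 1
    surface = np.zeros((n_i, n_j))
    if mb_norm == 0.0:
        return surface
    candidates = sliding_window_view(sr, (ba, bl))
    cross = np.einsum("ij,abij->ab", mb_zm, candidates)
    s1 = candidates.sum(axis=(2, 3))
    s2 = (candidates**2).sum(axis=(2, 3))
    var = np.maximum(s2 - s1**2 / (ba * bl), 0.0)
    norm = np.sqrt(var)
    np.divide(cross, mb_norm * norm, out=surface, where=norm > 0)
    return surface


def refine_subsample(
    surface: np.ndarray, integer_peak: tuple[int, int]
) -> tuple[float, float, bool]:
    """Sub-sample peak offset by 1-D parabolic fits through the peak.

    Fits a parabola through the peak and its two axial (resp. lateral)
    neighbors; the vertex offset is ``0.5 (l - r) / (l - 2c + r)``, clipped
    to [-0.5, 0.5] and set to 0 when the neighbors tie with the peak
    (degenerate parabola).  A peak on the surface border is not refined in
    that axis and the returned flag is set.
    """
    i, j = integer_peak
    n_i, n_j = surface.shape
    border = False

    def vertex(l: float, c: float, r: float) -> float:
        denom = l - 2.0 * c + r
        if denom == 0.0:
            return 0.0
        return float(np.clip(0.5 * (l - r) / denom, -0.5, 0.5))

    if 0 < i < n_i - 1:
        frac_a = vertex(surface[i - 1, j], surface[i, j], surface[i + 1, j])
    else:
        frac_a, border = 0.0, True
    if 0 < j < n_j - 1:
        frac_l = vertex(surface[i, j - 1], surface[i, j], surface[i, j + 1])
    else:
        frac_l, border = 0.0, True
    return frac_a, frac_l, border


def _lag_tie_rank(lags_a: np.ndarray, lags_l: np.ndarray) -> np.ndarray:
    """Deterministic preference order over lags for equal-NCC ties.

    Smaller lag magnitude wins, then smaller |axial|, then smaller
    |lateral|, then the non-negative sign (axial before lateral).
    Returns an integer rank per (lag_a, lag_l) pair; lower rank preferred.
    """
    di, dj = np.meshgrid(lags_a, lags_l, indexing="ij")
    keys = list(
        zip(
            (di**2 + dj**2).ravel(),
            np.abs(di).ravel(),
            np.abs(dj).ravel(),
            (di < 0).ravel(),
            (dj < 0).ravel(),
        )
    )
    order = sorted(range(len(keys)), key=lambda k: keys[k])
    rank = np.empty(len(keys), dtype=int)
    rank[order] = np.arange(len(keys))
    return rank.reshape(di.shape)


# ---------------------------------------------------------------------------
# Vectorized block matching
# ---------------------------------------------------------------------------


def vncc_displacement(
    f_pre: RFFrame, f_post: RFFrame, config: TrackingConfig | None = None
) -> DisplacementField:
    """Block-matching displacement field between two successive RF frames.

    Numerically identical to a naive per-block NCC loop over the same node
    grid; nodes whose search window would exit the frame are not part of
    the grid.  The number of axial nodes is
    ``floor((n_axial - block - 2 margin) / stride) + 1`` and analogously
    laterally.
    """
    if config is None:
        config = TrackingConfig()
    if f_pre.shape != f_post.shape:
        raise ValueError("frames must have equal shape")
    if not f_pre.same_grid(f_post):
        raise ValueError("frames must share acquisition metadata")

    ba = config.block_axial_samples(f_pre)
    bl = config.block_lateral_pitches
    ma = config.search_margin_axial
    ml = config.search_margin_lateral
    n_axial, n_lines = f_pre.shape
    if n_axial < ba + 2 * ma or n_lines < bl + 2 * ml:
        raise ValueError("frame too small for the block size and search margins")

    shift_a, shift_l = config.shifts(f_pre)
    n_nodes_a = (n_axial - ba - 2 * ma) // shift_a + 1
    n_nodes_l = (n_lines - bl - 2 * ml) // shift_l + 1
    starts_a = ma + shift_a * np.arange(n_nodes_a)
    starts_l = ml + shift_l * np.arange(n_nodes_l)

    pre = f_pre.samples
    post = f_post.samples
    pre_windows = sliding_window_view(pre, (ba, bl))
    pre_blocks = pre_windows[np.ix_(starts_a, starts_l)]
    pre_zm = pre_blocks - pre_blocks.mean(axis=(2, 3), keepdims=True)
    pre_norm = np.sqrt((pre_zm**2).sum(axis=(2, 3)))
    zero_var_pre = pre_norm == 0.0
    pre_unit = np.divide(
        pre_zm, pre_norm[..., None, None], out=np.zeros_like(pre_zm), where=~zero_var_pre[..., None, None]
    )

    post_windows = sliding_window_view(post, (ba, bl))
    lags_a = np.arange(-ma, ma + 1)
    lags_l = np.arange(-ml, ml + 1)
    surfaces = np.empty((n_nodes_a, n_nodes_l, lags_a.size, lags_l.size))
    n_blk = ba * bl
    for ia, di in enumerate(lags_a):
        rows = post_windows[starts_a + di]
        for jl, dj in enumerate(lags_l):
            blocks = rows[:, starts_l + dj]
            cross = np.einsum("abij,abij->ab", pre_unit, blocks)
            s1 = blocks.sum(axis=(2, 3))
            s2 = (blocks**2).sum(axis=(2, 3))
            norm = np.sqrt(np.maximum(s2 - s1**2 / n_blk, 0.0))
            zero_var_post = norm == 0.0
            ncc = np.divide(cross, norm, out=np.zeros_like(cross), where=~zero_var_post)
            ncc[zero_var_pre] = 0.0
            surfaces[:, :, ia, jl] = ncc

    # peak selection with deterministic tie-breaking
    flat = surfaces.reshape(n_nodes_a, n_nodes_l, -1)
    peak_val = flat.max(axis=2)
    is_candidate = flat >= (peak_val[..., None] - _NCC_TIE_TOL)
    tie = is_candidate.sum(axis=2) > 1
    rank = _lag_tie_rank(lags_a, lags_l).ravel()
    masked_rank = np.where(is_candidate, rank[None, None, :], rank.size)
    chosen = masked_rank.argmin(axis=2)
    ci, cj = np.unravel_index(chosen, (lags_a.size, lags_l.size))
    d_axial = lags_a[ci].astype(float)
    d_lateral = lags_l[cj].astype(float)
    peak_ncc = np.take_along_axis(flat, chosen[..., None], axis=2)[..., 0]

    flags = np.zeros((n_nodes_a, n_nodes_l), dtype=np.uint8)
    flags[zero_var_pre] |= FLAG_ZERO_VARIANCE
    flags[tie] |= FLAG_TIE
    if config.min_block_rms_ratio is not None and pre_norm.max() > 0:
        flags[pre_norm < config.min_block_rms_ratio * pre_norm.max()] |= FLAG_LOW_SIGNAL

    if config.subsample_refinement:
        interior_a = (ci > 0) & (ci < lags_a.size - 1)
        interior_l = (cj > 0) & (cj < lags_l.size - 1)
        node_idx = np.indices((n_nodes_a, n_nodes_l))
        a_idx, l_idx = node_idx[0], node_idx[1]

        def parab(left: np.ndarray, center: np.ndarray, right: np.ndarray) -> np.ndarray:
            denom = left - 2.0 * center + right
            frac = np.zeros_like(center)
            np.divide(0.5 * (left - right), denom, out=frac, where=denom != 0)
            return np.clip(frac, -0.5, 0.5)

        ci_in = np.clip(ci, 1, lags_a.size - 2)
        frac_a = parab(
            surfaces[a_idx, l_idx, ci_in - 1, cj],
            surfaces[a_idx, l_idx, ci_in, cj],
            surfaces[a_idx, l_idx, ci_in + 1, cj],
        )
        d_axial += np.where(interior_a, frac_a, 0.0)
        cj_in = np.clip(cj, 1, lags_l.size - 2)
        frac_l = parab(
            surfaces[a_idx, l_idx, ci, cj_in - 1],
            surfaces[a_idx, l_idx, ci, cj_in],
            surfaces[a_idx, l_idx, ci, cj_in + 1],
        )
        d_lateral += np.where(interior_l, frac_l, 0.0)
        flags[~(interior_a & interior_l)] |= FLAG_BORDER_PEAK

    # zero-variance and echo-free nodes carry no displacement information:
    # replace them by the nearest informative node so they do not
    # contaminate filtering and densification
    invalid = (flags & (FLAG_ZERO_VARIANCE | FLAG_LOW_SIGNAL)) > 0
    if invalid.any() and not invalid.all():
        from scipy.ndimage import distance_transform_edt

        _, nearest = distance_transform_edt(invalid, return_indices=True)
        d_axial = d_axial[nearest[0], nearest[1]]
        d_lateral = d_lateral[nearest[0], nearest[1]]

    if config.median_filter_size is not None:
        from scipy.ndimage import median_filter

        size = (
            min(config.median_filter_size, n_nodes_a),
            min(config.median_filter_size, n_nodes_l),
        )
        d_axial = median_filter(d_axial, size=size, mode="nearest")
        d_lateral = median_filter(d_lateral, size=size, mode="nearest")

    return DisplacementField(
        node_axial=starts_a + (ba - 1) / 2.0,
        node_lateral=starts_l + (bl - 1) / 2.0,
        d_axial=d_axial,
        d_lateral=d_lateral,
        peak_ncc=peak_ncc,
        flags=flags,
        search_margin_axial=ma,
        search_margin_lateral=ml,
    )


# ---------------------------------------------------------------------------
# Densification and cumulation
# ---------------------------------------------------------------------------


def densify_field(field: DisplacementField, frame_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear interpolation of node displacements to the dense pixel grid.

    Pixels outside the node hull take the value at the nearest hull point
    (constant extension — node grids never reach the frame border because
    search windows must fit inside the frame).  Returns (axial in samples,
    lateral in lines), each of shape ``frame_shape``.
    """
    zi = np.clip(np.arange(frame_shape[0], dtype=float), field.node_axial[0], field.node_axial[-1])
    xi = np.clip(np.arange(frame_shape[1], dtype=float), field.node_lateral[0], field.node_lateral[-1])

    def interp(values: np.ndarray) -> np.ndarray:
        if len(field.node_axial) == 1 and len(field.node_lateral) == 1:
            return np.full(frame_shape, values[0, 0])
        if len(field.node_axial) == 1:
            return np.tile(np.interp(xi, field.node_lateral, values[0]), (frame_shape[0], 1))
        if len(field.node_lateral) == 1:
            return np.tile(
                np.interp(zi, field.node_axial, values[:, 0])[:, None], (1, frame_shape[1])
            )
        rgi = RegularGridInterpolator(
            (field.node_axial, field.node_lateral), values, method="linear"
        )
        zz, xx = np.meshgrid(zi, xi, indexing="ij")
        return rgi(np.column_stack([zz.ravel(), xx.ravel()])).reshape(frame_shape)

    return interp(field.d_axial), interp(field.d_lateral)


def accumulate_displacement(
    fields: Sequence[DisplacementField],
    frame_shape: tuple[int, int],
    mm_per_sample: float,
) -> CdaMap:
    """Eulerian cumulation of incremental axial displacements into CD_A.

    Each incremental field is densified to the pixel grid, converted from
    RF samples to mm (``mm_per_sample = c / (2 fs)``), and summed at fixed
    pixel coordinates.
    """
    if len(fields) == 0:
        raise ValueError("need at least one displacement field")
    if mm_per_sample <= 0:
        raise ValueError("mm_per_sample must be positive")
    total = np.zeros(frame_shape)
    for f in fields:
        dense_a, _ = densify_field(f, frame_shape)
        total += dense_a * mm_per_sample
    return CdaMap(values=total, mm_per_sample=mm_per_sample)
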