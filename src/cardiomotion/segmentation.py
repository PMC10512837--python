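"""Semiautomatic regional and layer-specific LV myocardium segmentation.

From manually picked endocardial and epicardial key points (PLAX view) the
pipeline proceeds in five steps:

1. borders are interpolated with an arc-length-parameterized cubic spline;
2. the basal middle point (BMp, midpoint of the two basal endpoints) and
   the apical point (Ap, the border point farthest from the BMp) are found
   on each border;
3. each border is split at its apex into two sub-borders, and each
   sub-border into three sections of equal arc length;
4. corresponding endo/epi sections are joined by cross-wall cuts into six
   closed segment contours (apical/middle/basal, septal and lateral), and
   every myocardial pixel is assigned to exactly one segment;
5. each segment is stratified into 3 or 10 transmural layers of equal
   normalized wall-depth, ordered epicardium -> endocardium.

The transmural coordinate of a pixel is the distance-to-border ratio
``t = d_epi / (d_epi + d_endo)`` (t = 0 on the epicardium), which is exact
for concentric circles and well-behaved for elliptical walls.

Coordinates are in mm, axial depth increasing downward, 0-based pixel
indices; points are (axial_mm, lateral_mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import shapely
from scipy.interpolate import CubicSpline
from shapely.geometry import LineString, Polygon

from .frames import RFFrame

#: Section order along the border, anterior base -> apex -> posterior base.
#: The apical septal (A-SEP) / lateral (A-LAT) names follow the PLAX
#: six-segment convention; the mapping is configurable for other probe
#: orientations.
SEGMENT_NAMES: tuple[str, ...] = (
    "B-ANT-SEP",
    "M-ANT-SEP",
    "A-SEP",
    "A-LAT",
    "M-INF-LAT",
    "B-INF-LAT",
)


@dataclass(frozen=True)
class PixelGrid:
    """Physical positions of pixel centers (mm)."""

    axial_positions_mm: np.ndarray
    lateral_positions_mm: np.ndarray

    @classmethod
    def from_frame(cls, frame: RFFrame) -> "PixelGrid":
        return cls(frame.axial_positions_mm, frame.lateral_positions_mm)

    @classmethod
    def regular(
        cls,
        axial_range_mm: tuple[float, float],
        lateral_range_mm: tuple[float, float],
        spacing_mm: tuple[float, float],
    ) -> "PixelGrid":
        dz, dx = spacing_mm
        return cls(
            np.arange(axial_range_mm[0], axial_range_mm[1] + dz / 2, dz),
            np.arange(lateral_range_mm[0], lateral_range_mm[1] + dx / 2, dx),
        )

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.axial_positions_mm), len(self.lateral_positions_mm)

    @property
    def spacing_mm(self) -> tuple[float, float]:
        return (
            float(np.diff(self.axial_positions_mm).mean()),
            float(np.diff(self.lateral_positions_mm).mean()),
        )

    def pixel_centers(self) -> np.ndarray:
        """(N, 2) array of (axial_mm, lateral_mm) for all pixels, row-major."""
        zz, xx = np.meshgrid(self.axial_positions_mm, self.lateral_positions_mm, indexing="ij")
        return np.column_stack([zz.ravel(), xx.ravel()])


@dataclass
class BorderTrace:
    """Interpolated open border polyline, base -> apex -> base."""

    points: np.ndarray
    role: str = "endo"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 3 or self.points.shape[1] != 2:
            raise ValueError("a border needs >= 3 (axial, lateral) points")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ValueError("border contains duplicate consecutive points")
        if not LineString(self.points[:, ::-1]).is_simple:
            raise ValueError("border polyline must not self-intersect")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at every point (starts at 0)."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


class ApicalPoint(NamedTuple):
    point: np.ndarray
    index: int
    tie: bool


@dataclass
class LandmarkSet:
    """Basal middle points and apical points of both borders."""

    endo_bmp: np.ndarray
    epi_bmp: np.ndarray
    endo_apex: np.ndarray
    epi_apex: np.ndarray
    endo_apex_index: int
    epi_apex_index: int


@dataclass
class SegmentationResult:
    """Six segment masks plus per-segment transmural layer masks.

    ``segment_masks`` maps segment name to a boolean pixel mask; the six
    masks are pairwise disjoint and their union is ``myocardium_mask``.
    ``layer_masks[n][name]`` is the ordered (epicardium -> endocardium)
    list of ``n`` layer masks of that segment; per segment, layers are
    disjoint and tile the segment mask exactly.
    """

    grid: PixelGrid
    myocardium_mask: np.ndarray
    segment_masks: dict[str, np.ndarray]
    layer_masks: dict[int, dict[str, list[np.ndarray]]] = field(default_factory=dict)
    landmarks: LandmarkSet | None = None

    @property
    def pixel_geometry(self) -> tuple[float, float]:
        return self.grid.spacing_mm


# ---------------------------------------------------------------------------
# Steps 1-3: border interpolation, landmarks, equal-arc division
# ---------------------------------------------------------------------------


def interpolate_border(key_points: np.ndarray, n_points: int, role: str = "endo") -> BorderTrace:
    """Arc-length-parameterized cubic-spline resampling of picked key points.

    The spline passes through every key point; the returned trace has
    ``n_points`` samples equally spaced in arc length, with both endpoints
    preserved exactly.
    """
    kp = np.atleast_2d(np.asarray(key_points, dtype=float))
    if kp.shape[0] < 4:
        raise ValueError("need at least 4 key points")
    if n_points < kp.shape[0]:
        raise ValueError("n_points must not undersample the key points")
    steps = np.linalg.norm(np.diff(kp, axis=0), axis=1)
    if np.any(steps == 0):
        raise ValueError("duplicate consecutive key points")
    chord = np.concatenate([[0.0], np.cumsum(steps)])
    spline = CubicSpline(chord, kp, axis=0)

    # invert arc length on a dense evaluation of the spline
    dense_t = np.linspace(0.0, chord[-1], max(20 * n_points, 1000))
    dense_pts = spline(dense_t)
    dense_arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(dense_pts, axis=0), axis=1))]
    )
    target_arc = np.linspace(0.0, dense_arc[-1], n_points)
    t_of_arc = np.interp(target_arc, dense_arc, dense_t)
    pts = spline(t_of_arc)
    pts[0] = kp[0]
    pts[-1] = kp[-1]
    return BorderTrace(points=pts, role=role)


def basal_middle_point(border: BorderTrace) -> np.ndarray:
    """Midpoint of the two basal endpoints of the border."""
    return 0.5 * (border.points[0] + border.points[-1])


def apical_point(border: BorderTrace, bmp: np.ndarray) -> ApicalPoint:
    """Border point farthest from the basal middle point.

    Ties (within 1e-9 relative distance) are broken by the smallest index
    and flagged.
    """
    d = np.linalg.norm(border.points - np.asarray(bmp, dtype=float), axis=1)
    d_max = d.max()
    near = np.flatnonzero(d >= d_max * (1.0 - 1e-9))
    idx = int(near[0])
    return ApicalPoint(point=border.points[idx].copy(), index=idx, tie=near.size > 1)


def find_landmarks(endo: BorderTrace, epi: BorderTrace) -> LandmarkSet:
    """Basal middle points and apical points for both borders (Step 2)."""
    endo_bmp = basal_middle_point(endo)
    epi_bmp = basal_middle_point(epi)
    endo_ap = apical_point(endo, endo_bmp)
    epi_ap = apical_point(epi, epi_bmp)
    return LandmarkSet(
        endo_bmp=endo_bmp,
        epi_bmp=epi_bmp,
        endo_apex=endo_ap.point,
        epi_apex=epi_ap.point,
        endo_apex_index=endo_ap.index,
        epi_apex_index=epi_ap.index,
    )


def _split_equal_arc(points: np.ndarray, n_sections: int = 3) -> list[np.ndarray]:
    """Split a polyline into sections of equal arc length.

    Cut points at fractional positions are linearly interpolated and
    included as endpoints of both adjacent sections, so all original
    points are retained.
    """
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    sections: list[np.ndarray] = []
    prev_cut_pt = points[0]
    prev_idx = 0
    for k in range(1, n_sections + 1):
        target = total * k / n_sections
        if k == n_sections:
            sec = np.vstack([prev_cut_pt, points[prev_idx + 1 :]])
            sections.append(sec)
            break
        j = int(np.searchsorted(arc, target) - 1)
        j = min(max(j, 0), len(seg) - 1)
        frac = (target - arc[j]) / seg[j] if seg[j] > 0 else 0.0
        cut_pt = points[j] + frac * (points[j + 1] - points[j])
        sec = np.vstack([prev_cut_pt, points[prev_idx + 1 : j + 1], cut_pt])
        sections.append(sec)
        prev_cut_pt = cut_pt
        prev_idx = j
    return sections


def divide_border(border: BorderTrace, apex_index: int) -> list[np.ndarray]:
    """Split a border at its apex into 6 equal-arc sections (Step 3).

    The border is cut at the apex into two sub-borders, each divided into
    three sections of equal arc length; the 6 sections are returned in
    order anterior-base -> apex -> posterior-base.
    """
    if not 0 < apex_index < border.n_points - 1:
        raise ValueError("apex must be strictly interior to the border")
    first = border.points[: apex_index + 1]
    second = border.points[apex_index:]
    return _split_equal_arc(first, 3) + _split_equal_arc(second, 3)


# ---------------------------------------------------------------------------
# Step 4: segment contours and pixel assignment
# ---------------------------------------------------------------------------


def _segment_polygon(endo_section: np.ndarray, epi_section: np.ndarray) -> Polygon:
    # shapely uses (x, y); our points are (axial, lateral) -> pass as (lateral, axial)
    ring = np.vstack([endo_section, epi_section[::-1]])[:, ::-1]
    poly = Polygon(ring)
    if not poly.is_valid or poly.area == 0.0:
        raise ValueError("segment contour is degenerate or its cross-wall cuts intersect")
    return poly


def _wall_polygon(endo_points: np.ndarray, epi_points: np.ndarray) -> Polygon:
    ring = np.vstack([endo_points, epi_points[::-1]])[:, ::-1]
    poly = Polygon(ring)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def build_segments(
    endo_sections: Sequence[np.ndarray],
    epi_sections: Sequence[np.ndarray],
    pixel_grid: PixelGrid,
    segment_names: Sequence[str] = SEGMENT_NAMES,
    landmarks: LandmarkSet | None = None,
) -> SegmentationResult:
    """Assign every myocardial pixel to exactly one of six wall segments.

    Corresponding endo/epi sections are closed into quadrilateral-like
    contours by the two cross-wall cuts; pixel centers are assigned by
    point-in-polygon in a fixed documented order (boundary pixels go to
    the first containing segment; numerically unclaimed pixels to the
    nearest contour), so the six masks are pairwise disjoint and tile the
    myocardium mask exactly.
    """
    if len(endo_sections) != 6 or len(epi_sections) != 6:
        raise ValueError("expected 6 endo and 6 epi sections")
    if len(segment_names) != 6 or len(set(segment_names)) != 6:
        raise ValueError("expected 6 distinct segment names")

    polygons = [
        _segment_polygon(e, p) for e, p in zip(endo_sections, epi_sections)
    ]
    endo_full = np.vstack([endo_sections[0]] + [s[1:] for s in endo_sections[1:]])
    epi_full = np.vstack([epi_sections[0]] + [s[1:] for s in epi_sections[1:]])
    wall = _wall_polygon(endo_full, epi_full)

    centers = pixel_grid.pixel_centers()
    pts = shapely.points(centers[:, ::-1])  # (lateral, axial) -> (x, y)
    myo_flat = shapely.covers(wall, pts)
    shape = pixel_grid.shape

    assignment = np.full(centers.shape[0], -1, dtype=int)
    idx_myo = np.flatnonzero(myo_flat)
    remaining = idx_myo.copy()
    for s, poly in enumerate(polygons):
        if remaining.size == 0:
            break
        inside = shapely.covers(poly, pts[remaining])
        assignment[remaining[inside]] = s
        remaining = remaining[~inside]
    if remaining.size:
        # pixels on numeric gaps between contours: nearest contour wins
        dists = np.column_stack([shapely.distance(pts[remaining], poly) for poly in polygons])
        assignment[remaining] = dists.argmin(axis=1)

    segment_masks = {
        name: (assignment == s).reshape(shape) for s, name in enumerate(segment_names)
    }
    return SegmentationResult(
        grid=pixel_grid,
        myocardium_mask=myo_flat.reshape(shape),
        segment_masks=segment_masks,
        landmarks=landmarks,
    )


# ---------------------------------------------------------------------------
# Step 5: transmural layer stratification
# ---------------------------------------------------------------------------


def transmural_coordinate(
    points: np.ndarray, endo_border: BorderTrace, epi_border: BorderTrace
) -> np.ndarray:
    """Normalized wall depth t = d_epi / (d_epi + d_endo) for (N, 2) points.

    t = 0 on the epicardial border, t = 1 on the endocardial border.
    """
    p = np.atleast_2d(points)
    pts = shapely.points(p[:, ::-1])
    endo_line = LineString(endo_border.points[:, ::-1])
    epi_line = LineString(epi_border.points[:, ::-1])
    d_endo = shapely.distance(pts, endo_line)
    d_epi = shapely.distance(pts, epi_line)
    denom = d_endo + d_epi
    t = np.zeros(p.shape[0])
    np.divide(d_epi, denom, out=t, where=denom > 0)
    return t


def stratify_layers(
    segmentation: SegmentationResult,
    endo_border: BorderTrace,
    epi_border: BorderTrace,
    n_layers: int,
) -> SegmentationResult:
    """Divide every segment into ``n_layers`` equal-width transmural layers.

    Each myocardial pixel gets a layer index ``floor(t * n_layers)``
    (clamped) from its normalized wall depth t; layer masks are the
    intersection of a layer band with a segment mask, ordered
    epicardium -> endocardium (layer 1 = EpiL).  Modifies and returns
    ``segmentation``.
    """
    if n_layers not in (3, 10):
        raise ValueError("n_layers must be 3 or 10")
    grid = segmentation.grid
    centers = grid.pixel_centers()
    myo = segmentation.myocardium_mask.ravel()
    t = np.full(centers.shape[0], np.nan)
    t[myo] = transmural_coordinate(centers[myo], endo_border, epi_border)
    layer_idx = np.full(centers.shape[0], -1, dtype=int)
    layer_idx[myo] = np.clip((t[myo] * n_layers).astype(int), 0, n_layers - 1)
    layer_grid = layer_idx.reshape(grid.shape)

    per_segment: dict[str, list[np.ndarray]] = {}
    for name, seg_mask in segmentation.segment_masks.items():
        per_segment[name] = [(seg_mask & (layer_grid == k)) for k in range(n_layers)]
    segmentation.layer_masks[n_layers] = per_segment
    return segmentation


# ---------------------------------------------------------------------------
# Convenience: full Steps 1-5
# ---------------------------------------------------------------------------


def segment_myocardium(
    endo_key_points: np.ndarray,
    epi_key_points: np.ndarray,
    pixel_grid: PixelGrid,
    n_points: int = 400,
    layer_counts: Sequence[int] = (3, 10),
    segment_names: Sequence[str] = SEGMENT_NAMES,
) -> SegmentationResult:
    """Run the five segmentation steps from picked key points."""
    endo = interpolate_border(endo_key_points, n_points, role="endo")
    epi = interpolate_border(epi_key_points, n_points, role="epi")
    landmarks = find_landmarks(endo, epi)
    endo_sections = divide_border(endo, landmarks.endo_apex_index)
    epi_sections = divide_border(epi, landmarks.epi_apex_index)
    result = build_segments(
        endo_sections, epi_sections, pixel_grid, segment_names=segment_names, landmarks=landmarks
    )
    for n in layer_counts:
        stratify_layers(result, endo, epi, n)
    return result
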