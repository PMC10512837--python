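"""Synthetic RF speckle simulator with analytically known ground-truth motion.

Speckle is produced by the standard linear scatterer-convolution model: a
cloud of random sub-resolution point scatterers is convolved with a
separable point-spread function (Gaussian axial pulse envelope modulated by
a cosine carrier at the probe center frequency, Gaussian lateral beam
profile).  Tissue motion is imposed exactly by moving the scatterers
themselves between frames — never by resampling rendered frames — so the
inter-frame displacement field is known in closed form at every position.

The left-ventricle phantom is a half-elliptical annulus open at the base,
mimicking the parasternal long-axis (PLAX) view with the apex at maximal
depth.  A transmural-gradient motion model imposes a controlled
epicardium-to-endocardium motion difference across the wall, which the
downstream layer analysis should recover as the transmural motion index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .frames import RFFrame, sample_spacing_mm

#: mm padding beyond which a scatterer's PSF contribution is truncated
_PSF_TRUNCATION_SIGMAS = 4.5


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Region:
    """Rectangular extent in mm: axial (depth) and lateral intervals."""

    axial_min: float
    axial_max: float
    lateral_min: float
    lateral_max: float

    def __post_init__(self) -> None:
        if not (self.axial_max > self.axial_min and self.lateral_max > self.lateral_min):
            raise ValueError("region must have positive extent in both axes")

    @property
    def area_mm2(self) -> float:
        return (self.axial_max - self.axial_min) * (self.lateral_max - self.lateral_min)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized membership test for (N, 2) arrays of (axial, lateral) mm."""
        p = np.atleast_2d(points)
        return (
            (p[:, 0] >= self.axial_min)
            & (p[:, 0] <= self.axial_max)
            & (p[:, 1] >= self.lateral_min)
            & (p[:, 1] <= self.lateral_max)
        )


# ---------------------------------------------------------------------------
# Scatterer scenes
# ---------------------------------------------------------------------------


@dataclass
class ScattererScene:
    """A cloud of point scatterers inside a rectangular region.

    ``positions`` is an (N, 2) array of (axial_mm, lateral_mm); ``amplitudes``
    holds the real reflectivity of each scatterer.  The scene is a pure
    function of its construction arguments and ``seed``.
    """

    positions: np.ndarray
    amplitudes: np.ndarray
    region: Region
    seed: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.positions.shape[1] != 2:
            raise ValueError("positions must be (N, 2): (axial_mm, lateral_mm)")
        if self.amplitudes.shape != (self.positions.shape[0],):
            raise ValueError("amplitudes must be one scalar per scatterer")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("scatterer positions must be finite")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("scatterer amplitudes must be finite")

    @property
    def n_scatterers(self) -> int:
        return self.positions.shape[0]

    def replace_positions(self, positions: np.ndarray) -> "ScattererScene":
        return ScattererScene(
            positions=positions,
            amplitudes=self.amplitudes.copy(),
            region=self.region,
            seed=self.seed,
        )


def make_scatterer_field(
    region: Region,
    density_per_mm2: float,
    amplitude_sd: float = 1.0,
    seed: int = 0,
) -> ScattererScene:
    """Draw a uniform random scatterer cloud in ``region``.

    The scatterer count is ``round(density_per_mm2 * region.area_mm2)``;
    positions are i.i.d. uniform in the region and amplitudes zero-mean
    Gaussian with standard deviation ``amplitude_sd``.  Identical arguments
    (including ``seed``) produce bit-identical scenes.
    """
    if density_per_mm2 <= 0:
        raise ValueError("density_per_mm2 must be positive")
    if amplitude_sd <= 0:
        raise ValueError("amplitude_sd must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(density_per_mm2 * region.area_mm2))
    axial = rng.uniform(region.axial_min, region.axial_max, size=n)
    lateral = rng.uniform(region.lateral_min, region.lateral_max, size=n)
    amplitudes = rng.normal(0.0, amplitude_sd, size=n)
    return ScattererScene(
        positions=np.column_stack([axial, lateral]),
        amplitudes=amplitudes,
        region=region,
        seed=seed,
    )


def warp_scene(
    scene: ScattererScene,
    displacement_fn: Callable[[np.ndarray], np.ndarray],
) -> ScattererScene:
    """Move every scatterer by ``displacement_fn`` evaluated at its position.

    ``displacement_fn`` maps an (N, 2) array of (axial_mm, lateral_mm)
    positions to an (N, 2) array of (axial_mm, lateral_mm) displacements.
    Amplitudes are unchanged, so speckle decorrelation in the rendered
    frames comes only from scatterer rearrangement, as in real tissue.
    """
    disp = np.asarray(displacement_fn(scene.positions), dtype=float)
    if disp.shape != scene.positions.shape:
        raise ValueError("displacement_fn must return one (axial, lateral) pair per scatterer")
    return scene.replace_positions(scene.positions + disp)


# ---------------------------------------------------------------------------
# Point-spread function and rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsfParams:
    """Separable Gaussian-envelope PSF parameters.

    Defaults mimic a high-frequency small-animal probe: 21 MHz center
    frequency, sampled at 4x the carrier, a Gaussian pulse of ~60 %
    fractional bandwidth (envelope sigma of half a carrier period — a
    narrower pulse raises the RF correlation side-lobes one wavelength
    from the true lag and makes block matching peak-hop) and a lateral
    beam width of a couple of element pitches.
    """

    center_frequency: float = 21e6  # Hz
    sampling_frequency: float = 84e6  # Hz, >= 4x f0
    sound_speed: float = 1540.0  # m/s
    axial_pulse_sigma: float = 0.5 / 21e6  # s (Gaussian envelope sigma)
    lateral_beam_sigma: float = 0.15  # mm
    pitch: float = 0.09  # mm

    def __post_init__(self) -> None:
        for name in (
            "center_frequency",
            "sampling_frequency",
            "sound_speed",
            "axial_pulse_sigma",
            "lateral_beam_sigma",
            "pitch",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sampling_frequency < 4.0 * self.center_frequency:
            raise ValueError("sampling_frequency must be >= 4x center_frequency")

    @property
    def sample_spacing_mm(self) -> float:
        return sample_spacing_mm(self.sound_speed, self.sampling_frequency)

    @property
    def axial_sigma_mm(self) -> float:
        """Axial envelope sigma converted from pulse duration to depth."""
        return self.axial_pulse_sigma * self.sound_speed / 2.0 * 1e3

    @property
    def wavelength_mm(self) -> float:
        return self.sound_speed / (2.0 * self.center_frequency) * 1e3


def render_rf_frame(scene: ScattererScene, psf: PsfParams) -> RFFrame:
    """Render a scatterer scene to an RF frame by PSF superposition.

    The frame grid spans the scene region with axial step ``c / (2 fs)`` and
    lateral step ``pitch``.  Each scatterer contributes a separable kernel::

        a * exp(-(z - z_s)^2 / (2 sz^2)) * cos(4 pi f0 (z - z_s) / c)
            * exp(-(x - x_s)^2 / (2 sx^2))

    The sum is exactly linear in the amplitudes.  Scatterers outside the
    renderable extent contribute only through the tail of their kernel and
    are otherwise silently truncated.
    """
    region = scene.region
    ds = psf.sample_spacing_mm
    n_axial = int(np.floor((region.axial_max - region.axial_min) / ds)) + 1
    n_lines = int(np.floor((region.lateral_max - region.lateral_min) / psf.pitch)) + 1
    z_axis = region.axial_min + np.arange(n_axial) * ds
    x_axis = region.lateral_min + np.arange(n_lines) * psf.pitch

    sz = psf.axial_sigma_mm
    sx = psf.lateral_beam_sigma
    # carrier phase per mm of depth offset (pulse-echo: factor 2 path length)
    k_carrier = 4.0 * np.pi * psf.center_frequency / (psf.sound_speed * 1e3)

    frame = np.zeros((n_axial, n_lines))
    half_z = _PSF_TRUNCATION_SIGMAS * sz
    half_x = _PSF_TRUNCATION_SIGMAS * sx
    for (z_s, x_s), amp in zip(scene.positions, scene.amplitudes):
        i0 = max(0, int(np.ceil((z_s - half_z - region.axial_min) / ds)))
        i1 = min(n_axial, int(np.floor((z_s + half_z - region.axial_min) / ds)) + 1)
        j0 = max(0, int(np.ceil((x_s - half_x - region.lateral_min) / psf.pitch)))
        j1 = min(n_lines, int(np.floor((x_s + half_x - region.lateral_min) / psf.pitch)) + 1)
        if i0 >= i1 or j0 >= j1:
            continue  # outside renderable extent: truncated
        dz = z_axis[i0:i1] - z_s
        dx = x_axis[j0:j1] - x_s
        axial_kernel = np.exp(-0.5 * (dz / sz) ** 2) * np.cos(k_carrier * dz)
        lateral_kernel = np.exp(-0.5 * (dx / sx) ** 2)
        frame[i0:i1, j0:j1] += amp * np.outer(axial_kernel, lateral_kernel)

    return RFFrame(
        samples=frame,
        center_frequency=psf.center_frequency,
        sampling_frequency=psf.sampling_frequency,
        pitch=psf.pitch,
        sound_speed=psf.sound_speed,
        axial_origin_mm=region.axial_min,
        lateral_origin_mm=region.lateral_min,
    )


# ---------------------------------------------------------------------------
# Motion models and ground truth
# ---------------------------------------------------------------------------


class MotionModel:
    """Base class: a sequence of analytic inter-frame displacement fields.

    ``incremental(k, points)`` returns the (axial, lateral) displacement in
    mm applied between frame ``k`` and frame ``k + 1`` at material points
    given by their frame-``k`` positions.  Subclasses define fields smooth
    and small enough for block matching (a few RF samples per frame).
    """

    kind: str = "base"

    def __init__(self, n_frames: int):
        if n_frames < 2:
            raise ValueError("a motion model needs at least 2 frames")
        self.n_frames = int(n_frames)

    @property
    def n_pairs(self) -> int:
        return self.n_frames - 1

    def incremental(self, pair_index: int, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def cumulative(self, n_pairs: int, points: np.ndarray) -> np.ndarray:
        """Sum of the first ``n_pairs`` incremental fields at ``points``.

        All fields are evaluated at the given (initial, material)
        positions: a material point carries the motion determined by its
        own starting position, so the sum telescopes exactly.
        """
        if not 0 <= n_pairs <= self.n_pairs:
            raise ValueError("n_pairs out of range")
        p = np.atleast_2d(points)
        total = np.zeros((p.shape[0], 2))
        for k in range(n_pairs):
            total += self.incremental(k, p)
        return total

    def _check_pair(self, pair_index: int) -> None:
        if not 0 <= pair_index < self.n_pairs:
            raise ValueError(f"pair_index {pair_index} out of range [0, {self.n_pairs})")


class UniformMotion(MotionModel):
    """Rigid per-frame translation, identical for every frame pair."""

    kind = "uniform"

    def __init__(self, axial_mm_per_frame: float, lateral_mm_per_frame: float, n_frames: int):
        super().__init__(n_frames)
        self.axial_mm_per_frame = float(axial_mm_per_frame)
        self.lateral_mm_per_frame = float(lateral_mm_per_frame)

    def incremental(self, pair_index: int, points: np.ndarray) -> np.ndarray:
        self._check_pair(pair_index)
        p = np.atleast_2d(points)
        out = np.empty_like(p, dtype=float)
        out[:, 0] = self.axial_mm_per_frame
        out[:, 1] = self.lateral_mm_per_frame
        return out


class LinearAxialGradientMotion(MotionModel):
    """Axial displacement growing linearly with depth (uniform axial strain).

    d_axial(z) = offset + slope * (z - reference_depth), per frame pair.
    """

    kind = "linear_axial_gradient"

    def __init__(
        self,
        slope_per_frame: float,
        reference_depth_mm: float,
        n_frames: int,
        offset_mm_per_frame: float = 0.0,
    ):
        super().__init__(n_frames)
        self.slope_per_frame = float(slope_per_frame)
        self.reference_depth_mm = float(reference_depth_mm)
        self.offset_mm_per_frame = float(offset_mm_per_frame)

    def incremental(self, pair_index: int, points: np.ndarray) -> np.ndarray:
        self._check_pair(pair_index)
        p = np.atleast_2d(points)
        out = np.zeros_like(p, dtype=float)
        out[:, 0] = self.offset_mm_per_frame + self.slope_per_frame * (
            p[:, 0] - self.reference_depth_mm
        )
        return out


class TransmuralGradientMotion(MotionModel):
    """Axial motion interpolated across the wall from epicardium to endocardium.

    ``coord_fn`` maps positions to a transmural coordinate t in [0, 1]
    (t = 0 on the epicardium, t = 1 on the endocardium); the per-frame axial
    displacement at a point is ``epi + (endo - epi) * t``.  With layer
    analysis splitting the wall into 10 equal-width layers, a cumulative
    endo-epi difference of G mm corresponds to a transmural motion index of
    G / 10 mm per layer.
    """

    kind = "transmural_gradient"

    def __init__(
        self,
        coord_fn: Callable[[np.ndarray], np.ndarray],
        epi_mm_per_frame: float,
        endo_mm_per_frame: float,
        n_frames: int,
    ):
        super().__init__(n_frames)
        self.coord_fn = coord_fn
        self.epi_mm_per_frame = float(epi_mm_per_frame)
        self.endo_mm_per_frame = float(endo_mm_per_frame)

    def incremental(self, pair_index: int, points: np.ndarray) -> np.ndarray:
        self._check_pair(pair_index)
        p = np.atleast_2d(points)
        t = np.clip(np.asarray(self.coord_fn(p), dtype=float), 0.0, 1.0)
        out = np.zeros_like(p, dtype=float)
        out[:, 0] = self.epi_mm_per_frame + (self.endo_mm_per_frame - self.epi_mm_per_frame) * t
        return out


@dataclass
class GroundTruth:
    """Exact displacement oracle for a simulated sequence.

    Fields follow the material convention: they are evaluated at
    initial-geometry positions, and a material point keeps the motion
    determined by its own starting position.  The cumulative field after
    ``n`` frame pairs is therefore exactly the sum of the ``n``
    incremental fields.  For the small, smooth per-frame motions simulated
    here the fixed-grid (Eulerian) reading used by the tracker agrees to
    within the per-frame field variation, and for uniform motion exactly.
    """

    motion: MotionModel

    def incremental(self, pair_index: int, points: np.ndarray) -> np.ndarray:
        """Inter-frame (axial, lateral) displacement in mm at ``points``."""
        return self.motion.incremental(pair_index, points)

    def cumulative(self, n_pairs: int, points: np.ndarray) -> np.ndarray:
        """Sum of the first ``n_pairs`` incremental fields at ``points``."""
        return self.motion.cumulative(n_pairs, points)

    def dense_incremental(self, pair_index: int, frame: RFFrame) -> tuple[np.ndarray, np.ndarray]:
        """Incremental axial/lateral fields in mm on the full pixel grid."""
        zz, xx = np.meshgrid(frame.axial_positions_mm, frame.lateral_positions_mm, indexing="ij")
        pts = np.column_stack([zz.ravel(), xx.ravel()])
        d = self.incremental(pair_index, pts)
        return d[:, 0].reshape(frame.shape), d[:, 1].reshape(frame.shape)

    def dense_cumulative(self, n_pairs: int, frame: RFFrame) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative axial/lateral fields in mm on the full pixel grid."""
        zz, xx = np.meshgrid(frame.axial_positions_mm, frame.lateral_positions_mm, indexing="ij")
        pts = np.column_stack([zz.ravel(), xx.ravel()])
        d = self.cumulative(n_pairs, pts)
        return d[:, 0].reshape(frame.shape), d[:, 1].reshape(frame.shape)


def generate_sequence(
    scene: ScattererScene,
    psf: PsfParams,
    motion: MotionModel,
) -> tuple[list[RFFrame], GroundTruth]:
    """Render an RF sequence from warped copies of ``scene``.

    Frame 0 renders the scene as given; frame k renders the base scene
    displaced by the model's cumulative field through pair k - 1,
    evaluated at the original scatterer positions — every material
    scatterer carries the motion of its own starting point, so the
    imposed cumulative field equals the analytic ground truth exactly.
    Raises if any scatterer would leave the scene region (the ground
    truth would then no longer describe the rendered content).
    """
    frames: list[RFFrame] = [render_rf_frame(scene, psf)]
    for k in range(motion.n_pairs):
        current = warp_scene(scene, lambda pts, k=k: motion.cumulative(k + 1, pts))
        if not np.all(scene.region.contains(current.positions)):
            raise ValueError(
                f"motion model moved scatterers outside the scene region at pair {k}; "
                "enlarge the region padding or reduce the motion"
            )
        frames.append(render_rf_frame(current, psf))
    return frames, GroundTruth(motion=motion)


# ---------------------------------------------------------------------------
# LV phantom (half-elliptical annulus, PLAX-like)
# ---------------------------------------------------------------------------


def _half_ellipse_points(
    center: tuple[float, float],
    semi_lateral: float,
    semi_axial: float,
    n_points: int,
) -> np.ndarray:
    """Ordered (axial, lateral) points on a downward half-ellipse.

    Runs from the (+lateral) basal end through the apex (maximal depth) to
    the (-lateral) basal end; both endpoints lie on the basal line
    (axial = center depth).
    """
    theta = np.linspace(0.0, np.pi, n_points)
    z0, x0 = center
    axial = z0 + semi_axial * np.sin(theta)
    lateral = x0 + semi_lateral * np.cos(theta)
    return np.column_stack([axial, lateral])


def elliptical_transmural_coord(
    center: tuple[float, float],
    inner_axes: tuple[float, float],
    outer_axes: tuple[float, float],
) -> Callable[[np.ndarray], np.ndarray]:
    """Analytic transmural coordinate for the elliptical-annulus phantom.

    Returns a callable mapping (N, 2) positions to t in [0, 1] where t = 0
    on the outer (epicardial) ellipse and t = 1 on the inner (endocardial)
    ellipse.  The coordinate is defined by the unique member of the family
    of ellipses linearly interpolating the two borders that passes through
    the point, found by bisection; it is smooth across the wall and reduces
    to the radial fraction for concentric circles.
    """
    a_i, b_i = float(inner_axes[0]), float(inner_axes[1])
    a_o, b_o = float(outer_axes[0]), float(outer_axes[1])
    z0, x0 = center

    def coord(points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        dz = p[:, 0] - z0
        dx = p[:, 1] - x0

        def level(t: np.ndarray) -> np.ndarray:
            a = a_o + t * (a_i - a_o)
            b = b_o + t * (b_i - b_o)
            return (dx / a) ** 2 + (dz / b) ** 2

        lo = np.zeros(p.shape[0])
        hi = np.ones(p.shape[0])
        # level(t) increases with t (axes shrink); root of level(t) = 1
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            inside = level(mid) < 1.0
            lo = np.where(inside, mid, lo)
            hi = np.where(inside, hi, mid)
        t = 0.5 * (lo + hi)
        t[level(np.zeros_like(t)) > 1.0] = 0.0  # outside the epicardium
        t[level(np.ones_like(t)) < 1.0] = 1.0  # inside the endocardium
        return t

    return coord


def make_lv_phantom(
    inner_axes: tuple[float, float],
    outer_axes: tuple[float, float],
    center: tuple[float, float] = (1.0, 0.0),
    n_border_points: int = 13,
    density_per_mm2: float = 350.0,
    amplitude_sd: float = 1.0,
    seed: int = 0,
    pad_mm: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, ScattererScene]:
    """Half-elliptical annular LV phantom, open at the base.

    Parameters
    ----------
    inner_axes, outer_axes : (semi_lateral_mm, semi_axial_mm)
        Semi-axes of the endocardial (inner) and epicardial (outer)
        half-ellipses; the axial semi-axis points toward the apex at
        maximal depth.  Inner axes must be strictly smaller componentwise.
    center : (axial_mm, lateral_mm)
        Basal middle point of both ellipses (the basal line depth).
    n_border_points : int
        Number of manually-picked-style key points per border, ordered
        basal-anterior end -> apex -> basal-posterior end.
    density_per_mm2 : float
        Scatterer density inside the myocardial wall.  The default gives
        about five scatterers per resolution cell of the default PSF
        (fully developed speckle).
    pad_mm : float
        Margin added around the outer ellipse to the scene region so the
        wall stays renderable under motion.

    Returns
    -------
    (endo_key_points, epi_key_points, scene)
        Key points as (n, 2) arrays of (axial_mm, lateral_mm); the scene
        contains scatterers only inside the wall.
    """
    a_i, b_i = float(inner_axes[0]), float(inner_axes[1])
    a_o, b_o = float(outer_axes[0]), float(outer_axes[1])
    if not (0 < a_i < a_o and 0 < b_i < b_o):
        raise ValueError("inner semi-axes must be positive and strictly smaller than outer")
    if n_border_points < 4:
        raise ValueError("need at least 4 key points per border")
    z0, x0 = center

    endo_kp = _half_ellipse_points(center, a_i, b_i, n_border_points)
    epi_kp = _half_ellipse_points(center, a_o, b_o, n_border_points)

    region = Region(
        axial_min=z0 - pad_mm,
        axial_max=z0 + b_o + pad_mm,
        lateral_min=x0 - a_o - pad_mm,
        lateral_max=x0 + a_o + pad_mm,
    )
    field = make_scatterer_field(region, density_per_mm2, amplitude_sd, seed)
    dz = field.positions[:, 0] - z0
    dx = field.positions[:, 1] - x0
    in_wall = (
        (dz >= 0.0)
        & ((dx / a_o) ** 2 + (dz / b_o) ** 2 <= 1.0)
        & ((dx / a_i) ** 2 + (dz / b_i) ** 2 >= 1.0)
    )
    scene = ScattererScene(
        positions=field.positions[in_wall],
        amplitudes=field.amplitudes[in_wall],
        region=region,
        seed=seed,
    )
    return endo_kp, epi_kp, scene
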