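"""RF frame container and sample/millimetre geometry.

Coordinate convention used throughout the package: the first array axis is
axial (depth, increasing away from the probe, i.e. "downward"), the second
axis is the lateral beam-line index.  Physical positions are in millimetres;
axial sample spacing is ``c / (2 * fs)`` (pulse-echo round trip), lateral
line spacing is the element pitch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def sample_spacing_mm(sound_speed: float, sampling_frequency: float) -> float:
    """Axial depth covered by one RF sample, in mm.

    Parameters
    ----------
    sound_speed : float
        Speed of sound in m/s (1540 m/s for soft tissue).
    sampling_frequency : float
        RF sampling frequency in Hz.
    """
    return sound_speed / (2.0 * sampling_frequency) * 1e3


@dataclass
class RFFrame:
    """One 2-D grid of RF echo samples plus acquisition metadata.

    Attributes
    ----------
    samples : ndarray, shape (n_axial, n_lines)
        Raw RF values (before envelope detection).
    center_frequency : float
        Probe center frequency in Hz.
    sampling_frequency : float
        Axial sampling frequency in Hz.
    pitch : float
        Lateral element pitch in mm.
    sound_speed : float
        Assumed speed of sound in m/s.
    axial_origin_mm, lateral_origin_mm : float
        Physical position of sample (0, 0), in mm.
    """

    samples: np.ndarray
    center_frequency: float
    sampling_frequency: float
    pitch: float
    sound_speed: float = 1540.0
    axial_origin_mm: float = 0.0
    lateral_origin_mm: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("RF samples must be a 2-D array (n_axial, n_lines)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")
        for name in ("center_frequency", "sampling_frequency", "pitch", "sound_speed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sampling_frequency < 4.0 * self.center_frequency:
            raise ValueError(
                "sampling_frequency must be at least 4x the center frequency"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.samples.shape

    @property
    def n_axial(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    @property
    def wavelength_samples(self) -> float:
        """RF samples per wavelength at the center frequency."""
        return self.sampling_frequency / self.center_frequency

    @property
    def sample_spacing_mm(self) -> float:
        return sample_spacing_mm(self.sound_speed, self.sampling_frequency)

    @property
    def axial_positions_mm(self) -> np.ndarray:
        """Depth of every axial sample, in mm."""
        return self.axial_origin_mm + np.arange(self.n_axial) * self.sample_spacing_mm

    @property
    def lateral_positions_mm(self) -> np.ndarray:
        """Lateral position of every beam line, in mm."""
        return self.lateral_origin_mm + np.arange(self.n_lines) * self.pitch

    def with_samples(self, samples: np.ndarray) -> "RFFrame":
        """Copy of this frame with the RF grid replaced, metadata kept."""
        return RFFrame(
            samples=np.asarray(samples, dtype=float),
            center_frequency=self.center_frequency,
            sampling_frequency=self.sampling_frequency,
            pitch=self.pitch,
            sound_speed=self.sound_speed,
            axial_origin_mm=self.axial_origin_mm,
            lateral_origin_mm=self.lateral_origin_mm,
        )

    def same_grid(self, other: "RFFrame") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.sampling_frequency, other.sampling_frequency)
            and np.isclose(self.center_frequency, other.center_frequency)
            and np.isclose(self.pitch, other.pitch)
            and np.isclose(self.sound_speed, other.sound_speed)
        )
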