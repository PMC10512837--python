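"""Layer-averaged cumulative displacement and the transmural motion index.

For a segment stratified into ``n`` transmural layers, the layer profile is
the mean cumulative axial displacement CD_A per layer (epicardium ->
endocardium).  The transmural motion index (TMI) of a segment is the slope
of the ordinary least-squares straight-line fit of the 10-layer profile
against the layer index n = 1..10, in mm per layer: it quantifies the
cross-wall motion gradient independently of the insonation angle.  TMI is
computed on signed CD_A by default (positive = downward); an
absolute-value mode is available and clearly labeled in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import CdaMap
from .segmentation import SegmentationResult


@dataclass
class LayerProfile:
    """Mean CD_A per transmural layer of one segment, in mm (epi -> endo)."""

    segment_name: str
    values: np.ndarray
    pixel_counts: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.pixel_counts = np.asarray(self.pixel_counts, dtype=int)
        if self.values.shape != self.pixel_counts.shape:
            raise ValueError("values and pixel_counts must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("layer profile values must be finite")

    @property
    def n_layers(self) -> int:
        return len(self.values)

    def weighted_mean(self) -> float:
        """Pixel-count-weighted mean across layers (= the segment mean)."""
        return float(np.average(self.values, weights=self.pixel_counts))


@dataclass
class TmiResult:
    """Fitted transmural motion gradient of one segment.

    ``tmi`` is in mm per layer index (10 layers across the wall); the
    intercept of the fit is kept for diagnostics.
    """

    segment_name: str
    tmi: float
    intercept: float
    n_layers: int
    absolute: bool = False


def layer_profile(cda_map: CdaMap | np.ndarray, layer_masks: list[np.ndarray], segment_name: str = "") -> LayerProfile:
    """Mean CD_A over each layer mask, epicardium -> endocardium."""
    values = cda_map.values if isinstance(cda_map, CdaMap) else np.asarray(cda_map, dtype=float)
    means = []
    counts = []
    for k, mask in enumerate(layer_masks):
        m = np.asarray(mask, dtype=bool)
        n = int(m.sum())
        if n == 0:
            raise ValueError(f"empty layer mask: segment {segment_name!r}, layer {k + 1}")
        means.append(float(values[m].mean()))
        counts.append(n)
    return LayerProfile(segment_name=segment_name, values=np.array(means), pixel_counts=np.array(counts))


def tmi(profile: LayerProfile, absolute: bool = False) -> TmiResult:
    """OLS straight-line fit of the 10-layer profile against layer index.

    The first derivative of a first-order polynomial fit is its slope;
    with layer index n = 1..10 as abscissa the slope has units of mm per
    layer.  ``absolute=True`` fits |CD_A| instead of signed CD_A.
    """
    if profile.n_layers != 10:
        raise ValueError("TMI is defined on the 10-layer profile")
    y = np.abs(profile.values) if absolute else profile.values
    if not np.all(np.isfinite(y)):
        raise ValueError("layer profile contains non-finite values")
    n = np.arange(1, 11, dtype=float)
    slope, intercept = np.polyfit(n, y, 1)
    return TmiResult(
        segment_name=profile.segment_name,
        tmi=float(slope),
        intercept=float(intercept),
        n_layers=10,
        absolute=absolute,
    )


def segment_mean_cda(cda_map: CdaMap | np.ndarray, segment_mask: np.ndarray) -> float:
    """Signed mean CD_A over a segment mask, in mm.

    Positive values are downward motion (away from the probe), negative
    values upward.
    """
    values = cda_map.values if isinstance(cda_map, CdaMap) else np.asarray(cda_map, dtype=float)
    mask = np.asarray(segment_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty segment mask")
    return float(values[mask].mean())


def transmural_table(
    cda_map: CdaMap,
    segmentation: SegmentationResult,
    absolute_tmi: bool = False,
) -> pd.DataFrame:
    """Per-segment summary: mean CD_A, TMI and the 10-layer profile.

    One row per segment with columns ``segment``, ``mean_cda_mm``,
    ``tmi_mm_per_layer``, ``intercept_mm`` and ``layer_1`` .. ``layer_10``
    (layer 1 = epicardial layer).
    """
    if 10 not in segmentation.layer_masks:
        raise ValueError("segmentation must carry 10-layer masks for TMI")
    rows = []
    for name, seg_mask in segmentation.segment_masks.items():
        prof = layer_profile(cda_map, segmentation.layer_masks[10][name], name)
        fit = tmi(prof, absolute=absolute_tmi)
        row = {
            "segment": name,
            "mean_cda_mm": segment_mean_cda(cda_map, seg_mask),
            "tmi_mm_per_layer": fit.tmi,
            "intercept_mm": fit.intercept,
        }
        row.update({f"layer_{k + 1}": prof.values[k] for k in range(10)})
        rows.append(row)
    return pd.DataFrame(rows)
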