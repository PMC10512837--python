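"""Displacement-quality metrics and overlap optimization.

Two ground-truth-free metrics grade a displacement map over a region of
interest (ROI, the myocardium):

* **SNR** — the signed mean of the displacement over the ROI divided by its
  sample standard deviation: a smoothness measure of the map, not an
  acoustic signal-to-noise ratio.
* **DCCCC** — the displacement-compensated cross-correlation coefficient:
  the post-frame is warped back by the estimated field, and the ZNCC
  between the pre-frame and the compensated post-frame over the ROI is
  reported.  Perfect compensation gives 1; the higher the DCCCC, the more
  accurate the displacement estimate.

``overlap_sweep`` reruns the tracker over a list of block-overlap values
and records both metrics per overlap; ``select_optimal_overlap`` picks the
smallest overlap on the DCCCC plateau after median-filtering out
single-point spikes, making the accuracy-versus-cost compromise explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates, median_filter

from .frames import RFFrame
from .tracking import CdaMap, TrackingConfig, densify_field, vncc_displacement


@dataclass
class QualityRecord:
    """Metrics for one overlap setting of the tracker."""

    overlap_percent: float
    snr: float
    dcccc: float
    roi_mean_displacement: float  # mm
    roi_sd_displacement: float  # mm
    roi_mean_pre: float
    roi_mean_comp: float
    flagged: bool = False
    message: str = ""


@dataclass
class QualityReport:
    """Ordered sweep records plus the selected overlap."""

    records: list[QualityRecord]
    selected_overlap: float | None = None

    def __post_init__(self) -> None:
        overlaps = [r.overlap_percent for r in self.records]
        if any(b <= a for a, b in zip(overlaps, overlaps[1:])):
            raise ValueError("records must be ordered by strictly increasing overlap")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "overlap_percent": r.overlap_percent,
                    "snr": r.snr,
                    "dcccc": r.dcccc,
                    "roi_mean_displacement_mm": r.roi_mean_displacement,
                    "roi_sd_displacement_mm": r.roi_sd_displacement,
                    "flagged": r.flagged,
                    "message": r.message,
                }
                for r in self.records
            ]
        )


def snr(cda_map: CdaMap | np.ndarray, roi_mask: np.ndarray) -> float:
    """Signed mean over sample standard deviation (ddof=1) of CD_A in the ROI.

    A uniform field is noiseless: zero deviation returns ``+inf`` rather
    than raising, since it arises routinely in noise-free synthetic tests.
    """
    values = cda_map.values if isinstance(cda_map, CdaMap) else np.asarray(cda_map, dtype=float)
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("ROI mask shape must match the displacement map")
    roi = values[mask]
    if roi.size < 2:
        raise ValueError("ROI must contain at least 2 pixels")
    sd = roi.std(ddof=1)
    if sd == 0.0:
        return float("inf")
    return float(roi.mean() / sd)


def compensate_frame(
    f_post: RFFrame,
    dense_d_axial: np.ndarray,
    dense_d_lateral: np.ndarray,
) -> tuple[RFFrame, np.ndarray]:
    """Warp the post-frame back by the estimated field (role F^PostC).

    Realized by inverse mapping with bilinear interpolation: the output at
    pixel (x, y) samples the post-frame at (x + D_A(x, y), y + D_L(x, y)),
    with the displacement fields given in RF samples / beam lines on the
    full pixel grid.  Exact for integer uniform shifts and, by bilinearity,
    for frames linear in each coordinate.  Pixels whose lookup leaves the
    frame are returned as 0 and marked invalid in the returned mask.
    """
    shape = f_post.shape
    da = np.asarray(dense_d_axial, dtype=float)
    dl = np.asarray(dense_d_lateral, dtype=float)
    if da.shape != shape or dl.shape != shape:
        raise ValueError("dense displacement fields must match the frame shape")
    zz, xx = np.meshgrid(
        np.arange(shape[0], dtype=float), np.arange(shape[1], dtype=float), indexing="ij"
    )
    src_z = zz + da
    src_x = xx + dl
    valid = (src_z >= 0) & (src_z <= shape[0] - 1) & (src_x >= 0) & (src_x <= shape[1] - 1)
    comp = map_coordinates(f_post.samples, [src_z, src_x], order=1, mode="constant", cval=0.0)
    comp[~valid] = 0.0
    return f_post.with_samples(comp), valid


def dcccc(
    f_pre: RFFrame,
    f_post_c: RFFrame,
    roi_mask: np.ndarray,
    valid_mask: np.ndarray | None = None,
) -> float:
    """Zero-normalized correlation of pre-frame and compensated post-frame.

    Computed over ROI ∩ valid (border pixels whose compensated lookup left
    the frame are excluded).  Raises when either frame has zero variance
    over the evaluation set — the coefficient is undefined there.
    """
    if f_pre.shape != f_post_c.shape:
        raise ValueError("frames must have equal shape")
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != f_pre.shape:
        raise ValueError("ROI mask shape must match the frames")
    if valid_mask is not None:
        mask = mask & np.asarray(valid_mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("ROI ∩ valid must contain at least 2 pixels")
    a = f_pre.samples[mask]
    b = f_post_c.samples[mask]
    a_zm = a - a.mean()
    b_zm = b - b.mean()
    denom = np.sqrt((a_zm**2).sum() * (b_zm**2).sum())
    if denom == 0.0:
        raise ValueError("DCCCC undefined: zero variance over the ROI")
    return float(np.clip((a_zm * b_zm).sum() / denom, -1.0, 1.0))


def overlap_sweep(
    f_pre: RFFrame,
    f_post: RFFrame,
    overlaps: Sequence[float],
    roi_mask: np.ndarray,
    config: TrackingConfig | None = None,
) -> QualityReport:
    """Track one frame pair at each overlap and grade the result.

    For every overlap value the tracker is rerun, the single-pair axial map
    is densified and converted to mm for SNR, and the post-frame is
    displacement-compensated for DCCCC.  Per-overlap failures are recorded
    as flagged records; the sweep never aborts.  The report's
    ``selected_overlap`` is filled by the plateau rule.
    """
    overlaps = sorted(float(v) for v in overlaps)
    if len(overlaps) < 2:
        raise ValueError("need at least 2 overlap values")
    if any(not 10.0 <= v <= 99.9 for v in overlaps):
        raise ValueError("overlaps must lie in [10, 99.9]")
    base = config if config is not None else TrackingConfig()
    mm_per_sample = f_pre.sample_spacing_mm

    records: list[QualityRecord] = []
    for ov in overlaps:
        cfg = replace(base, overlap_percent=ov)
        try:
            fld = vncc_displacement(f_pre, f_post, cfg)
            dense_a, dense_l = densify_field(fld, f_pre.shape)
            axial_mm = dense_a * mm_per_sample
            roi = np.asarray(roi_mask, dtype=bool)
            snr_val = snr(axial_mm, roi)
            comp, valid = compensate_frame(f_post, dense_a, dense_l)
            dcccc_val = dcccc(f_pre, comp, roi, valid)
            eval_mask = roi & valid
            records.append(
                QualityRecord(
                    overlap_percent=ov,
                    snr=snr_val,
                    dcccc=dcccc_val,
                    roi_mean_displacement=float(axial_mm[roi].mean()),
                    roi_sd_displacement=float(axial_mm[roi].std(ddof=1)),
                    roi_mean_pre=float(f_pre.samples[eval_mask].mean()),
                    roi_mean_comp=float(comp.samples[eval_mask].mean()),
                )
            )
        except (ValueError, FloatingPointError) as exc:
            records.append(
                QualityRecord(
                    overlap_percent=ov,
                    snr=float("nan"),
                    dcccc=float("nan"),
                    roi_mean_displacement=float("nan"),
                    roi_sd_displacement=float("nan"),
                    roi_mean_pre=float("nan"),
                    roi_mean_comp=float("nan"),
                    flagged=True,
                    message=str(exc),
                )
            )
    report = QualityReport(records=records)
    try:
        report.selected_overlap = select_optimal_overlap(report)
    except ValueError:
        report.selected_overlap = None
    return report


def select_optimal_overlap(
    report: QualityReport | Sequence[QualityRecord],
    plateau_tolerance: float = 0.005,
    outlier_filter_width: int = 3,
) -> float:
    """Smallest overlap on the median-filtered DCCCC plateau.

    The DCCCC-versus-overlap curve is median-filtered (width
    ``outlier_filter_width``, nearest-edge handling) to suppress
    single-point spikes, then the smallest overlap whose filtered DCCCC
    reaches ``(1 - plateau_tolerance)`` of the filtered maximum is
    returned: higher overlaps buy no accuracy, only computational cost.
    Deterministic and invariant to record order.
    """
    records = report.records if isinstance(report, QualityReport) else list(report)
    valid = sorted(
        (r for r in records if not r.flagged and np.isfinite(r.dcccc)),
        key=lambda r: r.overlap_percent,
    )
    if not valid:
        raise ValueError("no valid records in the quality report")
    curve = np.array([r.dcccc for r in valid])
    filtered = median_filter(curve, size=min(outlier_filter_width, curve.size), mode="nearest")
    threshold = (1.0 - plateau_tolerance) * filtered.max()
    for r, v in zip(valid, filtered):
        if v >= threshold:
            return r.overlap_percent
    return valid[-1].overlap_percent  # unreachable: max always passes
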