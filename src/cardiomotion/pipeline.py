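"""End-to-end orchestration: simulate -> track -> sweep -> segment -> TMI.

A run is described by a single ``RunConfig`` (JSON-serializable); every
stage persists its artifact to the output directory so stages can be
re-run individually, and the effective configuration, seed and package
versions are recorded with the report.  Identical configuration and seed
produce bit-identical output tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cmio
from .frames import RFFrame
from .quality import QualityReport, overlap_sweep
from .segmentation import PixelGrid, SegmentationResult, segment_myocardium
from .synthrf import (
    GroundTruth,
    LinearAxialGradientMotion,
    PsfParams,
    TransmuralGradientMotion,
    UniformMotion,
    elliptical_transmural_coord,
    generate_sequence,
    make_lv_phantom,
)
from .tracking import CdaMap, TrackingConfig, accumulate_displacement, vncc_displacement
from .transmural import transmural_table

logger = logging.getLogger("cardiomotion")


@dataclass
class RunConfig:
    """Full description of one simulated subject run.

    The phantom defaults describe a rat-heart-scale PLAX wall (inner
    half-ellipse 4 x 6 mm, outer 6 x 8 mm, ~2 mm wall) imaged by a 21 MHz
    probe.  For the transmural motion kind, ``gradient_mm_per_layer`` is
    the target endo-epi cumulative motion difference expressed per
    ten-layer index, i.e. the TMI the analysis should recover.
    """

    outdir: str = "run"
    label: str = "run"
    seed: int = 0
    # --- simulation ---
    motion_kind: str = "transmural_gradient"  # uniform | linear_axial_gradient | transmural_gradient
    n_frames: int = 9
    inner_axes: tuple[float, float] = (4.0, 6.0)  # (semi_lateral, semi_axial) mm
    outer_axes: tuple[float, float] = (6.0, 8.0)
    center: tuple[float, float] = (1.0, 0.0)  # (axial, lateral) mm
    density_per_mm2: float = 350.0
    n_border_points: int = 13
    axial_mm_per_frame: float = 0.01  # uniform shift / epicardial base motion
    lateral_mm_per_frame: float = 0.0
    gradient_mm_per_layer: float = 0.02  # transmural kind: cumulative TMI target
    strain_per_frame: float = 0.002  # linear_axial_gradient slope (mm per mm depth)
    # --- tracking ---
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    sweep_overlaps: tuple[float, ...] | None = None  # when set, pick overlap by DCCCC
    # --- segmentation ---
    border_resample_points: int = 400
    layer_counts: tuple[int, ...] = (3, 10)
    # --- reporting ---
    make_figures: bool = False

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "tracking" in d and isinstance(d["tracking"], dict):
            d["tracking"] = TrackingConfig(**d["tracking"])
        for key in ("inner_axes", "outer_axes", "center", "layer_counts", "sweep_overlaps"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All tables of a pipeline run plus provenance."""

    config: RunConfig
    segment_table: pd.DataFrame  # per segment: mean CD_A, TMI, 10-layer profile
    long_table: pd.DataFrame  # long format for group comparison
    quality: QualityReport | None
    cda: CdaMap
    segmentation: SegmentationResult
    frames: list[RFFrame]
    truth: GroundTruth | None
    paths: dict[str, str]
    provenance: dict


def _build_motion(config: RunConfig):
    k = config.motion_kind
    if k == "uniform":
        return UniformMotion(config.axial_mm_per_frame, config.lateral_mm_per_frame, config.n_frames)
    if k == "linear_axial_gradient":
        return LinearAxialGradientMotion(
            slope_per_frame=config.strain_per_frame,
            reference_depth_mm=config.center[0],
            n_frames=config.n_frames,
            offset_mm_per_frame=config.axial_mm_per_frame,
        )
    if k == "transmural_gradient":
        coord = elliptical_transmural_coord(config.center, config.inner_axes, config.outer_axes)
        total_endo_extra = 10.0 * config.gradient_mm_per_layer
        per_pair_extra = total_endo_extra / (config.n_frames - 1)
        return TransmuralGradientMotion(
            coord_fn=coord,
            epi_mm_per_frame=config.axial_mm_per_frame,
            endo_mm_per_frame=config.axial_mm_per_frame + per_pair_extra,
            n_frames=config.n_frames,
        )
    raise ValueError(f"unknown motion kind {k!r}")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages and persist every intermediate artifact.

    Stage order: simulate (phantom + RF sequence with ground truth),
    optional overlap sweep (DCCCC-based selection on the middle frame
    pair), tracking + Eulerian cumulation into CD_A, five-step
    segmentation from the phantom key points, per-segment layer profiles
    and TMI.  A stage failure aborts with the stage name; earlier
    artifacts remain on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    psf = PsfParams()

    # --- stage 1: simulate -------------------------------------------------
    logger.info("stage simulate: phantom + %d frames", config.n_frames)
    total_motion = abs(config.axial_mm_per_frame) * (config.n_frames - 1) + 10.0 * abs(
        config.gradient_mm_per_layer
    )
    endo_kp, epi_kp, scene = make_lv_phantom(
        inner_axes=config.inner_axes,
        outer_axes=config.outer_axes,
        center=config.center,
        n_border_points=config.n_border_points,
        density_per_mm2=config.density_per_mm2,
        seed=config.seed,
        pad_mm=0.8 + total_motion,
    )
    motion = _build_motion(config)
    frames, truth = generate_sequence(scene, psf, motion)
    seq_path = outdir / "sequence.h5"
    cmio.write_sequence(seq_path, frames, seed=config.seed)
    kp_path = outdir / "borders.csv"
    cmio.write_keypoints_csv(kp_path, endo_kp, epi_kp)
    paths["sequence"] = str(seq_path)
    paths["borders"] = str(kp_path)

    # --- stage 2: segmentation (needed as ROI for the sweep) ---------------
    logger.info("stage segment: %d border points, layers %s", config.border_resample_points, config.layer_counts)
    grid = PixelGrid.from_frame(frames[0])
    segmentation = segment_myocardium(
        endo_kp,
        epi_kp,
        grid,
        n_points=config.border_resample_points,
        layer_counts=config.layer_counts,
    )
    seg_path = outdir / "segmentation.h5"
    cmio.write_segmentation(seg_path, segmentation)
    paths["segmentation"] = str(seg_path)

    # --- stage 3: optional overlap sweep -----------------------------------
    tracking_config = config.tracking
    quality: QualityReport | None = None
    if config.sweep_overlaps:
        mid = len(frames) // 2
        logger.info("stage sweep: overlaps %s on pair (%d, %d)", config.sweep_overlaps, mid - 1, mid)
        quality = overlap_sweep(
            frames[mid - 1],
            frames[mid],
            config.sweep_overlaps,
            segmentation.myocardium_mask,
            tracking_config,
        )
        sweep_path = outdir / "sweep.csv"
        quality.to_dataframe().to_csv(sweep_path, index=False)
        paths["sweep"] = str(sweep_path)
        if quality.selected_overlap is not None:
            tracking_config = replace(tracking_config, overlap_percent=quality.selected_overlap)

    # --- stage 4: tracking and cumulation ----------------------------------
    logger.info("stage track: overlap %.1f%%", tracking_config.overlap_percent)
    mm_per_sample = frames[0].sample_spacing_mm
    for k in range(motion.n_pairs):
        inc = motion.incremental(k, scene.positions)
        max_ax = np.abs(inc[:, 0]).max() / mm_per_sample
        max_lat = np.abs(inc[:, 1]).max() / frames[0].pitch
        if max_ax > tracking_config.search_margin_axial or max_lat > tracking_config.search_margin_lateral:
            raise ValueError(
                f"stage track: per-frame motion at pair {k} "
                f"({max_ax:.1f} samples / {max_lat:.1f} lines) exceeds the search margins "
                f"(±{tracking_config.search_margin_axial} / ±{tracking_config.search_margin_lateral}); "
                "increase n_frames or the margins"
            )
    fields = [
        vncc_displacement(frames[k], frames[k + 1], tracking_config)
        for k in range(len(frames) - 1)
    ]
    cda = accumulate_displacement(fields, frames[0].shape, mm_per_sample)
    disp_path = outdir / "displacement.h5"
    cmio.write_displacement(disp_path, fields, cda)
    paths["displacement"] = str(disp_path)

    # --- stage 5: layer profiles and TMI -----------------------------------
    logger.info("stage tmi")
    segment_table = transmural_table(cda, segmentation)
    seg_csv = outdir / "segments.csv"
    segment_table.to_csv(seg_csv, index=False)
    paths["segments"] = str(seg_csv)

    long_rows = []
    for _, row in segment_table.iterrows():
        for metric, value in (("mean_cda_mm", row["mean_cda_mm"]), ("tmi_mm_per_layer", row["tmi_mm_per_layer"])):
            long_rows.append(
                {
                    "group": config.label,
                    "subject": config.seed,
                    "segment": row["segment"],
                    "metric": metric,
                    "value": value,
                }
            )
    long_table = pd.DataFrame(long_rows)
    long_csv = outdir / "results_long.csv"
    long_table.to_csv(long_csv, index=False)
    paths["results_long"] = str(long_csv)

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
        "selected_overlap": None if quality is None else quality.selected_overlap,
        "effective_overlap": tracking_config.overlap_percent,
    }
    (outdir / "report.json").write_text(
        json.dumps({"provenance": provenance, "config": json.loads(config.to_json())}, indent=2, sort_keys=True)
    )
    paths["report"] = str(outdir / "report.json")

    report = RunReport(
        config=config,
        segment_table=segment_table,
        long_table=long_table,
        quality=quality,
        cda=cda,
        segmentation=segmentation,
        frames=frames,
        truth=truth,
        paths=paths,
        provenance=provenance,
    )
    if config.make_figures:
        from .viz import render_figures

        figure_paths = render_figures(report, outdir)
        paths.update(figure_paths)
    return report


def _versions() -> dict[str, str]:
    import h5py
    import matplotlib
    import scipy
    import shapely

    from . import __version__

    return {
        "cardiomotion": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "h5py": h5py.__version__,
        "shapely": shapely.__version__,
        "matplotlib": matplotlib.__version__,
    }
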