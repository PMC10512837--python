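"""HDF5 and CSV persistence for sequences, fields, masks and key points.

Sequence container schema (one HDF5 file):

* ``/frames``        — float array (n_frames, n_axial, n_lines)
* ``/truth_axial``   — optional (n_frames - 1, n_axial, n_lines), mm
* ``/truth_lateral`` — optional, same shape, mm
* attrs: ``f0``, ``fs``, ``pitch``, ``c``, ``seed``, ``axial_origin_mm``,
  ``lateral_origin_mm``, optional ``frame_range`` (systolic interval).

Border key points travel as CSV with columns
``border`` (endo|epi), ``index``, ``axial_mm``, ``lateral_mm``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .frames import RFFrame
from .tracking import CdaMap, DisplacementField
from .segmentation import SegmentationResult


def write_sequence(
    path: str | Path,
    frames: Sequence[RFFrame],
    truth_axial: np.ndarray | None = None,
    truth_lateral: np.ndarray | None = None,
    seed: int | None = None,
    frame_range: tuple[int, int] | None = None,
) -> None:
    if len(frames) == 0:
        raise ValueError("no frames to write")
    f0 = frames[0]
    stack = np.stack([f.samples for f in frames])
    with h5py.File(path, "w") as h5:
        h5.create_dataset("frames", data=stack)
        if truth_axial is not None:
            h5.create_dataset("truth_axial", data=np.asarray(truth_axial))
        if truth_lateral is not None:
            h5.create_dataset("truth_lateral", data=np.asarray(truth_lateral))
        h5.attrs["f0"] = f0.center_frequency
        h5.attrs["fs"] = f0.sampling_frequency
        h5.attrs["pitch"] = f0.pitch
        h5.attrs["c"] = f0.sound_speed
        h5.attrs["axial_origin_mm"] = f0.axial_origin_mm
        h5.attrs["lateral_origin_mm"] = f0.lateral_origin_mm
        if seed is not None:
            h5.attrs["seed"] = int(seed)
        if frame_range is not None:
            h5.attrs["frame_range"] = list(frame_range)


def read_sequence(path: str | Path) -> tuple[list[RFFrame], np.ndarray | None, np.ndarray | None, dict]:
    with h5py.File(path, "r") as h5:
        stack = h5["frames"][()]
        attrs = dict(h5.attrs)
        truth_axial = h5["truth_axial"][()] if "truth_axial" in h5 else None
        truth_lateral = h5["truth_lateral"][()] if "truth_lateral" in h5 else None
    frames = [
        RFFrame(
            samples=s,
            center_frequency=float(attrs["f0"]),
            sampling_frequency=float(attrs["fs"]),
            pitch=float(attrs["pitch"]),
            sound_speed=float(attrs["c"]),
            axial_origin_mm=float(attrs.get("axial_origin_mm", 0.0)),
            lateral_origin_mm=float(attrs.get("lateral_origin_mm", 0.0)),
        )
        for s in stack
    ]
    return frames, truth_axial, truth_lateral, attrs


def write_displacement(
    path: str | Path,
    fields: Sequence[DisplacementField],
    cda: CdaMap | None = None,
) -> None:
    with h5py.File(path, "w") as h5:
        for k, f in enumerate(fields):
            g = h5.create_group(f"fields/{k}")
            g.create_dataset("node_axial", data=f.node_axial)
            g.create_dataset("node_lateral", data=f.node_lateral)
            g.create_dataset("d_axial", data=f.d_axial)
            g.create_dataset("d_lateral", data=f.d_lateral)
            g.create_dataset("peak_ncc", data=f.peak_ncc)
            g.create_dataset("flags", data=f.flags)
            g.attrs["search_margin_axial"] = f.search_margin_axial
            g.attrs["search_margin_lateral"] = f.search_margin_lateral
        if cda is not None:
            d = h5.create_dataset("cda", data=cda.values)
            d.attrs["mm_per_sample"] = cda.mm_per_sample


def read_displacement(path: str | Path) -> tuple[list[DisplacementField], CdaMap | None]:
    fields: list[DisplacementField] = []
    cda = None
    with h5py.File(path, "r") as h5:
        if "fields" in h5:
            for k in sorted(h5["fields"], key=int):
                g = h5[f"fields/{k}"]
                fields.append(
                    DisplacementField(
                        node_axial=g["node_axial"][()],
                        node_lateral=g["node_lateral"][()],
                        d_axial=g["d_axial"][()],
                        d_lateral=g["d_lateral"][()],
                        peak_ncc=g["peak_ncc"][()],
                        flags=g["flags"][()],
                        search_margin_axial=int(g.attrs["search_margin_axial"]),
                        search_margin_lateral=int(g.attrs["search_margin_lateral"]),
                    )
                )
        if "cda" in h5:
            cda = CdaMap(values=h5["cda"][()], mm_per_sample=float(h5["cda"].attrs["mm_per_sample"]))
    return fields, cda


def write_keypoints_csv(path: str | Path, endo: np.ndarray, epi: np.ndarray) -> None:
    rows = []
    for border, pts in (("endo", endo), ("epi", epi)):
        for i, (z, x) in enumerate(np.atleast_2d(pts)):
            rows.append({"border": border, "index": i, "axial_mm": z, "lateral_mm": x})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_keypoints_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    out = {}
    for border in ("endo", "epi"):
        sub = df[df["border"] == border].sort_values("index")
        if sub.empty:
            raise ValueError(f"no {border!r} key points in {path}")
        out[border] = sub[["axial_mm", "lateral_mm"]].to_numpy()
    return out["endo"], out["epi"]


def write_segmentation(path: str | Path, result: SegmentationResult) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("myocardium", data=result.myocardium_mask)
        h5.create_dataset("grid/axial_positions_mm", data=result.grid.axial_positions_mm)
        h5.create_dataset("grid/lateral_positions_mm", data=result.grid.lateral_positions_mm)
        for name, mask in result.segment_masks.items():
            h5.create_dataset(f"segments/{name}", data=mask)
        for n, per_segment in result.layer_masks.items():
            for name, masks in per_segment.items():
                for k, mask in enumerate(masks):
                    h5.create_dataset(f"layers/{n}/{name}/{k}", data=mask)
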