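# cardiomotion

Segmental and transmural myocardial motion estimation from ultrasound
radio-frequency (RF) data.

`cardiomotion` is aimed at quantitative-ultrasound and cardiac-mechanics
researchers who want to measure how much, and how uniformly across the wall,
the left-ventricular (LV) myocardium moves during systole — from raw RF
frame sequences rather than B-mode video.  It provides:

* **VNCC speckle tracking** — vectorized zero-normalized cross-correlation
  (ZNCC) block matching between successive RF frames.  For each node of a
  regular grid, a matching block (default 4 wavelengths × 7 element pitches)
  is compared against all candidate blocks in a search region of the next
  frame; the lag of the correlation maximum, refined to sub-sample
  precision by a parabolic fit, is the displacement estimate.  Incremental
  axial displacements are accumulated on a fixed pixel grid into the
  cumulative axial displacement map CD_A (mm; positive = away from the
  probe).
* **Displacement-quality metrics** — SNR = D̄_ROI / σ_ROI (mean over
  standard deviation of displacement in the myocardial region of
  interest), and the displacement-compensated cross-correlation
  coefficient DCCCC: the ZNCC between the pre-frame F^Pre and the
  post-frame warped back by the estimated field,

  DCCCC = Σ (F^Pre − f̄)(F^PostC − ḡ) / √( Σ(F^Pre − f̄)² Σ(F^PostC − ḡ)² ),

  a ground-truth-free accuracy proxy used to pick the block-overlap
  parameter: `overlap_sweep` re-runs the tracker over candidate overlaps
  and `select_optimal_overlap` returns the smallest overlap on the
  median-filtered DCCCC plateau.
* **Semiautomatic LV segmentation** — from manually picked endocardial and
  epicardial key points (parasternal long-axis view): spline border
  interpolation, basal-middle-point and apical-point landmarks, division of
  each border into three equal-arc sections, six wall segments (A-SEP,
  M-ANT-SEP, B-ANT-SEP, A-LAT, M-INF-LAT, B-INF-LAT), and stratification of
  every segment into 3 or 10 equal-width transmural layers
  (epicardium → endocardium).
* **Transmural motion index (TMI)** — the slope of the ordinary
  least-squares line fitted to the mean CD_A of the 10 layers against the
  layer index, in mm/layer: a signed, angle-independent summary of the
  cross-wall motion gradient.
* **Group statistics** — exact-enumeration Mann–Whitney U tests (for the
  n ≈ 7 per group regime typical of small-animal studies) on segmental
  CD_A and TMI tables.
* **A synthetic RF simulator** — point-scatterer speckle with a separable
  Gaussian-envelope PSF (21 MHz-like probe), analytic motion models
  (uniform, depth-linear, transmural-gradient) and a half-elliptical
  annular LV phantom, so the whole chain is validated against exactly
  known ground truth.

## Worked example

Simulate a beating-wall phantom whose endocardium moves 0.2 mm further
than its epicardium over eight frame pairs (an imposed transmural gradient
of 0.02 mm/layer), track it, segment it and fit the TMI:

```python
from cardiomotion.pipeline import RunConfig, run_pipeline

config = RunConfig(
    outdir="demo",
    seed=7,
    motion_kind="transmural_gradient",
    gradient_mm_per_layer=0.02,   # imposed endo-epi gradient, mm per layer
    n_frames=9,
)
report = run_pipeline(config)
print(report.segment_table[["segment", "mean_cda_mm", "tmi_mm_per_layer"]]
      .round(4).to_string(index=False))
```

```
  segment  mean_cda_mm  tmi_mm_per_layer
B-ANT-SEP       0.1737            0.0181
M-ANT-SEP       0.1775            0.0193
    A-SEP       0.1818            0.0203
    A-LAT       0.1809            0.0204
M-INF-LAT       0.1783            0.0196
B-INF-LAT       0.1713            0.0162
```

Every segment moved ~0.17–0.18 mm downward on average (the imposed bulk
translation plus half the gradient), and the fitted TMI recovers the
imposed 0.02 mm/layer within ~10–20 % per segment — the residual is the
finite block-size and fixed-grid accumulation bias discussed in
`docs/methods.md`.  The same stages are scriptable from the shell:

```bash
cardiomotion simulate --motion transmural --frames 9 --seed 7 --out seq.h5
cardiomotion track --in seq.h5 --overlap 80 --out disp.h5
cardiomotion segment --keypoints seq.borders.csv --grid-from seq.h5 --out seg.h5
cardiomotion tmi --cda disp.h5 --seg seg.h5 --out tmi.csv
cardiomotion compare --table results.csv --pairs Sham1:MI1 --alpha 0.05
```

## Layout

```
src/cardiomotion/
  synthrf.py       # scatterer scenes, PSF rendering, motion models, LV phantom
  tracking.py      # ZNCC surfaces, VNCC block matching, CD_A accumulation
  quality.py       # SNR, displacement compensation, DCCCC, overlap selection
  segmentation.py  # borders, landmarks, 6 segments, 3/10 transmural layers
  transmural.py    # layer profiles, TMI, segment means
  group_stats.py   # exact Mann-Whitney U, comparison reports
  pipeline.py      # simulate -> track -> sweep -> segment -> TMI orchestration
  cli.py           # `cardiomotion` command-line interface
  io.py, viz.py    # HDF5/CSV persistence, figure rendering
```

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
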