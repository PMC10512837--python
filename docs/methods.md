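# Methods

This note documents the models, numerical choices and limitations behind
`cardiomotion`.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## RF speckle model

Frames are synthesized with the standard linear scatterer-convolution
model: sub-resolution point scatterers with zero-mean Gaussian
reflectivities are convolved with a separable point-spread function — a
Gaussian axial pulse envelope modulated by a cosine carrier at the probe
center frequency, and a Gaussian lateral beam profile.  There is no
attenuation, no nonlinear propagation, no reverberation and no electronic
noise; this is sufficient to exercise correlation-based tracking, which
only relies on speckle being quasi-stationary under small motion.

Defaults emulate a high-frequency small-animal probe:

| parameter | default | rationale |
|---|---|---|
| center frequency f₀ | 21 MHz | high-frequency small-animal imaging |
| sampling frequency fs | 4 × f₀ = 84 MHz | twice-Nyquist margin; RF wavelength = 4 samples |
| sound speed c | 1540 m/s | standard soft-tissue value; fixes the mm↔sample conversion c/(2fs) ≈ 9.17 µm |
| axial pulse sigma | 0.5 / f₀ s | ≈ 60–75 % fractional bandwidth. A longer pulse raises the RF-correlation side-lobes one carrier wavelength from the true lag and makes block matching peak-hop pervasively; sub-50 % bandwidth is also unrealistic for modern high-frequency arrays |
| lateral beam sigma | 0.15 mm | a couple of element pitches |
| element pitch | 0.09 mm | high-frequency linear-array scale |
| scatterer density | 350 /mm² | ≈ 5 scatterers per resolution cell → fully developed speckle |

Motion is imposed by moving the scatterers, never by resampling frames, so
sub-sample displacements are exact.  Each frame is rendered from the *base*
scene displaced by the cumulative field evaluated at the original
(material) positions: every scatterer carries the motion determined by its
own starting point, the incremental fields telescope exactly into the
cumulative field, and the imposed endocardium–epicardium difference of the
transmural model equals its nominal value regardless of wall compression.

The LV phantom is a half-elliptical annulus open at the base (apex at
maximal depth), mimicking the parasternal long-axis topology; its analytic
transmural coordinate interpolates between the two border ellipses and
reduces to the radial fraction for concentric circles.

### What the simulator does not emulate

Real myocardium adds: electronic and acoustic noise, attenuation and
depth-dependent gain, anisotropic fiber-dependent backscatter, out-of-plane
motion, valve/blood clutter, and surrounding moving tissue instead of
mathematically silent regions.  Tests passing on the phantom therefore
demonstrate the *algorithmic* correctness and the attainable accuracy under
clean speckle, not in vivo performance.

## Block matching (VNCC)

Matching blocks are 4 RF wavelengths × 7 pitches by default; the node-grid
stride is `max(1, round(block·(1 − overlap/100)))` per axis, so 99.9 %
overlap gives a one-sample stride.  The search margin defaults to ±8
samples axially and ±2 lines laterally and must exceed the per-frame
motion.  Correlation is computed on raw RF (not the envelope).  Ties at
the correlation maximum are broken deterministically: smallest lag
magnitude, then smallest |axial|, then smallest |lateral|, then the
non-negative sign.  The vectorized implementation is node-for-node
identical to a naive per-block loop; this is asserted against a
brute-force triple-loop oracle.

Three estimator refinements are applied after the argmax (each can be
disabled):

* **Parabolic sub-sample refinement** — a 1-D parabola through the peak
  and its two neighbors per axis; the vertex offset is clipped to ±0.5 and
  set to 0 for degenerate (tied) neighbors.  On identity frames the
  asymmetry of speckle autocorrelation leaves a small (< 0.25 sample)
  refinement residue; integer-lag recovery statements therefore refer to
  the unrefined path.
* **Median post-filter (3×3 nodes)** — raw-RF correlation carries carrier
  side-lobes one wavelength from the true lag; near half-sample offsets
  speckle fluctuation occasionally lets a side-lobe win.  These isolated
  one-wavelength outliers (a few percent of nodes at the worst-case
  half-sample offset) are removed by a small spatial median, the standard
  remedy in elastography.
* **Echo-free block gate** — a node whose pre-frame block RMS is below
  10 % (−20 dB) of the strongest block carries no displacement
  information; its estimate is replaced by the nearest informative node.
  The threshold is set to exceed the point-spread leakage level adjacent
  to bright boundaries: leakage tails are smooth and correlate deceptively
  well at near-zero lag, which otherwise biases the field near the
  receding wall edge.  For acquisitions with a genuinely large tissue
  dynamic range this threshold should be lowered.

Incremental fields are bilinearly interpolated from the node grid to the
pixel grid (constant extension beyond the node hull), converted to mm via
c/(2fs), and summed at fixed pixel coordinates (Eulerian cumulation) into
CD_A.  Eulerian summation is exact for uniform motion and first-order
accurate otherwise; for a cumulative motion that is large relative to the
spatial scale of the field it mixes material trajectories, which is one of
the two known bias sources in gradient recovery (below).  A Lagrangian
(material-tracking) mode is deliberately out of scope.

## Quality metrics and overlap selection

SNR uses the *signed* mean over the sample (N−1) standard deviation; a
uniform field returns +∞ rather than raising, since it arises in
noise-free synthetic tests.  Displacement compensation realizes the
warped post-frame by inverse mapping with bilinear interpolation (forward
scattering of samples would leave holes); pixels whose lookup leaves the
frame are excluded from DCCCC via a validity mask.  The overlap selector
median-filters the DCCCC-versus-overlap curve (width 3, nearest-edge) to
suppress single-point spikes and returns the smallest overlap reaching
99.5 % of the filtered maximum — making the accuracy-versus-cost
compromise explicit and deterministic.

## Segmentation

Borders are interpolated by cubic splines parameterized by chord length
and resampled uniformly in arc length (so "equal-length division" is
well-defined); endpoints are preserved exactly.  The basal middle point is
the midpoint of the two basal endpoints; the apex is the border point
farthest from it (ties flagged, smallest index wins).  Each border is
split at the apex and each sub-border into three equal-arc sections with
linearly interpolated cut points; corresponding endo/epi sections close
into six segment contours.  Pixel centers are assigned by
point-in-polygon in a fixed documented order; the rare pixels on numeric
gaps between contours go to the nearest contour, so the six masks tile
the myocardium mask exactly (asserted pixel-exactly in tests).

The transmural coordinate of a pixel is the distance-to-border ratio
t = d_epi / (d_epi + d_endo) (t = 0 on the epicardium), exact for
concentric circles and well-behaved for ellipses; the layer index is
⌊t·n⌋ clamped, n ∈ {3, 10}, ordered epicardium → endocardium.  On the
default elliptical phantom, layer means of the analytically imposed field
reproduce the imposed gradient to ≤ 0.1 % — segmentation contributes
negligibly to the recovery error.

## TMI

The ten layer means are fitted by ordinary least squares against the layer
index n = 1…10; the TMI is the fitted slope in mm/layer ("first derivative
of the first-order polynomial").  Ten points cannot be meaningfully
*interpolated* by a line, so a fit is the only sensible reading.  The
abscissa is the dimensionless layer index, not physical depth, keeping the
index comparable across walls of different thickness.  TMI is computed on
signed CD_A by default; an absolute-value mode exists and is labeled in
the result object.

### Known bias of end-to-end gradient recovery

Full-chain recovery (simulate → track → segment → fit) underestimates
imposed gradients by roughly 5–15 % (largest at 0.04 mm/layer, the
strongest motion).  Two mechanisms, both measured during development and
visible in the acceptance quantities: (i) the finite block (0.15 mm × 0.63
mm) averages motion across the wall and, at the wall borders, over partly
echo-free content, compressing the outermost layer means; (ii) Eulerian
cumulation over a sequence whose total motion (up to 0.4 mm) is a
substantial fraction of the wall thickness mixes material trajectories.
Both effects shrink with milder motion and thicker walls and are inherent
to fixed-grid block-matching pipelines of this design.

## Group statistics

The Mann–Whitney U statistic counts pairs with a > b plus half the ties.
For combined samples up to 16 the p-value is exact: all C(n_a+n_b, n_a)
labelings are enumerated (midranks handle ties); the two-sided p is the
probability of a U at least as far from n_a·n_b/2 as observed.  This is
the regime that matters for n = 7 per group, where the normal
approximation is poor; larger samples fall back to scipy's tie-corrected
asymptotic test.  No multiplicity correction is applied by default; a
Benjamini–Hochberg option exists but defaults off.  Because exact
p-values are discrete, the attained level at n = 7 vs 7 sits slightly
below the nominal α = 0.05 (the acceptance script measures ≈ 3–5 %
rejections under the null).

## Pipeline, determinism and problem sizes

A run is a single JSON-serializable `RunConfig`; every stage persists its
artifact (HDF5/CSV) so stages can be re-run individually, and provenance
(config hash, seed, versions) is stored with the report.  All randomness
flows from the single seed through `numpy.random.default_rng`; identical
config and seed give bit-identical CSV tables (asserted byte-wise).

Default study sizes were chosen once to keep the physics honest and the
suite fast: phantom wall 2 mm (inner half-ellipse 4 × 6 mm, outer
6 × 8 mm, rat-heart scale), nine frames per sequence so that the largest
imposed gradient stays below ~6 samples/frame (within the ±8-sample search
margin; the pipeline validates this and aborts otherwise), and 350
scatterers/mm².  Smaller phantoms (1.5 mm wall, 3–5 frames) are used in
unit tests purely to exercise the stages.

## Limitations

* Lateral displacement is estimated but carries no accuracy claims (RF
  resolution is far coarser laterally); all motion indices use the axial
  component.
* Eulerian cumulation and frame-0 segmentation masks bias layer profiles
  when cumulative motion approaches the layer thickness (see above).
* The segmentation is semiautomatic: border key points must be supplied
  (in vivo: picked by a sonographer; in silico: generated by the phantom).
* The six-segment naming assumes the default probe orientation; the
  mapping is configurable.
* No ECG gating: synthetic sequences carry an explicit frame range
  instead of a physiological trigger.
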