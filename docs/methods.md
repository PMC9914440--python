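# Methods

`memdyn` quantifies the lateral mobility and nanoscale clustering of membrane
proteins from three kinds of microscopy data: quantum-dot single-particle
tracking (QD-SPT) movies, STORM localization streams, and widefield
fluorescence images. No raw data ships with the package; a synthetic-data
module generates all three streams with known ground truth so every stage is
verifiable end to end.

## Single-particle trajectories

### Motion models

Particles move in 2D with frame interval τ (default 30 ms, 1200 frames per
acquisition):

* **free_brownian** — per-axis increments are i.i.d. N(0, 2·D·Δt).
* **confined_disc** — Brownian steps reflected at the boundary of a disc of
  radius R (hard confinement).
* **confined_ou** — Ornstein-Uhlenbeck mean reversion toward the disc
  center, advanced with the exact discrete update
  x(t+Δt) = c + (x(t)−c)·e^(−kΔt) + N(0, s²·(1−e^(−2kΔt))),
  with k = D/s² chosen so the stationary per-axis sd is s = R/2. The OU
  model is the default confined model because its plateau is analytic
  (per-axis stationary variance s²), which makes recovery testable.

Localization noise of sd σ_loc (default 25 nm, the QD pointing accuracy) is
added independently per visible frame after the motion is generated — the
standard SMLM error model, and the reason the MSD fit intercept is
interpretable as 4σ_loc². Blinking is a two-state Markov chain on visibility
(P(on→off), P(off→on) per frame); the true blinking statistics of QDs are
unknown here, so the defaults keep the dot visible and the probabilities are
free parameters. In multi-particle scenes, compartment discs can override
the local motion parameters; confined overrides act over a capture
neighborhood of 3 disc radii, because a pull that vanishes exactly at the
disc edge would leak particles into the free regime on every boundary
excursion rather than emulate stable trapping.

Lengths are µm throughout the SPT code and nm throughout the STORM code;
CSV tables are always nm (`x_nm`, `y_nm`) so both share one dialect, and the
converters are explicit.

### Linking and crossing removal

The upstream tracking software of a real rig is replaced by deterministic
frame-to-frame optimal assignment: per frame pair, the Hungarian algorithm
minimizes total squared displacement, jumps above `max_jump` are forbidden
(default 5·√(4·D_max·Δt) ≈ 1.73 µm with D_max = 1 µm²/s), and a track may
bridge up to 3 missing frames. These values are declared defaults, not
reconstructions of any particular software. Trajectory pairs that approach
within a crossing radius (default 0.5 µm, configurable — no published value
exists) in at least one common frame are removed in pairs, because crossing
QDs cannot be disambiguated.

### Per-trajectory metrics

* **MSD** — MSD(nτ) = (1/(N−n))·Σᵢ[(x_{i+n}−x_i)² + (y_{i+n}−y_i)²] for
  n = 1..N−1; with blinking gaps, pairs spanning missing frames are skipped
  and the divisor is the number of valid pairs; lags with zero pairs are
  omitted. The implementation is vectorized and is tested to ≤1e−10 relative
  against a literal double-loop oracle.
* **Diffusion coefficient** — OLS line through the first four MSD points
  (lags 1–4, origin excluded); D = slope/4, and the intercept estimates the
  localization-noise offset (≈4σ_loc² for static noise). Tracks missing any
  of lags 1–4 yield no estimate and are excluded with a logged count.
  Negative D or intercepts (pure noise) are retained in metric tables but
  excluded from log-scale statistics, again with logged counts.
* **Explored area** — the MSD value at fixed lags, default 0.42 s and
  0.45 s (lag indices 14 and 15 at τ = 30 ms), a confinement proxy. The lag
  list is configurable; each QD contributes one EA value per lag, so EA
  sample sizes are (#QDs)×(#lags).
* **Compartment label** — masks are binary images on the 190 nm camera
  grid; distances use the Euclidean distance transform of the mask raster
  (0 inside the mask), with localizations mapped to pixels by the floor
  convention (0-based, pixel centers at (i+0.5)·p). A trajectory is synaptic
  for a marker if ≥1 localization lies within the 760 nm inclusion radius
  (four pixels) of that marker's mask, extrasynaptic if every localization
  is at least that far from all masks; when two markers qualify the smaller
  minimal distance wins and exact ties are `unclassified`. The same geometry
  against an endocytic-zone mask yields `intra_EZ`/`extra_EZ`. There is no
  separate perisynaptic class; the inclusion zone *is* the synaptic label.
* **Dwell time** — per-frame in/out labels against the inclusion zone;
  dwell = (total in-frames)·τ / (number of in→out exits). With no exit the
  total in-time is reported with a censored flag. Dwell times under five
  frames (0.15 s at default τ) carry a discarded flag. The inclusion zone
  (not the bare mask overlap) defines "in", for consistency with the
  classification geometry.

## STORM post-processing

Input is a localization table (frame, x nm, y nm) from PSF fitting —
ThunderSTORM-style headers are accepted; fitting raw movies is out of scope.
Acquisitions are 30 000 frames at 50 ms.

* **Drift correction** — center of mass of a reference cluster over a
  2000-frame sliding window (step 500 frames). The reference is either all
  detections (single-cluster fields), a fixed box, or an auto-selected
  densest 500 nm box that is re-centered on the previous window's COM as the
  stage moves. Each window's COM is anchored at the window's *mean detection
  frame* rather than its nominal center — for a linear drift this makes the
  estimate exact regardless of how blinking bursts sample the window — and
  the per-frame trace is linear interpolation between anchors, extended
  linearly beyond the first/last anchor so drift is not clipped in the
  ~1000-frame margins the anchors cannot reach. Windows with fewer than 10
  reference detections are skipped and interpolated over. The trace is zero
  at the first valid window by construction, so recovered and injected drift
  are compared up to a constant offset.
* **Detection merging** — repeated detections of one blinking fluorophore
  are merged into a molecule when they fall within 2σ in space (σ = 25 nm
  default → 50 nm radius, a single global value since per-detection
  uncertainties are not carried) and 15 s in time of the molecule's running
  mean position / last detection. Chaining is transitive, so long blinking
  trains stay one molecule; detection counts are conserved exactly.
* **Rendering** — a 20 nm-pixel 2D histogram of detection counts, bounds
  from the data extent padded by one pixel (or a fixed origin/shape for
  reproducible framing). The pixel sum equals the detection count.
* **Nanocluster segmentation** — the binary image keeps pixels whose count
  clears both the intensity floor (1% of the maximum pixel count) and the
  density floor expressed per pixel (0.1 detections/nm² × 400 nm² = 40
  detections per 20 nm pixel); 8-connected components with at least 10
  detections inside their pixels become clusters. Cluster area is
  (#pixels)·p², the detection count is the sum over cluster pixels, and
  density = detections/area, so density·area equals the count exactly.
  Molecule counts are attached afterwards when a molecule table is given.
  Segmentation runs on detections, not merged molecules, since the density
  definition counts detections.

  Two interpretation notes. First, the density floor is applied per pixel
  during binarization (a `density_mode="component"` flag applies it to each
  component's detections/area instead): at component level the floor is
  equivalent to ≥40 detections per occupied pixel on average, which silently
  rejects any moderately dense cluster whose rendered footprint includes
  single-detection rim pixels, while the pixel-level reading trims those rim
  pixels and keeps the cluster. Either way the floor implies ≥40 detections
  per cluster, so the separate 10-detection minimum only binds when the
  density threshold is relaxed. Second, the floor's units are ambiguous in
  the field (per nm² vs per µm² appear interchangeably); the default is
  0.1 nm⁻² and the threshold is fully configurable.

  A bias worth knowing: pixel-count area is a coarse measure for clusters a
  few pixels across. For a planted 40 nm-radius disc (2 pixels) the
  ≥1-detection footprint overshoots the geometric area πR² by ~60–100%
  (every intersected rim pixel counts fully), while the 40-per-pixel density
  cut undershoots it by ~30–50% (partially covered rim pixels rarely reach
  the floor). The recovery tests therefore check cluster count, detection
  conservation, and the density·area identity exactly, but treat the area
  of few-pixel clusters as a biased estimator; comparisons of areas between
  conditions (same pixel grid, same thresholds) are unaffected in direction.

## Widefield quantification

Cluster detection runs on a background-flattened image — the raw image minus
its 3×3 median filter, clipped at zero (the third parameter of the original
acquisition software's "3×3×2" kernel is undocumented and treated as an
internal scaling not reproduced) — but all intensity measurements are taken
on the raw image; flattening only outlines clusters. The detection threshold
is a required per-experiment config value, never auto-chosen, mirroring the
fixed-exposure design in which compared condition sets are imaged
identically. Per ROI: cluster pixel areas (µm², camera pixel 190 nm),
mean raw intensity per cluster, and cluster count divided by ROI area.
The surface/total membrane fraction is mean(surface)/mean(total) within a
common dendritic ROI and is invariant to common gain. Ratiometric
chloride-probe traces subtract a background-ROI mean from both channels per
frame before dividing; frames whose denominator is ≤0 after subtraction are
flagged invalid. Which channel is the numerator is config-exposed.

## Statistics

SPT/STORM variables are approximately log-normal: values are divided by the
control group's median and log-transformed (control median maps to 0
exactly when the median is an order statistic). Two-group comparisons use
the Welch t-test when both groups pass Shapiro-Wilk at α = 0.05, otherwise
the two-sided Mann-Whitney U (exact null for n ≤ 20 without ties,
continuity-corrected normal approximation with mid-rank ties otherwise);
zero-variance groups fall back to Mann-Whitney.

For clustered super-resolution data, the **balanced Monte-Carlo
Mann-Whitney** procedure equalizes per-cell contributions. Per repetition
(1000 by default, seeded): m = the minimum per-neuron observation count
across both conditions; m observations are drawn without replacement from
every neuron; within each culture the selected values are divided by that
culture's selected-control median; cultures are pooled, logs applied, and
the U of treated vs control computed. Rows are sorted by
(culture, neuron, condition) before sampling so results are invariant to
input row order. The summary U is the median of the per-repetition U
values, and the reported p-value is its two-sided tail probability under
the MW null at the balanced per-repetition sample sizes. The aggregation
from 1000 U values to one p-value is genuinely underdetermined, so the
alternative — the median of per-repetition p-values — is always computed
alongside and can be made primary with `p_mode="median_p"`.

**Calibration domain.** The per-repetition U is still referred to an
exchangeable (i.i.d.) null, so the procedure controls the type-I error only
when within-neuron correlation is weak: with ~20 observations per neuron,
an intraclass correlation of 0.01 already inflates the rank-sum variance by
~20%. Balancing removes *dominance* of any single neuron or culture (its
stated purpose) — it is not a mixed-model correction. The synthetic
clustered generator therefore uses a large between-culture spread (log-sd
0.3, removed by the per-culture median normalization) and a small
between-neuron spread (log-sd 0.05, inside the calibration domain), with
observation log-sd 0.5 and per-neuron counts drawn from 12–28 so the
balanced selection is exercised. Passing calibration tests show the
procedure is correctly implemented and calibrated in this regime; they do
not show it is calibrated for data with strong per-cell effects.

## What the simulators do and do not emulate

Emulated: acquisition geometry and timing (1200 frames/30 ms SPT with
~25 nm accuracy; 30 000 frames/50 ms STORM; 16-bit 512×512 widefield),
free/confined motion, blinking gaps, emitter burst structure with repeated
detections, stage drift (linear or random-walk), compartment masks on the
190 nm grid, Gaussian puncta over smooth background, and clustered
log-normal observables. Not emulated: PSF shape and camera physics
(EM gain, Poisson–Gamma noise chains), 3D motion and z-drift, photobleaching
kinetics, real QD blinking statistics, chromatic registration error, or
biological heterogeneity beyond the stated random effects. Tests passing on
this synthetic material validate the estimators' correctness and
calibration under the stated models, not their robustness to the full
physics of a microscope.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng` seeds; identical
configs and seeds give bit-identical outputs (pipeline manifests record
SHA-256 checksums). Assignment ties in linking are broken by stable input
order. Distance transforms work at mask-pixel resolution. The test suite
and the acceptance script size their simulations to run on one CPU in a few
minutes: 500 trajectories of 1200 frames for diffusion/EA recovery, one
30 000-frame STORM stream with a 300-emitter reference cluster for drift,
600-detection planted nanoclusters, 1000 null pairs for rank-test
calibration, 200 null / 100 shifted clustered datasets (200 Monte-Carlo
repetitions each) for the balanced test, and 300 QDs per condition for the
confinement scenario.

## Known limitations

* Linking is greedy per frame pair (globally optimal within each pair, not
  across the whole movie) and carries no motion model or probabilistic
  gap-closing.
* Pixel-count nanocluster area is biased for clusters a few pixels across
  (see above); no sub-pixel area estimator is provided.
* Merging uses one global σ; per-detection uncertainties are ignored.
* The balanced Monte-Carlo test's p-value assumes weak within-neuron
  correlation; strongly clustered data need a hierarchical model that is
  out of scope here.
* Dwell times are computed on observed frames only; blinking gaps inside a
  synaptic visit are not imputed.
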