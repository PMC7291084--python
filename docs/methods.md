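# Methods

## The polar distribution score

The score summarises how anisotropically an organelle's fragments sit
around the cell. For a cell with fragment centroids (xᵢ, yᵢ) and
polar origin (cx, cy):

1. θᵢ = atan2(yᵢ − cy, xᵢ − cx). The radius is discarded; the score
   depends on angles only (so it is invariant to radial rescaling by
   construction).
2. The circular mean μ = atan2(mean sin θ, mean cos θ) is subtracted
   and the result wrapped to [−π, π). This makes the score invariant
   to rigid rotation of the fragment set: the mean co-rotates, so the
   normalised angles are unchanged.
3. The normalised angles are binned into n = 8 equal sectors and the
   score is Σₖ |fₖ − 1/n| over sector frequencies fₖ, bounded by
   [0, 2(1 − 1/n)] = [0, 1.75].

**Binning convention.** Sectors are *centred* on the zero mean: the
first sector spans [−π/8, π/8). After step 2 any concentrated cluster
of fragments is centred at angle 0; if 0 were a sector *edge*, the
cluster would split roughly evenly between two sectors and the score
would saturate at 1.5 instead of reaching its nominal maximum of 1.75
for "all fragments in one sector". Centring the sectors on the mean
makes the documented extremes attainable and the saturation behaviour
match the statistic's definition. Sectors are half-open; an angle
exactly on an edge belongs to the sector above it.

**Degenerate means.** When the resultant length is ≈ 0 (perfectly
symmetric configurations, e.g. two antipodal fragments or a fragment
at each sector centre), the mean direction is undefined. The mean is
pinned to 0 and the cell flagged; flagged cells are kept in scoring by
default, since their score is arbitrary only through bin-edge effects.
A fragment exactly at the polar origin has no angle and is dropped
with a warning.

**Polar origin.** The cell-mask centroid by default; the nucleus
centroid is available via `center="nucleus"`. The cell centroid needs
no nucleus channel and matches the idea of dividing *the cell* into
sectors; with an off-centre nucleus the two origins give different
scores, which is why the choice is exposed.

**Normalisation.** Per-treatment mean PDS divided by the NEG-control
mean. Values < 1 read as dispersed relative to control, > 1 as
compacted.

## Synthetic scenes

The generator emulates the two assay geometries the pipeline measures,
not photorealistic microscopy.

*Fixed cells.* Cells are perturbed ellipses (axis ratio 0.75–0.95,
low-order boundary ripples ≤ 6%) of radius 9 µm with one off-centre
elliptical nucleus; centres are rejection-sampled to prevent overlap,
and an image too small to host the requested cells raises an explicit
error rather than silently dropping cells. Golgi-like fragments are
discs (radius 0.2–0.4 µm) placed at angles drawn from a von Mises law
about the per-cell nucleus→centroid axis — concentration κ is the
single dispersion knob (κ = 0 uniform ring, κ → ∞ a single tight
cluster) — at radii 1.5–7 µm from the centre, clamped inside the cell
boundary. Fragment centres keep a best-effort minimum spacing of
1.5 µm (retry sampling, never an error), so that default scenes are
optically resolvable at the default PSF; at very high κ the spacing is
not always achievable and fragments may touch, as real compact Golgi
ribbons do. Endosome/lysosome-like puncta (0.15–0.3 µm) are placed
uniformly inside the cell with controllable count and intensity.

*Rendering.* Solid shapes are painted additively, blurred with a
Gaussian PSF (default σ = 0.15 µm) and offset by a constant background
(default 10); Gaussian read noise of chosen SD is added last and
clipped at 0. Blurring conserves integrated signal away from borders.
Poisson shot noise, photobleaching, 3D stacks and stage drift are not
modelled. Default calibration: 0.1 µm/pixel and 1 s/frame, so a 2 µm
tubule spans 20 pixels and a one-minute video is 60 frames.

*Time-lapse.* Carriers are discs (radius 0.2 µm) or capsules of set
centreline length (halfwidth 0.15 µm) moving at programmed speeds on
straight or random-walk paths; truth tracks record exact sub-pixel
positions. A carrier whose centre leaves the field has its track
truncated at the last in-bounds frame and flagged.

All randomness flows from a single `numpy` generator per scene, so
identical arguments and seed give bit-identical output.

*What passing these tests shows.* Estimators are validated against
exact truth under a simple, favourable imaging model. Recovery there
is necessary but not sufficient for real data, where debris, uneven
illumination, out-of-focus light and touching cells add failure modes
the generator does not produce.

## Segmentation and detection

Nuclei: Otsu threshold → hole filling → size filter (default
200 px) → distance-transform watershed with peak seeds (min distance
12 px) to split touching nuclei. Cells: Otsu foreground (union with
nuclei) and a watershed on inverted cell-channel intensity seeded by
the nucleus labels, so cells exactly partition the foreground; cells
touching the image border are excluded from quantification, and a
nucleus with no detectable cytoplasm is discarded with a warning.
Fragments: per-cell threshold at background median + k·MAD (default
k = 3) over the cell's marker pixels; when the background is
noise-free (MAD = 0) the fallback threshold is 10% of the in-cell
dynamic range above the median, which keeps PSF halos out of the
mask. Components are 4-connected (conservative splitting) and
size-filtered (default 4 px).

Fragment *area* is recorded on the half-maximum footprint — pixels at
or above half of (component peak + background median). Under Gaussian
blur the half-maximum contour tracks the underlying object boundary,
whereas the detection mask dilates with the threshold; on clean
default scenes the summed half-max area agrees with the generated disc
areas to within ~5%. Integrated intensity is summed over the full
detection mask, so blur tails are counted.

## Carrier analysis

Frames are preprocessed as an unsigned-integer ImageJ pipeline would:
clip(frame − 10, 0), Gaussian blur σ = 1 px, ×3. Detection is Otsu
thresholding with a 4 px size filter; a blank frame yields no
detections. Per-object length is measured on the half-max footprint:
compact objects get the equivalent diameter; elongated objects
(major/minor axis ≥ 2) get the maximum caliper (Feret) extent minus
the mean width (area divided by an end-corrected skeleton length),
which cancels the rounded-cap extension and recovers capsule
centreline lengths to within ~5% at default calibration.

Linking is greedy nearest-neighbour between consecutive frames:
candidate pairs in ascending distance order, each end used once,
accepted when the step is ≤ 1.5 µm (default), unmatched detections
start new tracks, no gap closing. Mean speed is path length over
duration; displacement is the straight-line start→end distance.
Tracks with displacement strictly greater than 2 µm are retained for
statistics; an alternative filter on the mean over frames of the
distance from the start is available via
`filter_tracks(..., criterion="frame_mean")`. Carriers with length
≥ 2 µm (inclusive) are tubular, shorter ones vesicular, with size
bins [1, 2), [2, 3), [3, ∞) µm for reporting.

## Screen statistics

Group comparisons against the NEG control use the two-sided
Mann–Whitney U test — exact null distribution for tie-free samples of
≤ 20 per side, continuity-corrected normal approximation otherwise —
with Bonferroni adjustment (p·m capped at 1) across treatments, or
one-way ANOVA with Bonferroni-corrected pairwise t-tests where a
parametric analysis is wanted. Significance stars follow the usual
thresholds (*** < 0.001, ** < 0.01, * < 0.05). Error bars are s.e.m.
over replicate means (three independent experiments by convention).
`stats.simulate_null_fwer` checks by simulation that the corrected
procedure keeps the family-wise error of a 21-arm screen at or below
the nominal level under the global null.

qPCR knockdown uses the ΔΔCt form: ΔCt = Ct_target − Ct_reference per
condition (replicates averaged), relative expression
2^−(ΔCt_treated − ΔCt_NEG), knockdown % = (1 − rel)·100. Passing
`ct_reference=None` gives the reference-free −ΔCt variant. The
transform is exactly invertible: applying +ΔΔCt then −ΔΔCt returns 1.

## Problem sizes and numerical choices

Validation experiments (`golgiscreen.experiments`) use 100–120 cells
per arm for dispersion/feature recovery, 25–30-frame 512×512 videos
with 3–4 carriers for kinematics, three simulated replicates for the
depletion-ratio readout, and 10⁴ replicates of the 21-arm, n = 25
global-null screen for error-rate calibration — scales at which the
recovered quantities are stable to within the tolerances the tests
assert. Degenerate-resultant detection uses a 1e−9 cutoff on the
resultant length; scores are compared to the loop oracle at 1e−12.

## Known limitations

- The segmentation substitutes a conventional nuclei-seeded watershed
  for the original interactive pipelines; it is validated against
  synthetic truth, not against any particular software's output.
- Greedy frame-to-frame linking has no gap closing or merge/split
  handling and will fragment tracks through missed detections or
  crossings; error rates are only characterised on synthetic data.
- Noisy, crowded scenes can merge nearby fragments into one detected
  component; counts are exact only when objects are resolvable at the
  rendered PSF.
- Length measurement assumes approximately uniform-width elongated
  objects; strongly curved or branched carriers are measured along
  the skeleton-corrected caliper and may be underestimated.
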