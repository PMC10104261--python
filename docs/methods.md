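# Methods

This note documents the models behind `condenscan`, the parameters that
matter, what the synthetic-data generators do and do not emulate, and
the numerical choices made where the design was genuinely open.  It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Cell geometry

Rod-shaped bacteria are modeled as spherocylinders: a cylinder of
diameter `width` (= 2r) with hemispherical caps, pole-to-pole length
`length`, volume

    V = π r² (length − 2r) + (4/3) π r³ .

The in-plane silhouette is the set of points within r of the central
axis segment.  Conventions used everywhere: pixel (row j, col i) has its
center at (x, y) = (i, j)·pixel_size, with the default pixel size
0.066 µm/px; point coordinates are (x, y) = (column, row); µm values are
pixel indices times the pixel size.

Per-cell length, width and orientation come from principal-axis extents
of the label's pixel footprint (+1 px for the footprint of edge pixels).
Extent-based widths carry a fraction-of-a-pixel negative bias that
enters the volume quadratically, so `cells.cell_volume_from_mask`
refines the width by inverting the silhouette area
A = wL − w² + πw²/4 (pixel counting of the area is unbiased).  On the
simulator's rendered silhouettes this estimator is accurate to ~3% in
volume; `cell_axes` itself keeps the plain extent contract.

Segmentation is a deliberately simple Otsu-threshold + connected-
components pipeline with a watershed pass for merged components and
removal of border-touching cells, adequate for the simulator's
fluorescence silhouettes.  Real phase-contrast data should be segmented
externally (e.g. Cellpose); external label masks are accepted verbatim
through `segment_cells(..., method="external-mask")`.

## EMCCD camera model and calibration

The detection chain is photons → Poisson photoelectrons → EM register →
Gaussian read noise → ADC.  The EM register is modeled as a Gamma
cascade: k photoelectrons produce Gamma(shape k, scale G) output
electrons, where G = em_factor × nominal_em.  This standard high-gain
approximation reproduces the factor-2 excess noise (output variance
2G²N), which the test suite checks by Monte Carlo.  Counts relate to
electrons by the conversion gain g (e⁻/count): counts = bias +
electrons/g.  Defaults mirror the calibrated constants of an Evolve-
class EMCCD: g = 1.40 e⁻/count, em_factor = 0.15, linear nominal-gain
range 5–600.

*Conversion gain* is estimated from paired flat-field frames at several
exposure times: mean signal regressed on the pair-difference variance
(var(A−B)/2 removes fixed-pattern nonuniformity).  With counts-space
shot-noise variance N/g² and mean N/g, the slope of mean vs variance is
g in e⁻/count — this fixes the axis orientation, which the recovery
tests confirm on gains {0.5, 1.0, 1.4, 2.0}.  Ordinary least squares
with a free intercept absorbs the read-noise floor.

*EM-gain factor*: the signal-per-time ratio between a short-exposure EM
image and a long-exposure no-EM image is the output gain at that
setting; its least-squares slope against the nominal setting is the
factor.

*Counts → photons*: photons = counts × g / (nominal_em × em_factor),
divisor 1 when the EM register is off (nominal gain below the linear
range).  No quantum-efficiency correction is applied, so "photons"
means detected photoelectrons; the round trip against the camera model
is exact in the noiseless unit test.

## Photons per molecule and concentrations

Per-molecule per-frame photon outputs are modeled Gamma-distributed
with mode 90 (shape 3, scale 45, mean 135); only the mode is
constrained by the calibration this emulates, the spread is a plausible
choice.  `photons_per_molecule` fits a Gamma law to the measured
integrated photons and reports shape, scale, mode (k−1)θ and mean kθ.
Two fitting methods are provided:

- `histogram` (default): least squares of the bin-averaged Gamma
  density against the normalized histogram.  EM excess noise broadens
  the measured distribution beyond a pure Gamma; the histogram fit
  keeps tracking the *peak*, which is the quantity of interest.
- `mle`: maximum likelihood.  Agrees with the histogram fit on clean
  Gamma samples but is dominated by the noise-broadened low tail on
  camera data and under-reports the peak by ~15%.

For photometry of isolated molecules the 2D Gaussian fit is run with
the width pinned to the calibrated PSF (`localize(...,
fit_sigma=False)`): width noise enters the integrated intensity
2πAσ² quadratically, and fixing a calibrated σ removes that variance
without biasing the position.  Tracking uses free-σ fits (bounded to
0.5–2.5× the PSF guess).

Copy numbers divide the cell's total detected photons (brightest five
frames of a movie, background-corrected over a 4-px-dilated cell mask so
PSF-blurred edge flux is kept) by a per-molecule photon value.  Because
total intensity is a *sum* over molecules, the unbiased divisor is the
Gamma mean kθ, not the mode; `estimate_concentration` takes the divisor
as an explicit argument so either convention can be used.  Concentration
is copies/(N_A·V): 1 µM ≈ 602 molecules/µm³.  The end-to-end recovery
test (segmentation → volume → photometry → concentration on 100
simulated cells) is accurate to ~3% with cell-to-cell scatter of ~4%.

Focus/no-focus populations are compared with Welch's t test on a seeded
random subsample of 100 cells per class (classes smaller than that are
used whole, with a warning); class means and SDs are reported on all
cells, and the (no-focus, focus) mean pair brackets the apparent
saturation concentration.

## Condensation, partitioning, FRAP

Background is the median of all pixels outside the cell regions, one
consistent estimator across all bulk-image operations.  Pixels are
background-corrected first and then min–max normalized per cell
(constant cells are flagged degenerate and excluded).  Focus detection
blurs with a 0.066-µm Gaussian, thresholds the normalized image
(default 0.5) and filters components by area ≥ 4 px and eccentricity
≤ 0.75 — the eccentricity bound keeps round objects and rejects
streaks.  Condensation fractions use strict inequality (I_n < t), which
makes an exact linear ramp yield fraction t exactly.  Partition ratios
average the per-focus mean intensities in multi-focus cells and divide
by the cytoplasm mean excluding all focus pixels.

FRAP curves are background-subtracted, optionally corrected for
acquisition photobleaching against an unbleached reference focus, and
anchored exactly: last pre-bleach frame = 1, first post-bleach frame
= 0.  The recovery fraction is the mean of the final five frames — the
plateau window is a package choice, as only plateau values are usually
reported.  No reaction–diffusion modeling of the recovery is attempted.

## Single-particle tracking

Frame-averaging blur: a camera integrating over the full frame time Δt
records the time-averaged position, and for free 2D diffusion the
measured MSD becomes

    MSD(τ) = 4 D (τ − Δt/3) + 4σ²,   τ = nΔt, n ≥ 1,

which at a one-frame lag is (8/3)·D·Δt + 4σ².  The per-track fit
regresses the time-averaged MSD at lags 1–5 frames (40–200 ms at the
40 ms default) on (τ − Δt/3): slope/4 = D_app, intercept/4 = σ².  The
one-frame-lag closed form is often quoted with the slope written as
(8/3)D for all lags; fitted across several lags that reading would
over-estimate D by 1.5×, so this package uses the full blur law, which
coincides with the printed one-frame form and recovers D without bias.
Fits require ≥ 6 steps and R² ≥ 0.7; a negative intercept keeps D_app
and flags σ undefined rather than clipping (clipping would bias pooled
precision estimates).

Statistical properties to be aware of (established by the test suite):
per-track D estimates from ~20-step tracks are right-skewed — the mean
is unbiased while the median sits ~5% low, converging for longer
tracks; and the 4σ² intercept is resolvable per track only when it
rivals the one-frame slope term, so localization precision is recovered
from the ensemble MSD pooled over tracks.

Linking solves a gated minimum-cost assignment per frame pair
(squared-displacement costs, non-assignment charged gate²) via the
Hungarian algorithm; optimality is verified against brute-force
enumeration for up to 6 molecules per frame.  The mixture over log₁₀
D_app is a two-component Gaussian mixture (EM, k-means initialization,
10 seeded restarts), components ordered slow/fast, with a `merged` flag
when the means are closer than the pooled component spread (one
effective state).  Localization heat maps normalize each cell (centroid
→ origin, poles → (±1, 0)), histogram over [−1, 1]², average the four
axis reflections and normalize to total 1.

## Dissolution tracking

Foci are detected with a single-scale Laplacian-of-Gaussian filter
matched to a 600-nm blob (σ = d/(2√2), zero crossing at the blob
radius); quality is the scale-normalized response amplitude in counts.
Reference thresholds from interactive tools are tool-internal units, so
the threshold here is exposed as a calibrated configuration value; the
pipeline defaults (quality 20 counts, white-tophat prefilter with a
5-px disk) are calibrated once against the generator's default photon
budget.  The tophat step (structuring element larger than the spot,
smaller than the cell half-width) cancels the smooth cell silhouette,
whose pole response otherwise sets the detection floor; with it the
floor is shot-noise limited, about 7×10² dense-phase molecules at the
default conditions.

Linking reuses the assignment core with a 3-px gate and adds gap
closing: tracks interrupted for ≤ 2 frames are joined when the gap
distance is ≤ 3 px (greedy minimum-cost merging, iterated to a fixed
point).  The four trajectory filters are applied in order: (i) only
tracks present in frame 0; (ii) tracks whose cell touches the
field-of-view border are dropped (needs per-frame masks, else skipped
with a warning); (iii) first-frame false positives via a manual
exclusion list and/or a quality cutoff (the reference workflow curates
these manually); (iv) tracks in cells that did not grow or divide are
dropped (movie-level annotation).  Lifespan = (last − first + 1) ×
frame interval; tracks alive in the final frame are censored but
included at their observed length, so a full-length movie of an inert
aggregate reports a movie-length mean lifespan.

## Synthetic-data generators

All generators are seeded and bit-reproducible, and return their ground
truth.  Choices and what they do (not) emulate:

- **Snapshots**: emitters are pixel-integrated 2D Gaussians (erf-exact,
  photon-conserving); bulk scenes render the summed photon flux of the
  ~10⁴–10⁵ molecules per cell as a smooth silhouette (a normal
  approximation of the per-molecule Gamma sum) — individual-molecule
  rendering at those counts would change nothing measurable.  No 3D
  PSF, no photophysics beyond an optional per-frame bleach probability.
- **Diffusion**: Brownian substeps (default 10 per frame) with specular
  reflection at the spherocylinder wall; frame-averaged positions give
  the blur law with a discrete-substep bias of (1 + 1/(2m²)), i.e. 0.5%
  at m = 10.
- **Dissolution movies**: one followed lineage, exponential length
  growth (doubling every 10 frames of 15 min by default), division at
  2× birth length with volumes halved; molecules partition binomially
  by volume (default) or deterministically.  Dense-phase content is
  total minus c_sat·V (condensate) or frozen at its initial value
  (aggregate).  The default per-molecule photon budget (2 photons/
  molecule/frame) was set so the detection floor sits well below the
  dense-phase content until the final frame before dissolution — at a
  4× lower budget the floor (set by dilute-phase shot noise) truncates
  measured lifespans by up to two frames near division events.  The
  focus pole is anchored in the image so a persisting focus moves less
  than the 3-px linking gate between frames.
- **FRAP movies**: single-exponential recovery of the bleached focus
  toward mobile_fraction × pre-bleach; no spatial diffusion of the
  bleached population.
- **Colocalization patterns**: reference Gaussian spot (σ 2 px) with
  chaperone channel as ring (radius 4 px), inner punctum (σ 1 px),
  speckled blob, or copy; geometries fit the 23×23 px ROI at 0.066
  µm/px.

Because the generators share these idealizations (flat background, no
cell-to-cell autofluorescence variation, no defocus, no photophysics),
passing tests demonstrate estimator correctness under the stated noise
model — not robustness to structured backgrounds or optical aberrations
in real movies.

## Colocalization analysis

Reference foci: threshold at 30% of the background-corrected image
maximum (per-image, as an explicit choice; a per-cell variant is a
caller-side substitution of the input), area ≥ 4 px, eccentricity
≤ 0.75.  ROIs (23×23 px) are cut identically in both channels around
each centroid, normalized per focus to the reference ROI maximum, then
averaged; after averaging, both projections are rescaled by the averaged
reference maximum so the reference peak is exactly 1 while the relative
chaperone intensity is preserved.  Both projections are fitted with an
isotropic 2D Gaussian plus offset (FWHM = 2√(2 ln 2)·σ·pixel size); a
fit on a peakless projection fails explicitly.  Note that a ring is not
a Gaussian: its least-squares Gaussian fit is simply the widest
effective profile, which is exactly what makes the FWHM ratio a robust
coating discriminator (ratio ≈ 2.3 for the default rosette vs ≈ 0.5
for the punctum, with zero overlap across seeds).

## Problem sizes

The validation suite uses: 10⁴ trajectories for the blur law, 512²
frames at six exposures for gain recovery, 2,000 detections for the
photon fits, 100 cells for concentration recovery, 5,000 tracks for the
mixture, 200 random instances for linking optimality, 100 movies for
lifespan recovery, and 50 seeds per colocalization pattern — sizes at
which the Monte-Carlo error is comfortably below each stated tolerance.

## Known limitations

- The localizer assumes sparse, in-focus emitters on a flat local
  background; it is not a replacement for production SMLM software with
  structured-background handling.
- Cell geometry assumes near-straight rods; curved or branched cells
  would need medial-axis geometry.
- Lifespan censoring is reported, not modeled; no survival analysis is
  performed on the censored lifespans.
- The FRAP module normalizes and summarizes curves; it deliberately
  does not extract diffusion or exchange rates.
- No lineage reconstruction: division handling is limited to the
  trajectory filters' cell-level bookkeeping.
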