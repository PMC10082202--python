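# Methods

This note documents the models, parameter choices and numerical decisions
behind `mfscan`, and what the simulator-based tests do and do not
demonstrate.

## Scene simulator

**Membrane surface.** The wavy microfilter surface is modeled as Gaussian
white noise low-pass filtered with a Gaussian kernel of σ equal to the
correlation length (default 500 µm), then rescaled to a target standard
deviation (default amplitude 15 µm).  The rescale uses the *analytic* std
of filtered unit noise (the root of the summed squared kernel weights,
computed on a kernel-radius-padded grid), so the field is a stationary
process: a patch smaller than the correlation length comes out nearly flat
at a random height offset drawn from N(0, amplitude²), rather than being
renormalized to full roughness.  This matters because one camera field
(0.92 × 0.85 mm at full scale, tens of µm in the scaled-down tests) is
much smaller than the correlation length: within-field height variation is
sub-µm while field-to-field offsets span ±15 µm, which is exactly the
regime that makes per-field autofocus necessary and sufficient.  The
15 µm amplitude is a modeling choice — the instrument's fine scan range
(50 µm centered on the coarse estimate) comfortably covers it.

**Objects.** Cells are soft-edged discs (CAFs: ellipses with eccentricity
up to 0.8 and random orientation, reflecting their wider shape variation);
the nucleus (DAPI) is drawn at 0.6 of the cell radius.  Marker logic is
exclusive by construction: mCTCs carry CK and no FAP, CAFs the reverse.
Pores are annuli with zero interior DAPI ("hollow"), each autofluorescent
in exactly one of CK/FAP; precipitates are small bright single-channel
spots placed without distance constraints so they can contaminate cells.
Default diameters: mCTC 15 ± 1.5 µm (all larger than the 8 µm screening
floor), CAF 20 ± 3 µm, pore 8 µm, precipitate ~2.5 µm.  Placement is
uniform rejection sampling with a configurable minimum center distance
(0 permits clumps) and bounded retries.

**Optics.** 20×/NA 0.4 objective, 0.23 µm/px (0.92 mm / 4000 px), depth of
field λ/(2·NA²) = 1.72 µm at λ = 0.55 µm.  Defocus maps to a Gaussian blur
σ_px = max(σ_min, k·|defocus|/pixel_size) with k calibrated so σ = 1.5 px
at one depth of field and σ_min = 0.4 px.  The blurred-disc profile is the
erf edge model with its center renormalized to the exact value
1 − exp(−r²/2σ²): without this, a strongly defocused disc would plateau at
half amplitude instead of fading, inflating the photon count (and hence
the Poisson noise floor of the focus metric) far from focus.  Per-channel
axial chromatic offsets shift each channel's best-focus plane.
Vignetting is a radial quadratic profile (strength 0.15).  Noise is
Poisson at 2000 photoelectrons full scale plus Gaussian read noise of
0.003 — a well-exposed sCMOS operating point at which the Tenengrad peak
of a populated field stands clearly above the metric's noise floor, as it
must for any instrument whose autofocus works at all.  Noise is
deterministic per (scene seed, channel, z, stage position).

**What the simulator does not model:** cell texture, physical PSFs
(Gibson–Lanni), camera gain/offset structure, staining chemistry, cell
clusters as a distinct class (clumps are just closely placed single
cells), autofluorescent debris beyond point precipitates.  Tests passing
on these scenes show the *algorithms* are correct and calibrated, not that
the detector's absolute performance transfers to real slides.

## Autofocus

Tenengrad is the unthresholded sum of squared 3×3 Sobel responses over the
valid interior (1-px border excluded); a threshold parameter exists and
defaults to 0.  The best-focus fit is 4-parameter Gaussian least squares
(amplitude, mean, sigma, offset), initialized at the discrete argmax with
σ₀ = the coarse step, and restricted by default to ±2 samples around the
argmax: with a 20 µm coarse step the metric peak spans only one to three
samples, and the remaining planes contribute only the noise floor, which
empirically pulled a full-sequence fit several µm off peak.  The full
sequence can be fitted with `window_halfwidth=None`.  If the argmax sits
at either end of the sweep the peak is not bracketed and the estimator
falls back to the argmax (ties toward lower z) with `converged=False`;
the same fallback handles non-convergence and fitted peaks outside the
scanned range.  On 100 simulated ±15 µm membranes the coarse sweep + fit
recovers the median cell height with ~1.3 µm median error, ≳95% of fields
within 2.5 µm — inside the "in-focus" band of the instrument.

## AIF fusion, shading, stitching

Patches are tiled with ≥ `patch_overlap` px of overlap (far-edge windows
shifted back onto the boundary) and blended with linear feathering ramps
normalized to unit weight; with zero overlap fusion is an exact per-patch
copy of the selected slice, so per-patch AIF sharpness dominates every
single plane exactly.  Whether the original instrument blended or tiled
disjointly is unknown; feathering is the default here.

The flat-field estimator is a deliberately simple retrospective one:
per-pixel median across ≥3 tiles, Gaussian-smoothed, normalized to mean 1,
floored at 1e−3.  It is scale-equivariant and recovers a synthetic
quadratic vignette to <5% relative error; it replaces low-rank
retrospective estimators as a documented, pluggable stand-in.

Registration is phase correlation (`normalization="phase"`) on the
mean-subtracted, Hann-windowed nominal overlap strips, refined by
Fourier-domain upsampling to 1/20 px.  The Hann window is load-bearing:
overlap strips are narrow (310 px at full scale) and sparse, and border
spectral leakage otherwise dominates.  Three guards return the nominal
offset flagged unreliable: overlap below `min_overlap_px`, a normalized
phase-correlation peak below 0.03 (featureless strip), and a residual
beyond `max_residual_px` (default 16; the end-to-end pipeline uses 4,
since the stage is subpixel-repeatable and larger apparent shifts are
spurious matches between different cells).  On noiseless jittered pairs
the median error is ~0.05 px.

Global placement accumulates measured pairwise shifts from the upper-left
anchor along the row-major chain (left neighbor, or the tile above for
column 0); loop-closure residuals are reported by tests (<1 px) but not
globally optimized.  Tiles are translated by the fractional shift via
Fourier shift on reflection-padded arrays (8 px pad against wraparound)
and blended with distance-to-border weights, which sum to one wherever
covered.

## Rule-based detector

Per-channel binarization is absolute or Otsu (near-constant images — range
< 0.05 — yield an empty mask, since Otsu has no bimodality to exploit).
CK and FAP events are segmented by distance-transform watershed seeded at
local maxima ≥ `watershed_min_distance` apart (default 0.6 × expected
diameter in px) and size-filtered inclusively; the default minimum area
derives from the 8 µm screening floor at 0.23 µm/px.  Classification:
a CK region is an mCTC iff mean(DAPI) ≥ `dapi_mean_min` and
mean(FAP) ≤ `negative_mean_max`; symmetric for CAFs.  `dapi_mean_min`
defaults to 0.10: the nucleus occupies ~36% of the cell footprint, so true
cells score ~0.13–0.4 under vignetting and residual defocus while hollow
pores score ~0.03 (background only) — 0.10 splits the two populations with
margin.  Scores are the positive-marker mean over a normalizer (0.8),
clipped to 1 — a heuristic that makes PR sweeps applicable to a method
that natively has no confidence.  The detector's characteristic failures
are modeled and asserted as inequalities, not fixed: heavily overlapped
cells may merge into one region (detections ≤ truth), and a precipitate in
the negative channel can push a real cell over the rejection ceiling.

## WSI orchestration

Tiling is 1000 px (configurable) with coverages shifted by half a tile
horizontally, vertically and diagonally; the diagonal grid (an extension
toggle, default on) covers the corner case where both axes straddle seams.
Any object smaller than half a tile is therefore fully interior to at
least one window — verified exhaustively on a position grid.  Detections
touching a tile border are dropped (the completely-visible rule), ensemble
members are clustered greedily by IoU ≥ 0.5 within label, fused as the
score-weighted coordinate mean with score = Σ member scores / k (absent
votes count zero), and the pooled coverages are deduplicated greedily by
descending score using overlap ratio = intersection / min(area) with
threshold 0.5 (IoU available as config).  Deduplication is idempotent and
never removes a cluster's top scorer.

## Evaluation

Matching is greedy by descending prediction score against unmatched
same-label ground truth at IoU ≥ 0.5 (center-in-box offered for
dot-derived GT).  The PR curve assigns matches once, sweeps every unique
score as a threshold, and integrates by trapezoid over recall, opened at
(0, precision of the top point) and closed at maximum recall.  Bootstrap
(default 1000 replicates, seeded) resamples patch units with replacement;
at WSI level each replicate is a uniformly placed axis-aligned crop of 90%
of the slide area (linear factor √0.9 per side) with boxes assigned by
center inclusion — the crop orientation and assignment rule are this
package's choices where the protocol is silent.  The two-proportion z-test
uses the pooled variance and the normal two-sided p-value; its empirical
type-I error at α = 0.05 is within 1% of nominal over 10⁴ simulations at
n = 500 per group.  Stars: \*p<0.05, \*\*p<0.01, \*\*\*p<0.001,
\*\*\*\*p<0.0001, else NS.

## Problem sizes

The test suite and acceptance studies run the same algorithms at reduced
geometry, a deliberate scaling of the study conditions: 224-px
single-field tiles for the autofocus study, 180 × 160 px pairs with
120 px nominal offset for registration, 2 × 2 grids of 200 × 180 px tiles
for the stitch oracle, and a 3 × 3 grid of 500 × 460 px tiles
(~300 × 327 µm, 50 mCTCs + 20 CAFs + 30 pores + 20 precipitates) for the
end-to-end run.  Tile overlap is kept at ~8% of tile width, matching the
full-scale 310 / 4000 ratio.  All object sizes, the pixel pitch, z-step
protocol and optics are at full scale, so focus curves, blur profiles and
per-cell pixel statistics are identical to a full-size run; only the
number of pixels and cells per slide is smaller.

## Known limitations

Chain accumulation (no global bundle adjustment) lets registration errors
compound on large grids; the residual clamp bounds but does not remove
this.  The heuristic CV score makes PR curves comparable but is not a
calibrated probability.  Otsu thresholds degrade on fields dominated by a
single bright object.  The simulator's clean marker exclusivity means
cross-channel bleed-through is untested.  The ensemble machinery is
exercised with the CV detector and mock detectors only — training a
learned detector is out of scope.
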