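# Methods

`thyrotex` quantifies the solid/cystic composition of thyroid nodules in
2-D ultrasound images and measures how far human readers and an automated
estimate disagree. It has three layers: a texture-based region estimator,
a synthetic phantom generator that provides ground truth for it, and the
observer-variability statistics used to compare readers.

## Region estimation model

A nodule (given as a binary mask on a grayscale image) is tiled into
square texture patches of `patch_size_px = 20` pixels, i.e.
5.296 × 5.296 mm at the default calibration of 0.2648 mm/px
(`pixel_spacing_mm = 5.296 / 20`). Patches are taken on a stride grid
(`stride_px = 10`, 50% overlap) over the mask's bounding box and kept when
at least `min_inside_fraction = 0.8` of their pixels lie inside the
nodule. The stride/overlap trade off boundary contamination against patch
count; both are configurable.

Each patch is read out as four 1-D signals of length 400 — row-major,
column-major, and two diagonal zig-zag scans — so that directional texture
appears as different serial structure while every signal remains a
permutation of the same pixels (a testable invariant). Each signal is
split into three frequency bands with an ideal zero-phase filter bank in
the discrete Fourier domain, with edges at 0.05 and 0.20 cycles/sample:

- low `[0, 0.05]`: echo level and slow shading (DC retained, so
  hypoechoic cysts remain separable by level);
- mid `(0.05, 0.20]`: macro-texture;
- high `(0.20, 0.50]`: speckle-scale granularity.

The Fourier implementation makes the three bands sum exactly to the
input and contributes no phase distortion. Each band is summarized by an
autoregressive model of order `ar_order = 2` fitted with Burg's method,
which is stable on 400-sample records; the features per band are the two
AR coefficients (regression convention) and `log(residual_variance +
1e-12)`, the floor keeping constant inputs finite. A zero-variance band
returns zero coefficients and zero variance by convention. The full
vector is 4 signals × 3 bands × 3 values = 36 features, ordered
signal-major, band-minor.

Patches are classified solid vs cystic by a random forest
(`rf_trees = 200`, scikit-learn defaults otherwise, fixed seed). For
training on phantoms, a patch is labeled cystic when more than 50% of its
in-nodule pixels carry the cystic truth label (majority rule). The
nodule-level cystic percentage is `100 × (cystic-predicted patches) /
(all patches)`; the solid percentage is the exact complement.
Pixel-weighted aggregation is deliberately not the default: the estimate
is defined on classification outputs. All cross-validation is grouped by
nodule, so reported accuracies reflect generalization to unseen nodules.

## Synthetic phantoms

No public image set accompanies this analysis task, so phantoms carry the
ground truth. Speckle is modelled as fully developed multiplicative
noise: a gamma variate with mean 1 and shape `speckle_shape` scales a
constant echogenicity level, followed by a Gaussian point-spread blur and
clipping to `[0, 1]`. Defaults, chosen once by the qualitative ultrasound
convention that cysts are near-anechoic and smooth while solid tissue is
brighter than parenchyma:

| compartment | mean intensity | gamma shape | blur σ (px) |
|---|---|---|---|
| background | 0.35 | 3.0 | 1.0 |
| solid      | 0.55 | 3.0 | 0.8 |
| cystic     | 0.06 | 6.0 | 1.2 |

A nodule is an ellipse that must fit the frame; its cystic compartment is
the union of 1–3 random ellipses grown by bisection on a common scale
until the area fraction is within ±2% of the requested
`cystic_fraction_true` (an error names the achieved fraction when the
geometry cannot reach the target). The default suite used throughout the
tests is 20 nodules of axes 45–70 × 40–65 px on 256 × 256 frames with
true cystic fractions evenly spanning 10–90% — sizes chosen so the whole
end-to-end evaluation runs in seconds on one CPU while each nodule still
hosts ~50–110 patches.

Simulated annotators warp the true boundary with a smooth random
displacement field of RMS amplitude `boundary_jitter_px` (zero jitter is
exactly the identity) and report cystic percentages as
`clip(round-to-step(truth + bias + noise), 0, 100)` with a default
5-point rounding step, matching the granularity clinicians typically use.
The three default annotators have experience-graded jitter/bias/noise
(1.5 px/0/4 pts for the senior reader; 3 px/±5/8–10 pts for the juniors).

What the phantoms do *not* emulate: attenuation and shadowing, probe
anisotropy, septations and comet-tail artifacts, mixed echotexture inside
one compartment, and operator-dependent gain. Passing recovery tests
therefore demonstrates that the feature-classifier chain works when the
two compartments differ in level and speckle statistics — not clinical
accuracy on patient images.

## Consensus mask averaging

Several annotators' binary masks are fused so the consensus area equals
the mean of the annotated areas. The pixelwise mean of the masks ranks
pixels by agreement; pixels are admitted in decreasing order of agreement
until the rounded mean pixel count is reached. Within one agreement
level, ties are broken by the distance transform of the union (interior
first), scaled below one agreement quantum so it never overrides the
consensus ordering. A pure threshold sweep over agreement levels cannot
in general realize the mean area (nested masks admit only as many
distinct areas as annotators); the tie-break refinement makes the target
achievable to within one pixel while the result remains a superlevel set
of the mean up to ties. Annotator sets with an empty common intersection
are rejected — there is no meaningful consensus region, and a silent
empty mask would poison downstream statistics. Averaging is 2-D,
per-slice.

## Observer statistics

For observers reporting cystic percentages per nodule, the variance
percentage against a reference is `VP = (obs1 − obs2) / obs1 × 100` with
the physician as `obs1` and the automated estimate as `obs2`. `VP` is NA
when `obs1 = 0 < obs2` (undefined deviation) and defined as 0 when both
are 0 — no deviation exists. The source table this package reproduces is
internally inconsistent on the 0/0 case (two such cells print NA, six
print 0); the 0/0 → 0 convention is applied uniformly and the two
NA-printed cells are flagged as discrepancies rather than matched.
Printed-style rendering truncates toward zero (97.77… → 97.7) at one
decimal by default with a two-decimal option, since the published table
mixes both precisions; recomputed cells are compared to printed ones at
|Δ| ≤ 0.1, which absorbs truncation without masking real errors.

Composition categories on the cystic percentage default to four bins with
edges at 10/50/90% (solid, predominantly solid, predominantly cystic,
cystic — standard ultrasound vocabulary); boundary values belong to the
upper bin. The original study's bins are not disclosed, so the scheme is
fully configurable and the published match percentages (19.2/57.6/42.3/
46.1%) are reported under the default scheme, not asserted. The
panel-level match percentage is ambiguous in its source description, so
both readings are computed: the fraction of nodules on which *all*
observers and the reference agree (primary), and the mean of the
per-observer pairwise match percentages. The significance test is an
uncorrected Pearson chi-squared on the observers × categories contingency
table of category counts, df = (r−1)(c−1); a single realized category
returns statistic 0, p = 1 with a warning.

## Numerical choices and limitations

- Burg recursion as implemented matches the independent `statsmodels`
  implementation to ~1e−8 on coefficients (checked in the tests); the
  residual variance uses the final prediction-error power, which differs
  from alternative normalizations by O(order/n).
- All generators are pure functions of their arguments including the
  seed; feature extraction contains no randomness at all.
- The exact signal-construction and decomposition used by the original
  system are not restated in its description; the four scan orders, the
  band edges and the AR order here are this package's own documented
  choices, isolated in `RunConfig` so alternates can be swapped in.
- Patch-count aggregation quantizes the estimate at `100 / n_patches`
  points, and boundary patches mix compartments; at the extreme fractions
  (near 0 or 100%) this bounds accuracy at a few percentage points.
- The published patient-level numbers (match percentages, p < 0.05)
  depend on undisclosed binning and test construction and on patient data
  that was never deposited; they are computed and reported under the
  defaults, never asserted as reproductions.
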