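# Methods

This note documents the models, parameter choices and numerical
conventions behind `thromboprofile`, and what the synthetic benchmarks do
and do not demonstrate.

## Image quantification

**FFT bandpass.** Background-illumination correction is a Gaussian band
filter in the frequency domain. For spatial frequency magnitude k
(cycles/px) the gain is

    G(k) = (1 − exp(−ln2 · (k·L)²)) · exp(−ln2 · (k·S)²)

with large cutoff L and optional small cutoff S in pixels (the low-pass
factor is omitted when S is unset, since sub-cutoff detail carries the
platelet structure of interest). A sinusoid whose wavelength equals the
cutoff is attenuated by exactly 50%; structures several times larger are
removed almost entirely and structures several times smaller pass nearly
intact. The frame mean is preserved (a flat frame passes unchanged) and
the result is clipped to [0, 255]. Because filtering is a pointwise
product in Fourier space it is exactly equivariant under cyclic shifts.
The default L = 120 px sits at the midpoint of the 60–200 px per-channel
range typical for these assays and is per-channel overridable. Filter
behavior on periodic test patterns is asserted on grids holding whole
periods; on incommensurate grids spectral leakage contaminates a naive
residual-amplitude measurement even though the filter itself is correct.

**Thresholding.** Otsu's method on the background-corrected frame, with
an additive manual offset (default 0) standing in for interactive
adjustment. Brightfield frames image platelet aggregates as phase-dense
dark objects and are inverted before thresholding (flag to disable);
fluorescence frames are not. Flat frames have no Otsu threshold and
yield an empty mask flagged `degenerate`. Foreground is strictly above
threshold + offset, so raising the offset is monotone non-increasing in
foreground area.

**Morphology chain (brightfield only).** Closing with a diamond (radius
5), closing with a disk (radius 3), dilation with a small disk (radius
1); "large/medium/small" radii are conventions of the assay, exposed in
the configuration. The chain operates on the *binary* mask; the
alternative reading (grayscale morphology before thresholding) is noted
but not implemented, because the chain's purpose here — re-bridging
stripe-fragmented detections — acts naturally on the detection mask.
Each step is extensive, so coverage never decreases through the chain,
and both closings are idempotent. Structuring elements are applied on a
background-padded copy, which makes the result identical to operating on
an infinite background plane and avoids spurious border coverage.

**Striped-brightfield protocol.** With an additive stripe pattern, any
midpoint threshold is crossed by background stripe crests, and a chain
of closings/dilations can only add foreground, never remove false
positives. The package's brightfield protocol therefore pairs the chain
with a conservatively *raised* manual threshold (+65 gray levels on the
inverted benchmark fixture): detection becomes pure but fragmented, and
the closings restore the lost in-object area. On the benchmark fixture
suite this reduces the mean |%SAC error| from ≈9 to ≈2 percentage points
and helps in every seed.

**%SAC.** 100 × foreground pixels / total pixels; asserted equal to
brute-force counting. Per-parameter per-microspot values are arithmetic
means of the per-image values.

## Fibrin kinetics

Curves are %SAC vs time on a 45-s grid over a 10-min observation window;
samples are the multiples of the interval in [0, duration] (t = 0,
0.75, …, 9.75 min — 14 samples), with the time-zero frame treated as
pre-perfusion background that cannot register an onset.

*Time to first fibrin* is the earliest sample (t > 0) whose %SAC exceeds
the labeling threshold (default 1 %SAC — the dotted-line threshold of
such assays is not standardized, so it is configuration-exposed).
Pc = −log₁₀ t_first; the log base is a convention choice and is
configurable. Runs without a crossing are censored at the window end
(t_first = 10 min, Pc = −1), keeping Pc finite and ranked below every
observed event. Grid crossing times are the default; linear
interpolation of the crossing is available behind a flag.

*Fibrin formation rate* is the OLS slope of %SAC on time using exactly
the samples in the closed window [1.5, 3.75] min (both endpoints lie on
the 45-s grid), the steepest part of a typical accumulation curve. The
window is fixed, not per-curve. On noiseless linear segments the slope
is exact to 1e-9.

Ordinal scores (0–5 or 0–3 scales) are validated per raw image and
snapped to a 0.5 grid; per-run means are unconstrained, so non-integer
heatmap values are expected.

## Multiparameter statistics

Scaling is linear per parameter over the complete run database:
v → 10(v − min)/(max − min); an all-equal column maps to 0 with a
degenerate flag (preserving "0 = database minimum"). Group heatmaps
average scaled values after database-wide scaling; subtraction heatmaps
remove the reference (wild-type) row and are antisymmetric under role
swap.

Effect sizes are computed on the raw per-run values, not the scaled
ones. Cohen's d uses the pooled SD with unbiased group variances;
r = d/√(d² + a) with a = (n₁+n₂)²/(n₁n₂) is bounded in (−1, 1),
sign-matching d, and reduces to the classical d↔r conversion at equal n
(a = 4). Significance uses the two-sided equal-variance t-test;
Benjamini–Hochberg adjustment across the parameter family per comparison
is the default ("where required"), with an off switch. Cells failing
significance or |r| < 0.3 (Cohen's conventional moderate effect, the
"moderate effect size" filter; configurable) are masked as NaN plus an
explicit mask matrix — never numeric zero. Zero-variance degenerate
comparisons get p = 1 (equal means) or p = 0 (deterministic difference).
Mann–Whitney U and Kruskal–Wallis wrappers are provided for single-
parameter group comparisons; all-tied inputs return p = 1 where the
tie-corrected statistics are undefined. A pretest helper compares two
age groups per parameter and declares them poolable when at most one
parameter differs at α = 0.05.

## Differential proteomics

Normalization is per-sample median-centering in log2 space (standard for
label-free ratio tables; pluggable via the sample-column argument) after
removal of a user-supplied contaminant list. The per-protein log2 ratio
is the median over test replicates minus the median over reference
replicates; p-values come from two-sided equal-variance t-tests (Welch
behind a flag), q-values from BH across all tested proteins, and
regulation from the strict rule |log2 ratio| > log2 1.5 (the boundary
itself is unchanged). Upstream identification filters (unique-peptide
counts, 1% protein FDR) are properties of the search pipeline and are
accepted as optional input columns, not recomputed. Overlap counts are
exact set intersections by protein id per direction; function-class
summaries are regulation × class contingency tables with an
`unassigned` row.

## Synthetic data: what it emulates and what it does not

*Frames* are overlapping disks with clustered centers (70% clustered,
30% uniform) on a flat background, plus an additive vertical sinusoidal
stripe, a smooth tilted-plane gradient, and Gaussian noise, at either
polarity. Disks are stamped until the target coverage is reached, which
keeps realized coverage within ±2 points of target (mean deviation
≤ 1 point over seeds) and makes the exact mask available. Not emulated:
sub-resolution platelet texture, partial-volume edges, optical blur,
out-of-focus fibrin strands, multi-layer (3-D) thrombi, or correlated
camera noise. Passing the recovery benchmarks therefore shows that the
pipeline's segmentation logic is unbiased on well-separated bimodal
images with the modeled artifacts — not that it reaches any particular
accuracy on real micrographs, where threshold and offset tuning against
reference images remains the operator's task.

*Kinetic curves* are piecewise-linear ramp-to-plateau with additive
noise, so the steepest-window slope and onset are analytically known;
real curves are smoother and can re-enter the window after plateau.

*Cohorts* draw parameters from latent Gaussians shifted by
d × baseline SD in non-reference groups; ordinal parameters are snapped
to their score grid, which slightly attenuates planted effects at the
scale edges. Defaults: 15 runs/group, reference baselines on native
scales.

*Proteomes* default to 1,533 proteins, 4 replicates/group, replicate
noise 0.2 log2 units, 9% up- and 9% down-regulated with effects drawn
uniformly from (0.9, 1.5) log2 units — strictly beyond the 1.5-fold
boundary, as the planted-truth contract requires.

## Problem sizes and numerical conventions

Benchmark fixtures are 256 × 256 px (the pipeline itself defaults to
full 1360 × 1024 frames); the recovery suites use 20 seeded fixtures at
coverages {5, 15, 25, 40}%, the FDR calibration uses 1,000 global-null
1,533-protein tables, and the proteome recovery uses 50 seeded tables —
sizes at which every benchmark statistic is stable to well within its
acceptance margin. Ties and boundaries: threshold foreground is strictly
above threshold; the fold-change boundary is exclusive; slope-window
endpoints are inclusive; BH uses the standard step-up with monotone
q-values. All generators use `numpy.random.default_rng` with explicit
seeds; every CSV/TSV output embeds the configuration hash, package
version and seed, and repeated runs with one seed are byte-identical.

## Known limitations

- The bandpass kernel mimics the *semantics* of the ImageJ tool
  (suppress structures larger than the cutoff), not its exact kernel;
  absolute %SAC values can differ from ImageJ output at the margin.
- Manual morphological/contraction/multilayer scoring is an input, not
  automated; the score validator only enforces scales and increments.
- The effect-filtered heatmap inherits the t-test's equal-variance
  assumption; strongly heteroscedastic parameters should use the Welch
  or nonparametric paths.
- Censored fibrin onsets are fixed at the window end rather than treated
  by survival methods; with many censored runs Pc group means are
  conservative.
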