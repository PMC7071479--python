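# Methods

## Fluorescence quantification model

The pipeline treats a double-labelled section as a pair of equal-shape 8-bit
rasters: red = LMTK2, green = phospho-tau (AT8). Segmentation operates on a
merged gray image, `gray = round((red + green)/2)` with half-up rounding.
The divisor 2 (rather than the 3 an RGB average with an empty blue channel
would use) keeps the merged intensity scale comparable to a single
channel's; a `mean3` merge rule is retained as an option. Merging before
thresholding is what makes the area filter insensitive to which of the two
proteins dominates a soma: a cell that is nearly all red and one that is
nearly all green have the same merged brightness when their summed signal
is the same.

Thresholding is Otsu by default. The original workflow used manually
adjusted values that are not recorded anywhere, so a `fixed` mode stands in
for manual adjustment; the chosen value is logged either way. The mask is
`gray > t` (strict). A constant image has no Otsu threshold and is reported
as a degenerate input rather than guessed at.

Connected components use 8-connectivity by default (4 is available); the
area filter keeps components with pixel area **strictly greater than
400** — a 20×20 square is excluded, a 21×21 square kept. Labels are ordered
by first pixel in a row-major scan. No hole filling or morphological
cleanup is applied, and none is claimed.

Measurement is *redirected*: sums of the original channel values over the
mask-derived pixel set (raw integrated density, identically area × mean).
Per ROI,

    R = red/(red+green),  G = green/(red+green),  X = (R − G)/(R + G).

`R + G = 1` for every measurable ROI and `X = 2R − 1`, so the three columns
are affinely equivalent. In particular **Spearman ρ(R, G) = −1 within any
group with at least two distinct R values: this is an identity of the
normalization, not a biological result.** The package reproduces the
perfect negative per-group correlation for exactly this reason and the
test suite asserts it as a construction-level invariant. A ROI with zero
total signal has no defined R, G or X; it is flagged and excluded from
statistics with a logged count, never silently dropped, so pair counts stay
honest. No background subtraction or bleed-through correction is applied
(the original protocol quenched autofluorescence chemically and describes
no computational correction).

Group tables report pooled per-ROI Spearman ρ and p, means of R, G and X,
their standard deviations, `se = sd_R/√n` and the pair count. The source
tables print a single SD/SE per group without naming the column; we report
all three columns' SDs. Spearman p-values are computed without any
reporting floor: an exact two-sided permutation enumeration for n ≤ 9
(there is no established exact option to delegate to) and the usual
t-approximation otherwise, so ρ = −1 at thousands of pairs genuinely
underflows to 0 rather than being clamped at a smallest printable value.
ρ itself is the Pearson correlation of midranks evaluated in exact integer
arithmetic (doubled midranks are integers), which is why perfectly
anti-monotone data yield exactly −1.0 rather than a float one ulp away.

## Synthetic virtual slides

The generator emulates what the analysis needs and nothing more: bright,
non-overlapping filled disks (neuron somata) on a dark background. Disks
are the simplest shape with an exact area oracle; the protocol never
describes soma shape. Per cell:

* radius uniform on `cell_radius_px_range` (default 13–18 px, comfortably
  above the 400 px area cut at the default image scale);
* total above-background signal T uniform on `total_intensity_range`
  (default 128–220 counts; the lower bound keeps rounding error below
  1/255, see below);
* red fraction f from a truncated normal on [0, 1] with standard deviation
  `red_fraction_sd` whose **location is solved (Brent) so the truncated
  mean equals `mean_red_fraction` exactly**. Plain truncation of
  N(ρ, σ) to [0, 1] would bias the realized mean toward 0.5 by up to ~0.09
  at the extreme group (ρ = 0.946), breaking parameter recovery; the
  mean-preserving parameterization keeps the group parameter interpretable
  as the true expected red fraction. A mean of exactly 0 or 1 is only
  allowed with zero spread.
* in-disk values: `red = background + round(f·T)`,
  `green = background + (T − round(f·T))`, so the above-background sum is
  exactly T — the invariable-sum assumption built in at the pixel level.
  With no noise, the measured in-disk fraction after background subtraction
  equals f within 1/255 (error ≤ 0.5/T ≤ 0.5/128).

Gaussian read noise (default sd 2 counts) is added everywhere, rounded and
clipped to [0, 255]. Placement is rejection sampling with a 1000-attempt
cap per cell ("image too crowded" otherwise); centers are kept more than
`r_i + r_j + 3` apart so rasterized disks (which extend r + 0.5 from the
center off-axis) are never even corner-adjacent — each planted cell is
recovered as exactly one connected component. Default background is 2
counts: since the measurement stage performs no background subtraction,
background pulls recovered R toward 0.5 by ≈ (ρ − 0.5)·2b/(T + 2b) ≈ 0.01
at b = 2, small against the ±0.03 recovery tolerance the tests use. All
randomness flows from `numpy.random.default_rng(seed)`; identical configs
give bitwise-identical images.

Group defaults are the four study conditions: mean red fractions
0.946 / 0.349 / 0.273 / 0.215 with per-ROI SDs 0.087 / 0.233 / 0.237 /
0.159 (control group first). The number of cells per field is a free
parameter (default 25) — the source protocol does not state field density.

What the generator does **not** emulate: point-spread optics, neuropil
texture, autofluorescence, touching or overlapping somata, chromatic
bleed-through, and DAB color chemistry (the chromogenic arm is simulated at
the score level, not the pixel level). Passing tests therefore demonstrate
that the *computational pipeline* is correct and calibrated under its own
stated assumptions, not that those assumptions hold on real tissue — in
particular the forced ρ = −1 says nothing about biology on any data.

## Chromogenic cohorts

Per-neuron scores are i.i.d. draws from a 4-point distribution over
{0, 1, 2, 3}; ten fields per case, default 300 neurons per case (≈30
scoreable neurons per 400× field, a typical cortical density). The
four-group cohort generator assigns each case a target mean evenly spaced
across its group's observed per-case range (defaults: 2.13–2.92 control,
1.07–1.70, 1.22–1.81, 1.00–1.55 for the NFT-affected groups) and draws
neuron scores from the two-point distribution on adjacent integers with
that mean, so realized case means scatter tightly around targets spanning
the whole range. Case means are averaged per case first, then unweighted
into group means.

The optional intensity auto-scorer counts cut points strictly below the
mean optical density (ties take the lower score; cut points must be
strictly ascending). The original scoring is visual, so cut points are user
configuration, not calibrated constants, and the pre-scored input path is
primary.

## Statistical plan

* **Normality gate**: Shapiro–Wilk at α = 0.05 (n ≥ 3, non-constant). The
  parametric path is used where it passes (chromogenic case means); the
  fluorescence proportions fail it and go to Spearman.
* **Six pairwise pooled-variance two-sided t-tests** in a fixed order:
  control vs each NFT-affected group, then NFT-affected pairs. No
  multiplicity correction by default, matching the original plan; Holm is
  available behind a flag.
* **ANCOVA**: OLS of case mean score on stage + region (categorical) plus
  age, final MMSE and APOE, with type-II F tests per term. APOE enters as
  ε4 allele count (0/1/2) by default — genotype strings such as "ε3–ε4"
  parse directly — with a one-hot genotype coding as the documented
  alternative. Cases with missing covariates are dropped listwise and their
  ids logged; constant covariates are reported as inestimable rather than
  silently absorbed; rank deficiency is flagged. The response is case-level
  (one row per case), matching the design's n.
* **Calibration**: the null simulation used to check ANCOVA size draws case
  means as group mean + Gaussian noise (sd 0.25) with covariates drawn
  independently, because under normal errors the covariate F-tests are
  exactly calibrated — the ≈5 % rejection check then tests the
  implementation, not central-limit slack. The discrete neuron-score
  generator is used everywhere the *effect* structure matters.

## Problem sizes and numerical choices

The test suite exercises: forced-correlation and worked-value checks at
~10–40 ROIs per group; parameter recovery at 2000 ROIs per group (80
simulated fields of 25 cells); the group-separation replication at 200
seeds × 20 cases × 300 neurons; ANCOVA calibration at 1000 replicates of a
20-case cohort. These sizes give Monte-Carlo error comfortably below the
asserted tolerances (recovery ±0.03 against a sampling SE ≈ 0.002 plus the
≈0.01 background bias; calibration bands at ±3 binomial SDs).

Fixed numerical conventions: half-up rounding in the channel merge; strict
inequalities for the threshold mask and the area filter; 16-bit TIFF input
rescaled to 8-bit by integer division by 257 (full-range linear); child
seeds derived from a master seed through `SeedSequence([seed, …indices])`
reduced mod 2³¹ so any stage can be re-run in isolation.

## Known limitations

Watershed splitting of touching cells is not implemented (the generator
never produces them; real tissue does). The chromogenic arm has no image
path — no color deconvolution or nucleus detection. Per-case numbers from
the original slides (group mean scores 2.59/1.28/1.43/1.24, the printed
group signal tables) are functions of that material and are *not*
reproduced numerically; the package reproduces their structure: group
ordering, significance pattern, and the construction-forced ρ = −1.
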