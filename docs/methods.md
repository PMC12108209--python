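# Methods

## Ratiometric roGFP2 quantification

Oxidation of roGFP2's engineered cysteine pair raises fluorescence excited
near 405 nm and lowers it near 488 nm, so the excitation ratio
`R = I405/I488` reports the sensor redox state independently of expression
level. Bracketing `R` between the fully reduced ratio `R_red` (10 mM DTT)
and the fully oxidized ratio `R_ox` (20 mM H2O2), the degree of oxidation is

    OxD = (R − R_red) / [ f · (R_ox − R) + (R − R_red) ],   f = I488_red / I488_ox,

and the Nernst equation maps OxD to the glutathione redox potential

    E_GSH = E0 − s · log10((1 − OxD)/OxD),   s = 1000 · ln(10) · R · T / (z F).

Defaults: `E0 = −272 mV`, `R = 8.315 J K⁻¹ mol⁻¹`, `T = 298.15 K`, `z = 2`,
`F = 96485 C mol⁻¹`, giving `s ≈ 29.58 mV`. These are exposed on
`RoGFPConstants` and loadable from config; note that −272 mV is a
convention-fixed midpoint and the temperature is kept at 298.15 K even where
a lab protocol quotes the midpoint at 30 °C — both are user-overridable
rather than silently reconciled.

**Intensity-factor orientation.** Both `f = I488_red/I488_ox` and its
reciprocal appear in the biosensor literature; both satisfy the boundary
conditions OxD(R_red)=0 and OxD(R_ox)=1 and differ only in the interior
curvature. The package's default is `I488_red/I488_ox` multiplying
`(R_ox − R)`; `invert_intensity_factor=True` selects the reciprocal. Under a
linear species-mixing model of the two sensor states, the reciprocal
orientation is the exactly self-consistent one; the synthetic generator is
therefore built to be exactly invertible under the *default* orientation
instead (see below), so the two conventions remain cleanly separated.

**Numerical choices.** Ratios outside `[R_red, R_ox]` — noise can push them
there — are clamped to the nearer endpoint and flagged (`ratio_clamped`)
rather than rejected, so batch processing survives. OxD is clamped into
`[ε, 1−ε]`, ε = 1e−6 by default, before the logarithm; passing `eps=None`
turns the clamp into a domain error. The closed-form inverse
`OxD(E) = 1/(1 + 10^((E0−E)/s))` is total and round-trips with the forward
map to better than 1e−12 across (0.001, 0.999).

## ROI quantification

ROIs are user-supplied circles in micrometers (the manual convention:
50 µm radius in the root proximal meristem, 150 µm mid-leaf); a pixel
belongs to an ROI iff its center lies inside the circle — simple and easy to
verify against brute-force enumeration. The biosensor ratio is formed from
background-corrected ROI *means* (ratio of means), which is robust when the
488 channel runs low; a per-pixel ratio mode exists for comparison and
agrees exactly on uniform fields. Background handling is deliberately
explicit because acquisition software conventions vary: a user-supplied
background ROI per channel (the pipeline's default) or an explicit constant;
corrected means are floored at 0. Pixels at a stated saturation level are
excluded and flagged, since saturation biases ratios asymmetrically.
Dye intensities are reported as percent of the control-group mean
("control %"), which maps the untreated wild type to exactly 100.

## Synthetic data

**Biosensor scenes.** The generator emulates two-excitation confocal
imaging of a tissue with a known OxD field (uniform, left–right gradient, or
two-region). Per pixel, `I488` interpolates linearly between the calibration
intensities, `I488(OxD) = I488_red + OxD · (I488_ox − I488_red)`, and
`I405 = R(OxD) · I488` where `R(OxD)` is the algebraic inverse of the OxD
formula above. This is the minimal model consistent with the quantification
chain, and guarantees that at zero noise the pipeline (ROI means → ratio →
OxD) returns the ground truth exactly; that invariant is tested both in
memory and through TIFF files. Each scene ships with fully reduced and fully
oxidized calibration scenes rendered under the same noise model. Noise is
Poisson shot noise on the expected counts plus additive Gaussian read noise
(default sd 10 a.u. on a ~400 a.u. reduced-channel signal), clipped at 0.
What this does *not* emulate: real tissue morphology, optical sectioning,
chromophore pH sensitivity, bleaching, or spatially structured background —
so passing recovery tests demonstrates correctness of the computational
chain, not robustness to every imaging artifact.

**Phenotype tables.** Trait vectors per genotype × treatment cell are drawn
from a multivariate normal with a target correlation matrix; the
lateral-root count margin is a rounded, zero-floored Gaussian copula (chosen
over Poisson regression because it preserves the target correlation
structure the downstream analysis consumes); root lengths are floored at
1 mm, intensities at 0. Non-PSD correlation matrices raise; there is no
silent repair. The shipped preset covers a wild type plus eight mutant
genotypes under control, two salt and two osmotic treatments, 45 seedlings
per group (the phenotyping replicate regime; redox assays in practice use
far smaller n). Its correlation matrix is built from a two-factor loading
model — an oxidative-stress axis (ROS and superoxide up; vitality and root
growth down) plus a shared vitality factor pushing the shoot–root vitality
correlation to ≈ +0.9 — which is positive-definite by construction. The
shoot-ROS ↔ lateral-root-count loading is genotype-specific: zeroed for
three mutants, strengthened for three others, mirroring the qualitative
pattern such experiments report. Treatment and genotype mean shifts are
illustrative presets (e.g. salt raising root superoxide by 37–59 % in the
wild type, vitality dropping under stress), user-editable, and not fitted to
any dataset.

## Statistics

One-way ANOVA is computed from explicit sums of squares (the MSE and error
df feed the post-hoc test); the all-identical degenerate case reports an
undefined F with a flag instead of raising.

**Duncan's multiple range test.** For a span of `p` consecutive ordered
means the critical range is `q_{1−(1−α)^(p−1)}(p, df) · sqrt(MSE/n)`, with
the studentized-range quantile computed numerically
(`scipy.stats.studentized_range`) rather than from printed tables, so any
df is supported; values agree with published tables to 3 decimals at
α = 0.05, p = 2–5, df = 10 and 20. For unbalanced designs `n` is the
harmonic mean of all group sizes and a warning flag is raised. The stepwise
containment rule (a span is non-significant if any enclosing span is) makes
non-significance hereditary on intervals of the ordered means, which permits
an exact compact letter display: letters are assigned to maximal
non-significant intervals (insert-and-absorb; ties in means broken by group
label for determinism), and the letter partition reproduces the pairwise
decisions exactly — a property the tests verify against an independent
brute-force span-enumeration oracle. For `p = 2` the protection level is α
itself, so adjacent-mean comparisons coincide with an unprotected
studentized-range (t-type) test. No multiple-testing correction is applied
across traits; the test controls comparisons within one trait only.

**Correlations.** Pearson matrices are computed per genotype (pooling
treatment conditions within genotype, matching how such panels are usually
presented; an `overall` grouping is also available) with cells undefined —
never 0 — below 3 complete pairs or at zero variance. Note that pooling
treatments mixes within-group correlation with between-treatment mean
structure; with the preset's effects both components carry the same signs,
which is precisely the situation the pooled convention assumes.

## Pipeline

The CLI (`simulate`, `quantify`, `redox`, `stats`, `all`) is a thin layer
over the library; file-based runs equal in-memory composition of the module
operations. Redox tables report mean ± SD in mV to 2 decimals with Duncan
letters per organ (small-n convention for redox assays); phenotype reports
use mean ± SE and control %. Every CSV embeds the config hash and seed in a
`#` header, and reruns with the same config and seed are byte-identical.
Missing per-batch calibration is a hard error naming the batch.

## Problem sizes in the tests

The test-suite and acceptance-script sizes are chosen to exercise the
statistics at realistic scale while staying quick: 96×96 px scenes, 200
Monte-Carlo scenes for recovery-bias bounds, 100 random instances (k ≤ 6)
for the Duncan oracle equivalence, and 45 seedlings per group across 45
groups for the correlation-structure checks.

## Known limitations

- The redox chain assumes full sensor equilibration with the glutathione
  couple and a fixed 2-electron transfer; pH sensitivity and glutaredoxin
  kinetics are out of scope.
- ROI placement is manual by design; there is no segmentation or
  registration.
- The phenotype generator's effect sizes are illustrative presets; only its
  correlation *structure* is a tested contract.
- Duncan's test is used because it is the field's convention for these
  panels; it does not control the familywise error rate as strictly as
  Tukey's HSD, and users comparing many groups should interpret single
  isolated letter splits accordingly.
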