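# Methods

This note records the models behind each analysis stage, the defaults and
why, what the synthetic generators do and do not emulate, and the design
choices made where the methods literature leaves the procedure open.

## Rotating-disc rheometry

**Model.** A disc of radius R (default 0.020 m) spins in a large bath of
water (ρ = 998 kg/m³, ν = 1.0×10⁻⁶ m²/s — 20 °C values) through a ramp
ω ∈ [0.1, 300] rad/s. For a clean disc, von Kármán similarity gives the
one-sided moment coefficient C_m^s = 1.935 Re^(−1/2) (laminar, Re ≤ 3×10⁵,
boundary inclusive) or 0.0365 Re^(−1/5) (turbulent), Re = ωR²/ν. Over this
ramp Re ≤ 1.2×10⁵, so the flow stays laminar throughout. A fouled disc
shows C_m(ω) = T/(½ρω²R⁵) above that baseline; the biofilm momentum
coefficient is

    C_f = mean over ω ∈ [30, 300] of [C_m(ω) − C_m^s(Re)].

The top decade is used because at low ω the torque (∝ ω²) is tiny and the
excess is noise-dominated. The window is configurable; a measured
clean-coupon baseline can be substituted for the theoretical one by
analyzing a blank run and subtracting its C_m instead.

**Detachment events.** Torque grows smoothly with ω except when aggregates
shed, which produces step drops. The detector subtracts the full-run
least-squares line from T(ω) (baseline correction), takes first differences
of the corrected torque over Δω (a discrete first derivative), and flags
midpoints whose slope falls below median − k·(1.4826·MAD), k = 3 by
default. Median/MAD statistics keep the threshold stable under the
heavy-tailed slope distribution the smooth trend induces; consecutive
flagged midpoints are merged into one event at the most negative slope.
Events are therefore localized to one sampling increment. Small drops at
low ω are intrinsically harder to detect because the torque released scales
with ω²; this matches the physics, not a detector artifact.

**Critical detachment shear stress.** The first (lowest-ω) event is
converted to the laminar rotating-disc wall-shear magnitude at the disc
edge, τ = C·ρ·R·√(νω³) with C = √(0.616² + 0.510²) ≈ 0.800 (radial and
tangential wall-shear components combined). When no event is detected the
value is reported as missing, never as zero.

**AUC** is the plain trapezoidal integral of the recorded curve (raw
torque, not the transformed series).

## Uniaxial indentation

**Contact point.** The pre-contact baseline (mean and SD) is estimated from
the first 10% of samples; contact is the first sample whose force exceeds
mean + 5·SD and stays above for 10 consecutive samples. Both constants are
configurable; the sustained-run requirement suppresses single-sample noise
excursions.

**Substratum.** Local slopes are windowed least-squares fits (11 samples).
The reference is the first full post-contact window; the substratum is
where the local slope first reaches 20× the reference. If that never
happens (very stiff films, or a run truncated at the 15 N termination
load), the final sample is used and a warning logged, so every curve
remains analyzable.

**Modulus.** Engineering strain is (δ − δ_c)/h; stress is force over the
full flat-probe area πr² (the 8 mm probe is ~20× wider than the film, so
full contact is assumed). The fit is performed on force vs displacement —
not stress vs strain — restricted to 0–20% strain, because the modulus
relation consumes a stiffness in N/m:

    E = slope · (1 − v²) / (2r).

The (1 − v²)/(2r) form is the dimensionally consistent reading of the
flat-punch force-displacement relationship (N/m × m⁻¹ → Pa); v = 0.5
treats the hydrated film as incompressible. Moduli are carried in Pa
internally; the kPa column in reports is display conversion only.

## Interaction index

IAI_Arg = E_DZA/E_Arg, IAI_Zn = E_DZA/E_Zn, IAI = IAI_Arg + IAI_Zn;
synergism at IAI ≤ 0.5, antagonism at IAI ≥ 4, additive between. The
published rule assigns IAI = 4 to both the additive and antagonism classes;
this package resolves the overlap to antagonism (the explicit inequality)
and says so in the result metadata. Replicate-level summaries default to
matched pairing — the i-th biological replicate of each group forms one
triple, reflecting parallel discs treated per replicate — with
all-combinations (every cross-group triple) available as a sensitivity
analysis; neither aggregation is claimed to reproduce any particular
published replicate-level value, since the published aggregation across
4 biological × 3 technical replicates is not specified.

## Image quantification

Channels are binarized with Otsu's threshold over the whole 3-D histogram
(reproducible without an operator; a `fixed:<value>` override exists, and
boolean stacks pass through). Biomass is thresholded biovolume per
substratum area. Column height uses the top-most occupied voxel per (y, x)
column — gappy columns count their full envelope height, the COMSTAT
convention — and empty columns enter the roughness denominator with height
0. Ra = Σ|h_i − h̄|/(N·h̄) is scale-invariant and 0 for a uniform layer.
Connected-volume filtering is not applied.

## Synthetic data

The generators emulate the instruments' outputs, not the biology:

* **Torque curves**: 72 log-spaced ω points over [0.1, 300] rad/s mapped to
  a 360 s ramp; T = ½ρω²R⁵·(C_m^s + C_f)·(1 + ε) with multiplicative
  ε ~ N(0, 1%) by default (torque ripple scales with load). Detachment is a
  piecewise-constant fractional drop in C_f at the event ω.
* **Indentation curves**: zero-force baseline, linear film compression with
  k = 2rE/(1 − v²), then a 50× stiffer substratum branch, truncated at the
  15 N termination load; additive force noise with SD equal to 2% of the
  force at 20% strain. Default thickness 200 µm (SD 20 µm), contact offset
  40–60 µm.
* **Stacks**: 40×64×64 voxels at (1.0, 0.5, 0.5) µm — a deliberately
  scaled-down field with canopy heights around 20 µm so grids stay small;
  all reported quantities are per-area or dimensionless, so the scale
  cancels. Cells: lognormal per-column heights filled from the substratum.
  EPS: either a uniform layer of set volume-per-area, or punctate columns
  covering a set fraction of the field with lognormal heights matched to
  the same expected volume.

The default four-group study uses the reported group parameters: moduli
(kPa) 27.28 ± 8.68 (untreated), 15.38 ± 7.97 (arginine), 11.14 ± 5.02
(zinc), 9.29 ± 2.87 (DZA), truncated below at 0.5 kPa; momentum
coefficients 0.063 ± 0.021 (untreated), 0.053 ± 0.023 (zinc),
0.037 ± 0.023 (DZA). The arginine group was not assayed by rheometry, so
it is assigned an intermediate 0.055 ± 0.023; ordering checks use only the
three measured groups. Detachment-event locations (150 / 100 / 80 / 40
rad/s, SD 15, drop fraction 0.4) and EPS geometry (layer for untreated;
punctate at coverage 0.6 / 0.5 / 0.3 with decreasing volume for arginine /
zinc / DZA) are the package's own choices mirroring the reported
qualitative directions. Replicates are drawn independently — real
replicate-to-replicate correlation structure is unknown and not modelled.
All draws derive from one seeded generator; identical spec + seed gives
bit-identical output.

**What passing tests show.** Recovery tests prove the analyzers invert the
generators under instrument-like noise; they do not certify performance on
real exports, whose noise is not Gaussian, whose films creep
viscoelastically during approach, and whose detachment need not be an
instantaneous drag drop.

## Statistics

Metrics are averaged over technical replicates to one value per biological
replicate before testing (the biological replicate is the experimental
unit; configurable). Groups are compared by one-way ANOVA with Tukey HSD
adjusted pairwise p-values; unadjusted pairwise p-values from the pooled
residual mean square are reported alongside, and are never above the Tukey
values. α defaults to 0.05.

## Problem sizes and known limitations

The acceptance suite runs 50-seed recovery grids, 100-seed event
localization, 50 paired stacks, and 100 generated studies (stacks skipped
where they feed no metric) — a few seconds end to end. Under the default
group parameters the four-group mean-modulus ordering
(untreated > arginine > zinc > DZA) holds in 86% of studies at the fixed
seed range; the three-group momentum-coefficient ordering
(untreated > zinc > DZA) holds in 73% — the group Cf distributions overlap
heavily (SDs 0.021–0.023 against mean gaps of 0.010–0.016 with four
coupons per group), so a per-study ordering is genuinely uncertain, and
single-study orderings of adjacent groups should not be over-read.
Other limitations: no viscoelastic (creep/oscillatory) rheology, no
Hertzian/adhesive contact mechanics, no instrument-binary file formats,
and no confocal PSF or noise modelling.
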