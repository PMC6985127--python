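# Methods

## Dose-response models

The organ equivalent dose (OED) reduces an inhomogeneous organ dose
distribution to the uniform dose with equal second-cancer induction risk.
All four models operate on a differential DVH with bin-center doses D_i,
bin volumes V_i and total volume V_0 = Σ V_i; they agree with the linear
model (mean dose) in the low-dose limit.

The mechanistic model's per-dose response is implemented in the combined
form

    f(D) = [ (1 − 2R) e^{−α′D} + R² − (1 − R)² e^{−α′D/(1−R)} ] / (α′R)

which is algebraically identical to the textbook product
`e^{−α′D}/(α′R) · [1 − 2R + R² e^{α′D} − (1−R)² e^{−α′R D/(1−R)}]` but
avoids evaluating `e^{+α′D}` (overflow-prone at high dose) and makes the
limits transparent: f(0) = 0 and f(D)/D → 1 as D → 0.  The leading
exponential multiplies the whole bracket; an additive reading of the same
expression diverges as α′ → 0 and is rejected on that ground.  R → 0 and
R → 1 are removable singularities; parameters are restricted to 0 < R < 1
rather than special-cased.

α′ applies to the total accumulated dose per bin with no extra
fraction-number correction: the shipped coefficients come from fits that
already fold fractionation (α/β = 3 Gy) into α′.  Registry defaults:
breast α′ = 0.041 (linear-exponential), 0.115 (plateau), 0.044 with
R = 0.15 (mechanistic); lung 0.022, 0.056, and 0.042 with R = 0.83.

## Excess absolute risk

EAR = OED · β′ · exp[γ_e(agex − 30) + γ_a ln(agea/70)], per 10,000
person-years.  β′, γ_e, γ_a are population parameters that are not uniquely
fixed by the dose data; the packaged defaults (breast β′ = 8.2,
γ_e = −0.037, γ_a = 1.7; lung β′ = 8.0, γ_e = 0.002, γ_a = 4.23) are
Schneider-style site-specific values from combined atomic-bomb/Hodgkin
fits.  They live in `data/risk_parameters.yaml` and are user-replaceable;
every EAR is therefore meaningful primarily in ratios and orderings, not as
an absolute incidence prediction.  The pipeline reports EAR under two age
policies: actual age at exposure with attained age 70, and the normalized
policy agex = 30 / agea = 70 that removes cohort age variability (the two
differ by the exact factor exp[γ_e(30 − agex)]).

## DVH conventions

* Uniform bins, default width 0.05 Gy — fine relative to the 2 Gy fraction
  scale; OED quantization error is bounded by half a bin width (verified
  against brute-force voxel sums).
* Bin centers represent D_i in all dose-weighted sums (midpoint rule,
  standard TPS export convention).
* V_x ("volume receiving more than x Gy") counts bins whose center exceeds
  x; reported in % of V_0 by default, cm³ on request.
* D_y interpolates the cumulative curve sampled at bin centers and returns
  the infimum dose at which the volume-at-or-above drops below y%.  This
  makes D_2 = D_50 = D_98 (and HI = 0) exact for a uniform-dose organ, and
  D_100 the minimum organ dose.
* Cumulative DVHs carry all n+1 bin edges and end at zero volume, so
  differential ↔ cumulative conversion is lossless.
* Grid reduction uses one bin more than max-dose/width so the hottest voxel
  never sits on the ambiguous top edge; V_0 equals masked voxel count ×
  voxel volume exactly.
* Masks are inclusive binary; partial-volume weighting is below the
  method's precision and out of scope.

## Setup-error model

A systematic setup error displaces the patient identically in every
fraction.  With the fluence unchanged, the dose distribution is — to the
accuracy relevant for risk ratios — rigid relative to the beams, so the
simulation translates the dose grid against the fixed anatomy (trilinear
resampling, nearest-edge extension outside the grid; zero-fill available).
This rigid-translation approximation replaces a TPS dose recomputation; it
is exact for the translation-invariant part of the field and is the central
modelling approximation of the module.  The default scenario set is ±5 mm
along each cardinal axis (six scenarios, the reported setup-error scale for
breast treatments); the worst case per organ/model is the scenario with the
largest |OED change|, reported with Δ% = (post − pre)/pre × 100.  Random
(per-fraction) errors average out over a course and are deliberately not
modelled.

## Synthetic cohort generator

The generator emulates the *structure* of planning-study data, not beam
physics.  Geometry: a 300 × 300 × 200 mm chest volume (2.5 mm isotropic
default spacing; coarser grids over the same volume are supported), with a
breast PTV ellipsoid, the CB placed so its nearest surface sits the
configured distance (1–4.5 cm) from the medial field edge, posterior lung
boxes (IL adjacent to the field, CL far from it), and a heart ellipsoid;
per-patient size jitter ±5% per semi-axis; right-sided cases mirror the
lateral axis.

Dose model, relative to the 50 Gy prescription, with r the distance (mm) to
the PTV surface:

    in-field:  N(1, σ_t)
    out-field: s_t · e^{−r/12} + f_t · e^{−r/150}, × (1 + 0.05 ε)

a steep "patient scatter" term (12 mm length) plus a shallow "head leakage"
term (150 mm length).  The leakage term decays gently rather than being
strictly constant: a perfectly flat floor would make the wedged-tangent
plan's contralateral-breast dose distance-independent and its setup-error
sensitivity exactly zero, while the techniques whose out-of-field dose it
dominates would lose any shift response in far organs — both contrary to
the behaviour the cohort analysis is meant to exhibit.  A 150 mm decay
keeps the term floor-like over organ scales while preserving a small,
shared spatial gradient.

Preset constants (fixed once; σ = in-field SD, s = scatter amplitude,
f = leakage amplitude):

| technique | σ     | s     | f     |
|-----------|-------|-------|-------|
| W-TF      | 0.030 | 0.010 | 0.010 |
| 2F-IMRT   | 0.025 | 0.120 | 0.002 |
| 6F-IMRT   | 0.018 | 0.130 | 0.011 |
| VMAT      | 0.012 | 0.140 | 0.020 |

These encode: leakage ordered 2F-IMRT < W-TF ≤ 6F-IMRT < VMAT (leakage
grows with monitor units and field number; tangential IMRT without wedges
is cleanest), and in-field heterogeneity ordered VMAT ≤ 6F-IMRT ≤ 2F-IMRT ≤
W-TF (arc and multi-field optimization homogenize the target).  The
wedged-tangent preset is leakage-dominated with a small steep-scatter
amplitude — its diffuse out-of-field dose (wedge-scatter-like) is what
makes W-TF the least sensitive to setup error while its contralateral dose
stays between 2F-IMRT and 6F-IMRT at the cohort median.

One seed per patient drives the noise field of all four technique grids, so
technique contrasts are paired.  Cohort composition defaults: 26 patients,
distance groups G1:G2:G3 = 4:5:4 (8/10/8 by largest remainder), left:right
= 1:1 within each group, ages uniform on 30–50 years.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: tangential beam paths through the ipsilateral
lung (synthetic IL doses are near-field scatter only, far below the tens of
Gy a real IL receives, so absolute IL risks are not comparable); wedge
Compton-scatter physics; realistic hot/cold-spot spatial correlation (noise
is voxel-independent); heart substructures; respiratory motion.  Only
orderings, distance trends and sensitivity contrasts are meaningful, which
is what the acceptance checks assert.

## Statistics

Paired technique contrasts use the Wilcoxon signed-rank test (exact null
distribution for n ≤ 25, normal approximation beyond; ties with an
all-zero difference vector report p = 1).  Distance-group contrasts use
one-way ANOVA with Levene's test reported alongside as the
variance-homogeneity pre-check.  Significance is read at P < 0.05 with no
multiple-testing correction (flagged in the report metadata); lateralities
are pooled, with laterality recorded per patient.  These are standard
procedures called from scipy.stats — the package's contribution is the risk
model layer, not the inference machinery.

## Problem sizes and numerical choices

Cohort-scale analyses in the test suite and the acceptance script run the
phantom at 5 mm spacing (60 × 60 × 40 voxels over the standard volume) —
organ means aggregate thousands of voxels, and the qualitative results are
resolution-stable, so the finer 2.5 mm default is reserved for
single-patient work.  The technique-ordering check aggregates 20
independent cohort seeds.  DVH quantization: OED tolerance half a bin
width; the gradient-shift identity is checked at 10⁻⁴ Gy bins.  Degenerate
inputs (empty masks, zero total volume, zero baseline EAR, shifts beyond
the grid) raise errors rather than returning sentinel values.

## Known limitations

* Absolute EARs inherit the β′/γ registry choice; comparisons across
  parameter sets are not meaningful.
* The rigid-translation setup-error model ignores tissue-density changes a
  real recomputation would capture.
* The linear no-threshold question and ERR (relative-risk) models are out
  of scope; so are DVH interpolation schemes beyond linear and any beam or
  MLC modelling.
* No heart risk parameters ship by default (no robust α′/R for heart);
  heart DVH metrics and constraints are still evaluated.
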