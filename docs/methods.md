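# Methods

## Coordinate and acquisition conventions

All positions are in millimetres with the origin at bregma, *x* increasing
rostrally (anterior) and *y* toward the animal's left. Pixel (row *r*,
col *c*) has its centre at `field_origin + ((c+0.5)·px, (r+0.5)·px)` where
`field_origin` is the posterior-right field corner and `px` the pixel size
(0.1 mm/px in the presets). An acquisition is 61 frames at 1 frame/min
(*t* = 0…60 min), the first frame recorded 15 min after the end of tracer
infusion (`t0_offset`). Stacks are stored as 16-bit multi-page TIFF with a
JSON sidecar carrying the physical metadata; writing rejects out-of-range
intensities rather than clipping, and censored values are written as empty
cells with an explicit flag, never sentinels.

## Transport model

The generator evolves a tracer amount field *c* (per pixel) on the imaging
plane by

    ∂c/∂t = D ∇²c − ∇·(v c) − λ c

with zero-flux boundaries. The initial condition is an isotropic Gaussian
bolus (total `bolus_amount`, width `bolus_sigma`) at the injection site;
the plume evolves for a `pre_roll` (default 15 min, matching the imaging
delay) before frame 0 is recorded. Recorded intensity is
`gain·c + background + N(0, σ_noise)`, clipped at zero — constant
autofluorescence plus additive camera read noise.

The velocity field is piecewise constant over the anterior (*x* > 0) and
posterior (*x* ≤ 0) halves of the field. This is the minimal flow model
that exposes exactly the quantities the ROI statistics claim to detect —
directional bulk transport superimposed on diffusion — while remaining
fully checkable against closed forms.

**Assumptions and what the generator does not emulate.** The model is
two-dimensional (no depth integration or skull scattering), the flow is
stationary and piecewise constant (no paravascular anatomy, no pulsatility),
noise is additive Gaussian (photon shot noise omitted) and the bolus is
deposited instantaneously (no ventricular reservoir slowly releasing
tracer). Passing tests therefore demonstrate that the *measurement chain*
recovers known transport differences; they say nothing about whether real
glymphatic flow follows this PDE.

## Integrator

Operator-split explicit stepping: flux-form upwind advection (face
velocities averaged from the adjacent cells, boundary fluxes zero),
flux-form FTCS diffusion, then exact exponential decay. Both spatial
updates are written as antisymmetric face exchanges, so tracer mass is
conserved to machine precision under zero-flux boundaries; the discrete
diffusion update grows each axis's second moment by exactly `2·D·dt` per
step, which is why the pure-diffusion run tracks the Gaussian spread law
`var(t) = σ₀² + 2Dt` to well under 1% before boundary contact.

The substep length is derived from the configuration (never user-set) to
keep the diffusion number `D·dt/px²` ≤ 0.2 per axis and the advective
Courant number ≤ 0.8; configurations whose bound would require more than
2×10⁶ substeps are rejected with a configuration error. Upwind advection
adds numerical diffusion of order `v·px/2`; at the preset velocities
(≤ 0.08 mm/min) and 0.1 mm pixels this is ≤ 0.004 mm²/min, small against
the preset diffusivity of 0.025 mm²/min.

## Condition presets

The paper-scale literature gives no intracerebral flow magnitudes, so the
preset velocities are calibration choices, documented as such. Both
presets share every parameter except the velocity field:

| parameter | value |
|---|---|
| grid | 64 × 128 px, 0.1 mm/px, field x ∈ [−6.4, 6.4], y ∈ [−3.2, 3.2] |
| injection site | (−1.6, −1.3) mm (1.6 mm posterior, 1.3 mm right-lateral of bregma) |
| bolus | 2×10⁵ AU, σ = 0.6 mm |
| diffusivity | 0.025 mm²/min |
| decay | 0.002 /min |
| background / noise | 10 AU / 1 AU (1-σ read noise) |
| sham flow | anterior half (0.08, 0) mm/min; posterior half (0.01, 0) |
| TBI flow | anterior half (0.03, 0); posterior half (−0.03, 0) |

The sham field is anterior-directed everywhere — brisk rostral to bregma,
slow caudal to it, so the plume lingers near the injection level and keeps
feeding the periventricular regions by lateral diffusion. The injured
field suppresses anterior transport and drains the posterior half
caudally. This is the smallest velocity contrast we found that yields the
full directional pattern (later FC/APC appearance, earlier PPC appearance,
lower APC/LLV slopes after injury) with every ROI still crossing its
appearance threshold inside the 60-min window; a uniform fast sham flow
cannot reproduce the slope pattern, because two-dimensional dilution makes
every near-field ROI decay regardless of flow direction.

Cohorts default to 14 sham and 12 injured animals with an inter-animal
coefficient of variation of 0.15 applied as independent unit-mean
lognormal factors on the diffusivity and on the velocity magnitude — a
typical between-animal spread for transport-rate parameters in small
rodent cohorts. Sub-seeds derive from `(cohort seed, animal index)`, so
enlarging a cohort never changes existing animals' data.

## ROI layout

* IS at the injection site; LLV its mirror across the rostro-caudal
  midline through bregma (the contralateral homologue; with the 1.3-mm
  lateral infusion offset this reproduces the 2.6-mm IS–LLV separation
  exactly).
* APC and PPC 2.6 mm anterior/posterior of LLV (centre-to-centre by
  default; a `spacing_mode="edge"` switch measures the 2.6 mm between
  circle perimeters instead, since the verbal description admits both
  readings).
* FC on the IS–LLV midline, +4.5 mm rostral of bregma.
* The 0.1-mm background circle is placed deterministically at whichever
  field corner maximises clearance to the analysis circles.

Rasterization is pixel-centre-in-circle with 0-based indices; masks are
exact under whole-pixel translation and converge to the analytic circle
area as the pixel size shrinks.

## Kinetic statistics

* **Normalized intensity** divides ROI by background mean frame-by-frame
  and raises on any non-positive background value (no silent epsilon). It
  is exactly invariant under global intensity rescaling.
* **Intensity/time** is ordinary least squares over the whole window; no
  plateau trimming, since the acquisition protocol defines no sub-window.
* **Appearance time** reports the first *sampled* time with signal ≥ 1.1 ×
  baseline (inclusive, with a 10⁻¹² relative slack absorbing the
  representation error of the threshold product). No sub-frame
  interpolation: at 1-min sampling, interpolating would invent precision.
  The baseline is the ROI's own first-frame mean by default — the reading
  that binds "for a particular ROI" to the ROI itself — with a
  `baseline_mode="background"` switch for the alternative (global
  background circle at *t* = 0). A never-crossing series is *censored*:
  reported as missing-with-flag and excluded from parametric comparisons
  with the exclusion count carried into the results, since any imputation
  of a latency beyond the window would be invented data.
* Slope and appearance time are computed on the raw mean-intensity series
  (normalization belongs to statistic 1 only); `rate_on_normalized=True`
  switches the slope to the normalized series.

## Group statistics

* **ROUT** (univariate form): the regression model degenerates to a robust
  location fit — centre = median, scale = robust SD of residuals (RSDR),
  estimated as the 68.27th percentile of absolute residuals with the
  small-sample correction n/(n−K), K = 1. Candidates are tested
  largest-residual-first against a two-tailed t threshold (df = n−1) at
  the step-down level Q·(n−i+1)/n, stopping at the first non-significant
  candidate. Q defaults to 1% (the method's published default; applied
  per ROI, per metric, per condition). Measured on clean normal samples
  (n = 20): ≈ 0.9% of points falsely flagged; a planted 8-SD outlier is
  caught in ≈ 100% of replicates.
* **Welch's t-test**: closed-form t and Welch–Satterthwaite df, two-sided
  p. Two zero-variance samples with equal means give p = 1 by convention;
  with unequal means, p = 0.
* **Two-way ANOVA**: statsmodels OLS with type-II sums of squares
  (identical to other types on balanced data); terms with zero sum of
  squares (constant data) report F = 0, p = 1. Post hoc comparisons of
  conditions within each level of the second factor use the residual mean
  square, Šídák-adjusted over the number of comparisons, or Tukey HSD on
  the studentized range with the full family of cell means
  (Tukey–Kramer form under imbalance).
* **Nested one-way ANOVA**: condition tested against the between-animal
  (within-condition) mean square, making F exactly invariant under
  within-animal duplication — pseudo-replication cannot manufacture
  significance. Tukey post hoc runs on animal-level means.
* **Per-ROI condition comparisons** (`compare_conditions`): censored
  exclusion → ROUT per condition → Welch; both raw and Šídák-adjusted
  (across ROIs) p-values are reported, as it is ambiguous whether such
  families are adjusted in practice; groups shrinking below two values are
  reported as not computable rather than dropped.

## IHC quantification

`CTF = integrated density − area × mean(background)` with user-supplied
region and background masks (background placement cannot be inferred from
a stained section; the synthetic fixture supplies one). CTF is exactly
offset-invariant and gain-linear, and negative values are preserved.
Hemispheres are averaged per (section, coronal level, region) — giving
three measures per brain per coronal section — and per-animal means over
sections are also exported, since pooling conventions differ between
analyses; the nested ANOVA is the appropriate test when sections stay
disaggregated.

## Reproducibility and problem sizes

Every stochastic step takes an explicit seed; a pipeline run writes a
manifest with the seed and a hash of the scientific configuration, and
rerunning reproduces all tables byte-identically. The shipped test suite
and the acceptance script use desk-scale sizes chosen to exercise each
property well inside statistical resolution: full cohorts of 14 + 12
animals at 61 frames on the 64×128 grid (≈ 6 s end to end), 10⁴ replicates
for the ROUT calibration, 10³ random datasets per closed-form oracle
check, and 100 random injection sites for the geometry invariants.

## Known limitations

* The transport model is a single-compartment 2-D PDE; it cannot represent
  depth-dependent signal, ventricular reservoir release, or paravascular
  channel anatomy, and its preset velocities are calibration choices, not
  measured physiology.
* Appearance times are quantised to the frame interval, so group means
  inherit 1-min granularity.
* The acquisition protocol names four kinetic measurements but specifies
  three; only the three specified ones are implemented.
* Censored appearance times are excluded rather than modelled
  (no survival-style analysis of influx latencies).
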