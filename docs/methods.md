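# Methods

## The estimand and the estimator

Grazing intensity is cumulative livestock occupancy per unit area: one
yak·hour is the occupancy contributed by one yak present for one hour.
The estimator observes the herd as repeated aerial snapshots — one image of
all animals per grazed hour, on a random subset of days per month — and
converts each observed position into one yak·hour of mass spread over the
surrounding area by a unit-mass kernel.

The kernel family is triangular; in two dimensions we concretise it as the
radially symmetric cone

    K(d) = 3 / (π h²) · (1 − d/h)   for d < h,  else 0,

whose normaliser makes ∫∫ K dA = 1 exactly, so "the integral of a single
kernel is the grazing intensity produced by one yak over one hour" holds by
construction. The default bandwidth h = 300 m matches the reported hourly
activity radius of yaks; the package deliberately offers no bandwidth
selection — h is a biological scale here, not a smoothing parameter to
cross-validate.

A monthly surface is assembled as

    I_month(x) = (D / m) · Σ_{monitored days} Σ_{snapshots s} (G / n_s) · Σ_{yaks} K(‖x − x_yak‖)

where D is days in the month, m the number of monitored days (design: 4–8;
other values are accepted with a warning), G the grazing hours per day
(default 13) and n_s the number of snapshots that day (design: 12–14). The
weight G/n_s makes each snapshot stand for the hours it represents; the
adjustment factor A = D/m scales monitored-day totals to the full month.
The published scale-up equation this design follows is not reprinted in the
source describing the field campaign, so this reconstruction is the
simplest unbiased choice preserving yak·hour units: a stationary herd of N
animals monitored 4 of 30 days with 12 snapshots over 12 grazed hours
integrates to N·12·30 yak·hours, which the tests assert.

Numerical choices: kernels are evaluated at cell centres (midpoint rule) at
1 m default resolution; mass is conserved to well under 1% at that cell
size. Kernels centred within h of the grid edge lose the off-grid mass;
this truncation is documented, not silently renormalised (an explicit
`renormalize_boundary` option divides by the locally retained kernel mass).
For large point sets a binned path snaps positions to cells and uses FFT
convolution; the displacement is at most half a cell, negligible against
h = 300 m at the 10 m cells the virtual study uses.

## Survey geometry

Footprint width is S_w·H/(f·1000) with H in millimetres (and length
likewise with S_l), i.e. the pinhole ground-coverage formula. True focal
lengths are not printed by manufacturers (lens markings are 35 mm
equivalents), so the default camera profiles pair the common 1/2.3″ sensor
(6.17 × 4.63 mm) with focal lengths 3.61 mm and 4.30 mm chosen to reproduce
each airframe's field-validated coverage (≈35 × 26 m at 20 m; ≈2.9 × 2.1 m
at 2 m with ≈0.09 cm/px). Profiles are configuration, not code.

Waypoint layouts are even grids matching the route designs (Rectangle:
3 × 4 over 100 × 200 m at 20 m; Belt: 4 × 4 over 40 × 40 m at 2 m); the
original layouts are not drawn anywhere, only their counts are fixed.
Footprints are treated as axis-aligned (no heading data exists). Exclusion
rules: waypoints inside a 50 m fence buffer or a 150 m campsite buffer are
dropped; images whose footprint is covered ≥ 50% by riverbed are excluded
(ties exclude — near-half coverage is the documented reason for dropping
such images).

## The virtual pasture

The generator's defaults are the study conditions: a square 113.64 ha
pasture, 278 yaks, May–October, 4–8 monitored days per month, 12–14
snapshots per day, 13 grazing hours.

**Movement.** Hourly positions are drawn from a distance-decay field
p(x) ∝ exp(−dist(x, c)/λ) around the active concentrator c, truncated to
the pasture, with λ = 300 m. Two mechanisms make the monthly fields differ
from one another, as they do in the real system: the concentrator rotates
monthly among four night pens on a 150 m circle around the campsite, and λ
carries seasonal multipliers (0.7 in July/August, 0.85 in September)
reflecting the smaller foraging radius in peak growing season. Successive
hours are blended with weight ρ = 0.5 (persistence), and recorded positions
are pulled toward the pen at the day's edges (night penning). The
persistence blend and edge pull modify the marginal distribution, so the
uniformity limit (λ → ∞ gives uniform positions) holds for the raw field
draw and is tested with those features disabled.

**Deposition and decay.** Pats arrive as a Poisson process with rate
1 pat·yak⁻¹·h⁻¹ at the yak position plus 0.5 m Gaussian jitter clipped to
the pasture. No deposition or decay rate was measured in the field, so
these are free parameters with documented defaults, and the package's
guarantees are phrased as *recovery of configured values*, never absolute
levels. Decay is exponential at δ = 0.2 month⁻¹ (slow), multiplied by 3
inside the riverbed strip (washout); survival compounds correctly across
repeated monthly steps because each pat carries its last-checked time.
Dung density at month m is by default the standing crop — all survivors
since season start — matching the cumulative framing; a fresh-only mode
exists for sensitivity runs.

**Observation.** Detection probability is defined only at the two flown
heights (1.0 at 2 m, 0.9316 at 20 m); unknown heights are an error rather
than an interpolation. The footprint centre is displaced by a uniform draw
in a 2 m disc per visit (the upper end of the reported 1–2 m GPS drift).
False positives are a separate Poisson term, default 0: simulated accuracy
is detected-true-pats / true-pats, and false positives are tracked
separately because the field accuracy formula's treatment of them is not
stated. All randomness flows through named substreams (movement, plan,
deposition, decay, detection) of one seed, so a run is bit-reproducible
and stages can be re-run independently.

**What the generator does not emulate:** vegetation growth and occlusion
(the suspected cause of late-season zero counts), inter-annual carryover of
old dung, weather-driven decay heterogeneity beyond the riverbed
multiplier, and herder decisions. Passing tests therefore demonstrate the
pipeline's internal consistency and statistical behaviour under the stated
generative model, not field-level accuracy.

## Calibration

For each accumulation window length k = 1..6, every window of k consecutive
months ending at a dung-census month is paired with that month's waypoint
dung densities. All feasible windows are enumerated (6, 5, 4, 3, 2, 1 pairs
for k = 1..6 over a six-month season); study-specific exclusions — e.g. a
June same-month pairing, or riverbed-dominated waypoints — are input flags,
never hard-coded. Each pair is fit by OLS of density (pats·m⁻²) on
cumulative intensity (yak·h·m⁻²), reporting slope, intercept, R² and the
slope F-test p-value; no multiplicity correction is applied (the report
states the number of tests). Degenerate pairs (zero density variance, as at
late-season sites where counts fall to zero) are flagged and excluded from
the trend rather than entered as R² = 0. The suitability trend is OLS of
per-pair R² on k, with replicated points per k.

The flight-height accuracy comparison follows the standard path: Shapiro–
Wilk normality per group and Levene homogeneity at α = 0.05, then one-way
ANOVA if both hold, otherwise a Mann–Whitney rank-sum fallback; the path
taken is always reported. Fractions are analysed untransformed by default
(arcsine-square-root optional).

Inverse prediction divides out the calibration: Î = (density − intercept)/
slope with a first-order interval ± 1.96·σ_resid/slope; non-positive slopes
are refused (the proxy premise requires density to increase with
intensity) and negative estimates are clamped to zero with a flag.

Parameter recovery uses the *binned occupancy* truth surface (a histogram
of all simulated yak-hours), not a KDE: dung is deposited at raw positions,
so only the raw occupancy gives an unbiased regression slope equal to the
deposition rate; regressing on a 300 m-smoothed surface would inflate the
slope by the smoothing-induced variance shrinkage. The KDE surface is the
estimator under evaluation, validated separately through its
mass-conservation and adjustment-factor properties.

## Problem sizes and determinism

The default virtual study simulates every daytime hour of 184 days for 278
yaks (≈665 k yak-hours and a similar number of pats) and runs in a few
seconds by using the binned KDE path on a 10 m study grid; exact kernel
stamping at 1 m resolution is used wherever mass conservation is asserted.
Unit tests run on a scaled-down season (25 yaks, 6-day months, 40 m cells)
that keeps every code path while staying sub-second; replicate-based
properties (e.g. the positive R²-vs-k trend in ≥95% of 20 seeded runs) use
the full default study. Seeds derive from a single integer via named
`SeedSequence` substreams; equal seeds give bit-identical outputs.

## Known limitations

* The adjustment-factor formula is a reconstruction (see above); if the
  published equation differs in its treatment of unequal snapshot cadence,
  monthly totals could differ by a bounded factor.
* Footprint extraction offers footprint-mean and centre-cell modes; which
  the original workflow used is unknown (default: footprint mean; a
  footprint smaller than one raster cell degrades to the containing cell).
* The camera constants reproduce printed coverage to within ~10%; exact
  sensor geometry per airframe is unknowable from printed specifications.
* Movement is a sequence of blended field draws, not a mechanistic
  trajectory model; it reproduces the radial gradient and monthly
  variation, not step-length or turning statistics.
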