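# Methods

## Model

The assessment model rests on the concept of allostasis: every stressor a
fish has to compensate adds to a cumulative physiological load, and welfare
degrades as that load grows. Each quantifiable welfare parameter is
standardised into an ordered list of intervals. An interval carries

* a **parameter score** `PS ∈ [-1, 0]` — the direction/size of the welfare
  influence (0 none or positive, -1 strongly negative), and
* a **score weight** `SW ∈ {1..5}` — the severity (intensity, duration,
  frequency) of the stressor state the interval represents.

Each parameter additionally carries a **parameter weight** `PW ∈ {1..5}`
for its relative relevance. Parameters are grouped into five modules by
measuring methodology — farm management (M), water quality (W), fish group
behaviour (FG), fish external appearance (FE), fish internal appearance
(FI) — and each module is graded independently:

    MG = 1 + Σ_i PS_i · SW_i^SWE · PW_i^PWE / Σ_i SW_i^SWE · PW_i^PWE

summed over the *measured* parameters of the module. The weighted-mean
normalisation makes the grade robust to missing data: an unmeasured or
inapplicable parameter (`NA`) contributes to neither numerator nor
denominator. The offset of 1 maps the result into [0, 1]; grades map to
categories critical [0, 0.25), poor [0.25, 0.5), acceptable [0.5, 0.75),
good [0.75, 1], always computed from the unrounded grade (reports round
half-up to 2 decimals for display only).

**Denominator form.** The exponents are applied in the denominator as well
as the numerator. With an exponent-free denominator a single severe
parameter (PS = -1, SW = PW = 5, exponent 1.7) would contribute
-5^3.4 against a weight of 25 and drive the grade far below 0. The
weighted-mean form is the only reading under which the grade is guaranteed
to stay in [0, 1], with the exact boundary behaviour MG = 1 iff every
PS = 0 and MG = 0 iff every PS = -1. This is a genuine modelling decision
and is covered by dedicated range/boundary tests.

**Exponents.** SWE = PWE = 1.7 for W, FG, FE and FI; module M uses SWE = 0
(management intervals affect fish indirectly, so a dynamic score weight
adds nothing — the engine's M grades are provably invariant to SW). Keeping
both exponents identical prevents either weight from overpowering the
other. The package includes the calibration harness that produced this
value: a grid search minimising category misclassifications over labelled
boundary datasets, ties broken toward the smallest exponent.
`make_boundary_dataset` inverts the grade equation to construct datasets
whose grade crosses a category boundary at a chosen exponent, which is how
the harness is tested (only 1.7 on a 1.0–2.5/0.1 grid classifies both
constructed sets correctly).

**Multi-fish sampling.** FE and FI parameters are scored on individual fish
(3–10 recommended; below 3 the package warns). The per-fish PS *and* SW are
averaged arithmetically per parameter before grading, giving possibly
non-integer effective weights that are used consistently in numerator and
denominator. Averaging the interval scores (rather than, say, taking the
median interval or grading each fish separately and averaging grades) keeps
single-fish assessments an exact special case and makes the averaged score
a continuous function of the sample.

## Derived measures

* **Unionized ammonia.** `NH3-N = TAN / (1 + 10^(pKa - pH))` with the
  freshwater equilibrium `pKa = 0.09018 + 2729.92 / T(K)` (Emerson 1975).
  Salinity correction is omitted (freshwater systems). This form reproduces
  both recorded farm values (0.04 mg/L TAN, pH 7.84, 16.9 °C → 0.001 mg/L;
  0.79 mg/L TAN, pH 7.5, 11.5 °C → 0.005 mg/L) at 3-decimal precision.
* **Oxygen saturation.** Percent of the freshwater equilibrium
  concentration from the Benson–Krause (1984) closed form, scaled by
  barometric pressure through the standard (P − p_wv)/(1 − p_wv) factor.
  Checked against published solubility tables to 0.5 % over 0–35 °C.
  Recorded farm saturations are *not* used as oracles: several are only
  consistent with sub-sea-level pressure at the site, which the fixtures do
  not record, so the model takes pressure as an explicit optional input
  (default 1 atm).
* **Fulton condition factor.** `K = 100·W/L³` with **standard** length.
  Verified against all six recorded farm values at their printed precision;
  the same computation with total length reproduces none of them.

## Default configuration

The shipped config carries the exact published structure: 80 parameters —
18 M, 14 W, 20 FG, 18 FE (Fulton K plus 17 ordinal traits), 10 FI — with
3/4/6/4/4 intervals per module respectively (FG's six intervals fold
severity and abundance into one ordinal scale). Within that structure the
quantitative entries are package defaults, stated in the config's
provenance field:

* interval PS values linearly spaced from 0 to −1 (e.g. {0, −0.5, −1} for
  three intervals) — the documented default for user-authored parameters;
* SW non-decreasing over severity (1,3,5 / 1,2,4,5 / 1,2,3,4,5,5);
* all PW at the documented default of 3 (the original expert-survey medians
  are not redistributable with the package);
* numeric W boundaries authored from general freshwater-aquaculture
  practice, wide enough to cover both salmonid and percid farms, with
  half-open [low, high) intervals, lower-inclusive, and ±inf outer
  sentinels. For two-sided parameters (pH, temperature, oxygen saturation)
  the interval *index* orders severity while the ranges tile the number
  line, so "too low" and "too high" can carry different severities.

Because the original per-interval tables and expert weights are not
available to this package, recomputed farm grades are *structurally*
comparable to the published six-farm table but not numerically identical
except where the result is analytic (an all-optimal module grades exactly
1.00 regardless of weights — farms 2 and 4, module FI). The acceptance
suite keeps the full 30-grade comparison as an explicit red marker of that
distance; the derived measures, counts, boundary behaviour and all
structural properties reproduce exactly.

Regulatory overrides substitute whole interval lists per parameter and are
validated like any other intervals; the original config is never mutated
and the jurisdiction is recorded in provenance.

## Ontology

The ontology is a bipartite graph: 14 welfare needs on one side,
parameters on the other, edges typed `affects` / `affected_by` / `both`.
Need–need and parameter–parameter edges are rejected by construction. The
packaged triple file carries all 14 needs, the 80 selected parameters
(criteria all true) plus two documented exclusions (viscerosomatic index —
not practicable on-farm; hematocrit — reacts to handling within minutes,
so not reliable), and a small reconstructed excerpt of the correlation
network around the needs *respiration* and *nutrition* (five links each).
The excerpt's edge set is synthetic — a consistent reconstruction, flagged
in the file's provenance — because the full published network (>200
parameters; respiration alone correlates with 44) is hosted externally.
Selection with all three criteria required returns exactly the 80 model
parameters.

## Synthetic-assessment generator

`generate_assessment(cfg, FixtureSpec(...))` draws deterministic
assessments for property testing: severity profiles `optimal` (every
parameter in interval 0), `worst` (lowest-PS interval), `mixed` (optimal or
first degraded), `random` (uniform over intervals), with `n_fish` per-fish
replicates (default 5, matching the farm-validation sampling) and a
missing-data fraction in [0, 1). Numeric values are drawn uniformly inside
the chosen interval (open outer ranges clipped to a finite width) so
interval resolution round-trips to the drawn interval. The generator
emulates the *format and coverage* of a farm visit, not farm dynamics:
values are independent across parameters and fish, so passing tests
demonstrate engine correctness and robustness to missing data, not realism
of correlated water chemistry or disease patterns.

## Numerical choices

* Grades are clamped to [0, 1] only to absorb float round-off at the exact
  analytic boundaries; the equation itself cannot leave the range.
* Engine-vs-oracle comparisons run at 1e-12 relative tolerance.
* Display rounding is half-up (`0.005 → 0.01`), matching tabular reporting;
  categorisation always precedes rounding.
* Boundary values of numeric intervals resolve to the interval whose lower
  bound they equal.
* Assessments with duplicate (parameter, fish) measurements are rejected at
  construction; a value outside every interval raises instead of degrading
  to NA, because silent missingness would inflate the grade.
* Reports embed a sha256 checksum of the canonical config dump; comparisons
  across different configs are refused.

## Problem sizes

The randomized suites use 500 scored sets for the equation oracle, 200
single-parameter perturbations for monotonicity, 1000 values for interval
resolution, and 100 seed pairs for generator entropy; the whole test suite
runs in a few seconds on one CPU.

## Limitations

* The quantitative default tables are package-authored stand-ins (see
  above); users reproducing published farm grades must supply the original
  interval tables as a config file.
* One config serves all species; species-specific optima (e.g. thermal
  windows for trout vs. pikeperch) should be expressed as override files.
* No aggregation across modules into a single index, by design.
* The ontology ships as flat JSON with GraphML export; OWL/RDF reasoning
  is out of scope.
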