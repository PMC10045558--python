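# Methods

`borondose` implements the computational chain of a preclinical boron
neutron capture therapy (BNCT) study in a rat glioma model: mixed-field
dose decomposition and photon-equivalent dosing, derivation of beam RBE
and per-carrier CBE factors from clonogenic assays through the
linear-quadratic (LQ) model, boron biodistribution summaries, and
survival-benefit statistics. A calibrated synthetic-data generator
stands in for the wet-lab measurements so that every stage is testable
offline. This note records the models, the calibration choices and
their limits.

## Mixed-field dose model

A thermal-neutron irradiation of boron-loaded tissue deposits dose
through four channels: the ¹⁰B(n,α)⁷Li capture reaction (D_B), the
¹⁴N(n,p)¹⁴C capture reaction (D_N), proton recoil ¹H(n,n)¹H (D_H) and
gamma rays (D_γ). The physical dose is the plain sum
D_B + D_N + D_H + D_γ; the biologically weighted dose is

    D_eq [Gy-Eq] = D_B·CBE + D_N·RBE_N + D_H·RBE_H + D_γ,

with RBE_N = RBE_H = 3.0 by default and the compound biological
effectiveness (CBE) specific to the boron carrier and tissue. With all
factors equal to 1 the weighted dose reduces exactly to the physical
sum; this identity is enforced by tests.

Kerma coefficients are configuration, never code. The shipped default
for the boron channel, 8.66 × 10⁻¹⁴ Gy·cm² per (µg ¹⁰B/g) of thermal
fluence, is the standard free-beam value; the effective in-tissue
coefficient of a given facility and depth can differ by a factor of
~1.5–2 because of flux attenuation and geometry, which is why every
beam configuration (`examples/beam.yml`, preset files) is explicitly a
calibration input.

Because published dose tables report only two totals (physical,
photon-equivalent) for the boron-free beam row, `beam_component_split`
inverts the 2×2 linear system

    (D_N+D_H) + D_γ = physical,   RBE_NH·(D_N+D_H) + D_γ = photon-equivalent

to recover the lumped high-LET and gamma parts. D_N and D_H are carried
separately in the data model (they are physically distinct) with a
lumped constructor for table-style inputs; since they share an RBE the
split between them never affects any downstream quantity.

Reconstructing the published tumor photon-equivalent doses from rounded
printed inputs (tumor physical dose minus the beam-only row, weighted by
the carrier's CBE) agrees with the printed column to within ±0.31 Gy-Eq;
exact agreement is not expected because the published values were
evidently computed from unrounded internals. The package tests this as
an approximate-consistency property at ±0.4 Gy-Eq.

## LQ model, RBE and CBE

Photon survival follows SF(D) = exp(−αD − βD²). Fitting is weighted
least squares on the log scale, −ln SF = αD + βD², with weights 1/SE²
(delta method from the replicate-dish standard errors) and α, β ≥ 0
enforced by non-negative least squares (`scipy.optimize.nnls`); the
unconstrained estimate is kept as a diagnostic. Survival fractions are
computed as the mean of per-dish plating efficiencies normalised to the
0 Gy control (three dishes per condition by default); SF > 1 from
sampling noise is flagged with a warning and fitted as-is rather than
rejected, which keeps bootstrap resamples unbiased at low dose.
Uncertainty comes from a parametric bootstrap: dish counts are redrawn
as Poisson around the fitted means and the constrained fit repeated;
percentile intervals from 199 replicates cover the generating (α, β) at
close to nominal rates in simulation (≈95% each at the default assay
design).

The endpoint inversion D(SF*) solves βD² + αD − ln(1/SF*) = 0 using the
cancellation-free root form 2L/(α + √(α² + 4βL)), with the β → 0 limit
L/α handled analytically. Beam RBE is the ratio of photon to beam dose
at the common endpoint SF = 0.1; the photon reference dose at that
endpoint is 6.45 Gy under the preset LQ parameters, which are chosen
with α/β = 10 Gy subject to that endpoint constraint (only the
combination α·6.45 + β·6.45² = ln 10 is identified by the endpoint, so
the α/β ratio is a realism choice, not a fitted quantity).

CBE inverts the photon-equivalent equation at the isoeffect endpoint:

    CBE = (D_photon(SF*) − RBE_NH·(D_N+D_H) − D_γ) / D_B.

The decomposition of a carrier group's endpoint field comes from a
time-scaled mixed-field model: the beam (non-boron) physical dose is a
tabulated lookup of irradiation time (0.48/1.01/1.21 Gy at 10/20/30 min,
linearly interpolated and extrapolated), split into high-LET and gamma
parts by the fixed fractions of the beam-only reference row (31.25% /
68.75%), while the boron dose grows linearly with time and with the
carrier's effective intracellular concentration. Two interpretation
points deserve record:

* The published per-group endpoint doses (0.75/0.85/1.48 Gy) are read
  as the **beam** physical dose at each group's endpoint. Read as mixed
  totals they are incompatible with the published CBE factors: the
  inversion is then bounded below by 6.45/0.75 ≈ 8.6 for any
  non-negative split, far above the published 2.69.
* The effective intracellular concentrations during irradiation are not
  published (they live in appendix tables unavailable here), so the
  presets store values calibrated such that the model reproduces the
  published CBE factors (2.69, 2.26, 0.75) exactly. Derived CBEs are
  therefore consistency-calibrated, not independent reproductions, and
  the package does not present them otherwise. CBE < 1 (the
  unconjugated carrier mixture) is valid and reported without warning;
  CBE < 0 indicates an inconsistent decomposition and is flagged.

## Biodistribution summaries

Tissue tables are summarised as arithmetic mean ± sample SD (n−1) per
carrier × time × tissue; single-animal cells report SD as missing, not
zero. Tumor-to-brain and tumor-to-blood ratios are ratios of means (not
means of ratios), which is how such tables are conventionally printed;
both unrounded and one-decimal half-up rounded values are kept. All six
published T/Bl ratios and the BPA 8/24 h T/Br ratios reproduce exactly
from the printed means after rounding. The cRGD-MID-AC 8 h and 24 h
T/Br cells do not: 17.0/0.9 = 18.9 vs the printed 18.5 and 13.1/0.7 =
18.7 vs 18.4. Those entries were evidently computed from unrounded
means, and no computation from the printed table can recover them more
closely than the input rounding allows (17.0±0.05 / 0.9±0.05 spans
17.9–20.0); the corresponding acceptance checks record this as a known
irreproducibility.

Washout retention is 100 × C(24 h exposure + washout t) / C(24 h
exposure). Group comparisons use the pooled-variance Student's t-test
(two-sided, α = 0.05) with Welch's correction available by flag.

## Survival analysis

Kaplan–Meier estimation, median CIs and the asymptotic log-rank test
are delegated to `lifelines`; ties follow the standard convention
(events before censorings). The median is the smallest t with
S(t) ≤ 0.5, except that when the curve sits exactly at 0.5 over an
interval — an even number of uncensored animals — the midpoint of the
bracketing event times is reported, matching the classical sample
median (e.g. 38.5 days for six animals). A curve that never reaches 0.5
has an undefined median, reported as such and rendered as an open
interval (``27-``) in summaries.

    %ILS = (MST_group − MST_ref) × 100 / MST_ref

uses the reference group's median by default; a flag switches the
denominator to the mean for studies that define it that way (the two
coincide for a symmetric reference group). Because rodent groups are
tiny (n = 4–7), the package adds an exact permutation log-rank test:
all label assignments are enumerated up to n = 12 (Monte Carlo beyond),
and the p-value is the fraction of assignments whose chi-square reaches
the observed one. The internal statistic is verified against lifelines
and against an independently coded oracle in the tests. Published
per-group p-values cannot be reproduced because individual animal times
were never published; the calibrated simulation instead checks the
power property that untreated vs the strongest treatment arm rejects at
the 0.05 level in well over 80% of replicates.

## Synthetic data

* **Colony assays** — per-dish counts ~ Poisson(seeded × PE₀ × SF),
  PE₀ = 0.6, three dishes per condition, seeding scaled to keep ~90
  expected colonies per dish (as a bench scientist would plate). The
  X-ray arm uses the photon LQ curve; neutron arms use the
  photon-isoeffect assumption SF = SF_photon(D_eq(t)), which makes the
  generator exactly consistent with the CBE inversion.
* **Tissue biodistribution** — zero-truncated normal draws around each
  published mean/SD, n = 4 animals (3 for the one smaller cell).
  Truncated normal, not lognormal, because the published cells are
  symmetric mean ± SD with small CVs.
* **Survival** — lognormal times (positive support, right skew: the
  50.3 ± 26.8 vs median 38.5 arm is strongly skewed), rounded to whole
  days and censored at the 90-day study horizon. The log-location is
  anchored at the printed median and the log-scale comes from the
  printed mean/SD coefficient of variation: a two-parameter lognormal
  cannot match mean, SD and median simultaneously, and the downstream
  endpoints (%ILS, median recovery) are median-based, so the median is
  the anchored quantity. Zero SD collapses a group onto its median
  exactly, which reproduces the published %ILS column end-to-end.
  Per-replicate sample medians of the small high-variance arms are
  intrinsically noisy (SD ≈ 10 days for n = 6, σ_log ≈ 0.5), so
  calibration is checked on the across-replicate average of the sample
  median (within ±4 days for every group), not per replicate.
* **Cellular uptake** — saturating first-order uptake
  C(t) = c_max(1 − e^(−kt)) and exponential washout whose 1 h retention
  matches the published percentage per cell line × carrier; c_max and k
  are realism choices reproducing the qualitative ordering (the amino
  acid analogue washes out fast, the albumin conjugates retain boron).
  Multiplicative lognormal replicate noise, CV 5% by default.

All generators are deterministic under a fixed seed, with independent
child streams per table kind. What passing tests show about real data
is limited by these emulations: no inter-animal pharmacokinetic
correlation, no plating-efficiency drift between assays, no informative
censoring, and uptake/washout curves are idealised single-compartment
forms.

## Numerical conventions and limitations

* Report rounding is one decimal, half-up (2.75 → 2.8), with
  full-precision companions retained; blank report cells mark
  carrier/tissue pairs with no known CBE rather than imputing one.
* Validation errors (bad inputs, schema violations) and computation
  errors are distinct exception families; the CLI maps them to exit
  codes 2 and 3.
* Problem sizes used by the test suite and the acceptance script —
  200 simulated assays × 199 bootstrap replicates, 500 survival
  replicates, 1000 t-test null replicates, exhaustive permutations up
  to n = 10 — were chosen to keep Monte Carlo error well below the
  tolerances being checked.
* Out of scope by design: neutron transport and depth–dose modelling,
  compartmental pharmacokinetics, cell-cycle/repair extensions of the
  LQ model, Cox regression and multiplicity adjustment.
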