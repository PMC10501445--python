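# Methods

## Model structure

The model is a cohort state-transition (Markov) model with four health
states: progression-free survival (PFS), first progressive disease (PD1),
second-and-later progressive disease (PD2) and death.  The cohort enters
100 % in PFS.  The cycle length is 21 days (one chemotherapy cycle); the
horizon is 7.44 years — `floor(7.44 × 365.25 / 21) = 129` cycles — by which
time essentially the whole cohort has died.  A half-cycle correction is
applied to all accruals by averaging adjacent-cycle state occupancies, and
both costs and health outcomes are discounted at 5 %/year, with the
discount factor evaluated at the cycle-start time.

### Transitions

Only two survival curves (PFS and OS) are available per arm, so
transitions are derived from them:

* **PFS → PD1**: `Prob(FtP) = (P(t) − P(t+1)) / P(t)` where `P` is the
  fitted PFS survival function evaluated at cycle boundaries (months).
* **PFS → death**: the per-cycle background all-cause mortality
  `1 − (1 − q)^(21/365.25)` from an annual probability `q` (default
  0.00718/year, a configurable scalar standing in for national life-table
  mortality around the cohort's mean age of 61.1 years).  If the two PFS
  exits sum above 1, the progression term is reduced (the mortality floor
  is preserved) and a warning logged.
* **PD1, PD2 → death**: `Prob(PtD) = (O(t) − O(t+1)) / (O(t) − P(t))`,
  clipped into [0, 1] with a logged warning when digitization noise or
  early-cycle geometry pushes the raw value outside the interval.  When
  `O(t) − P(t) ≤ 1e−12` the PD states are empty and the probability is 0.
* **PD1 → PD2**: the published figure separates first from later
  progression, but no third curve identifies that transition.  PD1 is
  therefore a *tunnel*: entrants receive second-line therapy for
  `secondline_duration` cycles (default 4, mirroring the 4-cycle
  induction) and then move to best supportive care.  This reproduces the
  intended cost structure (second-line chemo ± continued immunotherapy,
  then BSC) while using only `Prob(PtD)` for death.  The tunnel length is
  an explicit modelling choice, configurable in `ModelParams`.

A structural artifact worth knowing: the cohort starts with the PD states
empty, so the OS drop over the very first cycle cannot generate deaths
(background mortality aside).  The model's survivor fraction therefore
exceeds the OS curve by at most `1 − O(one cycle)` early on; because the
death probability is computed from the curves rather than from
occupancies, the offset decays over subsequent cycles (verified in the
test suite).  Total life-years are correspondingly biased upward by a few
per cent relative to the OS integral when progression is fast.

### Costs, utilities, adverse events

Per-cycle drug acquisition costs, AE management costs, utilities
(PFS 0.673, PD 0.473, death 0), AE disutilities and per-arm grade ≥3 AE
risks are the published input table's base-case values (2022 USD).  Cost
assignment per cycle:

* PFS, cycles 1–4 (induction): etoposide + carboplatin, plus serplulimab in
  the active arm, plus routine follow-up.
* PFS, later cycles (maintenance): serplulimab (active) or nothing
  (control), plus follow-up.
* PD1 (second line): a 50/50 mix (configurable) of irinotecan + carboplatin
  and etoposide + carboplatin, plus serplulimab for the fraction of active
  patients continuing immunotherapy (55.23 %; control 50.23 % continue
  placebo at zero cost), plus follow-up.
* PD2: best supportive care only.  Follow-up cost is applied to the
  on-treatment states (PFS, PD1), not the BSC state.

The AE burden is applied once at model entry — grade ≥3 events cluster in
induction — as `Σ risk × cost` added to cycle-1 cost (undiscounted, t=0)
and `Σ risk × disutility × one cycle length` subtracted from QALYs.  Both
the one-off convention and the one-cycle disutility duration are
configurable assumptions; duration-weighted alternatives would scale the
(small) QALY decrement.

Per-administration doses (serplulimab 4.5 mg/kg → 293 mg; etoposide
100 mg/m² × 3 days → 516 mg/cycle; carboplatin AUC 5 via Calvert with
Cockcroft–Gault clearance, male form → 481 mg, CrCl 71.23 mL/min) are
computed for auditing and unit-price workflows; the per-cycle costs used in
accrual are taken directly from the input table.  Dose rounding is
half-up at 0.5 mg (the rounding rule to "the nearest milligram" leaves
ties unspecified).

## Survival analysis

### Pseudo-IPD reconstruction

Digitized curve coordinates are cleaned (clamped to [0, 1], deduplicated,
re-monotonized by running minimum, `(0, 1)` prepended) and combined with
the at-risk table.  At-risk counts are interpreted as subjects entering the
interval `(T_i, T_{i+1}]`; the known decrement `n_i − n_{i+1}` is split
into events and censorings by exhaustive search over the (small) decrement,
choosing the split whose reconstructed product-limit value best matches the
digitized survival at the interval end.  Events sit at digitized drop
times (allocated across drops by largest remainder, ties to the earlier
drop); censorings are spaced uniformly through the interval; subjects
remaining after the last tabulated time are censored at the last digitized
time.  Targeting the *cumulative* survival rather than per-interval ratios
stops integer-rounding errors from accumulating: on noise-free fixtures the
round trip agrees with the input curve within `1/(2 n_i)` at every
boundary and within 0.02 sup-norm overall.  The contract is this
round-trip invariant, not bit-compatibility with any published
reconstruction code.

### Parametric fitting and selection

Five families are fitted by maximising the right-censored log-likelihood
`Σ_events log f(t) + Σ_censored log S(t)`: exponential (closed form,
`λ̂ = d/Σt`), Weibull in the rate form `S = exp(−λ t^γ)`, a location-scale
logistic **on time** (which leaks probability below t = 0; survival values
are reported as-is inside (0, 1) — this is deliberate, the family list
being taken literally), log-logistic and log-normal.  Optimisation runs on
log-transformed (positivity-constrained) parameters with L-BFGS-B, three
moment-based starts, and a gradient tolerance of 1e−8; non-convergent fits
raise with the final gradient norm.  The censored MLE is cross-checked
against independent fitters (lifelines) in the test suite.

Selection is minimum AIC (`2k − 2ℓ`), ties broken by minimum BIC
(`k ln n − 2ℓ`), then by the family order listed above — a deterministic
stand-in for the original analysis' unreported tie handling, which also
involved visual inspection.  Medians solve `S(m) = 0.5` in closed form for
Weibull/exponential and by bisection otherwise.

## Synthetic data

The generator emulates the trial's statistical structure: 585 patients
allocated 2:1 (390:195), Weibull event times calibrated so the median
matches the printed medians exactly (`λ = ln2 / m^γ`), administrative
censoring at 30 months of follow-up (a trial-like default; the real
follow-up distribution is unpublished).  Calibration shapes default to 1.2
(PFS) and 1.0 (OS) — documented placeholders, since the fitted shapes of
the source analysis are unreported.  Digitized-curve fixtures evaluate
S(t) on a reading grid (default 0.5-month steps) with optional ±0.005
uniform digitization noise followed by re-monotonization; risk tables carry
rounded expected at-risk counts on a coarser grid (default 3 months).

What the synthetic data do *not* emulate: correlated PFS/OS times within
subjects (irrelevant to a cohort model driven by arm-level curves),
non-administrative dropout, accrual-time staggering, and the true (unknown)
shape of the trial's hazard functions.  Consequently the package's
base-case totals approximate, but do not reproduce, the published ones —
the published scenario arithmetic is instead validated exactly through the
printed-totals surrogate (below).

## Economic analyses

* **ICER**: `ΔC/ΔQALY` and `ΔC/ΔLY` with dominance flags; ratios are
  suppressed when signs differ or `|ΔQALY| < 1e−12`.
* **Tornado**: every cost, utility, disutility, AE-risk and pathway-share
  parameter at ±20 % of base, discount over 0–8 %, horizon over
  2.00–7.44 years; bars ranked by ICER spread, reported in $/QALY.
  Background mortality is not varied (the published one-way analysis lists
  no such bar).
* **PSA**: 1000 draws; costs ~ Gamma (shape 25 ⇒ SD = 20 % of mean),
  utilities/disutilities/AE-risks/shares ~ Beta matched by moments to
  mean = base, SD = 20 % of mean (infeasible SDs are shrunk to the
  feasibility boundary and logged; degenerate 0/1 parameters stay fixed).
  Discount, horizon and survival parameters remain fixed, so cohort traces
  are computed once per arm and only the accrual step re-runs per draw.
  The published analysis states the distribution families but not their
  dispersions; SD = 20 % of the mean mirrors the ±20 % one-way ranges and
  is configurable.  Each draw is reproducible from `(seed, index)`.
* **CEAC**: fraction of draws with positive incremental NMB on a WTP grid
  (default $0–200,000 in $2,000 steps).
* **Price scenarios / threshold price**: the serplulimab price factor
  scales every place the drug cost enters (induction, maintenance,
  post-progression share).  The ICER is affine in the discount, so the
  threshold solve uses bisection to interval convergence with the
  closed-form affine solution as a cross-check (agreement to 1e−8).

### The printed-totals surrogate

The published per-arm totals, ICER and threshold discount are mutually
consistent and fully determine the scenario arithmetic: the implied QALY
gain is `26402/179161 ≈ 0.1474` (more precise than the rounded 0.15) and
the implied serplulimab-attributable per-patient cost is
`(33191 − 12304)/0.8165 ≈ $25,581`.  An `AffineBundle` built from these
quantities reproduces the published scenario ICERs ($37,423 at the
threshold discount, $92,365 at 50 %, $144,443 at 20 %, $213,879 at the
+20 % tornado endpoint) through the same price-scenario code path used by
the full model.  This validates the economics layer exactly even though
the unreported survival parameters make the base-case totals themselves
approximate.

## Numerical conventions

* Months are 365.25/12 days; a cycle is 21/30.4375 ≈ 0.6899 months.
* Money is kept at full precision internally; printed output rounds to
  cents.
* KM ties process events before censorings (standard product-limit
  convention).
* `prob_progress` returns 0 for an empty PFS state (`P(t) ≤ 1e−12`);
  `prob_pd_death` returns 0 when `O(t) − P(t) ≤ 1e−12`.  Note the
  degenerate case `P = O` therefore leaves PD occupants immortal rather
  than empty — with identical curves, progression still occurs but no
  PD death can be attributed; the empty-denominator rule wins.
* Problem sizes used by the verification workflow: 1000 PSA draws
  (matching the published analysis), 6000 subjects for synthetic
  parameter recovery, 10⁴ samples for distribution-recovery checks —
  large enough that Monte-Carlo error is well inside the stated
  tolerances.

## Known limitations

* The PD1/PD2 split is a tunnel-state approximation; the original
  parameterisation of first-to-later progression is not recoverable from
  the two published curves.
* Base-case totals depend on unpublished fitted survival parameters and are
  therefore calibrated approximations (medians exact, shapes assumed).
* Background mortality is a single scalar, not an age-varying life table.
* Subsequent-line therapies beyond continued serplulimab/placebo plus the
  two chemotherapy doublets are not modelled (the source analysis makes
  the same simplification).
* Utilities derive from NSCLC studies; true SCLC utilities are likely
  lower, which would raise the ICER.
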