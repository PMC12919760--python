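# Methods

This note documents the model, its assumptions, the synthetic inputs,
and the numerical and design choices behind `her2ce`. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Disease model

A cohort of women with HER2-positive early breast cancer and residual
invasive disease after neoadjuvant therapy enters adjuvant treatment
(T-DM1 or trastuzumab) at a median age of 52 years. The Markov state
space is:

* `residual_on` / `residual_off` — alive and disease-free, on or off
  adjuvant treatment. The split is cost/utility-only: both states share
  the same transition risks, and disease-free survivors move from on to
  off once the adjuvant course ends.
* `recurrence_1 … recurrence_12` — a 12-compartment monthly tunnel for
  non-metastatic (locoregional or contralateral) recurrence. Remission
  is automatic after 12 months if alive; the only risk inside the
  tunnel is background mortality, since no excess mortality is
  attributed to non-metastatic recurrence.
* `remission` — remission after non-metastatic recurrence, with a
  monthly probability of 0.0076 of progressing to first-line metastatic
  disease.
* `met_1l`, `met_2l` — first-line and later-line metastatic disease.
  Progression probabilities per month are arm-specific because the
  metastatic treatment mix depends on prior adjuvant exposure: after
  adjuvant T-DM1 we assume 1L therapy is trastuzumab-deruxtecan
  (monthly 1L→2L+ 0.0186) with later lines on HT (2L+→death 0.0315);
  after adjuvant trastuzumab, 1L is T-DM1 (0.0428) with later lines on
  T-DXd (0.0186). This mapping is an assumption (tagged as such in the
  bundle); metastatic regimens differentiate arms through cost and
  progression only, not through any additional survival effect.
* `death` — absorbing.

There is deliberately **no edge from the recurrence tunnel to 1L mBC**:
trial conventions classify metastatic disease within two months of a
locoregional recurrence as a metastatic first event, so no data exist
to parameterise that conditional transition. Any recurrence after
remission is metastatic.

Cycle length is one month, with 1 year = 12 cycles exactly. The horizon
is 48 years (576 cycles, to age 100). Occupancy used for payoffs is the
trapezoidal half-cycle average of start- and end-of-cycle occupancy
(the correction method itself is a design choice; it applies to both
costs and QALYs, and one-time transition costs — none in the base case
— would be exempt). Discounting is (1+r)^(−k/12) per cycle with r = 5%
per year for both costs and effects.

## Disease-free survival and the cure fraction

Exits from the residual states follow a mixture-cure model
S(t) = π + (1−π)·S_latent(t): a fraction π of patients is cured of the
disease event (but not of background mortality, which is layered on at
model assembly, not inside the cure fraction). The latent distribution
is one of exponential, Weibull, log-normal or log-logistic; candidates
are fitted by maximum likelihood — events contribute
−log[(1−π)f_latent(t)], censored records −log[π+(1−π)S_latent(t)] — and
ranked by AIC with BIC reported alongside (ties: fewer parameters, then
a fixed family order). The optimiser is bounded L-BFGS-B with a fixed
multistart over π ∈ {0.1, 0.5, 0.9}, data-driven latent starts, and an
objective tolerance of 1e-8, so refits are bit-reproducible. A fit with
π̂ within 1e-6 of 0 or 1 is flagged as a boundary solution (all-censored
data lands at π̂ = 1 by construction).

The fitted curve converts to per-cycle exit probabilities via
p_k = 1 − S((k+1)Δ)/S(kΔ). Each exit is split across destinations with
configurable shares — locoregional 0.40, metastatic 0.45, death 0.15 by
default. The event composition is not published; these shares are
assumptions chosen so all three first-event types occur at plausible
rates, and they are exposed in the bundle.

**Treatment effect and waning.** Fitting is per-arm by default (two
independent mixture-cure curves). The treated arm's *cycle-level*
hazard contrast against control is held in full until 84 months,
interpolated toward 1 log-linearly (linear-in-HR available as an
option) between 84 and 120 months, and equals 1 exactly from 120
months, after which both arms share the control hazard. A
proportional-hazards mode (single control curve plus one HR) is also
provided. In sensitivity analyses a drawn HR scales the fitted contrast
relative to its build-time reference, so a degenerate draw reproduces
the base case exactly. Log-linear interpolation is standard HTA
practice for effect waning: it is continuous, positive, and symmetric
on the log scale.

**Background mortality.** An annual life table is converted to monthly
probabilities via 1−(1−q)^(1/12) at the attained age 52 + k/12 and
combined with disease risks as independent competing risks,
1−(1−p)(1−q). No source life table is named for the original analysis,
so the package ships a synthetic Gompertz schedule
q(a) = min(1, 2.2·10⁻⁵·e^(0.092a)) — about 0.26%/year at 52, 3.5% at
80, 22% at 100 — replaceable by any `age,annual_q` CSV.

## Costs and utilities

Costs are 2024 US$ (conversion from local currency happens outside the
engine at 4071.35 COP/US$). Components per state: acquisition,
diagnostic tests, administration, adverse events, supportive care.
Acquisition is weight-based and linear in milligrams (price per minimum
concentration unit, no vial wastage): T-DM1 3.6 mg/kg × 14
administrations every 21 days; trastuzumab 8 mg/kg loading then
6 mg/kg × 13, with the price per mg for trastuzumab representing a
market-share-weighted average across presentations. Fourteen 21-day
administrations span 294 days, mapped to the first **10 monthly
cycles**; acquisition, administration and adverse-event costs accrue
only there (in `residual_on`), after which survivors carry the
off-treatment profile. The only adverse-event cost is an additional
complete blood count in the T-DM1 arm, per the source analysis's
adverse-event convention.

The published cost table reports only discounted *mean cost per
patient* by state and arm, not per-cycle rates. Accumulated cost is
linear in each monthly rate, so the packaged bundle **back-solves** the
monthly rates per arm from those published means through its own
base-case occupancy (rate = target mean / discounted occupancy-time).
These rates are tagged `calibrated`, not `paper`. Calibration is
per-arm because the published per-arm state means cannot be reproduced
by shared monthly rates plus occupancy differences alone — which is
realistic, as the downstream treatment mix (hence supportive-care
content) differs by arm. A consequence worth knowing: the base-case
per-arm state cost totals reproduce the published state means by
construction; the QALY side and all event dynamics are genuinely
computed from the fitted synthetic survival curves.

Utilities: 0.77 (residual on-treatment), 0.78 (off-treatment), 0.77
(non-metastatic recurrence), 0.78 (remission), 0.77 (1L mBC), 0.52
(2L+ mBC), 0 (death). QALYs are Σ occupancy·u·df/12; life-years use
u ≡ 1 for alive states, so QALYs ≤ life-years always.

The incremental summary labels a comparison Dominant (ΔC < 0, ΔE > 0),
Dominated (ΔC > 0, ΔE < 0) or Equivalent (both zero); otherwise it
reports ICER = ΔC/ΔE against the willingness-to-pay threshold
λ = US$6831/QALY (86% of 2024 GDP per capita). NMB = ΔE·λ − ΔC holds to
1e-9 on every emitted comparison.

## Synthetic trial data

`simulate_trial_ipd` draws per-arm invasive-disease-free times from the
mixture-cure model: the control arm's uncured subjects are log-normal
(meanlog 3.0, sdlog 0.9 — median uncured event time ≈ 20 months); the
treated arm's latent hazard is scaled by HR = 0.54 (the reported 46%
risk reduction), sampled by inverse transform through S_latent(t)^HR.
Administrative censoring is at 100.8 months (8.4 years of follow-up).
In the default *anchor-calibrated* mode the cure fractions are solved
so model survival at 84 months equals the published arm-level
disease-free survival, 85.58% (T-DM1) and 71.11% (trastuzumab) — the
anchor timepoint is not printed in the source and is an assumption
(84 months = trial follow-up); this yields π ≈ 0.694 (control) and
0.817 (treated). An *HR-only* mode keeps a common cure fraction
instead. Default size is 2000 per arm. All randomness flows through one
seeded generator.

What the generator does **not** emulate: delayed entry/accrual,
loss-to-follow-up before the administrative cut, covariate
heterogeneity, non-proportional latent hazards, and the
interval-coarsening of digitized curves (available separately as the
`coarsen` option of `km_estimate`). Passing tests therefore demonstrate
correctness of the machinery under the stated generating model, not
agreement with any real patient population.

## Sensitivity analyses

PSA (default 1000 draws): utilities ~ gamma (following the source's
stated choice of gamma rather than the conventional beta; draws are
truncated at 1), administration / adverse-event / supportive-care
monthly rates ~ log-normal, treatment effect ~ (multivariate) normal on
the log-HR scale, exponentiated. All distributions are moment-matched
to mean and SE. The source reports no SEs or bounds, so defaults are
20% of the mean for cost rates, 10% for utilities, and log-HR SE
0.1034 (back-derived from a 0.44–0.66 interval); all are arguments and
are logged with every PSA run. Draw failures are counted and reported,
never silently dropped. The CEAC is the fraction of draws with strictly
positive NMB per λ. Survival curves are not refitted per draw; the
effect uncertainty enters through the log-HR scaling.

The tornado varies one parameter at a time to its bounds (ranges must
bracket the base value) and sorts by |NMB(high) − NMB(low)|. Default
ranges: ±20% on weight, prices and the 1L supportive rate, ±25% on the
remission progression probability, the HR interval 0.44–0.66, discount
0–12%, and waning end 96–180 months. With these defaults the largest
swings come from the 1L supportive-care rate, the discount rate and the
HR; published tornados with different (unreported) ranges can order
parameters differently.

## Numerical choices and degenerate inputs

* Row-stochasticity is asserted to 1e-12 per matrix, occupancy
  conservation to 1e-10 per cycle over all 576 cycles.
* Competing risks within a row are combined as independent
  probabilities (1−Π(1−p)), which cannot exceed 1 by construction;
  user-supplied raw rows exceeding 1 beyond 1e-9 are errors.
* Survival curves are floored at 1e-300 before log-hazard differencing;
  a curve that is exactly zero at a cycle start raises (cohort
  exhausted) rather than returning NaN.
* `survival_to_cycle_prob` clips to [0,1] against floating-point dust.
* The per-arm cycle-hazard contrast may cross 1 in individual cycles
  (very early, where both hazards are ~1e-4, or late in follow-up as
  the control uncured pool depletes); the waning interpolation operates
  on whatever contrast the fit implies, and the implied treated
  survival remains above control throughout the effect window.
* Ranking ties (identical AIC) break toward fewer parameters, then the
  fixed order exponential < Weibull < log-normal < log-logistic.
* The micro-simulation oracle is a testing device only (it validates
  the cohort engine at n = 50 000 within binomial Monte-Carlo error);
  the cohort engine is the production path.

## Problem sizes used in the shipped checks

The test suite and acceptance script run the full 576-cycle horizon for
all cohort analyses; trial simulation and fitting use 2000 subjects per
arm (5000 for the Kaplan-Meier anchor check), 50 seeded replicates for
parameter-recovery and family-selection statistics, 50 000 individuals
for micro-simulation agreement, and 1000 PSA draws in the acceptance
script (smaller draw counts in unit tests). These sizes give
Monte-Carlo error comfortably inside every asserted tolerance.

## Known limitations

* Per-arm calibrated cost rates mean the base-case cost side mirrors
  the published state means by design; the model's added value is in
  the dynamics (survival, events, QALYs) and the uncertainty analyses.
* The synthetic life table is a stand-in, not a national table.
* Event-destination shares and the metastatic line mapping are
  assumptions; both are bundle-exposed and varied in sensitivity
  analyses only through their cost/QALY consequences.
* Gamma-distributed utilities can exceed 1 before truncation; capped
  draws are counted (`PSAResult.n_truncated`) rather than re-weighted,
  so heavy truncation shifts the effective utility mean slightly below
  its nominal value.
* No scenario analyses beyond those described (e.g. societal
  perspective, budget impact, EVPI) are implemented.
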