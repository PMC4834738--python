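# Methods

## Energy-balance model

The forward model is a two-compartment ordinary differential equation in
fat mass *F* and fat-free mass *L* (kg), integrated on a daily output grid
with adaptive Runge–Kutta (scipy `solve_ivp`, RK45, rtol 1e-8). The daily
energy imbalance *I − E* (kcal/day) is partitioned by the Forbes
companionship rule: the fat-free fraction of any mass change is
α(F) = C/(C+F) with C = 10.4 kg, so leaner bodies surrender more lean
tissue per kilogram. Tissue energy densities are fixed at ρ_F = 9400 and
ρ_L = 1800 kcal/kg; the effective energy density of weight change is
ρ(F) = α ρ_L + (1−α) ρ_F (≈ 7800 kcal/kg for the reference client).

Expenditure is

    E(t) = PAL · RMR₀ + β · I(t) + γ · (W(t) − W₀)

where RMR₀ is the Mifflin–St Jeor resting metabolic rate at baseline
(10 W + 6.25 H − 5 A − 161 for women, +5 for men; W kg, H cm, A years),
PAL = 1.5 represents light-to-moderate activity (the 150 min/week
guideline), β = 0.10 is the thermic effect of feeding, and γ is the slope
at which total expenditure follows weight away from baseline. Maintenance
intake solves I = PAL·RMR₀ + β·I, i.e. I_m = PAL·RMR₀/(1−β).

γ is the single calibrated coefficient. With textbook values alone
(γ ≈ PAL × 10 kcal/kg/day) the model loses far more weight in a year than
the reference prediction this package is built to match: a 50-year-old
woman, 65 in, 200 lb, restricting 500 kcal/day, should lose 17.4 lb (8.7 %)
in 12 months. Solving for the slope that reproduces that trajectory gives
γ = 52.12 kcal/day per kg. Physiologically γ bundles the cross-sectional
weight dependence of expenditure with the adaptive suppression of
expenditure (and drift in unmeasured behavior) under sustained restriction,
which is why it exceeds the cross-sectional slope; it is deliberately a
model coefficient, not a measured quantity, and is config-overridable like
every other parameter. Explicit adaptive-thermogenesis terms, the
high-exercise partition curve, and pediatric models are out of scope.

Baseline body composition is initialized from the Deurenberg body-fat
regression (BF% = 1.2·BMI + 0.23·age − 10.8·male − 5.4, clipped to
5–60 %). The model is insensitive to moderate initialization error: the
partition constant C dominates ρ(F) far more than the BF% estimate.

Consequences used as invariants: intake = maintenance holds weight exactly
(drift < 0.25 kg/365 d numerically); deeper restriction gives pointwise
lower trajectories; loss decelerates toward a plateau at
ΔW_eq = (1−β)·|Δ|/γ; energy bookkeeping closes (tissue-energy change equals
the time-integrated imbalance to integrator tolerance).

### Intake estimation

`estimate_intake` inverts the forward model. The observation span is cut
into consecutive windows (default 14 days; a piecewise-constant intake is
the finest resolution daily weights can support at realistic noise); within
each window the constant intake minimizing the sum of squared weight
residuals is found by bounded scalar minimization (±2500 kcal/day around
maintenance, xatol 0.25 kcal). The compartment state chains across windows
under the fitted intakes, starting from the baseline composition, so noise
does not re-anchor the state. Windows with fewer than two observations are
skipped and flagged, with the state advanced under the previous estimate.
With 0.3 kg daily noise and 28-day windows the recovered deficit of a
simulated −500 kcal/day client is unbiased with a per-client standard
deviation near 30 kcal/day.

## Weight-stream cleaning

Two rules, applied in timestamp order and fully audit-preserving (excluded
records keep their reason):

* **first-of-day** — earliest record per calendar date is retained, later
  ones marked `duplicate_same_day`; can be disabled for intraday studies.
* **±5 % filter** — a retained-candidate weight deviating strictly more
  than 5 % from the last *retained* weight is marked `outlier_gt_5pct` and
  never becomes the reference. Reading "last available" as last *retained*
  means a run of foreign weights (another household member on the scale)
  cannot poison subsequent comparisons, and makes the filter idempotent.
  Exactly 5 % is retained (an epsilon guard absorbs unit-conversion
  rounding at the boundary). Manual and device entries are cleaned
  identically, for auditability.

## Zone, flags, trigger

The zone is the predicted trajectory ± a band, default symmetric 2 % of
baseline weight (configurable as percent, absolute, or asymmetric). Flags
per client-day:

* GREEN — weight within [lower, upper], no warning condition.
* GREEN/YELLOW — in zone but (a) in the top 20 % of the band, or (b)
  *plateauing*: trailing 7-day least-squares slope non-negative with
  one-sided 95 % confidence (slope − 1.645·SE ≥ 0) while the prediction
  slopes down.
* RED — outside the zone (above without an adherent rate, or below).
* RED/GREEN — above the zone with trailing slope ≤ the predicted slope.
* NO_DATA — no retained weight.

The confidence requirement in (b) is a deliberate choice: daily weights
carry ~0.3 kg of hydration/clothing noise, so a raw 7-day slope has a
standard error (~0.06 kg/day) comparable to or larger than the predicted
loss rate (0.06 → 0.008 kg/day over a year). A raw `slope ≥ 0` rule would
flag a perfectly adherent client on 15–45 % of days; the one-sided test
keeps false plateau warnings near the nominal 5 % while still firing on
genuinely rising weight. Setting `plateau_z = 0` recovers the raw rule.
Slope conditions need ≥ 3 points in the trailing window; with fewer, only
the in/out position (and the positional top-of-band warning, which needs no
history) is evaluated.

The toolbox trigger fires when ≥ k of the most recent n daily flags
(default 3 of 5) are RED. RED/GREEN is excluded by default because it
signals recovering adherence (configurable). NO_DATA days occupy lookback
slots but never count toward k. Before n days of enrollment the trigger is
always false.

### A geometric limit on trigger latency

Under the defaults, a weight-stable (zero-adherence) client cannot be
flagged RED until the predicted center has fallen a full half-band below
baseline — 2 % of 90.7 kg ≈ 1.81 kg — and the model's initial loss rate
under −500 kcal/day is (1−β)·500/ρ ≈ 0.058 kg/day, so the earliest
sustained zone exit is ≥ 31 days regardless of noise. Monte-Carlo over 200
synthetic maintenance-intake clients puts the probability of triggering
within 30 days near 0.02, reaching >0.95 only around day 45. A target of
"trigger within 30 days" is therefore unattainable at the default band
width; programs wanting faster escalation should narrow the band (±1 % of
baseline reaches >0.95 by ~day 25) at the cost of more yellow/red noise for
adherent clients. The acceptance suite states the 30-day bound as given and
documents the measured probability rather than adjusting either default.

## Toolbox, tips, feedback

Episodes deploy the lowest-intensity strategy not yet
attempted-and-failed in the current escalation run; a success resets the
run (a later lapse is a fresh problem, so the cheapest remedy is retried
first); an exhausted catalogue raises a clinician-referral signal. An
episode succeeds if the final-day weight is back in the zone **or** the
least-squares slope over the episode is at most the predicted slope —
the operationalization of "improvement occurred", since a formula is
otherwise unspecified. Fewer than 3 retained weights defer evaluation and
extend the window by 7 days.

Tip delivery follows per-phase cadences (default weekly → biweekly →
monthly over three 8-week phases; "monthly" is 28 days for grid
determinism), with per-tip view/acknowledgment tracking. Feedback events
are template-driven and deterministic (template index = day mod catalogue
size): GREEN → congratulation + scheduled tip; fired trigger → toolbox
recommendation; ≥ 3 consecutive missing days → weigh-in reminder. Every
event records its provenance.

## Reports

Usage (days with weight/steps, graph and tip views), outcome (weight
change in lb and percent, zone-day partition: in + below + above +
no-data = days enrolled, enrollment day inclusive), toolbox (per-strategy
counts, per-episode weight change and mean steps), and group (per-client
rows plus mean/median). Percentages are rounded half-up to one decimal.
Counts use retained observations only.

## Synthetic clients

The generator emulates the telemetry the live system would receive. True
weight follows the forward model at effective intake
maintenance + adherence·Δ (+ lapse excess on lapse days); the scale adds
i.i.d. Gaussian noise, default sd 0.3 kg (day-to-day hydration/clothing
variation); days go missing at a configured probability (default 0.1);
foreign weights replace the day's record at probability 0.02 with an
offset drawn from ±6–12 % of true weight, which by construction exceeds
the 5 % filter so ground truth for the cleaning rules is unambiguous. Step
records arrive as two cumulative same-day syncs; view events emulate app
usage. Everything is a deterministic function of one integer seed.

What the generator does **not** model: autocorrelated water-weight cycles,
menstrual-cycle dynamics, weekend/weekday eating structure, or measurement
error correlated with weight. Tests passing on these clients demonstrate
the pipeline's logic and statistical calibration under idealized noise, not
field performance on real telemetry.

## Numerical choices and problem sizes

Adaptive RK45 at rtol 1e-8 agrees with a 0.01-day fixed-step Euler solution
to < 0.01 kg over a full year (cross-checked in tests). Monte-Carlo sizes —
200 clients for intake recovery and the end-to-end flag studies, 1000
series for the classifier/oracle comparison, 300 random streams for the
cleaning rules — were chosen to pin the estimated proportions to about a
percentage point while keeping the full suite around ten seconds.
Boundary conventions: exactly 5 % deviation retained; flag slope window
[d−6, d]; trigger evaluates only from day n of enrollment; zero-length
programs and horizons yield empty schedules and length-1 trajectories.

## Known limitations

The calibrated γ makes the model's long-run equilibrium shallower than
cross-sectional metabolism alone would predict; extrapolation beyond ~1–2
years or to prescriptions far from ±500 kcal/day inherits that choice.
The intake estimator assumes the baseline composition anchor is correct;
a biased baseline weight biases the first window's estimate. Flags are
computed from retained weights only, so an aggressive outlier filter can
convert real abrupt change into NO_DATA days until the reference
re-anchors. High-exercise programs need a different partition model and
are explicitly unsupported.
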