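# weightzone

A virtual weight-management engine for digital-health programs built around
daily self-weighing. Given a client's demographics and an energy
prescription (a kcal/day change from maintenance), it predicts the
individual weight-change trajectory from a dynamic energy-balance model,
draws a **zone of adherence** around that prediction, classifies each daily
weight into a color-coded adherence flag, estimates the energy actually
consumed from the weight record alone, tracks step goals, and drives an
escalating, fully auditable intervention toolbox. Everything is exercisable
offline on synthetic clients — no device integrations or external data are
required.

It is intended for researchers and engineers prototyping remotely delivered
weight-management interventions: the package is the analytic core such a
system needs, with file-based readers standing in for scale and
activity-tracker feeds.

## The model

Body weight is two compartments, fat mass *F* and fat-free mass *L*, with
constant energy densities ρ_F = 9400 and ρ_L = 1800 kcal/kg. A daily energy
imbalance between intake *I* and expenditure *E* is stored in (or drawn
from) the compartments according to the Forbes companionship rule — the
fat-free fraction of any mass change is α(F) = C/(C+F), C = 10.4 kg:

    dL/dt = α(F) · (I − E) / ρ(F),   dF/dt = (1 − α(F)) · (I − E) / ρ(F)

with ρ(F) = α ρ_L + (1−α) ρ_F the effective energy density of weight change.
Expenditure is anchored at baseline by a Mifflin–St Jeor resting metabolic
rate scaled by an activity factor (1.5, light-to-moderate activity), plus a
thermic effect of feeding of 0.10·I, and follows weight change at a
calibrated slope γ = 52.12 kcal/day per kg, which absorbs both the
cross-sectional weight dependence of expenditure and the adaptive
suppression seen under sustained restriction. γ is calibrated once so the
canonical worked example (50-year-old woman, 65 in, 200 lb, −500 kcal/day)
loses 17.4 lb, 8.7 % of baseline, over 12 months. Maintenance energy solves
I = 1.5·RMR + 0.10·I at baseline weight.

The same model runs in reverse: `estimate_intake` finds, per trailing
window of observed daily weights (default 14 days), the constant intake
whose forward trajectory best fits the observations in least squares —
an estimate of what the client actually ate.

Adherence is positional: the zone is the prediction ± 2 % of baseline
weight (configurable). Daily flags are GREEN (in zone), GREEN/YELLOW (in
zone but plateauing with one-sided 95 % confidence on the trailing 7-day
slope, or in the top 20 % of the band), RED (out of zone), and RED/GREEN
(above the zone but descending at least as fast as the prediction). Three
out-of-zone days in the last five (configurable k-of-n) escalate the client
into the toolbox, least-intense strategy first, each deployment evaluated
over a 14-day episode.

## Worked example

```
$ weightzone predict --sex female --age 50 --height-in 65 --weight-lb 200 \
      --delta-kcal -500 --days 365 --out trajectory.csv
maintenance energy: 2547 kcal/day
prescribed intake:  2047 kcal/day
predicted change over 365 days: -17.4 lb (-8.7%)
```

The maintenance line is the intake at which this client's weight is stable;
cutting 500 kcal/day from it is predicted to take her from 200.0 lb to
182.6 lb in a year, with the loss decelerating toward a plateau as
expenditure falls with weight. `trajectory.csv` holds the daily grid
(`day,predicted_weight_kg,predicted_weight_lb`).

A full virtual-clinic round trip on a synthetic client:

```
$ weightzone simulate --seed 7 --out-dir sim --days 90 --adherence 0.2
$ weightzone run --client-dir sim/client_000 --out-dir out
run complete for client_000: -1.8 lb over 90 days, 49.5% of days in zone,
3 toolbox episode(s); artifacts in out
```

The low-adherence client drifts above the zone, fires the 3-of-5 trigger,
and the engine escalates through the toolbox (the episode log in
`out/episodes.json` shows a failed `self_monitoring` episode followed by a
successful `increase_activity` one); `out/` also contains the cleaned
series, per-day flags, the feedback event stream, the rendered weight
graph, and usage/outcome/toolbox reports.

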