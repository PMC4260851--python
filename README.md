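# gaitsync

Closed-loop simulation of an adaptive music player that aligns its beat
with a walker's footfalls, plus the circular statistics used to evaluate
the result — no hardware, no audio.

## The problem

Runners and walkers synchronise to music spontaneously only under the
right conditions. An adaptive player can help by manipulating two things:
the music's **period** (stretch the tempo toward the observed cadence,
within the ±10% range a phase vocoder tolerates) and its **phase** (start
a song so its first beat lands on a predicted footfall, or keep nudging
the tempo so beats stay on the footfalls). Four controller designs span
this space:

| strategy | period | phase |
|---|---|---|
| 1 | adaptive every step | random |
| 2 | fixed per song | random |
| 3 | adaptive every step | aligned at song start (0° or 180°) |
| 4 | adaptive every step | continuously adapted to 0° |

`gaitsync` implements these controllers as an event-driven state machine,
couples them to a synthetic walker whose per-step phase correction follows
HKB coupled-oscillator dynamics (stable 0° attractor, weaker 180°
attractor, optional zero coupling for non-entrainers), and analyses the
resulting relative phases

φ = 360°·(t_step − t_prev_beat)/(t_next_beat − t_prev_beat), displayed in (−180°, +180°]

with the field's circular toolkit: mean direction with CI, mean resultant
length R, circular variance V = 1 − R, angular deviation s = √(2(1−R)),
circular skewness/kurtosis, the Rayleigh and Hodges–Ajne uniformity tests,
Watson's two-sample U², and per-participant synchronisation rates.

Intended users: movement-science and music-interaction researchers who
want to prototype alignment strategies or re-analyse footfall/beat event
logs (the analysis path runs on external CSV logs, not only simulations).

## Worked example

Compare the 0° and 180° starting-phase conditions of the phase-starting
strategy on a 10-walker cohort (10-minute trials, 30% non-entrainers):

```python
from gaitsync import StrategyConfig
from gaitsync.experiment import ExperimentConfig, CohortSpec, run_cohort

cfg = ExperimentConfig(
    conditions={
        "start0":   StrategyConfig(strategy=3, start_phase_deg=0.0),
        "start180": StrategyConfig(strategy=3, start_phase_deg=180.0),
    },
    cohort=CohortSpec(n_participants=10),
    duration_s=600.0,
    seed=7,
)
rep = run_cohort(cfg)
for lab, s in rep.pooled.items():
    print(f"{lab:9s} n={s.n:6d}  mean={s.mean_angle_deg:7.2f}deg  "
          f"R={s.R:.3f}  V={s.V:.3f}  s={s.s:.3f}  b={s.b:+.3f}  k={s.k:.3f}")
print("sync fraction:", rep.sync_fraction)
t = rep.watson[("start0", "start180")]
print(f"Watson U2 = {t.statistic:.3f}, p = {t.p_value:.2e}")
```

prints

```
start0    n= 11623  mean=  23.64deg  R=0.955  V=0.045  s=0.300  b=+0.005  k=0.834
start180  n= 11549  mean=-179.88deg  R=0.943  V=0.057  s=0.337  b=+0.000  k=0.795
sync fraction: {'start0': 1.0, 'start180': 1.0}
Watson U2 = 482.799, p = 0.00e+00
```

Read: both conditions lock the cohort (every participant individually
Rayleigh-significant), the 0° start concentrates phases near the beat with
the higher resultant length, the 180° start parks walkers at the weaker
anti-phase attractor, and Watson's U² confirms the two phase distributions
differ. Across all four strategies the pooled R orders
4 > 3(0°) > 2 > 1 — phase control matters more than period control.

The same pipeline is scriptable from the shell:

```
gaitsync simulate --config exp.yaml --seed 7 --out runs/
gaitsync analyze --footfalls f.csv --beats b.csv --out report/
gaitsync report --summary runs/summary.json --format markdown --out report/
```

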