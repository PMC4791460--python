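# alcatrack

Analysis pipeline for central-place-foraging seabird biologging data —
GPS tracks and time–depth-recorder (TDR) traces from breeding auks such
as the razorbill (*Alca torda*) — together with a synthetic-data
generator that provides ground truth for every stage.

The scientific questions the pipeline addresses:

1. **Do foraging routes cluster by breeding stage?**  Outbound paths are
   compared with the nearest-neighbour-analysis (NNA) distance — the
   mean distance from each point of one path to the nearest point of the
   other, symmetrised — then clustered hierarchically on the Euclidean
   distances between NNA-matrix rows, with node support from the
   approximately-unbiased (AU) multiscale bootstrap.
2. **Do trip duration and range differ between incubation and chick
   rearing?**  Linear mixed models with a per-bird random intercept,
   fitted by ML; evidence is |ΔAIC| > 2 against an intercept-only null.
3. **Where do birds dive, and is it productive?**  Dives (> 1 m after
   zero-offset drift correction) are positioned on the 1 Hz
   spline-interpolated track, colony bearings θ are compared across
   stages with two-sample KS tests, and chlorophyll-a is sampled at dive
   locations and tested inside vs outside a region of interest (ROI)
   with Bonferroni-corrected Welch t-tests and a bootstrap of random
   ROI-sized boxes.
4. **Is the aerial search heavy-tailed (Lévy-like) or exponential?**
   Turchin reorientation steps at mild (π/4) and radical (7π/8) turning
   thresholds; power-law and exponential models are fitted by least
   squares to the CCDF of step lengths normalised by the minimum
   observed length l_min,

       P(L > l) = (l / l_min)^(1 − μ),

   from the density (μ − 1) l_min^(μ−1) l^(−μ).  Exponents 1 < μ ≤ 3
   indicate heavy-tailed movement; μ > 3 is the signature of motion
   with a characteristic scale (effectively exponential).

Dive bouts are delimited by the bout-ending criterion: a two-process
exponential mixture fitted by maximum likelihood to inter-dive surface
intervals, with

    t_bec = ln((p_f λ_f) / (p_s λ_s)) / (λ_f − λ_s).

## Worked example

```python
import numpy as np
from alcatrack import simulate as sim, trips as tp, steps as st, dives as dv

cfg = sim.SimConfig(seed=42, n_birds=6, trips_per_bird=2.0, trips_per_bird_sd=0.5)
_, data = sim.gen_cohort(cfg)

all_trips = []
for bird_id, d in data["birds"].items():
    all_trips += tp.segment_trips(d["gps_xy"], bird_id=bird_id, stage=d["stage"])
table = tp.trip_table(all_trips)
res = tp.stage_effect_aic(table, "max_range_km")

fit = st.fit_ccdf(sim.gen_levy_steps(5000, 2.0, 1000.0, 42), "powerlaw")

intervals = []
for d in data["birds"].values():
    recs = dv.detect_dives(dv.zero_offset_correct(d["tdr"]["depth_m"].to_numpy()))
    intervals.append(dv.inter_dive_intervals(recs))
bm = dv.bout_ending_criterion(np.concatenate(intervals))
```

prints (via the formatting in the repository's example snippets):

```
10 trips from 6 birds
duration  3.2 +/- 0.9 h
max range 32.0 +/- 14.7 km
stage effect on range: 18.82 +/- 6.73 km, |dAIC| = 3.2
step-length fit: mu = 1.98 +/- 0.0001 -> heavy_tail
435 dives pooled, bout-ending criterion = 126 s
```

Reading the numbers: six synthetic birds made ten foraging trips beyond
the 1-km colony radius; incubating birds ranged ~19 km further than
chick-rearing birds and the mixed model prefers the stage model by 3.2
AIC units (evidence threshold 2).  A 5,000-step sample drawn from a
power law with true μ = 2 is fitted back at μ = 1.98 and labelled
heavy-tailed.  Pooled inter-dive intervals give a bout-ending criterion
of 126 s: surface pauses shorter than that are within a dive bout.

A command-line interface wraps the same functions:

```sh
alcatrack simulate --seed 1 --n-birds 18 --out cohort/
alcatrack trips-segment cohort/gps/bird_00.csv --colony -5.30 51.74
alcatrack dives-detect cohort/tdr/bird_00.csv
alcatrack pipeline cohort/ --nboot 1000 --out report.json
```

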