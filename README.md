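# odorsearch

Reactive versus cognitive odor-source localization, as a desk-scale
simulation and analysis pipeline.

Male moths find pheromone-releasing females despite turbulence breaking the
odor plume into sparse, intermittent patches.  Behavioral and
electrophysiological work suggests a simple reactive program: every
detection triggers a straight **upwind surge** (the On response of
multiphasic antennal-lobe neurons), a lost plume triggers **crosswind
zigzag casting** (the transient Off response), and prolonged silence falls
back to **spiral casting** (baseline).  The alternative is a *cognitive*
strategy, **infotaxis**, which maintains a Bayesian posterior over source
locations and greedily maximizes expected information gain.

This package rebuilds that comparison entirely on the desk:

* `odorsearch.plume` — the turbulent-plume mean encounter-rate field
  `R(r|r0) = R0/ln(λ/a) · exp((y0−y)V/2D) · K0(|r−r0|/λ)` with
  `λ = sqrt(Dτ/(1+V²τ/4D))`, Poissonized into detection events,
  plus the 90% parabolic plume contour;
* `odorsearch.reactive` — the three reactive state machines: `sp`
  (surge + arithmetic spiral), `za` (surge + zigzag + arithmetic spiral),
  `ze` (surge + zigzag + exponential spiral), with exact arc-length spiral
  kinematics and doubling zigzag legs at ±60°;
* `odorsearch.infotaxis` — the lattice belief, Poisson likelihood updates,
  Shannon entropy, and the five-action expected-entropy-gain rule;
* `odorsearch.arena` — trial orchestration in the 2.5 m × 4 m arena
  (start (0,0), source (0,2), 20 cm success disk), outcome adjudication,
  batches, and emission-rate calibration;
* `odorsearch.analysis` — path length, horizontal deviation Δx, track-angle
  histograms, >55° turn counts, success-rate summaries (mean of per-dose
  percentages), two-way ANOVA + pairwise Wilcoxon rank-sum reports, and
  notched box-plot summaries;
* `odorsearch.spikes` — PSTH, Bl/On/inhibition/Off segmentation, local
  coefficient of variation (CV2), trial-to-trial correlation, Fano factor,
  and the detection-event criterion (≥3 ISIs < 70 ms followed by an
  ISI > 350 ms);
* `odorsearch.synthetic` — seeded generators for triphasic and monophasic
  spike-train sets and plume detection sequences.

## Worked example

The packaged success/total counts of the original robotic assay reproduce
the published aggregate rates (the aggregate is the arithmetic mean of the
per-dose percentages):

```
$ odorsearch reproduce-table1-summary
Success rates (percent, mean of per-dose percentages)
  across strategies: minimum=85, medium=91, maximum=88
  per strategy (stimulated doses): sp=85, za=89, ze=84, it=93
  per strategy (all doses):        sp=68, za=71, ze=67, it=88
```

Infotaxis averages 93% over stimulated trials; the per-dose averages show
no dose dependence (85/91/88%).

Simulating ten maximum-dose trials and analyzing them shows the headline
efficiency result — zigzag casting beats spiral-only casting:

```
$ odorsearch simulate --strategy ze --dose max --n-trials 5 --seed 1 --out demo/run
5/5 successful trials written to demo/run
$ odorsearch simulate --strategy sp --dose max --n-trials 5 --seed 1 --out demo/run
5/5 successful trials written to demo/run
$ odorsearch analyze --run-dir demo/run
10 trials, 100% successful
  median path length sp/maximum: 4.61 m
  median path length ze/maximum: 3.20 m
```

Both strategies find the source, but the spiral-only searcher walks ~44%
farther: with the source two meters upwind and a 20 cm success disk, the
shortest possible path is 1.8 m, so `ze` carries ~78% overhead against
`sp`'s ~156%.

The same objects are available as a library:

```python
import odorsearch as osx

plume = osx.PlumeParams()            # calibrated turbulent-plume model
arena = osx.ArenaConfig()            # 2.5 x 4 m arena, source at (0, 2)
trials = osx.run_batch("za", "medium", plume, arena, n_trials=50, seed=0)
table = osx.metric_table(trials)     # path_length, delta_x, n_turns, ...
report = osx.compare_groups(table)   # ANOVA + pairwise Wilcoxon with stars
```

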