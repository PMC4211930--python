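# Methods

## The task

An agent starts at (0, 0) in a 2.5 m × 4 m arena and must reach a 20 cm
disk around an odor source at (0, 2), two meters upwind.  Wind blows
toward −y at V = 0.88 m/s.  A trial fails when the agent leaves the arena
or exceeds its time budget (600 s wall-clock for reactive strategies, 125
actions for infotaxis).  Everything is a pure function of configuration
and seed.

## Plume encounter model

Turbulence makes odor arrive as discrete patch encounters, modeled as an
inhomogeneous Poisson process with mean rate

    R(r | r0) = R0 / ln(λ/a) · exp((y0 − y) V / 2D) · K0(|r − r0| / λ),
    λ = sqrt(D τ / (1 + V² τ / 4D)),

for emission rate R0, patch lifetime τ, effective diffusivity D, wind V
and agent size a.  The advection exponential enhances the rate downwind of
the source; K0 is the modified Bessel function of the second kind.  The
K0 singularity is capped at distance a (a sensor has finite extent), and
the product is evaluated in exponentially-scaled form (`k0e`) so the
advection factor cannot overflow for sharp plumes.

**Environment calibration.**  No numeric plume parameters are available
for the original assay, so the environment was calibrated once,
against pilot batches, to reproduce the assay's *behavioral* regularities
(high reactive success at stimulated doses, low success without stimulus,
shorter paths at higher doses, zigzag strategies beating spiral-only
casting).  Defaults: R0 = 0.5 /s, τ = 400 s (patches outlive a trial),
D = 0.01 m²/s, a = 0.01 m, giving λ ≈ 0.023 m and a plume whose 1/e
half-width grows from ~0.2 m near the source to ~0.3 m at the start — a
narrow core consistent with a parabolic 90%-detection contour.  Dose
levels multiply R0 by 0/1/2/3 (none/minimum/medium/maximum): the effective
detection-event rate of an antenna saturates far below the 10-fold ratio
of the applied solution concentrations.  A position-independent false
detection rate of 0.005 /s emulates spurious sensor events; over a long
no-stimulus trial this yields detection counts of the same order as a
minimum-dose trial.  `arena.calibrate_emission` re-fits R0 to a target
mean detections-per-trial by integrating the rate along frozen pilot
paths, which makes the fit exactly linear in the target; the single-shot
fit carries a path-feedback bias of order 10–15% for large perturbations.

## Reactive strategies

All three strategies share the detection reflex: any detection restarts a
5 cm straight upwind surge (1 s at the 5 cm/s cruise speed).  What follows
a surge without further detections differs:

* `sp` — spiral casting immediately (the behavior a monophasic On-only
  neuron could drive);
* `za`, `ze` — crosswind zigzag casting: legs alternate ±60° about upwind,
  the first leg is 9 cm and every later leg doubles (equivalently, the leg
  length doubles at each crossing of the centerline through the position
  where zigzagging began, since every leg after the first crosses it
  exactly once).  After 19 s without a detection, zigzagging gives up and
  falls back to spiral casting — arithmetic for `za`, exponential for
  `ze`.

Spirals are ideal curves traversed at constant speed with exact arc-length
phase advance (closed-form inversion for the exponential, Newton on the
closed-form arc length for the arithmetic).  The original robot generated
its spirals from wheel-speed differences that are not reproducible here,
so their geometry is a design choice:

* casting starts **crosswind** — the entry tangent points 90° off the
  current heading, on a side that alternates between bouts so casting has
  no net lateral drift (a fixed handedness produces a systematic ~0.4 m
  lateral bias that strands the agent beside the plume);
* arithmetic spirals enter at a finite radius matching the spatial scale
  of the preceding phase: 0.05 m after a surge (`sp`), 0.1 m after the
  wide zigzag legs (`za`); pitch 0.024 m/rad;
* the exponential spiral (r = r0·e^{gφ}, r0 = 0.075 m, g = 0.2/rad) was
  chosen for overshoot recovery: in a deterministic probe started 0.3–0.4 m
  upwind of the source, it re-enters the plume with ~25% less path than
  the arithmetic spiral, which is the stated purpose of the exponential
  variant.  Mid-plume, where casts are interrupted by detections within a
  second or two, the two spiral kinds are nearly equivalent, and the
  za–ze path-length difference is on the order of 1% — matching the
  original finding that za–ze differences were not statistically
  significant.

Simulation tick: 0.1 s, with mode transitions resolved exactly within a
tick (leg and surge lengths do not depend on the tick).  Detections are
sampled once per tick.  Optional odometry noise (Gaussian position jitter
per tick) is off by default.

## Infotaxis

The belief lives on a 0.1 m lattice aligned with the start position
(25 × 41 cells), uniform prior minus the start cell.  After each action
the agent observes a Poisson count k over the dwell time (step/speed +
1 s wait = 3.5 s for moves at the 4 cm/s default; 3 s for `stay`) and
multiplies each cell's weight by Pois(k; R(pos|cell)·dt), zeroes the
occupied cell, and renormalizes.  Actions are forward/backward/left/
right/stay; the chosen action maximizes

    gain(a) = P_found·S + (1 − P_found) Σ_k ρ_k (S − S|k),

with the count expectation truncated to k ∈ {0, 1} (ρ1 = 1 − ρ0; a full-k
variant is available via `k_max`).  Ties are broken uniformly with the
trial's generator, one draw per decision, so episodes replay exactly.

The agent's likelihood model is deliberately *not* the environment plume:
the original robot's model parameters were calibrated to match measured
detection rates, not the physical plume.  With the environment's λ ≈ 2 cm,
silence carries almost no information on a 10 cm lattice and the agent
degenerates to a tie-broken random walk.  The model plume therefore uses
D = 0.25 m²/s (λ ≈ 0.57 m), a = 0.1 m (one step), R0 = 0.2 /s scaled with
the dose; at dose `none` it keeps the minimum-dose R0, because the
searcher does not know the source is absent.

## Trajectory analysis

Track angles are movement directions relative to upwind, computed on
segments resampled to 2 cm equal arc length so histograms are independent
of the simulation tick; bins are 10° wide and centered on multiples of
10°.  Turn counting defaults to the literal rule — count resampled
segments with |track angle| > 55° — with an event mode (heading *changes*
above threshold) available because the literal rule depends on segment
length.  Success-rate aggregates are arithmetic means of per-dose
percentages, the convention that reproduces the published aggregate rates
from the per-cell counts; pooled counting is available via a flag.
Group statistics: two-way ANOVA (strategy × dose, via statsmodels) on the
chosen metric and pairwise two-sided Wilcoxon rank-sum tests for all
strategy pairs per dose and dose pairs per strategy, reported with the
conventional star thresholds (*** < 0.001, ** < 0.01, * < 0.05) plus a
Holm-adjusted column.  Box summaries use median, quartiles, notches
median ± 1.58·IQR/√n, and outliers beyond 2.5·IQR from the quartiles.

## Spike-train statistics

The PSTH is the trial-averaged rate per bin.  Segmentation is a
threshold-crossing rule on the PSTH: the On starts at the first post-onset
bin above the baseline mean + 3 SD and ends at the first bin below the
baseline mean; if firing resumes within 0.1 s the response is labeled
monophasic (no inhibition, no Off windows), otherwise consecutive Off
windows of 2.5 s start at the first post-inhibition spike.  The local
coefficient of variation CV2 = mean of 2|Iᵢ₊₁−Iᵢ|/(Iᵢ₊₁+Iᵢ) over adjacent
ISI pairs; trial correlation is the mean pairwise Pearson correlation of
binned counts (pairs with *identical* vectors count as 1 — a zero-jitter
trial-locked On is perfect synchrony — while unequal pairs with a
zero-variance member are skipped); the Fano factor is the across-trial
variance/mean of per-bin counts averaged over bins.  Count statistics use
50 ms (correlation) and 125 ms (Fano) bins by default; the sub-millisecond
values printed in the source material are treated as a unit typo and
remain reachable through the bin-size arguments.  The detection-event
criterion fires at the spike ending the first ISI > 350 ms that
immediately follows at least three consecutive ISIs < 70 ms.

## Synthetic data

Spike-train generators are pure functions of (spec, seed).  The triphasic
default emulates the recorded response structure at seven trials: 5 Hz
Poisson baseline (CV2 ≈ 1, Fano ≈ 1), a 100 Hz On burst of 0.3 s drawn
once per set as a gamma-renewal template (shape 100, CV ≈ 0.1) shared
across trials up to optional Gaussian jitter, a 0.3 s silent inhibition,
and an Off phase decaying from 20 Hz back to baseline with a 3 s time
constant, generated as an inhomogeneous gamma-renewal process (shape 4)
via time rescaling so its regularity is intermediate.  The monophasic
generator returns straight to Poisson baseline after the On.

What the generators do **not** emulate: real MGC recordings have
refractory periods, rate adaptation within the On, across-neuron
heterogeneity, and jitter that grows through the burst.  Passing tests
therefore show that the statistics separate the regimes the generators
encode, not that they would segment arbitrary real recordings.

## Problem sizes and numerical choices

The test suite runs 150 trials per reactive strategy × stimulated dose
(60 at no stimulus) and compares medians; orderings whose populations may
legitimately tie (`ze` vs `za`, medium vs maximum dose) are asserted as
"not significantly greater" with one-sided rank-sum tests at α = 0.05,
while orderings the data affirm strictly (`za`/`ze` vs `sp`) are asserted
both on medians and at α = 0.01.  The acceptance script runs 60 trials per
stimulated cell and 40 at no stimulus.  Gain ties in infotaxis use a
1e-12 tolerance; belief updates renormalize each step and raise on an
all-zero posterior rather than silently resetting.

## Known limitations

* The simulated infotaxis agent is noiseless and the task is only 20
  steps deep, so its trajectories are nearly straight (median Δx ≈ 0, few
  sharp turns) and its median path length rivals the zigzag strategies —
  unlike the turn-rich, longer robotic infotaxis paths.  Its track-angle
  mass still lies entirely on the four cardinal directions.
* Cross-strategy Δx and turn-count orderings of the robotic assay are
  reproduced only partially (Δx(sp) exceeds the zigzag strategies at
  minimum dose only); these quantities depended on robot kinematics the
  simulation does not model.
* Detection physics is per-tick Poisson: no patch persistence, no bursty
  EAG artifacts, no sensor refractoriness.
* The false-positive mechanism is a uniform rate, so no-stimulus success
  rates (reactive ~5–35%) bracket but do not pin the assay's 17%.
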