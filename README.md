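# polscope

Does a fish with a faster metabolism take more risks? The
pace-of-life-syndrome (POLS) hypothesis says it should: individuals
with higher baseline energy demands are predicted to be bolder in
securing resources. `polscope` is a tested, reusable pipeline for
putting that prediction to work in adult zebrafish, for behavioral
ecologists and ecophysiologists who measure **routine metabolic rate
(RMR)** by closed-chamber respirometry and **boldness** in the novel
tank test — and for anyone who wants to power-check such a study before
running it, using simulated cohorts with known ground truth.

## What it computes

**Metabolism.** Blank-corrected oxygen consumption per 30-min trial,

    [O₂]_consumed = ([O₂]_f,1 − [O₂]_f,2) − ([O₂]_b,1 − [O₂]_b,2),

where *f* and *b* index the fish and blank chambers and 1, 2 the trial
start and end; RMR = [O₂]_consumed / mass (mg O₂/l/g per trial), with
QC that excludes non-positive consumption.

**Behavior.** Six measures from a 3D novel-tank trajectory: bottom
distance, center distance (thigmotaxis), distance traveled, percent of
1000 tank voxels explored, percent of time immobile (speed < 1.5 mm/s),
and max velocity (median of the top 5% of speeds). Boldness is the sum
of within-sex×strain z-scores of percent explored and bottom distance.

**Statistics.** The study's full battery: Shapiro–Wilk-gated
Pearson/Spearman correlations, one-way ICC repeatability with a
1000-resample subject bootstrap, 2×2 permutation ANOVAs (10,000
resamples, Type II SS, η²), gated Welch-t / Mann–Whitney / paired-t /
Wilcoxon signed-rank comparisons with Cohen's d, and the conventional
effect-size bands.

**Simulation.** A cohort generator with a latent bivariate-normal
(metabolic, boldness) trait pair at configurable correlation ρ_true,
allometric mass scaling of consumption, a persistent-random-walk
movement model whose depth preference and speed are driven by the
boldness trait, and a 16-h fasting manipulation (crossover for
respirometry, between-groups for behavior). See `docs/methods.md` for
the model and every default.

## Worked example

```python
from polscope import (CohortConfig, generate_cohort, compute_rmr, pair_sessions,
                      correlation_auto, icc_oneway, extract_profile, boldness_index)
from polscope.respirometry import results_to_frame
from polscope.trajectory import profiles_to_frame

# 4 cells x 30 fish, two respirometry days, no true metabolism-boldness link
cfg = CohortConfig(n_per_cell=30, rho_true=0.0, n_days=2)
table, truth = generate_cohort(cfg, seed=1)

results = [compute_rmr(r) for r in table.respirometry]
pairs, dropped = pair_sessions(results)
rep = correlation_auto(pairs["o2_consumed_day1"], pairs["o2_consumed_day2"])
icc = icc_oneway(pairs["o2_consumed_day1"], pairs["o2_consumed_day2"],
                 n_boot=1000, seed=1)
print(f"day-to-day consistency: {rep.method} r={rep.coefficient:.2f} (n={rep.n})")
print(f"repeatability: ICC={icc.estimate:.2f}, 95% CI=({icc.ci_low:.2f}, {icc.ci_high:.2f})")

profiles = [extract_profile(t) for t in table.trajectories.values()]
metrics = profiles_to_frame(profiles).merge(table.metadata, on="fish_id")
scored = boldness_index(metrics)
rmr = results_to_frame(results).query("session_day == 1 and qc_pass")[["fish_id", "rmr"]]
cell = scored.merge(rmr, on="fish_id").query("strain == 'TU' and sex == 'female'")
res = correlation_auto(cell["boldness_index"], cell["rmr"])
print(f"TU female boldness~RMR: {res.method} r={res.coefficient:.2f}, "
      f"p={res.p_value:.2f} (n={res.n})")
```

prints

```
day-to-day consistency: spearman r=0.81 (n=120)
repeatability: ICC=0.83, 95% CI=(0.75, 0.87)
TU female boldness~RMR: pearson r=-0.02, p=0.91 (n=30)
```

Read: oxygen consumption is a stable individual trait across days
(ICC 0.83 — the simulator plants repeatable metabolic phenotypes), and
with ρ_true = 0 the boldness×RMR correlation is, correctly, nothing
(r = −0.02, p = 0.91). Plant ρ_true = 0.6 instead and the screen lights
up.

## Command line

```
polscope simulate --seed 1 --outdir cohort/          # raw-data CSVs + ground truth
polscope metrics  --trajdir cohort/trajectories --out metrics.csv
polscope respiro  --in cohort/respirometry.csv --out rmr.csv
polscope analyze  --main cohort/ --outdir reports/   # analyze ingested data
polscope all      --seed 1 --outdir study/           # full simulated study
```

`polscope all` runs the complete design — repeatability, the
mass–consumption check, the sex×strain ANOVA on RMR, the
boldness/behavior × RMR correlation screen, and the fasting
manipulation — and writes `report.json`, tidy CSV tables, and a log of
every normality-gate decision. Reports are byte-identical across runs
with the same config and seed.

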