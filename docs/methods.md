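# Methods

`polscope` tests the pace-of-life-syndrome (POLS) prediction — that
individuals with higher baseline metabolic rates take more risks — in
adult zebrafish, using simulated cohorts with known latent structure so
that every stage of the analysis can be validated end to end.

## Measures

**Routine metabolic rate (RMR).** A fish swims freely for 30 min in a
sealed 500 ml chamber; dissolved O₂ (mg O₂/l) is read at the start and
end. A fish-free blank chamber run in parallel captures drift from
degassing and temperature, which is subtracted:

    O₂_consumed = ([O₂]_fish,t1 − [O₂]_fish,t2) − ([O₂]_blank,t1 − [O₂]_blank,t2)

RMR is O₂_consumed divided by body mass, reported **per trial** (mg
O₂/l/g per 30 min), not per hour: trials share a duration and chamber
volume, so any time or volume rescaling is a constant factor; the
duration is retained in the record so a per-hour transform is trivial.
Chamber volume is likewise not folded into the value (concentration
units with equal volumes); an absolute-mg variant is available via
`compute_rmr(..., absolute_mg=True)`.

QC excludes sessions with O₂_consumed ≤ 0. A live fish must consume
oxygen over 30 min; negative values indicate data-entry or instrument
error, and 0 is grouped with them as physiologically impossible. A
missing fish or blank reading invalidates the record outright — the
blank correction is the method's core, so no imputation is attempted.

**Behavior.** A 6-min novel-tank trial in a 15×15×15 cm tank yields a
single tracked 3D point per frame, from which six measures are taken:

- *bottom distance* — time-mean height above the floor (cm);
- *center distance* — time-mean horizontal distance from the tank's
  central vertical axis (cm), the thigmotaxis readout. Whether this
  should be measured in the horizontal plane or in 3D is a convention
  choice; the horizontal-plane reading matches the thigmotaxis
  interpretation and is the default, with a 3D variant behind
  `center_convention="3d"` for sensitivity analysis;
- *distance traveled* — summed frame-to-frame displacement (cm), with
  no smoothing: smoothing would shift the immobility break, and raw
  displacement is what the voxel and velocity measures see;
- *percent explored* — the tank is divided 10×10×10 into 1000 voxels
  (the natural factorization for a cube); a voxel counts as visited if
  any frame falls in it. Cells are half-open with the last cell closed
  at the wall so boundary positions always bin;
- *percent immobile* — share of inter-frame steps with speed strictly
  below a cut-off (default 1.5 mm/s, the conventional break between the
  immobile and swimming modes). `detect_immobility_threshold` can
  re-derive the cut-off from data as the deepest valley of a
  kernel-smoothed log₁₀-speed density between its two dominant modes;
  when no two-mode structure exists it falls back to the default and
  says so. Strict `<` at the boundary is immaterial for continuous data
  but fixed for testability;
- *max velocity* — the median of the top 5% of frame-to-frame speeds
  (mm/s), robust to single-frame tracking glitches. The top subset has
  ⌈0.05·n⌉ elements so it is never empty; at least 20 samples are
  required for the statistic to mean anything.

**Boldness index.** Percent explored and bottom distance — the two
measures that best separate bold from shy fish — are z-scored within
each sex × strain group (sample SD, n−1: groups are small and this is
the convention in behavioral scoring) and summed. Sum rather than mean:
the two differ by a constant factor, so every downstream correlation is
identical; the sum is documented as the definition.

## Statistical battery

- **Normality gate.** Shapiro–Wilk at α = 0.05 decides between
  Pearson's r and Spearman's ρ for correlations, and between
  Welch-t/paired-t and Mann–Whitney/Wilcoxon signed-rank for two-group
  comparisons (paired designs gate the per-subject differences). Every
  gate decision is logged in the report.
- **Repeatability.** One-way random-effects single-measure ICC
  (ICC(1,1)) across two sessions — the simplest estimator consistent
  with two unlabeled session columns; the day-label-swap invariance test
  documents this choice. 95% CI by percentile bootstrap over subjects
  (default 1000 resamples). Negative estimates (within-variance
  dominating) are reported as computed and flagged, not truncated.
- **Permutation ANOVA (2×2).** Observed F per term from the
  fixed-effects two-way ANOVA with interaction, Type II sums of squares
  (reduces to Type I when balanced; handles the unbalanced published
  cell sizes). The null distribution permutes the raw response vector
  wholesale (default 10,000 resamples) — exact under the global null
  being tested and verifiable by enumeration on tiny inputs, which is
  why raw-response permutation was chosen over residual permutation.
  p = (1 + #{F* ≥ F_obs}) / (1 + n_perm), so p ∈ (0, 1]. η² =
  SS_term/SS_total from the observed decomposition.
- **Effect sizes.** Pooled-SD Cohen's d for independent two-group
  designs (the classical form; a Welch-style denominator would differ
  only slightly and the pooled form is the conventional referent for
  the interpretation bands). Bands: small 0.01 < η² < 0.06,
  0.2 < d < 0.5; medium 0.06 ≤ η² < 0.14, 0.5 ≤ d < 0.8; large
  η² ≥ 0.14, d ≥ 0.8; below-small is negligible. Boundary values follow
  the inequalities exactly.
- **Rank tests.** Exact null distributions below 26 per group (no
  ties), tie/continuity-corrected normal approximation above. The
  paired nonparametric test is the Wilcoxon *signed-rank* test — the
  only coherent paired reading, since the rank-sum test is an
  independent-samples procedure.
- **Multiple testing.** The correlation screen reports raw p-values (as
  is conventional for this assay's screen) plus a Benjamini–Hochberg
  column for readers who want it; no correction is applied to the
  decisions.

## The cohort simulator

Each fish carries a latent `(metabolic_trait, boldness_trait)` pair,
bivariate standard normal at correlation ρ_true — the POLS link under
test, settable to 0 (the null), or any planted value for power and
recovery studies. Body mass is log-normal per sex (median 0.9 g female,
0.6 g male, σ_log 0.25: positive, right-skewed, in the adult zebrafish
range, females heavier).

**Respirometry.** True consumption is
`rmr_per_gram · mass^0.8 · exp(0.2·metabolic_trait)` mg O₂/l per trial
(`rmr_per_gram` = 2.0 gives ≈1.5 mg O₂/l for a typical fish — a
readily measurable drop against an 8.0 mg/l baseline). The mass
exponent 0.8 is intermediate allometric scaling — larger fish consume
more in total but less per gram — and is fully configurable. Both
chambers drift by `blank_drift` (0.1 mg/l per trial); every reading
gets i.i.d. noise (sd 0.1 mg/l, typical optical-meter accuracy), and a
log-normal session factor (σ = 0.08) models day-to-day biological
variability in activity state. These two within-fish terms against the
between-fish spread from mass and trait put day-to-day repeatability at
ICC ≈ 0.75–0.85, matching what stable metabolic phenotypes show in
practice. Since mass-per-gram scaling goes as mass^(−0.2), the lighter
males have slightly higher RMR — the sex effect emerges from the mass
structure without a separate knob. A 16-h fast multiplies consumption
by 0.85 (a moderate, physiologically plausible suppression), applied
within fish in the crossover design (fed and fasted sessions two days
apart, order randomized) or between groups for the behavior cohort.

**Movement.** No trajectory model is implied by the measures
themselves, so the simplest process expressing all six was chosen: a
persistent random walk (per-axis AR(1) velocity, persistence 0.9 at 30
frames/s) with an Ornstein–Uhlenbeck-style vertical relaxation (rate
1 s⁻¹) toward a preferred height z* = h_eff·15 cm, gated by a two-state
moving/frozen Markov chain (onset 0.02 s⁻¹, offset 0.2 s⁻¹ → ≈9% of
time frozen), inside reflecting walls. Reflection is implemented by
folding the unconstrained path with the tent map — the standard exact
reflection for additive increments — which keeps positions in-tank
without absorbing states and lets the whole path be computed by linear
filtering rather than a per-frame loop. The fish starts at the
horizontal center at z*, so the degenerate zero-speed configuration
stays put exactly.

Boldness reaches behavior through exactly two channels so the index's
ingredients are its direct readouts: preferred height
(logit(h_eff) = logit(0.45) + 0.6·boldness) and locomotor speed
(speed = 40·exp(0.25·boldness) mm/s). Mean height is therefore strictly
increasing in boldness, and exploration increases through both height
range and diffusivity. The frame interval defaults to 1/30 s — a plain
assumption about consumer depth cameras, not a measured value — and the
trial length to the standard 6 min.

**What the simulator does not emulate.** Tracking error and identity
loss, pose keypoints (fish are single points), wall-following bias,
social or startle behavior, temperature effects on metabolism, and any
tank-position or time-of-day effects. Passing recovery tests therefore
show the *analysis* is correct and calibrated, not that real zebrafish
behave like the movement model; with real data the attenuation of a
true metabolism–boldness correlation could differ substantially from
the simulated one.

## Numerical and design choices

- All randomness flows from `numpy.random.default_rng` seeds; cohort
  generation derives per-fish seeds from the cohort seed, and the study
  derives block seeds from the master seed via `SeedSequence.spawn`.
  Identical (config, seed) give byte-identical reports.
- Permutation p-values use +1 smoothing and `F* ≥ F_obs` with no
  tolerance; with continuous responses ties have probability zero.
- A degenerate all-equal response vector defines every F as 0, p = 1,
  η² = 0.
- Zero-variance groups are rejected by name in z-scoring and skipped
  with a log entry in the correlation screen (a constant metric carries
  no correlation information).
- `simulate_respirometry` flags sessions whose drop would exceed the
  chamber baseline (anoxia) rather than emitting negative O₂ readings.
- Problem sizes in the test suite are scaled to the check at hand:
  oracle-equivalence runs use 100 random trajectories of 60–250 frames;
  calibration studies use 200–500 replicates with 1000-resample
  permutations and 500-resample bootstraps; pipeline determinism tests
  use 20–30 s trials. The acceptance script runs the full published
  design (126 + 91 + 133 fish, full-length trials, 10,000 permutations,
  1000 bootstraps).

## Known limitations

- The movement model's stationary height distribution is only
  approximately centered on z* when z* sits near a wall (folding skews
  it inward); the long-run mean test tolerates this within 10%.
- ICC here is the one-way single-measure form; mixed-model
  repeatability (e.g. with fixed session effects) would differ when a
  systematic day effect exists. The simulator has no day effect, and
  the estimator choice is documented so users can compare.
- The crossover fasting ANOVA treats the two sessions of a fish as
  independent observations, mirroring the published analysis; the
  paired tests alongside it are the within-fish complement.
- In ingest mode the pipeline trusts upstream tracking: no outlier or
  gap handling is applied to trajectories.
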