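# Methods

`atsdnet` analyses repeated-measures time-series omics data (the motivating
application is serum lipidomics along a stepwise disease course) by tracking
how the *ratio* of every feature pair changes between adjacent time points,
turning those changes into signed dynamic networks, and mining the networks
for early-warning biomarker-ratio candidates. This note records the model,
the numerical choices, and the limits of what the synthetic validation shows.

## The model

### Feature ratios and effective ranges

For features `f_i`, `f_j` (canonical order `i < j`) the per-sample ratio at
time point `T_t` is `r_ijt = f_it / f_jt`. A ratio is read as a proxy for the
net conversion between two metabolites, which makes its *change over time*
the biologically interesting quantity, and makes every statistic invariant to
per-feature rescaling (calibration, unit choice).

At each time point the ratio's sample distribution is summarised by an
**effective range**

```
[u − h, u + h],   h = 2 · p_t · γ · σ
```

where `u` and `σ` are the sample mean and standard deviation of `r_ijt`
(population divisor `n`, i.e. a plain average of squared deviations over the
`n` repeated measures; switchable via `ddof`), `γ = 1.732 ≈ √3` is the
Chebyshev coefficient — at least `1 − 1/γ² = 2/3` of the population falls
within `u ± γσ` regardless of distribution — and `p_t` is the *sample
probability* of `T_t` inside the two-point window a network is built from:
`p_t = n_t / (n_t + n_{t+1})`. When both points carry the same subjects,
`p_t = 0.5` on both sides and the half-width reduces to `γσ`. The
probability enters both bounds symmetrically. For normal data the range
`u ± 1.732σ` empirically covers ≈ 91.7 % of samples (the suite checks this
by simulation); the 2/3 Chebyshev bound is the distribution-free floor.

### The non-overlapping ratio (NOR)

Between adjacent time points the two effective ranges change in one of four
ways: **upshift** (both bounds strictly increase), **downshift** (both
strictly decrease), **nested** (one range inside the other, bounds
inclusive), or **identical**. Nested and identical changes are regarded as
uninformative about directed pathway disturbance and carry no statistic.
For the two shift cases,

```
|NOR| = (L1 + L2 − 2·O) / (L1 + L2)
```

with `L1`, `L2` the range lengths and `O = max(0, min(ceilings) −
max(floors))` the overlap length; the sign is `+` for an upshift, `−` for a
downshift. `|NOR| = 1` exactly when the ranges are disjoint, `|NOR| → 0` as
they coincide, and `NOR(b→a) = −NOR(a→b)`. Two separated zero-width ranges
(a zero-variance degenerate case) are treated as fully disjoint, `|NOR| = 1`;
equal point ranges are identical; a point inside a wider range is nested.

### Dynamic networks

Network `DN-t` (for `1 ≤ t < N`) has the retained features as nodes; a pair
gets a red edge when `NOR ≥ τ` and a green edge when `NOR ≤ −τ`, with
`τ = 0.85` by default — an edge therefore marks a near-disjoint jump of the
ratio's effective range between `T_t` and `T_t+1`. Isolated nodes are kept
in every network so degree tables are comparable. Networks are built from
the model (diseased) group by default, since they describe the disease
trajectory; the control group serves the later univariate screen.

### Early-warning extraction

* **Dynamic concentration** (feature subset 1): given an onset point `T_s`
  (the typical point of the disease stage of interest) and a look-back of
  `N_e` time points, the networks `DN-i` with `s − N_e ≤ i < s − 1` are
  examined and the edges present *with the same colour* in every one are
  kept. With `T_s = 7`, `N_e = 3` the window is `{DN-4, DN-5}`, i.e. the
  three pre-onset-window points `T_4, T_5, T_6`: a persistent monotone
  disturbance ahead of late-stage disease.
* **Topological structure** (feature subset 2): the network with the most
  edges marks the key transition of the time course (ties go to the earliest,
  with a warning). Its nodes are ranked by degree; ties break first by the
  larger degree accumulated over all `N − 1` networks, then by canonical
  feature order. The ratios incident to the top `k` nodes (default
  `k = 1`) form the subset. Nesting in `k` is guaranteed by the total order.
* The two subsets combine by **intersection** (default) or union.

### Static pre-screen (SVM-RFE)

Wide panels are filtered before network construction. The `N_s` contiguous
disease stages give `N_s(N_s−1)/2` binary sub-problems, each contrasting the
model-group samples at the typical (last) time points of two stages. Each
sub-problem runs recursive feature elimination with a linear soft-margin SVM
(`C = 1`): features are standardised, the classifier is fitted, each feature
is scored by its squared hyperplane weight, and the lowest-scoring
`⌈elim_fraction · remaining⌉` features (at least one; weight ties drop the
larger canonical index first) are removed until none remain.

The elimination is embedded in repeated stratified cross-validation
(default 5-fold × 50 repeats). Within a repeat, every elimination step fits
one classifier per training fold, ranks features by the *fold-averaged*
squared weight, and scores the surviving subset by held-out accuracy; the
repeat's best subset is the most accurate one, ties going to the smaller
subset. A feature is selected for a sub-problem when it appears in at least
`selection_threshold = 0.5` of the repeats' best subsets, and the
sub-problems' selections are united. Driving the elimination from the
training folds — rather than once from the full sample — is deliberate: a
single full-sample path is deterministic, so repeats could only disagree
about subset *size* and the selection frequency would degenerate (in
particular, a signal-free sub-problem would hand a stable tail of
chance-separating features a frequency of 1). With fold-driven paths the
repeats are genuine re-runs and frequency separates consistent signal from
fold noise. The deterministic full-sample path remains available as
`elimination_path` for inspection.

Known behaviour worth stating: when classes are separated by several
within-group standard deviations (as they are whenever ratio shifts are
large enough to form network edges — see below), CV accuracy saturates at
100 % already for single features, and the smaller-subset tie-break then
retains a *minimal sufficient* subset, typically one feature per redundant
signal group. That is correct behaviour for a noise filter, but it means
the filter should not be expected to return *both* members of a planted
ratio pair, nor all members of a redundant feature group. On small samples
(7 + 7) a signal-free sub-problem still passes a handful of
chance-separating features — a real small-`n` phenomenon, not an artefact.

### Univariate screen and ROC

Candidates from the network analysis are screened univariately, with no
multiple-testing correction by default (a Benjamini–Hochberg flag exists):

* Welch two-sample t-test, model vs control, at **every** disease-stage time
  point ("any time point" is read as *all*, since the evidence table of the
  motivating study prints all six p-values below 0.05 for each candidate);
* paired t-test within model subjects, typical pre-onset point vs every
  disease-stage point (subjects missing at either point are dropped; fewer
  than two complete pairs, or identical pairs, give NaN, which conservatively
  fails the candidate).

A candidate passes only if *all* p-values fall below `alpha = 0.05`.

ROC analysis labels model-group samples at onset-stage points positive and
model-group samples at earlier points negative. The AUC is the
Mann–Whitney pair-counting estimator (ties count ½) — checked in the suite
against exhaustive enumeration and against an independent library
implementation; its standard error is Hanley–McNeil with a normal 95 % CI
clipped to [0, 1]. The best cut-off maximises Youden's `J = sensitivity +
specificity − 1` under the rule "positive if score ≥ cut-off", with ties
broken toward higher specificity, then the larger cut-off. Markers that
*decrease* with disease score AUC near 0 under this orientation and should
be inverted by the user (the complement identity `AUC(−s) = 1 − AUC(s)`
holds exactly). PCA summaries autoscale columns (constant columns dropped
with a warning) and report the variance captured by the first two
components.

## Synthetic cohorts

The generator emulates the motivating study design: 10 control + 7 model
subjects × 7 time points (119 samples) over three contiguous stages
(H = hepatitis at `T_1`, CIR = cirrhosis `T_2–T_4`, HCC `T_5–T_7`), plus an
external-validation variant (6 model subjects × 6 points, 36 samples). On
the natural-log scale each cell is

```
log f = baseline_i + subject_effect(s, i) + planted_shift + noise
```

* `baseline_i ~ U(0, 3)` (relative abundances spanning ~e³),
* per-(subject, feature) random intercepts, SD 0.10,
* i.i.d. residual noise, SD 0.15 (≈ 15 % CV, a realistic residual scale for
  internal-standard-normalised MS intensities),
* for each of the (default 4, disjoint) planted pairs, the lower-canonical
  feature gains `+0.8` per time step from the onset point `T_5` onward and
  its partner loses `0.4` per step — a cumulative ramp, so the pair's ratio
  rises ≈ 3.3-fold per step through the disease stage, mimicking the
  one-lipid-up / one-lipid-down pattern of a progression biomarker ratio.
  Control subjects never receive the shift.

The per-step ratio shift of `1.2` log units was fixed by a design (power)
calculation, not by tuning to tests: on the log scale a planted pair's
population NOR at a post-onset transition is
`min(1, tanh(δ/2) / (γ√(2(subject_sd² + noise_sd²))))`, so clearing the
edge threshold 0.85 with margin requires `tanh(δ/2) ≥ 0.85 · 0.442 = 0.375`;
`δ = 1.2` gives `tanh(0.6) = 0.537`, a ~40 % margin against `n = 7`
sampling noise. A corollary worth making explicit: a shift of 3× the noise
SD can **never** clear `τ = 0.85` in the population limit (the requirement
grows like `4.9×` the noise SD), so "moderate" effects are structurally
invisible to this statistic — the method is built for drastic, persistent
ratio disruptions, which is exactly what the motivating study reports.

What the generator does **not** emulate: chromatographic drift, batch
effects, missingness, heavy-tailed intensity error, correlated feature
blocks, or biology in which many features shift together. Passing
recovery tests therefore show that the pipeline finds the kind of planted,
persistent, large ratio shifts it was designed for at realistic noise —
not that it would enjoy the same sensitivity on real cohorts.

## Validation strategy and problem sizes

* Closed-form oracles: hand-computed effective ranges and NOR values;
  a discretised length-counting oracle for |NOR| on randomised interval
  pairs (10⁻⁶ agreement); exhaustive pair counting for the AUC on datasets
  up to 50 samples; solo-feature CV ranking and exhaustive subset
  enumeration as RFE oracles.
* Property tests (seeded/derandomised): NOR antisymmetry, bounds,
  disjointness ⇔ |NOR| = 1, scale invariance; τ-monotonicity and the
  handshake lemma for networks; window-widening monotonicity and k-nesting
  for the subset extractors; screen monotonicity in p.
* Simulation scale: effective-range coverage uses 1000 draws of `n = 200`;
  planted-pair recovery runs 10 seeds of the full discovery design (the
  planted pair must reach subset 1 and the intersection in ≥ 9/10); the
  zero-effect null calibration regenerates 100 cohorts and compares
  planted vs nuisance edge rates with a binomial test. Recovery
  experiments skip the static pre-screen by default (`run_filter=False`)
  for the reason given above: at edge-compatible effect sizes the filter
  deliberately thins redundant pairs to single representatives, so
  pair-recovery is a property of the network stage. Filter behaviour is
  validated separately (oracle agreement, enrichment of planted features
  over nuisance features across seeds, determinism).

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| `gamma` | 1.732 | Chebyshev coefficient (√3): ≥ 2/3 population coverage |
| `tau` | 0.85 | minimum \|NOR\| for an edge (near-disjoint ranges) |
| `onset_point` (`T_s`) | last stage's typical point | stage whose warning signal is sought |
| `lookback` (`N_e`) | 3 | pre-onset points examined; window `s−N_e ≤ i < s−1` |
| `k` | 1 | top-degree nodes kept in topology analysis |
| `combine_mode` | intersection | how subsets 1 and 2 merge |
| `elim_fraction` | 0.10 | features dropped per RFE iteration (min 1) |
| `n_folds × n_repeats` | 5 × 50 | repeated-CV protocol of the filter |
| `selection_threshold` | 0.5 | frequency for a feature to be retained |
| `C` | 1.0 | SVM penalty (linear kernel) |
| `alpha` | 0.05 | univariate screen level |
| sd divisor | `n` (ddof 0) | population-style σ in the effective range |

Time indices are 1-based (`T_1 … T_N`) throughout. Stages must span
consecutive time points; the typical point of a stage is its last point.
Missing cells are not allowed (ratios and SDs are undefined with missing
data); impute upstream or drop samples — unbalanced designs are accepted
and flagged, and each two-point window then uses its actual counts via
`p_t`. Abundances are used as given (no log transform is applied
internally; the generator is log-normal, not the pipeline).

## Known limitations

* Only canonical `i < j` ratio orientation is enumerated (`C(m,2)` ratios);
  the mirrored ratio carries the same information with opposite sign.
* Degree is the only centrality used; no community structure.
* The Hanley–McNeil CI is a large-sample normal interval; at AUC near 1 and
  small `n` it degenerates (width 0 at AUC = 1.0).
* The screen's NaN-fails-candidate rule is conservative by design.
* `|NOR| ≥ τ` with `τ = 0.85` is a *drastic-change* detector; subtle but
  real trends will not form edges (see the power corollary above).
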