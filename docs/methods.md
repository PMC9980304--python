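# Methods

This note documents the models, procedures and numerical choices behind
`evmap`, in the spirit of a package methods appendix: what is computed, under
which assumptions, and where the genuinely open design decisions were made.

## Problem setting

Microflow cytometry (μFCM) of plasma extracellular vesicles (EVs) records,
per detected particle, a large-angle light-scatter intensity (LALS, a
size/structure proxy) and fluorescence intensities for two surface markers.
A patient sample yields 10⁴–10⁷ such events per acquisition, run in
triplicate. The analysis task is to turn these heterogeneous event clouds
into per-patient features that predict a binary clinical state (here:
high-grade prostate cancer, grade group ≥ 3), and to integrate the resulting
μFCM risk score with standard-of-care (SOC) clinical variables.

## Event QC

The usable operating range of the instrument is an event rate of 400–20 000
events·s⁻¹ (below: too little signal; above: coincident particles). The QC
filter computes rate = events / duration per replicate and flags replicates
outside the window as `too_slow` / `too_fast`; flagged replicates are
excluded from all downstream stages but never deleted, and exclusion counts
are logged. Patients with zero passing replicates leave the cohort (logged).
Replicate averaging tolerates 1–3 passing replicates.

## ROI binning

Per channel, intensities are log10-transformed; values ≤ 0 are first
replaced by the smallest positive recorded value of that channel
(`log_floor`), which preserves ordering on a non-negative instrument scale.
Bin edges are **equal-width in the log domain** over the pooled cohort
range, clipped at the (0.001, 0.999) quantiles to keep single extreme
events from stretching the grid. The base of the logarithm and the clip are
package choices (the binning idea itself does not fix them); equal-width
log bins make the grid deterministic and portable. Edges are *frozen* with
the model: new data is assigned to the identical ROIs, and prediction on a
feature matrix built with different edges is a hard error.

Each channel pair (scatter–marker1, scatter–marker2, marker1–marker2) gets
a B × B grid (default B = 32, i.e. 1024 ROIs per bivariate histogram, 3072
features in total). Events outside the edge range **clamp** into the edge
bins, so binning never drops an event — ROI counts always sum to the event
count, and QC is the only event-dropping stage. Counts become particle
concentrations per mL of original plasma:

    concentration = count / (flow_rate × duration) × dilution_factor

(3.01 μL·min⁻¹ × 120 s = 6.02 μL analysed volume at the default settings),
then replicate grids are averaged arithmetically per patient. A fixed
rectangular log-domain gate with the same concentration arithmetic provides
the manual-gating baseline.

## Association maps

For a binary clinical feature, each ROI's per-patient concentrations are
scored with the midrank Mann–Whitney ROC AUC
(AUC = P(X⁺ > X⁻) + ½·P(X⁺ = X⁻)); AUC > 0.5 means higher concentration in
positives. For ordinal/interval features each ROI gets a Pearson r. ROIs
with no variation across patients are masked out, not reported as 0.5/0.
Patients missing a clinical feature are excluded from that feature's map
only.

The top-decile summary averages the highest k = round(0.10 · N_valid) AUC
values (half-up rounding, k ≥ 1; ties at the cut resolved by bin index, so
the selection is deterministic). Because AUCs far *below* 0.5 are equally
informative, a |AUC − 0.5| ranking is available behind a flag; the default
is the plain highest-values rule. The reported spread is the SD across the
included ROIs.

## Predictive modelling

Evaluation protocol: stratified five-fold cross-validation repeated
(default 10×) with fresh patient randomization per repeat; each repeat
scores every patient exactly once, out of fold, and the repeat's AUC is
computed on the pooled out-of-fold scores. Folds are stratified by label to
avoid class-empty folds at low prevalence; per-class remainders rotate
across folds so fold sizes are as equal as possible (215 patients → five
folds of 43). A label-poisoning test pins the out-of-fold discipline: a
patient's score is provably independent of its own label.

The learner panel for benchmarking (identical fold assignments across
learners, so comparisons are paired) ships with boosted trees (XGBoost),
bagged trees (random forest), L2-penalized logistic regression and
k-nearest neighbours; any sklearn-style classifier can be plugged in, and a
failing learner is recorded as missing rather than aborting the run.

Optimization of the boosted-tree model:

- **Grid search** over nrounds ∈ {50, 100, 150, 200, 250, 300, 400},
  max_depth ∈ {3, 4, 5, 6}, eta ∈ {0.01, 0.1} with gamma = 0,
  colsample_bytree = 1, min_child_weight = 1, subsample = 1 — 56
  combinations, all evaluated; ties in mean AUC break toward fewer rounds,
  then shallower trees.
- **Recursive feature elimination**: backward elimination dropping the
  lowest-ranked fraction of columns per step (default 50%, 75% in the
  nested pipeline), re-evaluating each size by repeated CV; the selected
  size maximizes mean AUC, ties favouring fewer features. Ranking uses
  **total split gain averaged over an ensemble of patient-subset models**
  (default 8 members at 80% subsampling). A single boosted model gives all
  gain to one member of each group of correlated ROIs, making single-model
  rankings unstable; subset-averaged gain spreads credit across the group,
  the same reason forest importances are used for RFE elsewhere. Remaining
  ties resolve by column order.
- **Ensembling**: the final model averages the probabilities of N members
  (paper-style N ∈ {3, …, 100}; default 12 in the nested pipeline, 25 in
  the variance experiments), each trained on a random 80% patient subset
  drawn without replacement (the subset size is a package choice — the
  source protocol does not state it; 80% keeps both classes present with
  high probability, and degenerate draws are redrawn with a logged notice).
  Members are seeded `base_seed + i`; a one-member, fraction-1.0 ensemble
  equals a single model exactly.

Grid search and RFE run **inside** the CV training folds (an inner 3-fold
CV) by default, so feature selection never sees validation labels; a
select-then-validate mode is available for parity experiments by running
the standalone `grid_search`/`rfe` functions first. Determinism: one
`base_seed` governs folds (`+ repeat`), ensemble subsets (`+ member`) and
learner seeding; models serialize to the library's JSON text format and
reload with bit-identical predictions.

## SOC integration and decision analysis

The combined model is a maximum-likelihood logistic regression on PSA
(untransformed by default; log-PSA behind a flag), age, DRE, family
history, previous negative biopsy, race (black = 1, other = 0) and the
μFCM score; the SOC-only comparator drops the score. The μFCM score used
is always the **out-of-fold** CV prediction. On separation or a singular
design the fit falls back to a small L2 penalty with a logged notice; a
constant score is dropped (it is collinear with the intercept), making the
combined model reduce exactly to SOC-only. Both a full-cohort fit and a
cross-validated scoring mode are provided, since either reading of the
protocol is defensible.

Correlated ROCs are compared with DeLong's method via structural
components (V₁₀/V₀₁ covariances); z = ΔAUC/SE with a two-sided normal
p-value, and zero variance degenerates to p = 1 with a warning. Decision
cutoffs are anchored at a target sensitivity (~90% by convention): among
cutoffs achieving sensitivity ≥ target, the one maximizing specificity is
reported (ties: the smallest such cutoff), with sensitivity, specificity,
PPV and NPV from the same confusion matrix and the cutoff at full
precision. Waterfall exports sort patients by predicted risk relative to
the cutoff.

## Synthetic cohorts

The generator emulates what the pipeline needs from real plasma μFCM data:
several log-normal particle populations per sample (Gaussian in log10
intensity over the three channels), spanning decades of intensity, with a
dominant dim/negative population and smaller marker-positive populations;
triplicate acquisitions; Poisson count noise per replicate; log-normal
between-patient composition variability (σ = 0.25); and clinical tables
with a PSA–class association, Gleason patterns consistent with the class
label, and dates of birth exercising the instruction-sheet transforms.

Composition factors are renormalized so the expected total per replicate
at the null composition equals the configured count (default 5 × 10⁴
events, i.e. 417 events·s⁻¹ — inside the QC window; this mirrors the lab
practice of diluting samples into the instrument's acceptable range).
Class effects then act on top: a count multiplier scales the planted
populations' expected counts (the default planted cohort triples two
populations, raising class-1 totals to ≈ 1.4×, still in-window), and/or a
mean shift moves their log-intensity centroid. With all multipliers 1 and
zero shifts the cohort is an exact null. Everything derives from one seed
(patient p uses `SeedSequence([seed, p])`), so cohorts are byte-identical
across runs.

The planted "footprint" used by ground-truth checks is the box of bins
covered by a planted population's log-mean ± 2σ per channel (≈ 95% of its
events), a definition that scales with bin width instead of a fixed grid
radius.

What the generator does **not** model: optical physics (Mie scatter),
detector noise floors, swarm/coincidence detection, spillover between
fluorescence channels, day-to-day instrument drift, and label noise in the
clinical grade groups. Passing tests on these cohorts therefore demonstrate
that the machinery recovers the signal structure it targets under realistic
count statistics — not that any particular clinical performance level would
be reached on patient data.

## Problem sizes in the shipped checks

The simulation-based checks run cohorts of 60 + 60 patients with
triplicates of 5 × 10⁴ expected events (the standard conditions above);
the optimized-pipeline checks use 3 CV repeats with a reduced inner grid
(nrounds ∈ {50, 100} × depth ∈ {3, 4} × eta = 0.1), the
ensemble-variability check uses the stated 10 repeats with 25-member
ensembles, and the map-argmax reproducibility check runs 10 cohorts of
30 + 30 patients. The ensemble-variability comparison uses an
intermediate effect size (1.5× multiplier): at the default 3× the
cross-validated AUC saturates at ≈ 1 and both variances collapse to zero,
which would make the comparison vacuous. A stress option of 5 × 10⁶
events per replicate exists for throughput exercises.

## Known limitations

- The FCS writer emits FCS 3.1 list mode, float32, single data segment;
  the reader handles FCS 3.0/3.1 with `F`/`D`/uniform-width `I` data
  types and ignores doubled-delimiter escapes in TEXT values.
- Bin-edge fitting pools all passing events in memory; cohorts far beyond
  ~10⁸ events would need a streaming quantile pass.
- Equal-width log binning is exactly invariant under power-law intensity
  transforms (affine maps of the log domain) once edges are refit; general
  monotone transforms change bin boundaries and are only approximately
  invariant.
- The manual-gating baseline uses fixed rectangles; no per-sample dynamic
  gating is attempted.
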