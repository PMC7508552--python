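# Methods

`shocktraj` re-implements, as a tested library, an analysis of time-evolving
septic-shock risk: algorithmic Sepsis-3 state labeling, a gradient-boosted
pre-shock risk score evaluated on last-observation-carried-forward (LOCF)
feature vectors, alignment of risk trajectories at the time of early
prediction (first above-threshold risk, `t_d`) or at the first intervention,
spectral clustering of the aligned trajectories with eigengap model
selection, per-cluster outcome/treatment stratification, and k-nearest-
neighbor classification of trajectories as a function of observation
duration. Because credentialed multi-center ICU databases cannot ship with
the package, every stage is exercised end-to-end on a synthetic EHR cohort
generator with known trajectory archetypes; the generator is first-class,
tested code and doubles as the test oracle.

Timestamps are float minutes from hospital admission throughout (the offset
convention of eICU-style extracts); user-facing summaries are in hours.

## Clinical-state labeling

Sepsis onset is the earliest time with suspected infection present (an
explicit per-patient flag/time) and a SOFA score of 2 or more. SOFA is
computed from the standard six-organ criterion table
(`sofa-1996-consensus/v1` in `label.py`); missing inputs leave a subscore at
0, the usual convention for sparse EHR extracts, so unobserved organs are
never scored. Two algorithmic simplifications are documented in the code:
any active vasopressor scores cardiovascular 3 (dose is not modeled), and
the respiratory subscore uses the PaO2/FiO2 cutoffs without a ventilation
gate.

Adequate fluid resuscitation follows the 2012 Surviving Sepsis Campaign
criteria: cumulative fluids >= 30 mL/kg, or attainment of urine output
> 0.5 mL/kg/hr, MAP >= 65 mmHg, or CVP in [8, 12] mmHg. The target-based
criteria count only at or after the first fluid bolus (a never-treated
patient cannot be "resuscitated"); this gate is configurable off. Urine
observations are hourly-rate readings, normalized by body weight.

Septic shock onset is the earliest time at which all criteria co-hold:
sepsis present, adequate resuscitation achieved, a vasopressor running,
most-recent lactate > 2 mmol/L (strict), and - in the default strict mode -
most-recent MAP >= 65 mmHg ("vasopressors required *to maintain* MAP"); a
lenient mode drops the MAP condition because the consensus wording does not
resolve pressor-refractory hypotension. LOCF lookback at shock evaluation is
capped at 24 h. First intervention is the earliest of antibiotic order,
vasopressor start, and adequate resuscitation.

## Risk model and trajectories

The pre-shock state is characterized by a binary-logistic gradient-boosted
tree model (xgboost) separating observation updates in the window
(t_shock - 2 h, t_shock - 1 h] of shock patients from sepsis-state updates
of never-shock patients. One training row per observation-update time;
identical consecutive vectors are deduplicated; missing features are passed
as native NaN rather than imputed, matching LOCF-with-gaps reality. Classes
are rebalanced with `scale_pos_weight`, so the score behaves like a
rebalanced posterior in (0, 1). Defaults (300 rounds, depth 6, eta 0.05,
`min_child_weight` 100, subsample/colsample 0.8, gamma 1) were chosen for
low held-out false-crossing rates on baseline physiology while retaining
sensitivity to mild sustained deterioration.

Per-patient trajectories are always scored **out of fold** (3 patient-level
cross-fit folds): labs are sampled every ~12 h, so a patient's laboratory
values are often literally identical between their training rows and the
rest of their record, and in-sample scoring lets the trees memorize patient
identity, producing spurious pre-transition threshold crossings. The
original analysis applies a previously trained model, and cross-fitting is
the faithful analogue on a self-contained cohort.

`t_d` is the first observation-update time, from sepsis onset on, with risk
at or above the detection threshold; risk for export/clustering is evaluated
at 1 h intervals on [t_d, t_d + 12 h] (or [-6, +12] h about the first
intervention; the -6 h extent reflects that risk separates several hours
before intervention). The detection threshold of the originating study is
not published; the default here is a fixed 0.15 on the logistic scale - an
early-warning application favors sensitivity (the cited operating point is
88% sensitivity / 84% specificity), and baseline-state scores sit near 0.01
- with quantile, target-specificity and Youden rules available in
`select_threshold`. Early warning time EWT = shock onset - t_d.

## Spectral clustering

Written out in full in `cluster.py`: Gaussian affinity
`w_ij = exp(-(d_ij/sigma)^2)` over Euclidean distances between trajectory
rows; graph Laplacian (symmetric-normalized by default, unnormalized
available); eigengap choice of k = argmax over 2..k_max of
lambda_{k+1} - lambda_k, ties toward smaller k; embedding in the bottom-k
eigenvectors with row renormalization; k-means (k-means++ seeding, 50
restarts, fixed seed). A result is flagged low-confidence when the winning
gap is under twice the median gap in the searched range.

The printed kernel has no bandwidth, and raw squared distances over a
13-dimensional risk vector can drive all off-diagonal weights to ~0.
Distances are therefore rescaled before the kernel; the default scale is the
median distance to the 7th nearest neighbor (a self-tuning bandwidth on the
within-cluster scale). This choice matters: scaling by the median *pairwise*
distance - also available - cannot resolve more than the two outermost bands
when several equally spaced trajectory levels are present, because the
kernel width is then set by the global spread. The literal unit-bandwidth
kernel is available as `distance_scaling="none"`. Clusters are finally
renumbered 1..k in descending septic-shock prevalence (ties to the larger
cluster), so cluster 1 is always the highest-risk group.

## Synthetic cohort generator

Each patient carries 28 clinical variables observed by homogeneous Poisson
sampling at feature-specific mean intervals (vitals ~hourly, blood gases
~8 h, chemistries ~12 h, lactate ~11 h) with an archetype-independent
baseline distribution, Gaussian measurement noise and physiologic clipping.
A latent sepsis -> pre-shock transition at a random time (14-24 h) shifts
lactate and heart rate up and blood pressures down through a logistic
sigmoid completing within a 30-60 min jump window. Archetype g scales the
shift by a severity in (1.0, 0.78, 0.65, 0.50); lactate scales convexly
(severity^1.6), which keeps only the mildest archetype's lactate plateau
near the 2 mmol/L shock criterion. Shock and mortality outcomes are drawn
per archetype (defaults 76/46/26/10% and 43/34/22/18%).

Treatment layers: fluids (500 mL boluses to 30 mL/kg) start at an
archetype-graded offset from the transition (+2.0/+1.5/+1.0/-0.5 h - the
mildest patients are often treated before deteriorating); antibiotics
similarly. Blood pressures partially recover once hemodynamic support of
either kind is running. Never-shock patients respond to treatment: their
latent deterioration recedes (fraction 0.8, tau 5 h) after the first
intervention. Shock-bound patients receive vasopressors in up to two
phases: a transient early episode (probability 8/22/35/55% by archetype,
weaned within 1-2 h) that grades how many patients are already on pressors
by the time of early warning, and a definitive sustained infusion at
3.5/5.5/9/18 h after the transition marking refractory hypotension - the
event that, together with the first lactate measurement above 2 mmol/L,
gates labeled shock onset and so produces the graded early-warning times.
These ladders were chosen, via pilot simulation before freezing, to
reproduce the direction (not the magnitudes) of the reported stratification:
higher-risk clusters have shorter EWT, fewer patients treated by t_d, and
positive intervention-minus-t_d offsets.

`severity_trajectory_matrix` exposes the latent severity ramp of each
patient sampled hourly over [transition, +12 h] plus i.i.d. noise
(SD 0.0325, placing adjacent archetype plateaus 4 noise-SDs apart). It is
the generator's ground-truth trajectory substrate: archetype-recovery
properties of the clustering stage (k = G by eigengap, ARI ~ 1) are
established there, where the separation condition is defined. The
*risk-model* trajectory matrix on the default cohort instead exhibits a
dominant two-band structure (sustained-high versus receding), and eigengap
honestly selects k = 2 on it; stratification gradients are therefore
evaluated on the archetype-recovering clusters combined with t_d, EWT and
treatment flags from the cross-fitted risk pipeline, restricted to
threshold crossers (the population the original tables describe).

What the generator does not emulate: real marginal distributions or
informative missingness beyond the Poisson schedules, comorbidities,
multi-modal blood-pressure recording, dose titration, or death-censored
observation. Passing tests therefore demonstrate the correctness and
calibration of the machinery under a known data-generating process, not
clinical performance.

## Stratification and classification

The stratification table reports, per outcome-ordered cluster: size, % of
cohort, % septic shock, % mortality, median EWT (over patients with both
t_d and shock onset), % adequately resuscitated and % on vasopressors by
t_d (both over shock patients, as in the table headers, and over all
members, as in the prose), and the mean first-intervention minus t_d offset
(positive = treated after threshold crossing). Feature contrasts between
two clusters take each patient's LOCF value 1 h before an anchor event and
compare clusters with two-sided Wilcoxon rank-sum tests, Bonferroni
corrected over the features tested; intervention-offset contrasts correct
over cluster pairs. Trajectory separation is quantified per timepoint by
the symmetrized Kullback-Leibler divergence between moment-matched
Gaussians (variances floored at 1e-6).

Classification follows the published protocol: clustering of the full
dataset gives ground-truth labels; a 70/30 patient split is drawn; the train
subset's full-window rows are re-clustered to produce training labels;
cluster numbers are matched by descending shock prevalence; both train and
test rows are truncated to the first m hours (m = 0 keeps the single
anchor-time value) and a 5-NN Euclidean vote predicts test labels, vote
ties resolving to the nearest tied-class neighbor. Bootstrap resampling of
the test set (1000 resamples, percentile 5-95%) gives 90% bands.

## Problem sizes and numerics

The acceptance analysis uses 1500 synthetic patients - large enough that
the smallest cluster's EWT median rests on a few dozen shock patients -
and archetype-recovery checks use 10 cohorts of 400. Dense symmetric
eigendecompositions (`scipy.linalg.eigh`) are used throughout (matrices are
at most ~1500^2); eigenpair residuals are verified below 1e-8 in tests.
Degenerate inputs are handled explicitly: zero-degree affinity rows raise,
exactly tied eigengaps resolve to the smallest k, zero embedding rows stay
zero, and zero pairwise distances skip rescaling.

## Known limitations

Cluster structure in risk space depends on the score surface of the boosted
model; with other hyperparameters the two-band geometry may coarsen or
sharpen. EWT magnitudes are a few hours rather than the tens of hours seen
in the motivating clinical cohorts, since the generator's horizon is 60 h.
The suspected-infection flag replaces coding-based infection ascertainment,
and comorbidity analyses are out of scope.
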