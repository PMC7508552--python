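# shocktraj

Time-evolving septic-shock risk analysis: algorithmic Sepsis-3 state
labeling, a gradient-boosted pre-shock risk score, spectral clustering of
risk trajectories with eigengap model selection, cluster-outcome
stratification, and k-nearest-neighbor trajectory classification — exercised
end-to-end on a seeded synthetic EHR cohort generator with known trajectory
archetypes.

## The problem

Sepsis is heterogeneous: patients with the same diagnosis differ widely in
outcome and in how they respond to treatment. One productive way to
stratify them is by the *time evolution* of a risk score rather than by a
snapshot. A boosted-tree model `r(x_t)` is trained to recognize the
pre-shock state — feature vectors drawn from the window
`(t_shock − 2 h, t_shock − 1 h]` of patients who progress to septic shock —
against sepsis-state samples of patients who never do, where `x_t` is the
last-observation-carried-forward vector of 28 clinical variables. The first
time `r(x_t) ≥ θ` is the time of early prediction `t_d`, and
`EWT = t_shock − t_d` is the early warning time.

Trajectories `r(t_d), r(t_d + 1 h), …, r(t_d + 12 h)` are clustered
spectrally: affinity `w_ij = exp(−(δ(x_i, x_j)/σ)²)` over Euclidean
distances, symmetric-normalized graph Laplacian, number of clusters k chosen
where the eigenvalue gap `λ_{k+1} − λ_k` is largest, k-means on the bottom-k
eigenvector embedding, and clusters numbered 1..k by descending septic-shock
prevalence. The resulting strata separate by shock prevalence, mortality,
median EWT, and how much treatment patients had already received at `t_d`;
a 5-NN classifier assigns new trajectories to strata from as little as a
single post-warning observation.

Intended users: researchers who need a tested, self-contained reference
implementation of this analysis chain — the labeling rules, the trajectory
machinery, the from-scratch spectral pipeline and the evaluation protocol —
together with a synthetic cohort generator that makes every stage testable
without access to credentialed ICU databases.

## Worked example

`examples/04_cluster_and_stratify.py` generates 600 synthetic patients,
labels Sepsis-3 states, scores risk out of fold, clusters trajectories and
stratifies the clusters:

```
eigengap selected k = 4; ARI vs generator archetypes = 1.00
         size  pct_shock  pct_mortality  median_ewt_h  pct_resus_by_td_all  mean_intervention_offset_h
cluster
1         104      67.31          43.27          3.07                19.23                       -0.32
2         144      51.39          32.64          4.32                46.53                       -1.51
3         123      45.53          21.95          6.65                59.35                       -3.02
4          10      30.00          10.00         14.20                90.00                       -6.34
```

The eigengap heuristic recovers the generator's four archetypes exactly
(ARI 1.0), and the ordered table reproduces the qualitative stratification
signature: the highest-risk cluster has the most shock and mortality, the
shortest time from early warning to shock onset, the fewest patients already
fluid-resuscitated at early warning, and intervention-time offsets closest
to "treated after the warning" (less negative), while the lowest-risk
cluster is the mirror image.

`examples/05_classify_trajectories.py` evaluates kNN cluster assignment as a
function of observation duration:

```
duration (h)  accuracy  [90% CI]
         0     0.773  [0.713, 0.827]
         1     0.993  [0.980, 1.000]
         2     1.000  [1.000, 1.000]
         ...
        12     1.000  [1.000, 1.000]
```

With a single observation after early prediction, about 77% of test
trajectories land in the right stratum; accuracy saturates as more of the
post-warning window is observed.

The other examples cover cohort generation (`01`), Sepsis-3 labeling (`02`)
and risk-trajectory computation (`03`). A thin CLI wraps the pipeline:
`shocktraj run-all --config cfg.yaml --seed 21 --outdir run/` writes every
intermediate artifact plus a manifest and log.

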