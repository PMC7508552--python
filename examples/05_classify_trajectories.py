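"""kNN classification of risk trajectories vs observation duration.

Full-window clustering provides ground-truth labels; the train subset is
re-clustered, cluster numbers are matched by descending shock prevalence,
and a 5-nearest-neighbor vote classifies test trajectories truncated to the
first m hours, with bootstrap 90% bands.
"""

from shocktraj import (ClusterParams, SynthConfig, evaluate_accuracy_vs_duration,
                       generate_cohort, order_clusters_by_outcome,
                       severity_trajectory_matrix, spectral_clustering)

config = SynthConfig(n_patients=500, seed=5)
records, truth = generate_cohort(config)
matrix = severity_trajectory_matrix(truth, config, seed=6)
result = spectral_clustering(matrix, ClusterParams(seed=5))
shock = truth.frame["shock"].to_numpy()
ordered = order_clusters_by_outcome(result, dict(zip(matrix.patient_ids, shock)))

ev = evaluate_accuracy_vs_duration(matrix, ordered.assignments, shock,
                                   ClusterParams(seed=5), n_boot=1000, seed=5)
print("duration (h)  accuracy  [90% CI]")
for m, acc, lo, hi in zip(ev.durations_h, ev.accuracy, ev.ci_lower, ev.ci_upper):
    print(f"{m:10.0f}  {acc:8.3f}  [{lo:.3f}, {hi:.3f}]")
# Accuracy grows with the amount of post-warning data; with well-separated
# trajectory archetypes even a single observation after early prediction
# assigns most patients to the correct risk stratum.
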