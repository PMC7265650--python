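"""Learn a metabolite network and compare functional node activities.

Simulates a two-group cohort whose metabolites come in pathway-aligned
correlated blocks (one pathway shifted in group 2), preprocesses the matrix
(detection filter + downshifted-normal imputation of left-censored missing
values), learns the decomposable Gaussian graphical model, splits it into
branches, and tests each branch's functional node activity between groups.
"""

from metaboflux import (SimulationConfig, assign_function, branch_decompose,
                        compare_groups, filter_detection,
                        impute_downshifted_normal, learn_network,
                        node_activity, pathway_annotation, simulate_omics)

config = SimulationConfig(n_samples=80, n_pathways=4, features_per_pathway=6,
                          within_block_correlation=0.7, group_shift=1.2,
                          shifted_pathways=(0,), missing_rate=0.15, seed=42)
metabolites, _, samples = simulate_omics(config)
print(f"simulated {metabolites.n_features} metabolites x "
      f"{metabolites.n_samples} samples, "
      f"{(~metabolites.observed_mask).mean():.0%} below detection")

filtered, report = filter_detection(metabolites, min_fraction=0.75)
imputed = impute_downshifted_normal(filtered, width=0.3, shift=1.8, seed=7)
print(f"detection filter kept {len(report.kept)}/{metabolites.n_features} features")

graph, trace = learn_network(imputed)
print(f"network: {graph.graph.number_of_nodes()} nodes, "
      f"{graph.graph.number_of_edges()} edges "
      f"({len(trace) - 1} BIC-accepted beyond the spanning tree)")

partition = assign_function(branch_decompose(graph, 4), pathway_annotation(config))
activities = node_activity(imputed, partition)
stats = compare_groups(activities, samples)
print("\nper-node group comparison (Mann-Whitney, BH-adjusted):")
print(stats.round(4).to_string())
print("\nnodes with q < 0.05 are the pathways whose activity separates the "
      "groups; the planted shift is in pathway_0.")
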