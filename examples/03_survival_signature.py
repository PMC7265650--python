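"""Build and validate a metabolite survival signature.

Plants a protective feature (negative log-hazard coefficient: higher
abundance, better prognosis), ranks features by median-split log-rank
p-value, builds the compound-covariate predictor (univariate Cox weights,
a-priori 50:50 median cutoff), and assesses it with leave-one-out
cross-validation plus a permutation test of the cross-validated log-rank
statistic.
"""

from metaboflux import (SimulationConfig, build_predictor, loocv_permutation,
                        rank_features, simulate_omics, simulate_survival)

config = SimulationConfig(n_samples=100, n_pathways=4, features_per_pathway=8,
                          missing_rate=0.0, group_shift=0.0, seed=5)
matrix, _, _ = simulate_omics(config)
data = simulate_survival(matrix, [("m_p0_f0", -1.5)], censor_rate=0.3, seed=6)
print(f"cohort: {data.n} samples, {int(data.event.sum())} events")

ranked = rank_features(matrix, data)
print(f"\n{ranked.attrs['n_significant']} features at log-rank p < 0.05; top 3:")
print(ranked.head(3).round(4).to_string(index=False))

predictor = build_predictor(matrix, data, k=3)
for f, w in zip(predictor.features, predictor.weights):
    tag = "protective" if w < 0 else "risk"
    print(f"  weight[{f}] = {w:+.3f} ({tag})")

cv_classes, logrank_p, perm_p = loocv_permutation(matrix, data, k=3,
                                                  n_perm=200, seed=7)
print(f"\nLOOCV risk groups: {(cv_classes == 'high').sum()} high / "
      f"{(cv_classes == 'low').sum()} low")
print(f"log-rank p of cross-validated groups: {logrank_p:.4g}")
print(f"permutation p (200 permutations, selection re-run per permutation): "
      f"{perm_p:.4g}")
print("\nthe planted feature should surface with a negative (protective) "
      "weight and a small permutation p.")
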