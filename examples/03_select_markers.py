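"""Screen metabolic markers for grain weight by PLS-DA Component-1 VIP.

Builds mid-parent predictors for the 2012 diallel hybrids, splits them into
large (>27 g), medium and small (<24 g) TGW subgroups, fits a PLS
discriminant model on the two extremes and keeps analytes whose Component-1
variable importance in projection (VIP) exceeds 1.5.
"""

from corehybrid import (POP1, ScenarioConfig, assign_subgroups,
                        build_predictors, permutation_test, retain_features,
                        select_markers, simulate_scenario, sum_normalize)
from corehybrid.preprocess import Autoscaler

config = ScenarioConfig(seed=42)
parents, pedigree, phenotypes, truth = simulate_scenario(config)
predictors = build_predictors(sum_normalize(retain_features(parents, 0.5)),
                              pedigree)

populations = pedigree.set_index("hybrid_id")["population"]
diallel = populations.index[populations == POP1]
subgroups = assign_subgroups(phenotypes[diallel])
print("subgroup sizes:", subgroups.value_counts().to_dict())

markers, da = select_markers(predictors, subgroups, vip_threshold=1.5,
                             n_components=4, cv_seed=config.seed)
print(f"PLS-DA: Q2 = {da.q2:.3f} (10-fold CV, large vs small)")

extremes = subgroups[subgroups.isin(["large", "small"])]
X = Autoscaler().fit_transform(predictors.loc[extremes.index])
p = permutation_test(X.to_numpy(), extremes.to_numpy(), n_components=4,
                     n_perm=1999, seed=config.seed)
print(f"permutation test: p = {p:.4g} ({1999} label permutations)")

recall = len(set(markers.analyte_ids) & set(truth.causal_analyte_ids)) \
    / len(truth.causal_analyte_ids)
baseline = len(markers) / predictors.shape[1]
print(f"markers at VIP > 1.5: {len(markers)} analytes; causal recall "
      f"{recall:.2f} = {recall / baseline:.1f}x the hypergeometric baseline")
print("A Q2 well above 0 with a permutation p at the achievable floor means "
      "the large/small separation is real, not overfitting.")
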