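"""Train and assess a regulon-membership classifier on synthetic promoters.

Generates 500 promoters of which 40 carry a planted 10 bp motif (~12 bits),
assembles the engineered feature matrix, cross-validates the elastic-net
logistic regression with promoter grouping and SMOTE-Tomek rebalancing, and
ranks features by linear SHAP."""

from regulonml import (
    ClassifierConfig,
    SyntheticConfig,
    assemble,
    build_pssm,
    cross_validate,
    default_sigma_pssms,
    fit_final,
    generate_pentamer_table,
    generate_regulon_dataset,
    shap_linear,
)

config = SyntheticConfig(seed=7)
promoters, labels, truth = generate_regulon_dataset(config)
pssm = build_pssm(probabilities=truth.planted_pwm, name="planted", source="ICA")
matrix = assemble(
    promoters, [pssm], default_sigma_pssms(), generate_pentamer_table(7),
    labels.to_frame(name="planted").astype(int),
)
print(f"feature matrix: {matrix.X.shape[0]} promoters x {matrix.X.shape[1]} features")

cc = ClassifierConfig(seed=7)
engineered = cross_validate(matrix, "planted", cc)
motif_only = cross_validate(matrix.motif_only(), "planted", cc,
                            feature_set="motif-only")
print(f"engineered features: mean AUROC {engineered.mean_auroc:.3f} "
      f"({engineered.status} at the 0.8 cutoff)")
print(f"motif score only:    mean AUROC {motif_only.mean_auroc:.3f}")
# AUROC is the probability that a regulon member's promoter outranks a
# non-member's; >= 0.8 marks a well-specified regulon.

model = fit_final(matrix, "planted", cc)
report = shap_linear(model, matrix.X)
print("top-5 features by mean |SHAP| (log-odds scale):")
for name in report.top5:
    print(f"  {name:24s} {report.mean_abs_shap[name]:.3f}")
# The planted motif's score should rank first: the classifier attributes the
# regulon structure to the binding-site strength it was built from.
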