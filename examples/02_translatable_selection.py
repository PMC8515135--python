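"""Select translatable components by consensus LASSO and fit the final
linear model.

The mouse phenotype is encoded ordinally (WT=0, HET=1, HO=2) and
regressed on the projected component scores over 10 repeats of
stratified 5-fold cross-validation; components with a nonzero LASSO
coefficient in at least 40% of the 50 runs enter the final ordinary
least-squares model, scored by leave-one-out RMSE.
"""

import transcompr as tc

bundle = tc.generate(
    tc.SimConfig(n_genes=800, n_human_per_class=25, n_mouse_per_group=5, seed=17)
)
result = tc.run_pipeline(bundle.human, bundle.mouse, bundle.homolog_map, seed=17)

print("selection frequencies (components reaching the 40% threshold):")
freq = result.consensus.frequencies
print(freq[freq >= 0.40].round(2).to_string())

final = result.final_model
print(f"\nfinal model on {len(final.selected)} components")
print(f"  LOO RMSE      : {final.loo_rmse:.3f}")
print(f"  in-sample RMSE: {final.in_sample_rmse:.3f}")
print("  coefficient p-values:")
for comp in final.selected:
    print(f"    {comp}: coef {final.coefficients[comp]:+.3f}  p {final.pvalues[comp]:.2e}")

best = tc.axis_alignment(result.pca, bundle.truth)["disease"].idxmax()
print(f"\nplanted disease axis lives on {best}; "
      f"selected: {best in result.consensus.selected}")
print("The phenotype spans 0..2, so an LOO RMSE well below the ~0.82 SD of "
      "the phenotype means the selected components genuinely order the "
      "genotype groups.")
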