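"""Simulate a bulk two-group study and detect cell-type-specific effects.

Generates a whole-blood-like mixture of six immune cell types with
tree-correlated differential genes (10% per cell type), runs the
full-interaction baseline test and the tree-prior analysis, and compares
their rankings against the known truth. Minor cell types (small mixing
proportions) are where the hierarchical prior helps most.
"""

from cedar import SimulationConfig, roc_auc, run_cedar, simulate_dataset

config = SimulationConfig(n_features=2000, n_per_group=100, seed=7)
bulk, props, truth = simulate_dataset(config)
print(f"simulated {bulk.n_features} genes x {bulk.n_samples} samples")
print("mean proportions:", dict(props.to_frame().mean().round(3)))

result = run_cedar(bulk, props, truth.design(), mode="cedar-m")
print("\nestimated hierarchy:", result.tree.to_newick().split(";")[0][:90], "...")

print(f"\n{'cell type':<14}{'AUC baseline':>14}{'AUC tree-prior':>16}{'called':>8}{'global FDR':>12}")
for ct in props.cell_types:
    labels = truth.z[ct].to_numpy()
    auc_base = roc_auc(-result.baseline.pvals[ct].to_numpy(), labels)
    auc_cedar = roc_auc(result.posteriors.posterior[ct].to_numpy(), labels)
    n_called = int(result.posteriors.calls[ct].sum())
    gfdr = result.global_fdr[ct]
    gfdr_s = "-" if gfdr is None else f"{gfdr:.3f}"
    print(f"{ct:<14}{auc_base:>14.3f}{auc_cedar:>16.3f}{n_called:>8}{gfdr_s:>12}")

print(
    "\nAUC compares each method's ranking with the simulated truth; 'called'\n"
    "counts genes with posterior > 0.95, and the global FDR is the mean\n"
    "local fdr (1 - posterior) of that called list."
)
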