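"""Estimate the cell-type hierarchy and node priors from the data alone.

The hierarchy does not need to be known: it is recovered by clustering
cell types on the correlation of their -log10 p-value profiles from the
baseline test, and every node's prior is the fraction of features
significant anywhere in the node's leafset.
"""

from cedar import (
    SimulationConfig,
    baseline_test,
    estimate_node_priors,
    estimate_tree,
    simulate_dataset,
)
from cedar.simulation import four_celltype_tree

# truth: neutrophils/monocytes and CD4/CD8 each share 90% of their
# differential genes; the two pairs are unrelated
gen_tree = four_celltype_tree("e", overlap=0.9)
config = SimulationConfig(
    n_features=2000,
    n_per_group=100,
    tree=gen_tree,
    dirichlet_alpha={"neutrophils": 27.94, "monocytes": 4.64, "CD8": 2.47, "CD4": 9.38},
    seed=11,
)
bulk, props, truth = simulate_dataset(config)

base = baseline_test(bulk, props, truth.design())
topology = estimate_tree(base, threshold=0.01)
priors = estimate_node_priors(base, topology, threshold=0.01)

print("generating hierarchy: ((neutrophils,monocytes),(CD4,CD8))")
print("estimated hierarchy: ", priors.tree.to_newick())
print("\nestimated node priors (fraction of genes differential in the node's set):")
for node, pi in sorted(priors.pi.items(), key=lambda kv: -kv[1]):
    print(f"  {node:<28} pi-hat = {pi:.3f}")
print(
    "\nBoth simulated pairs are recovered as clades. Each pair's node prior\n"
    "sits only slightly above its leaves' — the signature of strongly shared\n"
    "differential states. The estimates under-count the simulated 10% rate\n"
    "because only genes passing the p < 0.01 selection are counted; the\n"
    "conditional probabilities (the ratios) are what drive information\n"
    "sharing, and those are much less affected."
)
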