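"""Score a caller against simulation truth with the benchmark metrics.

Shows the metric toolbox on one replicate: AUC-ROC and AUC-PR for the
ranking, MCC and observed FDR for the binary calls, and the true
discovery rate (precision) of top-j lists.
"""

from cedar import (
    SimulationConfig,
    evaluate_cell_type,
    run_cedar,
    simulate_dataset,
)

config = SimulationConfig(n_features=2000, n_per_group=100, seed=19)
bulk, props, truth = simulate_dataset(config)
result = run_cedar(bulk, props, truth.design(), mode="cedar-s")

ct = "monocytes"
labels = truth.z[ct].to_numpy()
report = evaluate_cell_type(
    scores=result.posteriors.posterior[ct].to_numpy(),
    labels=labels,
    cell_type=ct,
    calls=result.posteriors.calls[ct].to_numpy(),
    tdr_js=[20, 50, 100, 200],
)

print(f"cell type: {ct} ({int(labels.sum())} truly differential genes of {len(labels)})")
print(f"AUC-ROC:       {report.auc_roc:.3f}")
print(f"AUC-PR:        {report.auc_pr:.3f}")
print(f"MCC:           {report.mcc:.3f}")
fdr = "-" if report.observed_fdr is None else f"{report.observed_fdr:.3f}"
print(f"observed FDR:  {fdr}  ({report.n_called} genes called at posterior > 0.95)")
print("TDR of top-j lists (fraction of true positives among the top j):")
for j, v in report.tdr.items():
    print(f"  top {j:>4}: {v:.3f}")
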