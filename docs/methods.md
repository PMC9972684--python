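# Methods

## Data model

Bulk signal `Y_gi` (feature `g`, sample `i`) is modeled as a
proportion-weighted average of pure cell-type signals. Conditional on the
per-cell-type differential indicators `Z_g ∈ {0,1}^K`,

    E[Y_gi | Z_g] = Σ_k θ_ik (μ_gk + C_iᵀ β_gk + Z_gk A_iᵀ δ_gk),

with `θ_ik` known (or estimated) proportions, `A` the tested covariate
(binary, continuous, or dummy-coded categorical) and `C_q` confounders.
Confounders flagged *cell-type-specific* get one coefficient per cell
type (columns `θ_k ⊙ C_q`); *shared* confounders a single common
coefficient (column `C_q`). There is no global intercept: the `θ`
columns span it because proportion rows sum to one. The configuration
`Z = 1…1` is exactly the full interaction model used by TOAST/CellDMC,
which is therefore the baseline test and the source of all empirical
estimates below.

Assumptions worth keeping in mind: Gaussian residuals per feature (fine
for log expression and per-CpG beta values, wrong for counts — a
negative-binomial likelihood is out of scope); proportions treated as
fixed known covariates; one tested covariate per run.

## Likelihood

For each of the 2^K configurations the design depends only on `z`, so a
single multi-response least-squares solve (LAPACK `lstsq`, minimum-norm
under rank deficiency, effective column count = matrix rank) serves all
G features. The per-feature log-likelihood is Gaussian with the plug-in
maximum-likelihood variance `σ̂² = RSS/N`, floored at 1e-12 so perfect
fits stay finite:

    loglik = −N/2 · (log 2πσ̂² + 1).

Two deliberate choices here. First, plug-in ML variance rather than REML
or an integrated marginal likelihood — this is the single biggest
modeling choice in the package; it keeps all 2^K fits cheap and
comparable, at the price of a mild large-model bias that an
information-criterion correction would remove. Second, the variance is
refit per configuration (not pooled across configurations), consistent
with each configuration being an independent least-squares model.
Configurations with `N ≤ P` are dropped with a warning and excluded from
the posterior sum. Cost contract: exactly 2^K (minus dropped)
factorizations regardless of G; K is capped at 12 for the exhaustive
paths.

## Prior over states: the cell-type hierarchy

A rooted tree (not necessarily bifurcating — it is a statistical
correlation device, not a lineage claim) has the K cell types as leaves.
Each node carries a binary state: the root is active with probability
`π_root`; any non-root node is active with conditional probability `p`
given an active parent and is forced inactive under an inactive parent;
siblings are independent given an active parent. A node's marginal prior
is therefore `π_root` times the product of `p` along its root path, and
is never larger than its parent's.

`P(Z_g = z)` marginalizes the internal states by an upward tree
recursion (linear in the number of nodes, any K); explicit enumeration
of all valid `(Z, D)` configurations is also provided for small K and
serves as the oracle in tests. All node probabilities are clamped to
`[1e-10, 1 − 1e-10]` at construction because the posterior divides by a
prior-weighted sum. Internal nodes are canonically ordered (children
sorted by leafset) so results do not depend on serialization order.
Trees serialize to Newick with `[&pi=..,p=..]` node comments (Newick has
no native slot for node probabilities) plus an equivalent YAML sidecar.

## Posterior and calling

Per feature, posterior weights `loglik(z) + log P(z)` are combined with
log-sum-exp — with hundreds of samples the candidate log-likelihoods
span hundreds of log units and would underflow otherwise. The posterior
for cell type `k` sums the weights of configurations with `z_k = 1`.
`1 − posterior` is the local fdr; calls use posterior > 0.95 by default;
a called list's global FDR is its mean local fdr (absent when the list
is empty). Rankings break posterior ties by log marginal likelihood,
then feature id, so they are deterministic. Global FDR is reported per
cell type, not pooled.

## Empirical estimation

*Baseline test.* The full model is fit once; each cell type's
interaction block is tested with the partial F statistic
`((RSS_red − RSS_full)/q) / (RSS_full/(N − rank_full))` (equivalent to
the squared t when q = 1). BH adjustment is computed alongside.

*Hierarchy.* Features significant in at least one cell type (raw p, or
BH fdr, below a threshold; default raw p < 0.01, user-configurable) are
kept; the cell-type distance is `(1 − cor(−log10 p_k, −log10 p_k′))/2`
with −log10 p capped at 300 against underflow; average linkage (UPGMA)
gives a bifurcating topology with deterministic lexicographic naming of
internal nodes. The quantity behaves as a distance (0 at perfect
correlation) and is treated as one. With fewer than 10 selected
features the estimate is meaningless and the single-layer topology is
returned with a warning. With K = 2 the topology is forced.

*Node priors.* `π̂_node` = fraction of features whose minimum p-value
over the node's leafset beats the threshold (leaves are singleton
leafsets), so `π̂` is automatically non-increasing from root to leaf;
`p̂ = π̂_node/π̂_parent`, clamped. These estimates under-count the true
differential rates when power is limited (only detected features are
counted); the conditional ratios, which drive information sharing, are
much less affected. Priors are always re-estimated on the supplied
topology, also for user trees.

*Single-layer variant.* All cell types under one root:
`π̂_root` = fraction significant anywhere, `p̂_k = π̂_k/π̂_root`. The
root is the only source of coupling.

*Proportions.* A reference-based least-squares deconvolver: each bulk
sample's marker vector regressed on mean pure-cell reference profiles,
negative coefficients truncated to zero, rows renormalized.

## Simulation engine

The generator emulates a two-group whole-blood expression study:

- **States** drawn top-down through a hierarchy; the default six-cell-type
  tree has `π_root = 0.4`, pair nodes so that every leaf's marginal is
  0.10, neutrophil/monocyte and CD4/CD8 overlap is 80%, CD4–B 62.5%,
  CD4–NK 50%. The cross-cluster overlap implied by these probabilities
  is 25% (joint 0.025 over marginal 0.1), although descriptions of this
  design sometimes quote ~12.5%; the implementation follows the stated
  node probabilities.
- **Pure profiles** `log2 X_gik ~ N(μ_gk + Z·lfc_gk, σ_gk²)` with
  `|lfc| ~ N(1, 0.2²)` and a random sign. The sign is drawn once per
  gene and shared across that gene's differential cell types (preserving
  cross-cell-type coherence); a per-(gene, cell type) mode is available.
  `lfc` magnitudes are drawn independently per gene × cell type.
- **Baselines** default to a synthetic stand-in for purified immune-cell
  microarray profiles: `μ_gk ~ N(6, 1.5²)` (log2 scale),
  `σ_gk = 0.1 + |N(0, 0.2²)|`; a user table can replace them. Headline
  benchmark numbers depend on the baselines, so absolute AUCs here are
  not comparable to analyses built on real purified-cell profiles.
- **Compositions** `θ_i ~ Dirichlet(27.94, 4.64, 2.47, 4.87, 2.30, 2.21)`
  (neutrophils, monocytes, CD8, CD4, B, NK — neutrophil mean 0.63),
  identical in cases and controls (no composition shift). A four-cell-type
  preset family covers independence, single-layer, one-pair, two-pair and
  fully nested correlation patterns at configurable overlap.
- **Bulk** `Y_gi = X_gi θ_iᵀ + ε_gi`, `ε_gi ~ N(0, η_g²)` with
  `η_g = 0.1 × max(control-group mean, case-group mean)` of the mixed
  signal, giving the expression-scaled noise of real arrays.

Everything is driven by one `numpy` Generator seed; identical
configurations are bit-identical. What the generator does **not**
emulate: count noise, batch effects, probe-level artifacts, composition
differences between groups, and real baseline profiles — passing tests
demonstrate correctness of the machinery and qualitative behavior, not
performance on any particular real dataset.

## Evaluation

AUC-ROC (midrank Mann–Whitney), AUC-PR (step interpolation), MCC,
observed FDR = FP/(FP+TP) (absent with no discoveries), and TDR(j) = the
precision of the top-j list. Baselines rank by ascending p-value,
posterior methods by descending posterior. Replicate summaries report
mean, median and IQR.

## Problem sizes and numerical notes

The bundled benchmark runs 2,000 features, 100 samples per group, six
cell types, ten replicates per scenario — sizes chosen so the whole
suite stays desk-scale while keeping per-cell-type AUC estimates stable
to a few thousandths. Degenerate inputs: proportion rows renormalized
with a warning when off by more than 1e-6 (zero rows are errors); missing
bulk values are errors; rank-deficient designs fall back to minimum-norm
solutions with a warning; dropped configurations and fallback topologies
carry stable machine-greppable warning codes (CEDAR-W001…W007).

## Known limitations

- Under truly independent differential states the single-layer model's
  posterior ranking can exceed the baseline F-test's AUC by a few
  hundredths at moderate sample sizes: averaging over sub-models that
  drop irrelevant interaction columns is a genuine model-selection gain
  unrelated to the hierarchy. It shrinks as sample size grows and the
  configurations become likelihood-separated.
- Plug-in variance makes posteriors slightly overconfident for small N;
  the 0.95 cutoff still controlled observed FDR at ~0.01–0.1 in the
  bundled benchmarks, with the best control in the major cell type.
- Prior estimation inherits the selection threshold: weak-signal studies
  under-estimate node priors.
- No count-data likelihood; apply to log expression or beta values.
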