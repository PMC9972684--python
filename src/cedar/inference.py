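"""Posterior probabilities of cell-type-specific differential states.

For each feature the 2^K candidate-model log-likelihoods are combined with
the exact tree prior over leaf-state vectors (internal-node states
marginalized by tree recursion, cached across features):

    P(Z_gk = 1 | Y_g) = sum_{z: z_k=1} L_g(z) P(z) / sum_z L_g(z) P(z)

All sums run in log space (log-sum-exp): with hundreds of samples the
Gaussian log-likelihoods of competing configurations span hundreds of log
units and would underflow otherwise. The local false discovery rate of a
(feature, cell type) is one minus its posterior; the global FDR of a called
list is the mean local fdr over the list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model import StateFitTable
from .tree import PROB_FLOOR, CellTypeTree

__all__ = ["PosteriorTable", "compute_posteriors", "call_features"]

DEFAULT_POSTERIOR_CUTOFF = 0.95


@dataclass
class PosteriorTable:
    """Per feature x cell type posterior, local fdr, and call."""

    posterior: pd.DataFrame  # features x cell types
    log_marginal: pd.Series  # per-feature log P(Y_g)
    cutoff: float | None = None
    calls: pd.DataFrame | None = None

    @property
    def local_fdr(self) -> pd.DataFrame:
        return 1.0 - self.posterior

    def to_frame(self) -> pd.DataFrame:
        """Wide table: `<ct>.posterior`, `<ct>.lfdr`, `<ct>.call` per cell type."""
        out = pd.DataFrame(index=self.posterior.index)
        for ct in self.posterior.columns:
            out[f"{ct}.posterior"] = self.posterior[ct]
            out[f"{ct}.lfdr"] = 1.0 - self.posterior[ct]
            if self.calls is not None:
                out[f"{ct}.call"] = self.calls[ct].astype(int)
        return out


def config_log_priors(
    tree: CellTypeTree, configs: list[tuple[int, ...]]
) -> np.ndarray:
    """Log prior mass of each leaf-state vector under the tree.

    Exact recursive marginalization over internal-node states; computed
    once per tree since the prior does not depend on the feature.
    """
    priors = np.array([tree.z_prior(z) for z in configs], dtype=float)
    return np.log(np.maximum(priors, PROB_FLOOR**2))


def compute_posteriors(
    state_fits: StateFitTable, tree: CellTypeTree
) -> PosteriorTable:
    """Posterior P(Z_gk = 1 | Y_g) for every feature and cell type."""
    if list(tree.leaf_labels) != list(state_fits.cell_types):
        raise ValueError(
            "tree leaves do not match the fitted cell types: "
            f"{list(tree.leaf_labels)} vs {list(state_fits.cell_types)}"
        )
    loglik, configs = state_fits.loglik_matrix()  # C x G
    log_prior = config_log_priors(tree, configs)  # C
    log_weights = loglik + log_prior[:, None]  # C x G
    log_total = logsumexp(log_weights, axis=0)  # G
    assert np.all(np.isfinite(log_total)), "posterior normalizer underflowed"
    k = len(state_fits.cell_types)
    post = np.empty((len(state_fits.feature_ids), k))
    zmat = np.array(configs)  # C x K
    for j in range(k):
        mask = zmat[:, j] == 1
        if not mask.any():
            post[:, j] = 0.0
            continue
        log_num = logsumexp(log_weights[mask], axis=0)
        post[:, j] = np.exp(log_num - log_total)
    post = np.clip(post, 0.0, 1.0)
    return PosteriorTable(
        posterior=pd.DataFrame(
            post, index=state_fits.feature_ids, columns=state_fits.cell_types
        ),
        log_marginal=pd.Series(log_total, index=state_fits.feature_ids),
    )


def call_features(
    post: PosteriorTable, cutoff: float = DEFAULT_POSTERIOR_CUTOFF
) -> tuple[PosteriorTable, dict[str, float | None]]:
    """Threshold posteriors and report the global FDR of each called list.

    A feature is called differential in a cell type when its posterior
    exceeds the cutoff (default 0.95). Per cell type, the global FDR of
    the called list is the mean local fdr over called features; ``None``
    marks cell types with an empty list.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie strictly between 0 and 1")
    calls = post.posterior > cutoff
    global_fdr: dict[str, float | None] = {}
    for ct in post.posterior.columns:
        called = calls[ct]
        if called.any():
            global_fdr[ct] = float((1.0 - post.posterior.loc[called[called].index, ct]).mean())
        else:
            global_fdr[ct] = None
    return (
        PosteriorTable(
            posterior=post.posterior,
            log_marginal=post.log_marginal,
            cutoff=cutoff,
            calls=calls,
        ),
        global_fdr,
    )


def rank_features(post: PosteriorTable, cell_type: str) -> pd.Index:
    """Features ranked most-to-least likely differential in one cell type.

    Ties on the posterior are broken by log marginal likelihood, then by
    feature identifier, so rankings are deterministic.
    """
    df = pd.DataFrame(
        {
            "posterior": post.posterior[cell_type],
            "logml": post.log_marginal,
        }
    )
    df["fid"] = df.index.astype(str)
    df = df.sort_values(
        by=["posterior", "logml", "fid"], ascending=[False, False, True],
        kind="mergesort",
    )
    return df.index
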