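"""State-dependent linear models for bulk mixtures.

The observed bulk signal of feature g in sample i is modeled as the
proportion-weighted average of unknown pure cell-type profiles,

    E[Y_gi | Z_g] = sum_k theta_ik (mu_gk + C_i' beta_gk + Z_gk A_i' delta_gk),

so for a fixed leaf-state vector z the model is linear with columns
theta_k (cell-type baselines), theta_k * C_q (cell-type-specific
confounders), C_q (shared confounders, one common coefficient across cell
types), and theta_k * A only for the cell types with z_k = 1. The design
depends on z but not on the feature, so each of the 2^K candidate models is
fit once for all G features by a single multi-response least-squares solve.

Likelihoods are Gaussian with the plug-in maximum-likelihood variance
RSS/N per feature and per state configuration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BulkMatrix",
    "ProportionMatrix",
    "Covariate",
    "DesignSpec",
    "StateFitTable",
    "build_design",
    "fit_all_states",
]

#: variance floor keeping log-likelihoods finite on (near-)perfect fits
VARIANCE_FLOOR = 1e-12


@dataclass
class BulkMatrix:
    """G x N matrix of observed bulk signals (log expression or beta values)."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("bulk values must be a 2-D matrix")
        g, n = self.values.shape
        if g != len(self.feature_ids) or n != len(self.sample_ids):
            raise ValueError("bulk matrix shape does not match its labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("bulk matrix contains missing or non-finite values")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class ProportionMatrix:
    """N x K matrix of per-sample cell-type proportions (rows sum to 1)."""

    values: np.ndarray
    cell_types: list[str]
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.cell_types):
            raise ValueError("proportion matrix shape does not match cell types")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("proportions must be finite and nonnegative")
        rowsums = self.values.sum(axis=1)
        if np.any(rowsums <= 0):
            raise ValueError("a proportion row sums to zero")
        if np.any(np.abs(rowsums - 1.0) > 1e-6):
            warnings.warn(
                "CEDAR-W001: proportion rows do not sum to 1; renormalizing",
                stacklevel=2,
            )
            self.values = self.values / rowsums[:, None]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cell_types(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        idx = self.sample_ids if self.sample_ids is not None else range(self.n_samples)
        return pd.DataFrame(self.values, index=idx, columns=self.cell_types)


@dataclass
class Covariate:
    """A confounder vector flagged shared or cell-type-specific."""

    name: str
    values: np.ndarray
    cell_type_specific: bool = False

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] > self.values.shape[1]:
            self.values = self.values.T  # accept column vectors


@dataclass
class DesignSpec:
    """Tested covariate plus confounders.

    The tested covariate may be binary, continuous, or dummy-coded
    categorical (rows of a 2-D array = dummy columns). Each confounder is
    flagged either cell-type-specific (interacted with every proportion
    column) or shared (one common coefficient).
    """

    tested: np.ndarray
    confounders: list[Covariate] = field(default_factory=list)
    tested_name: str = "A"

    def __post_init__(self) -> None:
        self.tested = np.atleast_2d(np.asarray(self.tested, dtype=float))
        if self.tested.shape[0] > self.tested.shape[1]:
            self.tested = self.tested.T
        if np.all(np.ptp(self.tested, axis=1) == 0):
            raise ValueError("tested covariate has zero variance")

    @property
    def n_samples(self) -> int:
        return self.tested.shape[1]

    def validate(self, n_samples: int) -> None:
        if self.tested.shape[1] != n_samples:
            raise ValueError("tested covariate length does not match sample count")
        for c in self.confounders:
            if c.values.shape[1] != n_samples:
                raise ValueError(f"confounder {c.name!r} length mismatch")


def build_design(
    theta: ProportionMatrix,
    design: DesignSpec,
    z: Sequence[int],
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for one leaf-state vector z, plus its column names.

    Columns: the K proportion columns (no global intercept — they span it
    because rows sum to one), proportion-by-confounder interactions for
    cell-type-specific confounders, one column per shared confounder, and
    proportion-by-tested-covariate interactions only for cell types with
    z_k = 1.
    """
    design.validate(theta.n_samples)
    if len(z) != theta.n_cell_types:
        raise ValueError("state vector length does not match cell-type count")
    th = theta.values
    cols: list[np.ndarray] = []
    names: list[str] = []
    for k, ct in enumerate(theta.cell_types):
        cols.append(th[:, k])
        names.append(f"theta.{ct}")
    for c in design.confounders:
        if c.cell_type_specific:
            for q in range(c.values.shape[0]):
                suffix = f".{q}" if c.values.shape[0] > 1 else ""
                for k, ct in enumerate(theta.cell_types):
                    cols.append(th[:, k] * c.values[q])
                    names.append(f"theta.{ct}:{c.name}{suffix}")
        else:
            for q in range(c.values.shape[0]):
                suffix = f".{q}" if c.values.shape[0] > 1 else ""
                cols.append(c.values[q])
                names.append(f"{c.name}{suffix}")
    for k, ct in enumerate(theta.cell_types):
        if z[k]:
            for q in range(design.tested.shape[0]):
                suffix = f".{q}" if design.tested.shape[0] > 1 else ""
                cols.append(th[:, k] * design.tested[q])
                names.append(f"theta.{ct}:{design.tested_name}{suffix}")
    return np.column_stack(cols), names


@dataclass
class StateFit:
    """Least-squares fit of one candidate model, shared by all features."""

    z: tuple[int, ...]
    column_names: list[str]
    coefficients: np.ndarray  # P x G
    rss: np.ndarray  # G
    sigma2: np.ndarray  # G, plug-in ML variance RSS/N (floored)
    loglik: np.ndarray  # G
    rank: int


@dataclass
class StateFitTable:
    """Fits for all retained leaf-state configurations."""

    fits: dict[tuple[int, ...], StateFit]
    feature_ids: list[str]
    cell_types: list[str]
    n_samples: int
    dropped: list[tuple[int, ...]] = field(default_factory=list)

    @property
    def configs(self) -> list[tuple[int, ...]]:
        return list(self.fits.keys())

    def loglik_matrix(self) -> tuple[np.ndarray, list[tuple[int, ...]]]:
        """(n_configs x G) log-likelihoods and the matching config list."""
        configs = self.configs
        return np.vstack([self.fits[c].loglik for c in configs]), configs


def _lstsq_fit(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Minimum-norm least squares of each column of y on x.

    Returns (coefficients P x G, rss per column, rank of x). Minimum-norm
    resolution keeps rank-deficient designs usable; effective column count
    for degrees of freedom is the matrix rank.
    """
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    return coef, rss, rank


def gaussian_loglik(rss: np.ndarray, n: int) -> np.ndarray:
    """Profile Gaussian log-likelihood with sigma^2 = RSS/N plugged in."""
    sigma2 = np.maximum(rss / n, VARIANCE_FLOOR)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def fit_all_states(
    bulk: BulkMatrix,
    theta: ProportionMatrix,
    design: DesignSpec,
    cell_types: Sequence[str] | None = None,
) -> StateFitTable:
    """Fit the 2^K candidate models, one shared solve per configuration.

    Each configuration's design depends only on z, so a single
    multi-response least-squares factorization serves all G features.
    Configurations with no residual degrees of freedom (N <= P) are
    dropped with a warning and excluded from any downstream posterior sum.
    """
    if cell_types is not None and list(cell_types) != list(theta.cell_types):
        raise ValueError("cell-type order mismatch between tree and proportions")
    k = theta.n_cell_types
    if bulk.n_samples != theta.n_samples:
        raise ValueError("bulk and proportion sample counts differ")
    n = bulk.n_samples
    y = bulk.values.T  # N x G
    fits: dict[tuple[int, ...], StateFit] = {}
    dropped: list[tuple[int, ...]] = []
    for bits in range(2**k):
        z = tuple((bits >> j) & 1 for j in range(k))
        x, names = build_design(theta, design, z)
        if n <= x.shape[1]:
            dropped.append(z)
            continue
        coef, rss, rank = _lstsq_fit(x, y)
        if rank < x.shape[1]:
            logger.warning(
                "CEDAR-W002: rank-deficient design for state %s (rank %d of %d); "
                "minimum-norm solution used",
                z,
                rank,
                x.shape[1],
            )
        fits[z] = StateFit(
            z=z,
            column_names=names,
            coefficients=coef,
            rss=rss,
            sigma2=np.maximum(rss / n, VARIANCE_FLOOR),
            loglik=gaussian_loglik(rss, n),
            rank=rank,
        )
    if dropped:
        warnings.warn(
            f"CEDAR-W003: dropped {len(dropped)} state configuration(s) with "
            "no residual degrees of freedom",
            stacklevel=2,
        )
    if not fits:
        raise ValueError("no state configuration has positive residual df")
    return StateFitTable(
        fits=fits,
        feature_ids=list(bulk.feature_ids),
        cell_types=list(theta.cell_types),
        n_samples=n,
        dropped=dropped,
    )
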