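"""Trait construction: repeated-measure averaging, covariate adjustment, centering.

The analysis trait is built in two stages, mirroring common practice for
longitudinal blood-pressure phenotypes: measurements repeated over time
points are averaged per individual, then the average is regressed on the
covariates by ordinary least squares and the residuals are carried forward.
The residuals have exactly zero mean, so the grand-mean subtraction in the
score statistics is a no-op performed defensively.

Adjustment deliberately ignores family structure (plain least squares): the
score test itself accounts for relatedness through the kinship quadratic
form, and the two-stage procedure keeps the null model free of variance
components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CollinearCovariatesError
from .dataio import PhenotypeTable


@dataclass
class TraitVector:
    """One numeric trait value per analyzed individual (trait units, e.g. mmHg)."""

    values: np.ndarray
    sample_ids: list[str]
    is_adjusted: bool = False
    grand_mean_removed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.sample_ids):
            raise ValueError("trait length must equal the analyzed-sample count")
        if self.grand_mean_removed:
            scale = max(1.0, float(np.abs(self.values).max(initial=0.0)))
            if abs(self.values.mean()) > 1e-10 * scale:
                raise ValueError("grand_mean_removed set but mean is not ~0")

    def centered(self) -> np.ndarray:
        """Values with the empirical grand mean removed (defensive if already 0)."""
        return self.values - self.values.mean()


def average_repeated_measures(
    pheno: PhenotypeTable, trait_columns: Sequence[str]
) -> TraitVector:
    """Per-individual arithmetic mean over the named measurement columns.

    Individuals missing any of the named columns are dropped (complete case).
    A single column is the identity up to the completeness filter.
    """
    cols = list(trait_columns)
    if not cols:
        raise ValueError("trait_columns must name at least one column")
    missing = [c for c in cols if c not in pheno.data.columns]
    if missing:
        raise KeyError(f"phenotype columns not found: {missing}")
    sub = pheno.data[cols].apply(pd.to_numeric)
    complete = ~sub.isna().any(axis=1)
    if not complete.any():
        raise ValueError("every individual is missing at least one trait column")
    sub = sub.loc[complete]
    return TraitVector(sub.mean(axis=1).to_numpy(), [str(i) for i in sub.index])


def adjust_covariates(trait: TraitVector, covariates=None) -> TraitVector:
    """Least-squares residuals of the trait on [intercept | covariates].

    ``covariates`` may be None (intercept only, i.e. centering), a 2-D array,
    or a DataFrame aligned with ``trait.sample_ids``.  The residuals have
    exactly zero mean and zero inner product with every covariate column;
    applying the operation twice with the same design returns the residuals
    unchanged (projection idempotence).

    Raises
    ------
    CollinearCovariatesError
        If the design matrix is rank-deficient, naming the offending columns.
    """
    n = len(trait.values)
    if covariates is None:
        X = np.ones((n, 1))
        names = ["intercept"]
    else:
        if isinstance(covariates, pd.DataFrame):
            names = ["intercept"] + [str(c) for c in covariates.columns]
            C = covariates.to_numpy(dtype=float)
        else:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            names = ["intercept"] + [f"covar_{k}" for k in range(C.shape[1])]
        if C.shape[0] != n:
            raise ValueError("covariate rows must match the trait length")
        if np.isnan(C).any():
            raise ValueError("covariate matrix must be complete (no NA)")
        X = np.column_stack([np.ones(n), C])

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Identify offending columns by incremental rank growth.
        offending = []
        r_prev = 0
        for k in range(X.shape[1]):
            r = np.linalg.matrix_rank(X[:, : k + 1])
            if r == r_prev:
                offending.append(names[k])
            r_prev = r
        raise CollinearCovariatesError(offending)

    beta, *_ = np.linalg.lstsq(X, trait.values, rcond=None)
    resid = trait.values - X @ beta
    resid -= resid.mean()  # exact zero mean despite floating-point round-off
    return TraitVector(
        resid, list(trait.sample_ids), is_adjusted=True, grand_mean_removed=True
    )
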