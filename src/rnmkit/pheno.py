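"""Phenotype preparation: adjustment, outlier QC, inverse-normal transform.

The interaction models downstream fit an intercept as their only fixed
effect, so every nuisance association — demographics, batch/center effects,
principal components, and crucially the lifestyle covariate itself — is
regressed out of the trait here first.  Adjusting for the interaction
covariate's own mean effect is what prevents a trait-covariate correlation
from masquerading as an interaction signal.  The prepared trait is then
outlier-screened at +/-3 SD and mapped to normal scores (rank-based inverse
normal transform), in that fixed order, with each step recorded in a
provenance trail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AdjustedPhenotype",
    "StandardizedCovariate",
    "adjust",
    "remove_outliers",
    "inverse_normal_transform",
    "standardize",
    "prepare_phenotype",
]


@dataclass
class AdjustedPhenotype:
    values: np.ndarray
    sample_ids: list
    provenance: list = field(default_factory=list)

    def with_step(self, values, sample_ids, step: str) -> "AdjustedPhenotype":
        return AdjustedPhenotype(
            values=np.asarray(values, dtype=float),
            sample_ids=list(sample_ids),
            provenance=self.provenance + [step],
        )


@dataclass
class StandardizedCovariate:
    """Covariate scaled to mean 0, SD 1 (sample SD, n-1 denominator)."""

    values: np.ndarray
    raw_name: str = "covariate"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if abs(self.values.mean()) > 1e-8 or abs(self.values.std(ddof=1) - 1) > 1e-8:
            raise ValueError("covariate is not standardized; use standardize()")


def adjust(y, covariate_table: pd.DataFrame, columns=None) -> AdjustedPhenotype:
    """OLS-residualize the trait on the named covariate columns (plus an
    intercept).

    Rows with missing values in y or any design column are dropped (and
    counted in the provenance).  A rank-deficient design triggers a warning;
    the minimum-norm least-squares fit still leaves residuals orthogonal to
    every design column.
    """
    if isinstance(y, AdjustedPhenotype):
        base_prov = y.provenance
        ids = list(y.sample_ids)
        yv = np.asarray(y.values, dtype=float)
    else:
        base_prov = []
        yv = np.asarray(y, dtype=float)
        ids = (
            list(covariate_table["IID"])
            if "IID" in covariate_table.columns
            else list(range(len(yv)))
        )
    if columns is None:
        columns = [c for c in covariate_table.columns if c != "IID"]
    if len(covariate_table) != len(yv):
        raise ValueError("phenotype and covariate table lengths differ")

    design_cols = covariate_table[list(columns)].to_numpy(dtype=float)
    ok = ~np.isnan(yv) & ~np.isnan(design_cols).any(axis=1)
    n_drop = int((~ok).sum())
    yv = yv[ok]
    X = np.column_stack([np.ones(ok.sum()), design_cols[ok]])
    kept_ids = [ids[i] for i in np.where(ok)[0]]

    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient adjustment design; collinear columns "
                      "contribute nothing to the fit", stacklevel=2)
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    step = f"adjust(columns={list(columns)}, dropped={n_drop})"
    return AdjustedPhenotype(values=resid, sample_ids=kept_ids,
                             provenance=base_prov + [step])


def remove_outliers(values, k_sd: float = 3.0):
    """Drop values more than k_sd SDs from the mean.

    Mean and SD are computed once on the input (no re-iteration).  Returns
    (kept values, boolean exclusion mask over the input).  A zero-SD input
    removes nothing.
    """
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    if sd == 0:
        mask = np.zeros(v.shape, dtype=bool)
    else:
        mask = np.abs(v - v.mean()) > k_sd * sd
    return v[~mask], mask


def inverse_normal_transform(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    The value with (average, tie-shared) rank r maps to
    Phi^-1((r - offset) / (n - 2*offset + 1)); with the default offset 3/8
    the denominator is n + 1/4.  Rank-based, so any monotone transform of the
    input yields the identical output.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("inverse normal transform needs n >= 2")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - offset) / (v.size - 2.0 * offset + 1.0))


def standardize(c_raw, name: str = "covariate") -> StandardizedCovariate:
    """Scale to mean 0, SD 1 (sample SD).  Constant input is rejected."""
    v = np.asarray(c_raw, dtype=float)
    sd = v.std(ddof=1)
    if not sd > 0:
        raise ValueError("covariate is constant; cannot standardize")
    return StandardizedCovariate(values=(v - v.mean()) / sd, raw_name=name)


def prepare_phenotype(
    y,
    covariate_table: pd.DataFrame,
    adjust_columns,
    k_sd: float = 3.0,
    int_offset: float = 3.0 / 8.0,
):
    """Full preparation pipeline in the canonical order
    adjust -> remove_outliers -> inverse_normal_transform.

    Returns the prepared AdjustedPhenotype together with the surviving row
    index into the adjusted sample (so covariates can be subset to match).
    """
    adj = adjust(y, covariate_table, adjust_columns)
    kept, mask = remove_outliers(adj.values, k_sd=k_sd)
    kept_idx = np.where(~mask)[0]
    ids = [adj.sample_ids[i] for i in kept_idx]
    transformed = inverse_normal_transform(kept, offset=int_offset)
    out = AdjustedPhenotype(
        values=transformed,
        sample_ids=ids,
        provenance=adj.provenance
        + [f"remove_outliers(k_sd={k_sd}, removed={int(mask.sum())})",
           f"inverse_normal_transform(offset={int_offset})"],
    )
    return out, kept_idx
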