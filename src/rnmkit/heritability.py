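"""SNP heritability under additive and reaction-norm fits, and the
"still-missing heritability" comparison.

Heritability is defined from the intercept components only,

    h^2 = s2_a0 / (s2_a0 + s2_t0),

i.e. the genetic share of variance at the covariate mean (c = 0); this
assumes environmental homogeneity of the sample.  When real interaction
variance exists but an additive-only (GREML) model is fitted, that variance
is absorbed into the residual, deflating h^2.  The ratio of change

    (h^2_MRNM - h^2_GREML) / h^2_GREML

quantifies how much heritability the additive model was missing; averaged
across analyses per trait with a normal-approximation 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reml import ModelFit, VarianceComponents

__all__ = [
    "HeritabilityRecord",
    "heritability",
    "variance_at",
    "compare",
    "ci_across_analyses",
]


@dataclass
class HeritabilityRecord:
    trait: str
    h2_greml: float
    h2_mrnm: float
    ratio_change: float
    legitimate: bool = True


def heritability(vc: VarianceComponents) -> float:
    """h^2 = s2_a0 / (s2_a0 + s2_t0); interaction components excluded."""
    denom = vc.sigma2_a0 + vc.sigma2_t0
    if denom <= 0:
        raise ValueError("total intercept variance must be positive")
    return vc.sigma2_a0 / denom


def variance_at(vc: VarianceComponents, c: float):
    """Diagnostic: (genetic, residual) variance at covariate value c.

    genetic  = s2_a0 + 2 s_a01 c + s2_a1 c^2
    residual = s2_t0 + 2 s_t01 c + s2_t1 c^2
    Never used for the headline h^2 ratio, which is evaluated at c = 0.
    """
    g = vc.sigma2_a0 + 2 * vc.sigma_a01 * c + vc.sigma2_a1 * c**2
    r = vc.sigma2_t0 + 2 * vc.sigma_t01 * c + vc.sigma2_t1 * c**2
    return g, r


def compare(null_fit: ModelFit, full_fit: ModelFit, trait: str = "") -> HeritabilityRecord:
    """Heritability under both fits and the ratio of change.

    On data with genuine interaction variance the additive fit inflates the
    residual, so the expected ratio is positive.  An illegitimate full fit
    (negative summed interaction variance) is flagged on the record.
    """
    if not (null_fit.converged and full_fit.converged):
        raise ValueError("both fits must have converged")
    from .inference import legitimacy_check

    h2_g = heritability(null_fit.vc_hat)
    h2_m = heritability(full_fit.vc_hat)
    ratio = (h2_m - h2_g) / h2_g if h2_g > 0 else np.nan
    return HeritabilityRecord(
        trait=trait,
        h2_greml=h2_g,
        h2_mrnm=h2_m,
        ratio_change=ratio,
        legitimate=legitimacy_check(full_fit),
    )


def ci_across_analyses(records) -> pd.DataFrame:
    """Per trait: mean ratio_change with a 95% CI (mean +/- 1.96 SE) over the
    trait's analyses; a single record yields a point estimate without CI.

    The ``significant`` flag marks traits whose CI excludes zero.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    rows = []
    by_trait: dict = {}
    for r in records:
        by_trait.setdefault(r.trait, []).append(r.ratio_change)
    for trait, ratios in by_trait.items():
        ratios = np.asarray(ratios, dtype=float)
        mean = float(ratios.mean())
        if ratios.size >= 2:
            se = float(ratios.std(ddof=1) / np.sqrt(ratios.size))
            lo, hi = mean - 1.96 * se, mean + 1.96 * se
            sig = bool(lo > 0 or hi < 0)
        else:
            se, lo, hi, sig = np.nan, np.nan, np.nan, False
        rows.append(
            {"trait": trait, "n_analyses": int(ratios.size), "mean_ratio": mean,
             "se": se, "ci_low": lo, "ci_high": hi, "significant": sig}
        )
    return pd.DataFrame(rows)
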