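"""Likelihood-ratio testing of GxE and RxE interaction, meta-analysis and
multiple-testing control.

Five comparisons among the four nested reaction-norm fits are reported:

======================  =========================  ==============================
test                    comparison                 detects
======================  =========================  ==============================
OVERALL                 full vs null               any interaction (GxE + RxE)
GXE_UNADJ               GxE-only vs null           GxE, not collinearity-corrected
RXE_UNADJ               RxE-only vs null           RxE, not collinearity-corrected
GXE_ORTHOGONAL          full vs RxE-only           GxE orthogonal to RxE
RXE_ORTHOGONAL          full vs GxE-only           RxE orthogonal to GxE
======================  =========================  ==============================

The orthogonal tests are the scientifically interesting ones: because the
GxE kernel (K o cc') and the RxE diagonal (c^2) both inflate variance with
|c|, the unadjusted tests are collinear, and only the full-vs-reduced
comparison attributes the signal to one component net of the other.
P-values from independent sample splits are combined with Fisher's method,
estimates by fixed-effect inverse-variance weighting, and grid-level
significance is Bonferroni-controlled.  A significant cell must additionally
pass the legitimacy rule: the estimated GxE + RxE slope variances must sum to
a nonnegative value (unconstrained REML can stray outside the legitimate
parameter space).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pheno import prepare_phenotype, standardize
from .reml import ModelFit, RemlOptions

logger = logging.getLogger(__name__)

__all__ = [
    "TEST_TYPES",
    "InteractionTestResult",
    "lrt",
    "run_five_tests",
    "legitimacy_check",
    "fisher_meta",
    "meta_estimates",
    "bonferroni_threshold",
    "run_grid",
]

#: test name -> (full spec, reduced spec)
TEST_TYPES = {
    "OVERALL": ("FULL", "NULL"),
    "GXE_UNADJ": ("GXE_ONLY", "NULL"),
    "RXE_UNADJ": ("RXE_ONLY", "NULL"),
    "GXE_ORTHOGONAL": ("FULL", "RXE_ONLY"),
    "RXE_ORTHOGONAL": ("FULL", "GXE_ONLY"),
}


@dataclass
class InteractionTestResult:
    test_type: str
    chi2: float
    df: int
    p: float
    legitimate: bool = True
    per_split_p: list = field(default_factory=list)
    meta_p: float | None = None

    @property
    def best_p(self) -> float:
        """Meta-analyzed p when available, else the single-fit p."""
        return self.meta_p if self.meta_p is not None else self.p


def lrt(fit_full: ModelFit, fit_reduced: ModelFit):
    """Likelihood-ratio chi-square between two nested converged fits.

    chi2 = max(0, 2 * (logL_full - logL_reduced)); df is the difference in
    free-parameter counts; p is the upper chi-square tail.
    """
    if not (fit_full.converged and fit_reduced.converged):
        raise ValueError("likelihood-ratio test requires converged fits")
    if not fit_reduced.spec.is_nested_in(fit_full.spec):
        raise ValueError(
            f"{fit_reduced.spec.name} is not nested in {fit_full.spec.name}"
        )
    raw = 2.0 * (fit_full.logL - fit_reduced.logL)
    if raw < -1e-4:
        raise ValueError(
            "full-model likelihood below the nested model's: convergence failure"
        )
    chi2 = max(0.0, raw)
    df = fit_full.spec.n_free - fit_reduced.spec.n_free
    p = float(stats.chi2.sf(chi2, df=df)) if df > 0 else 1.0
    return chi2, df, p


def run_five_tests(fits: dict) -> list:
    """All five model comparisons from the four fits (keys NULL, GXE_ONLY,
    RXE_ONLY, FULL).

    A non-converged fit invalidates only the tests that need it; the others
    are still produced.  The legitimacy flag on every result comes from the
    FULL fit's interaction variances (when the FULL fit is usable).
    """
    legit = True
    full = fits.get("FULL")
    if full is not None and full.converged:
        legit = legitimacy_check(full)
    results = []
    for name, (full_name, red_name) in TEST_TYPES.items():
        fa, fb = fits.get(full_name), fits.get(red_name)
        if fa is None or fb is None or not (fa.converged and fb.converged):
            logger.warning("test %s unavailable (non-converged fit)", name)
            continue
        try:
            chi2, df, p = lrt(fa, fb)
        except ValueError as exc:
            logger.warning("test %s unavailable: %s", name, exc)
            continue
        results.append(
            InteractionTestResult(test_type=name, chi2=chi2, df=df, p=p,
                                  legitimate=legit)
        )
    return results


def legitimacy_check(fit_full: ModelFit) -> bool:
    """True iff the estimated GxE + RxE slope variances sum to >= 0.

    Unconstrained REML can return (slightly) negative variance estimates; a
    cell whose summed interaction variance is negative lies outside the
    legitimate parameter space and is excluded from the significant set
    regardless of its p-value.  The boundary (sum exactly 0) is legitimate.
    """
    vc = fit_full.vc_hat
    return vc.sigma2_a1 + vc.sigma2_t1 >= 0


def fisher_meta(p_values) -> float:
    """Fisher's combination: -2 sum(ln p_i) ~ chi-square with 2k df."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        logger.warning("p-value of 0 clipped to the smallest positive float")
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    X = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(X, df=2 * p.size))


def meta_estimates(estimates, ses):
    """Fixed-effect inverse-variance pooling of per-split estimates."""
    e = np.asarray(list(estimates), dtype=float)
    s = np.asarray(list(ses), dtype=float)
    if e.shape != s.shape or e.size == 0:
        raise ValueError("estimates and ses must be equal-length and non-empty")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    if e.size == 1:
        return float(e[0]), float(s[0])
    w = 1.0 / s**2
    pooled = float(np.sum(w * e) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    return pooled, pooled_se


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """alpha / n_tests (e.g. 0.05 / 96 = 5.21e-4 for a 12x8 grid)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def _fit_four_models(y, K, c, options=None):
    from .reml import fit_nested_models

    return fit_nested_models(y, K, c, options)


def run_grid(
    traits: dict,
    covariates: dict,
    grm,
    splits: dict | None = None,
    adjust_tables: pd.DataFrame | None = None,
    alpha: float = 0.05,
    options: RemlOptions | None = None,
) -> pd.DataFrame:
    """Full trait x covariate interaction scan.

    Parameters
    ----------
    traits : {trait_name: phenotype vector} (raw; each is adjusted for the
        current covariate before fitting)
    covariates : {covariate_name: raw covariate vector}
    grm : GRM over the same samples
    splits : optional {sample_id: group}; the four models are fitted per
        split and p-values Fisher-combined.  None fits once on all samples.
    adjust_tables : optional extra adjustment columns (DataFrame aligned with
        samples) applied to every trait.
    alpha : family-wise error rate; the Bonferroni threshold is
        alpha / (n_traits * n_covariates).

    Returns a tidy DataFrame: one row per cell per test type, with per-split
    and meta-analyzed p-values, the legitimacy flag and the significance
    call.  A failing cell is logged and marked, and the scan continues.
    """
    n_cells = len(traits) * len(covariates)
    threshold = bonferroni_threshold(alpha, n_cells)
    sample_ids = list(grm.sample_ids)
    group_of = splits or {s: 0 for s in sample_ids}
    groups = sorted(set(group_of.values()))
    rows = []
    for trait_name, y_raw in traits.items():
        for cov_name, c_raw in covariates.items():
            try:
                cell = _run_cell(
                    y_raw, c_raw, grm, sample_ids, group_of, groups,
                    adjust_tables, options,
                )
            except Exception as exc:  # cell failure must not kill the scan
                logger.error("cell %s x %s failed: %s", trait_name, cov_name, exc)
                rows.append(
                    {"trait": trait_name, "covariate": cov_name,
                     "test_type": "ERROR", "chi2": np.nan, "df": 0,
                     "p": np.nan, "meta_p": np.nan, "legitimate": False,
                     "significant": False, "error": str(exc)}
                )
                continue
            for res in cell:
                rows.append(
                    {"trait": trait_name, "covariate": cov_name,
                     "test_type": res.test_type, "chi2": res.chi2,
                     "df": res.df, "p": res.p, "meta_p": res.best_p,
                     "legitimate": res.legitimate,
                     "significant": bool(res.best_p < threshold and res.legitimate),
                     "error": ""}
                )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["n_cells"] = n_cells
    return out


def _run_cell(y_raw, c_raw, grm, sample_ids, group_of, groups, adjust_tables,
              options):
    """One trait x covariate cell: per-split preparation, four fits, five
    tests, Fisher meta-analysis over splits."""
    y_raw = np.asarray(y_raw, dtype=float)
    c_raw = np.asarray(c_raw, dtype=float)
    per_split: list[list[InteractionTestResult]] = []
    for gidx in groups:
        idx = np.array([i for i, s in enumerate(sample_ids) if group_of[s] == gidx])
        table = pd.DataFrame({"IID": [sample_ids[i] for i in idx],
                              "covariate": c_raw[idx]})
        if adjust_tables is not None:
            extra = adjust_tables.iloc[idx].reset_index(drop=True)
            table = pd.concat([table, extra], axis=1)
        cols = [c for c in table.columns if c != "IID"]
        y_prep, kept = prepare_phenotype(y_raw[idx], table, cols)
        keep_idx = idx[kept]
        c_std = standardize(c_raw[keep_idx])
        k_sub = grm.subset(keep_idx)
        fits = _fit_four_models(y_prep.values, k_sub.values, c_std.values, options)
        res = run_five_tests(fits)
        if res:
            per_split.append(res)
    if not per_split:
        raise RuntimeError("no split produced a usable set of fits")
    combined = []
    for name in TEST_TYPES:
        split_results = [r for res in per_split for r in res if r.test_type == name]
        if not split_results:
            continue
        ps = [r.p for r in split_results]
        first = split_results[0]
        combined.append(
            InteractionTestResult(
                test_type=name,
                chi2=float(np.mean([r.chi2 for r in split_results])),
                df=first.df,
                p=first.p,
                legitimate=all(r.legitimate for r in split_results),
                per_split_p=ps,
                meta_p=fisher_meta(ps) if len(ps) >= 2 else None,
            )
        )
    return combined
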