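"""Individual risk prediction and trajectory stratification.

From a full-model fit, the expected phenotype of individual *i* is

    yhat_i = a0_i + a1_i * c_i + t1_i * c_i

(additive genetic value plus GxE and RxE interaction effects evaluated at
the individual's covariate level).  Individuals are stratified into bottom /
middle / top 20% groups by their estimated total interaction effect
(a1 + t1, or a single component for the GxE-only / RxE-only variants), each
group is split into prospective cases and controls, and a straight line of
yhat on c is fitted per group.  Intercepts and slopes are then aggregated
across analyses with a paired case-vs-control t-test, after orienting signs
so that "unfavorable" points the same way for every trait/covariate pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TrajectoryGroupSummary",
    "predict_risk",
    "stratify",
    "orient_signs",
    "group_lines",
    "aggregate",
    "FLIP_NAMES",
]

GROUPS = ("BOTTOM20", "MIDDLE20", "TOP20")

#: variables measured in a "higher is healthier" direction; their values are
#: sign-flipped so that larger always means higher metabolic risk
FLIP_NAMES = frozenset(
    {
        "hdl",
        "diet",
        "healthy diet",
        "pa:summed",
        "pa:walk",
        "pa:moderate",
        "pa:vigorous",
        "met",
        "physical activity",
    }
)

#: vocabulary of variables known to need no flip
KEEP_NAMES = frozenset(
    {
        "glucose", "hba1c", "tc", "ldl", "crp", "sodium", "potassium",
        "bmi", "whr", "systolic", "diastolic", "systolic bp", "diastolic bp",
        "age", "alc", "smk",
    }
)


@dataclass
class TrajectoryGroupSummary:
    group: str  # BOTTOM20 | MIDDLE20 | TOP20
    status: str  # "case" | "control"
    intercept: float
    slope: float
    n: int
    missing: bool = False


def predict_risk(blups, c) -> np.ndarray:
    """yhat = a0 + (a1 + t1) * c per individual.

    ``blups`` is a :class:`rnmkit.reml.Blups` (or any object with a0/a1/t1
    arrays) from the FULL-model fit.
    """
    c = np.asarray(c, dtype=float)
    a0, a1, t1 = (np.asarray(getattr(blups, k), dtype=float) for k in ("a0", "a1", "t1"))
    if not (a0.shape == a1.shape == t1.shape == c.shape):
        raise ValueError("BLUP and covariate lengths differ")
    return a0 + a1 * c + t1 * c


def stratify(interaction_effects, fractions: float = 0.2) -> np.ndarray:
    """Label bottom/middle/top `fractions` of individuals by effect size.

    BOTTOM20 is the lowest fraction, TOP20 the highest, MIDDLE20 the band of
    the same size centered on the median; everyone else is unlabeled ("").
    Ties are broken by a stable sort on position, so labels are deterministic.
    """
    e = np.asarray(interaction_effects, dtype=float)
    n = e.size
    if n < 5:
        raise ValueError("stratification needs at least 5 individuals")
    k = int(round(fractions * n))
    order = np.argsort(e, kind="stable")
    labels = np.full(n, "", dtype=object)
    labels[order[:k]] = "BOTTOM20"
    labels[order[n - k:]] = "TOP20"
    mid_start = (n - k) // 2
    labels[order[mid_start: mid_start + k]] = "MIDDLE20"
    return labels


def _flip_sign(name: str) -> int:
    key = name.strip().lower()
    if key in FLIP_NAMES:
        return -1
    if key not in KEEP_NAMES:
        warnings.warn(f"unknown variable name {name!r}; values left unchanged",
                      stacklevel=3)
    return 1


def orient_signs(trait_name: str, covariate_name: str, values) -> np.ndarray:
    """Orient values so the unfavorable direction is consistent across pairs.

    Values are negated when exactly one of the trait/covariate names belongs
    to the flip set (HDL, physical-activity measures, healthy diet); flipping
    both cancels.  Applying the function twice is the identity.
    """
    v = np.asarray(values, dtype=float)
    return v * (_flip_sign(trait_name) * _flip_sign(covariate_name))


def group_lines(yhat, c, groups, status) -> list:
    """Per (stratum, case/control) cell, OLS of yhat on c.

    Returns six TrajectoryGroupSummary entries; an empty cell is marked
    missing and skipped by aggregate().
    """
    yhat = np.asarray(yhat, dtype=float)
    c = np.asarray(c, dtype=float)
    groups = np.asarray(groups, dtype=object)
    status = np.asarray(status)
    out = []
    for grp in GROUPS:
        for stat_label, stat_val in (("case", 1), ("control", 0)):
            sel = (groups == grp) & (status == stat_val)
            n = int(sel.sum())
            if n < 2 or np.var(c[sel]) == 0:
                out.append(TrajectoryGroupSummary(grp, stat_label, np.nan,
                                                  np.nan, n, missing=True))
                continue
            slope, intercept = np.polyfit(c[sel], yhat[sel], 1)
            out.append(TrajectoryGroupSummary(grp, stat_label,
                                              float(intercept), float(slope), n))
    return out


def aggregate(summaries_by_analysis) -> dict:
    """Mean/SE of intercepts and slopes per cell across analyses, plus
    paired case-minus-control t-tests per stratum.

    ``summaries_by_analysis`` is a list (one entry per analysis) of the
    six-cell lists from group_lines().  Pairing is within analysis and
    stratum; analyses with a missing cell are dropped from that stratum's
    test.  Zero variance of the paired differences makes the test undefined
    (reported with p = NaN).
    """
    if len(summaries_by_analysis) < 2:
        raise ValueError("aggregation needs at least 2 analyses")
    out = {"cells": {}, "paired_tests": {}}
    for grp in GROUPS:
        for stat in ("case", "control"):
            vals = [
                s for analysis in summaries_by_analysis for s in analysis
                if s.group == grp and s.status == stat and not s.missing
            ]
            intercepts = np.array([s.intercept for s in vals])
            slopes = np.array([s.slope for s in vals])
            out["cells"][(grp, stat)] = {
                "n_analyses": len(vals),
                "intercept_mean": float(intercepts.mean()) if len(vals) else np.nan,
                "intercept_se": _se(intercepts),
                "slope_mean": float(slopes.mean()) if len(vals) else np.nan,
                "slope_se": _se(slopes),
            }
        pairs_i, pairs_s = [], []
        for analysis in summaries_by_analysis:
            case = _pick(analysis, grp, "case")
            ctrl = _pick(analysis, grp, "control")
            if case is None or ctrl is None:
                continue
            pairs_i.append(case.intercept - ctrl.intercept)
            pairs_s.append(case.slope - ctrl.slope)
        out["paired_tests"][grp] = {
            "intercept": _paired_t(pairs_i),
            "slope": _paired_t(pairs_s),
        }
    return out


def _pick(analysis, grp, stat):
    for s in analysis:
        if s.group == grp and s.status == stat and not s.missing:
            return s
    return None


def _se(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan


def _paired_t(diffs) -> dict:
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        return {"t": np.nan, "df": max(d.size - 1, 0), "p": np.nan,
                "mean_diff": float(d.mean()) if d.size else np.nan}
    if d.std(ddof=1) == 0:
        return {"t": np.nan, "df": d.size - 1, "p": np.nan,
                "mean_diff": float(d.mean())}
    t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
    p = 2.0 * stats.t.sf(abs(t), df=d.size - 1)
    return {"t": float(t), "df": d.size - 1, "p": float(p),
            "mean_diff": float(d.mean())}
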