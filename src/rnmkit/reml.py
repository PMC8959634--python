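"""Restricted maximum likelihood for reaction-norm mixed models.

The phenotype of individual *i* is modelled as

    y_i = mu + alpha0_i + alpha1_i * c_i + tau0_i + tau1_i * c_i

where ``c`` is a standardized environmental covariate, the genetic
intercept/slope pair (alpha0, alpha1) is a bivariate normal random effect with
covariance kernel K (the genomic relationship matrix) and 2x2 parameter block
[[s2_a0, s_a01], [s_a01, s2_a1]], and the residual pair (tau0, tau1) is
individual-specific with block [[s2_t0, s_t01], [s_t01, s2_t1]].

The implied phenotypic covariance is

    V = s2_a0*K + s_a01*(K o (c1' + 1c')) + s2_a1*(K o cc') + D
    D_ii = s2_t0 + 2*s_t01*c_i + s2_t1*c_i**2

with ``o`` the elementwise (Hadamard) product.  Four nested specifications are
supported: an additive-only null model (GREML), GxE-only, RxE-only, and the
full model with both interaction blocks.  Estimation is average-information
(AI) REML with an EM first step and step-halving; estimates are unconstrained
by default (they may go slightly negative), mirroring the usual behaviour of
variance-component software, so that likelihood-ratio statistics retain their
chi-square calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "PARAM_NAMES",
    "VarianceComponents",
    "ModelSpec",
    "MODEL_SPECS",
    "RemlOptions",
    "Blups",
    "ModelFit",
    "build_covariance",
    "reml_fit",
    "fit_nested_models",
    "compute_blups",
]

#: canonical parameter order used everywhere a parameter vector appears
PARAM_NAMES = (
    "sigma2_a0",
    "sigma_a01",
    "sigma2_a1",
    "sigma2_t0",
    "sigma_t01",
    "sigma2_t1",
)


@dataclass
class VarianceComponents:
    """The six (co)variance parameters of the reaction-norm model.

    ``sigma2_a0``/``sigma2_a1`` are the genetic intercept and slope (GxE)
    variances, ``sigma_a01`` their covariance; the ``t`` block is the residual
    analogue (``sigma2_t1`` is the RxE variance).
    """

    sigma2_a0: float = 0.0
    sigma_a01: float = 0.0
    sigma2_a1: float = 0.0
    sigma2_t0: float = 0.0
    sigma_t01: float = 0.0
    sigma2_t1: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "VarianceComponents":
        values = np.asarray(values, dtype=float)
        if values.shape != (6,):
            raise ValueError("expected 6 parameters in canonical order")
        return cls(**dict(zip(PARAM_NAMES, values)))

    @property
    def genetic_block(self) -> np.ndarray:
        return np.array(
            [[self.sigma2_a0, self.sigma_a01], [self.sigma_a01, self.sigma2_a1]]
        )

    @property
    def residual_block(self) -> np.ndarray:
        return np.array(
            [[self.sigma2_t0, self.sigma_t01], [self.sigma_t01, self.sigma2_t1]]
        )

    def validate(self, require_psd: bool = True) -> None:
        """Check nonnegative variances and PSD intercept-slope blocks."""
        for name in ("sigma2_a0", "sigma2_a1", "sigma2_t0", "sigma2_t1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if require_psd:
            for label, block in (
                ("genetic", self.genetic_block),
                ("residual", self.residual_block),
            ):
                if np.linalg.eigvalsh(block).min() < -1e-10:
                    raise ValueError(
                        f"{label} intercept-slope block is not positive semidefinite"
                    )


@dataclass(frozen=True)
class ModelSpec:
    """A nested model: which of the six parameters are free.

    NULL frees the two intercept variances (standard GREML); GXE_ONLY adds the
    genetic slope block; RXE_ONLY adds the residual slope block; FULL frees
    all six.
    """

    name: str
    free_params: tuple

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    def free_indices(self) -> np.ndarray:
        return np.array([PARAM_NAMES.index(p) for p in self.free_params])

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.free_params) <= set(other.free_params)


MODEL_SPECS = {
    "NULL": ModelSpec("NULL", ("sigma2_a0", "sigma2_t0")),
    "GXE_ONLY": ModelSpec(
        "GXE_ONLY", ("sigma2_a0", "sigma_a01", "sigma2_a1", "sigma2_t0")
    ),
    "RXE_ONLY": ModelSpec(
        "RXE_ONLY", ("sigma2_a0", "sigma2_t0", "sigma_t01", "sigma2_t1")
    ),
    "FULL": ModelSpec("FULL", PARAM_NAMES),
}


@dataclass
class RemlOptions:
    """Optimizer controls for :func:`reml_fit`."""

    max_iter: int = 100
    tol_logl: float = 1e-6
    tol_grad: float = 1e-4
    constrain: bool = False  # project intercept-slope blocks to PSD each step
    verbose: bool = False


@dataclass
class Blups:
    """Per-individual conditional means of the random effects."""

    a0: np.ndarray
    a1: np.ndarray
    t0: np.ndarray
    t1: np.ndarray


@dataclass
class ModelFit:
    """Result of one REML fit: estimates, likelihood and diagnostics."""

    spec: ModelSpec
    vc_hat: VarianceComponents
    logL: float
    vc_cov: np.ndarray  # sampling covariance of the free parameters (AI^-1)
    n_iter: int
    converged: bool
    beta_hat: float
    grad_norm: float
    blups: Blups | None = None
    n: int = 0

    def se(self, param: str) -> float:
        idx = list(self.spec.free_params).index(param)
        return float(np.sqrt(max(self.vc_cov[idx, idx], 0.0)))


def _as_array(x, attr_candidates=("values",)):
    for attr in attr_candidates:
        if hasattr(x, attr):
            x = getattr(x, attr)
    return np.asarray(x, dtype=float)


def build_covariance(k, c, vc: VarianceComponents) -> np.ndarray:
    """Assemble the n x n phenotypic covariance matrix V.

    ``k`` is the GRM (array or :class:`~rnmkit.qc.GRM`), ``c`` the standardized
    covariate.  The genetic part is s2_a0*K + s_a01*(K o (c1'+1c')) +
    s2_a1*(K o cc'); the residual part is diagonal with entries
    s2_t0 + 2*s_t01*c_i + s2_t1*c_i**2.
    """
    K = _as_array(k)
    cv = _as_array(c)
    n = K.shape[0]
    if K.shape != (n, n) or cv.shape != (n,):
        raise ValueError("GRM and covariate dimensions do not agree")
    csum = cv[:, None] + cv[None, :]
    V = (
        vc.sigma2_a0 * K
        + vc.sigma_a01 * (K * csum)
        + vc.sigma2_a1 * (K * np.outer(cv, cv))
    )
    V[np.diag_indices_from(V)] += (
        vc.sigma2_t0 + 2.0 * vc.sigma_t01 * cv + vc.sigma2_t1 * cv**2
    )
    return V


def _derivative_structures(K: np.ndarray, c: np.ndarray):
    """dV/dtheta for each of the six parameters.

    Dense matrices for the genetic block, diagonal vectors for the residual
    block (kept as vectors so traces and matvecs stay O(n^2) / O(n)).
    """
    ones = np.ones_like(c)
    return [
        ("dense", K),
        ("dense", K * (c[:, None] + c[None, :])),
        ("dense", K * np.outer(c, c)),
        ("diag", ones),
        ("diag", 2.0 * c),
        ("diag", c**2),
    ]


def _mat_vec(struct, v):
    kind, M = struct
    return M @ v if kind == "dense" else M * v


def _trace_PM(struct, P, P_diag):
    kind, M = struct
    if kind == "dense":
        # both symmetric: tr(P M) = sum_ij P_ij M_ij
        return float(np.sum(P * M))
    return float(P_diag @ M)


class _RemlWorkspace:
    """Per-iteration REML quantities at a given parameter vector.

    Fixed effects are an intercept only: all other adjustment is applied to
    the phenotype upstream, so X = 1.
    """

    def __init__(self, K, c, y):
        self.K = K
        self.c = c
        self.y = y
        self.n = y.shape[0]
        self.ones = np.ones(self.n)
        self.derivs = _derivative_structures(K, c)

    def evaluate(self, theta, need_inverse=True):
        vc = VarianceComponents.from_array(theta)
        V = build_covariance(self.K, self.c, vc)
        try:
            cho = cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        diag_l = np.diag(cho[0])
        if np.any(diag_l <= 0) or not np.all(np.isfinite(diag_l)):
            return None
        logdetV = 2.0 * float(np.sum(np.log(diag_l)))
        Vinv_y = cho_solve(cho, self.y, check_finite=False)
        Vinv_1 = cho_solve(cho, self.ones, check_finite=False)
        xtvix = float(self.ones @ Vinv_1)
        if xtvix <= 0:
            return None
        beta = float(self.ones @ Vinv_y) / xtvix
        Py = Vinv_y - Vinv_1 * beta
        yPy = float(self.y @ Py)
        logL = -0.5 * (logdetV + np.log(xtvix) + yPy)
        out = {
            "logL": logL,
            "beta": beta,
            "Py": Py,
            "xtvix": xtvix,
            "Vinv_1": Vinv_1,
        }
        if need_inverse:
            Vinv = cho_solve(cho, np.eye(self.n), check_finite=False)
            P = Vinv - np.outer(Vinv_1, Vinv_1) / xtvix
            out["P"] = P
        return out

    def score_and_ai(self, ev, free_idx):
        """REML score vector and average-information matrix (free params)."""
        P = ev["P"]
        Py = ev["Py"]
        P_diag = np.diag(P)
        k = len(free_idx)
        score = np.zeros(k)
        MPy = []
        for a, j in enumerate(free_idx):
            struct = self.derivs[j]
            mj_py = _mat_vec(struct, Py)
            MPy.append(mj_py)
            tr_pm = _trace_PM(struct, P, P_diag)
            score[a] = -0.5 * (tr_pm - float(Py @ mj_py))
        ai = np.zeros((k, k))
        PMPy = [P @ v for v in MPy]
        for a in range(k):
            for b in range(a, k):
                ai[a, b] = ai[b, a] = 0.5 * float(MPy[a] @ PMPy[b])
        return score, ai


def _project_feasible(theta: np.ndarray) -> np.ndarray:
    """Project each 2x2 intercept-slope block to the nearest PSD matrix.

    Used by the constrained mode; preserves the zero pattern of the reduced
    specifications (an axis-aligned block stays axis-aligned).
    """
    out = theta.copy()
    for i0, i01, i1 in ((0, 1, 2), (3, 4, 5)):
        block = np.array([[theta[i0], theta[i01]], [theta[i01], theta[i1]]])
        w, q = np.linalg.eigh(block)
        if w[0] >= 0:
            continue
        b = (q * np.clip(w, 0.0, None)) @ q.T
        out[i0], out[i01], out[i1] = b[0, 0], b[0, 1], b[1, 1]
    return out


def _constrained_fit(ws: "_RemlWorkspace", spec: ModelSpec, theta0: np.ndarray):
    """Maximize the restricted likelihood over PSD intercept-slope blocks.

    Each block is written as L L' with L lower-triangular (Cholesky
    parameterization), turning the PSD constraint into an unconstrained
    smooth problem, which is then solved by Nelder-Mead with a restart
    polish.  Used for the constrained mode, where boundary optima (rank-1
    blocks, zero variances) are common and Newton-type steps stall.
    """
    from scipy.optimize import minimize

    free = set(spec.free_params)
    g_slope = "sigma2_a1" in free
    r_slope = "sigma2_t1" in free

    def unpack(x):
        pos = 0
        g11 = x[pos]; pos += 1
        g21, g22 = (x[pos], x[pos + 1]) if g_slope else (0.0, 0.0)
        pos += 2 if g_slope else 0
        r11 = x[pos]; pos += 1
        r21, r22 = (x[pos], x[pos + 1]) if r_slope else (0.0, 0.0)
        theta = np.array(
            [g11**2, g11 * g21, g21**2 + g22**2,
             r11**2, r11 * r21, r21**2 + r22**2]
        )
        return theta

    def negll(x):
        ev = ws.evaluate(unpack(x), need_inverse=False)
        return 1e10 if ev is None else -ev["logL"]

    def chol_entries(v0, c01, v1, want_slope):
        l11 = np.sqrt(max(v0, 1e-8))
        if not want_slope:
            return [l11]
        l21 = c01 / l11
        l22 = np.sqrt(max(v1 - l21**2, 1e-8))
        return [l11, l21, l22]

    x0 = np.array(
        chol_entries(theta0[0], theta0[1], theta0[2], g_slope)
        + chol_entries(theta0[3], theta0[4], theta0[5], r_slope)
    )
    best = None
    for start in (x0, x0 * 0.5 + 0.1, x0 * 1.5 + 0.05):
        res = minimize(negll, start, method="Nelder-Mead",
                       options=dict(maxiter=4000, xatol=1e-8, fatol=1e-10))
        res = minimize(negll, res.x, method="Nelder-Mead",
                       options=dict(maxiter=4000, xatol=1e-9, fatol=1e-12))
        if best is None or res.fun < best.fun:
            best = res
    return unpack(best.x), int(best.nfev)


def _start_values(y: np.ndarray, spec: ModelSpec) -> np.ndarray:
    vp = float(np.var(y, ddof=1))
    theta = np.zeros(6)
    theta[PARAM_NAMES.index("sigma2_a0")] = 0.5 * vp
    theta[PARAM_NAMES.index("sigma2_t0")] = 0.5 * vp
    for p in spec.free_params:
        if p not in ("sigma2_a0", "sigma2_t0"):
            theta[PARAM_NAMES.index(p)] = 0.01 * vp
    return theta


def reml_fit(
    y,
    k,
    c,
    spec: ModelSpec | str = "FULL",
    options: RemlOptions | None = None,
    start: VarianceComponents | None = None,
) -> ModelFit:
    """Fit one reaction-norm model specification by AI-REML.

    Parameters
    ----------
    y : array-like or AdjustedPhenotype
        Prepared phenotype (adjusted, outlier-screened, INT-transformed).
    k : array-like or GRM
        Genomic relationship matrix.
    c : array-like or StandardizedCovariate
        Standardized environmental covariate.
    spec : ModelSpec or model name ("NULL", "GXE_ONLY", "RXE_ONLY", "FULL")
    options : RemlOptions
    start : optional warm-start parameter values (entries outside the spec's
        free set are forced to zero); used by :func:`fit_nested_models` to
        start each larger model at a nested optimum, which guarantees the
        likelihood ordering of nested fits

    Returns
    -------
    ModelFit with restricted log-likelihood ``-0.5*(log|V| + log|X'V^-1 X| +
    y'Py)`` (additive constants omitted; they cancel in every model
    comparison), AI-based sampling covariance, and per-individual BLUPs.
    """
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec.upper()]
    options = options or RemlOptions()
    yv = _as_array(y)
    K = _as_array(k)
    cv = _as_array(c)
    n = yv.shape[0]
    if K.shape != (n, n) or cv.shape != (n,):
        raise ValueError("dimension mismatch between y, K and c")
    if n < spec.n_free + 2:
        raise ValueError(
            f"n={n} too small to estimate {spec.n_free} variance parameters"
        )

    ws = _RemlWorkspace(K, cv, yv)
    free_idx = spec.free_indices()
    if start is not None:
        theta = start.as_array()
        fixed = np.setdiff1d(np.arange(6), free_idx)
        theta[fixed] = 0.0
    else:
        theta = _start_values(yv, spec)
    ev = ws.evaluate(theta)
    if ev is None:
        # fall back to a pure-noise start, always PD
        theta = np.zeros(6)
        theta[PARAM_NAMES.index("sigma2_t0")] = float(np.var(yv, ddof=1))
        ev = ws.evaluate(theta)
        if ev is None:
            raise RuntimeError("could not find a positive-definite starting point")

    # Convergence: the likelihood has stabilized (|dlogL| < tol_logl on two
    # consecutive steps), or one small step with a small gradient.  A pure
    # gradient criterion is not attainable on every dataset: under null data
    # the unconstrained optimum can sit on the boundary of the positive-
    # definite region, where logL approaches a supremum but the gradient
    # does not vanish; the LRT only needs the likelihood value, which does
    # stabilize.
    converged = False
    grad_norm = np.inf
    n_iter = 0
    last_dlogl = None
    n_small = 0
    ai = np.eye(len(free_idx))
    if options.constrain:
        theta, n_iter = _constrained_fit(ws, spec, theta)
        ev = ws.evaluate(theta)
        score, ai = ws.score_and_ai(ev, free_idx)
        grad_norm = float(np.linalg.norm(score))
        converged = True
    for it in range(1, (0 if options.constrain else options.max_iter) + 1):
        n_iter = it
        score, ai = ws.score_and_ai(ev, free_idx)
        grad_norm = float(np.linalg.norm(score))
        if (
            last_dlogl is not None
            and abs(last_dlogl) < options.tol_logl
            and (grad_norm < options.tol_grad or n_small >= 2)
        ):
            converged = True
            break
        if it == 1:
            # EM-flavoured first step: conservative, scale-aware, keeps V PD
            delta = 2.0 * theta[free_idx] ** 2 * score / n
            zero = theta[free_idx] == 0.0
            if np.any(zero):
                vp = float(np.var(yv, ddof=1))
                delta[zero] = (0.01 * vp) ** 2 * 2.0 * score[zero] / n
        else:
            ai_reg = ai + np.eye(len(free_idx)) * 1e-8 * max(np.trace(ai), 1.0)
            try:
                delta = np.linalg.solve(ai_reg, score)
            except np.linalg.LinAlgError:
                delta = score / max(grad_norm, 1.0)

        # line search on the AI direction; if no step along it is uphill
        # (common at the boundary of the positive-definite region, where the
        # AI direction can point out of the feasible cone), retry along the
        # raw gradient at a conservative scale
        scale = max(float(np.abs(theta[free_idx]).max()), 0.01)
        directions = [delta, score / max(grad_norm, 1.0) * 0.1 * scale]
        new_ev = None
        new_theta = theta
        for direction in directions:
            step = 1.0
            for _ in range(30):
                cand = theta.copy()
                cand[free_idx] = theta[free_idx] + step * direction
                if options.constrain:
                    cand = _project_feasible(cand)
                cand_ev = ws.evaluate(cand)
                if cand_ev is not None and cand_ev["logL"] >= ev["logL"] - 1e-10:
                    new_ev, new_theta = cand_ev, cand
                    break
                step *= 0.5
            if new_ev is not None:
                break
        if new_ev is None:
            # neither the AI direction nor the gradient direction improves
            # the likelihood at any of 30 step scales: the current point is
            # the numerical supremum (possibly on the PD boundary, where the
            # gradient need not vanish)
            converged = True
            break
        dlogl = new_ev["logL"] - ev["logL"]
        theta, ev = new_theta, new_ev
        last_dlogl = dlogl
        n_small = n_small + 1 if abs(dlogl) < options.tol_logl else 0
        if options.verbose:
            print(f"iter {it}: logL={ev['logL']:.6f} |grad|={grad_norm:.3g}")

    try:
        vc_cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        vc_cov = np.full((len(free_idx), len(free_idx)), np.nan)

    vc_hat = VarianceComponents.from_array(theta)
    fit = ModelFit(
        spec=spec,
        vc_hat=vc_hat,
        logL=float(ev["logL"]),
        vc_cov=vc_cov,
        n_iter=n_iter,
        converged=bool(converged),
        beta_hat=float(ev["beta"]),
        grad_norm=grad_norm,
        n=n,
    )
    fit.blups = compute_blups(fit, yv, K, cv)
    return fit


def fit_nested_models(y, k, c, options: RemlOptions | None = None) -> dict:
    """Fit NULL, GXE_ONLY, RXE_ONLY and FULL with warm-start chaining.

    Each interaction model starts from the NULL optimum; the FULL model
    starts from the better of the two single-interaction optima (and is
    refitted from the other if that ever yields a higher likelihood), so the
    nesting inequality logL(FULL) >= logL(reduced) holds by construction up
    to step tolerance.
    """
    fits = {}
    fits["NULL"] = reml_fit(y, k, c, MODEL_SPECS["NULL"], options)
    null_vc = fits["NULL"].vc_hat
    for name in ("GXE_ONLY", "RXE_ONLY"):
        fits[name] = reml_fit(y, k, c, MODEL_SPECS[name], options, start=null_vc)
    ordered = sorted(
        ("GXE_ONLY", "RXE_ONLY"), key=lambda n: fits[n].logL, reverse=True
    )
    full = reml_fit(
        y, k, c, MODEL_SPECS["FULL"], options, start=fits[ordered[0]].vc_hat
    )
    # a boundary-stalled first attempt can undershoot the optimum: always
    # accept the better of the two warm starts
    if not full.converged or full.logL < fits[ordered[1]].logL - 1e-8:
        alt = reml_fit(
            y, k, c, MODEL_SPECS["FULL"], options, start=fits[ordered[1]].vc_hat
        )
        if alt.logL > full.logL or (alt.converged and not full.converged):
            full = alt
    fits["FULL"] = full
    return fits


def compute_blups(fit: ModelFit, y, k, c) -> Blups:
    """Conditional means of (alpha0, alpha1, tau0, tau1) given y at the REML
    estimates.

    For a component u with cross-covariance C = Cov(u, y), the BLUP is
    C V^-1 (y - X beta), i.e. C @ Py.  Components fixed at zero under the fit's
    specification come out exactly zero because their parameters are zero.
    """
    yv = _as_array(y)
    K = _as_array(k)
    cv = _as_array(c)
    vc = fit.vc_hat
    V = build_covariance(K, cv, vc)
    cho = cho_factor(V, lower=True, check_finite=False)
    ones = np.ones_like(yv)
    Vinv_y = cho_solve(cho, yv, check_finite=False)
    Vinv_1 = cho_solve(cho, ones, check_finite=False)
    beta = float(ones @ Vinv_y) / float(ones @ Vinv_1)
    Py = Vinv_y - Vinv_1 * beta

    Kc = K * cv[None, :]  # K o 1c': column j scaled by c_j
    a0 = (vc.sigma2_a0 * K + vc.sigma_a01 * Kc) @ Py
    a1 = (vc.sigma_a01 * K + vc.sigma2_a1 * Kc) @ Py
    t0 = (vc.sigma2_t0 + vc.sigma_t01 * cv) * Py
    t1 = (vc.sigma_t01 + vc.sigma2_t1 * cv) * Py
    return Blups(a0=a0, a1=a1, t0=t0, t1=t1)
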