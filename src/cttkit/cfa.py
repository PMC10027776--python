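"""Maximum-likelihood confirmatory factor analysis on covariance structures.

The measurement model is x = nu + Lambda f + eps with uncorrelated errors,
factor variances fixed to 1 (factor covariances free), and the implied
covariance Sigma = Lambda Phi Lambda' + Theta.  Three nested constraint
levels mirror the classical test-theory taxonomy:

* ``congeneric``      -- loadings, intercepts and unique variances all free;
* ``tau_equivalent``  -- equal loadings within each factor block;
* ``parallel``        -- equal loadings and equal unique variances.

Each level speaks to how a sum of the indicators behaves: any well-fitting
one-factor model justifies a sum score, but the constraint level dictates
which reliability formula applies (see :mod:`cttkit.reliability`).

Estimation minimizes the normal-theory discrepancy

    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p   (+ mean term if modeled)

with analytic gradients, log-parameterized unique variances floored at 1e-6
(Heywood flagging), and deterministic jittered restarts.  Chi-square is
reported on the (n-1) * F_ML convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .composites import ItemMatrix
from .errors import (
    ConvergenceError,
    DimensionError,
    InputError,
    NotApplicableError,
    NumericError,
)

__all__ = [
    "SampleMoments",
    "FactorModelSpec",
    "FittedFactorModel",
    "FitIndexSet",
    "fit_cfa",
    "spearman_three_indicator",
    "fit_indices",
    "factor_scores_regression",
    "model_implied_cov",
]

THETA_FLOOR = 1e-6
GRAD_TOL = 1e-8
N_RESTARTS = 10

CONSTRAINTS = ("parallel", "tau_equivalent", "congeneric")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SampleMoments:
    """Sample covariance matrix (plus optional means and n) for p variables."""

    cov: np.ndarray
    labels: list[str] = None
    means: np.ndarray = None
    n: int = None

    def __post_init__(self):
        if isinstance(self.cov, pd.DataFrame):
            if self.labels is None:
                self.labels = [str(c) for c in self.cov.columns]
            self.cov = self.cov.to_numpy(dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.ndim != 2 or self.cov.shape[0] != self.cov.shape[1]:
            raise InputError("covariance matrix must be square")
        p = self.cov.shape[0]
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise InputError("covariance matrix asymmetric beyond 1e-8")
        self.cov = (self.cov + self.cov.T) / 2.0
        if self.labels is None:
            self.labels = [f"v{j + 1}" for j in range(p)]
        self.labels = [str(c) for c in self.labels]
        if len(self.labels) != p:
            raise DimensionError("label count does not match matrix order")
        eigmin = float(np.linalg.eigvalsh(self.cov).min())
        if eigmin <= 1e-12 * max(1.0, float(np.abs(self.cov).max())):
            raise InputError(
                f"covariance matrix is not positive definite (min eigenvalue {eigmin:.3g})"
            )
        if self.means is not None:
            self.means = np.asarray(self.means, dtype=float).ravel()
            if self.means.size != p:
                raise DimensionError("means length does not match matrix order")
        if self.n is not None:
            self.n = int(self.n)

    @property
    def p(self) -> int:
        return self.cov.shape[0]

    @classmethod
    def from_items(cls, items: ItemMatrix) -> "SampleMoments":
        if isinstance(items, pd.DataFrame):
            items = ItemMatrix.from_dataframe(items)
        if items.missing_mask.any():
            raise InputError("missing cells; moments require complete data")
        x = items.values
        return cls(
            cov=np.cov(x, rowvar=False, ddof=1),
            labels=list(items.item_labels),
            means=x.mean(axis=0),
            n=items.n_persons,
        )


@dataclass
class FactorModelSpec:
    """Simple-structure pattern: every item loads on exactly one factor.

    ``pattern`` maps item label -> factor label; ``constraint`` is one of
    ``parallel``, ``tau_equivalent``, ``congeneric``.  ``strict_means`` adds
    equal-intercept constraints within each factor block (only meaningful
    when sample means are supplied; without it the "essentially" variants
    are fitted).
    """

    pattern: dict
    constraint: str = "congeneric"
    strict_means: bool = False

    def __post_init__(self):
        if self.constraint not in CONSTRAINTS:
            raise InputError(
                f"constraint must be one of {CONSTRAINTS}, got {self.constraint!r}"
            )
        if not self.pattern:
            raise InputError("empty factor pattern")
        self.pattern = {str(k): str(v) for k, v in self.pattern.items()}

    @property
    def factor_labels(self) -> list[str]:
        seen = []
        for f in self.pattern.values():
            if f not in seen:
                seen.append(f)
        return seen

    @property
    def n_factors(self) -> int:
        return len(self.factor_labels)

    def resolve(self, labels: list[str]) -> np.ndarray:
        """Factor index of each item, ordered like ``labels``."""
        missing = [v for v in labels if v not in self.pattern]
        if missing:
            raise InputError(f"items missing from factor pattern: {missing}")
        fl = self.factor_labels
        idx = np.array([fl.index(self.pattern[v]) for v in labels], dtype=int)
        counts = np.bincount(idx, minlength=len(fl))
        if (counts < 1).any():
            raise InputError("every factor needs at least one item")
        if len(fl) == 1 and self.constraint == "congeneric" and counts[0] < 3:
            raise InputError(
                "a single congeneric factor needs at least 3 indicators for identification"
            )
        return idx


@dataclass
class FittedFactorModel:
    """ML estimates: loadings, unique variances, factor correlations."""

    lam: np.ndarray          # p x k loading matrix
    theta: np.ndarray        # length-p unique variances
    phi: np.ndarray          # k x k factor covariance, unit diagonal
    nu: np.ndarray           # optional intercepts (None if no mean structure)
    discrepancy: float       # F_ML at the optimum
    converged: bool
    n_iterations: int
    n_free: int
    labels: list[str] = None
    factor_labels: list[str] = None
    spec: FactorModelSpec = None
    warnings: list = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.lam.shape[0]

    @property
    def k(self) -> int:
        return self.lam.shape[1]


@dataclass
class FitIndexSet:
    """chi-square test and practical fit indices for one fitted model."""

    chisq: float
    df: int
    p_value: float
    rmsea: float
    rmsea_ci90: tuple
    cfi: float
    tli: float
    srmr: float


# ---------------------------------------------------------------------------
# Parameterization
# ---------------------------------------------------------------------------

class _ParamMap:
    """Maps the free-parameter vector onto (Lambda, Theta, Phi, nu).

    Loadings and log unique variances are tied within factor blocks
    according to the constraint level; factor correlations are atanh-
    parameterized; intercepts (if modeled) are free or tied per block.
    """

    def __init__(self, spec: FactorModelSpec, labels, with_means: bool):
        self.spec = spec
        self.labels = list(labels)
        self.fidx = spec.resolve(self.labels)
        self.p = len(self.labels)
        self.k = spec.n_factors
        self.with_means = with_means

        tie = spec.constraint in ("tau_equivalent", "parallel")
        # loading parameter index per item
        self.load_slot = self.fidx.copy() if tie else np.arange(self.p)
        self.n_load = self.k if tie else self.p
        tie_theta = spec.constraint == "parallel"
        self.theta_slot = self.fidx.copy() if tie_theta else np.arange(self.p)
        self.n_theta = self.k if tie_theta else self.p
        self.n_phi = self.k * (self.k - 1) // 2
        self.phi_rows, self.phi_cols = np.triu_indices(self.k, 1)
        if with_means:
            tie_nu = spec.strict_means
            self.nu_slot = self.fidx.copy() if tie_nu else np.arange(self.p)
            self.n_nu = self.k if tie_nu else self.p
        else:
            self.nu_slot = None
            self.n_nu = 0
        self.n_free = self.n_load + self.n_theta + self.n_phi + self.n_nu

    def split(self, x):
        i = 0
        load = x[i:i + self.n_load]; i += self.n_load
        ltheta = x[i:i + self.n_theta]; i += self.n_theta
        zphi = x[i:i + self.n_phi]; i += self.n_phi
        nu = x[i:i + self.n_nu]
        return load, ltheta, zphi, nu

    def unpack(self, x):
        load, ltheta, zphi, nu_par = self.split(x)
        lam = np.zeros((self.p, self.k))
        lam[np.arange(self.p), self.fidx] = load[self.load_slot]
        theta = np.exp(ltheta[self.theta_slot]) + THETA_FLOOR
        phi = np.eye(self.k)
        if self.n_phi:
            r = np.tanh(zphi)
            phi[self.phi_rows, self.phi_cols] = r
            phi[self.phi_cols, self.phi_rows] = r
        nu = nu_par[self.nu_slot] if self.with_means else None
        return lam, theta, phi, nu

    def pack(self, lam_item, ltheta_item, phi, nu_item=None):
        """Build a start vector from per-item quantities (ties averaged)."""
        def collapse(vals, slot, n):
            out = np.zeros(n)
            for s in range(n):
                out[s] = np.mean(vals[slot == s])
            return out

        x = [collapse(np.asarray(lam_item, float), self.load_slot, self.n_load),
             collapse(np.asarray(ltheta_item, float), self.theta_slot, self.n_theta)]
        if self.n_phi:
            r = np.clip(phi[self.phi_rows, self.phi_cols], -0.95, 0.95)
            x.append(np.arctanh(r))
        else:
            x.append(np.zeros(0))
        if self.with_means:
            x.append(collapse(np.asarray(nu_item, float), self.nu_slot, self.n_nu))
        return np.concatenate(x)


def _fml_and_grad(x, pm: _ParamMap, S, lndetS, xbar):
    lam, theta, phi, nu = pm.unpack(x)
    p = pm.p
    sigma = lam @ phi @ lam.T + np.diag(theta)
    sign, lndet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e12, np.zeros_like(x)
    try:
        siginv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        return 1e12, np.zeros_like(x)

    f = lndet + float(np.sum(siginv * S)) - lndetS - p
    d = None
    if pm.with_means:
        d = xbar - nu
        f += float(d @ siginv @ d)

    # dF/dSigma = Sigma^-1 (Sigma - S - dd') Sigma^-1
    resid = sigma - S
    if d is not None:
        resid = resid - np.outer(d, d)
    M = siginv @ resid @ siginv

    g_lam_full = 2.0 * (M @ lam @ phi)                 # p x k
    g_load_item = g_lam_full[np.arange(p), pm.fidx]    # per item
    g_load = np.zeros(pm.n_load)
    np.add.at(g_load, pm.load_slot, g_load_item)

    g_ltheta_item = np.diag(M) * (theta - THETA_FLOOR)
    g_ltheta = np.zeros(pm.n_theta)
    np.add.at(g_ltheta, pm.theta_slot, g_ltheta_item)

    parts = [g_load, g_ltheta]
    if pm.n_phi:
        lml = lam.T @ M @ lam
        _, _, zphi, _ = pm.split(x)
        g_z = 2.0 * lml[pm.phi_rows, pm.phi_cols] * (1.0 - np.tanh(zphi) ** 2)
        parts.append(g_z)
    else:
        parts.append(np.zeros(0))
    if pm.with_means:
        g_nu_item = -2.0 * (siginv @ d)
        g_nu = np.zeros(pm.n_nu)
        np.add.at(g_nu, pm.nu_slot, g_nu_item)
        parts.append(g_nu)
    return f, np.concatenate(parts)


def _start_values(pm: _ParamMap, S, xbar):
    p = pm.p
    var = np.diag(S)
    lam0 = np.empty(p)
    for g in range(pm.k):
        block = np.where(pm.fidx == g)[0]
        if block.size >= 2:
            off = S[np.ix_(block, block)].copy()
            np.fill_diagonal(off, np.nan)
            m = np.nanmean(off)
        else:
            m = np.nan
        base = np.sqrt(m) if np.isfinite(m) and m > 0 else None
        for j in block:
            lam0[j] = base if base is not None else 0.7 * np.sqrt(var[j])
    theta0 = np.maximum(var - lam0 ** 2, 0.1 * var)
    # start factor correlations at block-sum-score correlations
    phi0 = np.eye(pm.k)
    for a in range(pm.k):
        for b in range(a + 1, pm.k):
            ia, ib = pm.fidx == a, pm.fidx == b
            ca = float(np.ones(ia.sum()) @ S[np.ix_(ia, ia)] @ np.ones(ia.sum()))
            cb = float(np.ones(ib.sum()) @ S[np.ix_(ib, ib)] @ np.ones(ib.sum()))
            cab = float(np.ones(ia.sum()) @ S[np.ix_(ia, ib)] @ np.ones(ib.sum()))
            phi0[a, b] = phi0[b, a] = np.clip(cab / np.sqrt(ca * cb), -0.9, 0.9)
    return pm.pack(lam0, np.log(theta0), phi0,
                   xbar if pm.with_means else None)


def fit_cfa(moments: SampleMoments, spec: FactorModelSpec,
            n_restarts: int = N_RESTARTS) -> FittedFactorModel:
    """Fit the constrained single- or multi-factor model by ML.

    Factor variances are fixed at 1 (covariances free); a mean structure is
    fitted only when ``moments.means`` is supplied.  Deterministic jittered
    restarts guard against local minima; non-convergence after all restarts
    raises :class:`ConvergenceError` carrying the best state found.
    """
    if isinstance(moments, (pd.DataFrame, np.ndarray)):
        moments = SampleMoments(moments)
    with_means = moments.means is not None
    pm = _ParamMap(spec, moments.labels, with_means)
    S = moments.cov
    sign, lndetS = np.linalg.slogdet(S)
    if sign <= 0:
        raise InputError("sample covariance matrix is not positive definite")
    xbar = moments.means if with_means else None

    x0 = _start_values(pm, S, xbar)
    best = None
    for attempt in range(max(1, n_restarts)):
        if attempt == 0:
            xs = x0
        else:
            jitter_rng = np.random.default_rng(attempt)  # deterministic restarts
            xs = x0 + jitter_rng.normal(scale=0.2 * (1 + np.abs(x0)))
        res = optimize.minimize(
            _fml_and_grad, xs, args=(pm, S, lndetS, xbar),
            method="L-BFGS-B", jac=True,
            options={"maxiter": 5000, "ftol": 1e-15, "gtol": GRAD_TOL},
        )
        gnorm = float(np.max(np.abs(res.jac)))
        ok = res.fun < 1e11 and (res.success or gnorm < 1e-6)
        if best is None or res.fun < best[0].fun:
            best = (res, ok)
        if ok and attempt == 0:
            break
        if ok and best[0].fun <= res.fun + 1e-10:
            break

    res, ok = best
    lam, theta, phi, nu = pm.unpack(res.x)

    # fix factor orientation: first loading of each block positive
    for g in range(pm.k):
        first = int(np.where(pm.fidx == g)[0][0])
        if lam[first, g] < 0:
            lam[:, g] *= -1.0
            phi[g, :] *= -1.0
            phi[:, g] *= -1.0
            np.fill_diagonal(phi, 1.0)

    warns = []
    heywood = theta <= THETA_FLOOR * 10
    if heywood.any():
        bad = [moments.labels[j] for j in np.where(heywood)[0]]
        warns.append(f"Heywood case: unique variance at floor for {bad}")

    fitted = FittedFactorModel(
        lam=lam, theta=theta, phi=phi, nu=nu,
        discrepancy=float(res.fun), converged=bool(ok),
        n_iterations=int(res.nit), n_free=pm.n_free,
        labels=list(moments.labels), factor_labels=spec.factor_labels,
        spec=spec, warnings=warns,
    )
    if not ok:
        raise ConvergenceError(
            f"CFA did not converge after {n_restarts} restarts "
            f"(best F_ML = {res.fun:.6g})", best_state=fitted)
    return fitted


# ---------------------------------------------------------------------------
# Closed form for the just-identified 3-indicator model
# ---------------------------------------------------------------------------

def spearman_three_indicator(cov3) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form loadings/uniques for a 1-factor model on 3 indicators.

    With three indicators the congeneric model is just identified, and the
    tetrad-style solution lambda_1 = sqrt(c12*c13/c23) (cyclically) exactly
    reproduces the off-diagonal covariances.  Requires all three covariances
    strictly positive (the sign-indeterminate case is rejected).
    """
    if isinstance(cov3, pd.DataFrame):
        cov3 = cov3.to_numpy(dtype=float)
    c = np.asarray(cov3, dtype=float)
    if c.shape != (3, 3):
        raise DimensionError("spearman_three_indicator needs a 3x3 matrix")
    if not np.allclose(c, c.T, atol=1e-8):
        raise InputError("covariance matrix is not symmetric")
    c12, c13, c23 = c[0, 1], c[0, 2], c[1, 2]
    if min(c12, c13, c23) <= 0:
        raise NotApplicableError(
            "closed form needs strictly positive covariances (sign-indeterminate otherwise)"
        )
    lam = np.array([
        np.sqrt(c12 * c13 / c23),
        np.sqrt(c12 * c23 / c13),
        np.sqrt(c13 * c23 / c12),
    ])
    uniq = np.diag(c) - lam ** 2
    return lam, uniq


# ---------------------------------------------------------------------------
# Fit indices
# ---------------------------------------------------------------------------

def _ncp_search(target_prob, chisq, df, hi0=1.0, tol=1e-6):
    """Noncentrality lambda with ncx2.cdf(chisq, df, lambda) = target_prob."""
    if stats.chi2.cdf(chisq, df) < target_prob:
        return 0.0
    lo, hi = 0.0, hi0
    while stats.ncx2.cdf(chisq, df, hi) > target_prob:
        hi *= 2.0
        if hi > 1e8:
            break
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if stats.ncx2.cdf(chisq, df, mid) > target_prob:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def model_df(fitted: FittedFactorModel) -> int:
    p = fitted.p
    n_stats = p * (p + 1) // 2 + (p if fitted.nu is not None else 0)
    return n_stats - fitted.n_free


def fit_indices(fitted: FittedFactorModel, moments: SampleMoments,
                srmr_include_diagonal: bool = True) -> FitIndexSet:
    """Chi-square ((n-1) * F_ML), RMSEA with 90% CI, CFI, TLI, SRMR.

    The RMSEA interval inverts the noncentral chi-square distribution by
    bisection; CFI/TLI use the independence (diagonal-Sigma) baseline; SRMR
    averages squared correlation-metric residuals, by default including the
    diagonal terms (set ``srmr_include_diagonal=False`` for the
    off-diagonal-only dialect).
    """
    if moments.n is None:
        raise InputError("fit indices require the sample size n")
    if not fitted.converged:
        raise InputError("fit indices require a converged model")
    n, p = moments.n, fitted.p
    df = model_df(fitted)
    S = moments.cov
    sigma = model_implied_cov(fitted)

    sd = np.sqrt(np.diag(S))
    resid = (S - sigma) / np.outer(sd, sd)
    if srmr_include_diagonal:
        iu = np.triu_indices(p)
    else:
        iu = np.triu_indices(p, 1)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))

    if df <= 0:
        return FitIndexSet(chisq=0.0, df=0, p_value=1.0, rmsea=0.0,
                           rmsea_ci90=(0.0, 0.0), cfi=1.0, tli=1.0, srmr=srmr)

    chisq = (n - 1) * fitted.discrepancy
    p_value = float(stats.chi2.sf(chisq, df))
    rmsea = float(np.sqrt(max(0.0, chisq - df) / (df * (n - 1))))
    lam_lo = _ncp_search(0.95, chisq, df)
    lam_hi = _ncp_search(0.05, chisq, df)
    rmsea_ci = (float(np.sqrt(lam_lo / (df * (n - 1)))),
                float(np.sqrt(lam_hi / (df * (n - 1)))))

    # independence baseline: Sigma_b = diag(S)  =>  F_b = -ln|R|
    corr = S / np.outer(sd, sd)
    sign_r, lndet_r = np.linalg.slogdet(corr)
    f_base = -lndet_r if sign_r > 0 else np.inf
    chisq_b = (n - 1) * f_base
    df_b = p * (p - 1) // 2
    num = max(chisq - df, 0.0)
    den = max(chisq - df, chisq_b - df_b, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    if df_b > 0 and chisq_b / df_b > 1.0:
        tli = ((chisq_b / df_b) - (chisq / df)) / ((chisq_b / df_b) - 1.0)
    else:
        tli = 1.0
    return FitIndexSet(chisq=float(chisq), df=int(df), p_value=p_value,
                       rmsea=rmsea, rmsea_ci90=rmsea_ci,
                       cfi=float(cfi), tli=float(tli), srmr=srmr)


# ---------------------------------------------------------------------------
# Factor scores and implied moments
# ---------------------------------------------------------------------------

def regression_score_weights(fitted: FittedFactorModel, cov: np.ndarray) -> np.ndarray:
    """Regression-method scoring weights W = Phi Lambda' C^-1 (k x p)."""
    try:
        cinv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise NumericError("singular covariance matrix in factor scoring") from exc
    return fitted.phi @ fitted.lam.T @ cinv


def factor_scores_regression(
    fitted: FittedFactorModel, moments: SampleMoments, items: ItemMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Regression-method factor score estimates and their weight matrix.

    Weights W = Phi Lambda' S^-1 (from the analysis sample's covariance) are
    applied to the scoring sample's deviations from the *analysis* sample
    means, so a holdout sample can be scored with calibration weights.  When
    the scoring sample is the analysis sample, the scores have mean exactly
    zero per factor (the sample-specific centering built into estimated
    factor scores).
    """
    if isinstance(items, pd.DataFrame):
        items = ItemMatrix.from_dataframe(items)
    if items.n_items != fitted.p:
        raise DimensionError("item columns do not match the fitted model")
    if items.missing_mask.any():
        raise InputError("missing cells; factor scoring requires complete data")
    W = regression_score_weights(fitted, moments.cov)
    center = moments.means if moments.means is not None else items.values.mean(axis=0)
    scores = (items.values - center) @ W.T
    return scores, W


def model_implied_cov(fitted: FittedFactorModel) -> np.ndarray:
    """Implied covariance Sigma = Lambda Phi Lambda' + Theta (symmetric)."""
    sigma = fitted.lam @ fitted.phi @ fitted.lam.T + np.diag(fitted.theta)
    return (sigma + sigma.T) / 2.0
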