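"""Predicting composite or latent outcomes from a covariate, four ways.

Given a persons x items table, a block structure (items -> composite/factor),
and a predictor z (typically a 0/1 group code), the module implements the
four scoring-and-regression strategies commonly contrasted in the sum-score
debate:

* Method 1 -- regress the unit-weight sum of *all* items on z;
* Method 2 -- regress the unit-weight sum of each block on z;
* Method 3 -- factor-score regression with the Croon method-of-moments
  correction: fit a congeneric measurement model per block, score with
  regression weights, then correct the score covariance for the bias that
  measurement error and score shrinkage induce;
* Method 4 -- simultaneous ML estimation of measurement and structural
  parts (latent outcomes regressed on an error-free, single-indicator z).

Methods 1 and 2 share one entry point (`method_sum_regression`); blocks are
just composites.  Every result reports the raw slope B with SE and 95% CI,
the outcome-standardized slope d = B / SD(outcome), and the fully
standardized slope beta = d * SD(z).  Latent outcomes are identified by
fixing their model-implied *total* variance to 1, so for Methods 3 and 4
d equals B and beta equals the model-implied correlation of the factor
with z.  Method 3 SEs come from a seeded nonparametric bootstrap over
persons; Method 4 SEs from the inverse observed information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cfa import (
    FactorModelSpec,
    SampleMoments,
    fit_cfa,
    spearman_three_indicator,
)
from .composites import ItemMatrix
from .errors import ConvergenceError, DimensionError, InputError, NumericError

__all__ = [
    "GroupPredictor",
    "OutcomeEffect",
    "StructuralResult",
    "method_sum_regression",
    "croon_factor_score_regression",
    "simultaneous_latent_regression",
]


@dataclass
class GroupPredictor:
    """Per-person predictor codes (0/1 group membership or general numeric)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise InputError("predictor contains non-finite values")
        if np.ptp(self.values) == 0:
            raise InputError("predictor is constant")

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))

    def __len__(self) -> int:
        return self.values.size


@dataclass
class OutcomeEffect:
    """Raw and standardized slope of one outcome on the predictor."""

    B: float
    se: float
    ci95: tuple
    d: float
    beta: float


@dataclass
class StructuralResult:
    """Per-outcome effects for one of the four methods."""

    method: int
    outcomes: dict  # outcome label -> OutcomeEffect
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "outcomes": {
                k: {"B": v.B, "se": v.se, "ci95": list(v.ci95),
                    "d": v.d, "beta": v.beta}
                for k, v in self.outcomes.items()
            },
            "warnings": list(self.warnings),
        }


def _prepare(items, blocks, z):
    if isinstance(items, pd.DataFrame):
        items = ItemMatrix.from_dataframe(items)
    if items.missing_mask.any():
        raise InputError("missing cells; structural methods require complete data")
    if not isinstance(z, GroupPredictor):
        z = GroupPredictor(z)
    if len(z) != items.n_persons:
        raise DimensionError("predictor length does not match item rows")
    blocks = {str(k): str(v) for k, v in blocks.items()}
    missing = [v for v in items.item_labels if v not in blocks]
    if missing:
        raise InputError(f"items missing from block mapping: {missing}")
    order = []
    for lbl in items.item_labels:
        if blocks[lbl] not in order:
            order.append(blocks[lbl])
    members = {b: [i for i, lbl in enumerate(items.item_labels) if blocks[lbl] == b]
               for b in order}
    return items, blocks, z, order, members


# ---------------------------------------------------------------------------
# Methods 1 and 2: sum-score regression
# ---------------------------------------------------------------------------

def method_sum_regression(items, blocks, z) -> StructuralResult:
    """OLS of each unit-weight block composite on the predictor.

    A single block covering all items gives Method 1; one block per scale
    gives Method 2.  d standardizes B by the composite's sample SD, beta
    additionally multiplies by the sample SD of z (both n-1 formulas).
    """
    import statsmodels.api as sm

    items, blocks, z, order, members = _prepare(items, blocks, z)
    zv = z.values
    design = sm.add_constant(zv)
    outcomes = {}
    for b in order:
        y = items.values[:, members[b]].sum(axis=1)
        fit = sm.OLS(y, design).fit()
        B = float(fit.params[1])
        se = float(fit.bse[1])
        lo, hi = fit.conf_int(alpha=0.05)[1]
        sd_y = float(y.std(ddof=1))
        if sd_y == 0:
            raise InputError(f"composite '{b}' is constant")
        outcomes[b] = OutcomeEffect(
            B=B, se=se, ci95=(float(lo), float(hi)),
            d=B / sd_y, beta=B / sd_y * z.sd,
        )
    method = 1 if len(order) == 1 else 2
    return StructuralResult(method=method, outcomes=outcomes)


# ---------------------------------------------------------------------------
# Method 3: Croon-corrected factor-score regression
# ---------------------------------------------------------------------------

def _fit_block_measurement(cov_block, labels):
    """Congeneric loadings/uniques for one block (closed form when 3x3)."""
    c = np.asarray(cov_block, dtype=float)
    if c.shape[0] == 3 and min(c[0, 1], c[0, 2], c[1, 2]) > 0:
        return spearman_three_indicator(c)
    spec = FactorModelSpec({v: "f" for v in labels})
    fit = fit_cfa(SampleMoments(c, labels=labels), spec, n_restarts=3)
    return fit.lam[:, 0], fit.theta


def _croon_point_estimates(x, zv, members, order):
    """Corrected slope, factor SD and naive slope per block."""
    out = {}
    var_z = float(zv.var(ddof=1))
    for b in order:
        idx = members[b]
        xb = x[:, idx]
        S = np.cov(xb, rowvar=False, ddof=1)
        lam, theta = _fit_block_measurement(S, [str(i) for i in idx])
        sigma = np.outer(lam, lam) + np.diag(np.clip(theta, 0, None))
        W = lam @ np.linalg.inv(sigma)          # 1 x p_b regression weights
        wl = float(W @ lam)
        if abs(wl) < 1e-12:
            raise NumericError("W Lambda singular in Croon correction")
        c_xz = np.array([np.cov(xb[:, j], zv, ddof=1)[0, 1]
                         for j in range(xb.shape[1])])
        fhat_var = float(W @ S @ W)
        naive_B = float(W @ c_xz) / var_z
        f_var = (fhat_var - float(W @ np.diag(np.clip(theta, 0, None)) @ W)) / wl ** 2
        if f_var <= 0:
            raise NumericError(
                f"Croon-corrected factor variance non-positive for block '{b}'"
            )
        f_cov_z = float(W @ c_xz) / wl
        out[b] = (f_cov_z / var_z, float(np.sqrt(f_var)), naive_B)
    return out


def croon_factor_score_regression(
    items, blocks, z, n_boot: int = 499, seed: int = None,
    return_naive: bool = False,
) -> StructuralResult:
    """Factor-score regression with the Croon method-of-moments correction.

    Per block, a congeneric measurement model supplies regression-method
    scoring weights W; the correction maps the moments of the estimated
    scores back to the latent metric: var(f) = (W S W' - W Theta W') / (W
    Lambda)^2 and cov(f, z) = W c_xz / (W Lambda).  The slope B = cov(f, z)
    / var(z) is then free of the attenuation that plain (naive) factor-score
    regression suffers.  SEs and percentile CIs come from a nonparametric
    bootstrap over persons (``n_boot`` resamples; a seed is required when
    n_boot > 0).  ``return_naive`` attaches the uncorrected slopes for
    comparison.
    """
    items, blocks, z, order, members = _prepare(items, blocks, z)
    for b in order:
        if len(members[b]) < 3:
            raise InputError(f"block '{b}' needs >= 3 items for identification")
    x, zv = items.values, z.values
    point = _croon_point_estimates(x, zv, members, order)

    boot = {b: [] for b in order}
    skipped = 0
    if n_boot > 0:
        if seed is None:
            raise InputError("bootstrap requires a seed")
        rng = np.random.default_rng(seed)
        n = x.shape[0]
        for _ in range(n_boot):
            take = rng.integers(0, n, size=n)
            if np.ptp(zv[take]) == 0:
                skipped += 1
                continue
            try:
                est = _croon_point_estimates(x[take], zv[take], members, order)
            except (NumericError, ConvergenceError, InputError):
                skipped += 1
                continue
            for b in order:
                boot[b].append(est[b][0])

    outcomes = {}
    warnings = []
    if skipped:
        warnings.append(f"bootstrap: {skipped} of {n_boot} resamples skipped")
    for b in order:
        B, f_sd, _ = point[b]
        if len(boot[b]) >= 10:
            bs = np.asarray(boot[b])
            se = float(bs.std(ddof=1))
            lo, hi = (float(v) for v in np.percentile(bs, [2.5, 97.5]))
        else:
            se, lo, hi = float("nan"), float("nan"), float("nan")
        outcomes[b] = OutcomeEffect(B=B, se=se, ci95=(lo, hi),
                                    d=B / f_sd, beta=B / f_sd * z.sd)
    result = StructuralResult(method=3, outcomes=outcomes, warnings=warnings)
    if return_naive:
        result.naive_B = {b: point[b][2] for b in order}
    return result


# ---------------------------------------------------------------------------
# Method 4: simultaneous latent-variable regression
# ---------------------------------------------------------------------------

class _JointModel:
    """Joint covariance model for (items, z): x = Lambda f + eps, f = gamma z + zeta.

    z is an observed, error-free single-indicator variable with its variance
    fixed at the sample value.  Each latent outcome is identified by fixing
    its model-implied total variance to 1 (gamma_g = sin(t_g)/sd_z keeps the
    residual variance cos^2(t_g) positive); residual covariances between the
    zetas are free via atanh parameters.
    """

    def __init__(self, members, order, var_z):
        self.order = order
        self.members = members
        self.var_z = var_z
        self.k = len(order)
        self.p = sum(len(members[b]) for b in order)
        self.fidx = np.zeros(self.p, dtype=int)
        for g, b in enumerate(order):
            self.fidx[members[b]] = g
        self.rows, self.cols = np.triu_indices(self.k, 1)
        self.n_par = 2 * self.p + self.k + len(self.rows)

    def unpack(self, x):
        p, k = self.p, self.k
        lam_v = x[:p]
        theta = np.exp(x[p:2 * p]) + 1e-6
        t = x[2 * p:2 * p + k]
        u = x[2 * p + k:]
        gamma = np.sin(t) / np.sqrt(self.var_z)
        psi_d = np.cos(t) ** 2
        psi = np.diag(psi_d)
        if len(self.rows):
            r = np.tanh(u)
            off = r * np.sqrt(psi_d[self.rows] * psi_d[self.cols])
            psi[self.rows, self.cols] = off
            psi[self.cols, self.rows] = off
        return lam_v, theta, gamma, psi

    def implied(self, x):
        lam_v, theta, gamma, psi = self.unpack(x)
        lam = np.zeros((self.p, self.k))
        lam[np.arange(self.p), self.fidx] = lam_v
        phi_f = np.outer(gamma, gamma) * self.var_z + psi
        top = lam @ phi_f @ lam.T + np.diag(theta)
        cxz = lam @ gamma * self.var_z
        sigma = np.empty((self.p + 1, self.p + 1))
        sigma[:self.p, :self.p] = top
        sigma[:self.p, -1] = cxz
        sigma[-1, :self.p] = cxz
        sigma[-1, -1] = self.var_z
        return sigma

    def discrepancy(self, x, S, lndetS):
        sigma = self.implied(x)
        sign, lndet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e12
        try:
            siginv = np.linalg.inv(sigma)
        except np.linalg.LinAlgError:
            return 1e12
        return lndet + float(np.sum(siginv * S)) - lndetS - (self.p + 1)


def _numeric_hessian(fun, x0, h=1e-4):
    n = x0.size
    H = np.empty((n, n))
    hi = h * (1.0 + np.abs(x0))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = hi[i]
            ej = np.zeros(n); ej[j] = hi[j]
            fpp = fun(x0 + ei + ej)
            fpm = fun(x0 + ei - ej)
            fmp = fun(x0 - ei + ej)
            fmm = fun(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hi[i] * hi[j])
    return H


def simultaneous_latent_regression(items, blocks, z) -> StructuralResult:
    """Joint ML fit of measurement model plus latent regression on z.

    Because each latent outcome's total variance is fixed at 1, the raw
    slope B equals d, and beta = B * SD(z) is the model-implied correlation
    of the factor with z.  SEs come from the inverse observed information
    (numerical Hessian of the discrepancy scaled by (n-1)/2), with the delta
    method mapping to the reported slope.
    """
    items, blocks, z, order, members = _prepare(items, blocks, z)
    for b in order:
        if len(members[b]) < 3:
            raise InputError(f"block '{b}' needs >= 3 items for identification")
    x, zv = items.values, z.values
    n = x.shape[0]
    joint = np.column_stack([x, zv])
    S = np.cov(joint, rowvar=False, ddof=1)
    sign, lndetS = np.linalg.slogdet(S)
    if sign <= 0:
        raise InputError("joint sample covariance is singular")
    var_z = S[-1, -1]
    jm = _JointModel(members, order, var_z)

    # start at per-block measurement estimates + naive factor-score slopes
    lam0 = np.empty(jm.p)
    ltheta0 = np.empty(jm.p)
    t0 = np.empty(jm.k)
    fhat = np.empty((n, jm.k))
    for g, b in enumerate(order):
        idx = members[b]
        Sb = S[np.ix_(idx, idx)]
        lam_b, theta_b = _fit_block_measurement(Sb, [str(i) for i in idx])
        lam0[idx] = lam_b
        ltheta0[idx] = np.log(np.clip(theta_b, 1e-4, None))
        W = lam_b @ np.linalg.inv(np.outer(lam_b, lam_b)
                                  + np.diag(np.clip(theta_b, 1e-8, None)))
        fhat[:, g] = (x[:, idx] - x[:, idx].mean(axis=0)) @ W
        slope = float(np.cov(fhat[:, g], zv, ddof=1)[0, 1]) / var_z
        t0[g] = np.arcsin(np.clip(slope * np.sqrt(var_z), -0.9, 0.9))
    u0 = np.zeros(len(jm.rows))
    for m, (a, bb) in enumerate(zip(jm.rows, jm.cols)):
        r = float(np.corrcoef(fhat[:, a], fhat[:, bb])[0, 1])
        u0[m] = np.arctanh(np.clip(r, -0.9, 0.9))
    x0 = np.concatenate([lam0, ltheta0, t0, u0])

    obj = lambda par: jm.discrepancy(par, S, lndetS)
    best = None
    for attempt in range(5):
        xs = x0 if attempt == 0 else x0 + np.random.default_rng(attempt).normal(
            scale=0.1 * (1 + np.abs(x0)))
        res = optimize.minimize(obj, xs, method="L-BFGS-B",
                                options={"maxiter": 5000, "ftol": 1e-14})
        if best is None or res.fun < best.fun:
            best = res
        if res.fun < 1e11 and res.success:
            best = res if res.fun <= best.fun else best
            break
    res = best
    if res.fun >= 1e11:
        raise ConvergenceError(
            f"simultaneous latent regression failed (F = {res.fun:.3g})",
            best_state=res)

    lam_v, theta, gamma, psi = jm.unpack(res.x)
    H = _numeric_hessian(obj, res.x)
    info = 0.5 * (n - 1) * H
    try:
        cov_par = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov_par = np.linalg.pinv(info)

    sd_z = float(zv.std(ddof=1))
    outcomes = {}
    for g, b in enumerate(order):
        i_t = 2 * jm.p + g
        t_hat = res.x[i_t]
        B = float(np.sin(t_hat) / np.sqrt(var_z))
        dBdt = np.cos(t_hat) / np.sqrt(var_z)
        var_B = float(dBdt ** 2 * cov_par[i_t, i_t])
        se = float(np.sqrt(max(var_B, 0.0)))
        outcomes[b] = OutcomeEffect(
            B=B, se=se, ci95=(B - 1.959964 * se, B + 1.959964 * se),
            d=B, beta=B * sd_z,
        )
    warns = []
    if (theta <= 1e-5).any():
        warns.append("Heywood case: unique variance at floor in joint model")
    return StructuralResult(method=4, outcomes=outcomes, warnings=warns)
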