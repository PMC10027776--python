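"""Reliability estimators for sum scores and estimated factor scores.

All coefficients are ratios of true-score variance to total variance,
computed on the raw-score (covariance) metric:

* coefficient alpha        -- (p/(p-1)) * (1 - trace(C) / grand_sum(C));
* omega_total              -- (sum lambda)^2 / ((sum lambda)^2 + sum theta)
                              from a one-factor congeneric fit;
* factor-score reliability -- lambda' C^-1 lambda, the squared correlation
                              of regression factor-score estimates with the
                              true factor (their determinacy);
* sum-score reliability    -- (1'lambda)^2 / (1'C1);
* fs/sum correlation       -- 1'lambda / sqrt(lambda'C^-1 lambda * 1'C^-1 1);
* composite reliability    -- grand sum of the "reduced" covariance matrix
                              (diagonal var_j * r_xx,j) over the raw grand
                              sum, for composites of components with known
                              reliabilities.

Correlation-matrix input must be converted to covariances with supplied SDs
before calling these; nothing is rescaled silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cfa import SampleMoments, spearman_three_indicator, fit_cfa, FactorModelSpec
from .errors import DimensionError, InputError, NumericError

__all__ = [
    "ComponentReliabilities",
    "ReliabilityReport",
    "coefficient_alpha",
    "omega_total",
    "nicewander_quantities",
    "rae_composite_reliability",
    "reduced_covariance_sums",
    "reliability_report",
]


def _square_cov(cov) -> np.ndarray:
    if isinstance(cov, SampleMoments):
        return cov.cov
    if isinstance(cov, pd.DataFrame):
        cov = cov.to_numpy(dtype=float)
    c = np.asarray(cov, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise InputError("covariance matrix must be square")
    if not np.allclose(c, c.T, atol=1e-8):
        raise InputError("covariance matrix is not symmetric")
    return c


@dataclass
class ComponentReliabilities:
    """Known per-variable reliabilities r_xx in [0, 1]."""

    r_xx: np.ndarray

    def __post_init__(self):
        self.r_xx = np.asarray(self.r_xx, dtype=float).ravel()
        if ((self.r_xx < 0) | (self.r_xx > 1)).any() or not np.all(
            np.isfinite(self.r_xx)
        ):
            raise InputError("component reliabilities must lie in [0, 1]")


@dataclass
class ReliabilityReport:
    """All coefficients for one scale, with provenance of the inputs."""

    alpha: float
    omega_total: float
    fs_reliability: float
    sum_reliability: float
    fs_sum_correlation: float
    composite_reliability: float = None
    inputs_digest: dict = None

    def to_dict(self) -> dict:
        out = {
            "alpha": self.alpha,
            "omega_total": self.omega_total,
            "fs_reliability": self.fs_reliability,
            "sum_reliability": self.sum_reliability,
            "fs_sum_correlation": self.fs_sum_correlation,
        }
        if self.composite_reliability is not None:
            out["composite_reliability"] = self.composite_reliability
        if self.inputs_digest:
            out["inputs"] = self.inputs_digest
        return out


def coefficient_alpha(cov) -> float:
    """Coefficient alpha from an item covariance matrix.

    alpha = (p/(p-1)) * (1 - sum of variances / sum of all elements).  May be
    negative for pathological matrices (average negative covariance).
    """
    c = _square_cov(cov)
    p = c.shape[0]
    if p < 2:
        raise InputError("coefficient alpha needs at least 2 items")
    total = float(c.sum())
    if total == 0:
        raise InputError("composite variance is zero")
    return (p / (p - 1)) * (1.0 - float(np.trace(c)) / total)


def omega_total(lam, theta) -> float:
    """omega_T for a single-factor congeneric model.

    (sum of loadings)^2 over itself plus the sum of unique variances.
    """
    lam = np.asarray(lam, dtype=float).ravel()
    theta = np.asarray(theta, dtype=float).ravel()
    if lam.size != theta.size:
        raise DimensionError("loadings and unique variances differ in length")
    if np.all(lam == 0):
        raise InputError("all loadings zero; omega_T undefined")
    if (theta < -1e-10).any():
        raise InputError("negative unique variance")
    t = float(lam.sum()) ** 2
    return t / (t + float(np.clip(theta, 0, None).sum()))


def nicewander_quantities(lam, cov) -> tuple[float, float, float]:
    """Determinacy-based reliabilities for factor and sum scores.

    Returns ``(fs_reliability, sum_reliability, fs_sum_correlation)`` where
    fs_reliability = lambda' C^-1 lambda is the squared correlation of
    regression factor-score estimates with the true factor,
    sum_reliability = (1'lambda)^2 / (1'C1) the analogue for the unit-weight
    sum, and the third element their mutual correlation.  Population formulas;
    plugging in sample estimates of lambda and C gives sample estimates.
    """
    c = _square_cov(cov)
    lam = np.asarray(lam, dtype=float).ravel()
    p = c.shape[0]
    if lam.size != p:
        raise DimensionError("loading vector does not match covariance order")
    try:
        cinv = np.linalg.inv(c)
    except np.linalg.LinAlgError as exc:
        raise NumericError("singular covariance matrix") from exc
    ones = np.ones(p)
    fs_rel = float(lam @ cinv @ lam)
    sum_rel = float(lam.sum()) ** 2 / float(ones @ c @ ones)
    # corr(fhat, 1'x): cov = lambda'C^-1 C 1 = 1'lambda, var(fhat) = lambda'C^-1
    # lambda, var(1'x) = 1'C1
    fs_sum_corr = float(lam.sum()) / float(
        np.sqrt(lam @ cinv @ lam) * np.sqrt(ones @ c @ ones)
    )
    return fs_rel, sum_rel, fs_sum_corr


def reduced_covariance_sums(cov, rel: ComponentReliabilities) -> tuple[float, float]:
    """Grand sums of the raw and reduced covariance matrices.

    The reduced matrix keeps all off-diagonal covariances and replaces each
    diagonal entry by var_j * r_xx,j, its true-score variance.
    """
    c = _square_cov(cov)
    if not isinstance(rel, ComponentReliabilities):
        rel = ComponentReliabilities(rel)
    if rel.r_xx.size != c.shape[0]:
        raise DimensionError("reliability vector does not match covariance order")
    raw_sum = float(c.sum())
    reduced = c.copy()
    np.fill_diagonal(reduced, np.diag(c) * rel.r_xx)
    return raw_sum, float(reduced.sum())


def rae_composite_reliability(cov, rel) -> float:
    """Composite reliability of a sum of components with known reliabilities.

    Ratio of the reduced-matrix grand sum (true-score variance of the
    composite) to the raw-matrix grand sum (its total variance).
    """
    raw_sum, reduced_sum = reduced_covariance_sums(cov, rel)
    if raw_sum == 0:
        raise InputError("composite variance is zero")
    return reduced_sum / raw_sum


def reliability_report(
    moments, component_reliabilities=None, fitted=None
) -> ReliabilityReport:
    """Convenience wrapper: fit (or reuse) a one-factor model, report all coefficients.

    For 3-indicator scales with positive covariances the closed-form
    just-identified solution is used when no fitted model is supplied;
    otherwise a congeneric ML fit is performed.
    """
    if not isinstance(moments, SampleMoments):
        moments = SampleMoments(moments)
    c = moments.cov
    if fitted is not None:
        lam = fitted.lam[:, 0]
        theta = fitted.theta
        source = "supplied fit"
    elif c.shape[0] == 3 and min(c[0, 1], c[0, 2], c[1, 2]) > 0:
        lam, theta = spearman_three_indicator(c)
        source = "closed-form just-identified fit"
    else:
        spec = FactorModelSpec({v: "f1" for v in moments.labels})
        fit = fit_cfa(moments, spec)
        lam, theta = fit.lam[:, 0], fit.theta
        source = "ML congeneric fit"
    fs_rel, sum_rel, fs_sum_corr = nicewander_quantities(lam, c)
    composite = None
    digest = {
        "variables": list(moments.labels),
        "loading_source": source,
        "loadings": [float(v) for v in lam],
        "unique_variances": [float(v) for v in theta],
    }
    if component_reliabilities is not None:
        composite = rae_composite_reliability(c, component_reliabilities)
        rx = component_reliabilities
        rx = rx.r_xx if isinstance(rx, ComponentReliabilities) else np.asarray(rx, float)
        digest["component_reliabilities"] = [float(v) for v in rx]
    return ReliabilityReport(
        alpha=coefficient_alpha(c),
        omega_total=omega_total(lam, theta),
        fs_reliability=fs_rel,
        sum_reliability=sum_rel,
        fs_sum_correlation=fs_sum_corr,
        composite_reliability=composite,
        inputs_digest=digest,
    )
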