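"""Causal-effect estimators for two-sample MR.

Notation: for variant j, β_Xj ± se_Xj is the variant-exposure association
and β_Yj ± se_Yj the variant-outcome association, aligned to a common
effect allele.  All estimators regress outcome effects on exposure effects:

* Wald ratio (single variant): β_Yj / β_Xj.
* IVW: weighted regression through the origin, weights 1/se_Yj² — the
  classic inverse-variance-weighted meta-analysis of Wald ratios.
* Correlated-instrument IVW / Egger: generalized least squares with
  covariance Ω_jk = se_Yj·se_Yk·r_jk, for instruments pruned only to a
  liberal LD threshold (avoids double-counting correlated variants).
* MR-Egger: adds an unconstrained intercept (average directional
  pleiotropy); variants are recoded so β_Xj ≥ 0 before fitting.
* MVMR-IVW: joint weighted regression on several exposures' effects.

Heterogeneity is summarized by Cochran's Q over the weighted residuals.
Under ``multiplicative_random`` (the pipeline default) standard errors are
inflated by max(1, √(Q/dof)) and inference uses a t reference distribution;
``fixed`` uses the normal.  Odds-ratio transforms happen at the reporting
layer only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .diagnostics import i_squared, q_pvalue
from .errors import (
    CollinearityError,
    ConditioningError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
    ValidationError,
)
from .harmonize import HarmonizedInstruments
from .sumstats import LDMatrix

FIXED = "fixed"
MULT_RANDOM = "multiplicative_random"


@dataclass
class HeterogeneityStats:
    """Cochran's Q with its degrees of freedom, p-value, and I²."""

    Q: float
    dof: int
    pvalue: float
    I2_percent: float

    @classmethod
    def from_q(cls, Q: float, dof: int) -> "HeterogeneityStats":
        if dof < 1:
            return cls(Q=float(Q), dof=dof, pvalue=float("nan"), I2_percent=0.0)
        return cls(
            Q=float(Q), dof=dof, pvalue=q_pvalue(Q, dof), I2_percent=i_squared(Q, dof)
        )


@dataclass
class MREstimate:
    """One method's causal estimate (per SD of exposure; log-OR for binary outcomes)."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    exposure: str = ""
    outcome: str = ""
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    re_scale: float = 1.0
    heterogeneity: HeterogeneityStats | None = None


@dataclass
class MRInput:
    """Harmonized effects plus optional LD matrix and multivariable design."""

    harmonized: HarmonizedInstruments
    ld: LDMatrix | None = None
    exposure_matrix: np.ndarray | None = None
    exposure_se_matrix: np.ndarray | None = None
    exposure_names: list[str] | None = None

    def __post_init__(self):
        J = len(self.harmonized)
        if J < 1:
            raise ValidationError("MRInput requires at least one instrument")
        if self.ld is not None:
            if len(self.ld.variant_ids) != J:
                self.ld = self.ld.subset(self.harmonized.variant_ids)
        if self.exposure_matrix is not None:
            self.exposure_matrix = np.atleast_2d(np.asarray(self.exposure_matrix, float))
            K = self.exposure_matrix.shape[1]
            if self.exposure_matrix.shape[0] != J:
                raise ValidationError("exposure_matrix row count must equal J")
            if K < 1 or J <= K:
                raise ValidationError("multivariable estimation requires J > K >= 1")
            if self.exposure_names is None:
                self.exposure_names = [f"exposure_{k}" for k in range(K)]

    @property
    def J(self) -> int:
        return len(self.harmonized)


def _interval(beta, se, crit):
    return beta - crit * se, beta + crit * se


def wald_ratio(
    beta_x: float, se_x: float, beta_y: float, se_y: float
) -> MREstimate:
    """Single-variant causal estimate β_Y/β_X with first-order delta-method se."""
    if beta_x == 0:
        raise UndefinedRatioError("Wald ratio undefined for beta_x = 0")
    beta = beta_y / beta_x
    se = abs(se_y / beta_x)
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    lo, hi = _interval(beta, se, stats.norm.ppf(0.975))
    return MREstimate(
        method="wald_ratio",
        beta=float(beta),
        se=float(se),
        ci_low=float(lo),
        ci_high=float(hi),
        pvalue=p,
        n_snps=1,
    )


def ivw(
    input: MRInput, effects_model: str = MULT_RANDOM
) -> tuple[MREstimate, HeterogeneityStats]:
    """Inverse-variance weighted estimate with independent instruments.

    Weighted regression of β_Y on β_X through the origin, weights 1/se_Y².
    ``multiplicative_random`` inflates the fixed-effect se by
    max(1, √(Q/dof)) and uses t with J−1 dof; ``fixed`` uses the normal.
    Delegates to :func:`wald_ratio` at J = 1.
    """
    h = input.harmonized
    J = input.J
    if J == 1:
        est = wald_ratio(h.beta_x[0], h.se_x[0], h.beta_y[0], h.se_y[0])
        return est, HeterogeneityStats.from_q(0.0, 0)

    bx, by, sy = h.beta_x, h.beta_y, h.se_y
    if np.all(bx == 0):
        raise CollinearityError("all variant-exposure effects are zero")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se_fixed = denom**-0.5
    Q = float(np.sum(w * (by - beta * bx) ** 2))
    dof = J - 1
    return _finish_origin_fit(
        "ivw", beta, se_fixed, Q, dof, effects_model, n_snps=J
    )


def _finish_origin_fit(method, beta, se_fixed, Q, dof, effects_model, n_snps):
    het = HeterogeneityStats.from_q(Q, dof)
    if effects_model == MULT_RANDOM:
        scale = max(1.0, np.sqrt(Q / dof)) if dof > 0 else 1.0
        se = se_fixed * scale
        crit = stats.t.ppf(0.975, dof) if dof > 0 else stats.norm.ppf(0.975)
        p = float(2 * stats.t.sf(abs(beta / se), dof)) if dof > 0 else float(
            2 * stats.norm.sf(abs(beta / se))
        )
    elif effects_model == FIXED:
        scale = 1.0
        se = se_fixed
        crit = stats.norm.ppf(0.975)
        p = float(2 * stats.norm.sf(abs(beta / se)))
    else:
        raise ValidationError(f"unknown effects_model {effects_model!r}")
    lo, hi = _interval(beta, se, crit)
    est = MREstimate(
        method=method,
        beta=beta,
        se=float(se),
        ci_low=float(lo),
        ci_high=float(hi),
        pvalue=p,
        n_snps=n_snps,
        re_scale=float(scale),
        heterogeneity=het,
    )
    return est, het


def _omega_inverse(se_y: np.ndarray, r: np.ndarray):
    """Inverse of Ω_jk = se_Yj·se_Yk·r_jk with eigenvalue repair.

    Eigenvalues below 1e-8·λ_max are floored there (with a warning counting
    clipped modes); a condition number still above 1e12 is an error.
    """
    omega = np.outer(se_y, se_y) * r
    vals, vecs = np.linalg.eigh(omega)
    lam_max = vals[-1]
    if lam_max <= 0:
        raise ConditioningError(
            f"LD covariance has non-positive spectrum (largest eigenvalue {lam_max:.3g})"
        )
    floor = 1e-8 * lam_max
    n_clipped = int(np.sum(vals < floor))
    if n_clipped:
        warnings.warn(
            f"clipped {n_clipped} near-singular eigenvalue(s) of the LD covariance",
            RuntimeWarning,
            stacklevel=3,
        )
        vals = np.maximum(vals, floor)
    if vals[-1] / vals[0] > 1e12:
        raise ConditioningError(
            f"LD covariance singular after repair (smallest eigenvalue {vals[0]:.3g})"
        )
    return (vecs / vals) @ vecs.T


def ivw_correlated(
    input: MRInput, effects_model: str = MULT_RANDOM
) -> tuple[MREstimate, HeterogeneityStats]:
    """IVW for LD-correlated instruments via generalized least squares.

    beta = (β_XᵀΩ⁻¹β_X)⁻¹ β_XᵀΩ⁻¹β_Y with Ω_jk = se_Yj·se_Yk·r_jk; reduces
    to :func:`ivw` when the LD matrix is the identity.
    """
    if input.ld is None:
        raise ValidationError("ivw_correlated requires an LD matrix")
    h = input.harmonized
    J = input.J
    if J < 2:
        raise InsufficientInstrumentsError("correlated IVW requires J >= 2")
    bx, by = h.beta_x, h.beta_y
    if np.all(bx == 0):
        raise CollinearityError("all variant-exposure effects are zero")
    oinv = _omega_inverse(h.se_y, input.ld.r)
    denom = float(bx @ oinv @ bx)
    beta = float(bx @ oinv @ by) / denom
    se_fixed = denom**-0.5
    resid = by - beta * bx
    Q = float(resid @ oinv @ resid)
    return _finish_origin_fit(
        "ivw_correlated", beta, se_fixed, Q, J - 1, effects_model, n_snps=J
    )


def egger(
    input: MRInput, correlated: bool = False, effects_model: str = MULT_RANDOM
) -> tuple[MREstimate, HeterogeneityStats]:
    """MR-Egger regression: slope = causal effect, intercept = directional pleiotropy.

    Each variant is recoded so β_Xj ≥ 0 before fitting (sign flips propagate
    to the LD matrix when ``correlated``).  Intercept inference is two-sided
    t with J−2 dof; under ``multiplicative_random`` both standard errors are
    inflated by max(1, √(Q/(J−2))).
    """
    h = input.harmonized
    J = input.J
    if J < 3:
        raise InsufficientInstrumentsError("MR-Egger requires at least 3 instruments")

    s = np.where(h.beta_x < 0, -1.0, 1.0)
    bx = s * h.beta_x
    by = s * h.beta_y
    if np.ptp(bx) == 0:
        raise CollinearityError("no variation in variant-exposure effects")

    X = np.column_stack([np.ones(J), bx])
    if correlated:
        if input.ld is None:
            raise ValidationError("correlated Egger requires an LD matrix")
        r = input.ld.r * np.outer(s, s)
        oinv = _omega_inverse(h.se_y, r)
        xtw = X.T @ oinv
    else:
        w = 1.0 / h.se_y**2
        xtw = X.T * w
    xtwx = xtw @ X
    coef = np.linalg.solve(xtwx, xtw @ by)
    cov = np.linalg.inv(xtwx)
    resid = by - X @ coef
    if correlated:
        Q = float(resid @ oinv @ resid)
    else:
        Q = float(np.sum(w * resid**2))
    dof = J - 2
    het = HeterogeneityStats.from_q(Q, dof)

    scale = max(1.0, np.sqrt(Q / dof)) if effects_model == MULT_RANDOM else 1.0
    se_slope = float(np.sqrt(cov[1, 1])) * scale
    se_int = float(np.sqrt(cov[0, 0])) * scale
    slope, intercept = float(coef[1]), float(coef[0])
    crit = stats.t.ppf(0.975, dof)
    p_slope = float(2 * stats.t.sf(abs(slope / se_slope), dof))
    p_int = float(2 * stats.t.sf(abs(intercept / se_int), dof))
    lo, hi = _interval(slope, se_slope, crit)
    method = "egger_correlated" if correlated else "egger"
    est = MREstimate(
        method=method,
        beta=slope,
        se=se_slope,
        ci_low=float(lo),
        ci_high=float(hi),
        pvalue=p_slope,
        n_snps=J,
        intercept=intercept,
        intercept_se=se_int,
        intercept_p=p_int,
        re_scale=float(scale),
        heterogeneity=het,
    )
    return est, het


def mvmr_ivw(
    input: MRInput, effects_model: str = MULT_RANDOM
) -> tuple[list[MREstimate], HeterogeneityStats]:
    """Multivariable IVW: joint weighted regression on K exposures, no intercept.

    Returns one estimate per exposure; Q has J − K degrees of freedom.
    Reduces to :func:`ivw` at K = 1.
    """
    if input.exposure_matrix is None:
        raise ValidationError("mvmr_ivw requires an exposure_matrix")
    X = input.exposure_matrix
    J, K = X.shape
    if J <= K:
        raise InsufficientInstrumentsError(
            f"multivariable IVW requires more instruments than exposures (J={J}, K={K})"
        )
    sing = np.linalg.svd(X, compute_uv=False)
    if sing[-1] <= 1e-10 * sing[0]:
        null_vec = np.linalg.svd(X)[2][-1]
        names = input.exposure_names or [f"exposure_{k}" for k in range(K)]
        offenders = [
            names[k] for k in np.flatnonzero(np.abs(null_vec) > 0.3 / np.sqrt(K))
        ]
        raise CollinearityError(
            f"exposure effect matrix is rank deficient (involving: {', '.join(offenders)})"
        )

    h = input.harmonized
    by = h.beta_y
    w = 1.0 / h.se_y**2
    xtw = X.T * w
    xtwx = xtw @ X
    coef = np.linalg.solve(xtwx, xtw @ by)
    cov = np.linalg.inv(xtwx)
    resid = by - X @ coef
    Q = float(np.sum(w * resid**2))
    dof = J - K
    het = HeterogeneityStats.from_q(Q, dof)

    scale = max(1.0, np.sqrt(Q / dof)) if effects_model == MULT_RANDOM else 1.0
    if effects_model == MULT_RANDOM:
        crit = stats.t.ppf(0.975, dof)
        pfun = lambda z: float(2 * stats.t.sf(abs(z), dof))
    else:
        crit = stats.norm.ppf(0.975)
        pfun = lambda z: float(2 * stats.norm.sf(abs(z)))

    names = input.exposure_names or [f"exposure_{k}" for k in range(K)]
    estimates = []
    for k in range(K):
        se = float(np.sqrt(cov[k, k])) * scale
        beta = float(coef[k])
        lo, hi = _interval(beta, se, crit)
        estimates.append(
            MREstimate(
                method="mvmr_ivw",
                beta=beta,
                se=se,
                ci_low=float(lo),
                ci_high=float(hi),
                pvalue=pfun(beta / se),
                n_snps=J,
                exposure=names[k],
                re_scale=float(scale),
                heterogeneity=het,
            )
        )
    return estimates, het
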