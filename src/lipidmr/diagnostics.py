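"""Sensitivity machinery shared across analyses: heterogeneity and FDR.

Heterogeneity among per-variant causal estimates is summarized by Cochran's
Q and the I² index (the percentage of variation beyond chance).  Multiple
testing across an analysis arm's primary (IVW) tests is controlled with the
Benjamini-Hochberg step-up procedure; which tests form a family is an
explicit pipeline-configuration choice, never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


def i_squared(Q: float, dof: int) -> float:
    """I² heterogeneity percentage: max(0, (Q − dof)/Q)·100; 0 when Q = 0."""
    if Q < 0:
        raise ValidationError("Q must be >= 0")
    if dof < 1:
        raise ValidationError("dof must be >= 1")
    if Q == 0:
        return 0.0
    return max(0.0, (Q - dof) / Q) * 100.0


def q_pvalue(Q: float, dof: int) -> float:
    """Upper-tail chi-square p-value for Cochran's Q."""
    if dof < 1:
        return float("nan")
    return float(stats.chi2.sf(Q, dof))


@dataclass
class FdrResult:
    """Benjamini-Hochberg adjustment mapped back to input order."""

    ids: list[str]
    pvalues: np.ndarray
    qvalues: np.ndarray
    significant: np.ndarray
    q_star: float


def bh_fdr(pvalues, q_star: float = 0.05, ids=None) -> FdrResult:
    """Benjamini-Hochberg step-up adjusted q-values.

    q_(i) = min over j ≥ i of p_(j)·m/j over the sorted p-values, mapped
    back to input order; a test is significant when q ≤ ``q_star``.

    Raises
    ------
    ValidationError
        for p-values outside (0, 1] or q_star outside (0, 1).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("pvalues must be a nonempty 1-d vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    if not (0 < q_star < 1):
        raise ValidationError("q_star must be in (0, 1)")
    _, qvals, _, _ = multipletests(p, alpha=q_star, method="fdr_bh")
    if ids is None:
        ids = [str(i) for i in range(p.size)]
    return FdrResult(
        ids=list(ids),
        pvalues=p,
        qvalues=qvals,
        significant=qvals <= q_star,
        q_star=q_star,
    )
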