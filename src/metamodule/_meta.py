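"""Inverse-variance random-effects pooling (DerSimonian–Laird).

Shared by the survival screen (log hazard ratios) and the co-expression
module derivation (Fisher-z correlations): both pool per-cohort estimates
y_k with within-study variances v_k under the random-effects model
y_k ~ N(mu, v_k + tau2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PooledEstimate:
    """Random-effects summary of K per-study estimates."""

    beta: float          # pooled estimate (DL random effects)
    se: float            # standard error of the pooled estimate
    tau2: float          # DerSimonian–Laird between-study variance (>= 0)
    q_stat: float        # Cochran's Q on the fixed-effect weights
    p: float             # two-sided normal p for beta / se
    k: int               # number of studies pooled


def pool_inverse_variance(estimates, variances) -> PooledEstimate:
    """DerSimonian–Laird random-effects pool of per-study estimates.

    Parameters
    ----------
    estimates : array-like of float
        Per-study estimates (log hazard ratios, Fisher z values, ...).
    variances : array-like of float
        Within-study variances (squared standard errors), all > 0.

    Notes
    -----
    With fixed-effect weights w_k = 1/v_k:

        beta_F = sum(w y) / sum(w)
        Q      = sum(w (y - beta_F)^2)
        tau2   = max(0, (Q - (K-1)) / (sum(w) - sum(w^2)/sum(w)))

    then the random-effects weights w*_k = 1/(v_k + tau2) give the pooled
    estimate, its standard error (sum w*)^{-1/2} and a two-sided normal
    (Wald) p-value.  K = 1 passes the single study through with tau2 = 0.
    """
    y = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.ndim != 1 or y.shape != v.shape or y.size == 0:
        raise ValueError("estimates and variances must be equal-length, non-empty 1-d arrays")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("variances must be finite and > 0, estimates finite")

    k = y.size
    w = 1.0 / v
    sw = w.sum()
    beta_f = float((w * y).sum() / sw)
    q = float((w * (y - beta_f) ** 2).sum())
    if k > 1:
        denom = sw - (w ** 2).sum() / sw
        tau2 = max(0.0, (q - (k - 1)) / denom)
    else:
        tau2 = 0.0

    w_star = 1.0 / (v + tau2)
    beta_re = float((w_star * y).sum() / w_star.sum())
    se_re = float(1.0 / np.sqrt(w_star.sum()))
    p = float(2.0 * stats.norm.sf(abs(beta_re / se_re)))
    return PooledEstimate(beta=beta_re, se=se_re, tau2=tau2, q_stat=q, p=p, k=k)
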