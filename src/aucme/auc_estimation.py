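"""Observed (uncorrected) AUC estimators.

Two routes to the area under the ROC curve for a continuous marker with the
cases-high orientation (larger values indicate cases):

* the nonparametric Mann-Whitney estimator, the proportion of case-control
  pairs correctly ordered with ties counted 1/2, with either the DeLong
  structural-components variance (default) or the Hanley-McNeil
  exponential-approximation variance;
* the binormal closed form ``Phi((mu_x - mu_y) / sqrt(var_x + var_y))``.

AUC below 0.5 is reported as-is; there is no automatic flipping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit, ndtr
from scipy.stats import norm

__all__ = ["AUCEstimate", "mann_whitney_auc", "binormal_auc"]


@dataclass(frozen=True)
class AUCEstimate:
    """Point estimate of the AUC with standard error and confidence limits.

    ``se == 0`` only for degenerate inputs (perfect separation or constant
    pooled data), in which case ``degenerate`` is True and the interval
    collapses onto the estimate.
    """

    auc: float
    se: float
    ci_lower: float
    ci_upper: float
    estimator: str
    n_cases: int
    n_controls: int
    alpha: float = 0.05
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_lower <= self.ci_upper <= 1.0):
            raise ValueError("confidence limits must satisfy 0 <= lower <= upper <= 1")


def mw_components(cases: np.ndarray, controls: np.ndarray):
    """Mann-Whitney AUC with DeLong placement components.

    Returns ``(auc, var_delong, v10, v01)`` where ``v10``/``v01`` are the
    case/control placement values.  Array-level fast path shared with the
    simulation harness.
    """
    m = cases.shape[0]
    n = controls.shape[0]
    cmp_ = (controls[None, :] < cases[:, None]) + 0.5 * (
        controls[None, :] == cases[:, None]
    )
    v10 = cmp_.mean(axis=1)
    v01 = cmp_.mean(axis=0)
    # pair-count sum keeps the estimate exact (integer half-counts)
    auc = float(cmp_.sum() / (m * n))
    s10 = float(v10.var(ddof=1)) if m > 1 else 0.0
    s01 = float(v01.var(ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    return auc, var, v10, v01


def _hanley_mcneil_var(auc: float, m: int, n: int) -> float:
    # Hanley & McNeil (1982) exponential approximation; m cases, n controls.
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    return (
        auc * (1.0 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)
    ) / (m * n)


def mann_whitney_auc(
    cases,
    controls,
    alpha: float = 0.05,
    variance: str = "delong",
    ci_scale: str = "auc",
) -> AUCEstimate:
    """Nonparametric AUC estimate ``Pr(control < case)`` with tie credit 1/2.

    Parameters
    ----------
    cases, controls : sequences of float
        Marker values; larger values are taken to indicate cases.
    alpha : float
        Two-sided confidence level ``1 - alpha``.
    variance : {"delong", "hanley"}
        Variance estimator for the Mann-Whitney statistic.
    ci_scale : {"auc", "logit"}
        Scale on which the Wald interval is formed.  The default is the AUC
        scale, truncated to [0, 1]; the logit scale keeps limits inside
        (0, 1) and can behave better in small samples.

    Raises
    ------
    ValueError
        On an empty group or non-finite values.
    """
    x = np.asarray(cases, dtype=float).ravel()
    y = np.asarray(controls, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("marker values must be finite")
    if variance not in ("delong", "hanley"):
        raise ValueError("variance must be 'delong' or 'hanley'")
    if ci_scale not in ("auc", "logit"):
        raise ValueError("ci_scale must be 'auc' or 'logit'")

    m, n = x.size, y.size
    auc, var_delong, _, _ = mw_components(x, y)
    var = var_delong if variance == "delong" else _hanley_mcneil_var(auc, m, n)
    se = float(np.sqrt(max(var, 0.0)))

    degenerate = se == 0.0
    z = norm.ppf(1.0 - alpha / 2.0)
    if degenerate:
        lo = hi = auc
    elif ci_scale == "auc":
        lo = max(0.0, auc - z * se)
        hi = min(1.0, auc + z * se)
    else:
        se_logit = se / (auc * (1.0 - auc))
        lo = float(expit(logit(auc) - z * se_logit))
        hi = float(expit(logit(auc) + z * se_logit))
    return AUCEstimate(
        auc=auc,
        se=se,
        ci_lower=lo,
        ci_upper=hi,
        estimator="mann_whitney",
        n_cases=m,
        n_controls=n,
        alpha=alpha,
        degenerate=degenerate,
    )


def binormal_auc(mu_x: float, mu_y: float, var_x: float, var_y: float) -> float:
    """Closed-form AUC when both groups are normal.

    ``Phi((mu_x - mu_y) / sqrt(var_x + var_y))`` with the cases-high
    orientation.  Variances must be strictly positive.
    """
    if var_x <= 0.0 or var_y <= 0.0:
        raise ValueError("variances must be strictly positive")
    return float(ndtr((mu_x - mu_y) / np.sqrt(var_x + var_y)))
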