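"""Measurement-error corrections of the observed AUC.

Random within-subject measurement error attenuates the observed AUC toward
the null value 0.5.  Three corrections are implemented:

probit-shift (the package's core method)
    Assumes the case and control distributions differ by a location shift
    ``mu`` after probit transformation — no normality of the raw marker is
    required.  With probit-scale error variances expressed through the
    intraclass correlations ``ICC = 1/(1 + sigma_e^2)``,

        AUC_true = Phi( Phi^{-1}(AUC_obs) * b ),
        b = sqrt( (1/ICC_X + 1/ICC_Y) / 2 ).

    The observed AUC is the Mann-Whitney estimate on the primary
    measurement; replicates enter only through the per-group probit-scale
    ICCs.  Confidence limits come from a first-order delta method on
    ``a*b`` with ``a = Phi^{-1}(AUC_obs)``.

Faraggi (known error-to-signal ratio)
    Normal theory with equal variances and known
    ``theta^2 = sigma_e^2/sigma^2``:  ``AUC_true =
    Phi(Phi^{-1}(AUC_obs) * sqrt(1 + theta^2))``.

Reiser (normal theory, replicate-estimated variances)
    Estimates the true (between-subject) and error variances per group by
    one-way ANOVA on the raw scale and reports
    ``AUC_true = Phi(delta_hat)`` with
    ``delta_hat = (Xbar - Ybar)/sqrt(s2_Xtrue + s2_Ytrue)``; the CI is a
    delta method on ``delta_hat``.

The probit-shift and Faraggi formulas coincide when both ICCs equal
``1/(1 + theta^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .auc_estimation import AUCEstimate, mann_whitney_auc
from .icc_estimation import ICCEstimate, anova_components, probit_icc

__all__ = [
    "CorrectionResult",
    "probit_shift_correct",
    "probit_shift_ci",
    "probit_shift_from_dataset",
    "faraggi_correct",
    "reiser_correct",
    "inflation_factor",
]


@dataclass(frozen=True)
class CorrectionResult:
    """Corrected AUC with its provenance.

    ``inflation`` is the multiplier applied on the probit scale: ``b`` for
    the probit-shift method, ``sqrt(1 + theta^2)`` for Reiser/Faraggi; it
    is >= 1 whenever there is any measurement error.
    """

    auc_obs: float
    auc_corrected: float
    inflation: float
    ci_lower: float
    ci_upper: float
    alpha: float
    method: str  # probit_shift | reiser | faraggi
    theta2: float | None = None
    se_transformed: float | None = None  # SE of a*b (probit) or delta (Reiser)
    icc_x: float | None = None
    icc_y: float | None = None
    warnings: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.ci_lower - 1e-12 <= self.auc_corrected <= self.ci_upper + 1e-12):
            raise ValueError("CI must bracket the corrected AUC")


def inflation_factor(icc_x: float, icc_y: float) -> float:
    """Probit-scale attenuation multiplier ``sqrt((1/ICC_X + 1/ICC_Y)/2)``."""
    if icc_x <= 0.0 or icc_y <= 0.0:
        raise ValueError("ICCs must be strictly positive")
    return float(np.sqrt((1.0 / icc_x + 1.0 / icc_y) / 2.0))


def probit_shift_correct(auc_obs: float, icc_x: float, icc_y: float) -> float:
    """Point correction ``Phi(Phi^{-1}(AUC_obs) * b)``.

    ``auc_obs`` must lie strictly inside (0, 1); both ICCs strictly
    positive (values of 1 make the correction the identity).
    """
    if not 0.0 < auc_obs < 1.0:
        raise ValueError("auc_obs must lie strictly inside (0, 1)")
    return float(ndtr(ndtri(auc_obs) * inflation_factor(icc_x, icc_y)))


def faraggi_correct(auc_obs: float, theta2: float) -> float:
    """Normal-theory correction with a known error-to-signal ratio."""
    if not 0.0 < auc_obs < 1.0:
        raise ValueError("auc_obs must lie strictly inside (0, 1)")
    if theta2 < 0.0:
        raise ValueError("theta2 must be nonnegative")
    return float(ndtr(ndtri(auc_obs) * np.sqrt(1.0 + theta2)))


def _clip_auc(auc: float, m: int, n: int):
    """Keep Phi^{-1} defined under perfect separation."""
    eps = 1.0 / (2.0 * m * n)
    if auc <= 0.0 or auc >= 1.0:
        return float(np.clip(auc, eps, 1.0 - eps)), True
    return auc, False


def probit_shift_point_ci(
    auc: float,
    var_auc: float,
    icc_x: float,
    var_icc_x: float,
    icc_y: float,
    var_icc_y: float,
    alpha: float,
    m: int,
    n: int,
):
    """Delta-method machinery shared by the estimator and the simulation.

    Returns ``(auc_corrected, lo, hi, b, se_ab, clipped)``.  The variance of
    ``a*b`` is ``b^2 var(a) + a^2 var(b)`` with ``var(a) =
    var(AUC_obs)/phi(a)^2`` and ``var(b)`` propagated from the two ICC
    variances via ``db/dICC = -1/(4 b ICC^2)``, treating the three
    components as independent.
    """
    auc, clipped = _clip_auc(auc, m, n)
    a = float(ndtri(auc))
    b = inflation_factor(icc_x, icc_y)
    var_a = var_auc / float(norm.pdf(a)) ** 2
    db_dx = -1.0 / (4.0 * b * icc_x**2)
    db_dy = -1.0 / (4.0 * b * icc_y**2)
    var_b = db_dx**2 * var_icc_x + db_dy**2 * var_icc_y
    se_ab = float(np.sqrt(max(b**2 * var_a + a**2 * var_b, 0.0)))
    z = float(norm.ppf(1.0 - alpha / 2.0))
    est = float(ndtr(a * b))
    lo = float(ndtr(a * b - z * se_ab))
    hi = float(ndtr(a * b + z * se_ab))
    return est, lo, hi, b, se_ab, clipped


def probit_shift_ci(
    auc_estimate: AUCEstimate,
    icc_x: ICCEstimate,
    icc_y: ICCEstimate,
    alpha: float = 0.05,
) -> CorrectionResult:
    """Probit-shift correction with delta-method confidence limits.

    ``icc_x`` / ``icc_y`` are the case / control probit-scale ICC
    estimates.  A clamped ICC propagates a warning because the resulting
    interval can be unreliably wide.
    """
    warnings = []
    if icc_x.clamped or icc_y.clamped:
        warnings.append("clamped ICC: corrected AUC and CI may be unreliable")
    est, lo, hi, b, se_ab, clipped = probit_shift_point_ci(
        auc_estimate.auc,
        auc_estimate.se**2,
        icc_x.icc,
        icc_x.se**2,
        icc_y.icc,
        icc_y.se**2,
        alpha,
        auc_estimate.n_cases,
        auc_estimate.n_controls,
    )
    if clipped:
        warnings.append("observed AUC at boundary; clipped before probit")
    return CorrectionResult(
        auc_obs=auc_estimate.auc,
        auc_corrected=est,
        inflation=b,
        ci_lower=lo,
        ci_upper=hi,
        alpha=alpha,
        method="probit_shift",
        se_transformed=se_ab,
        icc_x=icc_x.icc,
        icc_y=icc_y.icc,
        warnings=tuple(warnings),
    )


def probit_shift_from_dataset(
    dataset,
    alpha: float = 0.05,
    primary_replicate: int = 1,
    convention: str = "vdw",
    variance: str = "delong",
) -> CorrectionResult:
    """Full probit-shift pipeline on a biomarker dataset.

    Mann-Whitney AUC on the primary measurement, per-group probit-scale
    ICCs from all replicates, then :func:`probit_shift_ci`.
    """
    auc = mann_whitney_auc(
        dataset.primary_values("case", primary_replicate),
        dataset.primary_values("control", primary_replicate),
        alpha=alpha,
        variance=variance,
    )
    icc_x = probit_icc(dataset, "case", convention)
    icc_y = probit_icc(dataset, "control", convention)
    return probit_shift_ci(auc, icc_x, icc_y, alpha)


def _group_summaries(table):
    """Reiser building blocks for one group's replicate table."""
    var_between, var_within, msb, msw, k_eff = anova_components(table)
    groups = [np.asarray(g, dtype=float) for g in table.measurements]
    means = np.array([g.mean() for g in groups])
    s_all = len(groups)
    mean_hat = float(means.mean())
    var_mean = float(means.var(ddof=1)) / s_all  # var of the mean of subject means
    s_rep = len([g for g in groups if len(g) >= 2])
    big_n = sum(len(g) for g in groups if len(g) >= 2)
    var_msb = 2.0 * msb**2 / (s_rep - 1)
    var_msw = 2.0 * msw**2 / (big_n - s_rep)
    var_vb = (var_msb + var_msw) / k_eff**2
    return mean_hat, var_mean, var_between, var_vb, msw


def reiser_correct(dataset, alpha: float = 0.05) -> CorrectionResult:
    """Normal-theory correction from replicate-estimated variance components.

    Both groups need replicated subjects.  Between-group independence is
    assumed; mean squares get chi-square large-sample variances.  If the
    estimated true-variance sum is not positive the correction is
    degenerate: it is clamped to a small floor and flagged.
    """
    warnings = []
    tx = dataset.replicate_table("case")
    ty = dataset.replicate_table("control")
    xbar, var_xbar, vbx, var_vbx, msw_x = _group_summaries(tx)
    ybar, var_ybar, vby, var_vby, msw_y = _group_summaries(ty)
    v_true = vbx + vby
    if v_true <= 0.0:
        v_true = 0.01 * (msw_x + msw_y)
        warnings.append("nonpositive true-variance sum; clamped")
    d = xbar - ybar
    delta = d / np.sqrt(v_true)
    var_delta = (var_xbar + var_ybar) / v_true + d**2 * (var_vbx + var_vby) / (
        4.0 * v_true**3
    )
    se_delta = float(np.sqrt(max(var_delta, 0.0)))
    z = float(norm.ppf(1.0 - alpha / 2.0))
    est = float(ndtr(delta))
    lo = float(ndtr(delta - z * se_delta))
    hi = float(ndtr(delta + z * se_delta))
    theta2 = (msw_x + msw_y) / v_true
    auc_obs = float(ndtr(d / np.sqrt(v_true + msw_x + msw_y)))
    return CorrectionResult(
        auc_obs=auc_obs,
        auc_corrected=est,
        inflation=float(np.sqrt(1.0 + theta2)),
        ci_lower=lo,
        ci_upper=hi,
        alpha=alpha,
        method="reiser",
        theta2=float(theta2),
        se_transformed=se_delta,
        warnings=tuple(warnings),
    )


def reiser_matrices(
    xmat: np.ndarray, ymat: np.ndarray, alpha: float = 0.05
):
    """Balanced-design Reiser fast path: ``(est, lo, hi)``.

    Same estimator as :func:`reiser_correct` for complete subjects x
    replicates matrices; used in the simulation loop.
    """
    z = float(norm.ppf(1.0 - alpha / 2.0))
    parts = []
    for mat in (xmat, ymat):
        s, k = mat.shape
        means = mat.mean(axis=1)
        msb = k * float(means.var(ddof=1))
        msw = float(np.sum((mat - means[:, None]) ** 2)) / (s * (k - 1))
        vb = (msb - msw) / k
        var_vb = (2.0 * msb**2 / (s - 1) + 2.0 * msw**2 / (s * (k - 1))) / k**2
        parts.append(
            (float(means.mean()), float(means.var(ddof=1)) / s, vb, var_vb, msw)
        )
    (xbar, var_xbar, vbx, var_vbx, msw_x) = parts[0]
    (ybar, var_ybar, vby, var_vby, msw_y) = parts[1]
    v_true = max(vbx, 0.0) + max(vby, 0.0)
    if v_true <= 0.0:
        v_true = 0.01 * (msw_x + msw_y)
    d = xbar - ybar
    delta = d / np.sqrt(v_true)
    var_delta = (var_xbar + var_ybar) / v_true + d**2 * (var_vbx + var_vby) / (
        4.0 * v_true**3
    )
    se = np.sqrt(max(var_delta, 0.0))
    return float(ndtr(delta)), float(ndtr(delta - z * se)), float(ndtr(delta + z * se))
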