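"""Intraclass correlation from distinguishable replicate measurements.

The one-way random-effects ANOVA decomposes replicate biomarker
measurements into a between-subject component ``sigma2_b`` and a
within-subject (error) component ``sigma2_w``; the consistency ICC is

    ICC = sigma2_b / (sigma2_b + sigma2_w),

i.e. the reliability of a single measurement.  Unbalanced designs use the
effective replicate count ``k0 = (N - sum(k_i^2)/N) / (s - 1)``.  Subjects
with a single measurement carry no information about the within-subject
variance and are excluded from the ANOVA.

ICCs can be computed on the raw measurement scale or, group by group, on
the probit (normal-scores) scale, where each replicate column is
rank-transformed independently; on that scale the ICC is invariant to any
strictly monotone distortion applied uniformly within a replicate column.

Because the downstream attenuation correction divides by the ICC, estimates
are clamped below at ``ICC_FLOOR`` (and the ANOVA between-subject component
at zero); the ``clamped`` flag records when this happened.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .transforms import normal_scores_array

__all__ = [
    "ICC_FLOOR",
    "ReplicateTable",
    "ICCEstimate",
    "anova_components",
    "icc_from_table",
    "probit_icc",
    "bootstrap_icc_se",
]

ICC_FLOOR = 0.01


@dataclass(frozen=True)
class ReplicateTable:
    """Per-subject replicate measurements, possibly unbalanced (k_i >= 1)."""

    subject_ids: tuple
    measurements: tuple  # tuple of 1-d float arrays, aligned with subject_ids
    scale: str = "raw"  # raw | probit

    @classmethod
    def from_flat(cls, subject_ids: Sequence, values: Sequence[float], scale="raw"):
        """Build from one row per measurement (long format)."""
        sid = np.asarray(subject_ids)
        val = np.asarray(values, dtype=float)
        ids, inv = np.unique(sid, return_inverse=True)
        groups = tuple(val[inv == i] for i in range(len(ids)))
        return cls(subject_ids=tuple(ids.tolist()), measurements=groups, scale=scale)

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, scale="raw"):
        """Build from a balanced subjects x replicates matrix."""
        mat = np.asarray(matrix, dtype=float)
        return cls(
            subject_ids=tuple(range(mat.shape[0])),
            measurements=tuple(mat[i] for i in range(mat.shape[0])),
            scale=scale,
        )


@dataclass(frozen=True)
class ICCEstimate:
    """One-way consistency ICC with its ANOVA components.

    ``se`` is Fisher's large-sample approximation evaluated at the
    (possibly clamped) estimate with ``k = k_eff``.
    """

    icc: float
    var_between: float
    var_within: float
    se: float
    n_subjects: int
    mean_replicates: float
    clamped: bool
    scale: str = "raw"
    warnings: tuple = field(default_factory=tuple)


def _replicated(table: ReplicateTable):
    kept = [np.asarray(m, dtype=float) for m in table.measurements if len(m) >= 2]
    if len(kept) < 2:
        raise ValueError(
            "ICC requires at least 2 subjects with >= 2 replicates "
            "(insufficient replication)"
        )
    return kept


def anova_components(table: ReplicateTable):
    """One-way ANOVA variance components from replicate measurements.

    Returns ``(var_between, var_within, msb, msw, k_eff)``.  ``var_between``
    is clamped at zero; ``var_within = msw``.
    """
    groups = _replicated(table)
    k_i = np.array([len(g) for g in groups], dtype=float)
    s = len(groups)
    big_n = k_i.sum()
    means = np.array([g.mean() for g in groups])
    grand = float(np.concatenate(groups).mean())
    ssb = float(np.sum(k_i * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - mu) ** 2) for g, mu in zip(groups, means)))
    msb = ssb / (s - 1)
    msw = ssw / (big_n - s)
    k_eff = (big_n - np.sum(k_i**2) / big_n) / (s - 1)
    var_between = max(0.0, (msb - msw) / k_eff)
    return var_between, msw, msb, msw, float(k_eff)


def fisher_icc_var(icc: float, k: float, s: int) -> float:
    """Fisher's large-sample variance of the one-way ICC.

    ``2 (1-rho)^2 (1 + (k-1) rho)^2 / (k (k-1) (s-1))`` with ``k`` the
    (effective) replicate count and ``s`` the number of subjects.
    """
    if k <= 1.0 or s <= 1:
        return float("nan")
    return (
        2.0
        * (1.0 - icc) ** 2
        * (1.0 + (k - 1.0) * icc) ** 2
        / (k * (k - 1.0) * (s - 1))
    )


def icc_from_table(table: ReplicateTable) -> ICCEstimate:
    """Consistency ICC with clamping and Fisher standard error."""
    var_between, var_within, msb, msw, k_eff = anova_components(table)
    groups = _replicated(table)
    s = len(groups)
    mean_k = float(np.mean([len(g) for g in groups]))
    total = var_between + var_within
    warnings = []
    if total <= 0.0:
        # all measurements identical: perfect agreement by convention
        icc, clamped = 1.0, False
        warnings.append("zero total variance; ICC set to 1")
    else:
        raw = var_between / total
        clamped = (msb - msw) / k_eff < 0.0 or raw < ICC_FLOOR
        icc = min(1.0, max(ICC_FLOOR, raw))
        if clamped:
            warnings.append(f"ICC clamped to floor {ICC_FLOOR}")
    se = float(np.sqrt(fisher_icc_var(icc, k_eff, s)))
    return ICCEstimate(
        icc=icc,
        var_between=var_between,
        var_within=var_within,
        se=se,
        n_subjects=s,
        mean_replicates=mean_k,
        clamped=clamped,
        scale=table.scale,
        warnings=tuple(warnings),
    )


def icc_from_matrix(mat: np.ndarray) -> tuple[float, float, bool]:
    """Balanced-design fast path: ``(icc, var(icc), clamped)``.

    Equivalent to ``icc_from_table(ReplicateTable.from_matrix(mat))`` for a
    complete subjects x replicates matrix; used in the simulation loop.
    """
    s, k = mat.shape
    means = mat.mean(axis=1)
    msb = k * float(means.var(ddof=1))
    msw = float(np.sum((mat - means[:, None]) ** 2)) / (s * (k - 1))
    total_minus = msb - msw
    var_between = max(0.0, total_minus / k)
    total = var_between + msw
    if total <= 0.0:
        return 1.0, 0.0, False
    raw = var_between / total
    clamped = total_minus < 0.0 or raw < ICC_FLOOR
    icc = min(1.0, max(ICC_FLOOR, raw))
    return icc, fisher_icc_var(icc, k, s), clamped


def probit_icc_matrix(mat: np.ndarray, convention: str = "vdw"):
    """ICC of a balanced replicate matrix after per-column normal scores."""
    return icc_from_matrix(normal_scores_array(mat, convention))


def probit_icc(dataset, group: str, convention: str = "vdw") -> ICCEstimate:
    """Probit-scale ICC for one group of a biomarker dataset.

    Each replicate column (all of the group's values for replicate index
    ``r``) is transformed to normal scores as one batch, so every replicate
    gets its own probit scale; the ICC is then the one-way ANOVA ICC of the
    transformed table.
    """
    sub = dataset.frame[dataset.frame["group"] == group]
    if sub.empty:
        raise ValueError(f"no measurements for group {group!r}")
    pieces = []
    for _, col in sub.groupby("replicate"):
        if len(col) < 2:
            continue
        scores = normal_scores_array(col["value"].to_numpy(), convention)
        pieces.append((col["subject_id"].to_numpy(), scores))
    if not pieces:
        raise ValueError(f"group {group!r} has no replicate column with >= 2 values")
    ids = np.concatenate([p[0] for p in pieces])
    vals = np.concatenate([p[1] for p in pieces])
    table = ReplicateTable.from_flat(ids, vals, scale="probit")
    return icc_from_table(table)


def bootstrap_icc_se(
    table: ReplicateTable, n_boot: int = 1000, seed: int | None = None
) -> float:
    """Subject-level nonparametric bootstrap SE of the ICC.

    Resamples subjects (with their full replicate vectors) with
    replacement; serves as a model-free alternative to the Fisher SE.
    """
    rng = np.random.default_rng(seed)
    groups = _replicated(table)
    s = len(groups)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, s, size=s)
        resampled = ReplicateTable(
            subject_ids=tuple(range(s)),
            measurements=tuple(groups[i] for i in idx),
            scale=table.scale,
        )
        stats[b] = icc_from_table(resampled).icc
    return float(stats.std(ddof=1))
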