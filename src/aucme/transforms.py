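"""Rank-based probit (normal-scores) transformation.

The probit transform maps a value through :math:`\\Phi^{-1}` of its empirical
CDF, producing an approximately standard-normal scale regardless of the
marginal distribution of the input.  It is rank-invariant: any strictly
increasing transformation of the raw values yields identical scores.  The
ECDF must be offset away from 0 and 1 so that :math:`\\Phi^{-1}` stays
finite; two standard conventions are supported:

``vdw``
    van der Waerden scores, :math:`p_i = r_i/(n+1)` (default).
``blom``
    Blom scores, :math:`p_i = (r_i - 3/8)/(n + 1/4)`.

Ties receive midranks, so tied observations map to equal scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

__all__ = ["ScoreVector", "normal_scores", "CONVENTIONS"]

CONVENTIONS = ("vdw", "blom")


@dataclass(frozen=True)
class ScoreVector:
    """Biomarker values paired with their probit-scale normal scores.

    Attributes
    ----------
    values : ndarray
        The input measurements, in input order (arbitrary units).
    scores : ndarray
        Matched probit-scale scores (dimensionless).  Monotone in
        ``values``; ties share a score; always finite.
    convention : str
        The ECDF offset convention used (``vdw`` or ``blom``).
    """

    values: np.ndarray
    scores: np.ndarray
    convention: str

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.values)


def _plotting_positions(ranks: np.ndarray, n: int, convention: str) -> np.ndarray:
    if convention == "vdw":
        return ranks / (n + 1.0)
    if convention == "blom":
        return (ranks - 0.375) / (n + 0.25)
    raise ValueError(
        f"unknown ECDF convention {convention!r}; expected one of {CONVENTIONS}"
    )


def normal_scores_array(values: np.ndarray, convention: str = "vdw") -> np.ndarray:
    """Normal scores of a 1-d (or column-wise 2-d) array; no wrapping.

    Fast path used by the simulation harness; columns of a 2-d array are
    transformed independently.
    """
    n = values.shape[0]
    if n < 2:
        raise ValueError("normal scores need at least 2 values")
    ranks = rankdata(values, method="average", axis=0)
    return ndtri(_plotting_positions(ranks, n, convention))


def normal_scores(values, convention: str = "vdw") -> ScoreVector:
    """Rank-based probit transformation of a sample.

    Parameters
    ----------
    values : sequence of float
        At least two finite measurements.
    convention : {"vdw", "blom"}
        ECDF offset keeping :math:`\\Phi^{-1}` finite at the extremes.

    Returns
    -------
    ScoreVector
        ``scores[i] = ndtri(p(r_i))`` where ``r_i`` is the midrank of
        ``values[i]`` among the ``n`` inputs.

    Raises
    ------
    ValueError
        On fewer than 2 values, non-finite input, or an unknown convention.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if arr.size < 2:
        raise ValueError("normal scores need at least 2 values (degenerate input)")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    scores = normal_scores_array(arr, convention)
    return ScoreVector(values=arr, scores=scores, convention=convention)
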