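"""Monte-Carlo study of the AUC measurement-error corrections.

Three generating models, each producing ``m`` cases and ``n`` controls
with ``k`` replicate observed values per subject.  Replicates share the
subject's true value and carry independent error draws, so replicates of
one subject are dependent:

Model I   (normal / normal)      X_obs = X_true + e,  X_true ~ N(mu, s2_true),
                                 e ~ N(0, s2_err).
Model II  (lognormal / normal)   log X_true ~ N(lambda + mu, s2_true),
                                 additive e ~ N(0, s2_err).
Model III (lognormal / lognormal) as Model II but log e ~ N(0, s2_err) —
                                 errors are strictly positive with mean
                                 exp(s2_err/2); they are deliberately not
                                 mean-centered.

The analytic true AUC is ``Phi((mu_x - mu_y)/sqrt(s2_Xtrue + s2_Ytrue))``
for Model I; for Models II/III the same expression applies on the log
scale because the exponential is rank-preserving.

``evaluate`` replays the study design: ``n_runs`` runs of ``n_datasets``
datasets each; per dataset the requested estimators (MW = uncorrected
Mann-Whitney, Reiser, Probit) produce an estimate and a CI; per run the
bias, MSE, and coverage against the analytic true AUC are averaged; the
report carries across-run means with normal-approximation 95% intervals.
Seeds derive deterministically from ``(base_seed, run, dataset)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import norm

from .auc_estimation import mw_components
from .correction import probit_shift_point_ci, reiser_matrices
from .dataset import BiomarkerDataset
from .icc_estimation import probit_icc_matrix

__all__ = [
    "SimulationConfig",
    "SimulationReport",
    "true_auc",
    "generate_dataset",
    "evaluate",
    "METHODS",
]

METHODS = ("MW", "Reiser", "Probit")

_DEFAULT_ERR = {"I": 0.5, "II": 1.0, "III": 1.0}


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of the simulation study.

    Defaults mirror the study conditions: 100 cases and 100 controls with
    two replicates each; Model I uses true variance 1 and error variance
    0.5, Models II/III unit log-scale variances throughout.
    """

    model: str  # I | II | III
    mu_x: float = 0.0
    mu_y: float = 0.0
    lam: float = 0.0  # lognormal baseline location (lambda)
    m: int = 100
    n: int = 100
    k: int = 2
    var_x_true: float = 1.0
    var_y_true: float = 1.0
    var_err_x: float | None = None  # None -> model default (I: 0.5, II/III: 1)
    var_err_y: float | None = None
    n_datasets: int = 1000
    n_runs: int = 100
    alpha: float = 0.05
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("I", "II", "III"):
            raise ValueError("model must be 'I', 'II', or 'III'")
        if min(self.m, self.n, self.k, self.n_datasets, self.n_runs) < 1:
            raise ValueError("m, n, k, n_datasets, n_runs must all be >= 1")
        if self.var_x_true <= 0 or self.var_y_true <= 0:
            raise ValueError("true variances must be positive")
        for v in (self.var_err_x, self.var_err_y):
            if v is not None and v < 0:
                raise ValueError("error variances must be nonnegative")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def err_x(self) -> float:
        return _DEFAULT_ERR[self.model] if self.var_err_x is None else self.var_err_x

    @property
    def err_y(self) -> float:
        return _DEFAULT_ERR[self.model] if self.var_err_y is None else self.var_err_y


def true_auc(config: SimulationConfig) -> float:
    """Analytic AUC of the error-free marker, ``Phi(mu / sqrt(s2x + s2y))``.

    For Models II/III the location shift acts on the log scale and the
    exponential preserves ranks, so the same expression applies.
    """
    mu = config.mu_x - config.mu_y
    return float(ndtr(mu / np.sqrt(config.var_x_true + config.var_y_true)))


def _generate_matrices(config: SimulationConfig, seed) -> tuple[np.ndarray, np.ndarray]:
    """Observed (subjects x replicates) matrices for cases and controls."""
    rng = np.random.default_rng(seed)
    sd_xt, sd_yt = np.sqrt(config.var_x_true), np.sqrt(config.var_y_true)
    sd_ex, sd_ey = np.sqrt(config.err_x), np.sqrt(config.err_y)
    m, n, k = config.m, config.n, config.k
    if config.model == "I":
        x_true = rng.normal(config.mu_x, sd_xt, m)
        x_err = rng.normal(0.0, sd_ex, (m, k))
        y_true = rng.normal(config.mu_y, sd_yt, n)
        y_err = rng.normal(0.0, sd_ey, (n, k))
    else:
        x_true = np.exp(rng.normal(config.lam + config.mu_x, sd_xt, m))
        y_true = np.exp(rng.normal(config.lam + config.mu_y, sd_yt, n))
        if config.model == "II":
            x_err = rng.normal(0.0, sd_ex, (m, k))
            y_err = rng.normal(0.0, sd_ey, (n, k))
        else:
            x_err = np.exp(rng.normal(0.0, sd_ex, (m, k)))
            y_err = np.exp(rng.normal(0.0, sd_ey, (n, k)))
    return x_true[:, None] + x_err, y_true[:, None] + y_err


def generate_dataset(config: SimulationConfig, seed) -> BiomarkerDataset:
    """One simulated dataset as a long-format :class:`BiomarkerDataset`."""
    xmat, ymat = _generate_matrices(config, seed)
    return BiomarkerDataset.from_arrays(xmat, ymat)


def _analyze(xmat, ymat, methods, alpha):
    """Per-dataset estimates: method -> (estimate, ci_lower, ci_upper)."""
    out = {}
    z = float(norm.ppf(1.0 - alpha / 2.0))
    need_mw = "MW" in methods or "Probit" in methods
    if need_mw:
        auc, var_auc, _, _ = mw_components(xmat[:, 0], ymat[:, 0])
        se = np.sqrt(max(var_auc, 0.0))
        if "MW" in methods:
            out["MW"] = (
                auc,
                max(0.0, auc - z * se),
                min(1.0, auc + z * se),
            )
        if "Probit" in methods:
            icc_x, var_icc_x, _ = probit_icc_matrix(xmat)
            icc_y, var_icc_y, _ = probit_icc_matrix(ymat)
            est, lo, hi, _, _, _ = probit_shift_point_ci(
                auc, var_auc, icc_x, var_icc_x, icc_y, var_icc_y,
                alpha, xmat.shape[0], ymat.shape[0],
            )
            out["Probit"] = (est, lo, hi)
    if "Reiser" in methods:
        out["Reiser"] = reiser_matrices(xmat, ymat, alpha)
    return out


@dataclass(frozen=True)
class SimulationReport:
    """Across-run performance summary in the bias/MSE/coverage layout.

    ``metrics[method]`` holds ``bias_x1000``, ``mse_x10000`` and
    ``coverage_pct``, each a ``(mean, ci_lower, ci_upper)`` triple across
    runs.
    """

    config: SimulationConfig
    auc_true: float
    metrics: dict
    n_failures: int = 0
    field_order: tuple = field(
        default=("bias_x1000", "mse_x10000", "coverage_pct"), repr=False
    )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric in self.field_order:
            row = {
                "lambda": self.config.lam,
                "mu_y": self.config.mu_y,
                "mu_x": self.config.mu_x,
                "auc_true": round(self.auc_true, 3),
                "measure": metric,
            }
            for method in METHODS:
                if method in self.metrics:
                    mean, lo, hi = self.metrics[method][metric]
                    row[method] = f"{mean:.1f} ({lo:.1f}, {hi:.1f})"
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "auc_true": self.auc_true,
            "n_failures": self.n_failures,
            "metrics": {
                method: {k: list(v) for k, v in vals.items()}
                for method, vals in self.metrics.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _run_ci(values: np.ndarray):
    mean = float(values.mean())
    if values.size < 2:
        return mean, mean, mean
    half = 1.96 * float(values.std(ddof=1)) / np.sqrt(values.size)
    return mean, mean - half, mean + half


def evaluate(config: SimulationConfig, methods=METHODS) -> SimulationReport:
    """Run the Monte-Carlo study for one parameter cell.

    Per run, ``n_datasets`` datasets are generated and analyzed; bias,
    MSE, and coverage against the analytic true AUC are averaged within
    runs and then summarized across runs.  Datasets on which an estimator
    fails are dropped and counted; more than 1% failures in a run aborts.
    """
    methods = tuple(m for m in METHODS if m in set(methods))
    if not methods:
        raise ValueError(f"methods must be a subset of {METHODS}")
    target = true_auc(config)
    runs = {meth: {"bias": [], "mse": [], "cov": []} for meth in methods}
    n_failures = 0
    for run in range(config.n_runs):
        acc = {meth: [] for meth in methods}
        fail = 0
        for ds in range(config.n_datasets):
            seed = np.random.SeedSequence([config.base_seed, run, ds])
            xmat, ymat = _generate_matrices(config, seed)
            try:
                res = _analyze(xmat, ymat, methods, config.alpha)
            except (ValueError, FloatingPointError):
                fail += 1
                if fail > 0.01 * config.n_datasets:
                    raise RuntimeError(
                        f"more than 1% of datasets failed in run {run}"
                    )
                continue
            for meth in methods:
                acc[meth].append(res[meth])
        n_failures += fail
        for meth in methods:
            arr = np.asarray(acc[meth])
            est, lo, hi = arr[:, 0], arr[:, 1], arr[:, 2]
            runs[meth]["bias"].append(est.mean() - target)
            runs[meth]["mse"].append(np.mean((est - target) ** 2))
            runs[meth]["cov"].append(np.mean((lo <= target) & (target <= hi)))
    metrics = {}
    for meth in methods:
        metrics[meth] = {
            "bias_x1000": _run_ci(1e3 * np.asarray(runs[meth]["bias"])),
            "mse_x10000": _run_ci(1e4 * np.asarray(runs[meth]["mse"])),
            "coverage_pct": _run_ci(100.0 * np.asarray(runs[meth]["cov"])),
        }
    return SimulationReport(
        config=config, auc_true=target, metrics=metrics, n_failures=n_failures
    )
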