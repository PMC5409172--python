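import numpy as np
import pytest

from aucme.auc_estimation import mw_components
from aucme.correction import probit_shift_from_dataset, reiser_correct
from aucme.icc_estimation import icc_from_matrix
from aucme.simulation import (
    METHODS,
    SimulationConfig,
    _analyze,
    _generate_matrices,
    evaluate,
    generate_dataset,
    true_auc,
)


@pytest.mark.parametrize(
    "model, mu, expected",
    [
        ("I", 0.25, 0.570),
        ("I", 0.5, 0.638),
        ("I", 1.0, 0.760),
        ("II", 1.0, 0.760),
        ("III", 0.5, 0.638),
    ],
)
def test_analytic_true_auc(model, mu, expected):
    cfg = SimulationConfig(model=model, mu_x=mu)
    assert true_auc(cfg) == pytest.approx(expected, abs=5e-4)


def test_equal_means_give_null_auc():
    assert true_auc(SimulationConfig(model="II", mu_x=0.3, mu_y=0.3)) == 0.5


@pytest.mark.parametrize(
    "kwargs",
    [
        {"model": "IV"},
        {"model": "I", "m": 0},
        {"model": "I", "var_x_true": 0.0},
        {"model": "I", "alpha": 1.5},
        {"model": "I", "var_err_x": -1.0},
    ],
)
def test_config_validation(kwargs):
    with pytest.raises(ValueError):
        SimulationConfig(**kwargs)


def test_model_defaults_for_error_variance():
    assert SimulationConfig(model="I").err_x == 0.5
    assert SimulationConfig(model="III").err_y == 1.0
    assert SimulationConfig(model="I", var_err_x=0.25).err_x == 0.25


def test_zero_error_gives_identical_replicates():
    cfg = SimulationConfig(model="I", mu_x=1.0, var_err_x=0.0, var_err_y=0.0, m=20, n=20)
    xmat, ymat = _generate_matrices(cfg, 0)
    assert np.all(xmat[:, 0] == xmat[:, 1])
    assert np.all(ymat[:, 0] == ymat[:, 1])


def test_model_i_sample_icc_matches_variance_ratio():
    # ICC = s2_true/(s2_true + s2_err) = 1/1.5 under the Model I defaults
    cfg = SimulationConfig(model="I", mu_x=1.0, m=2000, n=2000)
    xmat, _ = _generate_matrices(cfg, 123)
    icc, var_icc, _ = icc_from_matrix(xmat)
    assert abs(icc - 2 / 3) < 3 * np.sqrt(var_icc)


def test_model_ii_log_true_mean():
    cfg = SimulationConfig(model="II", mu_x=1.0, m=2000, n=2000, var_err_x=1e-18,
                           var_err_y=1e-18)
    xmat, _ = _generate_matrices(cfg, 5)
    log_true = np.log(xmat[:, 0])
    assert abs(log_true.mean() - 1.0) < 3 / np.sqrt(2000)


def test_model_iii_errors_are_positive():
    cfg = SimulationConfig(model="III", mu_x=1.0, m=200, n=200)
    xmat, ymat = _generate_matrices(cfg, 9)
    assert np.all(xmat > 0) and np.all(ymat > 0)


def test_generate_dataset_matches_matrix_stream():
    cfg = SimulationConfig(model="II", mu_x=0.5, m=15, n=12)
    ds = generate_dataset(cfg, np.random.SeedSequence([1, 2, 3]))
    xmat, ymat = _generate_matrices(cfg, np.random.SeedSequence([1, 2, 3]))
    np.testing.assert_array_equal(ds.replicate_matrix("case"), xmat)
    np.testing.assert_array_equal(ds.replicate_matrix("control"), ymat)


def test_fast_path_equals_dataset_pipeline():
    cfg = SimulationConfig(model="I", mu_x=1.0, m=60, n=60)
    seed = np.random.SeedSequence([2, 0, 0])
    xmat, ymat = _generate_matrices(cfg, seed)
    ds = generate_dataset(cfg, np.random.SeedSequence([2, 0, 0]))
    fast = _analyze(xmat, ymat, METHODS, 0.05)
    probit = probit_shift_from_dataset(ds)
    reiser = reiser_correct(ds)
    mw_auc, _, _, _ = mw_components(xmat[:, 0], ymat[:, 0])
    assert fast["MW"][0] == pytest.approx(mw_auc, abs=1e-14)
    assert fast["Probit"] == pytest.approx(
        (probit.auc_corrected, probit.ci_lower, probit.ci_upper), abs=1e-12
    )
    assert fast["Reiser"] == pytest.approx(
        (reiser.auc_corrected, reiser.ci_lower, reiser.ci_upper), abs=1e-12
    )


def test_evaluate_is_bit_reproducible():
    cfg = SimulationConfig(model="I", mu_x=0.5, m=30, n=30, n_datasets=20, n_runs=2,
                           base_seed=77)
    assert evaluate(cfg).to_json() == evaluate(cfg).to_json()


def test_null_calibration_all_methods():
    """At mu_X = mu_Y every estimator is centered at 0.5 with ~95% coverage."""
    cfg = SimulationConfig(model="I", mu_x=0.0, m=50, n=50, n_datasets=400, n_runs=1,
                           base_seed=31)
    rep = evaluate(cfg)
    for meth in METHODS:
        bias = rep.metrics[meth]["bias_x1000"][0]
        mse = rep.metrics[meth]["mse_x10000"][0]
        mc_se = np.sqrt(mse / 1e4) / np.sqrt(400) * 1e3
        assert abs(bias) < 3 * mc_se + 1.0
        assert 90.0 <= rep.metrics[meth]["coverage_pct"][0] <= 99.5


def test_attenuation_negative_mw_bias_in_all_models():
    for model in ("I", "II", "III"):
        cfg = SimulationConfig(model=model, mu_x=1.0, n_datasets=200, n_runs=1,
                               base_seed=13)
        rep = evaluate(cfg, ("MW",))
        assert rep.metrics["MW"]["bias_x1000"][0] < 0


def test_probit_has_smallest_absolute_bias_under_nonnormality():
    for model in ("II", "III"):
        cfg = SimulationConfig(model=model, mu_x=1.0, n_datasets=500, n_runs=1,
                               base_seed=17)
        rep = evaluate(cfg)
        bias = {m: abs(rep.metrics[m]["bias_x1000"][0]) for m in METHODS}
        assert bias["Probit"] < bias["Reiser"]
        assert bias["Probit"] < bias["MW"]


def test_report_frame_layout():
    cfg = SimulationConfig(model="I", mu_x=0.5, m=30, n=30, n_datasets=10, n_runs=2,
                           base_seed=3)
    frame = evaluate(cfg).to_frame()
    assert list(frame.columns) == [
        "lambda", "mu_y", "mu_x", "auc_true", "measure", "MW", "Reiser", "Probit",
    ]
    assert frame["measure"].tolist() == ["bias_x1000", "mse_x10000", "coverage_pct"]
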