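"""Subspace identification: block-Hankel construction, known-system
recovery oracles, simulation/prediction contracts, model file I/O."""
import warnings

import numpy as np
import pytest

from pulsetemp.metrics import fit_percent
from pulsetemp.subspace import (IdentificationDataset, SSModel,
                                build_block_hankel, load_model, n4sid_fit,
                                predict_ss, save_model, simulate_ss)


def random_stable_system(seed=7, n=4, m=3, l=2, radius=0.9):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n, n))
    a *= radius / np.max(np.abs(np.linalg.eigvals(a)))
    b = rng.normal(size=(n, m))
    c = rng.normal(size=(l, n))
    return SSModel(a, b, c, np.zeros((n, l)))


@pytest.fixture(scope="module")
def known_fit():
    """Noiseless identification of a known random stable 4th-order
    system from persistently exciting input."""
    truth = random_stable_system()
    rng = np.random.default_rng(3)
    u = rng.normal(size=(2000, 3))
    y = simulate_ss(truth, u)
    model = n4sid_fit(IdentificationDataset([(u, y)]), order=4, horizon=10)
    return truth, u, y, model


# ----------------------------------------------------------- block Hankel
def test_hankel_shift_structure():
    h = build_block_hankel(np.array([1.0, 2, 3, 4, 5]), 2)
    assert h.shape == (4, 2)  # 2i block rows, T - 2i + 1 columns
    np.testing.assert_allclose(h[0], [1, 2])
    np.testing.assert_allclose(h[1], [2, 3])  # each row shifts one sample
    np.testing.assert_allclose(h[3], [4, 5])


def test_hankel_column_count_and_channels():
    series = np.arange(301 * 2, dtype=float).reshape(301, 2)
    h = build_block_hankel(series, 10)
    assert h.shape == (40, 282)  # T - 2i + 1 columns
    # block row k holds samples k..k+j-1 of both channels
    np.testing.assert_allclose(h[2:4, 0], series[1])


def test_hankel_experiments_concatenate_without_spanning():
    a = np.arange(30.0)
    b = 100.0 + np.arange(30.0)
    h = np.hstack([build_block_hankel(a, 3), build_block_hankel(b, 3)])
    # no column mixes samples from both experiments
    assert not np.any((h.min(axis=0) < 50) & (h.max(axis=0) >= 100))


def test_hankel_too_short_rejected():
    with pytest.raises(ValueError, match="at least 20"):
        build_block_hankel(np.arange(10.0), 10)


# ------------------------------------------------------- known-system oracle
def test_markov_parameters_recovered(known_fit):
    truth, _, _, model = known_fit
    mp_true = truth.markov_parameters(10)
    mp_est = model.markov_parameters(10)
    rel = np.linalg.norm(mp_est - mp_true) / np.linalg.norm(mp_true)
    assert rel <= 1e-6


def test_noiseless_training_fit(known_fit):
    _, u, y, model = known_fit
    y_sim = simulate_ss(model, u)
    for k in range(y.shape[1]):
        assert fit_percent(y[:, k], y_sim[:, k]) >= 99.9


def test_unit_delay_identified_at_order_one():
    rng = np.random.default_rng(1)
    u = rng.normal(size=(500, 1))
    y = np.zeros((500, 1))
    y[1:, 0] = u[:-1, 0]
    model = n4sid_fit(IdentificationDataset([(u, y)]), order=1, horizon=5)
    mp = model.markov_parameters(4)[:, 0, 0]
    assert mp[0] == pytest.approx(1.0, abs=1e-8)
    np.testing.assert_allclose(mp[1:], 0.0, atol=1e-8)


def test_monotone_fit_in_order(known_fit):
    truth, u, _, _ = known_fit
    rng = np.random.default_rng(9)
    y = simulate_ss(truth, u) + 0.05 * rng.normal(size=(2000, 2))
    fits = []
    for order in (4, 5):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = n4sid_fit(IdentificationDataset([(u, y)]), order=order,
                          horizon=10)
        y_sim = simulate_ss(m, u)
        fits.append(np.mean([fit_percent(y[:, k], y_sim[:, k])
                             for k in range(2)]))
    assert fits[1] >= fits[0] - 0.1


def test_monte_carlo_consistency_under_noise():
    """Median simulation fit stays high when the outputs carry
    0.05 degC-scale innovation noise."""
    truth = random_stable_system()
    rng_u = np.random.default_rng(3)
    u = rng_u.normal(size=(2000, 3))
    y_clean = simulate_ss(truth, u)
    fits = []
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        y = y_clean + 0.05 * rng.normal(size=y_clean.shape)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = n4sid_fit(IdentificationDataset([(u, y)]), order=4,
                          horizon=10)
        y_sim = simulate_ss(m, u)
        fits.append(np.mean([fit_percent(y_clean[:, k], y_sim[:, k])
                             for k in range(2)]))
    assert np.median(fits) >= 95.0


def test_refinement_preserves_exact_fit(known_fit):
    _, u, y, _ = known_fit
    model = n4sid_fit(IdentificationDataset([(u, y)]), order=4, horizon=10,
                      refine=True)
    y_sim = simulate_ss(model, u)
    for k in range(2):
        assert fit_percent(y[:, k], y_sim[:, k]) >= 99.9


# ------------------------------------------------------ simulate / predict
def test_simulate_zero_input_and_superposition(known_fit):
    truth, u, _, _ = known_fit
    np.testing.assert_allclose(simulate_ss(truth, np.zeros((50, 3))), 0.0)
    u2 = np.random.default_rng(0).normal(size=u.shape)
    lhs = simulate_ss(truth, u + u2)
    rhs = simulate_ss(truth, u) + simulate_ss(truth, u2)
    np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-9)


def test_simulate_scalar_geometric_series():
    model = SSModel(A=[[0.5]], B=[[1.0]], C=[[1.0]], K=[[0.0]])
    y = simulate_ss(model, np.ones((12, 1)))[:, 0]
    expected = 2.0 * (1.0 - 0.5 ** np.arange(12))
    np.testing.assert_allclose(y, expected, rtol=1e-12)


def test_simulate_is_causal(known_fit):
    truth, u, _, _ = known_fit
    u2 = u.copy()
    u2[100:] += 5.0  # future change
    y1 = simulate_ss(truth, u)
    y2 = simulate_ss(truth, u2)
    np.testing.assert_allclose(y1[:101], y2[:101], rtol=1e-12)
    assert not np.allclose(y1[101:], y2[101:])


def test_predict_with_zero_gain_equals_simulate(known_fit):
    truth, u, y, _ = known_fit
    np.testing.assert_allclose(predict_ss(truth, u, y), simulate_ss(truth, u),
                               rtol=1e-12)


def test_predictor_recovers_innovations():
    """On data generated by the innovation form, the one-step residuals
    equal the injected innovations exactly."""
    rng = np.random.default_rng(2)
    base = random_stable_system(seed=12)
    k_dir = rng.normal(size=(4, 2))
    # scale the gain so the predictor dynamics stay stable and roundoff
    # is not amplified over the horizon
    scale = 0.05
    while np.max(np.abs(np.linalg.eigvals(
            base.A - scale * k_dir @ base.C))) >= 0.999:
        scale /= 2
    k_gain = scale * k_dir
    model = SSModel(base.A, base.B, base.C, k_gain)
    u = rng.normal(size=(300, 3))
    e = rng.normal(size=(300, 2))
    x = np.zeros(4)
    y = np.empty((300, 2))
    for t in range(300):
        y[t] = model.C @ x + e[t]
        x = model.A @ x + model.B @ u[t] + model.K @ e[t]
    y_hat = predict_ss(model, u, y)
    np.testing.assert_allclose(y - y_hat, e, rtol=1e-8, atol=1e-9)


# ------------------------------------------------------------ model object
def test_parameter_count_for_default_layout():
    model = random_stable_system()
    assert model.n_params == 44  # n^2 + n*m + p*n + n*p with D fixed at 0
    assert np.all(model.D == 0)


def test_unstable_model_flagged():
    with pytest.warns(UserWarning, match="unstable"):
        SSModel(A=[[1.2]], B=[[1.0]], C=[[1.0]], K=[[0.0]])


def test_order_exceeding_rank_warns():
    rng = np.random.default_rng(4)
    u = rng.normal(size=(800, 1))
    y = np.zeros((800, 1))
    y[1:, 0] = 0.5 * y[:-1, 0] + u[:-1, 0]  # first-order truth
    with pytest.warns(UserWarning, match="singular values"):
        n4sid_fit(IdentificationDataset([(u, y)]), order=4, horizon=6)


def test_fit_preconditions():
    rng = np.random.default_rng(0)
    u = rng.normal(size=(2000, 3))
    y = rng.normal(size=(2000, 2))
    ds = IdentificationDataset([(u, y)])
    with pytest.raises(ValueError, match="horizon"):
        n4sid_fit(ds, order=4, horizon=3)
    short = IdentificationDataset([(u[:100], y[:100])])
    with pytest.raises(ValueError, match="needs >="):
        n4sid_fit(short, order=4, horizon=10)


def test_model_json_round_trip(tmp_path, known_fit):
    *_, model = known_fit
    path = tmp_path / "model.json"
    save_model(model, path)
    back = load_model(path)
    np.testing.assert_allclose(back.A, model.A, rtol=1e-12)
    np.testing.assert_allclose(back.B, model.B, rtol=1e-12)
    np.testing.assert_allclose(back.K, model.K, rtol=1e-12)
    assert back.ts == model.ts
    # feedthrough must stay zero in the file format
    import json
    payload = json.loads(path.read_text())
    payload["D"] = [[1.0, 0, 0], [0, 0, 0]]
    path.write_text(json.dumps(payload))
    with pytest.raises(ValueError, match="feedthrough"):
        load_model(path)


def test_continuous_time_conversion_round_trips():
    import scipy.linalg

    model = random_stable_system(seed=21)
    a_c, b_c = model.to_continuous()
    aug = np.zeros((7, 7))
    aug[:4, :4] = a_c
    aug[:4, 4:] = b_c
    disc = scipy.linalg.expm(aug * model.ts)
    np.testing.assert_allclose(disc[:4, :4], model.A, atol=1e-9)
    np.testing.assert_allclose(disc[:4, 4:], model.B, atol=1e-9)
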