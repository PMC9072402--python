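"""Lagged ridge encoding: design, fitting, cross-validation, attribution."""

import numpy as np
import pytest

from mcdmeg.mcd_core import ParameterError
from mcdmeg.stimulus_design import default_stimulus_set
from mcdmeg.synthetic_data import (
    component_traces,
    default_ground_truth,
    make_design,
    make_layout,
    simulate_epochs,
)
from mcdmeg.trf_encoding import (
    COMPONENT_NAMES,
    LagWindow,
    component_contribution,
    crossval_score,
    fit_trf,
    lagged_design,
    predict_trf,
    windowed_scores,
)


@pytest.fixture(scope="module")
def trf_world(small_sset):
    """A small noise-free and a noisy synthetic world sharing one design."""
    layout = make_layout(12, (3, 4))
    design = make_design(n_participants=1, reps=6, task_blocks=1,
                         localizer_blocks=0, seed=2)
    stim_ids = sorted(design["stimulus"].unique())

    def build(snr, seed=4):
        truth = default_ground_truth(layout, n_participants=1, seed=1, snr=snr)
        truth.uni_gain_a[:] = 0.0
        truth.uni_gain_v[:] = 0.0
        epochs = simulate_epochs(truth, design, small_sset, layout, seed=seed)
        comps = np.stack([
            component_traces(small_sset.sequences[stim_ids.index(r.stimulus)],
                             truth.mcd_params[0])
            for r in design.itertuples(index=False)])
        folds = np.array([stim_ids.index(r.stimulus)
                          for r in design.itertuples(index=False)])
        return truth, epochs, comps, folds

    return build


class TestLaggedDesign:
    def test_single_zero_lag_is_identity(self):
        trace = np.random.default_rng(0).normal(size=(2, 30))
        lw = LagWindow(0.0, 1.0 / 250.0, 250.0)  # lags {0, 1}
        lw0 = LagWindow(-0.5 / 250, 0.5 / 250, 250.0)
        X = lagged_design(trace, LagWindow(0.0, 0.004, 250.0))
        # first column of each component block is the unshifted trace
        np.testing.assert_allclose(X[:, 0], trace[0])

    def test_column_count(self):
        trace = np.zeros((4, 50))
        lw = LagWindow(0.0, 0.1, 250.0)
        X = lagged_design(trace, lw)
        assert X.shape == (50, 4 * lw.n_lags)

    def test_shift_with_zero_padding_oracle(self):
        rng = np.random.default_rng(1)
        trace = rng.normal(size=(1, 40))
        lw = LagWindow(0.0, 12 / 250.0, 250.0)
        X = lagged_design(trace, lw)
        for li, L in enumerate(lw.lags):
            expected = np.zeros(40)
            expected[L:] = trace[0, :40 - L]
            np.testing.assert_allclose(X[:, li], expected)

    def test_invalid_window_rejected(self):
        with pytest.raises(ParameterError):
            LagWindow(0.5, 0.1, 250.0)


class TestFitTRF:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        comps = rng.normal(size=(3, 2, 60))
        epochs = rng.normal(size=(3, 4, 60))
        lw = LagWindow(0.0, 0.02, 250.0)
        model = fit_trf(epochs, comps, lw, ridge_lambda=0.0, standardize=False)
        X = np.vstack([lagged_design(c, lw) for c in comps])
        Y = np.concatenate([e.T for e in epochs], axis=0)
        W_ref = np.linalg.solve(X.T @ X, X.T @ Y)
        np.testing.assert_allclose(model.weights.reshape(4, -1), W_ref.T,
                                   atol=1e-8)

    def test_huge_penalty_shrinks_weights(self):
        rng = np.random.default_rng(3)
        comps = rng.normal(size=(2, 2, 50))
        epochs = rng.normal(size=(2, 3, 50))
        lw = LagWindow(0.0, 0.02, 250.0)
        model = fit_trf(epochs, comps, lw, ridge_lambda=1e12)
        assert np.abs(model.weights).max() < 1e-6

    def test_singular_design_rejected_at_zero_lambda(self):
        comps = np.zeros((2, 2, 50))
        epochs = np.zeros((2, 3, 50))
        lw = LagWindow(0.0, 0.02, 250.0)
        with pytest.raises(np.linalg.LinAlgError):
            fit_trf(epochs, comps, lw, ridge_lambda=0.0, standardize=False)

    def test_noise_free_ground_truth_recovery(self, trf_world):
        truth, epochs, comps, _ = trf_world(snr=0)
        model = fit_trf(epochs.data, comps, truth.trf_lag_window,
                        ridge_lambda=1e-8)
        err = (np.abs(model.weights - truth.trf_true).max()
               / np.abs(truth.trf_true).max())
        assert err < 0.01


class TestCrossvalScore:
    def test_fold_count_participants_by_stimuli(self):
        ids = np.array([f"p{p}/s{s}" for p in range(13) for s in range(6)])
        assert np.unique(ids).size == 78

    def test_noise_free_rho_near_one_on_driven_sensors(self, trf_world):
        truth, epochs, comps, folds = trf_world(snr=0)
        score = crossval_score(epochs.data, comps, folds,
                               truth.trf_lag_window, ridge_lambda=1e-6)
        for ci, name in enumerate(COMPONENT_NAMES):
            driven = truth.component_sensors[name]
            assert score.rho[driven, ci].mean() > 0.95

    def test_pure_noise_target_rho_near_zero(self, small_sset):
        layout = make_layout(6, (2, 3))
        design = make_design(n_participants=1, reps=4, task_blocks=1,
                             localizer_blocks=0, seed=5)
        stim_ids = sorted(design["stimulus"].unique())
        truth = default_ground_truth(layout, n_participants=1, seed=1, snr=5)
        comps = np.stack([
            component_traces(small_sset.sequences[stim_ids.index(r.stimulus)],
                             truth.mcd_params[0])
            for r in design.itertuples(index=False)])
        folds = np.array([stim_ids.index(r.stimulus)
                          for r in design.itertuples(index=False)])
        rng = np.random.default_rng(6)
        noise = rng.normal(size=(len(design), 6, 500))
        score = crossval_score(noise, comps, folds, truth.trf_lag_window,
                               ridge_lambda=100.0)
        assert np.abs(score.rho.mean(axis=0)).max() < 0.05

    def test_recovery_degrades_monotonically_with_noise(self, trf_world):
        corrs = []
        for snr in (0, 5.0, 1.0):
            truth, epochs, comps, _ = trf_world(snr=snr)
            lam = 1e-6 if snr == 0 else "nested"
            model_lam = 1e-6 if snr == 0 else 1000.0
            model = fit_trf(epochs.data, comps, truth.trf_lag_window,
                            ridge_lambda=model_lam)
            corrs.append(np.corrcoef(model.weights.ravel(),
                                     truth.trf_true.ravel())[0, 1])
        assert corrs[0] > corrs[1] > corrs[2]
        assert corrs[1] > 0.9  # SNR 5 recovery

    def test_nested_lambda_policy_beats_tiny_lambda_at_snr5(self, trf_world):
        truth, epochs, comps, folds = trf_world(snr=5.0)
        from mcdmeg.trf_encoding import _nested_lambda
        lam = _nested_lambda(epochs.data, comps, folds, truth.trf_lag_window)
        model = fit_trf(epochs.data, comps, truth.trf_lag_window, lam)
        model_tiny = fit_trf(epochs.data, comps, truth.trf_lag_window, 1e-6)
        r = np.corrcoef(model.weights.ravel(), truth.trf_true.ravel())[0, 1]
        r_tiny = np.corrcoef(model_tiny.weights.ravel(),
                             truth.trf_true.ravel())[0, 1]
        assert r > 0.9 and r > r_tiny


class TestComponentContribution:
    def test_attribution_specificity(self, trf_world):
        """Sensors driven only by one component score highest for it and
        near zero for an orthogonally assigned component, over many seeds."""
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            truth, epochs, comps, folds = trf_world(snr=5.0, seed=100 + seed)
            model = fit_trf(epochs.data, comps, truth.trf_lag_window, 1000.0)
            corr_sensors = truth.component_sensors["corr"]
            lag_sensors = truth.component_sensors["lag"]
            c_corr = component_contribution(model, epochs.data, comps,
                                            COMPONENT_NAMES.index("corr"))
            c_lag = component_contribution(model, epochs.data, comps,
                                           COMPONENT_NAMES.index("lag"))
            within = c_corr[corr_sensors].mean() + c_lag[lag_sensors].mean()
            cross = c_corr[lag_sensors].mean() + c_lag[corr_sensors].mean()
            if within > cross:
                wins += 1
        assert wins == n_seeds

    def test_zero_component_weights_flagged_rho_zero(self):
        rng = np.random.default_rng(7)
        comps = rng.normal(size=(2, 2, 50))
        epochs = rng.normal(size=(2, 3, 50))
        lw = LagWindow(0.0, 0.02, 250.0)
        model = fit_trf(epochs, comps, lw, 1.0)
        model.weights[:, 1, :] = 0.0
        contrib = component_contribution(model, epochs, comps, 1)
        np.testing.assert_array_equal(contrib, 0.0)

    def test_single_component_model_contribution_equals_full(self):
        rng = np.random.default_rng(8)
        comps = rng.normal(size=(3, 1, 60))
        epochs = rng.normal(size=(3, 2, 60))
        lw = LagWindow(0.0, 0.02, 250.0)
        model = fit_trf(epochs, comps, lw, 1.0)
        full = predict_trf(model, comps)
        only = predict_trf(model, comps, component=0)
        np.testing.assert_allclose(full, only)

    def test_collinearity_shares_attribution(self, small_sset):
        """When the correlation output and a subunit predictor are strongly
        correlated by construction, their attributions overlap (documented
        methodological caveat rather than a defect)."""
        layout = make_layout(4, (2, 2))
        design = make_design(n_participants=1, reps=5, task_blocks=1,
                             localizer_blocks=0, seed=9)
        stim_ids = sorted(design["stimulus"].unique())
        truth = default_ground_truth(layout, n_participants=1, seed=2, snr=0)
        params = truth.mcd_params[0]
        base = np.stack([
            component_traces(small_sset.sequences[stim_ids.index(r.stimulus)],
                             params)
            for r in design.itertuples(index=False)])
        # second predictor duplicates the first (perfect collinearity);
        # ridge splits the weight evenly between the two copies
        comps = np.stack([base[:, 2], base[:, 2].copy()], axis=1)
        lw = LagWindow(0.0, 0.1, 250.0)
        target = np.repeat(base[:, 2][:, None, :], 4, axis=1)  # driven by corr
        model = fit_trf(target, comps, lw, 10.0)
        c0 = component_contribution(model, target, comps, 0)
        c1 = component_contribution(model, target, comps, 1)
        assert c0.mean() > 0.9 and c1.mean() > 0.9  # overlapping attribution
        np.testing.assert_allclose(model.weights[:, 0], model.weights[:, 1],
                                   atol=1e-8)


class TestWindowedScores:
    def test_early_late_stationary(self, trf_world):
        truth, epochs, comps, folds = trf_world(snr=0)
        early, late = windowed_scores(epochs.data, comps, folds,
                                      truth.trf_lag_window,
                                      epoch_times=epochs.times,
                                      ridge_lambda=1e-6)
        driven = np.concatenate(list(truth.component_sensors.values()))
        e = np.array([early.rho[s, ci] for ci, n in enumerate(COMPONENT_NAMES)
                      for s in truth.component_sensors[n]])
        l = np.array([late.rho[s, ci] for ci, n in enumerate(COMPONENT_NAMES)
                      for s in truth.component_sensors[n]])
        assert e.mean() > 0.8 and l.mean() > 0.8

    def test_empty_window_rejected(self, trf_world):
        truth, epochs, comps, folds = trf_world(snr=0)
        with pytest.raises(ParameterError):
            windowed_scores(epochs.data, comps, folds, truth.trf_lag_window,
                            epoch_times=epochs.times, split_at=0.5,
                            early=(0.4, 0.4))

    def test_full_window_equals_unsplit(self, trf_world):
        truth, epochs, comps, folds = trf_world(snr=0)
        t0, t1 = float(epochs.times[0]), float(epochs.times[-1]) + 1e-6
        full_a, full_b = windowed_scores(
            epochs.data, comps, folds, truth.trf_lag_window,
            epoch_times=epochs.times, early=(t0, t1), late=(t0, t1),
            ridge_lambda=1e-6)
        unsplit = crossval_score(epochs.data, comps, folds,
                                 truth.trf_lag_window, ridge_lambda=1e-6)
        np.testing.assert_allclose(full_a.rho, unsplit.rho, atol=1e-10)
        np.testing.assert_allclose(full_b.rho, unsplit.rho, atol=1e-10)
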