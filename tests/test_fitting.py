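import numpy as np
import pytest

from ensemblerate.data import ValidationError
from ensemblerate.fitting import (
    CVResult,
    _fit_arrays,
    compare_models,
    fit_all,
    fit_model,
    loocv,
    trial_arrays,
)
from ensemblerate.models import get_model
from ensemblerate.synth import (
    DesignSpec,
    build_design,
    default_true_pleasures,
    simulate_dataset,
    configs_from_population,
)

from conftest import (
    flat_sigma,
    integer_true_pleasures,
    make_baselines,
    make_trial,
    noiseless_config,
)


def make_condition_trials(responses, images=("A", "B", "C", "D"), targets=None,
                          ttype="one_of_four"):
    targets = targets or [1 + i % 4 for i in range(len(responses))]
    return [
        make_trial(ttype=ttype, target=targets[i] if ttype == "one_of_four" else None,
                   response=r, index=i)
        for i, r in enumerate(responses)
    ]


class TestFitModel:
    def test_faithful_zero_params_and_rmse(self, toy_baselines):
        trials = make_condition_trials([7, 5, 4, 2], targets=[1, 2, 3, 4])
        fit = fit_model(trials, toy_baselines, "faithful")
        assert fit.params == {}
        # baselines at targets: 8, 4, 5, 3 -> errors -1, 1, -1, -1
        assert fit.train_rmse == pytest.approx(1.0)

    def test_attenuation_recovery_matches_grid_oracle(self):
        """Noiseless attenuation observer, 288 postcued trials; oracle is a
        dense 2-D grid search at step 0.01."""
        spec = DesignSpec(n_participants=1, n_blocks=16, alternation_start="postcue", seed=8)
        config = noiseless_config(single_model={
            "precue": ("high_pleasure_attenuation", {"P_beau": 4.6, "g": 0.5}),
            "postcue": ("high_pleasure_attenuation", {"P_beau": 4.6, "g": 0.5}),
        })
        config.true_pleasure = default_true_pleasures(spec.image_ids())
        ds = simulate_dataset(spec, [config])
        trials = ds.trials_for("p01", "postcue_1of4")
        assert len(trials) == 288
        fit = fit_model(trials, ds.baselines, "high_pleasure_attenuation")

        P, t, y = trial_arrays(trials, ds.baselines)
        pt = P[np.arange(len(P)), t - 1]
        best = (np.inf, None, None)
        for g in np.arange(0.0, 1.0001, 0.01):
            beaus = np.arange(1.0, 9.0001, 0.01)
            pred = np.where(pt[None, :] < beaus[:, None], pt[None, :],
                            beaus[:, None] + g * (pt[None, :] - beaus[:, None]))
            rmse = np.sqrt(np.mean((pred - y[None, :]) ** 2, axis=1))
            i = int(np.argmin(rmse))
            if rmse[i] < best[0]:
                best = (float(rmse[i]), float(beaus[i]), float(g))
        _, beau_grid, g_grid = best
        assert fit.params["P_beau"] == pytest.approx(beau_grid, abs=0.02)
        assert fit.params["g"] == pytest.approx(g_grid, abs=0.02)

    def test_attenuation_recovery_from_continuous_data(self):
        """With un-discretized baselines and responses the truth is
        recovered to +/- 0.05 (integer baselines leave the kink position
        underdetermined between rating levels, hence this separate check)."""
        rng = np.random.default_rng(12)
        P = rng.uniform(1, 9, size=(288, 4))
        t = rng.integers(1, 5, size=288)
        pt = P[np.arange(288), t - 1]
        y = np.where(pt < 4.6, pt, 4.6 + 0.5 * (pt - 4.6))
        fit = _fit_arrays(get_model("high_pleasure_attenuation"), P, t, y)
        assert fit.params["P_beau"] == pytest.approx(4.6, abs=0.05)
        assert fit.params["g"] == pytest.approx(0.5, abs=0.05)

    def test_linear_combined_exact_recovery(self):
        """y exactly a + b*Pbar; closed-form least-squares oracle."""
        rng = np.random.default_rng(0)
        P = rng.uniform(1, 9, size=(40, 4))
        t = np.zeros(40, dtype=int)
        pbar = P.mean(axis=1)
        y = -1.4 + 1.2 * pbar
        fit = _fit_arrays(get_model("linear_combined"), P, t, y)
        X = np.column_stack([np.ones(40), pbar])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert fit.params["a"] == pytest.approx(coef[0], abs=1e-9)
        assert fit.params["b"] == pytest.approx(coef[1], abs=1e-9)
        assert fit.params["a"] == pytest.approx(-1.4, abs=1e-4)
        assert fit.params["b"] == pytest.approx(1.2, abs=1e-4)

    def test_average_biased_exact_recovery(self):
        rng = np.random.default_rng(1)
        P = rng.uniform(1, 9, size=(60, 4))
        t = rng.integers(1, 5, size=60)
        pt = P[np.arange(60), t - 1]
        w_true = 0.37
        y = (1 - w_true) * pt + w_true * P.mean(axis=1)
        fit = _fit_arrays(get_model("average_biased"), P, t, y)
        assert fit.params["w"] == pytest.approx(w_true, abs=1e-9)

    def test_degenerate_identical_baselines_flagged(self):
        baselines = make_baselines(mapping={"A": 5, "B": 5, "C": 5, "D": 5})
        trials = make_condition_trials([4, 6, 5, 5, 4, 6])
        fit = fit_model(trials, baselines, "linear_single")
        assert fit.degenerate
        pred = get_model("linear_single").predict(fit.params, np.full((1, 4), 5.0), 1)
        assert pred == pytest.approx(5.0)  # best constant fit = mean response

    def test_too_few_trials(self, toy_baselines):
        trials = make_condition_trials([5, 6])
        with pytest.raises(ValidationError, match="at least"):
            fit_model(trials, toy_baselines, "weighted_avg_biased")

    def test_mixed_trial_types_rejected(self, toy_baselines):
        trials = [make_trial(response=5), make_trial(ttype="four_combined", response=5, index=1)]
        with pytest.raises(ValidationError, match="mix"):
            fit_model(trials, toy_baselines, "faithful")

    def test_wrong_family_for_type(self, toy_baselines):
        trials = make_condition_trials([5, 6, 7])
        with pytest.raises(ValidationError, match="applies to"):
            fit_model(trials, toy_baselines, "linear_combined")

    @pytest.mark.parametrize(
        "nested,nesting",
        [
            ("faithful", "average_biased"),
            ("faithful", "high_pleasure_attenuation"),
            ("faithful", "linear_single"),
            ("averaging", "weighted_avg_position"),
            ("averaging", "weighted_avg_pleasure_rank"),
            ("average_biased", "weighted_avg_biased"),
        ],
    )
    def test_nesting_training_rmse(self, nested, nesting):
        """A nesting family fitted to the same data does at least as well
        as its nested special case, up to optimizer tolerance."""
        rng = np.random.default_rng(3)
        P = rng.uniform(1, 9, size=(50, 4))
        t = rng.integers(1, 5, size=50)
        y = np.clip(np.round(P[np.arange(50), t - 1] + rng.normal(0, 1.2, 50)), 1, 9)
        sub = _fit_arrays(get_model(nested), P, t, y)
        sup = _fit_arrays(get_model(nesting), P, t, y)
        assert sup.train_rmse <= sub.train_rmse + 1e-6


class TestLOOCV:
    def test_zero_param_heldout_equals_full_predictions(self, toy_baselines):
        trials = make_condition_trials([7, 5, 4, 2, 6], targets=[1, 2, 3, 4, 1])
        cv = loocv(trials, toy_baselines, "faithful")
        P, t, y = trial_arrays(trials, toy_baselines)
        np.testing.assert_array_equal(cv.heldout_pred, P[np.arange(5), t - 1])
        assert cv.mean_heldout_rmse == pytest.approx(np.mean(np.abs(cv.heldout_err)))

    def test_noiseless_faithful_observer_zero_rmse(self, small_faithful_dataset):
        ds = small_faithful_dataset
        trials = ds.trials_for("p01", "precue_1of4")
        cv = loocv(trials, ds.baselines, "faithful")
        assert cv.mean_heldout_rmse == 0.0

    def test_five_trial_toy_matches_hand_loop(self, toy_baselines):
        """Independently coded LOOCV: per fold, unconstrained least squares
        for the average-biased weight via lstsq, then clip to [0, 1]."""
        trials = make_condition_trials([7, 4, 5, 3, 8], targets=[1, 2, 3, 4, 1])
        cv = loocv(trials, toy_baselines, "average_biased", warm=False)

        P, t, y = trial_arrays(trials, toy_baselines)
        pt = P[np.arange(5), t - 1]
        z = P.mean(axis=1) - pt
        expected_pred = np.empty(5)
        for i in range(5):
            train = [j for j in range(5) if j != i]
            w, *_ = np.linalg.lstsq(z[train, None], (y - pt)[train], rcond=None)
            w = float(np.clip(w[0], 0.0, 1.0))
            expected_pred[i] = (1 - w) * pt[i] + w * P[i].mean()
        np.testing.assert_allclose(cv.heldout_pred, expected_pred, atol=1e-10)
        np.testing.assert_allclose(
            cv.mean_heldout_rmse, np.mean(np.abs(y - expected_pred)), atol=1e-10
        )

    def test_pooled_mode(self, toy_baselines):
        trials = make_condition_trials([7, 5, 4, 2, 6], targets=[1, 2, 3, 4, 1])
        per_fold = loocv(trials, toy_baselines, "faithful", mode="per_fold")
        pooled = loocv(trials, toy_baselines, "faithful", mode="pooled")
        np.testing.assert_allclose(per_fold.heldout_err, pooled.heldout_err)
        assert pooled.mean_heldout_rmse == pytest.approx(
            np.sqrt(np.mean(per_fold.heldout_err ** 2))
        )
        assert per_fold.pooled_rmse == pytest.approx(pooled.mean_heldout_rmse)

    def test_warm_and_cold_starts_agree(self, small_faithful_dataset):
        ds = small_faithful_dataset
        trials = ds.trials_for("p02", "postcue_1of4")
        warm = loocv(trials, ds.baselines, "high_pleasure_attenuation", warm=True)
        cold = loocv(trials, ds.baselines, "high_pleasure_attenuation", warm=False)
        np.testing.assert_allclose(warm.heldout_pred, cold.heldout_pred, atol=1e-4)

    def test_fold_count_invariant(self, toy_baselines):
        trials = make_condition_trials([7, 5, 4, 2, 6, 3], targets=[1, 2, 3, 4, 1, 2])
        cv = loocv(trials, toy_baselines, "average_biased")
        assert cv.n_folds == len(trials)
        assert cv.fold_params.shape == (6, 1)
        assert cv.mean_heldout_rmse >= 0

    def test_faithful_pooled_rmse_tracks_response_sd(self):
        """Late-noise signature: the faithful model's pooled held-out RMSE
        approaches the observer's response SD (per target image)."""
        spec = DesignSpec(n_participants=1, n_blocks=16, alternation_start="precue", seed=5)
        # noise-free baselines so the faithful reference is exact
        sigma = {**flat_sigma(1.0), "baseline": 0.0}
        config = noiseless_config(sigma_late=sigma, seed=17)
        # mid-scale integer pleasures so edge clipping cannot bias the RMSE
        values = np.round(np.linspace(3, 7, spec.n_images))
        config.true_pleasure = {img: float(v) for img, v in zip(spec.image_ids(), values)}
        ds = simulate_dataset(spec, [config])
        trials = ds.trials_for("p01", "precue_1of4")
        assert len(trials) == 288
        cv = loocv(trials, ds.baselines, "faithful", mode="pooled")

        P, t, y = trial_arrays(trials, ds.baselines)
        pt = P[np.arange(len(P)), t - 1]
        variances = [np.var(y[pt == v], ddof=1) for v in np.unique(pt)]
        observed_sd = float(np.sqrt(np.mean(variances)))
        assert abs(cv.mean_heldout_rmse - observed_sd) / observed_sd < 0.10


def _cv(pid, model, condition, rmse):
    return CVResult(
        participant_id=pid, model=model, condition=condition,
        fold_params=np.empty((0, 0)), heldout_pred=np.empty(0),
        heldout_err=np.empty(0), mean_heldout_rmse=rmse, mean_params={},
    )


class TestCompareModels:
    def test_single_participant_winner_counts(self):
        table = compare_models([
            _cv("p01", "faithful", "precue_1of4", 1.0),
            _cv("p01", "averaging", "precue_1of4", 1.2),
        ])
        by_model = table.set_index("model")
        assert by_model.loc["faithful", "winner_count"] == 1
        assert by_model.loc["averaging", "winner_count"] == 0

    def test_ties_credit_all_models(self):
        table = compare_models([
            _cv("p01", "faithful", "precue_1of4", 1.0),
            _cv("p01", "averaging", "precue_1of4", 1.0 + 1e-12),
        ])
        assert table["winner_count"].tolist() == [1, 1]

    def test_sem_is_sample_sd_over_sqrt_n(self):
        rmses = [1.0, 1.3, 0.9]
        table = compare_models([
            _cv(f"p{i}", "faithful", "precue_1of4", r) for i, r in enumerate(rmses)
        ])
        expected = np.std(rmses, ddof=1) / np.sqrt(3)
        assert table.loc[0, "sem"] == pytest.approx(expected)
        assert table.loc[0, "mean_rmse"] == pytest.approx(np.mean(rmses))

    def test_missing_cell_rejected(self):
        with pytest.raises(ValidationError, match="missing"):
            compare_models([
                _cv("p01", "faithful", "precue_1of4", 1.0),
                _cv("p01", "averaging", "precue_1of4", 1.2),
                _cv("p02", "faithful", "precue_1of4", 1.1),
            ])


class TestFitAll:
    def test_small_grid_shape(self, small_faithful_dataset):
        fits, results = fit_all(
            small_faithful_dataset,
            models=["faithful", "average_biased", "faithful_averaging", "linear_combined"],
        )
        # 2 participants x (2 single models x 2 1of4 conditions
        #                   + 2 combined models x 2 combined conditions)
        assert len(fits) == 2 * (2 * 2 + 2 * 2)
        assert set(fits["condition"]) == {
            "precue_1of4", "postcue_1of4", "precue_combined", "postcue_combined"
        }
        assert "param:w" in fits.columns and "param:b" in fits.columns
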