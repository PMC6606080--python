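import numpy as np
import pandas as pd
import pytest
from scipy import stats

from histddm import (
    CohortSpec,
    FitConfig,
    ModelSpec,
    ParamSet,
    bin_trials,
    compare_group_aic,
    fit_model,
    generate_cohort,
    group_aic,
    history_shift,
    history_shift_from_fit,
    predicted_bin_probs,
    qmpe_loglik,
)
from histddm.qmpe import ContractError, DifficultyPooling, FitResult
from conftest import make_trials


HYBRID = ModelSpec("ddm_default", "hybrid")


class TestBinning:
    def test_default_pooling_gives_72_bins(self, drift_bias_observer):
        trials, _ = drift_bias_observer
        b = bin_trials(trials)
        assert b.n_difficulties == 3          # {0,3}, 9, 27  (81 excluded)
        assert b.n_cells == 12
        assert int(b.valid.sum()) == 72

    def test_counts_conserve_analyzed_trials(self, drift_bias_observer):
        trials, _ = drift_bias_observer
        b = bin_trials(trials)
        from histddm import history_valid
        hv = history_valid(trials)
        n_analyzed = (np.abs(hv["strength"]) != 81).sum()
        assert b.total == n_analyzed

    def test_ten_rts_fill_bins_1_2_2_2_2_1(self):
        rts = np.linspace(0.3, 1.2, 10)
        t = make_trials([1] * 11, rts=np.concatenate([[0.2], rts]),
                        stimuli=[1] * 11)
        b = bin_trials(t, difficulty_pooling=DifficultyPooling(exclude=(), pool=()))
        # all 10 history-valid trials share one cell (consistent, correct)
        filled = b.counts[b.counts > 0]
        assert filled.tolist() == [1, 2, 2, 2, 2, 1]

    def test_tied_rts_degenerate_cell_warns(self):
        t = make_trials([1] * 11, rts=[0.5] * 11, stimuli=[1] * 11)
        with pytest.warns(UserWarning, match="degenerate"):
            b = bin_trials(t, difficulty_pooling=DifficultyPooling(exclude=(), pool=()))
        assert b.total == 10

    def test_sparse_cell_collapses_to_median_split(self):
        choices = [1] * 4 + [-1] * 40
        t = make_trials(choices, stimuli=[1] * 44)
        with pytest.warns(UserWarning, match="median"):
            b = bin_trials(t, difficulty_pooling=DifficultyPooling(exclude=(), pool=()))
        assert b.total == 43
        assert set(b.n_bins) <= {1, 2, 6}

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            bin_trials(pd.DataFrame())


class TestLoglik:
    @pytest.mark.parametrize(
        "n,p,expected",
        [
            ([0, 0, 0], [0.2, 0.3, 0.5], 0.0),
            ([2], [0.5], np.log(0.25)),
            ([1, 1], [0.2, 0.8], np.log(0.16)),
        ],
    )
    def test_values(self, n, p, expected):
        assert qmpe_loglik(n, p) == pytest.approx(expected)

    def test_zero_probability_with_counts_rejected(self):
        with pytest.raises(ValueError):
            qmpe_loglik([1, 1], [0.0, 1.0])

    def test_probs_above_one_rejected(self):
        with pytest.raises(ValueError):
            qmpe_loglik([1, 1], [0.7, 0.7])


class TestPredictedProbs:
    def test_sums_to_one_with_floor(self, drift_bias_observer):
        trials, truth = drift_bias_observer
        b = bin_trials(trials)
        p = predicted_bin_probs(HYBRID, ParamSet(sv=0.5, v_bias=0.4), b,
                                n_rep=5, seed=1)
        assert p[b.valid].sum() == pytest.approx(1.0)
        assert np.all(p[b.valid] > 0)

    def test_unvisited_bins_get_floor(self, drift_bias_observer):
        trials, _ = drift_bias_observer
        b = bin_trials(trials)
        # enormous drift gain: errors essentially never occur, so error
        # cells survive only via the probability floor
        p = predicted_bin_probs(HYBRID, ParamSet(g=9.0, sv=0.0), b, n_rep=2, seed=2)
        floored = p[b.valid].min()
        assert floored > 0
        assert floored < 2e-5

    def test_monte_carlo_error_shrinks_with_reps(self, drift_bias_observer):
        trials, _ = drift_bias_observer
        b = bin_trials(trials)
        pp = ParamSet(sv=0.5, v_bias=0.4)
        spread = []
        for n_rep in (2, 8):
            ps = [predicted_bin_probs(HYBRID, pp, b, n_rep=n_rep, seed=s)
                  for s in (10, 11, 12)]
            spread.append(np.mean(np.std(ps, axis=0)))
        assert spread[1] < spread[0]

    def test_generating_model_self_consistency(self, drift_bias_observer):
        """A chi-square GOF of observed counts against probabilities
        predicted by the generating model itself should not reject."""
        trials, truth = drift_bias_observer
        b = bin_trials(trials)
        vb = float(truth[truth.param == "v_bias"].value.iloc[0])
        p = predicted_bin_probs(
            ModelSpec("ddm_default", "drift_bias"),
            ParamSet(a=1.0, g=1.0, ter=0.1, sv=0.5, v_bias=vb),
            b, n_rep=40, seed=3,
        )
        n_k = b.counts[b.valid].astype(float)
        p_k = p[b.valid]
        keep = n_k + b.total * p_k > 5
        chi2 = np.sum((n_k[keep] - b.total * p_k[keep]) ** 2 / (b.total * p_k[keep]))
        dof = keep.sum() - 1
        assert stats.chi2.sf(chi2, dof) > 0.01


class TestGroupAIC:
    def _fit(self, ll, n_free=5, tag=HYBRID):
        return FitResult(tag, ParamSet(), ll, n_free, {})

    def test_single_subject_formula(self):
        assert group_aic([self._fit(0.0, 5)]) == pytest.approx(10.0)

    def test_two_subject_arithmetic(self):
        fits = [self._fit(-100.0, 7), self._fit(-100.0, 7)]
        assert group_aic(fits) == pytest.approx(414.0)

    def test_better_model_negative_delta(self):
        good = [self._fit(-90.0)]
        base = [self._fit(-120.0)]
        cmp = compare_group_aic(good, base)
        assert cmp["delta_aic"] < 0
        assert cmp["decisive"]

    def test_mixed_specs_rejected(self):
        a = self._fit(-10.0)
        b = FitResult(ModelSpec("ddm_default", "ramp"), ParamSet(), -10.0, 6, {})
        with pytest.raises(ContractError):
            group_aic([a, b])


class TestHistoryShift:
    def test_equal_conditionals_zero_shift(self):
        p = ParamSet(z_bias=0.05)
        assert history_shift(p, p, "starting_point") == 0.0

    def test_repetition_orientation(self):
        plus = ParamSet(z_bias=0.05)    # z = 0.55a after a rightward choice
        minus = ParamSet(z_bias=-0.05)  # z = 0.45a after a leftward choice
        assert history_shift(plus, minus, "starting_point") > 0

    def test_coded_fit_equivalence(self):
        fit = FitResult(HYBRID, ParamSet(v_bias=0.15), -1.0, 7, {})
        assert history_shift_from_fit(fit, "drift_bias") == pytest.approx(0.3)

    def test_missing_condition_rejected(self):
        with pytest.raises(ContractError):
            history_shift(ParamSet(), None, "drift_bias")
        with pytest.raises(ValueError):
            history_shift(ParamSet(), ParamSet(), "leak")


class TestFitModel:
    def test_identical_seed_identical_result(self, drift_bias_observer):
        trials, _ = drift_bias_observer
        tiny = FitConfig(n_sessions=1, n_init=5, reps=(2, 3, 4), n_refine=1,
                         maxfev=20, maxfev_refine=10, seed=5)
        f1 = fit_model(HYBRID, trials, tiny)
        f2 = fit_model(HYBRID, trials, tiny)
        assert f1.loglik == f2.loglik
        assert f1.params == f2.params
        assert f1.stage_log["x"] == f2.stage_log["x"]

    def test_loglik_nonpositive_and_aic_consistent(self, drift_bias_observer):
        trials, _ = drift_bias_observer
        tiny = FitConfig(n_sessions=1, n_init=5, reps=(2, 3, 4), n_refine=1,
                         maxfev=20, maxfev_refine=10, seed=5)
        f = fit_model(HYBRID, trials, tiny)
        assert f.loglik <= 0
        assert f.aic_individual == pytest.approx(-2 * f.loglik + 2 * f.n_free)
        assert f.n_free == 7

    def test_drift_bias_sign_recovered_on_smoke_data(self):
        """Generating sign of the drift-history bias recovered across seeds."""
        cohort = CohortSpec(n_subjects=1, n_trials=500, master_seed=17,
                            param_distributions={"v_bias": ("constant", 0.5)})
        trials, _ = generate_cohort(cohort, ModelSpec("ddm_default", "drift_bias"))
        hits = 0
        n_runs = 5
        for k in range(n_runs):
            f = fit_model(ModelSpec("ddm_default", "drift_bias"), trials,
                          FitConfig.lean(seed=400 + k))
            hits += f.params.v_bias > 0
        assert hits >= n_runs - 1
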