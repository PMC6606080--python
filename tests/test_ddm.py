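import numpy as np
import pytest

from histddm import (
    ModelSpec,
    ParamSet,
    SimulationError,
    analytic_mean_dt,
    analytic_upper_prob,
    simulate_ddm,
)

NAIVE = ModelSpec("ddm_default", "none", "static")
BASE = ParamSet(a=1.0, g=1.0, ter=0.1, sv=0.0, sz=0.0)


@pytest.mark.parametrize(
    "v,a,z,expected",
    [
        (0.0, 1.0, 0.5, 0.5),
        (1.0, 1.0, 0.5, 0.7310585786),
        (1.0, 1.0, 0.62, 0.8218396892),
    ],
)
def test_analytic_upper_prob_values(v, a, z, expected):
    assert analytic_upper_prob(v, a, z) == pytest.approx(expected, abs=1e-5)


def test_analytic_upper_prob_domain():
    with pytest.raises(ValueError):
        analytic_upper_prob(1.0, 1.0, 1.5)


@pytest.mark.parametrize(
    "v,a,expected",
    [
        (0.0, 1.0, 0.25),
        (1.0, 1.0, 0.2310585786),
    ],
)
def test_analytic_mean_dt_values(v, a, expected):
    assert analytic_mean_dt(v, a) == pytest.approx(expected, abs=1e-6)


def test_analytic_mean_dt_continuous_at_zero_drift():
    assert abs(analytic_mean_dt(1e-6, 1.0) - analytic_mean_dt(0.0, 1.0)) < 1e-6


def test_simulator_matches_first_passage_oracles():
    res = simulate_ddm(NAIVE, BASE, m=[1.0], prev=[0.0], n_rep=50_000, seed=3)
    p_up = (res.choice == 1).mean()
    target_p = analytic_upper_prob(1.0, 1.0, 0.5)
    se_p = np.sqrt(target_p * (1 - target_p) / res.n_traces)
    assert abs(p_up - target_p) < 3 * se_p

    dt_sim = res.rt - BASE.ter
    se_t = dt_sim.std() / np.sqrt(res.n_traces)
    assert abs(dt_sim.mean() - analytic_mean_dt(1.0, 1.0)) < 3 * se_t


def test_zero_drift_symmetry():
    res = simulate_ddm(NAIVE, BASE, m=[0.0], prev=[0.0], n_rep=50_000, seed=4)
    p_up = (res.choice == 1).mean()
    assert abs(p_up - 0.5) < 3 * np.sqrt(0.25 / res.n_traces)


def test_identical_seed_bitwise_identical():
    a = simulate_ddm(NAIVE, BASE.replace(sv=0.5, sz=0.1), m=[1.0, -0.5], prev=[1.0, -1.0],
                     n_rep=500, seed=7)
    b = simulate_ddm(NAIVE, BASE.replace(sv=0.5, sz=0.1), m=[1.0, -0.5], prev=[1.0, -1.0],
                     n_rep=500, seed=7)
    assert np.array_equal(a.choice, b.choice)
    assert np.array_equal(a.rt, b.rt)
    assert np.array_equal(a.timed_out, b.timed_out)


def test_rt_respects_nondecision_time_and_timeout_cap():
    res = simulate_ddm(NAIVE, BASE.replace(ter=0.25), m=[0.0], prev=[0.0], n_rep=2000, seed=1)
    assert np.all(res.rt >= 0.25)
    cap = 0.25 + 300 * 0.005
    assert np.all(res.rt <= cap + 1e-12)
    assert np.all(res.rt[res.timed_out] == cap)


def test_infeasible_start_rejected_before_simulation():
    spec = ModelSpec("ddm_default", "starting_point")
    with pytest.raises(SimulationError):
        simulate_ddm(spec, BASE.replace(sz=0.3, z_bias=0.3), m=[1.0], prev=[1.0], n_rep=10, seed=0)


def test_bias_sign_flip_antisymmetry():
    """Flipping (m, prev) mirrors the choice fractions and RT distribution."""
    from scipy import stats

    spec = ModelSpec("ddm_default", "hybrid")
    p = BASE.replace(z_bias=0.1, v_bias=0.3)
    a = simulate_ddm(spec, p, m=[0.5], prev=[1.0], n_rep=30_000, seed=9)
    b = simulate_ddm(spec, p, m=[-0.5], prev=[-1.0], n_rep=30_000, seed=9)
    p_up_a = (a.choice == 1).mean()
    p_dn_b = (b.choice == -1).mean()
    assert abs(p_up_a - p_dn_b) < 3 * np.sqrt(0.5 / a.n_traces)
    assert stats.ks_2samp(a.rt, b.rt).statistic < 0.02


def _bias_consistent_by_quintile(res):
    """Fraction of +1 (bias-consistent, prev=+1) choices per RT quintile."""
    edges = np.quantile(res.rt, [0.2, 0.4, 0.6, 0.8])
    bins = np.searchsorted(edges, res.rt, side="left")
    return np.array([(res.choice[bins == b] == 1).mean() for b in range(5)])


def test_starting_point_bias_concentrates_in_fast_responses():
    spec = ModelSpec("ddm_default", "starting_point")
    res = simulate_ddm(spec, BASE.replace(sv=0.5, z_bias=0.18), m=[0.0], prev=[1.0],
                       n_rep=40_000, seed=11)
    frac = _bias_consistent_by_quintile(res)
    assert frac[0] > frac[4] + 0.05
    assert frac[0] > 0.5


def test_drift_bias_persists_into_slow_responses():
    spec = ModelSpec("ddm_default", "drift_bias")
    res = simulate_ddm(spec, BASE.replace(sv=0.5, v_bias=0.5), m=[0.0], prev=[1.0],
                       n_rep=40_000, seed=12)
    frac = _bias_consistent_by_quintile(res)
    assert np.all(frac > 0.5)


def test_ramp_bias_needs_time_to_act():
    """A pure ramp contributes nothing at t=0, so fast responses are unbiased."""
    spec = ModelSpec("ddm_default", "ramp")
    res = simulate_ddm(spec, BASE.replace(sv=0.5, s_ramp=2.5), m=[0.0], prev=[1.0],
                       n_rep=40_000, seed=13)
    frac = _bias_consistent_by_quintile(res)
    assert frac[4] > frac[0]
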