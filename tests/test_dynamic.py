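import numpy as np
import pytest
from scipy import stats

from histddm import (
    EvidenceTraces,
    ModelSpec,
    ParamSet,
    build_input_trace,
    psychophysical_kernel,
    simulate_ddm,
    simulate_dynamic_ddm,
    simulate_leaky,
)
from histddm.dynamic import (
    read_traces_csv,
    read_traces_hdf5,
    write_traces_csv,
    write_traces_hdf5,
)
from histddm.models import SpecError

DYN = ModelSpec("ddm_dynamic", "none", "static")
BASE = ParamSet(a=1.0, g=1.0, ter=0.1)


class TestInputTraces:
    def test_drop15_then_repeat5(self):
        raw = np.arange(1, 46, dtype=float)[None, :]
        tr = build_input_trace(raw)
        assert tr.n == 150
        assert np.all(tr.values[0, :5] == 16.0)
        assert np.all(tr.values[0, -5:] == 45.0)

    def test_constant_input_stays_constant(self):
        tr = build_input_trace(np.full((3, 45), 2.0))
        assert np.all(tr.values == 2.0)

    def test_pretrimmed_30_samples(self):
        tr = build_input_trace(np.ones((2, 30)), pre_trimmed=True)
        assert tr.values.shape == (2, 150)

    def test_wrong_sample_count_rejected(self):
        with pytest.raises(ValueError, match="45"):
            build_input_trace(np.ones((2, 40)))

    def test_csv_roundtrip(self, tmp_path):
        tr = EvidenceTraces(np.random.default_rng(0).normal(size=(4, 150)))
        p = tmp_path / "traces.csv"
        write_traces_csv(tr, p)
        back = read_traces_csv(p)
        assert np.allclose(back.values, tr.values)

    def test_hdf5_roundtrip(self, tmp_path):
        tr = EvidenceTraces(np.random.default_rng(1).normal(size=(4, 150)))
        p = tmp_path / "traces.h5"
        write_traces_hdf5({"s0": tr}, p, dt=0.005)
        back = read_traces_hdf5(p)
        assert np.allclose(back["s0"].values, tr.values)
        assert back["s0"].dt == 0.005


class TestDynamicDDM:
    def test_zero_traces_symmetric(self):
        M = np.zeros((1, 150))
        res = simulate_dynamic_ddm(DYN, BASE, M, [0.0], n_rep=30_000, seed=2)
        p_up = (res.choice == 1).mean()
        assert abs(p_up - 0.5) < 3 * np.sqrt(0.25 / res.n_traces)

    def test_constant_trace_matches_default_protocol_distributions(self):
        """With a constant input the dynamic protocol is the default-protocol
        DDM run during viewing; choice fractions and RT shapes must agree."""
        m = 1.0
        M = np.full((1, 150), m)
        dyn = simulate_dynamic_ddm(DYN, BASE, M, [0.0], n_rep=20_000, seed=3)
        dd = simulate_ddm(ModelSpec("ddm_default", "none"), BASE, [m], [0.0],
                          n_rep=20_000, seed=4, t_max=450)
        assert abs((dyn.choice == 1).mean() - (dd.choice == 1).mean()) < 0.012
        ks = stats.ks_2samp(dyn.rt[~dyn.timed_out], dd.rt[~dd.timed_out])
        assert ks.statistic < 0.02

    def test_trace_count_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            simulate_dynamic_ddm(DYN, BASE, np.zeros((3, 150)), [0.0], n_rep=10, seed=0)

    def test_drift_bias_above_half_in_every_quintile(self):
        spec = ModelSpec("ddm_dynamic", "drift_bias")
        M = np.zeros((1, 150))
        res = simulate_dynamic_ddm(spec, BASE.replace(v_bias=0.5), M, [1.0],
                                   n_rep=30_000, seed=5)
        edges = np.quantile(res.rt, [0.2, 0.4, 0.6, 0.8])
        bins = np.searchsorted(edges, res.rt, side="left")
        frac = np.array([(res.choice[bins == b] == 1).mean() for b in range(5)])
        assert np.all(frac > 0.5)


class TestLeaky:
    def test_lambda_zero_reduces_to_dynamic_ddm(self):
        spec = ModelSpec("leaky", "input_bias", "static")
        M = np.full((1, 150), 0.8)
        lk = simulate_leaky(spec, BASE.replace(lam=0.0, v_bias=0.3), M, [1.0],
                            n_rep=20_000, seed=6, engine="scalar")
        dspec = ModelSpec("ddm_dynamic", "drift_bias", "static")
        dy = simulate_dynamic_ddm(dspec, BASE.replace(v_bias=0.3), M, [1.0],
                                  n_rep=20_000, seed=7)
        assert abs((lk.choice == 1).mean() - (dy.choice == 1).mean()) < 0.015
        ks = stats.ks_2samp(lk.rt[~lk.timed_out], dy.rt[~dy.timed_out])
        assert ks.statistic < 0.025

    def test_dual_engine_symmetric_without_bias(self):
        spec = ModelSpec("leaky", "lambda_bias", "static")
        p = ParamSet(a=0.42, g=1.0, ter=0.1, lam=-2.5, lam_bias=0.0)
        M = np.zeros((1, 150))
        res = simulate_leaky(spec, p, M, [1.0], n_rep=30_000, seed=8,
                             lambda_sign_convention="negative_excites")
        p_up = (res.choice == 1).mean()
        assert abs(p_up - 0.5) < 3 * np.sqrt(0.25 / res.n_traces)

    def test_lambda_bias_requires_dual_engine(self):
        spec = ModelSpec("leaky", "lambda_bias", "static")
        with pytest.raises(SpecError, match="dual"):
            simulate_leaky(spec, ParamSet(a=0.42), np.zeros((1, 150)), [1.0],
                           engine="scalar")

    def test_antisymmetry_under_global_sign_flip(self):
        spec = ModelSpec("leaky", "input_bias", "static")
        p = BASE.replace(lam=-1.0, v_bias=0.3)
        M = np.random.default_rng(0).normal(0.5, 0.3, size=(5, 150))
        a = simulate_leaky(spec, p, M, np.ones(5), n_rep=8000, seed=9, engine="scalar")
        b = simulate_leaky(spec, p, -M, -np.ones(5), n_rep=8000, seed=9, engine="scalar")
        p_up_a = (a.choice == 1).mean()
        p_dn_b = (b.choice == -1).mean()
        assert abs(p_up_a - p_dn_b) < 3 * np.sqrt(0.5 / a.n_traces)
        ks = stats.ks_2samp(a.rt, b.rt)
        assert ks.statistic < 0.025

    def test_collapsing_bounds_shorten_mean_rt(self):
        static = ModelSpec("leaky", "input_bias", "static")
        coll = ModelSpec("leaky", "input_bias", "collapsing")
        p = BASE.replace(lam=-1.0, c_collapse=0.3)
        M = np.full((1, 150), 0.3)
        rs = simulate_leaky(static, p, M, [0.0], n_rep=15_000, seed=10, engine="scalar")
        rc = simulate_leaky(coll, p, M, [0.0], n_rep=15_000, seed=11, engine="scalar")
        assert rc.rt.mean() < rs.rt.mean()

    def test_effective_leak_sign_sets_temporal_weighting(self):
        """Self-excitatory dynamics weight early evidence (primacy): the
        choice-conditioned evidence kernel decays over the viewing period;
        leaky dynamics weight late evidence (recency): it rises."""
        import pandas as pd

        rng = np.random.default_rng(21)
        n = 4000
        M = rng.normal(0.0, 0.6, size=(n, 150))
        kernels = {}
        # bounds high enough that decisions fall mostly after stimulus
        # offset, so the kernel reflects the leak's temporal weighting
        # rather than early absorption
        for lam, a in ((+2.5, 2.0), (-4.0, 2.5)):
            spec = ModelSpec("leaky", "input_bias", "static")
            p = ParamSet(a=a, g=1.0, ter=0.1, lam=lam)
            res = simulate_leaky(spec, p, M, np.zeros(n), n_rep=1, seed=12, engine="scalar")
            trials = pd.DataFrame({
                "choice": res.choice, "strength": np.zeros(n),
            })
            kernels[lam] = psychophysical_kernel(M, trials, exclude_strength=None)
        early = slice(0, 50)
        late = slice(100, 150)
        k_primacy = kernels[+2.5]
        k_recency = kernels[-4.0]
        assert k_primacy[early].mean() > k_primacy[late].mean()
        assert k_recency[late].mean() > k_recency[early].mean()
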