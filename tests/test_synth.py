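"""Synthetic-data generators: determinism, closed-form limits, and
convergence of ensemble statistics to the nominal parameters."""

import numpy as np
import pytest
from scipy import stats

from kmburst.fitting import BoltzmannFit, HillFit, eval_boltzmann, eval_hill
from kmburst.synth import (
    ChannelSimSpec,
    NoiseSpec,
    StepProtocol,
    gen_action_current_train,
    gen_dose_response,
    gen_ikm_sweeps,
    gen_single_channel_iv,
    gen_single_channel_trace,
)

CTRL = BoltzmannFit(g_max=2.11, v_half=-26.8, q=1.86)
NGEN = BoltzmannFit(g_max=2.11, v_half=-44.3, q=2.01)
NOISELESS = NoiseSpec(trace_noise_sd=0.0, cell_cv=0.0, seed=0)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        for gen in (
            lambda s: gen_dose_response(HillFit(100, 9.8, 1.0), [1, 3, 10, 30, 100],
                                        NoiseSpec(seed=s), n_cells=5)["response_pct"].to_numpy(),
            lambda s: gen_single_channel_trace(
                ChannelSimSpec(open_probability=0.2, duration_ms=2000.0),
                NoiseSpec(seed=s)).values_pA,
            lambda s: gen_action_current_train(2.0, 20.0, noise=NoiseSpec(seed=s)).values_pA,
        ):
            a, b, c = gen(7), gen(7), gen(8)
            np.testing.assert_array_equal(a, b)
            assert not np.array_equal(a, c)

    def test_generators_use_independent_streams(self):
        # same seed, different generators -> uncorrelated noise
        t1 = gen_action_current_train(0.0, 20.0, noise=NoiseSpec(seed=1))
        t2 = gen_single_channel_trace(
            ChannelSimSpec(open_probability=0.0, duration_ms=20000.0),
            NoiseSpec(trace_noise_sd=1.0, seed=1), sample_interval_ms=0.2)
        r = np.corrcoef(t1.values_pA[:50000], t2.values_pA[:50000])[0, 1]
        assert abs(r) < 0.02


class TestIkmSweeps:
    def test_midpoint_step_gives_half_maximal_conductance(self):
        proto = StepProtocol(step_levels_mV=(-26.8,), step_duration_ms=2000.0)
        ss = gen_ikm_sweeps(proto, CTRL, noise=NOISELESS, v_half_jitter_sd=0.0)
        i_end = ss.end_of_pulse()["i_end_pA"].iloc[0]
        g = i_end / (-26.8 + 91.0)
        assert g == pytest.approx(CTRL.g_max / 2, rel=1e-2)

    def test_activation_shift_increases_current(self):
        proto = StepProtocol(step_levels_mV=(-10.0,))
        kw = dict(noise=NOISELESS, v_half_jitter_sd=0.0)
        i_ctrl = gen_ikm_sweeps(proto, CTRL, **kw).end_of_pulse()["i_end_pA"].iloc[0]
        i_ngen = gen_ikm_sweeps(proto, NGEN, **kw).end_of_pulse()["i_end_pA"].iloc[0]
        assert i_ngen > i_ctrl

    def test_zero_relaxation_time_gives_instant_step(self):
        proto = StepProtocol(step_levels_mV=(-10.0,), step_duration_ms=100.0)
        ss = gen_ikm_sweeps(proto, CTRL, tau_relax_ms=0.0, noise=NOISELESS,
                            v_half_jitter_sd=0.0)
        vals = ss.data["value_pA"].to_numpy()
        i_ss = CTRL.g_max * eval_boltzmann(CTRL, -10.0) * (-10.0 + 91.0)
        np.testing.assert_allclose(vals, i_ss, rtol=1e-12)

    def test_rejects_non_finite_parameters(self):
        with pytest.raises(ValueError, match="non-finite"):
            gen_ikm_sweeps(StepProtocol(), CTRL, tau_relax_ms=float("nan"))

    def test_rejects_empty_protocol(self):
        with pytest.raises(ValueError):
            StepProtocol(step_levels_mV=())


class TestDoseResponse:
    def test_noiseless_table_matches_hill_after_renormalization(self):
        hill = HillFit(100.0, 10.0, 1.0)
        conc = [1.0, 10.0, 30.0, 300.0]
        table = gen_dose_response(hill, conc, NOISELESS, n_cells=3)
        top = eval_hill(hill, 300.0)
        for c in conc:
            got = table.loc[table["conc_uM"] == c, "response_pct"].to_numpy()
            np.testing.assert_allclose(got, eval_hill(hill, c) * 100.0 / top, rtol=1e-12)
        # direct evaluation: 100*30/(10+30) = 75 before renormalization
        assert eval_hill(hill, 30.0) == pytest.approx(75.0)

    def test_mean_responses_monotone_over_reported_range(self):
        table = gen_dose_response(HillFit(100.0, 9.8, 1.0),
                                  [0.1, 1, 3, 10, 30, 100, 300],
                                  NoiseSpec(seed=4), n_cells=200)
        means = table.groupby("conc_uM")["response_pct"].mean().sort_index()
        assert np.all(np.diff(means.to_numpy()) > 0)

    def test_top_concentration_mean_is_100(self):
        table = gen_dose_response(HillFit(100.0, 9.8, 1.0), [1, 10, 300],
                                  NoiseSpec(seed=2), n_cells=50)
        assert table.loc[table["conc_uM"] == 300, "response_pct"].mean() == pytest.approx(100.0)

    def test_rejects_empty_concentrations(self):
        with pytest.raises(ValueError):
            gen_dose_response(HillFit(100, 9.8, 1), [], NoiseSpec(seed=0))


class TestSingleChannel:
    def test_closed_channel_is_baseline_noise(self):
        tr = gen_single_channel_trace(
            ChannelSimSpec(open_probability=0.0, duration_ms=5000.0),
            NoiseSpec(trace_noise_sd=0.5, seed=0))
        assert abs(np.mean(tr.values_pA)) < 0.05
        assert np.std(tr.values_pA) == pytest.approx(0.5, rel=0.05)

    def test_occupancy_converges_to_po(self):
        spec = ChannelSimSpec(n_channels=1, open_probability=0.211,
                              mean_open_time_ms=2.0, duration_ms=60000.0)
        tr = gen_single_channel_trace(spec, NoiseSpec(seed=9))
        occ = tr.meta["occupancy"]
        frac = occ.mean()
        n_cycles = 60000.0 / (2.0 + spec.closed_time_ms)
        se = np.sqrt(0.211 * 0.789 / n_cycles)
        assert abs(frac - 0.211) < 3 * se

    def test_multichannel_occupancy_is_binomial(self):
        spec = ChannelSimSpec(n_channels=3, open_probability=0.5,
                              mean_open_time_ms=5.0, duration_ms=60000.0)
        tr = gen_single_channel_trace(spec, NoiseSpec(seed=3))
        occ = tr.meta["occupancy"][:: 500]  # ~50 ms apart: near-independent
        counts = np.bincount(occ, minlength=4)
        expected = stats.binom.pmf(np.arange(4), 3, 0.5) * counts.sum()
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=3)

    def test_unresolvable_dwells_rejected(self):
        spec = ChannelSimSpec(open_probability=0.5, mean_open_time_ms=0.2,
                              duration_ms=1000.0)
        with pytest.raises(ValueError, match="unresolvable"):
            gen_single_channel_trace(spec, NoiseSpec(seed=0), sample_interval_ms=0.1)

    def test_inconsistent_po_and_dwells_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ChannelSimSpec(open_probability=0.5, mean_open_time_ms=2.0,
                           mean_closed_time_ms=1.0)


class TestActionCurrentTrain:
    def test_zero_rate_flat_baseline(self):
        tr = gen_action_current_train(0.0, 20.0, noise=NoiseSpec(seed=0))
        assert tr.meta["event_times_s"].size == 0
        assert np.abs(tr.values_pA).max() < 6.0  # noise only

    def test_event_count_near_expectation(self):
        tr = gen_action_current_train(1.21, 100.0, noise=NoiseSpec(seed=3))
        n = tr.meta["event_times_s"].size
        assert abs(n - 121) <= 3 * np.sqrt(121)

    def test_intervals_are_exponential(self):
        tr = gen_action_current_train(10.0, 60.0, noise=NoiseSpec(seed=5))
        iei = np.diff(tr.meta["event_times_s"])
        # onsets are Poisson; peak times shift them by a constant
        p = stats.kstest(iei, "expon", args=(0, 0.1)).pvalue
        assert p > 0.01

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            gen_action_current_train(-1.0, 10.0)


class TestSingleChannelIV:
    def test_zero_at_reversal(self):
        df = gen_single_channel_iv(180.0, 0.0, [0.0, 60.0], NOISELESS)
        assert df.loc[df["step_mV"] == 0.0, "amp_pA"].iloc[0] == 0.0

    def test_ohms_law_at_plus_60(self):
        df = gen_single_channel_iv(180.0, 0.0, [60.0, -60.0], NOISELESS)
        assert df.loc[df["step_mV"] == 60.0, "amp_pA"].iloc[0] == pytest.approx(10.8)

    def test_reported_conductance_pair_nearly_indistinguishable(self):
        pots = np.arange(-60.0, 61.0, 20.0)
        a = gen_single_channel_iv(178.0, 0.0, pots, NOISELESS)["amp_pA"]
        b = gen_single_channel_iv(180.0, 0.0, pots, NOISELESS)["amp_pA"]
        assert np.abs(a.to_numpy() - b.to_numpy()).max() < 0.15

    def test_too_few_potentials_rejected(self):
        with pytest.raises(ValueError):
            gen_single_channel_iv(180.0, 0.0, [10.0], NOISELESS)
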