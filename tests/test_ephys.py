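"""Electrophysiology metrics: spike detection, AP counts, charge transfer."""

import numpy as np
import pytest

import effluxion as ex
from effluxion.ephys import (
    EphysError,
    SweepSet,
    ap_protocol_count,
    charge_timecourse,
    charge_transfer,
    detect_aps,
    percent_of_control,
    read_sweeps_csv,
    write_sweeps_csv,
)
from effluxion.simulate import substream, vc_analytic_charge

DT = 2e-4


def spike_trace(times, n_samples=5000, dt=DT, rest=-65.0, peak=30.0, sigma=5e-4):
    t = dt * np.arange(n_samples)
    v = np.full(n_samples, rest)
    for te in times:
        v += (peak - rest) * np.exp(-0.5 * ((t - te) / sigma) ** 2)
    return v


class TestDetectAps:
    def test_flat_trace_has_no_spikes(self):
        assert detect_aps(np.full(5000, -65.0), DT).size == 0

    def test_three_constructed_spikes(self):
        truth = [0.1, 0.35, 0.8]
        found = detect_aps(spike_trace(truth), DT)
        assert found.size == 3
        np.testing.assert_allclose(found, truth, atol=3e-3)

    def test_refractory_merges_double_crossings(self):
        # two crossings 1 ms apart count once with a 2 ms refractory period
        v = spike_trace([0.100, 0.101])
        assert detect_aps(v, DT, refractory_s=0.002).size == 1

    def test_translation_and_offset_invariance(self):
        truth = [0.2, 0.5]
        base = detect_aps(spike_trace(truth), DT)
        shifted = detect_aps(spike_trace([t + 0.1 for t in truth]), DT)
        np.testing.assert_allclose(shifted - 0.1, base, atol=1e-9)
        lifted = detect_aps(spike_trace(truth) + 5.0, DT, threshold_mv=5.0)
        np.testing.assert_allclose(lifted, base, atol=1e-9)

    def test_nonfinite_samples_error(self):
        v = np.full(100, -65.0)
        v[50] = np.nan
        with pytest.raises(EphysError):
            detect_aps(v, DT)

    def test_noisy_simulated_trains_match_generator_events(self):
        """>=99% event-level agreement with the generator's ground truth at
        2 mV noise, over 200 random sweeps."""
        cfg = ex.CCSimConfig(noise_sigma_mV=2.0)
        total, matched = 0, 0
        for rep in range(34):  # 34 cells x 6 sweeps > 200 traces
            ss = ex.simulate_cc_sweeps(cfg, 0.0, rng=substream(3, "det", str(rep)))
            for sweep, truth in zip(ss.sweeps, ss.ground_truth["events"]):
                found = detect_aps(sweep, ss.dt)
                total += truth.size
                for te in truth:
                    if found.size and np.min(np.abs(found - te)) < 2e-3:
                        matched += 1
        assert total >= 200
        assert matched / total >= 0.99


class TestApProtocolCount:
    def make_set(self, sweeps):
        return SweepSet(
            mode="cc", dt=DT, sweeps=np.asarray(sweeps), step_window=(0.1, 0.9)
        )

    def test_flat_traces_count_zero(self):
        ss = self.make_set([np.full(5000, -65.0)] * 6)
        assert ap_protocol_count(ss).total == 0

    def test_generator_counts_sum_to_42(self):
        ss = ex.simulate_cc_sweeps(ex.CCSimConfig(noise_sigma_mV=0.0), 0.0)
        res = ap_protocol_count(ss)
        assert res.per_sweep_counts.tolist() == [2, 4, 6, 8, 10, 12]
        assert res.total == 42

    def test_full_drug_suppression_silences_all_sweeps(self):
        # saturating concentration: no action potentials left
        ss = ex.simulate_cc_sweeps(ex.CCSimConfig(noise_sigma_mV=0.0), 1e4)
        assert ap_protocol_count(ss).total == 0

    def test_counting_excludes_post_step_rebound(self):
        v = spike_trace([0.95])  # after the 0.1-0.9 s step window
        ss = self.make_set([v] + [np.full(5000, -65.0)] * 5)
        assert ap_protocol_count(ss).total == 0
        assert ap_protocol_count(ss, include_post_step=True).total == 1

    def test_wrong_sweep_count_errors_without_override(self):
        ss = self.make_set([np.full(5000, -65.0)] * 4)
        with pytest.raises(EphysError):
            ap_protocol_count(ss)
        assert ap_protocol_count(ss, allow_any_sweep_count=True).total == 0


class TestChargeTransfer:
    def test_rectangular_pulse(self):
        dt = 2e-5
        i = np.zeros(3000)
        i[round(0.01 / dt) : round(0.04 / dt) + 1] = -1000.0  # 30 ms at -1000 pA
        q = charge_transfer(i, dt, (0.01, 0.04), baseline_policy="none")
        assert abs(q) == pytest.approx(30.0, rel=1e-6)

    def test_zero_trace(self):
        assert charge_transfer(np.zeros(1000), 1e-4, (0.01, 0.05), "none") == 0.0

    def test_double_exponential_matches_closed_form(self):
        cfg = ex.VCSimConfig()
        ss = ex.simulate_vc_sweeps(cfg, 0.0)
        q = charge_transfer(ss.sweeps[0], ss.dt, ss.step_window, "none")
        assert q == pytest.approx(vc_analytic_charge(cfg), rel=1e-3)

    def test_linearity_in_the_signal(self, rng):
        dt = 1e-4
        i1 = rng.normal(size=2000)
        i2 = rng.normal(size=2000)
        w = (0.02, 0.18)
        q = lambda tr: charge_transfer(tr, dt, w, "none")
        assert q(3.0 * i1 - 2.5 * i2) == pytest.approx(3.0 * q(i1) - 2.5 * q(i2))

    def test_quadrature_converges_when_halving_dt(self):
        coarse = ex.VCSimConfig(dt_s=4e-5)
        fine = ex.VCSimConfig(dt_s=2e-5)
        qc = charge_transfer(
            ex.simulate_vc_sweeps(coarse, 0.0).sweeps[0], coarse.dt_s,
            (coarse.pre_s, coarse.pre_s + coarse.step_s), "none",
        )
        qf = charge_transfer(
            ex.simulate_vc_sweeps(fine, 0.0).sweeps[0], fine.dt_s,
            (fine.pre_s, fine.pre_s + fine.step_s), "none",
        )
        assert abs(qc / qf - 1) < 0.005

    def test_baseline_subtraction_removes_holding_current(self):
        dt = 2e-5
        i = np.full(3000, -120.0)  # holding offset
        i[round(0.01 / dt) : round(0.04 / dt) + 1] -= 1000.0
        q = charge_transfer(i, dt, (0.01, 0.04), baseline_policy="pre")
        assert abs(q) == pytest.approx(30.0, rel=1e-6)

    def test_window_outside_sweep_errors(self):
        with pytest.raises(EphysError):
            charge_transfer(np.zeros(100), 1e-4, (0.0, 1.0), "none")


class TestPercentOfControl:
    def test_all_equal_sweeps_are_100(self):
        pct = percent_of_control([-30.0] * 5, np.arange(5.0), (0.0, 2.5))
        np.testing.assert_allclose(pct, 100.0)

    def test_hand_arithmetic(self):
        pct = percent_of_control([-60.0, -60.0, -20.0], [0, 1, 2], (0.0, 1.5))
        np.testing.assert_allclose(pct, [100.0, 100.0, 100.0 / 3])

    def test_control_sweeps_average_exactly_100(self, rng):
        q = -rng.uniform(10, 60, size=12)
        t = np.arange(12.0)
        pct = percent_of_control(q, t, (0.0, 6.0))
        assert pct[:6].mean() == pytest.approx(100.0)

    def test_simulated_concentration_plateau(self):
        """3 uM with generator IC50 0.5 uM (nH 1): plateau at 1/7 of control."""
        cfg = ex.VCSimConfig(n_sweeps=4)
        ctl = ex.simulate_vc_sweeps(cfg, 0.0)
        drug = ex.simulate_vc_sweeps(cfg, 3.0)
        q = np.concatenate([charge_timecourse(ctl).q_ca, charge_timecourse(drug).q_ca])
        t = 15.0 * np.arange(8.0)
        pct = percent_of_control(q, t, (0.0, 59.0))
        np.testing.assert_allclose(pct[4:], 100.0 / 7, rtol=1e-6)

    def test_zero_control_mean_errors(self):
        with pytest.raises(EphysError):
            percent_of_control([0.0, 5.0], [0, 1], (0.0, 0.5))


def test_sweeps_csv_round_trip(tmp_path):
    ss = ex.simulate_cc_sweeps(ex.CCSimConfig(noise_sigma_mV=0.5), 1.0,
                               rng=substream(5, "io"), cell_id="cellA")
    write_sweeps_csv(ss, tmp_path / "s.csv", tmp_path / "s.yaml")
    back = read_sweeps_csv(tmp_path / "s.csv", tmp_path / "s.yaml")
    assert back.mode == "cc" and back.cell_id == "cellA"
    assert back.step_window == ss.step_window
    np.testing.assert_allclose(back.sweeps, ss.sweeps, rtol=1e-12)
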