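"""Synthetic-data generators: determinism, conservation, ground-truth recovery."""

import math

import numpy as np
import pytest

import effluxion as ex
from effluxion.ephys import ap_protocol_count, charge_timecourse, detect_aps
from effluxion.release import summarize, write_fractions_csv
from effluxion.simulate import SimConfigError, substream, vc_analytic_charge


class TestSuperfusion:
    def test_deterministic_given_seed(self, tmp_path):
        cfg = ex.ReleaseSimConfig()
        a = ex.simulate_superfusion(cfg, concentration_uM=1.0, rng=substream(9, "x"))
        b = ex.simulate_superfusion(cfg, concentration_uM=1.0, rng=substream(9, "x"))
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_fractions_csv([a], pa)
        write_fractions_csv([b], pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_conservation_exact_without_noise(self, quiet_release_cfg):
        fs = ex.simulate_superfusion(quiet_release_cfg, concentration_uM=3.0)
        total = fs.counts.sum() + fs.residual
        assert total == pytest.approx(quiet_release_cfg.initial_content_cpm, rel=1e-12)

    def test_conservation_in_expectation_with_noise(self):
        """Mean of (counts + residual) over 500 seeds within 3 SE of the
        initial content (Poisson noise only redistributes counts)."""
        cfg = ex.ReleaseSimConfig(poisson_noise=True)
        totals = []
        released = None
        for s in range(500):
            fs = ex.simulate_superfusion(cfg, rng=substream(s, "cons"))
            totals.append(fs.counts.sum() + fs.residual)
            released = released or cfg.initial_content_cpm - fs.residual
        se = math.sqrt(released / 500)  # Var(sum of Poisson counts) = expected sum
        assert abs(np.mean(totals) - cfg.initial_content_cpm) <= 3 * se

    def test_pure_depletion_has_constant_fractional_outflow(self):
        cfg = ex.ReleaseSimConfig(poisson_noise=False, evoked_fraction=0.0)
        fs = ex.simulate_superfusion(cfg)
        f = ex.fractional_outflow(fs)
        expected = 1 - math.exp(-cfg.basal_rate_per_min * cfg.fraction_len_min)
        np.testing.assert_allclose(f, expected, rtol=1e-9)

    def test_full_suppression_abolishes_s2_only(self, quiet_release_cfg):
        # saturating drug between the stimuli: S1 intact, S2 at zero
        fs = ex.simulate_superfusion(quiet_release_cfg, concentration_uM=1e6)
        summ = summarize(fs, quiet_release_cfg.protocol())
        assert summ.s_values[0] > 1.0
        # zero up to the second-order curvature of the exponential basal decay
        assert summ.s_values[1] == pytest.approx(0.0, abs=1e-3)

    def test_stationary_ratio_matches_independent_recursion(self, quiet_release_cfg):
        """S2/S1 from the pipeline agrees within 1% with a direct independent
        evaluation of the depletion recursion."""
        cfg = quiet_release_cfg
        fs = ex.simulate_superfusion(cfg)
        summ = summarize(fs, cfg.protocol())
        # independent forward recursion of the expected kinetics
        dtf = cfg.fraction_len_min
        per_frac = 1 - math.exp(-cfg.basal_rate_per_min * dtf)
        q = cfg.initial_content_cpm
        s_pct = {}
        pending = {}
        stim_idx = {int((t - cfg.start_min) / dtf): t for t in cfg.stim_times}
        for i in range(cfg.n_fractions):
            basal = q * per_frac
            evoked = pending.pop(i, 0.0)
            if i in stim_idx:
                e_tot = cfg.evoked_fraction * q
                s_pct[i] = 100 * e_tot / q
                evoked += cfg.window_split[0] * e_tot
                pending[i + 1] = cfg.window_split[1] * e_tot
            q -= basal + evoked
        s1, s2 = s_pct.values()
        assert summ.s2_over_s1 == pytest.approx(s2 / s1, rel=0.01)

    def test_impossible_release_rejected(self):
        cfg = ex.ReleaseSimConfig(basal_rate_per_min=2.0, evoked_fraction=0.9)
        with pytest.raises(SimConfigError):
            ex.simulate_superfusion(cfg)


class TestUptakePlate:
    def test_zero_cv_gives_identical_wells(self):
        cfg = ex.UptakeSimConfig(cv=0.0, condition_effects={"solvent": 0.0, "d": 0.3})
        plate = ex.simulate_uptake_plate(cfg)
        for cond in ("solvent", "d"):
            vals = plate.condition_values(cond)
            assert np.unique(vals).size == 1

    def test_condition_mean_arithmetic(self):
        cfg = ex.UptakeSimConfig(
            cv=0.0,
            applied_cpm=287.3e3,
            control_mean_fraction=11.75e3 / 287.3e3,
            condition_effects={"solvent": 0.0, "d22_10uM": 0.793},
        )
        plate = ex.simulate_uptake_plate(cfg)
        assert plate.condition_values("d22_10uM").mean() == pytest.approx(
            11.75e3 * 0.207, rel=1e-9
        )

    def test_neuron_free_plate_reproduces_neuronal_share(self):
        from effluxion.uptake import condition_summary, neuronal_fraction

        full = ex.UptakeSimConfig(cv=0.0, control_mean_fraction=11.75e3 / 287.3e3)
        free = ex.UptakeSimConfig(cv=0.0, control_mean_fraction=0.48e3 / 287.3e3)
        m_full = condition_summary(ex.simulate_uptake_plate(full), "solvent").mean
        m_free = condition_summary(ex.simulate_uptake_plate(free), "solvent").mean
        assert neuronal_fraction(m_full, m_free) == pytest.approx(95.91, abs=0.01)

    def test_lognormal_cv_calibration(self):
        cfg = ex.UptakeSimConfig(cv=0.15, n_wells=4000,
                                 condition_effects={"solvent": 0.0})
        vals = ex.simulate_uptake_plate(cfg, rng=substream(2, "cv")).condition_values(
            "solvent"
        )
        assert vals.mean() == pytest.approx(cfg.control_mean_cpm, rel=0.02)
        assert vals.std() / vals.mean() == pytest.approx(0.15, rel=0.1)

    def test_invalid_inhibition_rejected(self):
        with pytest.raises(SimConfigError):
            ex.simulate_uptake_plate(
                ex.UptakeSimConfig(condition_effects={"bad": 1.4})
            )


class TestCCSweeps:
    def test_noise_free_detector_recovers_event_list_exactly(self):
        cfg = ex.CCSimConfig(noise_sigma_mV=0.0)
        ss = ex.simulate_cc_sweeps(cfg, 0.5, rng=substream(4, "cc"))
        for sweep, truth in zip(ss.sweeps, ss.ground_truth["events"]):
            found = detect_aps(sweep, ss.dt)
            assert found.size == truth.size
            np.testing.assert_allclose(found, truth, atol=2e-3)

    def test_baseline_total_count(self):
        ss = ex.simulate_cc_sweeps(ex.CCSimConfig(noise_sigma_mV=0.0), 0.0)
        assert ap_protocol_count(ss).total == 42

    def test_saturating_drug_silences(self):
        ss = ex.simulate_cc_sweeps(ex.CCSimConfig(), 1e5)
        assert all(e.size == 0 for e in ss.ground_truth["events"])


class TestVCSweeps:
    def test_charge_matches_analytic_integral(self):
        cfg = ex.VCSimConfig()
        ss = ex.simulate_vc_sweeps(cfg, 0.0)
        res = charge_timecourse(ss, window_offset_s=0.0, baseline_policy="none")
        assert res.q_ca[0] == pytest.approx(vc_analytic_charge(cfg), rel=1e-3)
        assert ss.ground_truth["q_pC"][0] == pytest.approx(vc_analytic_charge(cfg))

    def test_full_suppression_gives_zero_charge(self):
        cfg = ex.VCSimConfig()
        ss = ex.simulate_vc_sweeps(cfg, 1e7)
        res = charge_timecourse(ss, window_offset_s=0.0, baseline_policy="none")
        # Hill inhibition approaches 1 only asymptotically: |q| < 1e-5 pC left
        assert res.q_ca[0] == pytest.approx(0.0, abs=1e-5)

    def test_monotone_suppression_with_concentration(self):
        cfg = ex.VCSimConfig()
        qs = [
            abs(charge_timecourse(ex.simulate_vc_sweeps(cfg, c)).q_ca[0])
            for c in (0.0, 0.2, 0.5, 1.0, 3.0, 10.0)
        ]
        assert all(a >= b for a, b in zip(qs, qs[1:]))
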