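"""Feedback analysis: baseline, resistance, drop detection, viability, control."""

import logging
import math
from dataclasses import replace

import numpy as np
import pytest

from cytoclamp import analysis, protocol
from cytoclamp.analysis import (
    calibrate_access_pair,
    classify_viability,
    control_loop,
    detect_injection_drops,
    estimate_resistance,
    zero_baseline,
)
from cytoclamp.circuit import SwitchState
from cytoclamp.core import CurrentTrace
from cytoclamp.protocol import NoiseModel, injection_script, run_experiment


def flat_trace(level_na, n=5000, dt=0.1, noise_sd=0.0, seed=0, command=-70.0):
    rng = np.random.default_rng(seed)
    cur = np.full(n, float(level_na))
    if noise_sd > 0:
        cur = cur + rng.normal(0, noise_sd, n)
    return CurrentTrace(dt, cur, np.full(n, float(command)))


class TestZeroBaseline:
    def test_constant_offset_removed_exactly(self):
        tr = flat_trace(3.0)
        out = zero_baseline(tr, window_ms=50.0)
        assert np.allclose(out.current_na, 0.0)

    def test_already_zero_unchanged(self):
        tr = flat_trace(0.0)
        assert np.array_equal(zero_baseline(tr, 50.0).current_na, tr.current_na)

    def test_window_over_command_step_rejected(self):
        cmd = np.full(1000, -70.0)
        cmd[300:] = -50.0
        tr = CurrentTrace(0.1, np.zeros(1000), cmd)
        with pytest.raises(ValueError, match="command step"):
            zero_baseline(tr, window_ms=50.0)

    def test_noisy_offset_residual_obeys_clt_bound(self):
        sd, n_win = 0.5, 2000
        tr = flat_trace(3.0, n=5000, noise_sd=sd, seed=42)
        out = zero_baseline(tr, window_ms=n_win * 0.1)
        residual = np.mean(out.current_na[:n_win]) + (
            np.mean(tr.current_na[:n_win]) - 3.0
        ) * 0  # the window mean is removed exactly
        assert abs(np.mean(out.current_na[:n_win])) < 1e-12
        # the *global* bias is bounded by the CLT error of the window mean
        assert abs(np.mean(out.current_na) ) < 4 * sd / math.sqrt(n_win) + 4 * sd / math.sqrt(5000)


class TestEstimateResistance:
    @staticmethod
    def pulse_trace(r_mohm, amp_mv=20.0, n_pulses=4, dt=0.1, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        period, width = 500, 100  # samples: 50 ms period, 10 ms pulse
        n = period * n_pulses
        cmd = np.zeros(n)
        for k in range(n_pulses):
            cmd[k * period + (period - width) : (k + 1) * period] = amp_mv
        cur = cmd / r_mohm
        if noise_sd > 0:
            cur = cur + rng.normal(0, noise_sd, n)
        return CurrentTrace(dt, cur, cmd)

    def test_ohms_law_example(self):
        # 20 mV pulse with 4 nA steady response -> 5 MOhm
        tr = self.pulse_trace(5.0)
        est = estimate_resistance(tr, pulse_amplitude_mv=20.0)
        assert est.megaohms == pytest.approx(5.0, rel=1e-9)
        assert not est.lower_bound

    def test_sealed_stage_recovered_within_two_percent(self, shsy5y):
        from cytoclamp.circuit import simulate_voltage_clamp
        from cytoclamp.protocol import Stage, TestPulse, stage_parameters

        sp = stage_parameters(Stage.SEALED, shsy5y.params)
        tr = simulate_voltage_clamp(sp, TestPulse().protocol(300.0), dt_ms=0.1)
        est = estimate_resistance(
            CurrentTrace(0.1, tr.current_na, tr.command_mv), pulse_amplitude_mv=20.0
        )
        assert est.megaohms == pytest.approx(1000.0, rel=0.02)

    def test_zero_amplitude_pulse_rejected(self):
        with pytest.raises(ValueError):
            estimate_resistance(self.pulse_trace(5.0), pulse_amplitude_mv=0.0)

    def test_no_pulse_rejected(self):
        with pytest.raises(ValueError, match="no test pulse"):
            estimate_resistance(flat_trace(0.0))

    def test_noise_dominated_measurement_reports_lower_bound(self):
        # 100 GOhm: 0.0002 nA response buried in 0.2 nA noise
        tr = self.pulse_trace(1e5, noise_sd=0.2, seed=3)
        est = estimate_resistance(tr, pulse_amplitude_mv=20.0)
        assert est.lower_bound
        assert est.megaohms > 0


class TestDetectInjectionDrops:
    def test_single_noise_free_event_recovered(self, shsy5y):
        s = injection_script(
            1, seed=0, noise=NoiseModel(gaussian_sd_na=0.0, event_sd_na=0.0)
        )
        exp = run_experiment(s, shsy5y.params)
        det = detect_injection_drops(exp.holding_trace())
        assert len(det.events) == 1
        t_true, a_true = exp.events_true[0]
        assert det.events[0].time_ms == pytest.approx(t_true, abs=1.0)
        assert det.events[0].amplitude_na == pytest.approx(a_true, abs=0.01)
        assert det.accumulated_drop_na == pytest.approx(-11.9, abs=0.01)
        assert det.success

    def test_flat_noise_only_trace_yields_no_events(self):
        det = detect_injection_drops(flat_trace(0.0, noise_sd=0.05, seed=1))
        assert det.events == ()
        assert not det.success

    def test_threshold_arithmetic_on_partial_drops(self, shsy5y):
        params = shsy5y.params
        noise = NoiseModel(gaussian_sd_na=0.0, event_sd_na=0.0)
        # two -6 nA events accumulate past the -11 nA threshold
        amp_two = -6.0
        s2 = injection_script(2, seed=0, noise=noise, amplitude_na=amp_two)
        det2 = detect_injection_drops(
            run_experiment(s2, params).holding_trace()
        )
        assert len(det2.events) == 2
        assert det2.accumulated_drop_na == pytest.approx(-12.0, abs=0.01)
        assert det2.success
        # a single -6 nA event does not
        s1 = injection_script(1, seed=0, noise=noise, amplitude_na=amp_two)
        det1 = detect_injection_drops(run_experiment(s1, params).holding_trace())
        assert det1.accumulated_drop_na == pytest.approx(-6.0, abs=0.01)
        assert not det1.success

    def test_varying_command_rejected(self):
        cmd = np.full(5000, -70.0)
        cmd[2000:2100] = -50.0
        tr = CurrentTrace(0.1, np.zeros(5000), cmd)
        with pytest.raises(ValueError, match="constant holding"):
            detect_injection_drops(tr)


class TestCalibration:
    @pytest.mark.parametrize(
        "drop, expected", [(-11.9, 0.02521), (-11.7, 0.02564)]
    )
    def test_printed_pairs(self, drop, expected, caplog):
        with caplog.at_level(logging.WARNING, logger="cytoclamp.analysis"):
            r = calibrate_access_pair(drop, -0.3)
        assert r == pytest.approx(expected, abs=5e-5)
        assert "outside" in caplog.text  # far below the 4-8 MOhm pipette range

    def test_round_trip_is_exact(self):
        from cytoclamp.circuit import injection_current

        for drop, e in [(-11.9, -0.3), (-11.7, -0.3), (2.0, 0.5)]:
            assert injection_current(e, calibrate_access_pair(drop, e)) == pytest.approx(
                drop, rel=1e-15
            )

    def test_zero_or_sign_mismatch_rejected(self):
        with pytest.raises(ValueError):
            calibrate_access_pair(0.0, -0.3)
        with pytest.raises(ValueError):
            calibrate_access_pair(-11.9, 0.0)
        with pytest.raises(ValueError):
            calibrate_access_pair(-11.9, 0.3)


def simulate_family(params, noise_sd=0.05, seed=0):
    protos = protocol.step_family(-80.0, 100.0, 20.0, epoch_ms=60.0, holding_mv=-70.0)
    return protocol.run_step_family(params, protos, dt_ms=0.01,
                                    noise_sd_na=noise_sd, seed=seed)


class TestViability:
    def test_pre_injection_cell_shows_both_channel_types(self, shsy5y):
        rep = classify_viability(simulate_family(shsy5y.params, seed=2))
        assert rep.k_active and rep.na_active
        assert rep.verdict == "viable"
        assert rep.peak_outward_na > 0 > rep.peak_inward_na

    def test_post_injection_cell_keeps_only_potassium(self, shsy5y):
        g = shsy5y.params.gating
        post = replace(
            shsy5y.params, gating=replace(g, na=replace(g.na, g_max_us=0.0))
        )
        rep = classify_viability(simulate_family(post, seed=3))
        assert rep.k_active and not rep.na_active
        assert rep.verdict == "viable"

    def test_silent_cell_is_non_viable(self, shsy5y):
        g = shsy5y.params.gating
        dead = replace(
            shsy5y.params,
            gating=replace(
                g,
                k=replace(g.k, g_max_us=0.0),
                na=replace(g.na, g_max_us=0.0),
            ),
        )
        rep = classify_viability(simulate_family(dead, seed=4))
        assert not rep.k_active
        assert rep.verdict == "non-viable"

    def test_too_few_levels_rejected(self, shsy5y):
        fam = simulate_family(shsy5y.params, seed=5)[:2]
        with pytest.raises(ValueError, match="3 step levels"):
            classify_viability(fam)


class TestControlLoop:
    def test_single_successful_episode(self, shsy5y):
        noise = NoiseModel(gaussian_sd_na=0.0, event_sd_na=0.0)
        seg = run_experiment(injection_script(1, seed=0, noise=noise),
                             shsy5y.params).holding_trace()
        log = control_loop([seg])
        assert [d.decision for d in log] == ["success"]

    def test_partial_drops_retry_then_succeed(self, shsy5y):
        noise = NoiseModel(gaussian_sd_na=0.0, event_sd_na=0.0)
        segs = [
            run_experiment(
                injection_script(1, seed=k, noise=noise, amplitude_na=-6.0),
                shsy5y.params,
            ).holding_trace()
            for k in range(3)
        ]
        log = control_loop(segs)
        assert [d.decision for d in log] == ["retry", "success"]
        assert log[-1].cumulative_drop_na == pytest.approx(-12.0, abs=0.01)

    def test_noise_only_stream_keeps_retrying(self):
        segs = [flat_trace(0.0, noise_sd=0.05, seed=k) for k in range(3)]
        log = control_loop(segs)
        assert [d.decision for d in log] == ["retry", "retry", "retry"]
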