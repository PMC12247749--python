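import math
from dataclasses import replace

import numpy as np
import pytest

from fusctl.control import ControllerConfig, DummyController, OpenLoopController
from fusctl.simulate import (
    GeneratorParams,
    LatentState,
    SonicationProtocol,
    SubjectModel,
    event_probability,
    harmonic_mean_level,
    ktrans_surrogate,
    mb_concentration,
    simulate_run,
    step_instability,
    synth_frame,
)


class TestMbConcentration:
    def test_zero_before_arrival(self, mouse):
        assert mb_concentration(0.0, mouse) == 0.0
        assert mb_concentration(mouse.arrival_time_s - 0.01, mouse) == 0.0

    def test_peak_normalized_to_one(self, mouse):
        r, c = mouse.rise_tau_s, mouse.clearance_tau_s
        t_peak = mouse.arrival_time_s + r * math.log(1 + c / r)
        assert mb_concentration(t_peak, mouse) == pytest.approx(1.0)

    def test_global_max_is_one_on_fine_grid(self, mouse):
        grid = np.linspace(0, 400, 40001)
        vals = np.array([mb_concentration(t, mouse) for t in grid])
        assert vals.max() == pytest.approx(1.0, abs=1e-6)
        assert np.all(vals >= 0) and np.all(vals <= 1)

    def test_single_global_maximum(self, mouse):
        grid = np.linspace(mouse.arrival_time_s, 400, 4000)
        vals = np.array([mb_concentration(t, mouse) for t in grid])
        d = np.sign(np.diff(vals))
        changes = np.sum(np.abs(np.diff(d[d != 0])) > 0)
        assert changes == 1  # rises then falls

    def test_value_at_peak_plus_tau_matches_grid_oracle(self, mouse):
        # oracle: brute-force evaluation of the unnormalized curve on a grid
        r, c = mouse.rise_tau_s, mouse.clearance_tau_s
        u = np.linspace(0, 1000, 200001)
        raw = (1 - np.exp(-u / r)) * np.exp(-u / c)
        peak_idx = raw.argmax()
        t_query = mouse.arrival_time_s + u[peak_idx] + c
        expected = raw[np.searchsorted(u, u[peak_idx] + c)] / raw[peak_idx]
        assert mb_concentration(t_query, mouse) == pytest.approx(expected, abs=1e-4)

    def test_rat_clears_faster_than_mouse(self, mouse, rat):
        t = 120.0
        assert rat.clearance_tau_s < mouse.clearance_tau_s
        assert mb_concentration(t, rat) < mb_concentration(t, mouse)


class TestStepInstability:
    def test_decays_to_zero_without_drive(self, mouse, params):
        p0 = replace(params, inst_noise_sd=0.0)
        state = LatentState(concentration=1.0, instability=2.0)
        rng = np.random.default_rng(0)
        trace = []
        for _ in range(200):
            state = step_instability(state, 0.0, mouse, p0, rng)
            trace.append(state.instability)
        # decays toward ~0 (a tiny softplus tail remains below p50)
        assert trace[-1] < 0.01
        assert all(b <= a for a, b in zip(trace[:50], trace[1:51]))

    def test_converges_to_fixed_point(self, mouse, params):
        # oracle: brute-force iteration reaches a fixed point of the map
        p0 = replace(params, inst_noise_sd=0.0)
        rng = np.random.default_rng(0)
        state = LatentState(concentration=1.0, instability=0.0)
        for _ in range(1000):
            state = step_instability(state, 0.33, mouse, p0, rng)
        once_more = step_instability(state, 0.33, mouse, p0, rng)
        assert once_more.instability == pytest.approx(state.instability, rel=1e-9)
        # closed form: gain * tanh(excess/sat) / (1 - retention)
        d = mouse.skull_transmission * 0.33 * 1.0
        w = p0.drive_softplus_width
        excess = w * math.log1p(math.exp((d - p0.p50) / w))
        expected = p0.inst_gain * math.tanh(excess / p0.inst_sat) / (
            1 - p0.inst_retention
        )
        assert state.instability == pytest.approx(expected, rel=1e-6)

    def test_strictly_increasing_in_pressure(self, mouse, params):
        p0 = replace(params, inst_noise_sd=0.0)
        state = LatentState(concentration=1.0, instability=0.5)
        lo = step_instability(state, 0.10, mouse, p0, np.random.default_rng(0))
        hi = step_instability(state, 0.11, mouse, p0, np.random.default_rng(0))
        assert hi.instability > lo.instability

    def test_history_with_one_higher_pulse_ends_higher(self, mouse, params):
        p0 = replace(params, inst_noise_sd=0.0)
        rng = np.random.default_rng(0)

        def run(pressures):
            st = LatentState(concentration=1.0, instability=0.0)
            for p in pressures:
                st = step_instability(st, p, mouse, p0, rng)
            return st.instability

        base = [0.2] * 10
        bumped = list(base)
        bumped[4] = 0.25
        assert run(bumped) > run(base)


class TestSynthFrame:
    def test_zero_pressure_levels_near_zero(self, mouse, params):
        rng = np.random.default_rng(3)
        frames = [
            synth_frame(0.0, LatentState(1.0, 0.0), mouse, params, rng)
            for _ in range(200)
        ]
        h7 = np.mean([f.harmonic_db[5] for f in frames])
        assert abs(h7) < 0.5
        p = event_probability(LatentState(1.0, 0.0), mouse, params)
        assert p < 1e-4  # sigma(beta0) << 1%

    def test_calibration_anchor_32db_at_p_model(self, mouse, params):
        # mean 7th-harmonic ~ 32 dB at 0.14 MPa, full concentration
        level = harmonic_mean_level(0.14, 1.0, mouse, params)
        assert level == pytest.approx(32.0, abs=0.5)

    def test_plateau_near_l_max(self, mouse, params):
        level = harmonic_mean_level(1.0, 1.0, mouse, params)
        assert level == pytest.approx(params.L_max, abs=0.1)

    def test_tumor_raises_event_probability(self, params):
        healthy = SubjectModel.default(tumor=False, seed=0, jitter=False)
        tumor = SubjectModel.default(tumor=True, seed=0, jitter=False)
        state = LatentState(concentration=1.0, instability=0.7)
        assert event_probability(state, tumor, params) > event_probability(
            state, healthy, params
        )

    def test_bolus_flag_raises_event_probability(self, mouse, params):
        high = LatentState(concentration=0.9, instability=0.7)
        low = LatentState(concentration=0.5, instability=0.7)
        assert event_probability(high, mouse, params) > event_probability(
            low, mouse, params
        )

    def test_event_probability_in_unit_interval(self, mouse, params):
        rng = np.random.default_rng(0)
        for _ in range(200):
            state = LatentState(rng.uniform(0, 1), rng.uniform(0, 3))
            assert 0.0 <= event_probability(state, mouse, params) <= 1.0

    def test_event_flag_consistent_with_broadband_level(self, mouse, params):
        rng = np.random.default_rng(1)
        state = LatentState(1.0, 1.2)
        for _ in range(300):
            f = synth_frame(0.3, state, mouse, params, rng)
            assert f.is_event == (f.broadband_db >= 6.0)


class TestSimulateRun:
    def test_zero_pressure_dummy_has_no_events(self, protocol, mouse, params):
        rec = simulate_run(protocol, mouse, DummyController(0.0), params, seed=4)
        assert rec.n_pulses == 130
        assert rec.event_count() == 0

    def test_seeded_determinism(self, protocol, mouse, params):
        ctrl = lambda: OpenLoopController(
            ControllerConfig(kind="OL", fixed_pressure_mpa=0.3, p_init_mpa=0.3)
        )
        a = simulate_run(protocol, mouse, ctrl(), params, seed=5)
        b = simulate_run(protocol, mouse, ctrl(), params, seed=5)
        assert a.pressures.tolist() == b.pressures.tolist()
        assert [f.broadband_db for f in a.frames] == [
            f.broadband_db for f in b.frames
        ]
        assert a.ktrans == b.ktrans

    def test_different_seeds_differ(self, protocol, mouse, params):
        ctrl = lambda: OpenLoopController(
            ControllerConfig(kind="OL", fixed_pressure_mpa=0.3, p_init_mpa=0.3)
        )
        a = simulate_run(protocol, mouse, ctrl(), params, seed=1)
        b = simulate_run(protocol, mouse, ctrl(), params, seed=2)
        assert [f.broadband_db for f in a.frames] != [
            f.broadband_db for f in b.frames
        ]

    def test_high_pressure_produces_events(self, protocol, params):
        total = 0
        for i in range(20):
            subj = SubjectModel.default(seed=100 + i)
            ctrl = OpenLoopController(
                ControllerConfig(kind="OL", fixed_pressure_mpa=0.33, p_init_mpa=0.33)
            )
            total += simulate_run(protocol, subj, ctrl, params, seed=600 + i).event_count()
        assert total > 0

    def test_marginal_event_rate_of_standard_experiment(self, protocol, params):
        # standard high-exposure mouse sonication: constant 0.30 MPa
        events = pulses = 0
        for i in range(30):
            subj = SubjectModel.default(seed=900 + i)
            ctrl = OpenLoopController(
                ControllerConfig(kind="OL", fixed_pressure_mpa=0.30, p_init_mpa=0.30)
            )
            rec = simulate_run(protocol, subj, ctrl, params, seed=3000 + i)
            events += rec.event_count()
            pulses += rec.n_pulses
        rate = 100 * events / pulses
        assert 5.0 <= rate <= 10.0

    def test_precursor_separability(self, training_records_small):
        # mean UH1 on pulses preceding events exceeds non-event precursors
        pre_event, pre_quiet = [], []
        for rec in training_records_small:
            frames = rec.frames
            for t in range(rec.n_pulses - 1):
                (pre_event if frames[t + 1].is_event else pre_quiet).append(
                    frames[t].ultraharmonic_db[0]
                )
        assert np.mean(pre_event) - np.mean(pre_quiet) >= 3.0


class TestKtransSurrogate:
    def test_floor_for_silent_record(self, protocol, mouse, params):
        rec = simulate_run(protocol, mouse, DummyController(0.0), params, seed=8)
        base = ktrans_surrogate(rec, noise_sd=0.0)
        assert base < 0.004  # near the floor

    def test_monotone_in_harmonic_levels(self, protocol, mouse, params):
        low = simulate_run(
            protocol,
            mouse,
            OpenLoopController(
                ControllerConfig(kind="OL", fixed_pressure_mpa=0.14, p_init_mpa=0.14)
            ),
            params,
            seed=9,
        )
        high = simulate_run(
            protocol,
            mouse,
            OpenLoopController(
                ControllerConfig(kind="OL", fixed_pressure_mpa=0.3, p_init_mpa=0.3)
            ),
            params,
            seed=9,
        )
        assert ktrans_surrogate(high, noise_sd=0.0) > ktrans_surrogate(
            low, noise_sd=0.0
        )

    def test_near_linear_far_from_saturation(self, protocol, mouse, params):
        rec = simulate_run(
            protocol,
            mouse,
            OpenLoopController(
                ControllerConfig(kind="OL", fixed_pressure_mpa=0.2, p_init_mpa=0.2)
            ),
            params,
            seed=10,
        )
        floor, amp, half = 0.0, 0.02, 1e7  # dose << half-saturation
        k1 = ktrans_surrogate(rec, floor=floor, amplitude=amp, dose_half=half, noise_sd=0.0)
        # doubling the dose: duplicate every frame
        rec.pulses = rec.pulses + rec.pulses
        k2 = ktrans_surrogate(rec, floor=floor, amplitude=amp, dose_half=half, noise_sd=0.0)
        assert k2 / k1 == pytest.approx(2.0, rel=0.05)


class TestSubjectModel:
    def test_rat_transmission_lower(self):
        m = SubjectModel.default("mouse", jitter=False)
        r = SubjectModel.default("rat", jitter=False)
        assert r.skull_transmission < m.skull_transmission

    def test_jitter_is_seeded(self):
        a = SubjectModel.default("mouse", seed=3)
        b = SubjectModel.default("mouse", seed=3)
        c = SubjectModel.default("mouse", seed=4)
        assert a.skull_transmission == b.skull_transmission
        assert a.skull_transmission != c.skull_transmission

    def test_invalid_species(self):
        with pytest.raises(ValueError):
            SubjectModel(species="dog")

    def test_rise_must_be_faster_than_clearance(self):
        with pytest.raises(ValueError):
            SubjectModel(rise_tau_s=100.0, clearance_tau_s=50.0)


class TestProtocol:
    def test_pulse_count(self, protocol):
        assert protocol.n_pulses == 130

    def test_non_integer_pulse_count_rejected(self):
        with pytest.raises(ValueError):
            SonicationProtocol(duration_s=130.5)
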