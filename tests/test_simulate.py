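"""Generator contracts: geometry, schedules, injected signal, reproducibility."""

import numpy as np
import pytest

import slowfield as sf
from slowfield.errors import InvalidConfigError
from slowfield.simulate import (
    GRASP,
    OPEN,
    mrcf_template,
    mrcf_topography,
    open_loop_schedule,
)


class TestSensorArray:
    def test_parietal_subset_size_and_geometry(self, array160):
        assert array160.n_sensors == 160
        assert array160.parietal_mask.sum() == 84
        norms = np.linalg.norm(array160.orientations, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)
        # sensors outside the conductor sphere
        assert np.all(np.linalg.norm(array160.positions, axis=1)
                      > array160.head_radius)

    def test_deterministic_for_seed(self):
        a = sf.make_sensor_array(160, seed=7)
        b = sf.make_sensor_array(160, seed=7)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.parietal_mask, b.parietal_mask)

    def test_minimal_array_is_all_parietal(self):
        a = sf.make_sensor_array(84, seed=0)
        assert a.parietal_mask.all()

    def test_too_few_sensors_rejected(self):
        with pytest.raises(InvalidConfigError):
            sf.make_sensor_array(83)


class TestSchedule:
    def test_open_loop_structure(self):
        sch = open_loop_schedule(sf.SimulationConfig())
        assert len(sch.cue_times) == 80
        assert sum(1 for m in sch.cue_types if m == GRASP) == 40
        assert np.allclose(np.diff(sch.cue_times), 5.5)
        assert sch.cue_times[0] >= 50.0

    def test_config_validation(self):
        with pytest.raises(InvalidConfigError):
            sf.SimulationConfig(erd_depth_alpha=1.2).validate()
        with pytest.raises(InvalidConfigError):
            sf.SimulationConfig(
                mrcf_amplitude={GRASP: -1.0, OPEN: 0.3}).validate()
        # identical types would make decoding chance by construction
        with pytest.raises(InvalidConfigError):
            sf.SimulationConfig(
                mrcf_amplitude={GRASP: 0.4, OPEN: 0.4},
                patch_center_dirs={GRASP: (0, 0, 1), OPEN: (0, 0, 1)},
            ).validate()

    def test_too_short_duration_rejected(self, array84):
        cfg = sf.SimulationConfig(seed=0, cues_per_type=8, duration_s=60.0)
        with pytest.raises(InvalidConfigError):
            sf.simulate_open_loop(cfg, array84)


class TestOpenLoopSignal:
    def test_null_generator_has_no_cue_locked_response(self, array84):
        cfg = sf.SimulationConfig(
            seed=5, cues_per_type=8,
            mrcf_amplitude={GRASP: 0.0, OPEN: 0.0},
            erd_depth_alpha=0.0, erd_depth_beta=0.0,
        )
        ses = sf.simulate_open_loop(cfg, array84)
        # cue-locked 500-ms mean in [0, 500) across trials: zero within 3 SE
        vals = []
        for t in ses.schedule.cue_times:
            i = int(round(t * 1000.0))
            vals.append(ses.data[:, i:i + 500].mean(axis=1))
        vals = np.asarray(vals)
        grand = vals.mean()
        se = vals.mean(axis=1).std(ddof=1) / np.sqrt(len(vals))
        assert abs(grand) < 3 * se + 1e-12

    def test_noiseless_trace_is_projected_template(self, array84):
        cfg = sf.SimulationConfig(
            seed=2, cues_per_type=1, cues_per_block=1,
            alpha_sd=0.0, beta_sd=0.0, noise_1f_sd=0.0, white_noise_sd=0.0,
        )
        ses = sf.simulate_open_loop(cfg, array84)
        t_cue = ses.schedule.cue_times[0]
        m = ses.schedule.cue_types[0]
        topo = mrcf_topography(cfg, array84, m)
        times = np.arange(-1000, 1001, dtype=float)
        expected = cfg.mrcf_amplitude[m] * np.outer(
            topo, mrcf_template(times))
        i0 = int(round(t_cue * 1000.0)) - 1000
        got = ses.data[:, i0:i0 + 2001]
        assert np.allclose(got, expected, atol=1e-10)

    def test_higher_amplitude_type_has_larger_average(self, default_session,
                                                      array84):
        cfg = sf.SimulationConfig(seed=3)
        topo = mrcf_topography(cfg, array84, GRASP)
        ch = int(np.argmax(np.abs(topo)))
        sign = np.sign(topo[ch])

        def mean_peak(movement):
            vals = []
            for t in default_session.schedule.cues_of_type(movement):
                i = int(round(t * 1000.0))
                vals.append(default_session.data[ch, i:i + 500].mean())
            return sign * np.mean(vals)

        assert mean_peak(GRASP) > mean_peak(OPEN)

    def test_trial_average_recovers_template_shape(self, default_session,
                                                   array84):
        """500-ms windowed cue-locked average correlates > 0.9 with the
        injected time course at default SNR over 40 trials."""
        cfg = sf.SimulationConfig(seed=3)
        topo = mrcf_topography(cfg, array84, GRASP)
        ch = int(np.argmax(np.abs(topo)))
        ends = np.arange(-900.0, 1101.0, 100.0)
        curves = []
        for t in default_session.schedule.cues_of_type(GRASP):
            i = np.array([int(round(t * 1000.0 + e)) for e in ends])
            curves.append([
                default_session.data[ch, j - 500:j].mean() for j in i])
        avg = np.mean(curves, axis=0)
        expected = [mrcf_template(np.arange(e - 500, e)).mean()
                    for e in ends]
        r = np.corrcoef(avg, expected)[0, 1]
        assert abs(r) > 0.9

    def test_erd_power_ratio(self, default_session):
        from slowfield.features import window_band_power

        cfg = sf.SimulationConfig(seed=3)
        base = np.mean([
            window_band_power(default_session.data[:, e - 500:e], "alpha",
                              1000.0).mean()
            for e in range(500, 50001, 1000)])
        mov = np.mean([
            window_band_power(
                default_session.data[:, int(t * 1000) + 500:
                                     int(t * 1000) + 1000],
                "alpha", 1000.0).mean()
            for t in default_session.schedule.cue_times])
        ratio = mov / base
        assert abs(ratio - (1.0 - cfg.erd_depth_alpha)) < 0.1

    def test_bitwise_reproducible(self, array84):
        cfg = sf.SimulationConfig(seed=9, cues_per_type=4)
        a = sf.simulate_open_loop(cfg, array84)
        b = sf.simulate_open_loop(
            sf.SimulationConfig(seed=9, cues_per_type=4), array84)
        assert np.array_equal(a.data, b.data)


class TestClosedLoopStream:
    def test_duration_and_alternation(self, array84):
        cfg = sf.SimulationConfig(seed=4)
        ses = sf.simulate_closed_loop_stream(cfg, array84)
        assert len(ses.schedule.instruction_times) == 22
        # 22 instructions at 7 s plus the 50-s head segment
        assert ses.duration_s >= 154.0 + 50.0
        types = ses.schedule.instruction_types
        assert all(a != b for a, b in zip(types, types[1:]))

    def test_invalid_instruction_lists(self, array84):
        cfg = sf.SimulationConfig(seed=4)
        with pytest.raises(InvalidConfigError):
            sf.simulate_closed_loop_stream(cfg, array84, [])
        with pytest.raises(InvalidConfigError):
            sf.simulate_closed_loop_stream(
                cfg, array84, [GRASP, GRASP, OPEN])

    def test_zero_burst_probability_is_noise(self, array84):
        cfg = sf.SimulationConfig(seed=4, burst_probability=0.0)
        ses = sf.simulate_closed_loop_stream(cfg, array84)
        assert len(ses.schedule.cue_times) == 0

    def test_deterministic_burst_times_without_jitter(self, array84):
        cfg = sf.SimulationConfig(
            seed=4, reaction_jitter_sd_ms=0.0, burst_probability=1.0,
            alpha_sd=0.0, beta_sd=0.0, noise_1f_sd=0.0, white_noise_sd=0.0,
        )
        ses = sf.simulate_closed_loop_stream(cfg, array84)
        # burst (ramp start) begins exactly latency after each instruction
        starts = ses.schedule.cue_times + cfg.mrcf_ramp_start_ms / 1000.0
        expected = ses.schedule.instruction_times + \
            cfg.reaction_latency_ms / 1000.0
        assert np.allclose(starts, expected, atol=1e-9)
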