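import numpy as np
import pytest

from cawave.kinetics import (
    distance_to_electrode,
    estimate_breakpoint,
    fit_amplitude_decay,
    fit_velocity,
)


def piecewise_times(d, v1=4.5, v2=6.0, bp=150.0):
    return np.where(d <= bp, d / v1, bp / v1 + (d - bp) / v2)


class TestDistance:
    def test_centroid_at_electrode(self):
        assert distance_to_electrode(np.array([[10.0, 20.0]]), (10.0, 20.0))[0] == 0.0

    def test_three_four_five(self):
        d = distance_to_electrode(np.array([[3.0, 4.0]]), (0.0, 0.0))
        assert d[0] == pytest.approx(5.0)

    def test_pixel_offset_scaled_to_um(self):
        px = 2.0
        d = distance_to_electrode(np.array([[3.0 * px, 4.0 * px]]), (0.0, 0.0))
        assert d[0] == pytest.approx(10.0)

    def test_celltable_dataframe_accepted(self):
        import pandas as pd

        cells = pd.DataFrame({"x_um": [0.0, 3.0], "y_um": [5.0, 4.0]})
        assert np.allclose(distance_to_electrode(cells, (0.0, 0.0)), [5.0, 5.0])


class TestVelocityFit:
    def test_exact_single_velocity(self):
        d = np.linspace(10, 490, 60)
        res = fit_velocity(d / 5.0, d)
        assert res.v_overall == pytest.approx(5.0, abs=1e-9)
        assert res.overall.r_squared == pytest.approx(1.0)

    def test_exact_piecewise_recovery(self):
        d = np.linspace(5, 495, 120)
        res = fit_velocity(piecewise_times(d), d)
        assert res.v_proximal == pytest.approx(4.5, rel=1e-6)
        assert res.v_distal == pytest.approx(6.0, rel=1e-6)

    def test_invariant_to_time_offset(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(10, 490, 80)
        t = piecewise_times(d) + rng.normal(0, 1, d.size)
        a = fit_velocity(t, d)
        b = fit_velocity(t + 100.0, d)
        assert b.v_overall == pytest.approx(a.v_overall, rel=1e-9)
        assert b.v_proximal == pytest.approx(a.v_proximal, rel=1e-9)

    def test_velocity_halves_when_distances_double(self):
        d = np.linspace(10, 240, 40)
        t = d / 5.0
        a = fit_velocity(t, d, breakpoint=100, max_distance=500)
        b = fit_velocity(t, 2 * d, breakpoint=200, max_distance=1000)
        assert b.v_overall == pytest.approx(2 * a.v_overall, rel=1e-9)

    def test_degenerate_distances_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_velocity(np.ones(10), np.full(10, 100.0), breakpoint=150)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_velocity(np.array([1.0, 2.0]), np.array([10.0, 20.0]))

    def test_breakpoint_grid_search_finds_kink(self):
        d = np.linspace(5, 495, 200)
        bp = estimate_breakpoint(piecewise_times(d), d)
        assert abs(bp - 150.0) <= 20.0


class TestAmplitudeDecay:
    def test_exact_exponential(self):
        d = np.linspace(0, 500, 100)
        a = 2.0 * np.exp(-d / 100.0)
        fit = fit_amplitude_decay(a, d, fit_range=(0.0, 500.0))
        assert fit.A0 == pytest.approx(2.0, rel=1e-6)
        assert fit.decay_length == pytest.approx(100.0, rel=1e-6)
        assert not fit.no_decay

    def test_constant_amplitudes_flagged_no_decay(self):
        d = np.linspace(100, 500, 50)
        fit = fit_amplitude_decay(np.full(50, 1.5), d)
        assert fit.no_decay
        assert np.isinf(fit.decay_length)

    def test_nonpositive_amplitudes_excluded_with_warning(self):
        d = np.linspace(100, 500, 50)
        a = 2.0 * np.exp(-(d - 100) / 150.0)
        a[3] = 0.0
        with pytest.warns(UserWarning, match="non-positive"):
            fit = fit_amplitude_decay(a, d)
        assert fit.n == 49
        assert fit.decay_length == pytest.approx(150.0, rel=1e-6)

    def test_all_excluded_is_error(self):
        d = np.linspace(100, 500, 10)
        with pytest.raises(ValueError, match="positive"):
            with pytest.warns(UserWarning):
                fit_amplitude_decay(np.zeros(10), d)


class TestRecoveryFromSimulation:
    def test_velocity_and_decay_recovered_from_traces(self):
        """Default-condition trace simulation recovers the configured wave."""
        from cawave.pipeline import analyze_trace_matrix
        from cawave.simgen import simulate_traces, trace_mode_config

        cfg = trace_mode_config(n_cells=1500, seed=3)
        sim = simulate_traces(cfg)
        an = analyze_trace_matrix(
            sim.raw, cfg.frame_interval, cfg.protocol,
            distances=sim.truth["distance_um"].to_numpy(),
        )
        assert an.velocity.v_proximal == pytest.approx(cfg.v_proximal, rel=0.10)
        assert an.velocity.v_distal == pytest.approx(cfg.v_distal, rel=0.10)
        assert an.amplitude_decay.decay_length == pytest.approx(
            cfg.amp_decay_length, rel=0.15
        )

    def test_proximal_slower_than_distal_across_seeds(self):
        """Sign of the biphasic split is recovered whenever configured."""
        from cawave.pipeline import analyze_trace_matrix
        from cawave.simgen import simulate_traces, trace_mode_config

        for seed in range(1, 11):
            cfg = trace_mode_config(n_cells=400, seed=seed)
            sim = simulate_traces(cfg)
            an = analyze_trace_matrix(
                sim.raw, cfg.frame_interval, cfg.protocol,
                distances=sim.truth["distance_um"].to_numpy(),
            )
            assert an.velocity.v_proximal < an.velocity.v_distal
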