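import numpy as np
import pytest

from cawave.simgen import (
    SimConfig,
    movie_mode_config,
    render_movie,
    simulate_if_images,
    simulate_traces,
    trace_mode_config,
)

QUIET = dict(
    period_jitter_sd=0.0,
    first_peak_jitter_sd=0.0,
    trace_noise_sd=0.0,
    freq_between_cell_sd=0.0,
    proximal_amp_jitter=0.0,
    distal_amp_jitter=0.0,
    non_responder_fraction=0.0,
)


class TestConfig:
    def test_probs_must_sum_to_one(self):
        cfg = trace_mode_config(n_cells=10)
        cfg.peak_count_probs = {1: 0.5, 2: 0.4}
        with pytest.raises(ValueError, match="sum to 1"):
            cfg.validate()

    def test_short_window_rejected(self):
        cfg = trace_mode_config(n_cells=10, n_frames=60)
        with pytest.raises(ValueError, match="window"):
            cfg.validate()

    def test_class_period_below_peak_width_rejected(self):
        cfg = trace_mode_config(n_cells=10)
        freqs = dict(cfg.class_freq_mhz)
        freqs[8] = 250.0  # 4 s period, below the 5 s minimum peak width
        cfg.class_freq_mhz = freqs
        with pytest.raises(ValueError, match="peak width"):
            cfg.validate()


class TestTraceSimulation:
    def test_single_distal_cell_first_peak_time(self):
        """d = 150 µm at 5 µm/s (no breakpoint effect): first peak at 30 s."""
        cfg = trace_mode_config(
            n_cells=1, seed=0, v_proximal=5.0, velocity_breakpoint=150.0,
            r_range=(149.999, 150.001), **QUIET,
        )
        sim = simulate_traces(cfg)
        assert sim.truth["true_first_peak_time_s"][0] == pytest.approx(30.0, abs=1e-3)

    def test_ground_truth_row_count(self):
        sim = simulate_traces(trace_mode_config(n_cells=500, seed=2))
        assert len(sim.truth) == 500

    def test_same_seed_bit_identical(self):
        a = simulate_traces(trace_mode_config(n_cells=80, seed=9))
        b = simulate_traces(trace_mode_config(n_cells=80, seed=9))
        assert np.array_equal(a.raw, b.raw)
        assert a.truth.equals(b.truth)

    def test_different_seed_differs(self):
        a = simulate_traces(trace_mode_config(n_cells=80, seed=9))
        b = simulate_traces(trace_mode_config(n_cells=80, seed=10))
        assert not np.array_equal(a.raw, b.raw)

    def test_noise_free_monotonicity_in_distance(self):
        """Jitter-free: t1 non-decreasing and distal amplitude non-increasing."""
        cfg = trace_mode_config(n_cells=300, seed=4, **QUIET)
        sim = simulate_traces(cfg)
        t = sim.truth.sort_values("distance_um")
        assert (np.diff(t["true_first_peak_time_s"]) >= -1e-9).all()
        beyond = t[t["distance_um"] >= cfg.amp_plateau]
        assert (np.diff(beyond["true_first_amp"]) <= 1e-9).all()

    def test_first_peaks_within_120s_out_to_500um(self):
        """The evoked wave reaches every cell inside 500 µm within 120 s."""
        sim = simulate_traces(trace_mode_config(n_cells=2000, seed=5))
        resp = sim.truth[sim.truth["responder"]]
        assert (resp["true_first_peak_time_s"] <= 120.0).all()

    def test_trace_frequency_matches_configured_period(self):
        """A jitter-free 3-peak class at 58.8 s period reads out 17.0 mHz."""
        from cawave.oscillations import cell_frequency, find_peaks
        from cawave.traces import compute_dff, smooth

        cfg = trace_mode_config(
            n_cells=40, seed=6,
            peak_count_probs={3: 1.0},
            class_freq_mhz={3: 1000.0 / 58.8},
            refractory_coefficient=0.0,
            **QUIET,
        )
        sim = simulate_traces(cfg)
        freqs = []
        for row in sim.raw:
            _, dff = compute_dff(row, 20)
            ps = find_peaks(smooth(dff), cfg.frame_interval, cfg.protocol.onset_time)
            freqs.append(cell_frequency(ps))
        # 1 s frame quantisation leaves ~±0.3 mHz around the exact value
        assert np.nanmean(freqs) == pytest.approx(17.0, abs=0.3)

    def test_refractory_delay_inflates_first_interval(self):
        cfg = trace_mode_config(
            n_cells=60, seed=7, peak_count_probs={3: 1.0},
            refractory_coefficient=2.0, **QUIET,
        )
        sim = simulate_traces(cfg)
        # proximal cells (big first peaks) must show longer 1->2 than 2->3
        from cawave.oscillations import find_peaks
        from cawave.traces import compute_dff, smooth

        prox = np.nonzero((sim.truth["distance_um"] < 100).to_numpy())[0]
        assert prox.size > 0
        for i in prox:
            _, dff = compute_dff(sim.raw[i], 20)
            ps = find_peaks(smooth(dff), 1.0, cfg.protocol.onset_time)
            iv = ps.intervals()
            assert iv[0] > iv[1] + 2.0


class TestRenderMovie:
    def test_zero_noise_flat_cell_has_zero_variance(self):
        cfg = movie_mode_config(
            n_cells=1, seed=0, noise_sd=0.0, baseline_sd=0.0,
            non_responder_fraction=1.0, **{k: v for k, v in QUIET.items()
                                           if k != "non_responder_fraction"},
        )
        sim = simulate_traces(cfg)
        stack = render_movie(sim)
        r = int(sim.truth["y_um"][0] / cfg.pixel_size)
        c = int(sim.truth["x_um"][0] / cfg.pixel_size)
        assert stack[:, r, c].std() == 0.0

    def test_cell_mask_mean_tracks_trace(self):
        """Rendered in-mask mean correlates perfectly with 1 + ΔF/F₀ at zero noise."""
        cfg = movie_mode_config(n_cells=5, seed=1, noise_sd=0.0, trace_noise_sd=0.0)
        sim = simulate_traces(cfg)
        stack = render_movie(sim).astype(float)
        for i in range(5):
            r = int(round(sim.truth["y_um"][i] / cfg.pixel_size))
            c = int(round(sim.truth["x_um"][i] / cfg.pixel_size))
            px = stack[:, r, c]
            model = 1.0 + sim.dff[i]
            rho = np.corrcoef(px, model)[0, 1]
            if np.ptp(model) > 0:
                assert rho > 0.999

    def test_background_level(self):
        cfg = movie_mode_config(n_cells=3, seed=2)
        sim = simulate_traces(cfg)
        stack = render_movie(sim)
        corner = stack[:, :20, :20].astype(float)  # electrode-free corner
        assert abs(corner.mean() - cfg.background_mean) < 3.0

    def test_tiff_roundtrip(self, tmp_path):
        import tifffile

        from cawave.simgen import write_movie

        cfg = movie_mode_config(n_cells=3, seed=3)
        sim = simulate_traces(cfg)
        stack = render_movie(sim)
        write_movie(stack, tmp_path / "m.tiff")
        back = tifffile.imread(tmp_path / "m.tiff")
        assert np.array_equal(back, stack)

    def test_same_seed_bit_identical_movie(self):
        cfg = movie_mode_config(n_cells=10, seed=4)
        a = render_movie(simulate_traces(cfg))
        b = render_movie(simulate_traces(cfg))
        assert np.array_equal(a, b)

    def test_separation_violation_rejected(self):
        cfg = movie_mode_config(n_cells=20, seed=5)
        sim = simulate_traces(cfg)
        sim.truth.loc[1, ["x_um", "y_um"]] = sim.truth.loc[0, ["x_um", "y_um"]].to_numpy() + 1.0
        with pytest.raises(ValueError, match="separation"):
            render_movie(sim)


class TestIFImages:
    def test_no_effect_groups_have_equal_truth_means(self):
        _, truth = simulate_if_images(6, effect={}, seed=0)
        g = truth.groupby(["region", "condition"])["true_marker"].mean()
        for region in ("CA1", "CA3", "DG"):
            # between-image and between-nucleus variability leave ~3% SEM
            ratio = g[region, "stimulated"] / g[region, "control"]
            assert ratio == pytest.approx(1.0, abs=0.1)

    def test_programmed_effect_ratio(self):
        _, truth = simulate_if_images(6, effect={"CA1": 1.5}, seed=1)
        g = truth.groupby(["region", "condition"])["true_marker"].mean()
        assert g["CA1", "stimulated"] / g["CA1", "control"] == pytest.approx(1.5, abs=0.1)
        assert g["DG", "stimulated"] / g["DG", "control"] == pytest.approx(1.0, abs=0.05)

    def test_image_pair_count(self):
        records, _ = simulate_if_images(3, seed=2)
        # 3 regions x 2 conditions x 3 replicates
        assert len(records) == 18
        assert all("nuclei_img" in r and "marker_img" in r for r in records)

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="effect"):
            simulate_if_images(2, effect={"CA2": 1.5})
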