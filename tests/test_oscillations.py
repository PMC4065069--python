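import numpy as np
import pytest

from cawave.oscillations import (
    PeakSet,
    cell_frequency,
    find_peaks,
    peak_count_by_distance,
    peak_count_class,
    summarize_classes,
)
from conftest import brute_force_peaks

ONSET = 20.0


class TestFindPeaks:
    def test_single_gaussian_bump(self, gaussian_bump):
        y = gaussian_bump(200, centres=[100.0], sd=5.0)
        ps = find_peaks(y, 1.0, onset_time=ONSET)
        assert ps.n_peaks == 1
        assert ps.peak_times[0] == pytest.approx(100.0 - ONSET, abs=1.0)

    def test_two_bumps_sixty_seconds_apart_match_oracle(self, gaussian_bump):
        y = gaussian_bump(250, centres=[80.0, 140.0], sd=5.0)
        oracle = brute_force_peaks(y, min_width=5.0)
        assert len(oracle) == 2
        ps = find_peaks(y, 1.0, onset_time=ONSET)
        assert ps.n_peaks == 2
        assert np.allclose(ps.peak_times + ONSET, oracle, atol=1.0)
        assert ps.intervals()[0] == pytest.approx(60.0, abs=1.0)

    def test_narrow_spike_rejected(self):
        """A 2-s-wide transient is below the 5 s minimum peak width."""
        y = np.zeros(120)
        y[60] = 1.0
        y[59] = y[61] = 0.5  # ~2 s at half height
        ps = find_peaks(y, 1.0, onset_time=ONSET)
        assert ps.n_peaks == 0

    def test_end_censored_peak_kept_when_rise_complete(self):
        """Rising flank complete, decay cut by the recording end."""
        t = np.arange(120.0)
        y = np.clip((t - 104.0) / 10.0, 0.0, None)
        y[t > 114] = 1.0 - (t[t > 114] - 114.0) * 0.02
        ps = find_peaks(y, 1.0, onset_time=ONSET)
        assert ps.n_peaks == 1

    def test_small_wobble_near_major_peak_ignored(self, gaussian_bump):
        y = gaussian_bump(200, centres=[100.0], sd=6.0)
        y[108] += 0.03  # low-prominence wobble on the shoulder
        ps = find_peaks(y, 1.0, onset_time=ONSET, min_prominence=0.1)
        assert ps.n_peaks == 1


class TestClassification:
    @pytest.mark.parametrize("n,expected", [(3, 3), (8, 8), (11, ">8"), (0, 0)])
    def test_peak_count_class(self, n, expected):
        assert peak_count_class(n) == expected

    def test_comb_frequency_is_reciprocal_period(self):
        ps = PeakSet(0, np.array([0.0, 50.0, 100.0]), np.ones(3))
        assert cell_frequency(ps) == pytest.approx(20.0)

    def test_two_peak_frequency(self):
        ps = PeakSet(0, np.array([0.0, 60.0]), np.ones(2))
        assert cell_frequency(ps) == pytest.approx(1000.0 / 60.0)

    def test_single_peak_frequency_undefined(self):
        ps = PeakSet(0, np.array([30.0]), np.ones(1))
        assert np.isnan(cell_frequency(ps))

    def test_exclude_first_interval_flag(self):
        # refractory-inflated first interval: 80 s, then regular 50 s
        ps = PeakSet(0, np.array([0.0, 80.0, 130.0, 180.0]), np.ones(4))
        assert cell_frequency(ps) == pytest.approx(1000.0 / 60.0)
        assert cell_frequency(ps, exclude_first_interval=True) == pytest.approx(20.0)


class TestSummaries:
    def test_identical_three_peak_cells(self):
        """Cells with a 58.8 s period oscillate at 17.0 mHz, SD 0."""
        peaksets = [
            PeakSet(i, np.array([10.0, 68.8, 127.6]), np.ones(3)) for i in range(20)
        ]
        s = summarize_classes(peaksets).set_index("peak_class")
        assert s.loc[3, "n_cells"] == 20
        assert s.loc[3, "mean_frequency_mhz"] == pytest.approx(1000 / 58.8, abs=0.01)
        assert s.loc[3, "sd_frequency_mhz"] == pytest.approx(0.0, abs=1e-9)
        assert s.loc[4, "n_cells"] == 0

    def test_one_cell_per_class(self):
        peaksets = []
        for k in range(1, 9):
            times = np.arange(k) * 40.0 + 5.0
            peaksets.append(PeakSet(k, times, np.ones(k)))
        s = summarize_classes(peaksets).set_index("peak_class")
        assert (s.loc[1:8, "n_cells"] == 1).all()

    def test_transition_interval_columns(self):
        ps = PeakSet(0, np.array([0.0, 30.0, 70.0]), np.ones(3))
        s = summarize_classes([ps]).set_index("peak_class")
        assert s.loc[3, "mean_interval_1_2_s"] == pytest.approx(30.0)
        assert s.loc[3, "mean_interval_2_3_s"] == pytest.approx(40.0)


class TestCountByDistance:
    def test_all_single_peak_cells_in_first_bin(self):
        peaksets = [PeakSet(i, np.array([5.0]), np.ones(1)) for i in range(10)]
        table = peak_count_by_distance(peaksets, np.full(10, 25.0), max_distance=500)
        row = table.set_index("peak_class").loc[1]
        assert row["[0,50)"] == pytest.approx(1.0)

    def test_rows_normalise_to_one_or_zero(self):
        rng = np.random.default_rng(11)
        peaksets, dists = [], []
        for i in range(200):
            k = rng.integers(1, 6)
            peaksets.append(PeakSet(i, np.sort(rng.uniform(0, 300, k)), np.ones(k)))
            dists.append(rng.uniform(0, 500))
        table = peak_count_by_distance(peaksets, np.array(dists), max_distance=500)
        sums = table.drop(columns=["peak_class", "n_cells"]).sum(axis=1)
        for total, n in zip(sums, table["n_cells"]):
            assert total == pytest.approx(1.0 if n else 0.0)

    def test_distance_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="distances"):
            peak_count_by_distance([PeakSet(0, np.array([1.0]), np.ones(1))], np.array([]))


class TestRecoveryOnSimulatedTraces:
    def test_peak_counts_recovered(self):
        """Jitter-free traces: exact count recovery; default noise: >= 95%."""
        from cawave.pipeline import analyze_trace_matrix
        from cawave.simgen import simulate_traces, trace_mode_config

        quiet = dict(
            period_jitter_sd=0.0,
            first_peak_jitter_sd=0.0,
            trace_noise_sd=0.0,
            freq_between_cell_sd=0.0,
            proximal_amp_jitter=0.0,
            distal_amp_jitter=0.0,
        )
        cfg = trace_mode_config(n_cells=400, seed=1, **quiet)
        sim = simulate_traces(cfg)
        an = analyze_trace_matrix(sim.raw, cfg.frame_interval, cfg.protocol)
        resp = sim.truth["responder"].to_numpy()
        assert np.array_equal(
            an.cells["n_peaks"].to_numpy()[resp],
            sim.truth["true_peak_count"].to_numpy()[resp],
        )

        for seed in range(1, 6):
            cfg = trace_mode_config(n_cells=400, seed=seed)
            sim = simulate_traces(cfg)
            an = analyze_trace_matrix(sim.raw, cfg.frame_interval, cfg.protocol)
            resp = sim.truth["responder"].to_numpy()
            agree = (
                an.cells["n_peaks"].to_numpy()[resp]
                == sim.truth["true_peak_count"].to_numpy()[resp]
            ).mean()
            assert agree >= 0.95
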