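"""Synthetic calcium movies and immunofluorescence images with ground truth.

The generator emulates the structure of a stimulus-evoked radial calcium
wave in a slice network so that every analysis stage can be validated by
parameter recovery:

* time-to-first-peak follows a piecewise-linear distance/latency law
  (apparent velocity 4.5 µm/s up to a 150 µm breakpoint, 6.0 µm/s beyond)
  plus Gaussian jitter;
* first-peak ΔF/F₀ amplitude is large and broadly scattered within 100 µm of
  the electrode and decays exponentially with distance beyond it;
* each responding cell draws a peak-count class (1..8 or >8) from a
  configurable mixture and oscillates with a class-specific base frequency;
  the first-to-second interval carries an extra refractory delay
  proportional to the first-peak amplitude;
* individual transients have a linear rise and an exponential decay (a small
  near-electrode subpopulation decays linearly instead).

Cells are placed with distance drawn uniformly between the radial limits and
a uniform angle inside the field, emulating the banded cell-dense layers of
a slice rather than a uniform sheet.  All randomness derives from a single
seed; per-cell substreams make traces independent of cell order.

Trace mode returns ΔF/F₀-domain traces directly (fast, used for large-n
population studies); movie mode renders the traces into a multi-page TIFF
stack for the full image-based pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .protocol import StimProtocol

__all__ = [
    "SimConfig",
    "SimResult",
    "trace_mode_config",
    "movie_mode_config",
    "simulate_traces",
    "render_movie",
    "simulate_if_images",
]

# marginal peak-count mixture: class 3 is the mode (18%), 2.3% of cells show
# 8 peaks, 15.7% show more than 8, and over half of all cells show >= 4
DEFAULT_PEAK_COUNT_PROBS: dict = {
    1: 0.10,
    2: 0.13,
    3: 0.18,
    4: 0.14,
    5: 0.11,
    6: 0.09,
    7: 0.07,
    8: 0.023,
    ">8": 0.157,
}

# class-specific oscillation frequencies (mHz); periods are their reciprocals
DEFAULT_CLASS_FREQ_MHZ: dict = {
    2: 13.0,
    3: 17.0,
    4: 22.0,
    5: 26.0,
    6: 29.0,
    7: 30.0,
    8: 33.0,
    ">8": 40.0,
}


@dataclass
class SimConfig:
    """All generator parameters. Defaults define the standard study conditions."""

    # field geometry
    field_size: tuple[int, int] = (256, 256)  # (rows, cols) px
    pixel_size: float = 2.0  # µm / px
    n_frames: int = 330
    frame_interval: float = 1.0  # s
    protocol: StimProtocol = field(default_factory=StimProtocol)
    electrode_xy: tuple[float, float] = (0.0, 0.0)  # µm, field corner

    # cell placement
    n_cells: int = 300
    cell_radius_range: tuple[float, float] = (5.0, 8.0)  # µm
    min_cell_separation: float = 16.0  # µm, enforced when placing for movies
    enforce_separation: bool = True
    r_range: tuple[float, float] = (10.0, 470.0)  # radial placement limits, µm

    # wave kinetics
    v_proximal: float = 4.5  # µm/s
    v_distal: float = 6.0  # µm/s
    velocity_breakpoint: float = 150.0  # µm
    first_peak_jitter_sd: float = 1.0  # s
    fast_responder_fraction: float = 0.0  # distal synaptically-driven outliers

    # first-peak amplitude; the scale is set so the dimmest first peaks at
    # 500 µm still clear the 0.25 excursion inclusion criterion after
    # smoothing — responders are detectable by construction, as in a real
    # population where the criterion itself defines the responder set
    amp_at_zero: float = 10.0  # ΔF/F0
    amp_plateau: float = 100.0  # µm; decay applies beyond this distance
    amp_decay_length: float = 150.0  # µm
    proximal_amp_jitter: float = 0.5  # lognormal sigma inside the plateau
    distal_amp_jitter: float = 0.1  # lognormal sigma beyond the plateau

    # oscillation structure
    peak_count_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_PEAK_COUNT_PROBS)
    )
    class_freq_mhz: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_FREQ_MHZ))
    freq_between_cell_sd: float = 2.5  # mHz
    period_jitter_sd: float = 2.0  # s, within-cell interval jitter
    refractory_coefficient: float = 1.0  # s per ΔF/F0 unit, delays peak 2
    subsequent_amp_frac: float = 0.5  # later peaks relative to the first
    subsequent_amp_floor: float = 0.3  # ΔF/F0

    # transient waveform
    rise_time: float = 6.0  # s
    decay_tau: float = 15.0  # s
    linear_decay_fraction: float = 0.01  # cells <= 60 µm with linear decay

    # responsiveness and noise
    non_responder_fraction: float = 0.10
    trace_noise_sd: float = 0.0  # ΔF/F0-domain noise (trace mode)
    noise_sd: float = 40.0  # intensity units, per rendered pixel
    baseline_mean: float = 1500.0  # cell baseline fluorescence
    baseline_sd: float = 150.0
    background_mean: float = 200.0

    seed: int = 0

    # --- derived quantities -------------------------------------------------
    @property
    def class_period_s(self) -> dict:
        """Base inter-peak period per class, seconds (1000 / frequency)."""
        return {k: 1000.0 / f for k, f in self.class_freq_mhz.items()}

    @property
    def recording_end_s(self) -> float:
        """Last frame time relative to stimulation onset, seconds."""
        return (self.n_frames - 1) * self.frame_interval - self.protocol.onset_time

    def validate(self) -> None:
        probs = np.array(list(self.peak_count_probs.values()), dtype=float)
        if not np.isclose(probs.sum(), 1.0, atol=1e-6):
            raise ValueError(f"peak_count_probs must sum to 1, got {probs.sum():.4f}")
        if (probs < 0).any():
            raise ValueError("peak_count_probs must be non-negative")
        if self.v_proximal <= 0 or self.v_distal <= 0:
            raise ValueError("velocities must be > 0")
        if self.amp_decay_length <= 0:
            raise ValueError("amp_decay_length must be > 0")
        for k, period in self.class_period_s.items():
            if period <= 5.0:
                raise ValueError(
                    f"class period for class {k} ({period:.1f} s) must exceed the "
                    "5 s minimum peak width"
                )
        if self.r_range[0] <= 0 or self.r_range[1] <= self.r_range[0]:
            raise ValueError(f"invalid r_range {self.r_range}")
        # a 3-peak cell at the far edge must fit its train in the window
        far_t1 = self.first_peak_time(self.r_range[1])
        t3 = far_t1 + 2 * self.class_period_s[3]
        if t3 > self.recording_end_s:
            raise ValueError(
                "recording window too short: a 3-peak train at the far edge ends "
                f"at {t3:.0f} s but the window closes at {self.recording_end_s:.0f} s"
            )

    def first_peak_time(self, distance: float) -> float:
        """Noise-free time-to-first-peak (s since onset) at a distance (µm)."""
        bp = self.velocity_breakpoint
        if distance <= bp:
            return distance / self.v_proximal
        return bp / self.v_proximal + (distance - bp) / self.v_distal

    def first_peak_amp(self, distance: float) -> float:
        """Noise-free first-peak amplitude (ΔF/F0) at a distance (µm)."""
        excess = max(0.0, distance - self.amp_plateau)
        return self.amp_at_zero * np.exp(-excess / self.amp_decay_length)


def trace_mode_config(n_cells: int = 5000, seed: int = 0, **overrides) -> SimConfig:
    """Standard configuration for fast large-population trace simulations.

    Placement separation is not enforced (no rendering), radial range spans
    the full 0–500 µm analysis window and a small amount of ΔF/F₀-domain
    noise stands in for pixel noise.
    """
    cfg = SimConfig(
        n_cells=n_cells,
        seed=seed,
        enforce_separation=False,
        r_range=(10.0, 500.0),
        trace_noise_sd=0.02,
    )
    return replace(cfg, **overrides) if overrides else cfg


def movie_mode_config(n_cells: int = 300, seed: int = 0, **overrides) -> SimConfig:
    """Standard configuration for rendered-movie simulations.

    The electrode sits at the centre of a 512×512 px field (2 µm/px) so
    every distance annulus has room for its share of cells under the
    minimum-separation constraint; a corner electrode in a small field
    cannot hold the proximal cell density and would skew the radial
    distribution of the population.
    """
    cfg = SimConfig(
        n_cells=n_cells,
        seed=seed,
        field_size=(512, 512),
        electrode_xy=(512.0, 512.0),
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class SimResult:
    """Traces plus ground truth from one simulation run."""

    raw: np.ndarray  # (n_cells, n_frames) raw-fluorescence traces
    dff: np.ndarray  # (n_cells, n_frames) noise-free ΔF/F0 traces
    truth: pd.DataFrame  # per-cell ground truth
    config: SimConfig


# ---------------------------------------------------------------------------
# placement

def _place_cells(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Sample (x, y) µm positions: distance uniform in r_range, angle uniform.

    Rejection-samples angles so every cell lies inside the field; with
    ``enforce_separation`` a cell is re-drawn until it clears
    ``min_cell_separation`` from all accepted cells (bounded retries).
    """
    h_um = cfg.field_size[0] * cfg.pixel_size
    w_um = cfg.field_size[1] * cfg.pixel_size
    ex, ey = cfg.electrode_xy
    margin = cfg.cell_radius_range[1] if cfg.enforce_separation else 0.0
    pts: list[tuple[float, float]] = []
    for _ in range(cfg.n_cells):
        for attempt in range(300):
            d = rng.uniform(*cfg.r_range)
            theta = rng.uniform(0.0, 2.0 * np.pi)
            x, y = ex + d * np.cos(theta), ey + d * np.sin(theta)
            if not (margin <= x <= w_um - margin and margin <= y <= h_um - margin):
                continue
            if cfg.enforce_separation and any(
                (x - px) ** 2 + (y - py) ** 2 < cfg.min_cell_separation**2
                for px, py in pts
            ):
                continue
            pts.append((x, y))
            break
        else:
            raise RuntimeError(
                f"could not place cell {len(pts)} after 300 attempts; "
                "lower n_cells or min_cell_separation"
            )
    return np.array(pts)


# ---------------------------------------------------------------------------
# per-cell trace synthesis

def _truncated_normal(rng: np.random.Generator, mu: float, sd: float, lower: float) -> float:
    if sd <= 0:
        return max(mu, lower)
    for _ in range(200):
        v = rng.normal(mu, sd)
        if v >= lower:
            return v
    return lower + abs(rng.normal(0.0, sd / 10.0))


def _draw_peak_train(
    cfg: SimConfig,
    rng: np.random.Generator,
    t1: float,
    amp: float,
) -> tuple[np.ndarray, float]:
    """Peak times (s since onset) for one cell and its base period.

    The class is drawn from the peak-count mixture; the cell's base
    oscillation frequency comes from a normal around the class frequency,
    truncated from below so the whole train fits inside the recording
    window (cells that cannot sustain their drawn count at a feasible
    frequency drop one peak and retry).
    """
    classes = list(cfg.peak_count_probs.keys())
    probs = np.array([cfg.peak_count_probs[k] for k in classes], dtype=float)
    k = classes[rng.choice(len(classes), p=probs / probs.sum())]
    if k == 1:
        return np.array([t1]), np.nan

    count = int(k) if k != ">8" else int(rng.choice([9, 10], p=[0.6, 0.4]))
    min_count = 9 if k == ">8" else 2
    margin = 4.0  # keeps the last apex clear of the window edge
    refractory = cfg.refractory_coefficient * amp
    mu = cfg.class_freq_mhz[k]
    sd = cfg.freq_between_cell_sd
    while True:
        t_avail = cfg.recording_end_s - margin - t1 - refractory
        if t_avail > 0:
            f_min = 1000.0 * (count - 1) / t_avail
            if f_min <= mu + 4 * sd or count <= min_count:
                break
        if count <= min_count:
            f_min = mu  # degenerate geometry; pin at the class mean
            break
        count -= 1
    f_cell = _truncated_normal(rng, mu, sd, f_min)
    period = 1000.0 / f_cell

    intervals = rng.normal(period, cfg.period_jitter_sd, size=count - 1)
    intervals = np.clip(intervals, 6.0, None)
    intervals[0] += refractory
    times = t1 + np.concatenate([[0.0], np.cumsum(intervals)])
    times = times[times <= cfg.recording_end_s - 2.0]
    return times, period


def _transient(
    t_rel: np.ndarray, amp: float, rise: float, tau: float, linear: bool
) -> np.ndarray:
    """One calcium transient: linear rise to the apex, then decay."""
    y = np.zeros_like(t_rel)
    rising = (t_rel >= -rise) & (t_rel < 0)
    y[rising] = amp * (1.0 + t_rel[rising] / rise)
    falling = t_rel >= 0
    if linear:
        y[falling] = amp * np.clip(1.0 - t_rel[falling] / (2.0 * tau), 0.0, None)
    else:
        y[falling] = amp * np.exp(-t_rel[falling] / tau)
    return y


def simulate_traces(cfg: SimConfig) -> SimResult:
    """Generate per-cell ΔF/F₀ traces and the ground-truth table.

    Returns raw-fluorescence traces (baseline × (1 + ΔF/F₀) plus optional
    trace-domain noise), the noise-free ΔF/F₀ traces and a per-cell truth
    DataFrame with position, distance, responder flag, true first-peak time
    and amplitude, realised peak count and base period.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    cell_streams = ss.spawn(cfg.n_cells + 1)[1:]

    positions = _place_cells(cfg, master)
    ex, ey = cfg.electrode_xy
    distances = np.hypot(positions[:, 0] - ex, positions[:, 1] - ey)

    n_t = cfg.n_frames
    frame_times = np.arange(n_t) * cfg.frame_interval  # absolute seconds
    onset = cfg.protocol.onset_time
    raw = np.empty((cfg.n_cells, n_t))
    dff_clean = np.zeros((cfg.n_cells, n_t))
    rows = []
    for i in range(cfg.n_cells):
        rng = np.random.default_rng(cell_streams[i])
        d = distances[i]
        responder = rng.random() >= cfg.non_responder_fraction
        fast = responder and rng.random() < cfg.fast_responder_fraction
        linear_decay = d <= 60.0 and rng.random() < cfg.linear_decay_fraction

        if responder:
            if fast:
                t1 = abs(rng.normal(2.0, 1.0))
            else:
                t1 = cfg.first_peak_time(d) + rng.normal(0.0, cfg.first_peak_jitter_sd)
                t1 = max(t1, 0.5)
            sigma = (
                cfg.proximal_amp_jitter
                if d <= cfg.amp_plateau
                else cfg.distal_amp_jitter
            )
            amp = cfg.first_peak_amp(d) * rng.lognormal(0.0, sigma)
            times, period = _draw_peak_train(cfg, rng, t1, amp)
            sub = max(cfg.subsequent_amp_floor, cfg.subsequent_amp_frac * amp)
            amps = np.concatenate(
                [[amp], sub * rng.lognormal(0.0, 0.05, size=times.size - 1)]
            )
            trace = np.zeros(n_t)
            for tp, a in zip(times, amps):
                trace += _transient(
                    frame_times - (onset + tp), a, cfg.rise_time, cfg.decay_tau,
                    linear_decay,
                )
            trace[frame_times < onset] = 0.0  # stimulus causality
            dff_clean[i] = trace
            n_peaks = int(times.size)
            t_first, a_first = float(times[0]), float(amp)
        else:
            times = np.empty(0)
            period = np.nan
            n_peaks = 0
            t_first, a_first = np.nan, np.nan

        F0 = max(master.normal(cfg.baseline_mean, cfg.baseline_sd), 50.0)
        noisy = dff_clean[i] + (
            rng.normal(0.0, cfg.trace_noise_sd, size=n_t)
            if cfg.trace_noise_sd > 0
            else 0.0
        )
        raw[i] = F0 * (1.0 + noisy)
        rows.append(
            {
                "cell_id": i,
                "x_um": positions[i, 0],
                "y_um": positions[i, 1],
                "distance_um": d,
                "responder": responder,
                "true_first_peak_time_s": t_first,
                "true_first_amp": a_first,
                "true_peak_count": n_peaks,
                "true_period_s": period,
                "baseline_F": F0,
                "linear_decay": linear_decay,
                "fast_responder": fast,
            }
        )
    truth = pd.DataFrame(rows)
    return SimResult(raw=raw, dff=dff_clean, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# rendering

def render_movie(sim: SimResult) -> np.ndarray:
    """Render simulated traces as a T×H×W uint16 fluorescence movie.

    Each cell is a disk at its centroid whose intensity follows
    baseline × (1 + ΔF/F₀); pixels outside cells sit at the background level.
    Gaussian read noise is added everywhere.  Raises if any cell pair
    violates the configured minimum separation.
    """
    from skimage.draw import disk as draw_disk

    cfg = sim.config
    truth = sim.truth
    pos = truth[["x_um", "y_um"]].to_numpy()
    if len(pos) > 1:
        from scipy.spatial import cKDTree

        tree = cKDTree(pos)
        d_nn, _ = tree.query(pos, k=2)
        if (d_nn[:, 1] < cfg.min_cell_separation - 1e-9).any():
            raise ValueError(
                "cell placement violates min_cell_separation; regenerate with "
                "enforce_separation=True"
            )

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
    h, w = cfg.field_size
    n_t = cfg.n_frames
    radii_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD15C]))
    radii_um = radii_rng.uniform(*cfg.cell_radius_range, size=len(truth))

    masks = []
    for (x, y), r_um in zip(pos, radii_um):
        rr, cc = draw_disk(
            (y / cfg.pixel_size, x / cfg.pixel_size),
            r_um / cfg.pixel_size,
            shape=(h, w),
        )
        masks.append((rr, cc))

    dff = sim.dff
    F0 = truth["baseline_F"].to_numpy()
    stack = np.empty((n_t, h, w), dtype=np.uint16)
    for t in range(n_t):
        frame = np.full((h, w), cfg.background_mean, dtype=float)
        for i, (rr, cc) in enumerate(masks):
            frame[rr, cc] = F0[i] * (1.0 + dff[i, t])
        if cfg.noise_sd > 0:
            frame += rng.normal(0.0, cfg.noise_sd, size=frame.shape)
        stack[t] = np.clip(frame, 0, 65535).astype(np.uint16)
    return stack


def write_movie(stack: np.ndarray, path) -> None:
    """Write a T×H×W stack as a multi-page TIFF."""
    import tifffile

    tifffile.imwrite(path, stack, photometric="minisblack")


# ---------------------------------------------------------------------------
# immunofluorescence image simulation

IF_REGIONS = ("CA1", "CA3", "DG")


def simulate_if_images(
    n_per_group: int,
    effect: dict | None = None,
    seed: int = 0,
    regions: tuple[str, ...] = IF_REGIONS,
    image_size: tuple[int, int] = (256, 256),
    n_nuclei: int = 40,
    nucleus_axes_px: tuple[float, float] = (4.0, 6.0),
    nuclei_level: float = 3000.0,
    marker_mean: float = 1000.0,
    between_nucleus_sd: float = 150.0,
    between_image_sd: float = 50.0,
    pixel_noise_sd: float = 50.0,
    background: float = 100.0,
) -> tuple[list[dict], pd.DataFrame]:
    """Two-channel nucleus/marker image pairs with known marker intensities.

    For each region and each condition (``control`` / ``stimulated``),
    ``n_per_group`` image pairs are generated: a nuclei channel with
    elliptical nuclei on a dark background, and a marker channel in which
    each nucleus carries a known mean intensity.  The stimulated group's
    marker intensity is multiplied by ``effect[region]`` (default 1.0) in
    the named regions only.

    Returns the image records (dicts with region, condition, replicate and
    both uint16 channels) and a per-nucleus truth DataFrame.
    """
    effect = dict(effect or {})
    unknown = set(effect) - set(regions)
    if unknown:
        raise ValueError(f"effect keys must be subset of {regions}, got {sorted(unknown)}")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")

    from skimage.draw import ellipse as draw_ellipse

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1F1F]))
    h, w = image_size
    records, truth_rows = [], []
    for region in regions:
        mult = float(effect.get(region, 1.0))
        for condition in ("control", "stimulated"):
            scale = mult if condition == "stimulated" else 1.0
            for rep in range(n_per_group):
                image_offset = rng.normal(0.0, between_image_sd)
                nuc = np.full((h, w), background, dtype=float)
                mark = np.full((h, w), background, dtype=float)
                centres: list[tuple[float, float]] = []
                placed = 0
                attempts = 0
                while placed < n_nuclei and attempts < n_nuclei * 60:
                    attempts += 1
                    r = rng.uniform(12, h - 12)
                    c = rng.uniform(12, w - 12)
                    if any((r - pr) ** 2 + (c - pc) ** 2 < 18**2 for pr, pc in centres):
                        continue
                    a = rng.uniform(*nucleus_axes_px)
                    b = rng.uniform(*nucleus_axes_px)
                    rr, cc = draw_ellipse(
                        r, c, a, b, shape=(h, w), rotation=rng.uniform(0, np.pi)
                    )
                    level = scale * rng.normal(marker_mean, between_nucleus_sd)
                    level = max(level, 0.0) + image_offset
                    nuc[rr, cc] = nuclei_level
                    mark[rr, cc] = level
                    centres.append((r, c))
                    truth_rows.append(
                        {
                            "region": region,
                            "condition": condition,
                            "replicate": rep,
                            "nucleus": placed,
                            "row_px": r,
                            "col_px": c,
                            "true_marker": level,
                        }
                    )
                    placed += 1
                nuc += rng.normal(0.0, pixel_noise_sd, size=nuc.shape)
                mark += rng.normal(0.0, pixel_noise_sd, size=mark.shape)
                records.append(
                    {
                        "region": region,
                        "condition": condition,
                        "replicate": rep,
                        "nuclei_img": np.clip(nuc, 0, 65535).astype(np.uint16),
                        "marker_img": np.clip(mark, 0, 65535).astype(np.uint16),
                    }
                )
    return records, pd.DataFrame(truth_rows)
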