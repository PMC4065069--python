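"""End-to-end orchestration: simulate/segment → traces → peaks → kinetics.

The central entry point for array data is :func:`analyze_trace_matrix`, which
takes raw per-cell fluorescence traces and runs ΔF/F₀ normalisation,
smoothing, responder filtering, peak detection and classification, and the
distance-resolved wave fits.  :func:`run_calcium_pipeline` wraps it with
file I/O (TIFF in, CSV/YAML out) for the command-line interface, and
:func:`run_recovery_suite` repeats simulation + analysis across seeds to
tabulate configured-versus-recovered parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinetics import fit_amplitude_decay, fit_velocity
from .oscillations import (
    PeakSet,
    cell_frequency,
    find_peaks,
    peak_count_by_distance,
    peak_count_class,
    summarize_classes,
)
from .protocol import StimProtocol
from .segmentation import SegParams, reference_image, segment
from .simgen import SimConfig, SimResult, render_movie, simulate_traces, write_movie
from .traces import classify_responder, compute_dff, smooth

logger = logging.getLogger("cawave")

__all__ = [
    "TraceAnalysis",
    "AnalysisParams",
    "analyze_trace_matrix",
    "analyze_movie",
    "run_calcium_pipeline",
    "run_recovery_suite",
]


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable parameters of the trace/peak/kinetics stages."""

    baseline_frames: int = 20
    smooth_window: int = 9
    min_excursion: float = 0.25
    min_peak_width: float = 5.0
    min_prominence: float = 0.1
    breakpoint: float = 150.0
    max_distance: float = 500.0
    amp_fit_range: tuple[float, float] = (100.0, 500.0)
    exclude_first_interval: bool = False


@dataclass
class TraceAnalysis:
    """Per-cell analysis results plus population summaries."""

    cells: pd.DataFrame  # one row per cell
    peaksets: list[PeakSet]  # responders only, aligned with cells[responder]
    dff_smoothed: np.ndarray  # (n_cells, T)
    class_summary: pd.DataFrame | None = None
    velocity: object | None = None  # WaveKineticsResult
    amplitude_decay: object | None = None  # AmplitudeDecayFit
    count_by_distance: pd.DataFrame | None = None

    @property
    def n_responders(self) -> int:
        return int(self.cells["responder"].sum())


def analyze_trace_matrix(
    raw: np.ndarray,
    frame_interval: float,
    protocol: StimProtocol,
    distances: np.ndarray | None = None,
    params: AnalysisParams | None = None,
    cell_ids: np.ndarray | None = None,
) -> TraceAnalysis:
    """Run the trace pipeline on an (n_cells, T) raw-fluorescence matrix.

    When ``distances`` (µm from the electrode, one per cell) are provided the
    velocity, amplitude-decay and count-by-distance analyses run as well.
    """
    p = params or AnalysisParams()
    raw = np.asarray(raw, dtype=float)
    n_cells, n_t = raw.shape
    onset_frame = int(round(protocol.onset_time / frame_interval))
    ids = np.arange(n_cells) if cell_ids is None else np.asarray(cell_ids)

    sm_all = np.empty_like(raw)
    rows, peaksets = [], []
    for i in range(n_cells):
        F0, dff = compute_dff(raw[i], p.baseline_frames)
        sm = smooth(dff, p.smooth_window)
        sm_all[i] = sm
        ok, reason = classify_responder(sm, onset_frame, p.min_excursion)
        row = {
            "cell": int(ids[i]),
            "F0": F0,
            "responder": ok,
            "exclusion_reason": reason,
            "n_peaks": 0,
            "peak_class": 0,
            "frequency_mhz": np.nan,
            "first_peak_time_s": np.nan,
            "first_peak_amp": np.nan,
        }
        if ok:
            ps = find_peaks(
                sm,
                frame_interval,
                onset_time=protocol.onset_time,
                min_peak_width=p.min_peak_width,
                min_prominence=p.min_prominence,
                label=int(ids[i]),
            )
            peaksets.append(ps)
            row["n_peaks"] = ps.n_peaks
            row["peak_class"] = peak_count_class(ps)
            row["frequency_mhz"] = cell_frequency(ps, p.exclude_first_interval)
            if ps.n_peaks:
                row["first_peak_time_s"] = float(ps.peak_times[0])
                row["first_peak_amp"] = float(ps.peak_amplitudes[0])
        rows.append(row)
    cells = pd.DataFrame(rows)
    if distances is not None:
        cells["distance_um"] = np.asarray(distances, dtype=float)

    result = TraceAnalysis(cells=cells, peaksets=peaksets, dff_smoothed=sm_all)
    if peaksets:
        result.class_summary = summarize_classes(peaksets, p.exclude_first_interval)
    if distances is not None and peaksets:
        resp = cells["responder"] & (cells["n_peaks"] >= 1)
        t1 = cells.loc[resp, "first_peak_time_s"].to_numpy()
        d = cells.loc[resp, "distance_um"].to_numpy()
        a = cells.loc[resp, "first_peak_amp"].to_numpy()
        result.velocity = fit_velocity(t1, d, p.breakpoint, p.max_distance)
        result.amplitude_decay = fit_amplitude_decay(a, d, p.amp_fit_range)
        result.count_by_distance = peak_count_by_distance(
            peaksets, d, max_distance=p.max_distance
        )
    return result


def analyze_movie(
    stack: np.ndarray,
    pixel_size: float,
    protocol: StimProtocol,
    electrode_xy: tuple[float, float],
    frame_interval: float = 1.0,
    seg_params: SegParams | None = None,
    params: AnalysisParams | None = None,
) -> tuple[TraceAnalysis, pd.DataFrame, np.ndarray]:
    """Image-based pipeline: segment the movie, extract traces, analyse.

    Segmentation runs on the temporal mean of the pre-stimulus baseline
    frames: baseline brightness is activity-independent, so the reference
    histogram stays cleanly bimodal (background vs cells) and responding
    and non-responding cells are detected alike.  Returns the trace
    analysis, the cell table and the label map.
    """
    from .kinetics import distance_to_electrode
    from .traces import extract_traces

    n_base = (params or AnalysisParams()).baseline_frames
    ref = reference_image(stack[:n_base], "temporal_mean")
    label_map, cell_table = segment(ref, seg_params or SegParams(), pixel_size)
    if len(cell_table) == 0:
        raise ValueError("segmentation found no cells in the reference image")
    raw_traces = extract_traces(stack, label_map)
    labels = cell_table["label"].to_numpy()
    raw = np.stack([raw_traces[int(lab)] for lab in labels])
    distances = distance_to_electrode(cell_table, electrode_xy)
    analysis = analyze_trace_matrix(
        raw, frame_interval, protocol, distances=distances, params=params,
        cell_ids=labels,
    )
    return analysis, cell_table, label_map


# ---------------------------------------------------------------------------
# config-driven run

@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (YAML-serialisable)."""

    out_dir: str = "cawave_out"
    seed: int = 0
    input_tiff: str | None = None  # analyse an existing movie when set
    pixel_size: float = 2.0
    frame_interval: float = 1.0
    electrode_xy: tuple[float, float] | None = (0.0, 0.0)
    protocol: StimProtocol = field(default_factory=StimProtocol)
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    trace_only: bool = False
    seg: SegParams = field(default_factory=SegParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("out_dir", "seed", "input_tiff", "pixel_size",
                    "frame_interval", "trace_only"):
            if key in doc:
                kwargs[key] = doc[key]
        if "electrode_xy" in doc:
            kwargs["electrode_xy"] = (
                tuple(doc["electrode_xy"]) if doc["electrode_xy"] is not None else None
            )
        if "protocol" in doc:
            kwargs["protocol"] = StimProtocol.from_dict(doc["protocol"])
        if "simulate" in doc:
            kwargs["simulate"] = dict(doc["simulate"] or {})
        if "seg" in doc:
            kwargs["seg"] = SegParams(**doc["seg"])
        if "analysis" in doc:
            a = dict(doc["analysis"])
            if "amp_fit_range" in a:
                a["amp_fit_range"] = tuple(a["amp_fit_range"])
            kwargs["analysis"] = AnalysisParams(**a)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.input_tiff is not None:
            if not Path(self.input_tiff).exists():
                raise FileNotFoundError(f"input_tiff does not exist: {self.input_tiff}")
            if self.electrode_xy is None:
                raise ValueError(
                    "electrode_xy is required when analysing a real movie"
                )

    def echo(self) -> dict:
        return {
            "cawave_version": __version__,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "input_tiff": self.input_tiff,
            "pixel_size": self.pixel_size,
            "frame_interval": self.frame_interval,
            "electrode_xy": list(self.electrode_xy) if self.electrode_xy else None,
            "protocol": self.protocol.to_dict(),
            "simulate": self.simulate,
            "trace_only": self.trace_only,
            "seg": {
                "intensity_threshold": self.seg.intensity_threshold,
                "min_area": self.seg.min_area,
                "min_radius": self.seg.min_radius,
                "min_separation": self.seg.min_separation,
            },
            "analysis": {
                "baseline_frames": self.analysis.baseline_frames,
                "smooth_window": self.analysis.smooth_window,
                "min_excursion": self.analysis.min_excursion,
                "min_peak_width": self.analysis.min_peak_width,
                "min_prominence": self.analysis.min_prominence,
                "breakpoint": self.analysis.breakpoint,
                "max_distance": self.analysis.max_distance,
                "amp_fit_range": list(self.analysis.amp_fit_range),
                "exclude_first_interval": self.analysis.exclude_first_interval,
            },
        }


def _write_peaks_csv(peaksets: list[PeakSet], path: Path) -> None:
    rows = []
    for ps in peaksets:
        for j, (t, a) in enumerate(zip(ps.peak_times, ps.peak_amplitudes), start=1):
            rows.append({"cell": ps.label, "peak_index": j, "time_s": t, "amplitude": a})
    pd.DataFrame(rows, columns=["cell", "peak_index", "time_s", "amplitude"]).to_csv(
        path, index=False
    )


def _write_traces_csv(raw: np.ndarray, analysis: TraceAnalysis, path: Path) -> None:
    n_cells, n_t = raw.shape
    cells = analysis.cells["cell"].to_numpy()
    df = pd.DataFrame(
        {
            "cell": np.repeat(cells, n_t),
            "frame": np.tile(np.arange(n_t), n_cells),
            "raw_F": raw.ravel(),
            "dff_smoothed": analysis.dff_smoothed.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


def run_calcium_pipeline(cfg: PipelineConfig) -> dict:
    """Execute a full run and write the report bundle to ``cfg.out_dir``.

    Artefacts: ``cells.csv``, ``traces.csv``, ``responders.csv``,
    ``peaks.csv``, ``class_summary.csv``, ``kinetics.yaml``,
    ``count_by_distance.csv``, ``config_echo.yaml`` and ``run_log.txt``.
    Returns a manifest dict mapping artefact names to paths.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    echo = cfg.echo()
    cfg_hash = hashlib.sha256(
        json.dumps(echo, sort_keys=True).encode()
    ).hexdigest()[:16]

    log_lines = [f"cawave {__version__} run, config hash {cfg_hash}, seed {cfg.seed}"]

    if cfg.input_tiff is not None:
        import tifffile

        stack = tifffile.imread(cfg.input_tiff)
        log_lines.append(f"stage input: loaded {cfg.input_tiff} shape {stack.shape}")
        analysis, cell_table, _ = analyze_movie(
            stack, cfg.pixel_size, cfg.protocol, cfg.electrode_xy,
            cfg.frame_interval, cfg.seg, cfg.analysis,
        )
        raw_matrix = None
    else:
        sim_kwargs = dict(cfg.simulate)
        sim_kwargs.setdefault("seed", cfg.seed)
        base = SimConfig(protocol=cfg.protocol)
        sim_cfg = replace(base, **sim_kwargs)
        sim = simulate_traces(sim_cfg)
        log_lines.append(
            f"stage simulate: {sim_cfg.n_cells} cells, trace_only={cfg.trace_only}"
        )
        sim.truth.to_csv(out / "ground_truth.csv", index=False, float_format="%.6g")
        if cfg.trace_only:
            distances = sim.truth["distance_um"].to_numpy()
            analysis = analyze_trace_matrix(
                sim.raw, sim_cfg.frame_interval, sim_cfg.protocol,
                distances=distances, params=cfg.analysis,
            )
            cell_table = sim.truth[["cell_id", "x_um", "y_um", "distance_um"]]
            raw_matrix = sim.raw
        else:
            stack = render_movie(sim)
            write_movie(stack, out / "movie.tiff")
            log_lines.append("stage render: wrote movie.tiff")
            analysis, cell_table, _ = analyze_movie(
                stack, sim_cfg.pixel_size, sim_cfg.protocol, sim_cfg.electrode_xy,
                sim_cfg.frame_interval, cfg.seg, cfg.analysis,
            )
            raw_matrix = None

    manifest = {}
    cell_table.to_csv(out / "cells.csv", index=False, float_format="%.6g")
    manifest["cells"] = out / "cells.csv"
    analysis.cells.to_csv(out / "responders.csv", index=False, float_format="%.6g")
    manifest["responders"] = out / "responders.csv"
    _write_peaks_csv(analysis.peaksets, out / "peaks.csv")
    manifest["peaks"] = out / "peaks.csv"
    if raw_matrix is not None:
        _write_traces_csv(raw_matrix, analysis, out / "traces.csv")
        manifest["traces"] = out / "traces.csv"
    if analysis.class_summary is not None:
        analysis.class_summary.to_csv(
            out / "class_summary.csv", index=False, float_format="%.6g"
        )
        manifest["class_summary"] = out / "class_summary.csv"
    if analysis.count_by_distance is not None:
        analysis.count_by_distance.to_csv(
            out / "count_by_distance.csv", index=False, float_format="%.6g"
        )
        manifest["count_by_distance"] = out / "count_by_distance.csv"
    def _builtin(obj):
        if isinstance(obj, dict):
            return {k: _builtin(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_builtin(v) for v in obj]
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        return obj

    kin = {}
    if analysis.velocity is not None:
        kin["velocity"] = analysis.velocity.to_dict()
    if analysis.amplitude_decay is not None:
        ad = analysis.amplitude_decay
        kin["amplitude_decay"] = {
            "A0": ad.A0,
            "decay_length_um": None if np.isinf(ad.decay_length) else ad.decay_length,
            "no_decay": ad.no_decay,
            "r_squared": ad.r_squared,
            "n": ad.n,
            "fit_range_um": list(ad.fit_range),
        }
    with open(out / "kinetics.yaml", "w") as fh:
        yaml.safe_dump(_builtin(kin), fh, sort_keys=False)
    manifest["kinetics"] = out / "kinetics.yaml"
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=False)
    manifest["config_echo"] = out / "config_echo.yaml"
    log_lines.append(
        f"done: {analysis.n_responders} responders / {len(analysis.cells)} cells"
    )
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    manifest["run_log"] = out / "run_log.txt"
    for line in log_lines:
        logger.info(line)
    return manifest


# ---------------------------------------------------------------------------
# recovery harness

def run_recovery_suite(
    n_seeds: int,
    n_cells: int = 2000,
    base_seed: int = 1,
    overrides: dict | None = None,
    params: AnalysisParams | None = None,
) -> pd.DataFrame:
    """Configured-versus-recovered parameter table across simulation seeds.

    For each seed a trace-mode population is simulated and analysed; the
    table reports the recovered proximal/distal velocities, amplitude decay
    length, class-frequency means (k = 3..8) and the 3- and 8-peak class
    fractions, next to their configured values and pass/fail at the standard
    tolerances (velocities ±10%, decay length ±15%, frequencies ±2 mHz,
    fractions within the binomial 95% interval).
    """
    from .simgen import trace_mode_config

    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    rows = []
    for s in range(base_seed, base_seed + n_seeds):
        cfg = trace_mode_config(n_cells=n_cells, seed=s, **(overrides or {}))
        sim = simulate_traces(cfg)
        analysis = analyze_trace_matrix(
            sim.raw, cfg.frame_interval, cfg.protocol,
            distances=sim.truth["distance_um"].to_numpy(), params=params,
        )

        def add(name, configured, recovered, tol_kind, tol):
            if tol_kind == "rel":
                ok = abs(recovered - configured) <= tol * abs(configured)
            elif tol_kind == "abs":
                ok = abs(recovered - configured) <= tol
            else:  # binomial
                n = analysis.n_responders
                half = 1.96 * np.sqrt(configured * (1 - configured) / max(n, 1))
                ok = abs(recovered - configured) <= half
            rows.append(
                {
                    "seed": s,
                    "quantity": name,
                    "configured": configured,
                    "recovered": recovered,
                    "tolerance": tol,
                    "pass": bool(ok),
                }
            )

        v = analysis.velocity
        add("v_proximal_um_s", cfg.v_proximal, v.v_proximal, "rel", 0.10)
        add("v_distal_um_s", cfg.v_distal, v.v_distal, "rel", 0.10)
        ad = analysis.amplitude_decay
        add("amp_decay_length_um", cfg.amp_decay_length, ad.decay_length, "rel", 0.15)
        summary = analysis.class_summary.set_index("peak_class")
        for k in range(3, 9):
            add(
                f"class_{k}_frequency_mhz",
                cfg.class_freq_mhz[k],
                float(summary.loc[k, "mean_frequency_mhz"]),
                "abs",
                2.0,
            )
        n_resp = analysis.n_responders
        for k in (3, 8):
            frac = float(summary.loc[k, "n_cells"]) / n_resp
            add(f"class_{k}_fraction", cfg.peak_count_probs[k], frac, "binom", np.nan)
    return pd.DataFrame(rows)
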