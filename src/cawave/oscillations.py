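"""Major-peak detection and oscillation-frequency analysis.

Peaks are local maxima of the smoothed ΔF/F₀ trace whose width at half
prominence is at least a minimum peak width (default 5 s) and whose
prominence clears a floor (default 0.1 ΔF/F₀); small local wobbles riding on
a major transient are thereby ignored.  A cell's oscillation frequency is
1000 / mean(inter-peak interval in seconds), expressed in millihertz.

Cells are grouped into peak-count classes 1..8, with more than eight peaks
pooled into a ``">8"`` class; per-class frequency statistics and the
distribution of each class over distance-from-electrode bins are the two
population summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "PeakSet",
    "find_peaks",
    "peak_count_class",
    "cell_frequency",
    "summarize_classes",
    "peak_count_by_distance",
]

CLASS_GT8 = ">8"


@dataclass
class PeakSet:
    """Detected major peaks of one cell, in time order."""

    label: int
    peak_times: np.ndarray  # seconds since stimulation onset
    peak_amplitudes: np.ndarray  # smoothed ΔF/F0 at the peak frame

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        if self.peak_times.size != self.peak_amplitudes.size:
            raise ValueError("peak_times and peak_amplitudes must match")
        if self.peak_times.size > 1 and not np.all(np.diff(self.peak_times) > 0):
            raise ValueError("peak_times must be strictly increasing")

    @property
    def n_peaks(self) -> int:
        return int(self.peak_times.size)

    def intervals(self) -> np.ndarray:
        """Consecutive inter-peak intervals in seconds."""
        return np.diff(self.peak_times)


def find_peaks(
    dff_smoothed: np.ndarray,
    frame_interval: float,
    onset_time: float = 20.0,
    min_peak_width: float = 5.0,
    min_prominence: float = 0.1,
    label: int = 0,
) -> PeakSet:
    """Detect major peaks in a smoothed ΔF/F₀ series.

    The width criterion is evaluated at half prominence.  A peak whose decay
    is cut off by the end of the recording is kept if its rising flank is
    complete (its mirrored left half-width satisfies the criterion);
    truncated terminal rises are never counted because a maximum at the very
    last sample is not a local maximum.

    Peak times are reported in seconds since stimulation onset.
    """
    x = np.asarray(dff_smoothed, dtype=float)
    if frame_interval <= 0:
        raise ValueError(f"frame_interval must be > 0, got {frame_interval}")
    if min_peak_width < frame_interval:
        raise ValueError("min_peak_width must be at least one frame interval")

    idx, _ = signal.find_peaks(x)
    if idx.size == 0:
        return PeakSet(label, np.empty(0), np.empty(0))

    proms, left_bases, right_bases = signal.peak_prominences(x, idx)
    # a peak whose decay runs into the recording end has its prominence (and
    # width) truncated on the right; judge such peaks by their rising flank
    censored = right_bases >= x.size - 1
    left_proms = x[idx] - np.array(
        [x[lo : p + 1].min() for lo, p in zip(left_bases, idx)]
    )
    eff_proms = np.where(censored, np.maximum(proms, left_proms), proms)
    keep_prom = eff_proms >= min_prominence
    idx, censored = idx[keep_prom], censored[keep_prom]
    if idx.size == 0:
        return PeakSet(label, np.empty(0), np.empty(0))
    prom_data = (
        eff_proms[keep_prom], left_bases[keep_prom], right_bases[keep_prom]
    )

    widths, _, left_ips, _ = signal.peak_widths(
        x, idx, rel_height=0.5, prominence_data=prom_data
    )
    min_w = min_peak_width / frame_interval
    mirrored = 2.0 * (idx - left_ips)  # rising flank reflected about the apex
    keep_width = (widths >= min_w) | (censored & (mirrored >= min_w))

    idx = idx[keep_width]
    times = idx * frame_interval - onset_time
    return PeakSet(label, times, x[idx])


def peak_count_class(ps: PeakSet | int) -> int | str:
    """Peak-count class: 0, 1..8, or ``">8"``."""
    n = ps if isinstance(ps, int) else ps.n_peaks
    if n < 0:
        raise ValueError("peak count cannot be negative")
    return n if n <= 8 else CLASS_GT8


def cell_frequency(ps: PeakSet, exclude_first_interval: bool = False) -> float:
    """Oscillation frequency of one cell in mHz, NaN for < 2 peaks.

    By default all consecutive inter-peak intervals contribute, including the
    first-to-second interval that carries the amplitude-dependent refractory
    delay; ``exclude_first_interval=True`` drops it (requires >= 3 peaks for
    a defined value).
    """
    iv = ps.intervals()
    if exclude_first_interval:
        iv = iv[1:]
    if iv.size == 0:
        return float("nan")
    return 1000.0 / float(iv.mean())


def summarize_classes(
    peaksets: list[PeakSet], exclude_first_interval: bool = False
) -> pd.DataFrame:
    """Per peak-count-class population statistics.

    Returns one row per class (1..8 and ``">8"``) with the cell count, the
    mean and SD of per-cell frequency (mHz; classes with >= 2 peaks), and
    the mean inter-peak interval for each transition 1→2 ... 7→8.
    """
    if not peaksets:
        raise ValueError("no peak sets supplied")
    classes: list[int | str] = list(range(1, 9)) + [CLASS_GT8]
    by_class: dict[int | str, list[PeakSet]] = {k: [] for k in classes}
    for ps in peaksets:
        k = peak_count_class(ps)
        if k == 0:
            continue
        by_class[k].append(ps)

    rows = []
    for k in classes:
        members = by_class[k]
        freqs = np.array(
            [cell_frequency(ps, exclude_first_interval) for ps in members]
        )
        freqs = freqs[np.isfinite(freqs)]
        row: dict = {
            "peak_class": k,
            "n_cells": len(members),
            "mean_frequency_mhz": freqs.mean() if freqs.size else np.nan,
            "sd_frequency_mhz": freqs.std(ddof=1) if freqs.size > 1 else np.nan,
        }
        for j in range(1, 8):
            ivs = [
                ps.intervals()[j - 1] for ps in members if ps.n_peaks > j
            ]
            row[f"mean_interval_{j}_{j + 1}_s"] = (
                float(np.mean(ivs)) if ivs else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def peak_count_by_distance(
    peaksets: list[PeakSet],
    distances: np.ndarray,
    bin_width: float = 50.0,
    max_distance: float | None = None,
) -> pd.DataFrame:
    """Distribution of each peak-count class over distance bins.

    Rows are classes, columns distance bins; each row is normalised to sum
    to 1 over bins (the proportion of that class's cells found in each bin).
    Classes with no cells yield a zero row.
    """
    distances = np.asarray(distances, dtype=float)
    if len(peaksets) != distances.size:
        raise ValueError("distances must be available for every cell")
    if max_distance is None:
        max_distance = float(distances.max()) if distances.size else bin_width
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    if edges[-1] < max_distance:
        edges = np.append(edges, edges[-1] + bin_width)

    classes: list[int | str] = list(range(1, 9)) + [CLASS_GT8]
    table = np.zeros((len(classes), edges.size - 1))
    index = {k: i for i, k in enumerate(classes)}
    for ps, d in zip(peaksets, distances):
        k = peak_count_class(ps)
        if k == 0:
            continue
        b = min(int(np.searchsorted(edges, d, side="right")) - 1, edges.size - 2)
        table[index[k], max(b, 0)] += 1

    sums = table.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(sums > 0, table / sums, 0.0)
    cols = [f"[{edges[i]:.0f},{edges[i + 1]:.0f})" for i in range(edges.size - 1)]
    out = pd.DataFrame(norm, columns=cols)
    out.insert(0, "peak_class", classes)
    out.insert(1, "n_cells", sums.ravel().astype(int))
    return out
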