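"""Per-cell ΔF/F₀ trace extraction, smoothing and responder classification.

The normalised calcium signal is ΔF/F₀ = (F − F₀)/F₀ where F₀ is the mean
raw fluorescence of the cell over the baseline frames acquired before
stimulation.  Traces are denoised with a centred moving-average filter
(default 9 frames) before peak analysis.

A cell is excluded from further analysis ("non-responder") if the maximum of
its smoothed trace occurs before stimulation onset, or if the excursion of
the smoothed trace (max − mean) is below a threshold (default 0.25 ΔF/F₀).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "CalciumTrace",
    "extract_traces",
    "compute_dff",
    "smooth",
    "classify_responder",
    "build_traces",
]

REASON_NONE = "none"
REASON_PRE_STIM = "pre_stim_peak"
REASON_LOW_AMP = "low_amplitude"


@dataclass
class CalciumTrace:
    """Raw and normalised fluorescence time course of one cell."""

    label: int
    raw_F: np.ndarray
    F0: float
    dff: np.ndarray
    dff_smoothed: np.ndarray
    responder: bool = True
    exclusion_reason: str = REASON_NONE

    def __post_init__(self) -> None:
        if len(self.dff) != len(self.raw_F):
            raise ValueError("dff and raw_F must have the same length")


def extract_traces(stack: np.ndarray, label_map: np.ndarray) -> dict[int, np.ndarray]:
    """Mean intensity over each labelled mask, per frame.

    Returns a dict mapping label -> 1-D array of length T.
    """
    stack = np.asarray(stack)
    label_map = np.asarray(label_map)
    if stack.ndim != 3:
        raise ValueError("stack must be T x H x W")
    if label_map.shape != stack.shape[1:]:
        raise ValueError(
            f"label map shape {label_map.shape} does not match frame "
            f"geometry {stack.shape[1:]}"
        )
    labels = np.unique(label_map)
    labels = labels[labels > 0]
    if labels.size == 0:
        return {}
    means = np.empty((stack.shape[0], labels.size))
    for t in range(stack.shape[0]):
        means[t] = ndi.mean(stack[t], labels=label_map, index=labels)
    return {int(lab): means[:, j].copy() for j, lab in enumerate(labels)}


def trace_for_labels(
    stack: np.ndarray, label_map: np.ndarray, labels: list[int]
) -> dict[int, np.ndarray]:
    """Like :func:`extract_traces` but for an explicit label list.

    Raises if a requested label is absent from the map.
    """
    present = set(np.unique(label_map).tolist())
    missing = [lab for lab in labels if lab not in present]
    if missing:
        raise ValueError(f"labels absent from label map: {missing}")
    all_traces = extract_traces(stack, label_map)
    return {lab: all_traces[lab] for lab in labels}


def compute_dff(raw: np.ndarray, baseline_frames: int = 20) -> tuple[float, np.ndarray]:
    """Baseline F₀ (mean of the first ``baseline_frames`` samples) and ΔF/F₀."""
    raw = np.asarray(raw, dtype=float)
    if baseline_frames < 1 or baseline_frames >= raw.size:
        raise ValueError(
            f"baseline_frames must be in [1, {raw.size - 1}], got {baseline_frames}"
        )
    F0 = float(raw[:baseline_frames].mean())
    if F0 <= 0:
        raise ValueError(f"non-positive baseline F0 ({F0}); cell flagged")
    return F0, (raw - F0) / F0


def smooth(dff: np.ndarray, window: int = 9) -> np.ndarray:
    """Centred moving average with shrinking symmetric windows at the edges.

    Every output sample is the mean of the input over the in-range part of a
    window of ``window`` samples centred on it, so the output has the same
    length as the input and a constant series is left unchanged.
    """
    dff = np.asarray(dff, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window > dff.size:
        raise ValueError(f"window {window} exceeds series length {dff.size}")
    kernel = np.ones(window)
    sums = np.convolve(dff, kernel, mode="same")
    counts = np.convolve(np.ones_like(dff), kernel, mode="same")
    return sums / counts


def classify_responder(
    dff_smoothed: np.ndarray,
    onset_frame: int,
    min_excursion: float = 0.25,
    pre_stim_cutoff: str = "onset",
    offset_frame: int | None = None,
) -> tuple[bool, str]:
    """Apply the responder inclusion filter to a smoothed trace.

    A cell is a non-responder if its smoothed-trace maximum occurs before
    the stimulus (``pre_stim_peak``) or if max − mean of the smoothed trace
    falls below ``min_excursion`` (``low_amplitude``).  The pre-stimulus
    cutoff is the onset frame by default; with ``pre_stim_cutoff='offset'``
    the frame at which the stimulus completes is used instead.
    """
    dff_smoothed = np.asarray(dff_smoothed, dtype=float)
    if not 0 <= onset_frame < dff_smoothed.size:
        raise ValueError(f"onset_frame {onset_frame} outside series")
    if pre_stim_cutoff == "onset":
        cutoff = onset_frame
    elif pre_stim_cutoff == "offset":
        if offset_frame is None:
            raise ValueError("offset_frame required when pre_stim_cutoff='offset'")
        cutoff = offset_frame
    else:
        raise ValueError(f"unknown pre_stim_cutoff {pre_stim_cutoff!r}")

    if int(np.argmax(dff_smoothed)) < cutoff:
        return False, REASON_PRE_STIM
    if float(dff_smoothed.max() - dff_smoothed.mean()) < min_excursion:
        return False, REASON_LOW_AMP
    return True, REASON_NONE


def build_traces(
    raw_traces: dict[int, np.ndarray],
    baseline_frames: int = 20,
    smooth_window: int = 9,
    onset_frame: int = 20,
    min_excursion: float = 0.25,
) -> list[CalciumTrace]:
    """Run the full per-cell trace pipeline: ΔF/F₀, smoothing, filtering."""
    out = []
    for label, raw in sorted(raw_traces.items()):
        F0, dff = compute_dff(raw, baseline_frames)
        sm = smooth(dff, smooth_window)
        ok, reason = classify_responder(sm, onset_frame, min_excursion)
        out.append(
            CalciumTrace(
                label=label,
                raw_F=np.asarray(raw, dtype=float),
                F0=F0,
                dff=dff,
                dff_smoothed=sm,
                responder=ok,
                exclusion_reason=reason,
            )
        )
    return out
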