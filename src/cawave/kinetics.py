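"""Distance-resolved wave kinetics: propagation velocity and amplitude decay.

The evoked wave is characterised by regressing time-to-first-peak on distance
from the stimulating electrode.  The fit is done overall and on two segments
split at a fixed breakpoint (default 150 µm); apparent velocity is the
reciprocal of the fitted slope, in µm/s.  First-peak amplitude beyond a
plateau region decays exponentially with distance and is fitted by ordinary
least squares on log-amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "WaveKineticsResult",
    "AmplitudeDecayFit",
    "distance_to_electrode",
    "fit_velocity",
    "fit_amplitude_decay",
    "estimate_breakpoint",
]


@dataclass
class SegmentFit:
    velocity: float  # µm/s
    slope: float  # s/µm
    intercept: float  # s
    r_squared: float
    n: int


@dataclass
class WaveKineticsResult:
    """Velocity fits of the radial wave (overall + two segments)."""

    overall: SegmentFit
    proximal: SegmentFit
    distal: SegmentFit
    breakpoint: float
    max_distance: float

    @property
    def v_overall(self) -> float:
        return self.overall.velocity

    @property
    def v_proximal(self) -> float:
        return self.proximal.velocity

    @property
    def v_distal(self) -> float:
        return self.distal.velocity

    def to_dict(self) -> dict:
        return {
            "breakpoint_um": self.breakpoint,
            "max_distance_um": self.max_distance,
            "v_overall_um_s": self.overall.velocity,
            "v_proximal_um_s": self.proximal.velocity,
            "v_distal_um_s": self.distal.velocity,
            "r2_overall": self.overall.r_squared,
            "r2_proximal": self.proximal.r_squared,
            "r2_distal": self.distal.r_squared,
            "n_overall": self.overall.n,
            "n_proximal": self.proximal.n,
            "n_distal": self.distal.n,
        }


@dataclass
class AmplitudeDecayFit:
    """Exponential fit A(d) = A0 * exp(-(d - range_start) / decay_length)."""

    A0: float
    decay_length: float  # µm; inf when no decay is detectable
    r_squared: float
    n: int
    fit_range: tuple[float, float]
    no_decay: bool = False


def distance_to_electrode(cells, electrode_xy: tuple[float, float]) -> np.ndarray:
    """Euclidean distance (µm) from each cell centroid to the electrode tip.

    ``cells`` is a CellTable DataFrame with ``x_um``/``y_um`` columns, or an
    (n, 2) array of centroids in µm.
    """
    if hasattr(cells, "columns"):
        xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(cells, dtype=float).reshape(-1, 2)
    ex, ey = electrode_xy
    return np.hypot(xy[:, 0] - ex, xy[:, 1] - ey)


def _ols_segment(times: np.ndarray, dists: np.ndarray) -> SegmentFit:
    if dists.size < 3:
        raise ValueError(f"need at least 3 cells per fit segment, got {dists.size}")
    if np.ptp(dists) == 0:
        raise ValueError("degenerate fit: zero variance in distances")
    res = stats.linregress(dists, times)
    if res.slope <= 0:
        warnings.warn("non-positive time-on-distance slope; velocity undefined")
        velocity = float("inf") if res.slope == 0 else float("nan")
    else:
        velocity = float(1.0 / res.slope)
    return SegmentFit(
        velocity=velocity,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(dists.size),
    )


def fit_velocity(
    first_peak_times: np.ndarray,
    distances: np.ndarray,
    breakpoint: float = 150.0,
    max_distance: float = 500.0,
) -> WaveKineticsResult:
    """Regress time-to-first-peak on distance; velocity = 1/slope.

    Fits three ordinary least-squares lines: over the full range
    [0, max_distance], the proximal segment [0, breakpoint] and the distal
    segment [breakpoint, max_distance].  Times are in seconds since
    stimulation onset, distances in µm.
    """
    t = np.asarray(first_peak_times, dtype=float)
    d = np.asarray(distances, dtype=float)
    if t.size != d.size:
        raise ValueError("times and distances must have equal length")
    ok = np.isfinite(t) & np.isfinite(d) & (d <= max_distance)
    t, d = t[ok], d[ok]
    prox = d <= breakpoint
    dist = d >= breakpoint
    return WaveKineticsResult(
        overall=_ols_segment(t, d),
        proximal=_ols_segment(t[prox], d[prox]),
        distal=_ols_segment(t[dist], d[dist]),
        breakpoint=breakpoint,
        max_distance=max_distance,
    )


def fit_amplitude_decay(
    first_amps: np.ndarray,
    distances: np.ndarray,
    fit_range: tuple[float, float] = (100.0, 500.0),
) -> AmplitudeDecayFit:
    """Fit A(d) = A0 exp(-(d - fit_range[0]) / λ) by OLS on log amplitude.

    Non-positive amplitudes inside the range are excluded with a warning; a
    non-negative log-amplitude slope is reported as ``no_decay`` with an
    infinite decay length.
    """
    a = np.asarray(first_amps, dtype=float)
    d = np.asarray(distances, dtype=float)
    if a.size != d.size:
        raise ValueError("amplitudes and distances must have equal length")
    lo, hi = fit_range
    in_range = (d >= lo) & (d <= hi) & np.isfinite(a) & np.isfinite(d)
    bad = in_range & (a <= 0)
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} non-positive amplitudes from decay fit")
    sel = in_range & (a > 0)
    if sel.sum() == 0:
        raise ValueError("no positive amplitudes inside the fit range")
    if sel.sum() < 5:
        raise ValueError(f"need at least 5 cells in the fit range, got {int(sel.sum())}")
    x = d[sel] - lo
    res = stats.linregress(x, np.log(a[sel]))
    if res.slope >= 0:
        return AmplitudeDecayFit(
            A0=float(np.exp(res.intercept)),
            decay_length=float("inf"),
            r_squared=float(res.rvalue**2),
            n=int(sel.sum()),
            fit_range=(lo, hi),
            no_decay=True,
        )
    return AmplitudeDecayFit(
        A0=float(np.exp(res.intercept)),
        decay_length=float(-1.0 / res.slope),
        r_squared=float(res.rvalue**2),
        n=int(sel.sum()),
        fit_range=(lo, hi),
    )


def estimate_breakpoint(
    first_peak_times: np.ndarray,
    distances: np.ndarray,
    candidates: np.ndarray | None = None,
    max_distance: float = 500.0,
) -> float:
    """Grid-search the two-segment breakpoint minimising pooled residual SSE.

    Optional diagnostic; the standard analysis keeps the breakpoint fixed.
    """
    t = np.asarray(first_peak_times, dtype=float)
    d = np.asarray(distances, dtype=float)
    if candidates is None:
        candidates = np.arange(60.0, max_distance - 50.0, 10.0)
    best_bp, best_sse = None, np.inf
    for bp in candidates:
        prox, dist = d <= bp, d >= bp
        if prox.sum() < 3 or dist.sum() < 3:
            continue
        sse = 0.0
        for m in (prox, dist):
            res = stats.linregress(d[m], t[m])
            resid = t[m] - (res.intercept + res.slope * d[m])
            sse += float(resid @ resid)
        if sse < best_sse:
            best_bp, best_sse = float(bp), sse
    if best_bp is None:
        raise ValueError("no candidate breakpoint admits 3 cells per segment")
    return best_bp


def plot_wave_fits(result: WaveKineticsResult, times, distances, amps=None,
                   decay: AmplitudeDecayFit | None = None, path=None):
    """Scatter + fitted lines for the velocity (and optionally decay) fits.

    Requires matplotlib (optional dependency); saves to ``path`` if given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_ax = 2 if amps is not None else 1
    fig, axes = plt.subplots(1, n_ax, figsize=(5 * n_ax, 4))
    axes = np.atleast_1d(axes)
    ax = axes[0]
    ax.scatter(distances, times, s=4, alpha=0.4, color="grey")
    for seg, lo, hi, color in (
        (result.proximal, 0, result.breakpoint, "tab:blue"),
        (result.distal, result.breakpoint, result.max_distance, "tab:red"),
    ):
        xs = np.linspace(lo, hi, 20)
        ax.plot(xs, seg.intercept + seg.slope * xs, color=color,
                label=f"{seg.velocity:.1f} µm/s")
    ax.set_xlabel("distance from electrode (µm)")
    ax.set_ylabel("time to first peak (s)")
    ax.legend()
    if amps is not None:
        ax2 = axes[1]
        ax2.scatter(distances, amps, s=4, alpha=0.4, color="grey")
        if decay is not None and not decay.no_decay:
            xs = np.linspace(*decay.fit_range, 50)
            ax2.plot(xs, decay.A0 * np.exp(-(xs - decay.fit_range[0]) / decay.decay_length),
                     color="tab:red", label=f"λ = {decay.decay_length:.0f} µm")
            ax2.legend()
        ax2.set_xlabel("distance from electrode (µm)")
        ax2.set_ylabel("first-peak ΔF/F₀")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
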