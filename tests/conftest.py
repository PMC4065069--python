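import numpy as np
import pytest


@pytest.fixture(scope="session")
def gaussian_bump():
    """Factory for smooth test traces made of Gaussian bumps."""

    def make(n_frames, centres, heights=None, sd=5.0, dt=1.0):
        t = np.arange(n_frames) * dt
        heights = heights or [1.0] * len(centres)
        y = np.zeros(n_frames)
        for c, h in zip(centres, heights):
            y += h * np.exp(-0.5 * ((t - c) / sd) ** 2)
        return y

    return make


def brute_force_peaks(y, min_width, dt=1.0):
    """Independent peak oracle: exhaustive local-maximum scan + width check.

    A sample is a peak if strictly greater than both neighbours; its width
    is measured by walking outwards to the first samples at or below half
    its height above the surrounding minima.
    """
    peaks = []
    n = len(y)
    for i in range(1, n - 1):
        if not (y[i] > y[i - 1] and y[i] > y[i + 1]):
            continue
        left_min = min(y[: i + 1])
        right_min = min(y[i:])
        half = y[i] - 0.5 * (y[i] - max(left_min, right_min))
        lo = i
        while lo > 0 and y[lo] > half:
            lo -= 1
        hi = i
        while hi < n - 1 and y[hi] > half:
            hi += 1
        if (hi - lo) * dt >= min_width:
            peaks.append(i)
    return peaks


def brute_force_regional_maxima(dist):
    """Independent watershed-seed oracle: exhaustive plateau-aware scan.

    Counts connected plateaus of positive distance-map values that have no
    strictly greater 8-neighbour anywhere along their border.
    """
    from scipy import ndimage as ndi

    dist = np.asarray(dist, dtype=float)
    maxima = np.ones_like(dist, dtype=bool)
    h, w = dist.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            shifted = np.full_like(dist, -np.inf)
            r0, r1 = max(dr, 0), h + min(dr, 0)
            c0, c1 = max(dc, 0), w + min(dc, 0)
            shifted[r0:r1, c0:c1] = dist[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
            maxima &= dist >= shifted
    maxima &= dist > 0
    # merge plateau pixels into connected regions; discard plateaus that
    # touch a strictly-greater neighbour via any member pixel
    lab, n = ndi.label(maxima, structure=np.ones((3, 3)))
    count = 0
    for region in range(1, n + 1):
        rows, cols = np.nonzero(lab == region)
        level = dist[rows[0], cols[0]]
        ok = True
        for r, c in zip(rows, cols):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and dist[rr, cc] > level:
                        ok = False
        if ok:
            count += 1
    return count
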