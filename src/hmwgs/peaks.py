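"""Baseline correction, peak detection and trapezoidal integration."""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import find_peaks

from .chromatogram import Chromatogram, ChromatogramFormatError


@dataclasses.dataclass(frozen=True)
class Peak:
    """A detected chromatographic peak.

    ``apex_rt`` is refined by 3-point parabolic interpolation; ``area`` is
    the trapezoidal integral between ``left`` and ``right`` (minutes).
    ``merged`` marks peaks formed by collapsing local maxima closer than
    the minimum separation — likely co-eluting species.
    """

    apex_rt: float
    area: float
    height: float
    left: float
    right: float
    merged: bool = False


def correct_baseline(chrom: Chromatogram, edge_window: float = 0.5,
                     clip: bool = True) -> Chromatogram:
    """Subtract a straight line fitted to the first and last ``edge_window``
    minutes of the trace (assumed peak-free); optionally clip at zero."""
    if chrom.span < 2 * edge_window:
        raise ValueError(
            f"trace span {chrom.span:.2f} min too short for baseline fit"
        )
    t, y = chrom.time, chrom.intensity
    mask = (t <= t[0] + edge_window) | (t >= t[-1] - edge_window)
    slope, intercept = np.polyfit(t[mask], y[mask], 1)
    corrected = y - (slope * t + intercept)
    if clip:
        corrected = np.maximum(corrected, 0.0)
    return Chromatogram(t.copy(), corrected, line_id=chrom.line_id)


def _parabolic_apex(t: np.ndarray, y: np.ndarray, i: int) -> tuple:
    """Refine apex position/height from the 3 samples around index ``i``."""
    if i == 0 or i == len(y) - 1:
        return float(t[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not locally concave; keep the grid point
        return float(t[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dt = t[1] - t[0]
    apex_t = float(t[i] + delta * dt)
    apex_h = float(y1 - 0.25 * (y0 - y2) * delta)
    return apex_t, apex_h


def detect_peaks(
    chrom: Chromatogram,
    min_height: float = 2.5,
    min_separation: float = 0.02,
    max_half_width: float = 0.048,
    min_prominence: float | None = None,
) -> list[Peak]:
    """Detect peaks on a baseline-corrected uniform trace.

    Candidate maxima must exceed ``min_height`` *and* have topographic
    prominence of at least ``min_prominence`` (defaults to ``min_height``);
    the prominence requirement rejects noise wiggles riding on the flank
    of a tall peak, whose absolute height can be large while their rise
    above the local profile is only noise-sized. Maxima closer together
    than ``min_separation`` are collapsed into a single peak (reported at
    the tallest maximum and flagged ``merged``). Integration bounds are
    the flanking minima towards the neighbouring peaks, or
    ``apex ± max_half_width``, whichever is nearer to the apex.
    """
    chrom.require_uniform()
    t, y = chrom.time, chrom.intensity
    dt = chrom.dt
    if min_prominence is None:
        min_prominence = min_height
    idx, _ = find_peaks(y, height=min_height, prominence=min_prominence)
    if len(idx) == 0:
        return []

    # cluster maxima separated by less than min_separation
    clusters: list[list[int]] = [[int(idx[0])]]
    for i in idx[1:]:
        if (t[i] - t[clusters[-1][-1]]) < min_separation:
            clusters[-1].append(int(i))
        else:
            clusters.append([int(i)])

    reps = [max(c, key=lambda i: y[i]) for c in clusters]
    merged_flags = [len(c) > 1 for c in clusters]

    peaks: list[Peak] = []
    for j, (i, is_merged) in enumerate(zip(reps, merged_flags)):
        apex_t, apex_h = _parabolic_apex(t, y, i)
        # flanking minima towards neighbouring peaks (or trace edges)
        lo = reps[j - 1] if j > 0 else 0
        hi = reps[j + 1] if j + 1 < len(reps) else len(y) - 1
        left_valley = t[lo + int(np.argmin(y[lo:i + 1]))] if i > lo else t[lo]
        right_valley = t[i + int(np.argmin(y[i:hi + 1]))] if hi > i else t[hi]
        left = max(float(left_valley), apex_t - max_half_width)
        right = min(float(right_valley), apex_t + max_half_width)
        li = int(np.searchsorted(t, left - 1e-12))
        ri = int(np.searchsorted(t, right + 1e-12)) - 1
        ri = max(ri, li + 1)
        area = float(np.trapezoid(y[li:ri + 1], t[li:ri + 1]))
        peaks.append(Peak(apex_rt=apex_t, area=area, height=apex_h,
                          left=float(t[li]), right=float(t[ri]),
                          merged=is_merged))
    peaks.sort(key=lambda p: p.apex_rt)
    return peaks
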