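"""Per-cell polarity statistics from cortical intensity profiles.

Two numbers summarize a crescent: the *peak angle* — the angular position of
the global maximum of the circular intensity profile — and the
*peak-to-trough ratio* — the peak value divided by the mean of the two
nearest local minima flanking it in each circular direction.  A uniform
(unpolarized) cortical signal has ratio ~1; the ratio grows with crescent
contrast.  Profiles are lightly smoothed (circular moving mean, 5 samples
by default) before the extremum search, and both peak and trough values are
read from the smoothed curve for internal consistency.

``polarity_contrast_test`` compares per-cell ratios of the polarity channel
against a membrane control channel with a two-sided Mann-Whitney test and
reports mean +/- SD per channel at both the cell and embryo level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as _stats
from .errors import InputError
from .profiles import CorticalProfile

__all__ = [
    "PolarityMeasurement",
    "ContrastTestResult",
    "find_peak",
    "peak_to_trough_ratio",
    "polarity_contrast_test",
    "measurements_frame",
]

_FLAT_TOL = 1e-12


@dataclass(frozen=True)
class PolarityMeasurement:
    """Crescent summary for one cell and channel."""

    cell_id: str
    embryo_id: str
    channel: str
    peak_angle: float | None  # degrees relative to AP; None when no peak
    peak_value: float
    trough_values: tuple[float, float]
    peak_to_trough_ratio: float
    no_peak: bool = False


@dataclass(frozen=True)
class ContrastTestResult:
    """Polarity-vs-control comparison of peak-to-trough ratios."""

    stat: _stats.StatResult
    summary: pd.DataFrame  # mean +/- SD per channel, cell and embryo levels


def _smooth_circular(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return np.asarray(y, dtype=float)
    if window % 2 == 0:
        raise InputError("smoothing window must be odd")
    k = np.ones(window) / window
    n = y.size
    ext = np.concatenate([y[-(window // 2):], y, y[: window // 2]])
    return np.convolve(ext, k, mode="valid")[:n]


def _circular_runs(indices: np.ndarray, n: int) -> list[np.ndarray]:
    """Group sorted sample indices into circularly contiguous runs."""
    if indices.size == 0:
        return []
    runs = [[indices[0]]]
    for i in indices[1:]:
        if i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == n - 1:
        runs[0] = runs.pop() + runs[0]
    return [np.array(r) for r in runs]


def _peak_index(y: np.ndarray) -> float:
    """Index of the global max; plateau ties go to the circular midpoint.

    Returns a float index (may be half-integer inside a plateau).
    """
    n = y.size
    at_max = np.flatnonzero(y >= y.max() - _FLAT_TOL)
    runs = _circular_runs(at_max, n)
    run = max(runs, key=len)
    # midpoint along the circular run (indices may wrap past n)
    seq = run.astype(float).copy()
    for j in range(1, seq.size):
        if seq[j] < seq[j - 1]:
            seq[j:] += n
    return float(seq[0] + (seq[-1] - seq[0]) / 2.0) % n


def _angle_at(profile: CorticalProfile, idx: float) -> float:
    """Angular position at a (possibly fractional) sample index."""
    n = profile.n_samples
    i0 = int(np.floor(idx)) % n
    i1 = (i0 + 1) % n
    t = idx - np.floor(idx)
    a0 = profile.angular_position[i0]
    a1 = profile.angular_position[i1]
    d = (a1 - a0 + 180.0) % 360.0 - 180.0  # shorter-path interpolation
    from ._angles import wrap_full

    return wrap_full(a0 + t * d)


def find_peak(profile: CorticalProfile, smoothing_window: int = 5):
    """Angle and value of the global maximum of the circular profile.

    Returns ``(peak_angle_deg, peak_value)``; a constant profile returns
    ``(None, value)`` (the "no-peak" flag).  Plateau ties resolve to the
    circular midpoint of the plateau.
    """
    y = _smooth_circular(profile.values, smoothing_window)
    if np.ptp(y) <= _FLAT_TOL:
        return None, float(y[0])
    idx = _peak_index(y)
    return _angle_at(profile, idx), float(y.max())


def _walk_to_minimum(y: np.ndarray, start: int, direction: int) -> int:
    """First circular local minimum encountered walking from ``start``."""
    n = y.size
    i = start
    for _ in range(n):
        j = (i + direction) % n
        if y[j] > y[i] + _FLAT_TOL:
            return i
        i = j
    return int(np.argmin(y))  # pathological: monotone plateau all around


def peak_to_trough_ratio(profile: CorticalProfile,
                         smoothing_window: int = 5) -> PolarityMeasurement:
    """Peak-to-trough polarity statistic for one profile.

    The peak is the global circular maximum of the smoothed profile; the two
    troughs are the nearest local minima walking from the peak in each
    circular direction (a single shared minimum counts twice).  A constant
    profile yields ratio 1.0 with the no-peak flag set.
    """
    y = _smooth_circular(profile.values, smoothing_window)
    if np.ptp(y) <= _FLAT_TOL:
        v = float(y[0])
        return PolarityMeasurement(
            cell_id=profile.cell_id,
            embryo_id=profile.embryo_id,
            channel=profile.channel,
            peak_angle=None,
            peak_value=v,
            trough_values=(v, v),
            peak_to_trough_ratio=1.0,
            no_peak=True,
        )
    idx = _peak_index(y)
    start = int(round(idx)) % y.size
    i_fwd = _walk_to_minimum(y, start, +1)
    i_bwd = _walk_to_minimum(y, start, -1)
    troughs = (float(y[i_bwd]), float(y[i_fwd]))
    peak_value = float(y[start])
    ratio = peak_value / float(np.mean(troughs))
    return PolarityMeasurement(
        cell_id=profile.cell_id,
        embryo_id=profile.embryo_id,
        channel=profile.channel,
        peak_angle=_angle_at(profile, idx),
        peak_value=peak_value,
        trough_values=troughs,
        peak_to_trough_ratio=ratio,
        no_peak=False,
    )


def measurements_frame(measurements) -> pd.DataFrame:
    """Tabulate PolarityMeasurement records."""
    return pd.DataFrame(
        [
            dict(
                cell_id=m.cell_id,
                embryo_id=m.embryo_id,
                channel=m.channel,
                peak_angle=np.nan if m.peak_angle is None else m.peak_angle,
                peak_value=m.peak_value,
                trough_a=m.trough_values[0],
                trough_b=m.trough_values[1],
                peak_to_trough_ratio=m.peak_to_trough_ratio,
                no_peak=m.no_peak,
            )
            for m in measurements
        ]
    )


def polarity_contrast_test(polarity_cells, control_cells,
                           exact_threshold: int = 20) -> ContrastTestResult:
    """Two-sided Mann-Whitney on per-cell peak-to-trough ratios, polarity
    channel versus membrane control, with mean +/- SD per channel."""
    pol = list(polarity_cells)
    ctl = list(control_cells)
    if not pol or not ctl:
        raise InputError("both measurement groups must be non-empty")
    x = np.array([m.peak_to_trough_ratio for m in pol])
    y = np.array([m.peak_to_trough_ratio for m in ctl])
    stat = _stats.mann_whitney(x, y, exact_threshold=exact_threshold)
    frames = []
    for label, group in (("polarity", pol), ("membrane", ctl)):
        df = measurements_frame(group)
        s = _stats.two_level_summary(df, "peak_to_trough_ratio")
        s.insert(0, "channel", label)
        frames.append(s)
    return ContrastTestResult(stat=stat, summary=pd.concat(frames, ignore_index=True))
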