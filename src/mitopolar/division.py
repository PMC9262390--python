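"""Division angles, spindle rotation tracking, and rose histograms.

The division angle is the angle between the (undirected) spindle pole axis
and the AP body axis, measured at anaphase or later.  Signed angles live in
(-90, 90], positive counterclockwise from AP in the anterior-up view (the
sign convention is a package convention; mirrored domains produce mirrored
signs).  The folded angle |signed| in [0, 90] runs from 0 (AP-aligned) to
90 (DV-aligned).  Rotation direction is classified from the net signed
angular displacement between spindle assembly and anaphase, with
consecutive-frame differences taken along the shorter arc; a net
displacement below 1 degree counts as "none".

Rose histograms report the percentage of spindles per angular bin, the
presentation used for division-orientation cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import _angles
from .errors import DetectionError, GeometryError, InputError, RangeError

__all__ = [
    "SpindleObservation",
    "DivisionRecord",
    "RoseHistogram",
    "detect_poles",
    "spindle_axis_angle",
    "fold_angle",
    "track_rotation",
    "rose_histogram",
    "embryo_mean_angles",
    "records_frame",
]

_EPS = 1e-9


@dataclass(frozen=True)
class SpindleObservation:
    """One spindle axis measurement in one frame."""

    cell_id: str
    frame: int
    pole_a: tuple[float, float]  # (x, y) pixel coords
    pole_b: tuple[float, float]
    signed_angle: float  # degrees in (-90, 90]

    def __post_init__(self) -> None:
        if np.allclose(self.pole_a, self.pole_b):
            raise GeometryError("spindle poles must be distinct")
        if not -90.0 - _EPS < self.signed_angle <= 90.0 + _EPS:
            raise RangeError(f"signed_angle {self.signed_angle} outside (-90, 90]")


@dataclass(frozen=True)
class DivisionRecord:
    """Final orientation and rotation summary for one division."""

    cell_id: str
    embryo_id: str
    domain_id: str
    side: str
    final_signed_angle: float  # (-90, 90]
    folded_angle: float  # [0, 90]
    rotation_direction: str  # {"cw", "ccw", "none"}
    total_rotation: float  # degrees >= 0


@dataclass(frozen=True)
class RoseHistogram:
    """Percentage-per-bin circular histogram of division angles."""

    bin_edges: np.ndarray
    percentages: np.ndarray
    n: int
    range_kind: str  # {"folded", "signed"}


def observation(cell_id: str, frame: int, pole_a, pole_b,
                ap_direction=_angles.AP_UP) -> SpindleObservation:
    """Build a SpindleObservation, computing the signed axis angle."""
    return SpindleObservation(
        cell_id=cell_id,
        frame=frame,
        pole_a=tuple(map(float, pole_a)),
        pole_b=tuple(map(float, pole_b)),
        signed_angle=spindle_axis_angle(pole_a, pole_b, ap_direction),
    )


# ---------------------------------------------------------------------------
# pole detection
# ---------------------------------------------------------------------------


def detect_poles(frame: np.ndarray, contour, smooth_sigma: float = 1.0,
                 min_distance: int = 3, threshold_rel: float = 0.2,
                 refine_radius: int = 3):
    """Locate the two spindle poles inside a cell contour.

    The frame is smoothed, local maxima inside the contour are found, and
    the two strongest are refined to sub-pixel positions by the
    intensity-weighted centroid of a small window (background-subtracted).
    Returns ``(pole_a, pole_b)`` as (x, y) tuples.

    Raises :class:`DetectionError` when fewer than two maxima exceed the
    relative threshold.
    """
    from skimage.draw import polygon as draw_polygon
    from skimage.feature import peak_local_max

    img = ndimage.gaussian_filter(np.asarray(frame, dtype=float), smooth_sigma)
    mask = np.zeros(img.shape, dtype=bool)
    rr, cc = draw_polygon(contour.vertices[:, 1], contour.vertices[:, 0],
                          shape=img.shape)
    mask[rr, cc] = True
    if not mask.any():
        raise DetectionError(f"contour {contour.cell_id} covers no pixels")
    vmax = img[mask].max()
    coords = peak_local_max(
        img,
        min_distance=min_distance,
        threshold_abs=threshold_rel * vmax,
        labels=mask.astype(int),
    )
    if coords.shape[0] < 2:
        raise DetectionError(
            f"contour {contour.cell_id}: found {coords.shape[0]} maxima, need 2"
        )
    strengths = img[coords[:, 0], coords[:, 1]]
    top = coords[np.argsort(strengths)[::-1][:2]]

    poles = []
    h, w = img.shape
    for r0, c0 in top:
        y0, y1 = max(r0 - refine_radius, 0), min(r0 + refine_radius + 1, h)
        x0, x1 = max(c0 - refine_radius, 0), min(c0 + refine_radius + 1, w)
        win = img[y0:y1, x0:x1] - img[y0:y1, x0:x1].min()
        tot = win.sum()
        yy, xx = np.mgrid[y0:y1, x0:x1]
        poles.append((float((xx * win).sum() / tot), float((yy * win).sum() / tot)))
    return tuple(poles)


# ---------------------------------------------------------------------------
# angles
# ---------------------------------------------------------------------------


def spindle_axis_angle(pole_a, pole_b, ap_direction=_angles.AP_UP) -> float:
    """Signed axial angle of the pole-pole axis relative to the AP axis.

    Both axes are undirected; the result lies in (-90, 90], positive when
    the spindle axis is rotated counterclockwise from AP in the anterior-up
    view.
    """
    ax, ay = float(pole_a[0]), float(pole_a[1])
    bx, by = float(pole_b[0]), float(pole_b[1])
    vx, vy_up = bx - ax, -(by - ay)
    if vx == 0 and vy_up == 0:
        raise GeometryError("coincident spindle poles")
    apx, apy_up = float(ap_direction[0]), -float(ap_direction[1])
    if apx == 0 and apy_up == 0:
        raise GeometryError("null AP direction")
    cross = apx * vy_up - apy_up * vx
    dot = apx * vx + apy_up * vy_up
    return _angles.wrap_axial(np.rad2deg(np.arctan2(cross, dot)))


def fold_angle(signed_angle: float) -> float:
    """Fold a signed division angle in (-90, 90] to [0, 90]."""
    if not -90.0 - _EPS < signed_angle <= 90.0 + _EPS:
        raise RangeError(f"signed angle {signed_angle} outside (-90, 90]")
    return abs(float(signed_angle))


# ---------------------------------------------------------------------------
# rotation tracking
# ---------------------------------------------------------------------------


def track_rotation(observations, anaphase_frame: int, embryo_id: str = "sim",
                   domain_id: str = "MD1", side: str = "unassigned",
                   none_threshold: float = 1.0) -> DivisionRecord:
    """Summarize a spindle's trajectory into a DivisionRecord.

    The final angle is the first observation at or after ``anaphase_frame``.
    Net displacement sums shorter-arc differences between consecutive
    frames up to that point; its sign gives the rotation direction
    (positive = counterclockwise), magnitudes below ``none_threshold``
    degrees classify as "none".
    """
    obs = list(observations)
    if len(obs) < 2:
        raise InputError("track_rotation needs >= 2 observations")
    frames = [o.frame for o in obs]
    if any(b <= a for a, b in zip(frames, frames[1:])):
        raise InputError("observations must be ordered by strictly increasing frame")
    ids = {o.cell_id for o in obs}
    if len(ids) != 1:
        raise InputError("observations mix cell ids")
    at_or_after = [o for o in obs if o.frame >= anaphase_frame]
    if not at_or_after:
        raise InputError("anaphase_frame beyond the observation sequence")
    final_obs = at_or_after[0]
    angles = np.array([o.signed_angle for o in obs if o.frame <= final_obs.frame])
    diffs = _angles.axial_difference(angles[1:], angles[:-1])
    net = float(np.sum(diffs))
    if abs(net) < none_threshold:
        direction = "none"
    else:
        direction = "ccw" if net > 0 else "cw"
    return DivisionRecord(
        cell_id=final_obs.cell_id,
        embryo_id=embryo_id,
        domain_id=domain_id,
        side=side,
        final_signed_angle=final_obs.signed_angle,
        folded_angle=fold_angle(final_obs.signed_angle),
        rotation_direction=direction,
        total_rotation=abs(net),
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def rose_histogram(angles, bin_width: float = 15.0,
                   range_kind: str = "folded") -> RoseHistogram:
    """Percentage-per-bin histogram of division angles.

    ``range_kind`` is ``"folded"`` ([0, 90]) or ``"signed"`` ((-90, 90]).
    ``bin_width`` must divide the angular span exactly.
    """
    a = np.asarray(angles, dtype=float).ravel()
    if a.size == 0:
        raise InputError("rose_histogram requires at least one angle")
    if range_kind == "folded":
        lo, hi = 0.0, 90.0
    elif range_kind == "signed":
        lo, hi = -90.0, 90.0
    else:
        raise InputError(f"unknown range_kind {range_kind!r}")
    span = hi - lo
    nbins = span / bin_width
    if abs(nbins - round(nbins)) > 1e-9 or bin_width <= 0:
        raise InputError(f"bin_width {bin_width} does not divide the {span} degree span")
    nbins = int(round(nbins))
    if a.min() < lo - _EPS or a.max() > hi + _EPS:
        raise RangeError("angles outside the declared range")
    if range_kind == "signed" and np.any(a <= lo - _EPS):
        raise RangeError("signed angles must lie in (-90, 90]")
    edges = lo + bin_width * np.arange(nbins + 1)
    idx = np.clip(np.floor((a - lo) / bin_width).astype(int), 0, nbins - 1)
    counts = np.bincount(idx, minlength=nbins)
    return RoseHistogram(
        bin_edges=edges,
        percentages=100.0 * counts / a.size,
        n=int(a.size),
        range_kind=range_kind,
    )


def records_frame(records) -> pd.DataFrame:
    """Tabulate DivisionRecord objects."""
    return pd.DataFrame(
        [
            dict(
                cell_id=r.cell_id,
                embryo_id=r.embryo_id,
                domain_id=r.domain_id,
                side=r.side,
                final_signed_angle=r.final_signed_angle,
                folded_angle=r.folded_angle,
                rotation_direction=r.rotation_direction,
                total_rotation=r.total_rotation,
            )
            for r in records
        ]
    )


def embryo_mean_angles(records) -> pd.DataFrame:
    """Arithmetic mean folded division angle per embryo (one row each)."""
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    if df.empty:
        raise InputError("no division records")
    out = (
        df.groupby("embryo_id")["folded_angle"]
        .agg(n="count", mean_folded_angle="mean")
        .reset_index()
    )
    return out
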