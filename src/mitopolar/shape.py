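"""Moment-equivalent ellipse fits of cell contours and the long-axis rule.

``fit_ellipse`` reproduces region-based "fit ellipse" semantics: the
ellipse shares the polygon's area, centroid, and the orientation/axis ratio
of its second central area moments, computed by the exact polygon (Green's
theorem) moment formulas rather than from rasterized pixels.  The long-axis
(Hertwig's) rule test then correlates interphase long-axis angles with
final division angles; for the head mitotic domains this correlation is
absent, distinguishing force-oriented from shape-oriented divisions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _angles
from . import stats as _stats
from .errors import GeometryError, InputError
from .profiles import CellContour

__all__ = ["ShapeFit", "LongAxisRuleResult", "fit_ellipse", "aspect_ratio",
           "long_axis_rule_test", "fits_frame"]


@dataclass(frozen=True)
class ShapeFit:
    """Moment-equivalent ellipse of one cell contour."""

    cell_id: str
    centroid: tuple[float, float]  # (x, y) pixel coords
    major_axis_length: float  # pixels (full axis)
    minor_axis_length: float
    orientation: float  # degrees in (-90, 90] relative to AP
    aspect_ratio: float  # major/minor >= 1
    unreliable_axis: bool = False  # near-circular: orientation ill-defined


def _polygon_moments(v: np.ndarray):
    """Signed area, centroid and central second moments of a polygon.

    Vertices are (x, y_up); returns (area, cx, cy, mxx, mxy, myy) with the
    second moments centered and normalized by area (i.e. a covariance).
    """
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        raise GeometryError("zero-area polygon")
    cx = ((x + x1) * cross).sum() / (6.0 * a)
    cy = ((y + y1) * cross).sum() / (6.0 * a)
    # second moments about the origin
    ixx = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0
    iyy = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0
    ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    # central, normalized by area (sign cancels)
    mxx = ixx / a - cx * cx
    myy = iyy / a - cy * cy
    mxy = ixy / a - cx * cy
    return a, cx, cy, mxx, mxy, myy


def fit_ellipse(contour: CellContour, unreliable_below: float = 1.02) -> ShapeFit:
    """Fit the moment-equivalent ellipse of a traced cell contour.

    The ellipse has the polygon's exact area and centroid, with axis
    lengths and orientation from the eigen-decomposition of the polygon's
    central second-moment tensor.  Orientation is the major-axis angle
    relative to AP in (-90, 90]; contours with aspect ratio below
    ``unreliable_below`` are flagged as having an ill-defined axis.
    """
    # work in the anterior-up view (y up) so orientation signs match
    v = np.stack([contour.vertices[:, 0], -contour.vertices[:, 1]], axis=1)
    a, cx, cy_up, mxx, mxy, myy = _polygon_moments(v)
    cov = np.array([[mxx, mxy], [mxy, myy]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam2, lam1 = float(evals[0]), float(evals[1])
    if lam2 <= 0:
        raise GeometryError("degenerate contour: zero minor second moment")
    semi_major = 2.0 * np.sqrt(lam1)
    semi_minor = 2.0 * np.sqrt(lam2)
    # rescale so the ellipse area matches the polygon area exactly
    s = np.sqrt(abs(a) / (np.pi * semi_major * semi_minor))
    semi_major *= s
    semi_minor *= s
    vx, vy_up = evecs[0, 1], evecs[1, 1]  # major-axis eigenvector
    orientation = _angles.wrap_axial(np.rad2deg(np.arctan2(-vx, vy_up)))
    ar = semi_major / semi_minor
    return ShapeFit(
        cell_id=contour.cell_id,
        centroid=(float(cx), float(-cy_up)),
        major_axis_length=2.0 * semi_major,
        minor_axis_length=2.0 * semi_minor,
        orientation=float(orientation),
        aspect_ratio=float(ar),
        unreliable_axis=bool(ar < unreliable_below),
    )


def aspect_ratio(fit: ShapeFit) -> float:
    """Major/minor axis ratio of a fit."""
    if fit.minor_axis_length <= 0:
        raise GeometryError("degenerate ellipse: zero minor axis")
    return fit.major_axis_length / fit.minor_axis_length


def fits_frame(fits) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                cell_id=f.cell_id,
                centroid_x=f.centroid[0],
                centroid_y=f.centroid[1],
                major_axis_length=f.major_axis_length,
                minor_axis_length=f.minor_axis_length,
                orientation=f.orientation,
                aspect_ratio=f.aspect_ratio,
                unreliable_axis=f.unreliable_axis,
            )
            for f in fits
        ]
    )


@dataclass(frozen=True)
class LongAxisRuleResult:
    """Shape/division correlation, folded and signed variants."""

    n: int
    folded_spearman: _stats.CorrelationResult
    folded_pearson: _stats.CorrelationResult
    signed_spearman: _stats.CorrelationResult
    signed_pearson: _stats.CorrelationResult


def long_axis_rule_test(interphase_fits, division_records,
                        exact_threshold: int = 9) -> LongAxisRuleResult:
    """Correlate interphase long-axis angles with division angles.

    Cells are joined on ``cell_id``.  The primary comparison folds both
    angles to [0, 90]; the signed variant correlates the raw (-90, 90]
    angles, since published analyses do not always state which was used.
    Requires at least three matched cells.
    """
    fit_by_id = {f.cell_id: f for f in interphase_fits}
    pairs = [
        (fit_by_id[r.cell_id], r)
        for r in division_records
        if r.cell_id in fit_by_id
    ]
    if len(pairs) < 3:
        raise InputError(f"only {len(pairs)} matched cells; need >= 3")
    shape_signed = np.array([f.orientation for f, _ in pairs])
    div_signed = np.array([r.final_signed_angle for _, r in pairs])
    shape_folded = np.abs(shape_signed)
    div_folded = np.abs(div_signed)
    return LongAxisRuleResult(
        n=len(pairs),
        folded_spearman=_stats.spearman(shape_folded, div_folded,
                                        exact_threshold=exact_threshold),
        folded_pearson=_stats.pearson_r2(shape_folded, div_folded),
        signed_spearman=_stats.spearman(shape_signed, div_signed,
                                        exact_threshold=exact_threshold),
        signed_pearson=_stats.pearson_r2(shape_signed, div_signed),
    )
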