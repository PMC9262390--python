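"""Angle conventions shared by all modules.

Images are stored row-major with row 0 at the top.  The anterior-posterior
(AP) body axis is the image vertical with anterior at the top, so in the
anterior-up view the x axis points right and the "view" y axis points up
(``y_up = -row``).  Angles are measured in degrees relative to the AP axis,
positive counterclockwise in that view.

Two angle flavours appear:

* full-circle *position* angles in ``(-180, 180]`` (where on the perimeter a
  point sits, e.g. a crescent center), and
* *axial* angles in ``(-90, 90]`` for undirected lines (spindle axes, cell
  long axes), where ``theta`` and ``theta + 180`` are the same axis.
"""

from __future__ import annotations

import math

import numpy as np

AP_UP = (0.0, -1.0)  # AP direction in image coordinates (dx, drow): anterior up


def wrap_full(deg):
    """Wrap angle(s) to (-180, 180]."""
    d = np.asarray(deg, dtype=float)
    out = -((-d + 180.0) % 360.0 - 180.0)
    out = np.where(out <= -180.0, out + 360.0, out)
    return float(out) if np.isscalar(deg) or out.ndim == 0 else out


def wrap_axial(deg):
    """Wrap axial angle(s) to (-90, 90]."""
    d = np.asarray(deg, dtype=float)
    out = -((-d + 90.0) % 180.0 - 90.0)
    out = np.where(out <= -90.0, out + 180.0, out)
    return float(out) if np.isscalar(deg) or out.ndim == 0 else out


def axial_difference(a, b):
    """Shorter-path signed difference a - b between axial angles, in [-90, 90)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    out = (d + 90.0) % 180.0 - 90.0
    return float(out) if np.ndim(out) == 0 else out


def position_angle(dx, drow):
    """Full-circle angle of an image-space displacement relative to AP.

    ``dx`` is the column offset, ``drow`` the row offset (down-positive).
    Returns degrees in (-180, 180], counterclockwise-positive in the
    anterior-up view.
    """
    y_up = -np.asarray(drow, dtype=float)
    x = np.asarray(dx, dtype=float)
    ang = np.rad2deg(np.arctan2(-x, y_up))
    return wrap_full(ang)


def axis_angle(dx, drow):
    """Axial angle of an undirected image-space direction relative to AP."""
    return wrap_axial(position_angle(dx, drow))


def axis_direction(theta_deg):
    """Unit vector (dx, drow) of an axis at ``theta_deg`` from AP (anterior-up view)."""
    t = math.radians(theta_deg)
    # rotating AP=(0, 1) in the y-up frame CCW by theta gives (-sin t, cos t)
    return (-math.sin(t), -math.cos(t))
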