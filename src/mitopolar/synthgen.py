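"""Synthetic mitotic-domain generator with per-cell ground truth.

Emulates the statistical structure of live imaging of a mirrored pair of
epithelial mitotic domains during gastrulation: polygonal cells laid out on
a jittered hexagonal lattice clipped to two elliptical clusters mirrored
about the image midline; a uniform cortical membrane channel; a polarity
channel whose cortical intensity carries a single angular crescent; and a
spindle channel in which two poles assemble at a random orientation and
rotate along the shorter arc toward a final division angle statistically
coupled to the crescent angle.

The cortical polarity signal along a cell boundary follows a von
Mises-shaped multiplicative modulation

    I(phi) = base * (1 + a * exp(kappa * (cos(phi - phi_crescent) - 1)))

where ``phi`` is the angular position of the boundary point about the cell
centroid, ``a`` the crescent contrast and ``kappa`` its angular
concentration.  The peak elevation over baseline is exactly ``a * base`` at
``phi = phi_crescent``.

Defaults describe a domain-1-like condition: ~40 cells per side, crescent
centers mirrored at +/-20 degrees from the AP axis, crescent contrast 1,
concentration 4, division angles scattered 10 degrees (SD) about the
crescent angle, and Gaussian camera noise at 5% of the cortical baseline.

Randomness is counter-based: every cell draws from its own deterministic
stream derived from the root seed, so enlarging the domain does not
reshuffle existing cells, and identical (config, seed) reproduce all
outputs bit-exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point

from . import _angles
from .errors import ConfigurationError, GenerationError
from .profiles import CellContour

__all__ = [
    "NoiseModel",
    "SyntheticDomainConfig",
    "DomainGeometry",
    "generate_domain",
    "render_polarity_image",
    "render_membrane_image",
    "render_spindle_timelapse",
    "make_profile_dataset",
    "make_angle_dataset",
]

# stream ids for counter-based per-cell RNG
_S_GEOM, _S_ANGLES, _S_SHAPE, _S_IMAGE, _S_PROFILE, _S_DATASET = range(6)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass(frozen=True)
class NoiseModel:
    """Imaging noise: optional Poisson shot noise, then additive Gaussian."""

    gaussian_sd: float = 10.0  # a.u.
    poisson: bool = False

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ConfigurationError("gaussian_sd must be >= 0")

    @property
    def enabled(self) -> bool:
        return self.poisson or self.gaussian_sd > 0


@dataclass(frozen=True)
class SyntheticDomainConfig:
    """Full generative parameterization of one mirrored domain pair."""

    n_cells_per_side: int = 40
    image_size: int = 512  # pixels, square
    pixel_scale: float = 0.2  # micrometres per pixel
    membrane_cortex_intensity: float = 200.0  # a.u.
    cytoplasm_intensity: float = 40.0  # a.u.
    crescent_contrast: float = 1.0  # a >= 0
    crescent_concentration: float = 4.0  # kappa > 0
    crescent_center_left_deg: float = 20.0  # theta_c per side; mirrored signs
    crescent_center_right_deg: float = -20.0
    crescent_angle_sd: float = 10.0  # degrees
    division_coupling_sd: float = 10.0  # sigma_div, degrees
    rotation_rate: float = 10.0  # degrees per frame
    n_frames: int = 15
    anaphase_frame: int = 12  # frame index from which the axis is fixed
    pole_separation: float = 4.0  # micrometres
    pole_sigma: float = 0.6  # micrometres (blob width)
    pole_intensity: float = 300.0  # a.u.
    interphase_aspect_ratio_mean: float = 1.3
    interphase_aspect_ratio_sd: float = 0.15
    double_sided_crescent: bool = False
    noise: NoiseModel = field(default_factory=NoiseModel)
    psf_sigma: float = 1.0  # pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_side < 1:
            raise ConfigurationError("n_cells_per_side must be >= 1")
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32 pixels")
        if self.crescent_contrast < 0:
            raise ConfigurationError("crescent_contrast a must be >= 0")
        if self.crescent_concentration <= 0:
            raise ConfigurationError("crescent_concentration kappa must be > 0")
        if self.division_coupling_sd < 0 or self.crescent_angle_sd < 0:
            raise ConfigurationError("angular SDs must be >= 0")
        if not 0 <= self.anaphase_frame < self.n_frames:
            raise ConfigurationError("anaphase_frame must lie within the time-lapse")
        if self.rotation_rate < 0 or self.pole_separation <= 0 or self.pole_sigma <= 0:
            raise ConfigurationError("kinematic/blob parameters must be positive")
        if self.pixel_scale <= 0:
            raise ConfigurationError("pixel_scale must be > 0")

    def crescent_center(self, side: str) -> float:
        return self.crescent_center_left_deg if side == "left" else self.crescent_center_right_deg


@dataclass
class DomainGeometry:
    """Generated contours for both phases, keyed by cell_id order of truth."""

    mitotic: list  # list[CellContour], rounded-up mitotic outlines
    interphase: list  # list[CellContour], elongated interphase outlines
    config: SyntheticDomainConfig

    def mitotic_by_id(self) -> dict:
        return {c.cell_id: c for c in self.mitotic}

    def interphase_by_id(self) -> dict:
        return {c.cell_id: c for c in self.interphase}


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _cluster_centers(size: int) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.array([0.27 * size, 0.5 * size]),
        np.array([0.73 * size, 0.5 * size]),
    )


def _hex_lattice(center: np.ndarray, pitch: float, n_rings: int) -> np.ndarray:
    pts = []
    for row in range(-n_rings, n_rings + 1):
        y = center[1] + row * pitch * np.sqrt(3) / 2
        x0 = center[0] + (pitch / 2 if row % 2 else 0.0)
        for col in range(-n_rings, n_rings + 1):
            pts.append((x0 + col * pitch, y))
    return np.array(pts)


def _cell_polygon(center: np.ndarray, radius: float, rng: np.random.Generator,
                  n_vertices: int = 12, jitter: float = 0.08) -> np.ndarray:
    rot = rng.uniform(0, 2 * np.pi)
    ang = rot + 2 * np.pi * np.arange(n_vertices) / n_vertices
    r = radius * (1.0 + jitter * rng.uniform(-1, 1, size=n_vertices))
    return np.stack([center[0] + r * np.cos(ang), center[1] + r * np.sin(ang)], axis=1)


def _anterior_most_index(vertices: np.ndarray) -> int:
    # anterior is the top of the image: smallest row coordinate
    return int(np.argmin(vertices[:, 1]))


def _elongate(vertices: np.ndarray, centroid: np.ndarray, axis_deg: float,
              aspect_ratio: float) -> np.ndarray:
    """Area-preserving anisotropic stretch along an axis at ``axis_deg``."""
    s = np.sqrt(aspect_ratio)
    dx, drow = _angles.axis_direction(axis_deg)
    u = np.array([dx, drow])
    w = np.array([-u[1], u[0]])
    rel = vertices - centroid
    along = rel @ u
    across = rel @ w
    return centroid + np.outer(along * s, u) + np.outer(across / s, w)


def generate_domain(config: SyntheticDomainConfig):
    """Lay out two mirrored cell clusters and draw the per-cell truth table.

    Returns ``(geometry, truth)`` where ``geometry`` is a
    :class:`DomainGeometry` and ``truth`` a DataFrame with one row per cell:
    crescent angle, final signed division angle, initial spindle angle,
    rotation direction, interphase long-axis angle and aspect ratio, plus
    centroid and inradius bookkeeping columns.
    """
    size = config.image_size
    n = config.n_cells_per_side
    left_c, right_c = _cluster_centers(size)
    # cluster radius available per side, with a margin for the cortex/PSF
    r_avail = min(0.23 * size, 0.42 * size)
    # hexagonal pitch so that n cells fill ~85% of an ellipse of that radius
    pitch = np.sqrt(0.85 * np.pi * r_avail**2 * 0.88 * (2 / np.sqrt(3)) / n)
    n_rings = int(np.ceil(r_avail / pitch)) + 2

    lattice = _hex_lattice(left_c, pitch, n_rings)
    # elliptical cluster, slightly elongated along AP (vertical)
    d2 = ((lattice[:, 0] - left_c[0]) / 0.88) ** 2 + ((lattice[:, 1] - left_c[1]) / 1.0) ** 2
    order = np.argsort(d2, kind="stable")
    if n > lattice.shape[0]:
        raise GenerationError("lattice too small for requested cell count")
    left_centers = lattice[order[:n]]

    radius = 0.36 * pitch
    mitotic: list[CellContour] = []
    interphase: list[CellContour] = []
    rows = []
    for i in range(n):
        for side, base_center in (("left", left_centers[i]), ("right", None)):
            if side == "left":
                center = base_center.copy()
                cid = f"L{i:03d}"
            else:
                center = np.array([size - left_centers[i][0], left_centers[i][1]])
                cid = f"R{i:03d}"
            g = _rng(config.seed, _S_GEOM, i, 0 if side == "left" else 1)
            center = center + g.uniform(-0.06 * pitch, 0.06 * pitch, size=2)
            verts = _cell_polygon(center, radius, g)
            ref = _anterior_most_index(verts)
            contour = CellContour(cid, "sim", side, verts, reference_point=ref)

            a_rng = _rng(config.seed, _S_ANGLES, i, 0 if side == "left" else 1)
            crescent = _angles.wrap_full(
                config.crescent_center(side) + a_rng.normal(0, config.crescent_angle_sd)
            )
            final = _angles.wrap_axial(crescent + a_rng.normal(0, config.division_coupling_sd))
            initial = _angles.wrap_axial(a_rng.uniform(-90.0, 90.0))
            net = _angles.axial_difference(final, initial)
            direction = "none" if abs(net) < 1.0 else ("ccw" if net > 0 else "cw")

            s_rng = _rng(config.seed, _S_SHAPE, i, 0 if side == "left" else 1)
            ar = max(1.0, s_rng.normal(config.interphase_aspect_ratio_mean,
                                       config.interphase_aspect_ratio_sd))
            long_axis = _angles.wrap_axial(s_rng.uniform(-90.0, 90.0))
            c = contour.centroid
            iverts = _elongate(verts, c, long_axis, ar)
            icontour = CellContour(cid, "sim", side, iverts,
                                   reference_point=_anterior_most_index(iverts),
                                   phase="interphase")

            boundary = contour.polygon.exterior
            inradius = boundary.distance(Point(c))

            mitotic.append(contour)
            interphase.append(icontour)
            rows.append(
                dict(
                    cell_id=cid,
                    embryo_id="sim",
                    side=side,
                    centroid_x=c[0],
                    centroid_y=c[1],
                    inradius_px=inradius,
                    true_crescent_angle=crescent,
                    true_final_division_angle_signed=final,
                    true_initial_spindle_angle=initial,
                    true_rotation_direction=direction,
                    true_total_rotation=abs(net),
                    interphase_long_axis_angle=long_axis,
                    interphase_aspect_ratio=ar,
                )
            )

    truth = pd.DataFrame(rows)
    geometry = DomainGeometry(mitotic=mitotic, interphase=interphase, config=config)
    return geometry, truth


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def crescent_modulation(phi_deg, crescent_deg, contrast, kappa, double_sided=False):
    """Multiplicative cortical modulation 1 + a*exp(kappa*(cos(dphi)-1))."""
    d = np.deg2rad(np.asarray(phi_deg, dtype=float) - crescent_deg)
    m = 1.0 + contrast * np.exp(kappa * (np.cos(d) - 1.0))
    if double_sided:
        m += contrast * np.exp(kappa * (np.cos(d - np.pi) - 1.0))
    return m


def _apply_psf_and_noise(img: np.ndarray, config: SyntheticDomainConfig,
                         channel_key: int, apply_noise: bool) -> np.ndarray:
    if config.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, config.psf_sigma)
    if apply_noise and config.noise.enabled:
        rng = _rng(config.seed, _S_IMAGE, channel_key)
        if config.noise.poisson:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if config.noise.gaussian_sd > 0:
            img = img + rng.normal(0, config.noise.gaussian_sd, size=img.shape)
    return img


def _fill_cells(img: np.ndarray, geometry: DomainGeometry, value: float) -> None:
    from skimage.draw import polygon as draw_polygon

    for c in geometry.mitotic:
        rr, cc = draw_polygon(c.vertices[:, 1], c.vertices[:, 0], shape=img.shape)
        img[rr, cc] = value


def _stamp_cortex(img: np.ndarray, contour: CellContour, intensity_fn,
                  half_thickness: float = 1.0, sigma: float = 0.5,
                  step: float = 0.25) -> None:
    """Paint a cortical band with a flat-top cross-section along the boundary.

    Pixels within ``half_thickness`` of the boundary take ``I(phi)``
    exactly; beyond that the band falls off as a Gaussian shoulder of width
    ``sigma``.  Max-compositing over boundary samples keeps the band
    thickness uniform and independent of local rasterization, so the
    pre-blur centerline value equals I(phi).
    """
    v = np.vstack([contour.vertices, contour.vertices[:1]])
    seg = np.diff(v, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    nsamp = max(16, int(np.ceil(total / step)))
    s = np.arange(nsamp) * (total / nsamp)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
    t = (s - cum[idx]) / seg_len[idx]
    pts = v[idx] + seg[idx] * t[:, None]

    c = contour.centroid
    phi = _angles.position_angle(pts[:, 0] - c[0], pts[:, 1] - c[1])
    vals = intensity_fn(phi)

    reach = int(np.ceil(half_thickness + 3 * sigma))
    offs = np.arange(-reach, reach + 1)
    ox, oy = np.meshgrid(offs, offs)
    px = np.round(pts[:, 0]).astype(int)[:, None] + ox.ravel()[None, :]
    py = np.round(pts[:, 1]).astype(int)[:, None] + oy.ravel()[None, :]
    d = np.hypot(px - pts[:, 0:1], py - pts[:, 1:2])
    excess = np.clip(d - half_thickness, 0.0, None)
    contrib = vals[:, None] * np.exp(-(excess**2) / (2.0 * sigma * sigma))
    inside = (px >= 0) & (px < img.shape[1]) & (py >= 0) & (py < img.shape[0])
    np.maximum.at(
        img,
        (py[inside], px[inside]),
        contrib[inside],
    )


def render_polarity_image(geometry: DomainGeometry, truth: pd.DataFrame,
                          config: SyntheticDomainConfig | None = None,
                          apply_noise: bool = True) -> np.ndarray:
    """Render the polarity channel: cytoplasm-filled cells with a crescent-
    modulated cortical ring, then PSF blur and noise."""
    config = config or geometry.config
    img = np.zeros((config.image_size, config.image_size), dtype=float)
    _fill_cells(img, geometry, config.cytoplasm_intensity)
    crescent = dict(zip(truth["cell_id"], truth["true_crescent_angle"]))
    base = config.membrane_cortex_intensity
    for c in geometry.mitotic:
        phi_c = crescent[c.cell_id]
        _stamp_cortex(
            img,
            c,
            lambda phi, phi_c=phi_c: base
            * crescent_modulation(
                phi,
                phi_c,
                config.crescent_contrast,
                config.crescent_concentration,
                config.double_sided_crescent,
            ),
        )
    return _apply_psf_and_noise(img, config, channel_key=0, apply_noise=apply_noise)


def render_membrane_image(geometry: DomainGeometry,
                          config: SyntheticDomainConfig | None = None,
                          apply_noise: bool = True) -> np.ndarray:
    """Render the membrane control channel: uniform cortical intensity,
    same PSF/noise pipeline as the polarity channel."""
    config = config or geometry.config
    img = np.zeros((config.image_size, config.image_size), dtype=float)
    _fill_cells(img, geometry, config.cytoplasm_intensity)
    base = config.membrane_cortex_intensity
    for c in geometry.mitotic:
        _stamp_cortex(img, c, lambda phi: np.full(len(phi), base))
    return _apply_psf_and_noise(img, config, channel_key=1, apply_noise=apply_noise)


def spindle_angle_at_frame(initial: float, final: float, rate: float,
                           frame: int, anaphase_frame: int) -> float:
    """Axis angle at a frame: constant-rate rotation along the shorter arc
    from ``initial`` toward ``final``, frozen from ``anaphase_frame`` on."""
    t = min(frame, anaphase_frame)
    need = _angles.axial_difference(final, initial)
    travelled = min(abs(need), rate * t)
    return _angles.wrap_axial(initial + np.sign(need) * travelled)


def render_spindle_timelapse(truth: pd.DataFrame,
                             config: SyntheticDomainConfig,
                             apply_noise: bool = True) -> np.ndarray:
    """Render the spindle channel time-lapse: two Gaussian pole blobs per
    cell rotating toward the final division angle.

    Raises :class:`GenerationError` if the pole separation does not fit
    inside a cell (requires the truth table's ``inradius_px`` column).
    """
    sep_px = config.pole_separation / config.pixel_scale
    sigma_px = config.pole_sigma / config.pixel_scale
    if "inradius_px" in truth.columns:
        if (sep_px / 2.0 > truth["inradius_px"]).any():
            raise GenerationError("pole_separation larger than a cell inradius")
    size = config.image_size
    stack = np.zeros((config.n_frames, size, size), dtype=float)
    half = int(np.ceil(4 * sigma_px))
    for frame in range(config.n_frames):
        img = stack[frame]
        for row in truth.itertuples(index=False):
            theta = spindle_angle_at_frame(
                row.true_initial_spindle_angle,
                row.true_final_division_angle_signed,
                config.rotation_rate,
                frame,
                config.anaphase_frame,
            )
            dx, drow = _angles.axis_direction(theta)
            for sgn in (+1.0, -1.0):
                px = row.centroid_x + sgn * dx * sep_px / 2.0
                py = row.centroid_y + sgn * drow * sep_px / 2.0
                x0, x1 = int(px) - half, int(px) + half + 1
                y0, y1 = int(py) - half, int(py) + half + 1
                x0c, x1c = max(x0, 0), min(x1, size)
                y0c, y1c = max(y0, 0), min(y1, size)
                if x0c >= x1c or y0c >= y1c:
                    continue
                yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
                img[y0c:y1c, x0c:x1c] += config.pole_intensity * np.exp(
                    -((xx - px) ** 2 + (yy - py) ** 2) / (2 * sigma_px**2)
                )
        stack[frame] = _apply_psf_and_noise(img, config, channel_key=100 + frame,
                                            apply_noise=apply_noise)
    return stack


# ---------------------------------------------------------------------------
# image-free datasets
# ---------------------------------------------------------------------------


def make_profile_dataset(config: SyntheticDomainConfig, n_cells: int = 10,
                         n_embryos: int = 3, n_samples: int = 100):
    """Sample cortical profiles directly from I(phi) + noise, bypassing
    rendering.

    Returns ``(profiles, truth)``: a list of raw :class:`CorticalProfile`
    (normalize with ``config.cytoplasm_intensity``) traced counterclockwise
    from the anterior point, and a truth table of crescent angles.  Cells
    are labelled ``right`` so the counterclockwise trace already follows
    the orientation convention.
    """
    from .profiles import CorticalProfile

    fractions = np.arange(n_samples) / n_samples
    phi = _angles.wrap_full(fractions * 360.0)  # ccw from the anterior point
    base = config.membrane_cortex_intensity
    profiles = []
    rows = []
    for e in range(n_embryos):
        eid = f"embryo{e:02d}"
        for c in range(n_cells):
            rng = _rng(config.seed, _S_PROFILE, e, c)
            crescent = _angles.wrap_full(
                config.crescent_center_right_deg
                + rng.normal(0, config.crescent_angle_sd)
            )
            raw = base * crescent_modulation(
                phi, crescent, config.crescent_contrast,
                config.crescent_concentration, config.double_sided_crescent,
            )
            if config.noise.gaussian_sd > 0:
                raw = raw + rng.normal(0, config.noise.gaussian_sd, size=n_samples)
            cid = f"{eid}_c{c:03d}"
            profiles.append(
                CorticalProfile(
                    cell_id=cid,
                    embryo_id=eid,
                    side="right",
                    channel="polarity",
                    arclength_fraction=fractions.copy(),
                    angular_position=phi.copy(),
                    raw_intensity=raw,
                    traversal="ccw",
                )
            )
            rows.append(dict(cell_id=cid, embryo_id=eid, side="right",
                             true_crescent_angle=crescent))
    return profiles, pd.DataFrame(rows)


def make_angle_dataset(n_embryos: int, n_cells: int, distribution, seed: int = 0):
    """Draw a division-angle table with embryo grouping.

    ``distribution`` is ``{"kind": "uniform"}`` (folded angles uniform on
    [0, 90]) or ``{"kind": "wrapped_normal", "mu": ..., "sd": ...}`` (signed
    angles normal about mu, wrapped to (-90, 90], then folded).
    """
    kind = distribution.get("kind")
    if kind not in ("uniform", "wrapped_normal"):
        raise ConfigurationError(f"unknown angle distribution {kind!r}")
    rows = []
    for e in range(n_embryos):
        eid = f"embryo{e:02d}"
        for c in range(n_cells):
            rng = _rng(seed, _S_DATASET, e, c)
            if kind == "uniform":
                folded = rng.uniform(0.0, 90.0)
                signed = folded * rng.choice([-1.0, 1.0])
            else:
                signed = _angles.wrap_axial(
                    rng.normal(distribution["mu"], distribution["sd"])
                )
                folded = abs(signed)
            rows.append(dict(embryo_id=eid, cell_id=f"{eid}_c{c:03d}",
                             signed_angle=signed, folded_angle=folded))
    return pd.DataFrame(rows)
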