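"""File formats: TIFF rasters, contour/profile/result CSV tables, flat
configuration files, and derived plots.

All tables are plain CSV with documented headers; all round trips are
lossless (tables exactly, rasters voxel-for-voxel).  Plots are derived
artifacts only — no analysis number is ever read back from a plot.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .division import RoseHistogram
from .errors import ParseError
from .profiles import CellContour, CorticalProfile

__all__ = [
    "read_image", "write_image",
    "read_contours_csv", "write_contours_csv",
    "read_profiles_csv", "write_profiles_csv",
    "read_table", "write_table",
    "write_config", "read_config",
    "plot_rose", "plot_mean_profiles",
]


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------


def write_image(path, image: np.ndarray) -> None:
    """Write a 2D image or a (frames, H, W) stack as multi-page TIFF."""
    tifffile.imwrite(str(path), np.asarray(image), photometric="minisblack")


def read_image(path) -> np.ndarray:
    return tifffile.imread(str(path))


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------

_CONTOUR_COLS = ["cell_id", "embryo_id", "side", "phase", "reference_point",
                 "vertex_index", "x", "y"]


def write_contours_csv(contours, path) -> None:
    """Long-format contour table: one row per vertex."""
    rows = []
    for c in contours:
        for i, (x, y) in enumerate(c.vertices):
            rows.append(dict(cell_id=c.cell_id, embryo_id=c.embryo_id,
                             side=c.side, phase=c.phase,
                             reference_point=c.reference_point,
                             vertex_index=i, x=x, y=y))
    pd.DataFrame(rows, columns=_CONTOUR_COLS).to_csv(path, index=False)


def read_contours_csv(path) -> list[CellContour]:
    """Read and validate a contour table; invalid polygons raise ParseError."""
    df = pd.read_csv(path)
    missing = set(_CONTOUR_COLS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing contour columns {sorted(missing)}")
    out = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("vertex_index")
        try:
            out.append(
                CellContour(
                    cell_id=str(cid),
                    embryo_id=str(grp["embryo_id"].iloc[0]),
                    side=str(grp["side"].iloc[0]),
                    vertices=grp[["x", "y"]].to_numpy(float),
                    reference_point=int(grp["reference_point"].iloc[0]),
                    phase=str(grp["phase"].iloc[0]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: cell {cid}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

_PROFILE_META = ["cell_id", "embryo_id", "side", "channel", "line_width",
                 "traversal", "cytoplasm_mean"]


def write_profiles_csv(profiles, path) -> None:
    """Long-format profile table: one row per perimeter sample."""
    frames = []
    for p in profiles:
        df = pd.DataFrame(
            dict(
                sample_index=np.arange(p.n_samples),
                arclength_fraction=p.arclength_fraction,
                angular_position=p.angular_position,
                raw_intensity=p.raw_intensity,
                normalized_intensity=(
                    np.full(p.n_samples, np.nan)
                    if p.normalized_intensity is None
                    else p.normalized_intensity
                ),
            )
        )
        df.insert(0, "cell_id", p.cell_id)
        df.insert(1, "embryo_id", p.embryo_id)
        df.insert(2, "side", p.side)
        df.insert(3, "channel", p.channel)
        df["line_width"] = p.line_width
        df["traversal"] = p.traversal
        df["cytoplasm_mean"] = np.nan if p.cytoplasm_mean is None else p.cytoplasm_mean
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_profiles_csv(path) -> list[CorticalProfile]:
    df = pd.read_csv(path)
    out = []
    for (cid, channel), grp in df.groupby(["cell_id", "channel"], sort=False):
        grp = grp.sort_values("sample_index")
        norm = grp["normalized_intensity"].to_numpy(float)
        cyto = grp["cytoplasm_mean"].iloc[0]
        out.append(
            CorticalProfile(
                cell_id=str(cid),
                embryo_id=str(grp["embryo_id"].iloc[0]),
                side=str(grp["side"].iloc[0]),
                channel=str(channel),
                arclength_fraction=grp["arclength_fraction"].to_numpy(float),
                angular_position=grp["angular_position"].to_numpy(float),
                raw_intensity=grp["raw_intensity"].to_numpy(float),
                normalized_intensity=None if np.isnan(norm).all() else norm,
                cytoplasm_mean=None if pd.isna(cyto) else float(cyto),
                line_width=int(grp["line_width"].iloc[0]),
                traversal=str(grp["traversal"].iloc[0]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# generic tables and configs
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out


def write_config(config, path) -> None:
    """Write a (possibly nested) config dataclass as a flat key-value file."""
    d = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
    flat = _flatten(d)
    with open(path, "w") as fh:
        yaml.safe_dump(flat, fh, sort_keys=True, default_flow_style=False)


def read_config(path) -> dict:
    """Read a flat key-value config file back into a nested dict."""
    with open(path) as fh:
        flat = yaml.safe_load(fh) or {}
    nested: dict = {}
    for key, value in flat.items():
        parts = key.split(".")
        d = nested
        for p in parts[:-1]:
            d = d.setdefault(p, {})
        d[parts[-1]] = value
    return nested


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------


def plot_rose(hist: RoseHistogram, path, title: str = "") -> None:
    """Polar histogram with percentage of spindles on the radial axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    centers = np.deg2rad((hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2.0)
    width = np.deg2rad(np.diff(hist.bin_edges))
    ax.bar(centers, hist.percentages, width=width, bottom=0.0,
           edgecolor="black", alpha=0.7)
    ax.set_theta_zero_location("N")
    if hist.range_kind == "folded":
        ax.set_thetamin(0)
        ax.set_thetamax(90)
    else:
        ax.set_thetamin(-90)
        ax.set_thetamax(90)
    ax.set_title(title or f"n = {hist.n} spindles (% per bin)")
    fig.savefig(str(path), bbox_inches="tight")
    plt.close(fig)


def plot_mean_profiles(per_embryo: dict, grand: np.ndarray,
                       fractions: np.ndarray, path, title: str = "") -> None:
    """Per-embryo mean intensity curves with the grand mean overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for eid, curve in per_embryo.items():
        ax.plot(fractions, curve, lw=1, alpha=0.7, label=eid)
    ax.plot(fractions, grand, lw=2.5, color="black", label="grand mean")
    ax.set_xlabel("arclength fraction from start")
    ax.set_ylabel("normalized intensity")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.savefig(str(path), bbox_inches="tight")
    plt.close(fig)
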