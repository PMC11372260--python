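"""Maximum-intensity projections, overlay rendering, and agreement plots.

MIPs follow the de-facto PET convention: inverted gray (high uptake dark),
display window SUV 0-10 by default.  Segmentation overlays are projected by
maximum along the same axis — a lesion is shown if any voxel along the ray
is segmented — and drawn in red at fixed opacity.  All numbers on the
agreement plots come from :mod:`tmtvbench.harness`; plotting never
recomputes statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np
from PIL import Image

from .harness import DiffStats
from .pet_io import MaskVolume, PETVolume

__all__ = ["ProjectionImage", "mip", "mip_mask", "render", "agreement_plots"]

#: Axis collapsed by each projection plane (RAS+ volumes).
_PLANE_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass
class ProjectionImage:
    """2-D maximum projection with the pixel spacing of the kept axes."""

    data: np.ndarray
    plane: str
    pixel_spacing_mm: tuple[float, float]  # spacing of (row-axis, col-axis) pre-display


def _project(values: np.ndarray, grid, plane: str) -> ProjectionImage:
    try:
        axis = _PLANE_AXIS[plane]
    except KeyError:
        raise ValueError(f"plane must be one of {sorted(_PLANE_AXIS)}, got {plane!r}")
    data = values.max(axis=axis)
    kept = [i for i in range(3) if i != axis]
    spacing = (grid.spacing_mm[kept[0]], grid.spacing_mm[kept[1]])
    return ProjectionImage(data, plane, spacing)


def mip(pet: PETVolume, plane: str = "coronal") -> ProjectionImage:
    """Pixelwise maximum of SUV along the axis orthogonal to ``plane``."""
    return _project(pet.values, pet.grid, plane)


def mip_mask(mask: MaskVolume, plane: str = "coronal") -> ProjectionImage:
    """Binary projection of a mask (max of mask>0 along the ray)."""
    return _project((mask.labels > 0).astype(np.uint8), mask.grid, plane)


def _display_array(proj: ProjectionImage) -> np.ndarray:
    # volume-axis layout is (first-kept, second-kept); show the second kept
    # axis (z for coronal/sagittal, y for axial) vertically, increasing up
    return np.flipud(proj.data.T)


def render(
    proj: ProjectionImage,
    mask_proj: ProjectionImage | None = None,
    out_path=None,
    display_max_suv: float = 10.0,
) -> np.ndarray:
    """Render a projection as an inverted-gray RGB image, optional overlay.

    Pixel aspect honours the physical spacing: the output is resized along
    the coarser axis so 1 display pixel is square in millimetres.  Returns
    the RGB array; writes a PNG when ``out_path`` is given.
    """
    gray = 1.0 - np.clip(_display_array(proj) / float(display_max_suv), 0.0, 1.0)
    rgb = np.repeat((gray * 255).astype(np.uint8)[..., None], 3, axis=2)
    if mask_proj is not None:
        if mask_proj.data.shape != proj.data.shape:
            raise ValueError("mask projection shape does not match PET projection")
        overlay = _display_array(mask_proj) > 0
        alpha = 0.4
        red = np.array([220, 30, 30], dtype=float)
        blended = (1 - alpha) * rgb[overlay].astype(float) + alpha * red
        rgb[overlay] = blended.astype(np.uint8)

    row_sp = proj.pixel_spacing_mm[1]  # display rows run along the 2nd kept axis
    col_sp = proj.pixel_spacing_mm[0]
    h, w = rgb.shape[:2]
    s = min(row_sp, col_sp)
    out_h, out_w = round(h * row_sp / s), round(w * col_sp / s)
    img = Image.fromarray(rgb)
    if (out_h, out_w) != (h, w):
        img = img.resize((out_w, out_h), Image.NEAREST)
    if out_path is not None:
        img.save(Path(out_path))
    return np.asarray(img)


def agreement_plots(stats: DiffStats, out_prefix) -> list[Path]:
    """Scatter (value vs reference, identity line) and difference plot with
    mean +/- 1.96 sd bands taken directly from ``stats``."""
    if stats.table is None or len(stats.table) < 2:
        raise ValueError("need a diff table with >= 2 cases")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    t = stats.table
    paths = []

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(t["reference"], t["value"], s=18, alpha=0.7)
    lim = [0, max(t["reference"].max(), t["value"].max()) * 1.05]
    ax.plot(lim, lim, "k--", lw=1, label="identity")
    ax.set_xlabel("reference TMTV (cm³)")
    ax.set_ylabel("measured TMTV (cm³)")
    ax.legend()
    p = out_prefix.with_name(out_prefix.name + "_scatter.png")
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(t["reference"], t["diff"], s=18, alpha=0.7)
    ax.axhline(stats.mean_diff, color="k", lw=1)
    for band in (stats.mean_diff - 1.96 * stats.sd_diff, stats.mean_diff + 1.96 * stats.sd_diff):
        ax.axhline(band, color="gray", lw=1, ls="--")
    ax.set_xlabel("reference TMTV (cm³)")
    ax.set_ylabel("measured − reference (cm³)")
    p = out_prefix.with_name(out_prefix.name + "_difference.png")
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)
    return paths
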