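"""Membrane surface grids: thickness and curvature maps.

Each leaflet is represented as a Monge patch z = f(x, y) on a regular
periodic grid built from headgroup bead positions (cell value = mean z of
the beads binned to it; empty cells filled by iterative averaging of the
periodic 4-neighborhood). Thickness is the pointwise difference between the
upper and lower leaflet surfaces. Mean (H) and Gaussian (K) curvature follow
from central finite differences with periodic wrap:

    H = [(1 + f_y^2) f_xx - 2 f_x f_y f_xy + (1 + f_x^2) f_yy]
        / [2 (1 + f_x^2 + f_y^2)^(3/2)]
    K = (f_xx f_yy - f_xy^2) / (1 + f_x^2 + f_y^2)^2

With this convention H < 0 at a crest bulging toward +z (a dome) and H > 0
in a bowl opening toward +z.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .system import AnalysisSystem


@dataclass
class SurfaceGrid:
    """Leaflet z-surface on a periodic regular (x, y) grid."""

    z: np.ndarray  # (nx, ny) nm
    spacing: tuple[float, float]  # (dx, dy) nm
    mask: np.ndarray | None = None  # cells that had >=1 sample before fill

    @property
    def shape(self) -> tuple[int, int]:
        return self.z.shape


def grid_surface(points, box, nx: int, ny: int, smoothing_sigma: float = 0.0) -> SurfaceGrid:
    """Bin (x, y, z) samples to a periodic grid of mean z values.

    Empty cells are filled by iteratively averaging filled periodic
    4-neighbors (synchronous sweeps, deterministic); optional periodic
    Gaussian smoothing (sigma in cells) is applied afterwards.
    """
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ParameterError("grid_surface needs at least one point")
    box = np.asarray(box, dtype=float)
    if np.any(box[:2] <= 0):
        raise ParameterError("box lengths must be positive")
    nx, ny = int(nx), int(ny)
    if nx < 3 or ny < 3:
        raise ParameterError("surface grids must be at least 3x3")

    xy = points[:, :2] - box[:2] * np.floor(points[:, :2] / box[:2])
    ix = np.minimum((xy[:, 0] / box[0] * nx).astype(int), nx - 1)
    iy = np.minimum((xy[:, 1] / box[1] * ny).astype(int), ny - 1)
    total = np.zeros((nx, ny))
    count = np.zeros((nx, ny))
    np.add.at(total, (ix, iy), points[:, 2])
    np.add.at(count, (ix, iy), 1.0)
    mask = count > 0
    z = np.where(mask, total / np.maximum(count, 1), 0.0)

    filled = mask.copy()
    while not filled.all():
        neigh_sum = np.zeros_like(z)
        neigh_cnt = np.zeros_like(z)
        for shift, axis in (((1,), 0), ((-1,), 0), ((1,), 1), ((-1,), 1)):
            zf = np.roll(np.where(filled, z, 0.0), shift, axis=axis)
            cf = np.roll(filled.astype(float), shift, axis=axis)
            neigh_sum += zf
            neigh_cnt += cf
        newly = (~filled) & (neigh_cnt > 0)
        z = np.where(newly, neigh_sum / np.maximum(neigh_cnt, 1), z)
        filled |= newly

    if smoothing_sigma > 0:
        z = ndimage.gaussian_filter(z, smoothing_sigma, mode="wrap")
    return SurfaceGrid(z=z, spacing=(box[0] / nx, box[1] / ny), mask=mask)


def thickness_map(upper: SurfaceGrid, lower: SurfaceGrid) -> np.ndarray:
    """Pointwise z_upper - z_lower (nm)."""
    if upper.shape != lower.shape or not np.allclose(upper.spacing, lower.spacing):
        raise ParameterError("upper and lower surface grids must match in shape and spacing")
    return upper.z - lower.z


@dataclass
class CurvatureMaps:
    H: np.ndarray  # mean curvature, nm^-1
    K: np.ndarray  # Gaussian curvature, nm^-2


def _periodic_derivatives(z: np.ndarray, dx: float, dy: float):
    fx = (np.roll(z, -1, axis=0) - np.roll(z, 1, axis=0)) / (2 * dx)
    fy = (np.roll(z, -1, axis=1) - np.roll(z, 1, axis=1)) / (2 * dy)
    fxx = (np.roll(z, -1, axis=0) - 2 * z + np.roll(z, 1, axis=0)) / dx**2
    fyy = (np.roll(z, -1, axis=1) - 2 * z + np.roll(z, 1, axis=1)) / dy**2
    fxy = (
        np.roll(np.roll(z, -1, axis=0), -1, axis=1)
        - np.roll(np.roll(z, -1, axis=0), 1, axis=1)
        - np.roll(np.roll(z, 1, axis=0), -1, axis=1)
        + np.roll(np.roll(z, 1, axis=0), 1, axis=1)
    ) / (4 * dx * dy)
    return fx, fy, fxx, fyy, fxy


def curvature_maps(surface: SurfaceGrid) -> CurvatureMaps:
    """Mean and Gaussian curvature of a Monge-patch surface grid."""
    z = surface.z
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ParameterError("curvature needs a grid of at least 3x3")
    dx, dy = surface.spacing
    fx, fy, fxx, fyy, fxy = _periodic_derivatives(z, dx, dy)
    g = 1.0 + fx**2 + fy**2
    H = ((1 + fy**2) * fxx - 2 * fx * fy * fxy + (1 + fx**2) * fyy) / (2 * g**1.5)
    K = (fxx * fyy - fxy**2) / g**2
    return CurvatureMaps(H=H, K=K)


def leaflet_surfaces(
    system: AnalysisSystem, frame: int, nx: int, ny: int, smoothing_sigma: float = 0.0
) -> tuple[SurfaceGrid, SurfaceGrid]:
    """Upper and lower leaflet surfaces from headgroup beads of one frame."""
    coords = system.frames.coordinates[frame]
    box = system.frames.box[frame]
    head = system.headgroup_indices()
    leaf = system.leaflets(frame)
    pts = {"upper": [], "lower": []}
    for idx, side in zip(head, leaf):
        pts[side].append(coords[idx])
    if not pts["upper"] or not pts["lower"]:
        raise ParameterError("one leaflet is empty; cannot build surfaces")
    upper = grid_surface(np.concatenate(pts["upper"]), box, nx, ny, smoothing_sigma)
    lower = grid_surface(np.concatenate(pts["lower"]), box, nx, ny, smoothing_sigma)
    return upper, lower


def membrane_maps(
    system: AnalysisSystem,
    nx: int = 20,
    ny: int = 20,
    smoothing_sigma: float = 0.0,
    stride: int = 1,
    curvature_of_mean_surface: bool = False,
) -> dict[str, np.ndarray]:
    """Time-averaged thickness and curvature maps of the bilayer.

    By default curvature is computed per frame and then averaged; set
    ``curvature_of_mean_surface`` to instead take the curvature of the
    time-mean upper surface.
    """
    frames = range(0, system.frames.n_frames, stride)
    thick = np.zeros((nx, ny))
    Hsum = np.zeros((nx, ny))
    Ksum = np.zeros((nx, ny))
    upper_sum = np.zeros((nx, ny))
    n = 0
    spacing = None
    for f in frames:
        upper, lower = leaflet_surfaces(system, f, nx, ny, smoothing_sigma)
        spacing = upper.spacing
        thick += thickness_map(upper, lower)
        upper_sum += upper.z
        if not curvature_of_mean_surface:
            cm = curvature_maps(upper)
            Hsum += cm.H
            Ksum += cm.K
        n += 1
    thick /= n
    if curvature_of_mean_surface:
        cm = curvature_maps(SurfaceGrid(upper_sum / n, spacing))
        H, K = cm.H, cm.K
    else:
        H, K = Hsum / n, Ksum / n
    return {"thickness": thick, "mean_curvature": H, "gaussian_curvature": K}


def write_grid(grid: np.ndarray, path_prefix, meta: dict | None = None) -> None:
    """Plain-text matrix plus JSON metadata sidecar."""
    prefix = Path(path_prefix)
    np.savetxt(str(prefix) + ".txt", grid, fmt="%.6g")
    meta = dict(meta or {})
    meta["shape"] = list(grid.shape)
    Path(str(prefix) + ".json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def render_grid_png(grid: np.ndarray, path, title: str = "", unit: str = "") -> None:
    """Optional PNG heatmap of a thickness/curvature/density grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(grid.T, origin="lower", cmap="viridis")
    fig.colorbar(im, ax=ax, label=unit)
    ax.set_title(title)
    ax.set_xlabel("x bin")
    ax.set_ylabel("y bin")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
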