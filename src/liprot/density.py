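"""In-plane lipid density maps and the depletion-enrichment index.

Density maps are time-averaged 2D histograms of selected lipid bead (x, y)
positions, wrapped into [0, L). The depletion-enrichment index of a lipid
type compares its composition fraction inside a shell around the protein to
its bulk (whole-membrane) composition fraction: >1 means the type is
enriched near the protein, <1 depleted.

The protein is assumed to be kept centered in the box across frames
(trajectory pre-processing); a warning is issued if it drifts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .contacts import neighbor_pairs
from .errors import ParameterError
from .system import AnalysisSystem

DEFAULT_SHELL_RADIUS_NM = 1.4  # twice the default contact cutoff


@dataclass
class DensityMap:
    grid: np.ndarray  # (nx, ny); mean counts per frame per cell (or per nm^2)
    extent: tuple[float, float]  # box x/y lengths, nm
    bin_size: tuple[float, float]  # nm
    lipid_type: str
    leaflet: str  # upper | lower | both
    n_frames: int
    mode: str = "count"  # count | area

    def write(self, path_prefix) -> None:
        """Plain-text grid (one row per y-bin) plus a JSON sidecar."""
        prefix = Path(path_prefix)
        np.savetxt(str(prefix) + ".txt", self.grid.T, fmt="%.6g")
        meta = {
            "extent_nm": list(self.extent),
            "bin_size_nm": list(self.bin_size),
            "lipid_type": self.lipid_type,
            "leaflet": self.leaflet,
            "n_frames": self.n_frames,
            "mode": self.mode,
            "shape": list(self.grid.shape),
        }
        Path(str(prefix) + ".json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def _check_centered(system: AnalysisSystem) -> None:
    prot = system.protein_particle_indices()
    for f in range(system.frames.n_frames):
        box = system.frames.box[f]
        centroid = system.frames.coordinates[f][prot, :2].mean(axis=0)
        if np.any(np.abs(centroid - box[:2] / 2) > 0.1 * box[:2]):
            warnings.warn(
                "protein centroid is more than 10% of the box away from the box "
                "center in x/y; density maps assume a pre-centered protein",
                stacklevel=3,
            )
            return


def density_map_2d(
    system: AnalysisSystem,
    lipid_type: str,
    beads: str = "headgroup",
    bins: tuple[int, int] = (40, 40),
    leaflet: str = "both",
    mode: str = "count",
) -> DensityMap:
    """Time-averaged 2D histogram of lipid bead positions in the membrane plane.

    mode="count" gives mean counts per frame per cell (sum * n_frames equals
    the total number of bead observations exactly); mode="area" divides by
    the cell area (nm^-2).
    """
    if lipid_type not in system.lipid_molecules:
        raise ParameterError(f"unknown lipid type {lipid_type!r}")
    if leaflet not in ("upper", "lower", "both"):
        raise ParameterError(f"leaflet must be upper/lower/both, got {leaflet!r}")
    nx, ny = int(bins[0]), int(bins[1])
    if nx < 1 or ny < 1:
        raise ParameterError("bins must be >=1 in each direction")
    _check_centered(system)

    mol_beads = system.lipid_particle_indices(lipid_type, beads=beads)
    if sum(idx.size for idx in mol_beads) == 0:
        raise ParameterError(
            f"zero selected beads for lipid type {lipid_type!r} with beads={beads!r}"
        )
    # molecule positions of this type within the full leaflet assignment
    all_types = system.lipid_types
    type_slice_start = sum(
        len(system.lipid_molecules[t]) for t in all_types[: all_types.index(lipid_type)]
    )

    grid = np.zeros((nx, ny), dtype=float)
    n_frames = system.frames.n_frames
    for f in range(n_frames):
        coords = system.frames.coordinates[f]
        box = system.frames.box[f]
        keep = range(len(mol_beads))
        if leaflet != "both":
            leaf = system.leaflets(f)
            keep = [
                m for m in range(len(mol_beads))
                if leaf[type_slice_start + m] == leaflet
            ]
        for m in keep:
            idx = mol_beads[m]
            if idx.size == 0:
                continue
            xy = coords[idx, :2]
            xy = xy - box[:2] * np.floor(xy / box[:2])  # wrap into [0, L)
            ix = np.minimum((xy[:, 0] / box[0] * nx).astype(int), nx - 1)
            iy = np.minimum((xy[:, 1] / box[1] * ny).astype(int), ny - 1)
            np.add.at(grid, (ix, iy), 1.0)
    grid /= n_frames
    extent = (float(system.frames.box[0][0]), float(system.frames.box[0][1]))
    bin_size = (extent[0] / nx, extent[1] / ny)
    if mode == "area":
        grid = grid / (bin_size[0] * bin_size[1])
    elif mode != "count":
        raise ParameterError(f"mode must be 'count' or 'area', got {mode!r}")
    return DensityMap(grid, extent, bin_size, lipid_type, leaflet, n_frames, mode)


def contour_levels(dmap: DensityMap, levels) -> list[float]:
    """Iso-value thresholds at the given fractions of the map maximum."""
    out = []
    vmax = float(dmap.grid.max())
    for lv in levels:
        if not (0 < lv <= 1):
            raise ParameterError(f"contour level must be in (0, 1], got {lv}")
        out.append(lv * vmax)
    return out


@dataclass
class EnrichmentResult:
    lipid_type: str
    shell_radius: float
    local_fraction: float
    bulk_fraction: float
    index: float
    n_frames_used: int


def shell_composition(
    system: AnalysisSystem, r0: float = DEFAULT_SHELL_RADIUS_NM, stride: int = 1
) -> tuple[dict[str, float], int]:
    """Time-averaged composition fractions of the lipid shell around the protein.

    A molecule is in the shell when any of its beads is within r0 of any
    protein bead (minimum image). Frames with an empty shell are skipped.
    Returns (type -> mean fraction, number of frames used).
    """
    if r0 <= 0:
        raise ParameterError(f"shell radius must be positive, got {r0}")
    if stride < 1:
        raise ParameterError(f"stride must be >=1, got {stride}")
    prot = system.protein_particle_indices()
    types = system.lipid_types
    lip_beads = []
    bead_type = {}
    bead_mol = {}
    for t in types:
        for m, r in enumerate(system.lipid_molecules[t]):
            for a in system.residues[r].particle_indices:
                lip_beads.append(a)
                bead_type[int(a)] = t
                bead_mol[int(a)] = (t, m)
    lip_beads = np.asarray(lip_beads, dtype=np.intp)

    sums = {t: 0.0 for t in types}
    used = 0
    for f in range(0, system.frames.n_frames, stride):
        coords = system.frames.coordinates[f]
        box = system.frames.box[f]
        shell_mols = {bead_mol[b] for _, b in neighbor_pairs(coords, box, prot, lip_beads, r0)}
        if not shell_mols:
            continue
        used += 1
        total = len(shell_mols)
        for t in types:
            sums[t] += sum(1 for tt, _ in shell_mols if tt == t) / total
    if used == 0:
        raise ParameterError(
            f"no lipid molecule ever entered the {r0} nm shell; "
            "increase the shell radius"
        )
    return {t: sums[t] / used for t in types}, used


def enrichment_index(
    system: AnalysisSystem,
    lipid_type: str,
    r0: float = DEFAULT_SHELL_RADIUS_NM,
    stride: int = 1,
) -> EnrichmentResult:
    """Depletion-enrichment index of one lipid type around the protein."""
    if lipid_type not in system.lipid_molecules:
        raise ParameterError(f"unknown lipid type {lipid_type!r}")
    half = float(system.frames.box.min()) / 2
    if r0 >= half:
        raise ParameterError(
            f"shell radius {r0} nm >= half the smallest box length ({half} nm)"
        )
    local, used = shell_composition(system, r0=r0, stride=stride)
    bulk = len(system.lipid_molecules[lipid_type]) / system.n_lipid_molecules
    return EnrichmentResult(
        lipid_type=lipid_type,
        shell_radius=r0,
        local_fraction=local[lipid_type],
        bulk_fraction=bulk,
        index=local[lipid_type] / bulk,
        n_frames_used=used,
    )
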