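"""Synthetic coarse-grained membrane-protein systems with known ground truth.

Generators build Martini-named bilayer + protein-cylinder systems entirely
in memory (optionally written as GRO + XTC so the full I/O path is
exercised). They are test scaffolding with exact, constructed answers —
lipids sit on lattices, the protein is a bead cylinder, motion models are
simple jitter/remixing — not physically realistic dynamics.

All randomness comes from a single seed; the same spec and seed reproduce
the output exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .io import FrameSet, Topology, write_gro, write_trajectory
from .lipids import default_database
from .system import AnalysisSystem, build_system

#: bead templates (headgroup bead included), Martini-like naming
LIPID_TEMPLATES: dict[str, list[str]] = {
    "POPC": ["NC3", "PO4", "GL1", "GL2", "C1A", "D2A", "C3A", "C4A", "C1B", "C2B", "C3B", "C4B"],
    "DPPC": ["NC3", "PO4", "GL1", "GL2", "C1A", "C2A", "C3A", "C4A", "C1B", "C2B", "C3B", "C4B"],
    "POPE": ["NH3", "PO4", "GL1", "GL2", "C1A", "D2A", "C3A", "C4A", "C1B", "C2B", "C3B", "C4B"],
    "CHOL": ["ROH", "R1", "R2", "R3", "R4", "R5", "C1", "C2"],
    "POP2": ["P1", "P2", "PO4", "GL1", "GL2", "C1A", "C2A", "C3A", "C4A", "C1B", "C2B"],
}

_HEADGROUP = {"POPC": "PO4", "DPPC": "PO4", "POPE": "PO4", "CHOL": "ROH", "POP2": "PO4"}

RESNAME_PALETTE = [
    "ALA", "LEU", "PHE", "SER", "ARG", "ASP", "VAL", "LYS", "TYR", "THR",
    "GLU", "ILE", "GLY", "ASN", "TRP", "MET", "PRO", "GLN", "CYS", "HIS",
]

_BEAD_DZ = 0.30  # vertical bead spacing within a lipid, nm
_HEAD_OFFSET = 1.75  # headgroup height above/below the bilayer midplane, nm


@dataclass
class FixtureSpec:
    """Recipe for a synthetic bilayer + protein-cylinder trajectory."""

    box: tuple[float, float, float] = (12.0, 12.0, 10.0)
    n_lipids: dict[str, int] = field(default_factory=lambda: {"POPC": 28, "CHOL": 4})
    protein_radius: float = 1.0
    protein_residues: int = 12
    beads_per_residue: int = 3
    n_frames: int = 10
    dt_ps: float = 1000.0
    motion: str = "static"  # static | gaussian | mix | uniform
    jitter_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.n_lipids.values()) or not self.n_lipids:
            raise ParameterError("n_lipids must hold positive per-leaflet counts")
        if self.n_frames < 1 or self.protein_residues < 1 or self.beads_per_residue < 1:
            raise ParameterError("counts must be positive")
        if self.motion not in ("static", "gaussian", "mix", "uniform"):
            raise ParameterError(f"unknown motion model {self.motion!r}")
        for t in self.n_lipids:
            if t not in LIPID_TEMPLATES:
                raise ParameterError(f"no bead template for lipid type {t!r}")


def _protein_cylinder(spec: FixtureSpec):
    """Bead cylinder at the box center spanning the membrane core."""
    cx, cy, cz = spec.box[0] / 2, spec.box[1] / 2, spec.box[2] / 2
    n_res, bpr = spec.protein_residues, spec.beads_per_residue
    height = 3.0
    names, resids, resnames = [], [], []
    coords = []
    n_beads = n_res * bpr
    for i in range(n_res):
        z = cz + (i - (n_res - 1) / 2) * (height / max(n_res - 1, 1))
        for b in range(bpr):
            angle = 2 * math.pi * (i * bpr + b) / n_beads
            coords.append(
                [cx + spec.protein_radius * math.cos(angle),
                 cy + spec.protein_radius * math.sin(angle),
                 z]
            )
            names.append("BB" if b == 0 else f"SC{b}")
            resids.append(i + 1)
            resnames.append(RESNAME_PALETTE[i % len(RESNAME_PALETTE)])
    return names, resids, resnames, np.asarray(coords)


def _lattice_sites(spec: FixtureSpec, n_needed: int) -> np.ndarray:
    """(x, y) lattice sites avoiding the protein footprint, deterministic order."""
    lx, ly = spec.box[0], spec.box[1]
    cx, cy = lx / 2, ly / 2
    # annular lipids sit roughly one CG bead diameter off the protein surface
    excl = spec.protein_radius + 0.4
    m = max(int(math.ceil(math.sqrt(n_needed))), 2)
    while True:
        ax, ay = lx / m, ly / m
        sites = []
        for i in range(m):
            for j in range(m):
                x, y = (i + 0.5) * ax, (j + 0.5) * ay
                if (x - cx) ** 2 + (y - cy) ** 2 > excl**2:
                    sites.append([x, y])
        if len(sites) >= n_needed:
            return np.asarray(sites)
        m += 1


def _lipid_molecule(lipid_type: str, site_xy, leaflet: str, z_mid: float) -> np.ndarray:
    beads = LIPID_TEMPLATES[lipid_type]
    head_idx = beads.index(_HEADGROUP[lipid_type])
    sign = 1.0 if leaflet == "upper" else -1.0
    z_head = z_mid + sign * _HEAD_OFFSET
    coords = np.empty((len(beads), 3))
    coords[:, 0] = site_xy[0]
    coords[:, 1] = site_xy[1]
    for k in range(len(beads)):
        coords[k, 2] = z_head - sign * (k - head_idx) * _BEAD_DZ
    return coords


def make_membrane_trajectory(spec: FixtureSpec) -> tuple[Topology, FrameSet]:
    """Bilayer on two z-offset lattices around a central protein cylinder."""
    rng = np.random.default_rng(spec.seed)
    z_mid = spec.box[2] / 2

    names, resids, resnames, prot_coords = _protein_cylinder(spec)
    coords0 = [prot_coords]
    n_per_leaflet = sum(spec.n_lipids.values())
    sites = _lattice_sites(spec, n_per_leaflet)
    resid = spec.protein_residues
    mol_atom_slices = []  # (start, stop) per lipid molecule, for rigid moves
    atom_count = prot_coords.shape[0]
    type_sequence = [t for t in sorted(spec.n_lipids) for _ in range(spec.n_lipids[t])]
    for leaflet in ("upper", "lower"):
        order = rng.permutation(len(sites))[:n_per_leaflet]
        for t, s in zip(type_sequence, order):
            mol = _lipid_molecule(t, sites[s], leaflet, z_mid)
            resid += 1
            beads = LIPID_TEMPLATES[t]
            names.extend(beads)
            resids.extend([resid] * len(beads))
            resnames.extend([t] * len(beads))
            coords0.append(mol)
            mol_atom_slices.append((atom_count, atom_count + len(beads)))
            atom_count += len(beads)
    base = np.concatenate(coords0)

    n_atoms = base.shape[0]
    frames = np.empty((spec.n_frames, n_atoms, 3))
    box = np.tile(np.asarray(spec.box, dtype=float), (spec.n_frames, 1))
    for f in range(spec.n_frames):
        frame = base.copy()
        if spec.motion == "mix":
            # re-mix lipid molecules over lattice sites (rigid xy translation)
            half = len(mol_atom_slices) // 2
            for mols in (mol_atom_slices[:half], mol_atom_slices[half:]):
                order = rng.permutation(len(sites))[: len(mols)]
                for (a0, a1), s in zip(mols, order):
                    frame[a0:a1, 0] = sites[s][0] + (frame[a0:a1, 0] - frame[a0, 0])
                    frame[a0:a1, 1] = sites[s][1] + (frame[a0:a1, 1] - frame[a0, 1])
        elif spec.motion == "uniform":
            for a0, a1 in mol_atom_slices:
                xy = rng.uniform(0, 1, size=2) * np.asarray(spec.box[:2])
                frame[a0:a1, 0] = xy[0]
                frame[a0:a1, 1] = xy[1]
        if spec.motion == "gaussian" and spec.jitter_sigma > 0:
            frame += rng.normal(0.0, spec.jitter_sigma, size=frame.shape)
        frames[f] = frame
    times = np.arange(spec.n_frames) * spec.dt_ps
    topo = Topology.from_atom_records(names, resids, resnames)
    return topo, FrameSet(frames, box, times)


def make_membrane_system(spec: FixtureSpec) -> AnalysisSystem:
    topo, frames = make_membrane_trajectory(spec)
    return build_system(topo, frames, default_database())


def write_fixture_files(
    topology: Topology, frames: FrameSet, gro_path, traj_path=None
) -> None:
    """Write frame 0 as GRO and, optionally, all frames as XTC/TRR/DCD."""
    write_gro(topology, frames.coordinates[0], frames.box[0], gro_path)
    if traj_path is not None:
        write_trajectory(traj_path, frames.coordinates, frames.box, frames.times)


# ---------------------------------------------------------------------------
# scripted contact schedules
# ---------------------------------------------------------------------------


def make_scripted_contact_system(
    schedule: dict[tuple[int, int], set],
    n_frames: int,
    cutoff: float = 0.7,
    n_residues: int | None = None,
    n_molecules: int | None = None,
    dt_ps: float = 1000.0,
    lipid_type: str = "POPC",
) -> AnalysisSystem:
    """System whose contact series equals a prescribed schedule exactly.

    ``schedule`` maps (protein residue index, lipid molecule index) to the
    set of frames in which that molecule touches that residue. In scheduled
    frames the molecule's single headgroup bead sits at 0.7*cutoff from the
    residue bead; otherwise it parks at 3*cutoff. Residues are spaced
    5*cutoff apart so placements near one residue can never graze another.
    A molecule may contact at most one residue per frame.
    """
    if n_residues is None:
        n_residues = max((r for r, _ in schedule), default=0) + 1
    if n_molecules is None:
        n_molecules = max((m for _, m in schedule), default=0) + 1
    for (r, m), fr in schedule.items():
        if r >= n_residues or m >= n_molecules:
            raise ParameterError(f"schedule entry ({r}, {m}) outside the system")
        if any(f >= n_frames or f < 0 for f in fr):
            raise ParameterError(f"schedule entry ({r}, {m}) has frames outside 0..{n_frames - 1}")
    # at most one residue per molecule per frame
    per_frame: dict[tuple[int, int], int] = {}
    for (r, m), fr in schedule.items():
        for f in fr:
            if (m, f) in per_frame and per_frame[(m, f)] != r:
                raise ParameterError(
                    f"molecule {m} scheduled with two residues in frame {f}"
                )
            per_frame[(m, f)] = r

    s = 5 * cutoff
    x0, y0, z0 = 2 * cutoff, 2 * cutoff, 2 * cutoff
    box = (x0 + n_residues * s + 2 * cutoff, y0 + 5 * cutoff, 4.2 * cutoff)

    names = ["BB"] * n_residues + ["PO4"] * n_molecules
    resids = list(range(1, n_residues + n_molecules + 1))
    resnames = ["ALA"] * n_residues + [lipid_type] * n_molecules

    res_x = x0 + np.arange(n_residues) * s
    home = {}
    for (r, m), fr in schedule.items():
        home.setdefault(m, r)
    coords = np.empty((n_frames, n_residues + n_molecules, 3))
    coords[:, :, 2] = z0
    for f in range(n_frames):
        coords[f, :n_residues, 0] = res_x
        coords[f, :n_residues, 1] = y0
        for m in range(n_molecules):
            r_contact = per_frame.get((m, f))
            r_home = r_contact if r_contact is not None else home.get(m, m % n_residues)
            coords[f, n_residues + m, 0] = res_x[r_home]
            offset = 0.7 * cutoff if r_contact is not None else 3 * cutoff
            coords[f, n_residues + m, 1] = y0 + offset
    boxes = np.tile(np.asarray(box), (n_frames, 1))
    times = np.arange(n_frames) * dt_ps
    topo = Topology.from_atom_records(names, resids, resnames)
    return build_system(topo, FrameSet(coords, boxes, times), default_database())


def schedule_presence(
    schedule: dict[tuple[int, int], set], n_residues: int, n_molecules: int, n_frames: int
) -> np.ndarray:
    """Ground-truth presence array (n_residues, n_molecules, n_frames)."""
    out = np.zeros((n_residues, n_molecules, n_frames), dtype=bool)
    for (r, m), fr in schedule.items():
        for f in fr:
            out[r, m, f] = True
    return out


# ---------------------------------------------------------------------------
# planted shell enrichment
# ---------------------------------------------------------------------------


def make_enrichment_system(
    n_per_type: dict[str, int],
    shell_counts: dict[str, int],
    n_frames: int = 100,
    r0: float = 1.4,
    box: tuple[float, float, float] = (20.0, 20.0, 10.0),
    seed: int = 0,
) -> AnalysisSystem:
    """System with an exactly planted shell composition around the protein.

    Each frame, ``shell_counts[t]`` randomly chosen molecules of each type
    are placed inside the r0 shell of the protein cylinder and the rest well
    outside it, so the time-averaged local composition is the planted one
    and the expected enrichment index of type t is
    (shell_counts[t] / sum(shell_counts)) / (n_per_type[t] / sum(n_per_type)).

    Lipids are single headgroup beads; geometry only, no dynamics.
    """
    for t, k in shell_counts.items():
        if k > n_per_type.get(t, 0):
            raise ParameterError(f"shell count for {t!r} exceeds its molecule count")
    rng = np.random.default_rng(seed)
    spec = FixtureSpec(box=box, protein_radius=1.0, protein_residues=8, beads_per_residue=3)
    names, resids, resnames, prot = _protein_cylinder(spec)
    cx, cy = box[0] / 2, box[1] / 2
    prot_z = prot[:, 2]

    types = sorted(n_per_type)
    mol_type = [t for t in types for _ in range(n_per_type[t])]
    n_mols = len(mol_type)
    resid = spec.protein_residues
    for t in mol_type:
        resid += 1
        names.append(_HEADGROUP.get(t, "PO4"))
        resids.append(resid)
        resnames.append(t)

    n_atoms = prot.shape[0] + n_mols
    coords = np.empty((n_frames, n_atoms, 3))
    coords[:, : prot.shape[0]] = prot
    # radial bands: shell placement guarantees distance to the nearest protein
    # bead < r0; outside placement guarantees > r0 by a wide margin
    rho_shell = (spec.protein_radius + 0.25, spec.protein_radius + min(r0 - 0.3, 1.0))
    rho_out = (spec.protein_radius + r0 + 2.0, min(box[0], box[1]) / 2 - 0.5)
    type_slices = {}
    start = 0
    for t in types:
        type_slices[t] = np.arange(start, start + n_per_type[t])
        start += n_per_type[t]
    for f in range(n_frames):
        in_shell = np.zeros(n_mols, dtype=bool)
        for t in types:
            k = shell_counts.get(t, 0)
            if k:
                chosen = rng.choice(type_slices[t], size=k, replace=False)
                in_shell[chosen] = True
        for m in range(n_mols):
            lo, hi = rho_shell if in_shell[m] else rho_out
            rho = rng.uniform(lo, hi)
            ang = rng.uniform(0, 2 * math.pi)
            a = prot.shape[0] + m
            coords[f, a, 0] = cx + rho * math.cos(ang)
            coords[f, a, 1] = cy + rho * math.sin(ang)
            coords[f, a, 2] = rng.choice(prot_z) if in_shell[m] else box[2] / 2
    boxes = np.tile(np.asarray(box), (n_frames, 1))
    topo = Topology.from_atom_records(names, resids, resnames)
    return build_system(topo, FrameSet(coords, boxes, np.arange(n_frames) * 1000.0))


# ---------------------------------------------------------------------------
# analytic surfaces
# ---------------------------------------------------------------------------


def make_analytic_surface_points(shape, n_points: int, box, seed: int = 0) -> np.ndarray:
    """Sample (x, y) uniformly in the box and set z from a closed form.

    shape: ("flat", z0) | ("sinusoid", A, wavelength, axis) | ("plane", a, b)
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    xy = rng.uniform(0, 1, size=(n_points, 2)) * box[:2]
    kind = shape[0]
    if kind == "flat":
        z = np.full(n_points, float(shape[1]))
    elif kind == "sinusoid":
        _, amp, wavelength, axis = shape
        z = amp * np.sin(2 * math.pi * xy[:, axis] / wavelength)
    elif kind == "plane":
        _, a, b = shape
        z = a * xy[:, 0] + b * xy[:, 1]
    else:
        raise ParameterError(f"unknown surface shape {kind!r}")
    return np.column_stack([xy, z])
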