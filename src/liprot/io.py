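"""Coordinate and trajectory I/O.

Internal units are fixed: lengths in nm, times in ps. GRO files are already
in nm; PDB files (angstrom) are converted on read and write. Only
orthorhombic periodic boxes are supported — triclinic boxes raise, because
all downstream minimum-image arithmetic assumes a rectangular cell.

GRO and PDB are parsed here directly (the error contracts — line numbers,
box checks, B-factor column format — are part of this module's interface);
binary trajectory formats (XTC/TRR/DCD) are delegated to MDAnalysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError, ParseError

ANGSTROM_PER_NM = 10.0


# ---------------------------------------------------------------------------
# in-memory containers
# ---------------------------------------------------------------------------


@dataclass
class Topology:
    """Per-particle names plus the residue grouping derived from them.

    Residues are maximal runs of particles sharing (chain, residue number,
    residue name); this matches how GRO/PDB writers lay out molecules.
    """

    atom_names: list[str]
    atom_resindex: np.ndarray  # (n_atoms,) 0-based residue index per atom
    residue_names: list[str]
    residue_resids: np.ndarray  # original (file) residue numbers
    residue_chains: list[str]
    residue_atom_indices: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.residue_atom_indices:
            n_res = len(self.residue_names)
            idx = [[] for _ in range(n_res)]
            for a, r in enumerate(self.atom_resindex):
                idx[r].append(a)
            self.residue_atom_indices = [np.asarray(i, dtype=np.intp) for i in idx]

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    @classmethod
    def from_atom_records(cls, names, resids, resnames, chains=None) -> "Topology":
        n = len(names)
        if chains is None:
            chains = [""] * n
        resindex = np.empty(n, dtype=np.intp)
        res_names: list[str] = []
        res_ids: list[int] = []
        res_chains: list[str] = []
        prev = None
        for a in range(n):
            key = (chains[a], int(resids[a]), resnames[a])
            if key != prev:
                res_names.append(resnames[a])
                res_ids.append(int(resids[a]))
                res_chains.append(chains[a])
                prev = key
            resindex[a] = len(res_names) - 1
        return cls(
            atom_names=list(names),
            atom_resindex=resindex,
            residue_names=res_names,
            residue_resids=np.asarray(res_ids, dtype=np.intp),
            residue_chains=res_chains,
        )


@dataclass
class FrameSet:
    """A set of frames: coordinates (nm), orthorhombic boxes (nm), times (ps)."""

    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    box: np.ndarray  # (n_frames, 3)
    times: np.ndarray  # (n_frames,)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ParameterError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.box.shape != (self.n_frames, 3):
            raise ParameterError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise ParameterError("all box lengths must be positive")
        if np.any(np.diff(self.times) < 0):
            raise ParameterError("frame times must be non-decreasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------


def _parse_gro_box(line: str, lineno: int) -> np.ndarray:
    fields = line.split()
    if len(fields) not in (3, 9):
        raise ParseError(f"line {lineno}: malformed GRO box line: {line!r}")
    try:
        vals = [float(x) for x in fields]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed GRO box line: {line!r}") from exc
    if len(vals) == 9 and any(abs(v) > 1e-9 for v in vals[3:]):
        raise ParseError(
            f"line {lineno}: unsupported box: triclinic GRO box with "
            "non-zero off-diagonal components (only orthorhombic boxes are supported)"
        )
    return np.asarray(vals[:3], dtype=float)


def read_gro(path) -> tuple[Topology, FrameSet]:
    """Read a (single-frame) GROMACS GRO file. Positions are in nm."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: truncated GRO file ({len(lines)} lines)")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as exc:
        raise ParseError(f"line 2: expected atom count, got {lines[1]!r}") from exc
    if len(lines) < n_atoms + 3:
        raise ParseError(
            f"{path}: truncated GRO file: expected {n_atoms + 3} lines, got {len(lines)}"
        )
    names, resids, resnames = [], [], []
    coords = np.empty((n_atoms, 3), dtype=float)
    for i in range(n_atoms):
        lineno = i + 3
        line = lines[i + 2]
        if len(line) < 44:
            raise ParseError(f"line {lineno}: GRO atom line too short: {line!r}")
        try:
            resids.append(int(line[0:5]))
            resnames.append(line[5:10].strip())
            names.append(line[10:15].strip())
            coords[i, 0] = float(line[20:28])
            coords[i, 1] = float(line[28:36])
            coords[i, 2] = float(line[36:44])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: malformed GRO atom line: {line!r}") from exc
    box_lineno = n_atoms + 3
    box_line = lines[n_atoms + 2]
    if not box_line.strip():
        raise ParseError(f"line {box_lineno}: missing GRO box line")
    box = _parse_gro_box(box_line, box_lineno)
    if np.any(box <= 0):
        raise ParseError(f"line {box_lineno}: non-positive box length in {box_line!r}")
    topo = Topology.from_atom_records(names, resids, resnames)
    frames = FrameSet(coords[None, :, :], box[None, :], np.zeros(1))
    return topo, frames


def write_gro(topology: Topology, coordinates: np.ndarray, box, path, title="liprot") -> None:
    """Write one frame as GRO (nm)."""
    coordinates = np.asarray(coordinates, dtype=float)
    box = np.asarray(box, dtype=float)
    lines = [title, f"{topology.n_atoms:5d}"]
    for a in range(topology.n_atoms):
        r = topology.atom_resindex[a]
        resid = int(topology.residue_resids[r]) % 100000
        lines.append(
            f"{resid:5d}{topology.residue_names[r]:<5.5s}{topology.atom_names[a]:>5.5s}"
            f"{(a + 1) % 100000:5d}"
            f"{coordinates[a, 0]:8.3f}{coordinates[a, 1]:8.3f}{coordinates[a, 2]:8.3f}"
        )
    lines.append(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------


def read_pdb(path) -> tuple[Topology, FrameSet]:
    """Read the first model of a PDB file, converting angstrom to nm."""
    path = Path(path)
    names, resids, resnames, chains = [], [], [], []
    coords: list[list[float]] = []
    box = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6]
        if rec == "CRYST1":
            try:
                a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
                alpha = float(line[33:40])
                beta = float(line[40:47])
                gamma = float(line[47:54])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed CRYST1 record") from exc
            if any(abs(ang - 90.0) > 1e-3 for ang in (alpha, beta, gamma)):
                raise ParseError(
                    f"line {lineno}: unsupported box: non-orthorhombic CRYST1 angles"
                )
            box = np.array([a, b, c]) / ANGSTROM_PER_NM
        elif rec in ("ATOM  ", "HETATM"):
            if len(line) < 54:
                raise ParseError(f"line {lineno}: PDB atom line too short: {line!r}")
            try:
                names.append(line[12:16].strip())
                resnames.append(line[17:21].strip())
                chains.append(line[21].strip())
                resids.append(int(line[22:26]))
                coords.append(
                    [
                        float(line[30:38]) / ANGSTROM_PER_NM,
                        float(line[38:46]) / ANGSTROM_PER_NM,
                        float(line[46:54]) / ANGSTROM_PER_NM,
                    ]
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed PDB atom line: {line!r}") from exc
        elif rec in ("ENDMDL",):
            break
    if not names:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    if box is None:
        # PDB files without CRYST1 get a generous pseudo-box; contacts on such
        # input are only safe if the system is far from the boundary.
        xyz = np.asarray(coords)
        box = (xyz.max(axis=0) - xyz.min(axis=0)) + 10.0
    topo = Topology.from_atom_records(names, resids, resnames, chains)
    frames = FrameSet(np.asarray(coords)[None, :, :], np.asarray(box)[None, :], np.zeros(1))
    return topo, frames


def read_coordinates(path) -> tuple[Topology, FrameSet]:
    """Read a coordinate file (GRO or PDB) into a 1-frame FrameSet."""
    suffix = Path(path).suffix.lower()
    if suffix == ".gro":
        return read_gro(path)
    if suffix == ".pdb":
        return read_pdb(path)
    raise ParseError(f"unknown coordinate file extension {suffix!r} (expected .gro or .pdb)")


# ---------------------------------------------------------------------------
# trajectories (delegated to MDAnalysis)
# ---------------------------------------------------------------------------

_TRAJ_READERS = {".xtc": "XTC", ".trr": "TRR", ".dcd": "DCD"}


def read_trajectory(path, topology: Topology, stride: int = 1) -> FrameSet:
    """Read an XTC/TRR/DCD trajectory, keeping frames 0, stride, 2*stride, ...

    Coordinates are converted from MDAnalysis angstrom to nm; times are ps.
    """
    if stride < 1:
        raise ParameterError(f"stride must be a positive integer, got {stride}")
    suffix = Path(path).suffix.lower()
    if suffix not in _TRAJ_READERS:
        raise ParseError(
            f"unknown trajectory extension {suffix!r} (expected .xtc, .trr or .dcd)"
        )
    import MDAnalysis as mda

    reader_cls = getattr(mda.coordinates, _TRAJ_READERS[suffix])
    reader = getattr(reader_cls, f"{_TRAJ_READERS[suffix]}Reader")(str(path))
    try:
        if reader.n_atoms != topology.n_atoms:
            raise ParseError(
                f"{path}: particle count mismatch: trajectory has {reader.n_atoms} "
                f"particles, topology has {topology.n_atoms}"
            )
        coords, boxes, times = [], [], []
        for i, ts in enumerate(reader):
            if i % stride:
                continue
            dims = ts.dimensions
            if dims is None or np.any(dims[:3] <= 0):
                raise ParseError(f"{path}: frame {i} has no valid box")
            if any(abs(ang - 90.0) > 1e-3 for ang in dims[3:6]):
                raise ParseError(f"{path}: unsupported box: non-orthorhombic frame {i}")
            coords.append(ts.positions / ANGSTROM_PER_NM)
            boxes.append(dims[:3] / ANGSTROM_PER_NM)
            times.append(ts.time)
    finally:
        reader.close()
    return FrameSet(np.asarray(coords), np.asarray(boxes), np.asarray(times))


def write_trajectory(path, coordinates: np.ndarray, box: np.ndarray, times: np.ndarray) -> None:
    """Write frames (nm, ps) to an XTC/TRR/DCD file via MDAnalysis."""
    import MDAnalysis as mda

    coordinates = np.asarray(coordinates, dtype=float)
    n_frames, n_atoms, _ = coordinates.shape
    u = mda.Universe.empty(n_atoms, trajectory=True)
    with mda.Writer(str(path), n_atoms=n_atoms) as w:
        for f in range(n_frames):
            u.atoms.positions = coordinates[f] * ANGSTROM_PER_NM
            u.dimensions = [
                box[f][0] * ANGSTROM_PER_NM,
                box[f][1] * ANGSTROM_PER_NM,
                box[f][2] * ANGSTROM_PER_NM,
                90.0,
                90.0,
                90.0,
            ]
            u.trajectory.ts.time = float(times[f])
            u.trajectory.ts.frame = f
            w.write(u.atoms)


# ---------------------------------------------------------------------------
# B-factor projection
# ---------------------------------------------------------------------------


def write_bfactor_pdb(
    topology: Topology,
    coordinates: np.ndarray,
    box,
    per_residue_values,
    path,
    residue_indices=None,
    scaling: str = "none",
) -> None:
    """Write a PDB whose B-factor column carries a per-residue scalar.

    ``per_residue_values`` holds one value per residue in ``residue_indices``
    (default: all residues). With ``scaling="linear-to-range"`` values are
    min-max rescaled to [0, 99.99]; with ``scaling="none"`` they must already
    fit the fixed-width %6.2f column.
    """
    values = np.asarray(per_residue_values, dtype=float)
    if residue_indices is None:
        residue_indices = np.arange(topology.n_residues)
    residue_indices = np.asarray(residue_indices, dtype=np.intp)
    if values.shape != residue_indices.shape:
        raise ParameterError(
            f"value count mismatch: {values.size} values for {residue_indices.size} residues"
        )
    if not np.all(np.isfinite(values)):
        raise ParameterError("non-finite B-factor values are not allowed")
    if scaling == "linear-to-range":
        vmin, vmax = values.min(), values.max()
        if vmax > vmin:
            values = (values - vmin) / (vmax - vmin) * 99.99
        else:
            values = np.zeros_like(values)
    elif scaling == "none":
        if values.min() < -99.99 or values.max() > 999.99:
            raise ParameterError(
                "B-factor values outside the representable %6.2f range; "
                "use scaling='linear-to-range'"
            )
    else:
        raise ParameterError(f"unknown scaling {scaling!r}")

    value_of_residue = dict(zip(residue_indices.tolist(), values.tolist()))
    coordinates = np.asarray(coordinates, dtype=float) * ANGSTROM_PER_NM
    box = np.asarray(box, dtype=float) * ANGSTROM_PER_NM
    lines = [
        f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}  90.00  90.00  90.00 P 1           1"
    ]
    serial = 0
    for r in range(topology.n_residues):
        b = value_of_residue.get(r, 0.0)
        chain = (topology.residue_chains[r] or "A")[0]
        for a in topology.residue_atom_indices[r]:
            serial += 1
            name = topology.atom_names[a]
            name_f = f" {name:<3.3s}" if len(name) < 4 else name[:4]
            lines.append(
                f"ATOM  {serial % 100000:5d} {name_f} {topology.residue_names[r]:<4.4s}"
                f"{chain}{int(topology.residue_resids[r]) % 10000:4d}    "
                f"{coordinates[a, 0]:8.3f}{coordinates[a, 1]:8.3f}{coordinates[a, 2]:8.3f}"
                f"{1.00:6.2f}{b:6.2f}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bfactors(path) -> tuple[np.ndarray, np.ndarray]:
    """Read per-residue B-factors back from a PDB (first atom of each residue)."""
    resids, values = [], []
    prev = None
    for line in Path(path).read_text().splitlines():
        if line[:6] in ("ATOM  ", "HETATM"):
            key = (line[21], int(line[22:26]), line[17:21].strip())
            if key != prev:
                resids.append(int(line[22:26]))
                values.append(float(line[60:66]))
                prev = key
    return np.asarray(resids), np.asarray(values)
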