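"""Lipid-protein contact detection under periodic boundary conditions.

A residue and a lipid molecule are "in contact" in a frame when any selected
bead of the molecule lies within the cutoff distance (inclusive) of any bead
of the residue, measured with the minimum-image convention in an
orthorhombic box. Neighbor search uses a cell list (cell edge >= cutoff,
27-cell periodic neighborhood) and is contractually identical to the
O(N^2) minimum-image scan.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .system import AnalysisSystem

DEFAULT_CUTOFF_NM = 0.7  # customary for Martini-resolution bead sizes


def min_image_distance(p, q, box) -> float:
    """Euclidean distance between two points under the minimum-image convention."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ParameterError("box lengths must be positive")
    d = p - q
    d -= box * np.rint(d / box)
    return float(np.sqrt((d * d).sum()))


def _check_cutoff(cutoff: float, box) -> None:
    if cutoff <= 0:
        raise ParameterError(f"cutoff must be positive, got {cutoff}")
    half = float(np.min(box)) / 2.0
    if cutoff >= half:
        raise ParameterError(
            f"cutoff {cutoff} nm >= half the smallest box length ({half} nm); "
            "reduce the cutoff or use a larger box (minimum-image validity)"
        )


def brute_force_pairs(coordinates, box, idx_a, idx_b, cutoff) -> set[tuple[int, int]]:
    """Reference O(N^2) minimum-image pair scan (oracle for the cell list)."""
    box = np.asarray(box, dtype=float)
    _check_cutoff(cutoff, box)
    a = np.asarray(coordinates, dtype=float)[np.asarray(idx_a, dtype=np.intp)]
    b = np.asarray(coordinates, dtype=float)[np.asarray(idx_b, dtype=np.intp)]
    pairs: set[tuple[int, int]] = set()
    c2 = cutoff * cutoff
    for i, ia in enumerate(np.asarray(idx_a, dtype=np.intp)):
        d = a[i] - b
        d -= box * np.rint(d / box)
        d2 = (d * d).sum(axis=1)
        for j in np.nonzero(d2 <= c2)[0]:
            pairs.add((int(ia), int(np.asarray(idx_b)[j])))
    return pairs


def neighbor_pairs(coordinates, box, idx_a, idx_b, cutoff) -> set[tuple[int, int]]:
    """All (a, b) index pairs within cutoff (inclusive) under minimum image.

    Cell-list implementation; results are identical to brute_force_pairs.
    """
    box = np.asarray(box, dtype=float)
    _check_cutoff(cutoff, box)
    idx_a = np.asarray(idx_a, dtype=np.intp)
    idx_b = np.asarray(idx_b, dtype=np.intp)
    if idx_a.size == 0 or idx_b.size == 0:
        return set()
    coords = np.asarray(coordinates, dtype=float)
    pos_a = coords[idx_a] - box * np.floor(coords[idx_a] / box)
    pos_b = coords[idx_b] - box * np.floor(coords[idx_b] / box)

    ncell = np.maximum(np.floor(box / cutoff).astype(int), 1)
    cell_len = box / ncell
    cell_b = np.minimum((pos_b / cell_len).astype(int), ncell - 1)
    # bucket b particles by flat cell id
    flat_b = (cell_b[:, 0] * ncell[1] + cell_b[:, 1]) * ncell[2] + cell_b[:, 2]
    order = np.argsort(flat_b, kind="stable")
    sorted_flat = flat_b[order]
    buckets: dict[int, np.ndarray] = {}
    start = 0
    for k in range(1, len(order) + 1):
        if k == len(order) or sorted_flat[k] != sorted_flat[start]:
            buckets[int(sorted_flat[start])] = order[start:k]
            start = k

    offsets = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)])
    cell_a = np.minimum((pos_a / cell_len).astype(int), ncell - 1)
    c2 = cutoff * cutoff
    pairs: set[tuple[int, int]] = set()
    for i in range(idx_a.size):
        neigh = (cell_a[i] + offsets) % ncell
        flat = np.unique((neigh[:, 0] * ncell[1] + neigh[:, 1]) * ncell[2] + neigh[:, 2])
        cand_lists = [buckets[f] for f in flat if int(f) in buckets]
        if not cand_lists:
            continue
        cand = np.concatenate(cand_lists)
        d = pos_a[i] - pos_b[cand]
        d -= box * np.rint(d / box)
        d2 = (d * d).sum(axis=1)
        for j in cand[d2 <= c2]:
            pairs.add((int(idx_a[i]), int(idx_b[j])))
    return pairs


@dataclass
class ContactParams:
    """Parameters of the contact search."""

    cutoff: float = DEFAULT_CUTOFF_NM
    stride: int = 1
    lipid_selection: str | dict = "all"  # "all" | "headgroup", or per-type dict
    residue_selection: list[int] | None = None  # protein residue indices (0-based)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ParameterError(f"cutoff must be positive, got {self.cutoff}")
        if int(self.stride) < 1:
            raise ParameterError(f"stride must be >=1, got {self.stride}")
        self.stride = int(self.stride)

    def beads_for(self, lipid_type: str) -> str:
        if isinstance(self.lipid_selection, dict):
            return self.lipid_selection.get(lipid_type, "all")
        return self.lipid_selection


@dataclass
class ContactSeries:
    """Per (residue, lipid type) contact presence over frames.

    presence[t] is a boolean array (n_selected_residues, n_molecules_of_t,
    n_frames); counts are derived by summing over molecules.
    """

    presence: dict[str, np.ndarray]
    residue_indices: np.ndarray  # 0-based indices into system.residues
    molecule_residue_indices: dict[str, np.ndarray]
    frame_times: np.ndarray  # ps
    cutoff: float = DEFAULT_CUTOFF_NM

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    @property
    def lipid_types(self) -> list[str]:
        return sorted(self.presence)

    @property
    def dt_ps(self) -> float:
        """Frame spacing in ps (1000 ps fallback for single-frame series)."""
        if len(self.frame_times) > 1:
            return float(self.frame_times[1] - self.frame_times[0])
        return 1000.0

    def counts(self, lipid_type: str) -> np.ndarray:
        """Distinct molecules of a type in contact, (n_residues, n_frames)."""
        return self.presence[lipid_type].sum(axis=1)

    def residue_presence(self, lipid_type: str) -> np.ndarray:
        """OR over molecules: (n_residues, n_frames) boolean."""
        return self.presence[lipid_type].any(axis=1)

    # -- serialization ------------------------------------------------------

    def to_dataframe(self, sparse: bool = True) -> pd.DataFrame:
        rows = []
        for t in self.lipid_types:
            pres = self.presence[t]
            r_idx, m_idx, f_idx = np.nonzero(pres)
            for r, m, f in zip(r_idx, m_idx, f_idx):
                rows.append(
                    (
                        int(self.residue_indices[r]),
                        t,
                        int(self.molecule_residue_indices[t][m]),
                        int(f),
                        float(self.frame_times[f]),
                        1,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=["residue_id", "lipid_type", "lipid_mol_id", "frame", "time_ps", "in_contact"],
        )

    def save(self, path) -> None:
        """Write a compressed columnar export (deterministic bytes)."""
        df = self.to_dataframe()
        header = (
            f"# liprot contact series; cutoff_nm={self.cutoff}; "
            f"n_frames={self.n_frames}\n"
        )
        with gzip.GzipFile(path, "wb", mtime=0) as fh:
            fh.write(header.encode())
            fh.write(df.to_csv(index=False).encode())


def compute_contact_series(system: AnalysisSystem, params: ContactParams | None = None) -> ContactSeries:
    """Detect contacts on every analyzed frame and build the series."""
    if params is None:
        params = ContactParams()
    residues = (
        np.asarray(params.residue_selection, dtype=np.intp)
        if params.residue_selection is not None
        else np.asarray(system.protein_residue_indices, dtype=np.intp)
    )
    # per-residue protein bead index list, and bead -> residue position map
    prot_beads = []
    bead_res_pos = {}
    for pos, r in enumerate(residues):
        for a in system.residues[r].particle_indices:
            prot_beads.append(a)
            bead_res_pos[int(a)] = pos
    prot_beads = np.asarray(prot_beads, dtype=np.intp)

    types = system.lipid_types
    mol_res = {t: np.asarray(system.lipid_molecules[t], dtype=np.intp) for t in types}
    lip_beads = []
    bead_mol = {}  # bead -> (type, molecule position)
    for t in types:
        for m, idx in enumerate(system.lipid_particle_indices(t, beads=params.beads_for(t))):
            for a in idx:
                lip_beads.append(a)
                bead_mol[int(a)] = (t, m)
    lip_beads = np.asarray(lip_beads, dtype=np.intp)

    frame_ids = np.arange(0, system.frames.n_frames, params.stride)
    presence = {
        t: np.zeros((residues.size, mol_res[t].size, frame_ids.size), dtype=bool) for t in types
    }
    for out_f, f in enumerate(frame_ids):
        coords = system.frames.coordinates[f]
        box = system.frames.box[f]
        for pa, la in neighbor_pairs(coords, box, prot_beads, lip_beads, params.cutoff):
            t, m = bead_mol[la]
            presence[t][bead_res_pos[pa], m, out_f] = True
    return ContactSeries(
        presence=presence,
        residue_indices=residues,
        molecule_residue_indices=mol_res,
        frame_times=system.frames.times[frame_ids],
        cutoff=params.cutoff,
    )
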