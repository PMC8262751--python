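"""Topology classification and the analysis system container.

Every residue is classified as protein (canonical amino-acid names plus HIS
protonation variants), lipid (a name known to the LipidDatabase) or unknown.
Input is expected to contain only protein and lipids; in strict mode
water/ion residue names are rejected outright, mirroring the preprocessing
restriction that solvent must be stripped before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, SolventError, SystemError_
from .io import FrameSet, Topology
from .lipids import LipidDatabase, default_database

PROTEIN_RESNAMES = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
        # HIS protonation variants (CHARMM / Martini naming)
        "HSD", "HSE", "HSP", "HID", "HIE", "HIP",
    }
)

#: Residue names that indicate un-stripped solvent in strict mode.
SOLVENT_RESNAMES = frozenset({"W", "WF", "NA+", "CL-", "ION", "SOL", "TIP3"})

CATEGORY_PROTEIN = "protein"
CATEGORY_LIPID = "lipid"
CATEGORY_UNKNOWN = "unknown"


def classify_residues(names, db: LipidDatabase | None = None, strict: bool = True) -> list[str]:
    """Map residue names to {protein, lipid, unknown}.

    In strict mode, water/ion names raise SolventError naming the offender.
    """
    if db is None:
        db = default_database()
    if len(names) == 0:
        raise ParameterError("classify_residues requires a non-empty name list")
    categories = []
    for name in names:
        if name in PROTEIN_RESNAMES:
            categories.append(CATEGORY_PROTEIN)
        elif name in db:
            categories.append(CATEGORY_LIPID)
        elif strict and name in SOLVENT_RESNAMES:
            raise SolventError(
                f"residue {name!r} looks like water/ions; input must contain only "
                "protein and lipid particles (strip solvent before analysis)"
            )
        else:
            categories.append(CATEGORY_UNKNOWN)
    return categories


@dataclass
class ResidueRecord:
    index: int
    name: str
    resid: int  # original (file) residue number, user-facing
    particle_indices: np.ndarray
    category: str


LEAFLET_UPPER = "upper"
LEAFLET_LOWER = "lower"


def assign_leaflets(coordinates: np.ndarray, headgroup_indices: list[np.ndarray]) -> np.ndarray:
    """Assign each lipid molecule to the upper or lower leaflet of a planar bilayer.

    The midplane is the global mean headgroup z over all molecules in the
    frame; molecules at or above it go to the upper leaflet (ties go upper).
    Assumes a single bilayer with its normal along z.
    """
    if len(headgroup_indices) < 2:
        raise ParameterError(
            f"leaflet assignment needs >=2 lipid molecules, got {len(headgroup_indices)}"
        )
    z = np.array([coordinates[idx, 2].mean() for idx in headgroup_indices])
    midplane = z.mean()
    return np.where(z >= midplane, LEAFLET_UPPER, LEAFLET_LOWER)


@dataclass
class AnalysisSystem:
    """A classified topology bound to a frame set.

    proteins: list of protein entities, each a list of residue indices
      (split on chain breaks / non-consecutive numbering).
    lipid_molecules: lipid type -> list of residue indices (one Martini lipid
      molecule is one residue).
    """

    topology: Topology
    frames: FrameSet
    residues: list[ResidueRecord]
    proteins: list[list[int]]
    lipid_molecules: dict[str, list[int]]
    database: LipidDatabase = field(default_factory=default_database)

    # -- convenience selections ---------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.frames.n_frames

    @property
    def protein_residue_indices(self) -> list[int]:
        return [r for chain in self.proteins for r in chain]

    @property
    def n_protein_residues(self) -> int:
        return sum(len(p) for p in self.proteins)

    @property
    def n_lipid_molecules(self) -> int:
        return sum(len(v) for v in self.lipid_molecules.values())

    @property
    def lipid_types(self) -> list[str]:
        return sorted(self.lipid_molecules)

    def protein_particle_indices(self) -> np.ndarray:
        idx = [self.residues[r].particle_indices for r in self.protein_residue_indices]
        return np.concatenate(idx) if idx else np.empty(0, dtype=np.intp)

    def lipid_particle_indices(self, lipid_type: str, beads: str = "all") -> list[np.ndarray]:
        """Per-molecule particle indices for a lipid type.

        beads: "all" or "headgroup" (headgroup beads from the database).
        """
        out = []
        head = set(self.database.headgroup_beads(lipid_type)) if beads == "headgroup" else None
        for r in self.lipid_molecules[lipid_type]:
            idx = self.residues[r].particle_indices
            if head is not None:
                keep = [a for a in idx if self.topology.atom_names[a] in head]
                idx = np.asarray(keep, dtype=np.intp)
            out.append(idx)
        return out

    def headgroup_indices(self, lipid_types=None) -> list[np.ndarray]:
        """Headgroup bead indices per lipid molecule (for leaflets/surfaces)."""
        types = self.lipid_types if lipid_types is None else list(lipid_types)
        out = []
        for t in types:
            for idx in self.lipid_particle_indices(t, beads="headgroup"):
                if idx.size == 0:  # fall back to all beads if names don't match
                    idx = self.residues[self.lipid_molecules[t][0]].particle_indices
                out.append(idx)
        return out

    def leaflets(self, frame: int, lipid_types=None) -> np.ndarray:
        return assign_leaflets(self.frames.coordinates[frame], self.headgroup_indices(lipid_types))


def build_system(
    topology: Topology,
    frames: FrameSet,
    db: LipidDatabase | None = None,
    strict: bool = True,
) -> AnalysisSystem:
    """Classify a topology and bind it to its frames."""
    if db is None:
        db = default_database()
    if frames.n_atoms != topology.n_atoms:
        raise SystemError_(
            f"particle count mismatch: frames have {frames.n_atoms} particles, "
            f"topology has {topology.n_atoms}"
        )
    categories = classify_residues(topology.residue_names, db, strict=strict)
    residues = [
        ResidueRecord(
            index=r,
            name=topology.residue_names[r],
            resid=int(topology.residue_resids[r]),
            particle_indices=topology.residue_atom_indices[r],
            category=categories[r],
        )
        for r in range(topology.n_residues)
    ]

    proteins: list[list[int]] = []
    current: list[int] = []
    prev_key = None
    for r, rec in enumerate(residues):
        if rec.category != CATEGORY_PROTEIN:
            if current:
                proteins.append(current)
                current = []
            prev_key = None
            continue
        key = (topology.residue_chains[r], rec.resid)
        if current and not (
            key[0] == prev_key[0] and key[1] == prev_key[1] + 1
        ):
            proteins.append(current)
            current = []
        current.append(r)
        prev_key = key
    if current:
        proteins.append(current)

    lipid_molecules: dict[str, list[int]] = {}
    for r, rec in enumerate(residues):
        if rec.category == CATEGORY_LIPID:
            lipid_molecules.setdefault(rec.name, []).append(r)

    if not proteins:
        raise SystemError_("zero protein residues in input")
    if not lipid_molecules:
        raise SystemError_("zero lipid residues in input")
    return AnalysisSystem(
        topology=topology,
        frames=frames,
        residues=residues,
        proteins=proteins,
        lipid_molecules=lipid_molecules,
        database=db,
    )
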