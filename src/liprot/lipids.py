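"""Lipid residue database.

Maps lipid residue names (Martini coarse-grained naming by default) to their
headgroup bead names and a coarse class tag. The headgroup beads define the
leaflet surfaces and the default "headgroup" bead selection in contact and
density analyses. Users can extend the database from a YAML file without
touching code::

    DOPS:
      headgroup: [PO4]
      class: phospholipid

A bare list is accepted as shorthand for the headgroup entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass(frozen=True)
class LipidEntry:
    name: str
    headgroup_beads: tuple[str, ...]
    class_tag: str = "lipid"

    def __post_init__(self) -> None:
        if not self.headgroup_beads:
            raise ParameterError(f"lipid {self.name!r} needs >=1 headgroup bead")


#: Martini defaults. Phospholipid headgroups sit on the PO4 phosphate bead,
#: cholesterol on the ROH hydroxyl bead, and PIP-like lipids expose their
#: phosphate beads in addition to PO4.
_MARTINI_DEFAULTS: dict[str, tuple[tuple[str, ...], str]] = {
    "POPC": (("PO4",), "phospholipid"),
    "DOPC": (("PO4",), "phospholipid"),
    "DPPC": (("PO4",), "phospholipid"),
    "DLPC": (("PO4",), "phospholipid"),
    "POPE": (("PO4",), "phospholipid"),
    "DOPE": (("PO4",), "phospholipid"),
    "POPS": (("PO4",), "phospholipid"),
    "DOPS": (("PO4",), "phospholipid"),
    "POPG": (("PO4",), "phospholipid"),
    "POPA": (("PO4",), "phospholipid"),
    "DPSM": (("PO4",), "sphingolipid"),
    "CHOL": (("ROH",), "sterol"),
    "POP2": (("PO4", "P1", "P2"), "phosphoinositide"),
    "POP1": (("PO4", "P1"), "phosphoinositide"),
    "POP3": (("PO4", "P1", "P2", "P3"), "phosphoinositide"),
    "PIP2": (("PO4", "P1", "P2"), "phosphoinositide"),
}


@dataclass
class LipidDatabase:
    """Registry of recognized lipid residue names."""

    entries: dict[str, LipidEntry] = field(default_factory=dict)

    @classmethod
    def martini(cls) -> "LipidDatabase":
        """Database pre-populated with common Martini lipid names."""
        return cls(
            {
                name: LipidEntry(name, beads, tag)
                for name, (beads, tag) in _MARTINI_DEFAULTS.items()
            }
        )

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> LipidEntry:
        return self.entries[name]

    def names(self) -> list[str]:
        return sorted(self.entries)

    def add(self, name: str, headgroup_beads, class_tag: str = "lipid") -> None:
        self.entries[name] = LipidEntry(name, tuple(headgroup_beads), class_tag)

    def headgroup_beads(self, name: str) -> tuple[str, ...]:
        return self.entries[name].headgroup_beads

    def update_from_yaml(self, path) -> None:
        """Merge user lipid definitions from a YAML mapping file."""
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ParameterError(f"lipid config {path} must be a YAML mapping")
        for name, value in data.items():
            if isinstance(value, dict):
                beads = value.get("headgroup", [])
                tag = value.get("class", "lipid")
            else:
                beads, tag = value, "lipid"
            if isinstance(beads, str):
                beads = [beads]
            self.add(str(name), [str(b) for b in beads], str(tag))


def default_database() -> LipidDatabase:
    return LipidDatabase.martini()
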