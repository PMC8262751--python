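"""Per-residue, per-lipid-type interaction metrics and network aggregation.

From a ContactSeries this module computes, for each protein residue and
lipid type:

* occupancy — fraction of frames with at least one molecule in contact,
* mean_count / sum_count — distinct molecules in contact per frame,
* duration statistics — maximal runs of consecutive in-contact frames are
  events; a k-frame run lasts k*dt. Events truncated by the trajectory end
  still count (no censoring correction).

It also aggregates metrics into a lipid-type <-> residue-class network whose
node sizes are composition fractions and edge widths the average of a chosen
metric, for network-graph visualization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contacts import ContactSeries
from .errors import ParameterError
from .system import AnalysisSystem

PS_PER_NS = 1000.0

#: Residue classes by physicochemical character (configurable via YAML).
DEFAULT_RESIDUE_CLASSES: dict[str, str] = {}
for _cls, _names in {
    "hydrophobic": ["ALA", "VAL", "LEU", "ILE", "MET", "PRO", "GLY", "CYS"],
    "aromatic": ["PHE", "TRP", "TYR"],
    "polar": ["SER", "THR", "ASN", "GLN", "HIS", "HSD", "HSE", "HSP"],
    "positive": ["ARG", "LYS"],
    "negative": ["ASP", "GLU"],
}.items():
    for _n in _names:
        DEFAULT_RESIDUE_CLASSES[_n] = _cls


def load_residue_classes(path) -> dict[str, str]:
    """Read a YAML mapping class -> [residue names] into residue -> class."""
    data = yaml.safe_load(Path(path).read_text())
    mapping: dict[str, str] = {}
    for cls, names in data.items():
        for n in names:
            mapping[str(n)] = str(cls)
    return mapping


def occupancy(presence) -> float:
    """Fraction of frames with >=1 molecule in contact.

    ``presence`` is a binary matrix (n_frames, n_molecules) or a 1D series.
    """
    presence = np.asarray(presence, dtype=bool)
    if presence.ndim == 1:
        presence = presence[:, None]
    if presence.shape[0] < 1:
        raise ParameterError("occupancy needs at least one frame")
    return float(presence.any(axis=1).mean())


@dataclass
class DurationStats:
    events_ns: np.ndarray
    longest_ns: float
    mean_ns: float
    n_events: int


def contact_durations(presence, dt_ps: float) -> DurationStats:
    """Run-length duration statistics for one molecule's binary series."""
    if dt_ps <= 0:
        raise ParameterError(f"dt must be positive, got {dt_ps}")
    x = np.asarray(presence, dtype=bool).astype(np.int8)
    if x.size == 0 or not x.any():
        return DurationStats(np.empty(0), 0.0, 0.0, 0)
    padded = np.concatenate([[0], x, [0]])
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    runs = ends - starts
    events_ns = runs * dt_ps / PS_PER_NS
    return DurationStats(events_ns, float(events_ns.max()), float(events_ns.mean()), len(runs))


METRIC_COLUMNS = [
    "occupancy",
    "mean_count",
    "sum_count",
    "longest_duration_ns",
    "mean_duration_ns",
    "n_events",
]


def build_metrics_table(
    series: ContactSeries, system: AnalysisSystem, include_empty: bool = True
) -> pd.DataFrame:
    """One row per (protein, residue, lipid type) with the contact metrics.

    Durations aggregate over molecules: longest is the max over molecules,
    mean is over all events of all molecules of the type.
    """
    res_protein = {}
    for p, chain in enumerate(system.proteins):
        for r in chain:
            res_protein[r] = p
    dt = series.dt_ps
    rows = []
    for t in series.lipid_types:
        pres = series.presence[t]  # (n_res, n_mol, n_frames)
        counts = pres.sum(axis=1)
        any_pres = pres.any(axis=1)
        for pos, r in enumerate(series.residue_indices):
            occ = float(any_pres[pos].mean())
            if occ == 0.0 and not include_empty:
                continue
            events = []
            longest = 0.0
            for m in range(pres.shape[1]):
                st = contact_durations(pres[pos, m], dt)
                if st.n_events:
                    events.append(st.events_ns)
                    longest = max(longest, st.longest_ns)
            all_events = np.concatenate(events) if events else np.empty(0)
            rec = system.residues[r]
            rows.append(
                {
                    "protein": res_protein.get(int(r), 0),
                    "residue_id": rec.resid,
                    "residue_name": rec.name,
                    "lipid_type": t,
                    "occupancy": occ,
                    "mean_count": float(counts[pos].mean()),
                    "sum_count": int(counts[pos].sum()),
                    "longest_duration_ns": longest,
                    "mean_duration_ns": float(all_events.mean()) if all_events.size else 0.0,
                    "n_events": int(all_events.size),
                }
            )
    cols = ["protein", "residue_id", "residue_name", "lipid_type"] + METRIC_COLUMNS
    return pd.DataFrame(rows, columns=cols)


def build_network(
    table: pd.DataFrame,
    system: AnalysisSystem,
    metric: str = "mean_count",
    class_map: dict[str, str] | None = None,
    expand_class: str | None = None,
) -> dict:
    """Lipid-type <-> residue-class interaction network payload.

    Lipid node size is the type's fraction of all lipid molecules; class node
    size is the class's fraction of protein residues. Collapsed edge width is
    the mean of ``metric`` over all residues of the class (per lipid type);
    with ``expand_class`` the residues of that class appear individually.
    """
    if metric not in METRIC_COLUMNS:
        raise ParameterError(f"unknown metric {metric!r}; choose from {METRIC_COLUMNS}")
    if class_map is None:
        class_map = DEFAULT_RESIDUE_CLASSES
    n_lipids = system.n_lipid_molecules
    nodes = [
        {"id": t, "group": "lipid", "size": len(system.lipid_molecules[t]) / n_lipids}
        for t in system.lipid_types
    ]

    res_class = {}
    for r in system.protein_residue_indices:
        res_class[r] = class_map.get(system.residues[r].name, "other")
    n_prot = len(res_class)
    class_counts: dict[str, int] = {}
    for c in res_class.values():
        class_counts[c] = class_counts.get(c, 0) + 1
    nodes += [
        {"id": c, "group": "residue_class", "size": class_counts[c] / n_prot}
        for c in sorted(class_counts)
    ]

    tbl = table.copy()
    tbl["_class"] = [class_map.get(n, "other") for n in tbl["residue_name"]]
    links = []
    for t in system.lipid_types:
        sub = tbl[tbl["lipid_type"] == t]
        by_class = sub.groupby("_class")[metric].mean()
        for c in sorted(class_counts):
            width = float(by_class.get(c, 0.0))
            links.append({"source": t, "target": c, "width": width})

    if expand_class is not None:
        sub = tbl[tbl["_class"] == expand_class]
        for _, row in sub.iterrows():
            rid = f"{row['residue_name']}{row['residue_id']}"
            node = {"id": rid, "group": "residue", "size": 1.0 / n_prot}
            if node not in nodes:
                nodes.append(node)
            links.append(
                {"source": row["lipid_type"], "target": rid, "width": float(row[metric])}
            )

    return {"schema_version": 1, "metric": metric, "nodes": nodes, "links": links}


def to_networkx(payload: dict):
    """Network payload as a networkx.Graph (node attrs: group/size; edge: width)."""
    import networkx as nx

    g = nx.Graph(metric=payload.get("metric"))
    for node in payload["nodes"]:
        g.add_node(node["id"], group=node["group"], size=node["size"])
    for edge in payload["links"]:
        g.add_edge(edge["source"], edge["target"], width=edge["width"])
    return g
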