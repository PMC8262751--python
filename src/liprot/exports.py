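"""Serialization of analysis results for visualization.

Three payloads: a structure heatmap (per-residue metric written into PDB
B-factors so viewers can color the protein surface), a lipid-residue
network graph (JSON nodes/links), and an aligned multi-protein sequence
heatmap (metric values scattered onto alignment columns, gaps masked).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ParameterError
from .io import write_bfactor_pdb
from .system import AnalysisSystem


def export_structure_heatmap(
    table: pd.DataFrame,
    system: AnalysisSystem,
    lipid_type: str,
    metric: str,
    out_prefix,
    frame: int = 0,
    scaling: str = "none",
) -> np.ndarray:
    """Write <prefix>.pdb (B-factor = metric) and <prefix>.csv for one lipid type.

    Returns the per-residue values in protein residue order.
    """
    sub = table[table["lipid_type"] == lipid_type]
    if metric not in table.columns:
        raise ParameterError(f"metric {metric!r} not in table columns")
    value_by_resid = dict(zip(sub["residue_id"], sub[metric]))
    res_idx = system.protein_residue_indices
    missing = [system.residues[r].resid for r in res_idx if system.residues[r].resid not in value_by_resid]
    if missing:
        raise ParameterError(
            f"metrics table is missing residues {missing} for lipid type {lipid_type!r}"
        )
    values = np.array([value_by_resid[system.residues[r].resid] for r in res_idx], dtype=float)

    prefix = Path(out_prefix)
    write_bfactor_pdb(
        system.topology,
        system.frames.coordinates[frame],
        system.frames.box[frame],
        values,
        str(prefix) + ".pdb",
        residue_indices=np.asarray(res_idx, dtype=np.intp),
        scaling=scaling,
    )
    pd.DataFrame(
        {
            "residue_id": [system.residues[r].resid for r in res_idx],
            "residue_name": [system.residues[r].name for r in res_idx],
            metric: values,
        }
    ).to_csv(str(prefix) + ".csv", index=False)
    return values


@dataclass
class SequenceHeatmap:
    """Per-protein metric values placed on alignment columns (1-based)."""

    proteins: list[str]
    n_columns: int
    values: np.ndarray  # (n_proteins, n_columns); NaN at gaps
    mask: np.ndarray  # True where the cell is an alignment gap

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.proteins, columns=np.arange(1, self.n_columns + 1)
        )

    def to_json(self) -> dict:
        return {
            "schema_version": 1,
            "proteins": self.proteins,
            "n_columns": self.n_columns,
            "values": [
                [None if m else float(v) for v, m in zip(row, mrow)]
                for row, mrow in zip(self.values, self.mask)
            ],
        }


def read_alignment(path) -> dict[str, str]:
    """Aligned FASTA -> ordered {name: aligned sequence}."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq)
    if not records:
        raise ParameterError(f"no sequences found in alignment {path}")
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        raise ParameterError("alignment sequences have differing lengths")
    return records


def export_sequence_heatmap(
    tables: dict[str, pd.DataFrame],
    alignment: dict[str, str],
    lipid_type: str,
    metric: str,
) -> SequenceHeatmap:
    """Scatter each protein's per-residue metric onto its alignment columns.

    ``tables`` maps protein name -> metrics table; residue order in each
    table (for the chosen lipid type) must match the ungapped sequence.
    """
    proteins = list(alignment)
    n_cols = len(next(iter(alignment.values())))
    values = np.full((len(proteins), n_cols), np.nan)
    mask = np.ones((len(proteins), n_cols), dtype=bool)
    for i, name in enumerate(proteins):
        if name not in tables:
            raise ParameterError(f"no metrics table given for protein {name!r}")
        sub = tables[name][tables[name]["lipid_type"] == lipid_type]
        vals = sub[metric].to_numpy(dtype=float)
        seq = alignment[name]
        ungapped = sum(1 for c in seq if c != "-")
        if ungapped != len(vals):
            raise ParameterError(
                f"protein {name!r}: alignment has {ungapped} residues but the "
                f"metrics table has {len(vals)}"
            )
        k = 0
        for col, c in enumerate(seq):
            if c != "-":
                values[i, col] = vals[k]
                mask[i, col] = False
                k += 1
    return SequenceHeatmap(proteins=proteins, n_columns=n_cols, values=values, mask=mask)


def export_network_json(payload: dict, path) -> None:
    """Write a nodes/links network payload with stable key order.

    Node sizes are renormalized per group to sum to exactly 1 on write.
    """
    payload = json.loads(json.dumps(payload))  # deep copy, plain types
    for group in ("lipid", "residue_class"):
        nodes = [n for n in payload.get("nodes", []) if n.get("group") == group]
        total = sum(n["size"] for n in nodes)
        if total > 0:
            for n in nodes:
                n["size"] = n["size"] / total
    ordered = {
        "schema_version": payload.get("schema_version", 1),
        "metric": payload.get("metric"),
        "nodes": [
            {"id": n["id"], "group": n["group"], "size": n["size"]}
            for n in payload.get("nodes", [])
        ],
        "links": [
            {"source": e["source"], "target": e["target"], "width": e["width"]}
            for e in payload.get("links", [])
        ],
    }
    Path(path).write_text(json.dumps(ordered, indent=2) + "\n")


def load_network_json(path) -> dict:
    return json.loads(Path(path).read_text())
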