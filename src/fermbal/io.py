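"""Readers and writers for the plain-text interchange formats.

Traces are CSV ``time_h,current_A`` (or ``time_h,voltage_V``); metabolite
panels are long CSV ``species,value,unit``; reactor specs are YAML or JSON;
OTU tables are TSV with taxa as rows and samples as columns (first column the
taxon id); taxonomy is two-column TSV; trees are newick.  Reports go out as
JSON with input hashes for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .stoich import MetabolitePanel, ReactorSpec

__all__ = [
    "read_trace",
    "write_trace",
    "read_panel",
    "write_panel",
    "read_reactor_spec",
    "write_reactor_spec",
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "write_tree",
    "write_report",
    "sha256_of",
]

_PANEL_UNITS = {
    "ethanol": "umol/L",
    "acetate": "umol/L",
    "hydrogen": "umol",
    "biomass": "umol/L",
    "substrate_consumed_fraction": "fraction",
    "substrate_final": "g/L",
}


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_trace(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (time, signal)")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def write_trace(
    path: str | Path,
    time_h: np.ndarray,
    signal: np.ndarray,
    signal_name: str = "current_A",
) -> None:
    pd.DataFrame({"time_h": time_h, signal_name: signal}).to_csv(path, index=False)


def read_panel(path: str | Path) -> MetabolitePanel:
    df = pd.read_csv(path)
    expected = {"species", "value", "unit"}
    if set(df.columns) != expected:
        raise ValueError(f"{path}: panel CSV needs columns {sorted(expected)}")
    kwargs: dict[str, float] = {}
    for _, row in df.iterrows():
        species = str(row["species"])
        if species not in _PANEL_UNITS:
            raise ValueError(f"{path}: unknown panel species {species!r}")
        if str(row["unit"]) != _PANEL_UNITS[species]:
            raise ValueError(
                f"{path}: {species} must be in {_PANEL_UNITS[species]}, "
                f"got {row['unit']!r}"
            )
        kwargs[species] = float(row["value"])
    return MetabolitePanel(**kwargs)


def write_panel(path: str | Path, panel: MetabolitePanel) -> None:
    rows = []
    for species, unit in _PANEL_UNITS.items():
        value = getattr(panel, species)
        if value is not None:
            rows.append({"species": species, "value": value, "unit": unit})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_reactor_spec(path: str | Path) -> ReactorSpec:
    path = Path(path)
    payload = (
        json.loads(path.read_text())
        if path.suffix == ".json"
        else yaml.safe_load(path.read_text())
    )
    return ReactorSpec(**payload)


def write_reactor_spec(path: str | Path, spec: ReactorSpec) -> None:
    path = Path(path)
    payload = {
        "reactor_id": spec.reactor_id,
        "applied_potential": spec.applied_potential,
        "liquid_volume": spec.liquid_volume,
        "initial_substrate": spec.initial_substrate,
        "duration": spec.duration,
        "substrate_molar_mass": spec.substrate_molar_mass,
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def read_otu_table(path: str | Path) -> pd.DataFrame:
    """TSV with taxa as rows, samples as columns -> samples x taxa DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.T.astype(np.int64)


def write_otu_table(path: str | Path, table: pd.DataFrame) -> None:
    table.T.rename_axis("taxon").to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["taxon", "family"])
    return dict(zip(df["taxon"], df["family"]))


def write_taxonomy(path: str | Path, taxonomy: Mapping[str, str]) -> None:
    pd.DataFrame(sorted(taxonomy.items())).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_tree(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_tree(path: str | Path, tree: TreeNode) -> None:
    tree.write(str(path), format="newick")


def write_report(path: str | Path, payload: Mapping, **input_paths: str | Path) -> None:
    """Write a JSON report with a provenance block of input hashes."""
    provenance = {name: sha256_of(p) for name, p in input_paths.items()}
    doc = dict(payload)
    if provenance:
        doc["provenance"] = provenance
    Path(path).write_text(json.dumps(doc, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
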