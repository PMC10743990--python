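"""Configuration, file formats, and run logging for the pipeline.

Formats: activity tables as CSV with declared columns and units; screening
libraries as .smi (one ``SMILES id`` pair per line) or SDF; run
configuration as YAML; model bundles via joblib with a manifest.  All
randomness in a run flows from a single top-level seed fanned out per
stage.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import joblib
import pandas as pd
import yaml
from rdkit import Chem

from .curation import (
    ActivityRecord,
    AuditEntry,
    CurationError,
    LabeledDataset,
    StandardizedCompound,
    standardize,
)

UNIT_TO_UM = {"um": 1.0, "µm": 1.0, "uM": 1.0, "nm": 1e-3, "mm": 1e3, "m": 1e6}


class IOError_(ValueError):
    pass


@dataclass
class RunConfig:
    """Pipeline settings; defaults reproduce the protocol's constants."""

    train_table: str = ""
    test_table: str = ""
    library: str = ""
    output_dir: str = "results"
    representations: list[str] = field(default_factory=lambda: ["morgan"])
    algorithms: list[str] = field(default_factory=lambda: ["RF", "SVM", "KNN", "MLP"])
    active_threshold_um: float = 0.1
    inactive_threshold_um: float = 0.5
    cs_cutoff: float = 0.8
    novelty_max_sim: float = 0.40
    cluster_sim_cutoff: float = 0.70
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.active_threshold_um < self.inactive_threshold_um:
            raise IOError_("label thresholds must satisfy 0 < active < inactive")
        if not 0.5 <= self.cs_cutoff <= 1:
            raise IOError_("cs_cutoff must lie in [0.5, 1]")
        if not 0 < self.novelty_max_sim <= 1:
            raise IOError_("novelty_max_sim must lie in (0, 1]")
        if not 0 < self.cluster_sim_cutoff <= 1:
            raise IOError_("cluster_sim_cutoff must lie in (0, 1]")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed derived from the top seed."""
        h = 0
        for ch in stage:
            h = (h * 131 + ord(ch)) % (2**31 - 1)
        return (self.seed * 9973 + h) % (2**31 - 1)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _to_um(value: float, units: str) -> float:
    key = str(units).strip().lower().replace("μ", "u")
    if key not in {k.lower() for k in UNIT_TO_UM}:
        raise IOError_(f"undeclared potency units {units!r}")
    factor = {k.lower(): v for k, v in UNIT_TO_UM.items()}[key]
    return value * factor


def read_activity_csv(path: str) -> list[ActivityRecord]:
    """Read an activity table CSV with columns
    (compound_id, smiles, value, units, type, relation)."""
    df = pd.read_csv(path)
    required = {"compound_id", "smiles", "value", "units", "type"}
    missing = required - set(df.columns)
    if missing:
        raise IOError_(f"activity table {path} lacks columns {sorted(missing)}")
    if "relation" not in df.columns:
        df["relation"] = "="
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ActivityRecord(
                compound_id=str(row.compound_id),
                smiles=str(row.smiles),
                potency_value=_to_um(float(row.value), row.units),
                potency_type=str(row.type),
                relation=str(row.relation),
            )
        )
    return records


def read_activity_sdf(path: str) -> list[ActivityRecord]:
    """Read an activity table from an SDF with equivalent properties."""
    records = []
    for mol in Chem.SDMolSupplier(path):
        if mol is None:
            continue
        props = mol.GetPropsAsDict()
        records.append(
            ActivityRecord(
                compound_id=str(props.get("compound_id", mol.GetProp("_Name"))),
                smiles=Chem.MolToSmiles(mol),
                potency_value=_to_um(
                    float(props["value"]), props.get("units", "uM")
                ),
                potency_type=str(props.get("type", "IC50")),
                relation=str(props.get("relation", "=")),
            )
        )
    return records


def read_smiles_file(path: str) -> list[tuple[str, str]]:
    """Read a .smi file: one record per line, SMILES then id, whitespace
    separated.  Missing ids are synthesized from line numbers."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"line{i + 1}"
            out.append((cid, smiles))
    return out


def standardize_library(
    entries: list[tuple[str, str]]
) -> tuple[list[StandardizedCompound], list[AuditEntry]]:
    """Standardize a raw library; rejections go to an audit list."""
    compounds, audit = [], []
    for cid, smiles in entries:
        try:
            compounds.append(standardize(smiles, cid))
        except CurationError as exc:
            audit.append(AuditEntry(cid, smiles, str(exc)))
    return compounds, audit


def write_dataset_csv(dataset: LabeledDataset, path: str) -> None:
    pd.DataFrame(
        {
            "compound_id": dataset.ids,
            "smiles": dataset.smiles,
            "structure_key": [c.compound.structure_key for c in dataset.compounds],
            "potency_um": [c.potency_um for c in dataset.compounds],
            "pIC50": [c.pic50 for c in dataset.compounds],
            "label": dataset.labels,
        }
    ).to_csv(path, index=False)


def read_dataset_csv(path: str, role: str) -> LabeledDataset:
    from .curation import LabeledCompound

    df = pd.read_csv(path)
    compounds = [
        LabeledCompound(
            compound=StandardizedCompound(
                compound_id=str(r.compound_id),
                smiles_std=str(r.smiles),
                structure_key=str(r.structure_key),
            ),
            label=str(r.label),
            potency_um=float(r.potency_um),
            pic50=float(r.pIC50),
        )
        for r in df.itertuples(index=False)
    ]
    return LabeledDataset(role=role, compounds=compounds)


def write_audit_log(audit: list[AuditEntry], path: str) -> None:
    with open(path, "w") as fh:
        for entry in audit:
            fh.write(entry.line() + "\n")


def write_hits_csv(hits, path: str) -> None:
    rows = []
    for h in hits:
        rows.append(
            {
                "compound_id": h.compound.compound_id,
                "smiles": h.compound.smiles_std,
                "cs": h.cs,
                "member_ps": ";".join(f"{p:.6f}" for p in h.member_ps),
                "max_train_similarity": h.max_train_similarity,
                "cluster_id": h.cluster_id,
                "is_cluster_representative": h.is_cluster_representative,
                "pains_alerts": ";".join(h.pains_alerts),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_funnel_json(counts: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(counts, fh, indent=2)


def save_model(model, path: str) -> None:
    """Persist a trained classifier (or consensus) with its manifest."""
    joblib.dump(model, path)


def load_model(path: str):
    return joblib.load(path)


def write_run_log(path: str, stages: dict) -> None:
    """Structured run log: seeds, checksums, per-stage record counts."""
    with open(path, "w") as fh:
        json.dump(stages, fh, indent=2, default=str)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
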