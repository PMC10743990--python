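"""Curation of raw bioactivity tables into binary-labeled datasets.

Raw activity records (one row per measurement) are standardized, deduplicated
by canonical structure, aggregated per compound with a 25% outlier rule, and
labeled active/inactive by potency thresholds:

* active:   potency <= 0.1 uM  (pIC50 >= 7)
* inactive: potency >= 0.5 uM  (pIC50 <= 6.3)
* compounds strictly between the thresholds are excluded.

Every dropped input record lands in an audit log with a reason, so that
``n_input == n_used + n_dropped`` holds for every run.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

ACTIVE_THRESHOLD_UM = 0.1
INACTIVE_THRESHOLD_UM = 0.5
OUTLIER_REL_TOL = 0.25

POTENCY_TYPES = ("IC50", "Ki")

ACTIVE = "active"
INACTIVE = "inactive"
EXCLUDED = "excluded"

RDLogger.DisableLog("rdApp.*")


class CurationError(ValueError):
    """Raised for contract violations in the curation pipeline."""


class StandardizationError(CurationError):
    """A single SMILES could not be standardized. Carries the offending input."""

    def __init__(self, smiles: str, reason: str):
        self.smiles = smiles
        self.reason = reason
        super().__init__(f"cannot standardize {smiles!r}: {reason}")


@dataclass(frozen=True)
class ActivityRecord:
    """One raw potency measurement for one compound."""

    compound_id: str
    smiles: str
    potency_value: float  # uM
    potency_type: str  # IC50 | Ki
    relation: str = "="

    def __post_init__(self):
        if not (self.potency_value > 0):
            raise CurationError(
                f"potency_value must be positive, got {self.potency_value}"
            )
        if self.potency_type not in POTENCY_TYPES:
            raise CurationError(
                f"potency_type must be one of {POTENCY_TYPES}, got {self.potency_type!r}"
            )


@dataclass(frozen=True)
class StandardizedCompound:
    compound_id: str
    smiles_std: str
    structure_key: str


@dataclass(frozen=True)
class CuratedCompound:
    compound: StandardizedCompound
    potency_um: float
    n_used: int
    n_raw: int


@dataclass(frozen=True)
class LabeledCompound:
    compound: StandardizedCompound
    label: str  # active | inactive
    potency_um: float
    pic50: float


@dataclass
class LabeledDataset:
    """Curated, deduplicated, binary-labeled compound set."""

    role: str  # train | test
    compounds: list[LabeledCompound] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.compounds)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.compounds]

    @property
    def smiles(self) -> list[str]:
        return [c.compound.smiles_std for c in self.compounds]

    @property
    def ids(self) -> list[str]:
        return [c.compound.compound_id for c in self.compounds]

    def n_active(self) -> int:
        return sum(1 for c in self.compounds if c.label == ACTIVE)

    def n_inactive(self) -> int:
        return sum(1 for c in self.compounds if c.label == INACTIVE)


@dataclass(frozen=True)
class AuditEntry:
    compound_id: str
    smiles: str
    reason: str

    def line(self) -> str:
        return f"{self.compound_id}\t{self.smiles}\t{self.reason}"


_uncharger = rdMolStandardize.Uncharger()
_fragment_chooser = rdMolStandardize.LargestFragmentChooser()


def standardize(smiles: str, compound_id: str = "") -> StandardizedCompound:
    """Standardize a SMILES: keep the largest fragment, neutralize charges,
    and emit a canonical SMILES plus an InChIKey-based identity key.

    Raises :class:`StandardizationError` on unparseable or empty structures;
    batch callers catch it and record the rejection instead of aborting.
    """
    if not smiles or not smiles.strip():
        raise StandardizationError(smiles, "empty input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError(smiles, "unparseable SMILES")
    if mol.GetNumHeavyAtoms() == 0:
        raise StandardizationError(smiles, "no heavy atoms")
    mol = _fragment_chooser.choose(mol)
    mol = _uncharger.uncharge(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - defensive
        raise StandardizationError(smiles, f"sanitization failed: {exc}")
    smiles_std = Chem.MolToSmiles(mol)
    key = Chem.MolToInchiKey(mol)
    if not key:
        # InChI occasionally refuses exotica; canonical SMILES is still a
        # deterministic identity for deduplication.
        key = smiles_std
    return StandardizedCompound(
        compound_id=compound_id, smiles_std=smiles_std, structure_key=key
    )


def _survivors(values: Sequence[float]) -> list[float]:
    """Apply the 25% rule in a single pass against the initial mean."""
    m = sum(values) / len(values)
    return [v for v in values if abs(v - m) / m <= OUTLIER_REL_TOL]


def aggregate_potency(values: Sequence[float]) -> float | None:
    """Aggregate replicate potency measurements (uM) for one compound.

    n=1 -> the value; n=2 -> mean; n>=3 -> drop values deviating more than
    25% from the mean (single pass), return the mean of the survivors.
    Returns ``None`` (DISCARD) when no value survives.
    """
    if not values:
        raise CurationError("aggregate_potency requires a non-empty list")
    if any(v <= 0 for v in values):
        raise CurationError("potency values must be positive")
    if len(values) == 1:
        return values[0]
    if len(values) == 2:
        return (values[0] + values[1]) / 2.0
    surv = _survivors(values)
    if not surv:
        return None
    return sum(surv) / len(surv)


def assign_label(potency_um: float) -> str:
    """Threshold a potency (uM) into active / inactive / excluded."""
    if not (potency_um > 0):
        raise CurationError("potency must be positive")
    if potency_um <= ACTIVE_THRESHOLD_UM:
        return ACTIVE
    if potency_um >= INACTIVE_THRESHOLD_UM:
        return INACTIVE
    return EXCLUDED


def pic50(potency_um: float) -> float:
    """-log10 of a potency given in micromolar, expressed on the molar scale."""
    return -math.log10(potency_um * 1e-6)


def build_dataset(
    records: Iterable[ActivityRecord], role: str
) -> tuple[LabeledDataset, list[AuditEntry]]:
    """Run the full curation pipeline over raw records.

    standardize -> group by structure_key -> aggregate replicates with the
    25% rule -> label by thresholds -> drop excluded/discarded compounds.
    Returns the dataset plus a per-record audit log of everything dropped.
    Only ``relation == "="`` measurements are used; censored records are
    audited, not aggregated.
    """
    if role not in ("train", "test"):
        raise CurationError(f"role must be train or test, got {role!r}")
    records = list(records)
    types = {r.potency_type for r in records}
    if len(types) > 1:
        raise CurationError(f"mixed potency types in one table: {sorted(types)}")

    audit: list[AuditEntry] = []
    # structure_key -> (representative StandardizedCompound, list of (record, value))
    groups: dict[str, tuple[StandardizedCompound, list[ActivityRecord]]] = {}
    order: list[str] = []
    for rec in records:
        if rec.relation != "=":
            audit.append(
                AuditEntry(rec.compound_id, rec.smiles, f"censored relation {rec.relation!r}")
            )
            continue
        try:
            std = standardize(rec.smiles, rec.compound_id)
        except StandardizationError as exc:
            audit.append(AuditEntry(rec.compound_id, rec.smiles, exc.reason))
            continue
        if std.structure_key not in groups:
            groups[std.structure_key] = (std, [])
            order.append(std.structure_key)
        groups[std.structure_key][1].append(rec)

    compounds: list[LabeledCompound] = []
    n_used_total = 0
    for key in order:
        std, recs = groups[key]
        values = [r.potency_value for r in recs]
        if len(values) >= 3:
            m = sum(values) / len(values)
            kept = []
            for r in recs:
                if abs(r.potency_value - m) / m <= OUTLIER_REL_TOL:
                    kept.append(r)
                else:
                    audit.append(
                        AuditEntry(
                            r.compound_id,
                            r.smiles,
                            f"replicate outlier: {r.potency_value} vs mean {m:.6g} (>25%)",
                        )
                    )
            if not kept:
                continue  # every replicate already audited (DISCARD)
            value = sum(r.potency_value for r in kept) / len(kept)
            used = kept
        else:
            value = aggregate_potency(values)
            used = recs
        label = assign_label(value)
        if label == EXCLUDED:
            for r in used:
                audit.append(
                    AuditEntry(
                        r.compound_id,
                        r.smiles,
                        f"excluded band: aggregated potency {value:.6g} uM in (0.1, 0.5)",
                    )
                )
            continue
        curated = CuratedCompound(
            compound=std, potency_um=value, n_used=len(used), n_raw=len(recs)
        )
        n_used_total += curated.n_used
        compounds.append(
            LabeledCompound(compound=std, label=label, potency_um=value, pic50=pic50(value))
        )

    dataset = LabeledDataset(role=role, compounds=compounds)
    if not compounds:
        err = CurationError("curation produced an empty dataset")
        err.audit = audit  # type: ignore[attr-defined]
        raise err
    if n_used_total + len(audit) != len(records):  # pragma: no cover - defensive
        warnings.warn("curation audit does not reconcile with input count")
    return dataset, audit
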