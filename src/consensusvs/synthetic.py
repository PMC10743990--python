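"""Synthetic activity tables and screening libraries with planted ground
truth.

Actives are benzofuran-2-carboxamide analogs built by decorating a planted
scaffold with a fixed substituent vocabulary (small alkyl/alkoxy/amino
chains, halogens, amide linkers); decoys come from scaffold-free template
families (benzamides, indole/benzothiophene carboxamides, sulfonamides,
piperazines) that deliberately include near-miss bicyclic cores so
similarity filters are exercised nontrivially.  Potencies are drawn from
log-normal distributions truncated away from the excluded 0.1-0.5 uM band,
a configurable fraction of compounds receives three replicate measurements
including one >25% outlier, and every output is fully determined by the
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from rdkit import Chem

from .curation import ActivityRecord

PLANTED_SMARTS = "c1ccc2occc2c1"  # benzofuran core

ACTIVE_TEMPLATES = (
    "O=C(N{r})c1cc2ccccc2o1",
    "O=C(N{r})c1cc2cc({x})ccc2o1",
    "O=C(N{r})c1cc2ccc({x})cc2o1",
    "{r}Nc1cc2ccccc2o1",
)

DECOY_TEMPLATES = (
    "O=C(N{r})c1ccccc1",
    "O=C(N{r})c1ccncc1",
    "O=C(N{r})c1ccc({x})cc1",
    "O=C(N{r})c1cc2ccccc2[nH]1",
    "O=C(N{r})c1cc2ccccc2s1",
    "O=S(=O)(N{r})c1ccccc1",
    "{r}N1CCN(C)CC1",
    "{r}Oc1ccc({x})cc1",
)

# training decoration vocabulary
R_GROUPS = (
    "C", "CC", "CCC", "CCCC", "C(C)C", "CC(C)C", "CCO", "CCCO", "CCN",
    "CCCN", "CCOC", "CCSC", "Cc1ccccc1", "CCc1ccccc1", "C1CCCCC1",
    "CC1CCCCC1", "CCN(C)C", "CCOCC", "CCC(C)C", "CCCCC",
)
X_GROUPS = ("F", "Cl", "Br", "C", "CC", "OC", "N", "O")

# held-out vocabulary for screening-library analogs (disjoint from above)
R_GROUPS_LIBRARY = (
    "CC(C)(C)C", "CCCOC", "CCCCN", "CCCCO", "CCS", "CC(C)O", "CCCC(C)C",
    "C1CCCC1", "CC1CCCC1", "CCCN(C)C", "CCOC(C)C", "CCCSC",
)
X_GROUPS_LIBRARY = ("I", "CCC", "OCC", "C(C)C")

# scaffold embedded in remote frameworks: these keep the planted core but
# shed the carboxamide periphery, so they stay structurally novel
# (low whole-molecule similarity to training actives)
REMOTE_ANALOG_TEMPLATES = (
    "O=S(=O)(N1CCN(Cc2cc3ccccc3o2)CC1)c1ccc({x})cc1",
    "O=C(c1ccc({x})cc1)N1CCC(Cc2cc3ccccc3o2)CC1",
    "{x}c1ccc(-c2nc3ccccc3s2)cc1Cc1cc2ccccc2o1",
    "O=C(Nc1ccc({x})nc1)C1CCN(Cc2cc3ccccc3o2)CC1",
)


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study conditions for the generated activity tables.

    Potency medians respect the labeling thresholds (active median well
    below 0.1 uM, inactive median well above 0.5 uM) so that curation
    recovers the planted classes exactly.
    """

    n_actives: int = 200
    n_inactives: int = 200
    seed: int = 0
    planted_smarts: str = PLANTED_SMARTS
    active_potency: tuple[float, float] = (0.02, 0.6)  # median uM, sigma(ln)
    inactive_potency: tuple[float, float] = (5.0, 0.8)
    replicate_fraction: float = 0.1

    # truncation bounds keeping aggregated values clear of the excluded band
    active_max_um: float = 0.095
    inactive_min_um: float = 0.51

    def __post_init__(self):
        if self.n_actives < 1 or self.n_inactives < 1:
            raise SyntheticError("n_actives and n_inactives must be >= 1")
        if not (self.active_potency[0] <= 0.1 and self.inactive_potency[0] >= 0.5):
            raise SyntheticError(
                "potency medians must respect the labeling thresholds"
            )
        if Chem.MolFromSmarts(self.planted_smarts) is None:
            raise SyntheticError(f"invalid planted SMARTS {self.planted_smarts!r}")


def _enumerate(templates, r_groups, x_groups) -> list[str]:
    """All template instantiations, canonicalized, deduplicated, in
    deterministic order."""
    seen, out = set(), []
    for tmpl in templates:
        if "{x}" in tmpl:
            fills = product(r_groups, x_groups)
        else:
            fills = ((r, None) for r in r_groups)
        for r, x in fills:
            smi = tmpl.format(r=r, x=x) if x is not None else tmpl.format(r=r)
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            canonical = Chem.MolToSmiles(mol)
            if canonical not in seen:
                seen.add(canonical)
                out.append(canonical)
    return out


def _pick_compounds(config: SyntheticConfig, rng: np.random.Generator):
    patt = Chem.MolFromSmarts(config.planted_smarts)
    actives = [
        s
        for s in _enumerate(ACTIVE_TEMPLATES, R_GROUPS, X_GROUPS)
        if Chem.MolFromSmiles(s).HasSubstructMatch(patt)
    ]
    decoys = [
        s
        for s in _enumerate(DECOY_TEMPLATES, R_GROUPS, X_GROUPS)
        if not Chem.MolFromSmiles(s).HasSubstructMatch(patt)
    ]
    if len(actives) < config.n_actives:
        raise SyntheticError(
            f"vocabulary supports at most {len(actives)} distinct actives"
        )
    if len(decoys) < config.n_inactives:
        raise SyntheticError(
            f"vocabulary supports at most {len(decoys)} distinct decoys"
        )
    a_idx = rng.choice(len(actives), size=config.n_actives, replace=False)
    d_idx = rng.choice(len(decoys), size=config.n_inactives, replace=False)
    return [actives[i] for i in sorted(a_idx)], [decoys[i] for i in sorted(d_idx)]


def _sample_potency(
    rng: np.random.Generator, median: float, sigma: float, lo: float | None,
    hi: float | None,
) -> float:
    """Log-normal draw truncated to [lo, hi] by resampling."""
    for _ in range(10_000):
        v = float(rng.lognormal(mean=np.log(median), sigma=sigma))
        if (lo is None or v >= lo) and (hi is None or v <= hi):
            return v
    raise SyntheticError("truncated potency sampling failed")  # pragma: no cover


def generate_dataset(
    config: SyntheticConfig, potency_type: str = "IC50"
) -> tuple[list[ActivityRecord], pd.DataFrame]:
    """Activity records plus a ground-truth table.

    A ``replicate_fraction`` subset of compounds receives three replicate
    measurements whose injected outlier deviates >25% from the replicate
    mean, exercising the aggregation rule without moving the label.
    """
    rng = np.random.default_rng(config.seed)
    actives, decoys = _pick_compounds(config, rng)
    records: list[ActivityRecord] = []
    truth_rows = []
    for group, smiles_list in (("A", actives), ("D", decoys)):
        is_active = group == "A"
        median, sigma = (
            config.active_potency if is_active else config.inactive_potency
        )
        lo = None if is_active else config.inactive_min_um
        hi = config.active_max_um if is_active else None
        for i, smi in enumerate(smiles_list):
            cid = f"{group}{i:04d}"
            v = _sample_potency(rng, median, sigma, lo, hi)
            replicated = rng.random() < config.replicate_fraction
            values = [v, v * 1.02, v * 1.9] if replicated else [v]
            for val in values:
                records.append(
                    ActivityRecord(
                        compound_id=cid,
                        smiles=smi,
                        potency_value=float(val),
                        potency_type=potency_type,
                    )
                )
            truth_rows.append(
                {
                    "compound_id": cid,
                    "smiles": smi,
                    "is_active": is_active,
                    "true_potency_um": v,
                    "n_replicates": len(values),
                }
            )
    truth = pd.DataFrame(truth_rows)
    return records, truth


def generate_screening_library(
    config: SyntheticConfig, n_library: int = 500, hit_fraction: float = 0.2
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """A screening library of (id, SMILES) plus ground-truth membership.

    ``hit_fraction`` of the library are planted-scaffold analogs decorated
    with a held-out vocabulary (never identical to training compounds); the
    rest are decoys from the same held-out vocabulary.
    """
    if not 0 <= hit_fraction <= 1:
        raise SyntheticError("hit_fraction must lie in [0, 1]")
    rng = np.random.default_rng(config.seed + 1)
    patt = Chem.MolFromSmarts(config.planted_smarts)
    # reproduce the training selection from the seed so the library never
    # contains a compound identical to a training one
    train_actives, train_decoys = _pick_compounds(
        config, np.random.default_rng(config.seed)
    )
    taken = set(train_actives) | set(train_decoys)
    all_r = R_GROUPS + R_GROUPS_LIBRARY
    all_x = X_GROUPS + X_GROUPS_LIBRARY
    close = [
        s
        for s in _enumerate(ACTIVE_TEMPLATES, all_r, all_x)
        if s not in taken and Chem.MolFromSmiles(s).HasSubstructMatch(patt)
    ]
    remote = [
        s
        for s in _enumerate(REMOTE_ANALOG_TEMPLATES, ("C",), all_x)
        if s not in taken and Chem.MolFromSmiles(s).HasSubstructMatch(patt)
    ]
    decoys = [
        s
        for s in _enumerate(DECOY_TEMPLATES, all_r, all_x)
        if s not in taken and not Chem.MolFromSmiles(s).HasSubstructMatch(patt)
    ]
    n_hits = int(round(n_library * hit_fraction))
    n_remote = min(n_hits // 2, len(remote))
    n_close = n_hits - n_remote
    n_decoys = n_library - n_hits
    if n_close > len(close):
        raise SyntheticError(f"at most {len(close)} distinct close analogs available")
    if n_decoys > len(decoys):
        raise SyntheticError(f"at most {len(decoys)} distinct decoys available")
    r_idx = rng.choice(len(remote), size=n_remote, replace=False)
    c_idx = rng.choice(len(close), size=n_close, replace=False)
    d_idx = rng.choice(len(decoys), size=n_decoys, replace=False)
    picked = (
        [(remote[j], "remote") for j in sorted(r_idx)]
        + [(close[j], "close") for j in sorted(c_idx)]
        + [(decoys[j], "decoy") for j in sorted(d_idx)]
    )
    entries, truth_rows = [], []
    for i, (smi, family) in enumerate(picked):
        lid = f"L{i:05d}"
        entries.append((lid, smi))
        truth_rows.append(
            {
                "compound_id": lid,
                "smiles": smi,
                "contains_scaffold": family != "decoy",
                "analog_family": family,
            }
        )
    return entries, pd.DataFrame(truth_rows)


def write_fixture_files(
    config: SyntheticConfig,
    out_dir: str,
    n_library: int = 500,
    hit_fraction: float = 0.2,
    potency_type: str = "IC50",
) -> dict[str, str]:
    """Write the CSV/SMILES files the pipeline ingests plus ground truth."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    records, truth = generate_dataset(config, potency_type=potency_type)
    table = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "smiles": [r.smiles for r in records],
            "value": [r.potency_value for r in records],
            "units": "uM",
            "type": [r.potency_type for r in records],
            "relation": [r.relation for r in records],
        }
    )
    paths = {
        "activity_table": os.path.join(out_dir, "activity_table.csv"),
        "dataset_truth": os.path.join(out_dir, "dataset_truth.csv"),
        "library": os.path.join(out_dir, "library.smi"),
        "library_truth": os.path.join(out_dir, "library_truth.csv"),
        "ground_truth_json": os.path.join(out_dir, "ground_truth.json"),
    }
    table.to_csv(paths["activity_table"], index=False)
    truth.to_csv(paths["dataset_truth"], index=False)
    library, lib_truth = generate_screening_library(
        config, n_library=n_library, hit_fraction=hit_fraction
    )
    with open(paths["library"], "w") as fh:
        for lid, smi in library:
            fh.write(f"{smi} {lid}\n")
    lib_truth.to_csv(paths["library_truth"], index=False)
    with open(paths["ground_truth_json"], "w") as fh:
        json.dump(
            {
                "planted_smarts": config.planted_smarts,
                "seed": config.seed,
                "n_actives": config.n_actives,
                "n_inactives": config.n_inactives,
                "n_library": n_library,
                "hit_fraction": hit_fraction,
            },
            fh,
            indent=2,
        )
    return paths
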