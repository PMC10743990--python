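"""Atom-level explanation of consensus predictions.

Per-bit Shapley values are estimated with a model-agnostic permutation
scheme: features are revealed one at a time in a random order (and, for
antithetic variance reduction, in the reversed order), replacing background
values with the explained compound's values, and the marginal change in the
model's mean output is credited to the revealed feature.  A single
forward/reverse pass is exact for models with up to second-order
interactions; repeats with fresh permutations refine the estimate for
higher-order models.  The estimator is additive by construction: the base
value (mean prediction over the background) plus the sum of all per-bit
scores telescopes exactly to the model's probability score for the
explained compound.

Morgan on-bits are then retro-mapped to their generating atom environments
(center atom plus all atoms within the bit's radius), and each atom a
receives the weight

    fw_a = sum over features containing a of  fc / (n_Atoms * n_occ)

where fc is the bit's Shapley score, n_Atoms the environment's atom count
and n_occ the number of occurrences of the bit in the molecule.  Final atom
weights are averaged over the consensus members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Draw import rdMolDraw2D

from .consensus import ConsensusModel
from .curation import StandardizedCompound
from .modeling import TrainedClassifier
from .representations import (
    FP_N_BITS,
    MORGAN_RADIUS,
    FeatureMatrix,
    featurize_mol,
)

DEFAULT_N_PERMUTATIONS = 10
DEFAULT_BACKGROUND_SIZE = 100


class AttributionError(ValueError):
    pass


@dataclass
class FeatureAttribution:
    """Signed per-bit scores fc for one model and one compound.

    Positive scores push the prediction toward active.  ``base_value`` plus
    the sum of all scores equals the model's PS for the compound (additivity).
    """

    model_name: str
    values: np.ndarray  # (n_features,)
    base_value: float
    on_bits: tuple[int, ...]

    @property
    def ps(self) -> float:
        return float(self.base_value + self.values.sum())


def _masked_means(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    order: np.ndarray,
) -> np.ndarray:
    """g[k] = mean over background rows of f(z) with order[:k] revealed."""
    nv = len(order)
    n_bg, d = background.shape
    g = np.empty(nv + 1)
    cur = background.astype(np.float64, copy=True)
    g[0] = float(np.mean(predict_fn(cur)))
    # cap scratch matrices at ~32 MB
    block = max(1, 4_000_000 // max(1, n_bg * d))
    k = 0
    while k < nv:
        steps = order[k : k + block]
        Z = np.empty((len(steps), n_bg, d))
        for s, j in enumerate(steps):
            cur[:, j] = x[j]
            Z[s] = cur
        vals = np.asarray(predict_fn(Z.reshape(-1, d))).reshape(len(steps), n_bg)
        g[k + 1 : k + 1 + len(steps)] = vals.mean(axis=1)
        k += len(steps)
    return g


def permutation_shap(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Antithetic permutation Shapley estimates for one input row.

    Returns (phi, base_value) with ``base_value + phi.sum()`` equal to
    ``predict_fn(x)`` up to floating-point summation.  Features identical
    across the input and every background row get an exact zero.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=np.float64))
    if background.shape[0] == 0:
        raise AttributionError("background must be non-empty")
    if background.shape[1] != x.size:
        raise AttributionError("background width does not match input length")
    if n_permutations < 1:
        raise AttributionError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    varying = np.nonzero(np.any(background != x, axis=0))[0]
    phi = np.zeros(x.size)
    base = float(np.mean(predict_fn(background)))
    if len(varying) == 0:
        return phi, base
    for _ in range(n_permutations):
        order = rng.permutation(varying)
        for direction in (order, order[::-1]):
            g = _masked_means(predict_fn, x, background, direction)
            np.add.at(phi, direction, np.diff(g))
    phi /= 2 * n_permutations
    return phi, base


def _as_mol(compound) -> Chem.Mol:
    smiles = (
        compound.smiles_std
        if isinstance(compound, StandardizedCompound)
        else str(compound)
    )
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise AttributionError(f"unparseable SMILES {smiles!r}")
    return mol


def shap_attributions(
    model: TrainedClassifier,
    compound,
    background: FeatureMatrix | np.ndarray,
    seed: int = 0,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
) -> FeatureAttribution:
    """Permutation-Shapley bit scores of one model for one compound."""
    if model.spec.representation != "morgan":
        raise AttributionError(
            "attribution retro-mapping is defined for the morgan representation"
        )
    if isinstance(background, FeatureMatrix):
        background = background.data
    mol = _as_mol(compound)
    x = featurize_mol(mol, "morgan").astype(np.float64)
    phi, base = permutation_shap(
        model.predict_ps, x, background, n_permutations=n_permutations, seed=seed
    )
    return FeatureAttribution(
        model_name=model.spec.name,
        values=phi,
        base_value=base,
        on_bits=tuple(int(i) for i in np.nonzero(x)[0]),
    )


@dataclass(frozen=True)
class BitEnvironment:
    atoms: tuple[int, ...]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class BitAtomMap:
    """Morgan on-bit -> generating atom environments of one molecule."""

    n_mol_atoms: int
    environments: dict[int, list[BitEnvironment]] = field(default_factory=dict)

    def n_occ(self, bit: int) -> int:
        return len(self.environments[bit])


def retro_map_bits(compound) -> BitAtomMap:
    """Map every Morgan on-bit of a molecule to its atom environments.

    Each environment is the center atom plus every atom touched by a bond
    within the bit's radius.  Hash collisions put several environments under
    one bit; their number is the bit's occurrence count n_occ.
    """
    mol = _as_mol(compound)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=MORGAN_RADIUS, fpSize=FP_N_BITS
    )
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    gen.GetFingerprint(mol, additionalOutput=ao)
    bit_info = ao.GetBitInfoMap()
    out = BitAtomMap(n_mol_atoms=mol.GetNumAtoms())
    for bit, envs in bit_info.items():
        lst = []
        for atom_idx, radius in envs:
            if radius == 0:
                atoms = {atom_idx}
            else:
                bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom_idx)
                atoms = {atom_idx}
                for bid in bond_ids:
                    bond = mol.GetBondWithIdx(bid)
                    atoms.add(bond.GetBeginAtomIdx())
                    atoms.add(bond.GetEndAtomIdx())
            lst.append(BitEnvironment(atoms=tuple(sorted(atoms))))
        out.environments[int(bit)] = lst
    return out


@dataclass
class AtomAttribution:
    """Per-atom weights fw_a, per consensus member and averaged."""

    per_model: dict[str, np.ndarray]
    weights: np.ndarray  # mean across members

    @classmethod
    def from_per_model(cls, per_model: dict[str, np.ndarray]):
        stacked = np.stack(list(per_model.values()))
        return cls(per_model=per_model, weights=stacked.mean(axis=0))


def atom_weights(
    attributions: Sequence[FeatureAttribution], bit_map: BitAtomMap
) -> AtomAttribution:
    """Distribute per-bit scores onto atoms: fw_a = sum fc/(n_Atoms*n_occ).

    Per model, each environment of a mapped bit spreads fc/n_occ uniformly
    over its atoms; the final weight is the mean across models.  On-bits
    carrying a nonzero score but missing from the map trigger a warning and
    are left out of the conservation balance.
    """
    if not attributions:
        raise AttributionError("need at least one feature attribution")
    per_model: dict[str, np.ndarray] = {}
    for attr in attributions:
        unmapped = [
            b for b in attr.on_bits
            if attr.values[b] != 0 and b not in bit_map.environments
        ]
        if unmapped:
            warnings.warn(
                f"{len(unmapped)} scored on-bit(s) missing from the bit-atom map; "
                "excluded from the conservation balance"
            )
        w = np.zeros(bit_map.n_mol_atoms)
        for bit, envs in bit_map.environments.items():
            fc = attr.values[bit]
            if fc == 0:
                continue
            n_occ = len(envs)
            for env in envs:
                share = fc / (env.n_atoms * n_occ)
                for a in env.atoms:
                    w[a] += share
        per_model[attr.model_name] = w
    return AtomAttribution.from_per_model(per_model)


def explain_compound(
    consensus: ConsensusModel,
    compound,
    background: FeatureMatrix | np.ndarray,
    seed: int = 0,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
) -> tuple[AtomAttribution, list[FeatureAttribution], BitAtomMap]:
    """End-to-end explanation of a consensus prediction for one compound."""
    attrs = [
        shap_attributions(
            m, compound, background, seed=seed + i, n_permutations=n_permutations
        )
        for i, m in enumerate(consensus.members)
    ]
    bit_map = retro_map_bits(compound)
    return atom_weights(attrs, bit_map), attrs, bit_map


def render_atom_weights(compound, attribution: AtomAttribution, path: str) -> str:
    """Draw the molecule with atoms shaded by signed weight.

    Warm (red) marks atoms pushing toward active, cool (blue) toward
    inactive; writes SVG (or PNG when the path ends in .png).
    """
    mol = _as_mol(compound)
    if mol.GetNumAtoms() != attribution.weights.size:
        raise AttributionError("weight vector does not match molecule atom count")
    w = attribution.weights
    scale = np.abs(w).max()
    highlight, colors = [], {}
    if scale > 0:
        for i, wi in enumerate(w):
            t = abs(wi) / scale
            if t < 1e-12:
                continue
            highlight.append(i)
            colors[i] = (1.0, 1.0 - 0.8 * t, 1.0 - 0.8 * t) if wi > 0 else (
                1.0 - 0.8 * t, 1.0 - 0.8 * t, 1.0)
    if path.endswith(".png"):
        drawer = rdMolDraw2D.MolDraw2DCairo(400, 400)
    else:
        drawer = rdMolDraw2D.MolDraw2DSVG(400, 400)
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer, mol, highlightAtoms=highlight, highlightAtomColors=colors
    )
    drawer.FinishDrawing()
    mode = "wb" if path.endswith(".png") else "w"
    data = drawer.GetDrawingText()
    try:
        with open(path, mode) as fh:
            fh.write(data)
    except OSError as exc:
        raise AttributionError(f"cannot write depiction to {path}: {exc}")
    return path
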