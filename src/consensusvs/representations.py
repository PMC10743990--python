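"""Molecular representations: six fingerprints, one descriptor vector,
and Tanimoto similarity.

Seven representation kinds are supported:

``morgan``      circular fingerprint, radius 2, hashed to 2048 bits
``rdkit``       subgraph path fingerprint, 2048 bits
``layered``     layered substructure fingerprint, 2048 bits
``pattern``     SMARTS-pattern substructure fingerprint, 2048 bits
``pharm2d``     2D-pharmacophore fingerprint over {acceptor, donor,
                positive ionizable, negative ionizable, aromatic} features,
                2-3 point combinations, topological distance bins
                (0-2, 2-5, 5-8 bonds)
``pubchem``     881-key substructure fingerprint (see :mod:`.pubchem_fp`)
``descriptors`` 128 physicochemical/topological descriptors, pinned manifest

All featurizers are deterministic for fixed inputs.
"""

from __future__ import annotations

import hashlib
import os
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import ChemicalFeatures, Descriptors, rdFingerprintGenerator
from rdkit.Chem.Pharm2D import Generate as Pharm2DGenerate
from rdkit.Chem.Pharm2D.SigFactory import SigFactory

from .curation import StandardizedCompound
from .pubchem_fp import N_BITS as PUBCHEM_N_BITS
from .pubchem_fp import pubchem_fingerprint

FP_N_BITS = 2048
MORGAN_RADIUS = 2
PHARM2D_FAMILIES = ("Acceptor", "Donor", "PosIonizable", "NegIonizable", "Aromatic")
PHARM2D_BINS = ((0, 2), (2, 5), (5, 8))

BIT_KINDS = ("morgan", "rdkit", "layered", "pattern", "pharm2d", "pubchem")
KINDS = BIT_KINDS + ("descriptors",)

# 128 descriptors: the non-fragment RDKit descriptor set without the
# numerically explosive Ipc, topped up with four common fragment counts.
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "MaxAbsEStateIndex", "MaxEStateIndex", "MinAbsEStateIndex", "MinEStateIndex",
    "qed", "SPS", "MolWt", "HeavyAtomMolWt", "ExactMolWt", "NumValenceElectrons",
    "NumRadicalElectrons", "MaxPartialCharge", "MinPartialCharge",
    "MaxAbsPartialCharge", "MinAbsPartialCharge", "FpDensityMorgan1",
    "FpDensityMorgan2", "FpDensityMorgan3", "BCUT2D_MWHI", "BCUT2D_MWLOW",
    "BCUT2D_CHGHI", "BCUT2D_CHGLO", "BCUT2D_LOGPHI", "BCUT2D_LOGPLOW",
    "BCUT2D_MRHI", "BCUT2D_MRLOW", "AvgIpc", "BalabanJ", "BertzCT", "Chi0",
    "Chi0n", "Chi0v", "Chi1", "Chi1n", "Chi1v", "Chi2n", "Chi2v", "Chi3n",
    "Chi3v", "Chi4n", "Chi4v", "HallKierAlpha", "Kappa1", "Kappa2", "Kappa3",
    "LabuteASA", "PEOE_VSA1", "PEOE_VSA10", "PEOE_VSA11", "PEOE_VSA12",
    "PEOE_VSA13", "PEOE_VSA14", "PEOE_VSA2", "PEOE_VSA3", "PEOE_VSA4",
    "PEOE_VSA5", "PEOE_VSA6", "PEOE_VSA7", "PEOE_VSA8", "PEOE_VSA9",
    "SMR_VSA1", "SMR_VSA10", "SMR_VSA2", "SMR_VSA3", "SMR_VSA4", "SMR_VSA5",
    "SMR_VSA6", "SMR_VSA7", "SMR_VSA8", "SMR_VSA9", "SlogP_VSA1",
    "SlogP_VSA10", "SlogP_VSA11", "SlogP_VSA12", "SlogP_VSA2", "SlogP_VSA3",
    "SlogP_VSA4", "SlogP_VSA5", "SlogP_VSA6", "SlogP_VSA7", "SlogP_VSA8",
    "SlogP_VSA9", "TPSA", "EState_VSA1", "EState_VSA10", "EState_VSA11",
    "EState_VSA2", "EState_VSA3", "EState_VSA4", "EState_VSA5", "EState_VSA6",
    "EState_VSA7", "EState_VSA8", "EState_VSA9", "VSA_EState1", "VSA_EState10",
    "VSA_EState2", "VSA_EState3", "VSA_EState4", "VSA_EState5", "VSA_EState6",
    "VSA_EState7", "VSA_EState8", "VSA_EState9", "FractionCSP3",
    "HeavyAtomCount", "NHOHCount", "NOCount", "NumAliphaticCarbocycles",
    "NumAliphaticHeterocycles", "NumAliphaticRings", "NumAromaticCarbocycles",
    "NumAromaticHeterocycles", "NumAromaticRings", "NumHAcceptors",
    "NumHDonors", "NumHeteroatoms", "NumRotatableBonds",
    "NumSaturatedCarbocycles", "NumSaturatedHeterocycles", "NumSaturatedRings",
    "RingCount", "MolLogP", "MolMR", "fr_NH2", "fr_amide", "fr_ether",
    "fr_halogen",
)
N_DESCRIPTORS = 128
assert len(DESCRIPTOR_NAMES) == N_DESCRIPTORS


class RepresentationError(ValueError):
    pass


class FeaturizationError(RepresentationError):
    """A single molecule could not be featurized."""

    def __init__(self, smiles: str, reason: str):
        self.smiles = smiles
        self.reason = reason
        super().__init__(f"cannot featurize {smiles!r}: {reason}")


@dataclass
class FeatureMatrix:
    """A compound set encoded under one representation kind."""

    kind: str
    ids: list[str]
    data: np.ndarray  # shape (n_compounds, n_features)

    def __post_init__(self):
        if self.data.ndim != 2 or self.data.shape[0] != len(self.ids):
            raise RepresentationError("row count must equal compound count")

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(self.kind.encode())
        h.update(np.ascontiguousarray(self.data).tobytes())
        return h.hexdigest()

    def to_csv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(self.data, index=self.ids).to_csv(path)


@lru_cache(maxsize=1)
def _morgan_generator():
    return rdFingerprintGenerator.GetMorganGenerator(
        radius=MORGAN_RADIUS, fpSize=FP_N_BITS
    )


@lru_cache(maxsize=1)
def _sig_factory() -> SigFactory:
    fdef = os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
    factory = ChemicalFeatures.BuildFeatureFactory(fdef)
    skip = [f for f in set(factory.GetFeatureFamilies()) if f not in PHARM2D_FAMILIES]
    sig = SigFactory(factory, minPointCount=2, maxPointCount=3, skipFeats=skip)
    sig.SetBins(list(PHARM2D_BINS))
    sig.Init()
    return sig


def pharm2d_size() -> int:
    """Length of the pharm2d vector; fixed by the feature/bin scheme."""
    return _sig_factory().GetSigSize()


def n_features(kind: str) -> int:
    if kind in ("morgan", "rdkit", "layered", "pattern"):
        return FP_N_BITS
    if kind == "pubchem":
        return PUBCHEM_N_BITS
    if kind == "pharm2d":
        return pharm2d_size()
    if kind == "descriptors":
        return N_DESCRIPTORS
    raise RepresentationError(f"unknown representation kind {kind!r}")


def _as_mol(compound) -> tuple[str, Chem.Mol]:
    if isinstance(compound, StandardizedCompound):
        smiles = compound.smiles_std
    else:
        smiles = str(compound)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(smiles, "unparseable SMILES")
    return smiles, mol


def _bitvect_to_array(bv, length: int) -> np.ndarray:
    arr = np.zeros(length, dtype=np.uint8)
    arr[list(bv.GetOnBits())] = 1
    return arr


def featurize_mol(mol: Chem.Mol, kind: str) -> np.ndarray:
    """Feature vector for a single RDKit molecule."""
    if kind == "morgan":
        return _bitvect_to_array(_morgan_generator().GetFingerprint(mol), FP_N_BITS)
    if kind == "rdkit":
        return _bitvect_to_array(Chem.RDKFingerprint(mol, fpSize=FP_N_BITS), FP_N_BITS)
    if kind == "layered":
        return _bitvect_to_array(Chem.LayeredFingerprint(mol, fpSize=FP_N_BITS), FP_N_BITS)
    if kind == "pattern":
        return _bitvect_to_array(Chem.PatternFingerprint(mol, fpSize=FP_N_BITS), FP_N_BITS)
    if kind == "pharm2d":
        fp = Pharm2DGenerate.Gen2DFingerprint(mol, _sig_factory())
        return _bitvect_to_array(fp, pharm2d_size())
    if kind == "pubchem":
        return pubchem_fingerprint(mol)
    if kind == "descriptors":
        values = np.empty(N_DESCRIPTORS, dtype=np.float64)
        n_bad = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, name in enumerate(DESCRIPTOR_NAMES):
                try:
                    v = getattr(Descriptors, name)(mol)
                except Exception:
                    v, n_bad = 0.0, n_bad + 1
                if not np.isfinite(v):
                    v, n_bad = 0.0, n_bad + 1
                values[i] = v
        if n_bad:
            warnings.warn(
                f"{n_bad} descriptor value(s) imputed to 0 for {Chem.MolToSmiles(mol)}"
            )
        return values
    raise RepresentationError(f"unknown representation kind {kind!r}")


def featurize(compounds: Iterable, kind: str) -> FeatureMatrix:
    """Encode a compound list (StandardizedCompound or SMILES) as a matrix."""
    if kind not in KINDS:
        raise RepresentationError(f"unknown representation kind {kind!r}")
    ids, rows = [], []
    for i, compound in enumerate(compounds):
        cid = (
            compound.compound_id
            if isinstance(compound, StandardizedCompound)
            else f"cpd{i}"
        )
        _, mol = _as_mol(compound)
        rows.append(featurize_mol(mol, kind))
        ids.append(cid)
    if not rows:
        return FeatureMatrix(kind=kind, ids=[], data=np.zeros((0, n_features(kind))))
    dtype = np.float64 if kind == "descriptors" else np.uint8
    return FeatureMatrix(kind=kind, ids=ids, data=np.asarray(rows, dtype=dtype))


# --- Tanimoto similarity ---------------------------------------------------


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a&b| / |a|b| of two binary vectors.

    Two empty (all-zero) vectors are identical by convention -> 1.0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise RepresentationError(
            f"fingerprint length mismatch: {a.shape} vs {b.shape}"
        )
    inter = int(np.sum((a != 0) & (b != 0)))
    union = int(np.sum((a != 0) | (b != 0)))
    if union == 0:
        return 1.0
    return inter / union


def tanimoto_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity between the rows of two binary matrices.

    Zero-vector conventions match :func:`tanimoto`: sim(0, 0) = 1, and the
    similarity of a zero vector with any nonzero vector is 0.
    """
    A = (np.asarray(A) != 0).astype(np.float64)
    B = (np.asarray(B) != 0).astype(np.float64)
    if A.shape[1] != B.shape[1]:
        raise RepresentationError("fingerprint length mismatch")
    inter = A @ B.T
    na = A.sum(axis=1)[:, None]
    nb = B.sum(axis=1)[None, :]
    union = na + nb - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    return sim


def max_similarity_to_set(
    query: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Per query row, the maximum Tanimoto similarity to any reference row."""
    return tanimoto_matrix(np.atleast_2d(query), reference).max(axis=1)
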