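"""881-bit substructure-key fingerprint following the public PubChem layout.

The key list is organized in the seven documented sections of the PubChem
substructure fingerprint specification and totals exactly 881 bits:

1. hierarchical element counts                      (114 bits)
2. ring counts by size, composition and saturation  (148 bits)
3. simple bonded atom pairs                         (64 bits)
4. atom nearest-neighbor patterns, any bond order   (90 bits)
5. detailed atom neighborhoods with bond orders     (44 bits)
6. simple linear substructure chains                (253 bits)
7. complex ring-substitution patterns               (168 bits)

Sections 3-7 are expressed as SMARTS; sections 1-2 are computed from atom
tables and SSSR ring perception.  Every key is a monotone substructure
predicate: adding atoms to a molecule can only switch bits on, never off.
The table is generated deterministically at import time.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations_with_replacement, product

import numpy as np
from rdkit import Chem

N_BITS = 881

# --- section 1: element counts -------------------------------------------

_ELEMENT_COUNTS: list[tuple[str, int]] = []
for sym, thresholds in [
    ("H", (4, 8, 16, 32)),
    ("Li", (1, 2)),
    ("B", (1, 2, 4)),
    ("C", (2, 4, 8, 16, 32)),
    ("N", (1, 2, 4, 8)),
    ("O", (1, 2, 4, 8, 16)),
    ("F", (1, 2, 4)),
    ("Na", (1, 2)),
    ("Si", (1, 2)),
    ("P", (1, 2, 4)),
    ("S", (1, 2, 4, 8)),
    ("Cl", (1, 2, 4, 8)),
    ("K", (1, 2)),
    ("Br", (1, 2, 4)),
    ("I", (1, 2, 4)),
]:
    for t in thresholds:
        _ELEMENT_COUNTS.append((sym, t))
for sym in (
    "Be Mg Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Ge As Se Kr Rb Sr "
    "Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te Xe Cs Ba La Ce Pr "
    "Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt Au "
    "Hg Tl Pb Bi U"
).split():
    _ELEMENT_COUNTS.append((sym, 1))
assert len(_ELEMENT_COUNTS) == 114

# --- section 2: ring counts ----------------------------------------------

_RING_SIZE_COUNTS = {3: (1, 2), 4: (1, 2), 5: (1, 2, 3, 4, 5), 6: (1, 2, 3, 4, 5),
                     7: (1, 2), 8: (1, 2), 9: (1,), 10: (1,)}
_RING_CATEGORIES = (
    "any",
    "carbon-only saturated or aromatic",
    "nitrogen-containing saturated or aromatic",
    "heteroatom-containing saturated or aromatic",
    "carbon-only unsaturated non-aromatic",
    "nitrogen-containing unsaturated non-aromatic",
    "heteroatom-containing unsaturated non-aromatic",
)
_RING_KEYS: list[tuple[int, str, int]] = [
    (size, cat, t)
    for size, counts in _RING_SIZE_COUNTS.items()
    for cat in _RING_CATEGORIES
    for t in counts
]
_AROMATIC_RING_KEYS = [("aromatic", t) for t in (1, 2, 3, 4)] + [
    ("heteroaromatic", t) for t in (1, 2, 3, 4)
]
assert len(_RING_KEYS) + len(_AROMATIC_RING_KEYS) == 148

# --- sections 3-7: SMARTS keys -------------------------------------------

_SYM2NUM = {
    "H": 1, "Li": 3, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Na": 11,
    "Mg": 12, "Al": 13, "Si": 14, "P": 15, "S": 16, "Cl": 17, "K": 19,
    "As": 33, "Se": 34, "Br": 35, "Sn": 50, "I": 53, "Hg": 80, "Pb": 82,
}


def _atom_q(sym: str, min_h: int = 0) -> str:
    """SMARTS atom query by atomic number, optionally requiring >= min_h H."""
    n = _SYM2NUM[sym]
    if min_h == 0:
        return f"[#{n}]"
    hs = ",".join(f"H{k}" for k in range(min_h, 5))
    return f"[#{n};{hs}]"


def _pair_smarts(a: str, b: str) -> str:
    # H is encoded as an H-count constraint on the heavy partner
    if a == "H":
        a, b = b, a
    if b == "H":
        return _atom_q(a, min_h=1)
    return f"{_atom_q(a)}~{_atom_q(b)}"


_ATOM_PAIRS = [
    ("Li", "H"), ("Li", "Li"), ("B", "H"), ("B", "B"), ("B", "C"), ("B", "N"),
    ("B", "O"), ("B", "F"), ("B", "Si"), ("B", "P"), ("B", "S"), ("B", "Cl"),
    ("B", "Br"), ("C", "H"), ("C", "C"), ("C", "N"), ("C", "O"), ("C", "F"),
    ("C", "Na"), ("C", "Mg"), ("C", "Al"), ("C", "Si"), ("C", "P"), ("C", "S"),
    ("C", "Cl"), ("C", "As"), ("C", "Se"), ("C", "Br"), ("C", "I"), ("N", "H"),
    ("N", "N"), ("N", "O"), ("N", "F"), ("N", "Si"), ("N", "P"), ("N", "S"),
    ("N", "Cl"), ("N", "Br"), ("O", "H"), ("O", "O"), ("O", "Mg"), ("O", "Na"),
    ("O", "Al"), ("O", "Si"), ("O", "P"), ("O", "K"), ("F", "P"), ("F", "S"),
    ("Al", "H"), ("Al", "Cl"), ("Si", "H"), ("Si", "Si"), ("Si", "Cl"),
    ("P", "H"), ("P", "P"), ("As", "H"), ("As", "As"), ("S", "H"), ("S", "S"),
    ("S", "Cl"), ("Se", "H"), ("Se", "Se"), ("Sn", "C"), ("Hg", "C"),
]
assert len(_ATOM_PAIRS) == 64


def _neighbor_smarts(center: str, neighbors: tuple[str, ...]) -> str:
    n_h = sum(1 for x in neighbors if x == "H")
    heavy = [x for x in neighbors if x != "H"]
    s = _atom_q(center, min_h=n_h)
    for x in heavy:
        s += f"(~{_atom_q(x)})"
    return s


def _build_neighbor_keys() -> list[tuple[str, str]]:
    keys: list[tuple[str, str]] = []
    specs = [
        ("C", ("H", "C", "N", "O", "S", "F", "Cl", "Br", "I"), 2),
        ("N", ("H", "C", "N", "O", "S", "Cl"), 2),
        ("O", ("H", "C", "N", "O", "P", "S"), 2),
    ]
    for center, vocab, k in specs:
        for combo in combinations_with_replacement(vocab, k):
            name = f"{center}({')('.join('~' + x for x in combo)})"
            keys.append((name, _neighbor_smarts(center, combo)))
    for combo in (("C", "C", "C"), ("C", "C", "N"), ("C", "C", "O")):
        name = f"C({')('.join('~' + x for x in combo)})"
        keys.append((name, _neighbor_smarts("C", combo)))
    assert len(keys) == 90
    return keys


def _build_detailed_keys() -> list[tuple[str, str]]:
    multiple = ["=C", "#C", "=N", "#N", "=O", "=S"]
    single = ["-C", "-N", "-O", "-S", "-F", "-Cl", "-Br"]
    pats = [("C", m, s) for m, s in product(multiple, single)][:38]
    pats += [
        ("N", "=C", "-C"), ("N", "=O", "-C"), ("N", "=O", "-O"),
        ("S", "=O", "=O"), ("S", "=O", "-C"), ("P", "=O", "-O"),
    ]
    keys = []
    for center, b1, b2 in pats:
        name = f"{center}({b1})({b2})"

        def branch(b: str) -> str:
            return f"({b[0]}{_atom_q(b[1:])})"

        keys.append((name, f"{_atom_q(center)}{branch(b1)}{branch(b2)}"))
    assert len(keys) == 44
    return keys


def _dedupe_chains(chains: list[str]) -> list[str]:
    """Drop reversal duplicates of linear chain patterns, keep first seen."""

    def rev(c: str) -> str:
        toks = []
        i = 0
        while i < len(c):
            if c[i : i + 2] in ("Cl", "Br"):
                toks.append(c[i : i + 2])
                i += 2
            else:
                toks.append(c[i])
                i += 1
        return "".join(reversed(toks))

    seen, out = set(), []
    for c in chains:
        key = min(c, rev(c))
        if key not in seen:
            seen.add(key)
            out.append(c)
    return out


def _build_chain_keys() -> list[tuple[str, str]]:
    atoms3 = ["C", "N", "O", "S"]
    bonds = ["-", "="]
    chains = [
        f"{a1}{b1}{a2}{b2}{a3}"
        for a1 in atoms3 for b1 in bonds for a2 in atoms3
        for b2 in bonds for a3 in atoms3
    ]
    chains = _dedupe_chains(chains)
    arom = [
        f"{a1}:{a2}:{a3}"
        for a1 in ("c", "n", "o", "s") for a2 in ("c", "n") for a3 in ("c", "n", "o", "s")
    ]
    chains += _dedupe_chains(arom)
    four = [
        f"{a1}{b1}{a2}-{a3}{b2}{a4}"
        for a1 in ("C", "N", "O") for b1 in bonds for a2 in ("C", "N", "O")
        for a3 in ("C", "N", "O") for b2 in bonds for a4 in ("C", "N", "O")
    ]
    chains += _dedupe_chains(four)
    chains = chains[:253]
    assert len(chains) == 253
    return [(c, c) for c in chains]


def _build_complex_keys() -> list[tuple[str, str]]:
    subs = ["C", "N", "O", "S", "F", "Cl", "Br"]
    keys = []
    ring_templates = {
        "benzene": {"ortho": "{x}c1ccccc1{y}", "meta": "{x}c1cccc({y})c1",
                    "para": "{x}c1ccc({y})cc1"},
        "cyclohexane": {"ortho": "{x}C1CCCCC1{y}", "meta": "{x}C1CCCC({y})C1",
                        "para": "{x}C1CCC({y})CC1"},
    }
    for ring, positions in ring_templates.items():
        for pos, tmpl in positions.items():
            for x, y in combinations_with_replacement(subs, 2):
                sma = tmpl.format(x=x, y=y)
                keys.append((f"{ring} {pos} {x}/{y}", sma))
    assert len(keys) == 168
    return keys


@lru_cache(maxsize=1)
def _smarts_keys() -> list[tuple[str, Chem.Mol]]:
    """Compile the SMARTS sections once; order defines bit positions 262-880."""
    entries: list[tuple[str, str]] = []
    entries += [(f"{a}~{b}", _pair_smarts(a, b)) for a, b in _ATOM_PAIRS]
    entries += _build_neighbor_keys()
    entries += _build_detailed_keys()
    entries += _build_chain_keys()
    entries += _build_complex_keys()
    assert len(entries) == 64 + 90 + 44 + 253 + 168
    compiled = []
    for name, sma in entries:
        patt = Chem.MolFromSmarts(sma)
        if patt is None:  # pragma: no cover - table is static
            raise ValueError(f"invalid SMARTS key {name!r}: {sma!r}")
        compiled.append((name, patt))
    return compiled


# --- ring classification ---------------------------------------------------


def _ring_flags(mol: Chem.Mol):
    """Per SSSR ring: (size, aromatic, saturated, has_N, has_hetero)."""
    ri = mol.GetRingInfo()
    out = []
    for atom_ids, bond_ids in zip(ri.AtomRings(), ri.BondRings()):
        atoms = [mol.GetAtomWithIdx(i) for i in atom_ids]
        bonds = [mol.GetBondWithIdx(i) for i in bond_ids]
        aromatic = all(b.GetIsAromatic() for b in bonds)
        saturated = all(b.GetBondType() == Chem.BondType.SINGLE for b in bonds)
        has_n = any(a.GetAtomicNum() == 7 for a in atoms)
        has_het = any(a.GetAtomicNum() != 6 for a in atoms)
        out.append((len(atom_ids), aromatic, saturated, has_n, has_het))
    return out


def _ring_in_category(flags, cat: str) -> bool:
    size, aromatic, saturated, has_n, has_het = flags
    sat_or_arom = aromatic or saturated
    unsat_non_arom = (not aromatic) and (not saturated)
    if cat == "any":
        return True
    if cat == "carbon-only saturated or aromatic":
        return sat_or_arom and not has_het
    if cat == "nitrogen-containing saturated or aromatic":
        return sat_or_arom and has_n
    if cat == "heteroatom-containing saturated or aromatic":
        return sat_or_arom and has_het
    if cat == "carbon-only unsaturated non-aromatic":
        return unsat_non_arom and not has_het
    if cat == "nitrogen-containing unsaturated non-aromatic":
        return unsat_non_arom and has_n
    return unsat_non_arom and has_het


def pubchem_fingerprint(mol: Chem.Mol) -> np.ndarray:
    """Compute the 881-bit substructure-key fingerprint for one molecule."""
    bits = np.zeros(N_BITS, dtype=np.uint8)
    pos = 0

    counts: dict[str, int] = {}
    n_h = 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        counts[sym] = counts.get(sym, 0) + 1
        n_h += atom.GetTotalNumHs(includeNeighbors=False)
    n_h += counts.get("H", 0)
    counts["H"] = n_h
    for sym, t in _ELEMENT_COUNTS:
        if counts.get(sym, 0) >= t:
            bits[pos] = 1
        pos += 1

    rings = _ring_flags(mol)
    for size, cat, t in _RING_KEYS:
        n = sum(1 for fl in rings if fl[0] == size and _ring_in_category(fl, cat))
        if n >= t:
            bits[pos] = 1
        pos += 1
    n_arom = sum(1 for fl in rings if fl[1])
    n_het_arom = sum(1 for fl in rings if fl[1] and fl[4])
    for kind, t in _AROMATIC_RING_KEYS:
        n = n_arom if kind == "aromatic" else n_het_arom
        if n >= t:
            bits[pos] = 1
        pos += 1

    for _, patt in _smarts_keys():
        if mol.HasSubstructMatch(patt):
            bits[pos] = 1
        pos += 1

    assert pos == N_BITS
    return bits


def key_names() -> list[str]:
    """Human-readable names of all 881 keys, in bit order."""
    names = [f">= {t} {sym}" for sym, t in _ELEMENT_COUNTS]
    names += [f">= {t} {cat} ring(s) of size {size}" for size, cat, t in _RING_KEYS]
    names += [f">= {t} {kind} ring(s)" for kind, t in _AROMATIC_RING_KEYS]
    names += [name for name, _ in _smarts_keys()]
    return names
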