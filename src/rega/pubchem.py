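"""881-position substructure-key fingerprint in the PubChem/CACTVS layout.

The key table (``data/pubchem_keys.tsv``) follows the structure of the
PubChem substructure fingerprint: a hierarchical element-count section
(115 keys), a ring-system section (148 keys) and a SMARTS section
(618 keys). The SMARTS section is a synthetic reconstruction of the
CACTVS key classes evaluated with RDKit substructure matching; the block
width is fixed at 881 but bit-for-bit parity with the original CACTVS
engine is not promised.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np
from rdkit import Chem

N_BITS = 881


@dataclass(frozen=True)
class _Key:
    bit: int
    kind: str        # element | ring | smarts
    payload: str
    min_count: int


@functools.lru_cache(maxsize=1)
def _load_keys() -> tuple[_Key, ...]:
    text = resources.files("rega.data").joinpath("pubchem_keys.tsv").read_text()
    keys = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        bit, kind, payload, cnt = line.split("\t")
        keys.append(_Key(int(bit), kind, payload, int(cnt)))
    if len(keys) != N_BITS:
        raise RuntimeError(f"pubchem key table has {len(keys)} entries, expected {N_BITS}")
    return tuple(keys)


@functools.lru_cache(maxsize=1)
def _compiled_smarts() -> dict[str, Chem.Mol]:
    out = {}
    for key in _load_keys():
        if key.kind == "smarts" and key.payload not in out:
            patt = Chem.MolFromSmarts(key.payload)
            if patt is None:
                raise RuntimeError(f"invalid SMARTS in key table: {key.payload!r}")
            out[key.payload] = patt
    return out


def _element_counts(mol: Chem.Mol) -> dict[str, int]:
    counts: dict[str, int] = {}
    n_h = 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        counts[sym] = counts.get(sym, 0) + 1
        if atom.GetAtomicNum() != 1:
            n_h += atom.GetTotalNumHs()
    counts["H"] = counts.get("H", 0) + n_h
    return counts


def _ring_counts(mol: Chem.Mol) -> dict[str, int]:
    """Count SSSR rings bucketed by (size, saturation/aromaticity, composition)."""
    info = mol.GetRingInfo()
    counts: dict[str, int] = {}

    def bump(payload: str) -> None:
        counts[payload] = counts.get(payload, 0) + 1

    for atom_ids, bond_ids in zip(info.AtomRings(), info.BondRings()):
        size = len(atom_ids)
        atoms = [mol.GetAtomWithIdx(i) for i in atom_ids]
        bonds = [mol.GetBondWithIdx(i) for i in bond_ids]
        aromatic = all(b.GetIsAromatic() for b in bonds)
        saturated = all(b.GetBondType() == Chem.BondType.SINGLE for b in bonds)
        carbon_only = all(a.GetAtomicNum() == 6 for a in atoms)
        has_nitrogen = any(a.GetAtomicNum() == 7 for a in atoms)
        has_hetero = not carbon_only

        if aromatic:
            bump("arom:any")
            if has_hetero:
                bump("arom:hetero")
        if size < 3 or size > 10:
            continue
        bump(f"{size}:any")
        if saturated or aromatic:
            if carbon_only:
                bump(f"{size}:sa_carbon")
            if has_nitrogen:
                bump(f"{size}:sa_nitrogen")
            if has_hetero:
                bump(f"{size}:sa_hetero")
        else:
            if carbon_only:
                bump(f"{size}:un_carbon")
            if has_nitrogen:
                bump(f"{size}:un_nitrogen")
            if has_hetero:
                bump(f"{size}:un_hetero")
    return counts


def pubchem_fingerprint(mol: Chem.Mol) -> np.ndarray:
    """Compute the 881-bit substructure-key vector for one molecule.

    Returns a ``uint8`` array of length 881 with entries in {0, 1}.
    """
    if mol is None:
        raise ValueError("mol is None")
    keys = _load_keys()
    patts = _compiled_smarts()
    elements = _element_counts(mol)
    rings = _ring_counts(mol)

    bits = np.zeros(N_BITS, dtype=np.uint8)
    smarts_count_cache: dict[str, int] = {}
    for key in keys:
        if key.kind == "element":
            ok = elements.get(key.payload, 0) >= key.min_count
        elif key.kind == "ring":
            ok = rings.get(key.payload, 0) >= key.min_count
        else:
            patt = patts[key.payload]
            if key.min_count == 1:
                ok = mol.HasSubstructMatch(patt)
            else:
                if key.payload not in smarts_count_cache:
                    smarts_count_cache[key.payload] = len(
                        mol.GetSubstructMatches(patt, uniquify=True)
                    )
                ok = smarts_count_cache[key.payload] >= key.min_count
        if ok:
            bits[key.bit] = 1
    return bits
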