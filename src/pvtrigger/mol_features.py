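"""Structure standardization and the four molecular representations.

Input SMILES are "washed" (largest organic fragment, neutralization of
standard acid/base groups, canonicalization); standardized molecules are then
featurized as

* a pinned, ordered panel of 83 2D descriptors (shipped in
  ``data/descriptors_83.txt``; molecular weight, Crippen logP, H-bond
  donors/acceptors, TPSA, kappa shape indices, BertzCT, ring counts and
  E-state aggregates among them),
* MACCS structural keys reported as the 166 keyed bits,
* ECFP4: Morgan circular fingerprints of radius 2 folded to 1024 bits,
* molecular graphs with per-atom and per-directed-bond feature vectors for
  the message-passing models.

Featurization is a pure function of the canonical SMILES.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeRecord",
    "MolGraph",
    "DESCRIPTOR_NAMES",
    "ATOM_FDIM",
    "BOND_FDIM",
    "standardize",
    "descriptors",
    "maccs",
    "ecfp4",
    "build_graph",
    "featurize_table",
]


@lru_cache(maxsize=1)
def _descriptor_panel() -> list[str]:
    ref = importlib.resources.files("pvtrigger.data") / "descriptors_83.txt"
    names = [ln.strip() for ln in ref.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    assert len(names) == 83, "pinned descriptor panel must have 83 entries"
    return names


DESCRIPTOR_NAMES: tuple[str, ...] = tuple(_descriptor_panel())


@dataclass(frozen=True)
class MoleculeRecord:
    cid: str
    name: str
    smiles_raw: str
    smiles_std: str
    parse_ok: bool


def standardize(smiles_raw: str, cid: str = "", name: str = "") -> MoleculeRecord:
    """Wash a raw SMILES: largest organic fragment, neutralize, canonicalize.

    Unparseable input yields ``parse_ok=False`` (such records are excluded
    from featurization downstream rather than raising).
    """
    if not smiles_raw:
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        return MoleculeRecord(cid, name, smiles_raw, "", False)
    try:
        mol = rdMolStandardize.LargestFragmentChooser(preferOrganic=True).choose(mol)
        mol = rdMolStandardize.Uncharger().uncharge(mol)
        Chem.SanitizeMol(mol)
        smiles_std = Chem.MolToSmiles(mol)
    except Exception:  # noqa: BLE001 - any standardization failure is data
        return MoleculeRecord(cid, name, smiles_raw, "", False)
    return MoleculeRecord(cid, name, smiles_raw, smiles_std, True)


def _mol(record: MoleculeRecord) -> Chem.Mol:
    if not record.parse_ok:
        raise ValueError(f"molecule {record.cid or record.smiles_raw!r} did not parse")
    return Chem.MolFromSmiles(record.smiles_std)


def descriptors(record: MoleculeRecord) -> pd.Series:
    """The pinned 83-descriptor vector (NaN, with a warning, on failure)."""
    mol = _mol(record)
    values = []
    for dname in DESCRIPTOR_NAMES:
        try:
            values.append(float(getattr(Descriptors, dname)(mol)))
        except Exception:  # noqa: BLE001
            logger.warning("descriptor %s failed for %s", dname, record.cid)
            values.append(float("nan"))
    return pd.Series(values, index=list(DESCRIPTOR_NAMES), name=record.cid)


def maccs(record: MoleculeRecord) -> np.ndarray:
    """The 166 keyed MACCS bits (the implementation's placeholder bit 0 is
    dropped)."""
    fp = MACCSkeys.GenMACCSKeys(_mol(record))
    bits = np.zeros(fp.GetNumBits(), dtype=np.uint8)
    for b in fp.GetOnBits():
        bits[b] = 1
    return bits[1:]


@lru_cache(maxsize=1)
def _morgan_gen():
    return rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)


def ecfp4(record: MoleculeRecord) -> np.ndarray:
    """Morgan radius-2 circular fingerprint folded to 1024 bits."""
    fp = _morgan_gen().GetFingerprint(_mol(record))
    bits = np.zeros(1024, dtype=np.uint8)
    for b in fp.GetOnBits():
        bits[b] = 1
    return bits


_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")  # + 'other' slot
ATOM_FDIM = len(_ELEMENTS) + 1 + 4  # one-hot element, degree, charge, aromatic, Hs
BOND_FDIM = 6  # bond-order one-hot (4) + conjugated + in-ring


@dataclass
class MolGraph:
    """Heavy-atom molecular graph with directed-bond incidence arrays.

    ``bond_src[b] -> bond_dst[b]`` is directed bond b; ``rev[b]`` indexes its
    reverse. Bond features are shared between a bond and its reverse.
    """

    atom_features: np.ndarray          # (n_atoms, ATOM_FDIM)
    bond_features: np.ndarray          # (n_bonds_directed, BOND_FDIM)
    bond_src: np.ndarray               # (n_bonds_directed,)
    bond_dst: np.ndarray
    rev: np.ndarray

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bond_features.shape[0]


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    f = np.zeros(ATOM_FDIM, dtype=float)
    sym = atom.GetSymbol()
    f[_ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS)] = 1.0
    base = len(_ELEMENTS) + 1
    f[base + 0] = atom.GetDegree() / 4.0
    f[base + 1] = float(atom.GetFormalCharge())
    f[base + 2] = float(atom.GetIsAromatic())
    f[base + 3] = atom.GetTotalNumHs() / 4.0
    return f


_BOND_ORDER = {Chem.BondType.SINGLE: 0, Chem.BondType.DOUBLE: 1,
               Chem.BondType.TRIPLE: 2, Chem.BondType.AROMATIC: 3}


def _bond_features(bond: Chem.Bond) -> np.ndarray:
    f = np.zeros(BOND_FDIM, dtype=float)
    f[_BOND_ORDER.get(bond.GetBondType(), 0)] = 1.0
    f[4] = float(bond.GetIsConjugated())
    f[5] = float(bond.IsInRing())
    return f


def build_graph(record: MoleculeRecord) -> MolGraph:
    """Molecular graph over heavy atoms; each bond yields two directed edges."""
    mol = _mol(record)
    atoms = np.array([_atom_features(a) for a in mol.GetAtoms()], dtype=float)
    if atoms.size == 0:
        raise ValueError("molecule has no atoms")
    src, dst, feats = [], [], []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bf = _bond_features(bond)
        src += [u, v]
        dst += [v, u]
        feats += [bf, bf]
    n_b = len(src)
    rev = np.arange(n_b) ^ 1 if n_b else np.zeros(0, dtype=int)
    return MolGraph(
        atom_features=atoms,
        bond_features=(np.array(feats, dtype=float)
                       if feats else np.zeros((0, BOND_FDIM))),
        bond_src=np.array(src, dtype=int),
        bond_dst=np.array(dst, dtype=int),
        rev=np.asarray(rev, dtype=int),
    )


def featurize_table(molecules: pd.DataFrame, kind: str):
    """Featurize a (cid, drugname, smiles, ...) table; unparseable rows are
    dropped with a warning.

    ``kind``: 'descriptors' -> DataFrame (n x 83); 'maccs'/'ecfp4' ->
    DataFrame of bits; 'graph' -> list of MolGraph aligned with the returned
    index.
    """
    records = [standardize(row.smiles, cid=str(row.cid), name=str(row.drugname))
               for row in molecules.itertuples()]
    ok = [r.parse_ok for r in records]
    if not all(ok):
        logger.warning("excluding %d unparseable molecules", ok.count(False))
    kept = [r for r in records if r.parse_ok]
    idx = [r.cid for r in kept]
    if kind == "descriptors":
        return pd.DataFrame([descriptors(r) for r in kept], index=idx)
    if kind == "maccs":
        return pd.DataFrame([maccs(r) for r in kept], index=idx)
    if kind == "ecfp4":
        return pd.DataFrame([ecfp4(r) for r in kept], index=idx)
    if kind == "graph":
        return [build_graph(r) for r in kept], idx
    raise ValueError(f"unknown feature kind {kind!r}")
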