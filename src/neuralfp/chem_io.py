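"""Molecule and label ingestion.

Molecules enter as SMILES (or SDF) and are converted to heavy-atom graphs
with a canonical atom ordering, then featurized into the per-atom one-hot
matrix that seeds the fingerprint network.  Drug-ADR labels enter as a
SIDER-style four-column TSV and become a dense binary ``LabelMatrix``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

BOND_ORDERS = ("single", "double", "triple", "aromatic")
N_BOND_FEATURES = 6  # one-hot order (4) + conjugated + in-ring

_RDKIT_BOND_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


class ChemIOError(ValueError):
    """Raised for malformed molecular or label input."""


@dataclass(frozen=True)
class EncodingSpec:
    """Vocabulary and ranges of the per-atom one-hot encoding.

    The atom feature vector concatenates: one-hot element, one-hot heavy-atom
    degree (0..max_degree), one-hot attached-hydrogen count (0..max_h),
    one-hot implicit valence (0..max_valence) and a single aromaticity flag.
    Out-of-range values raise instead of clipping.
    """

    elements: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si")
    max_degree: int = 5
    max_h: int = 4
    max_valence: int = 5

    @property
    def n_features(self) -> int:
        return len(self.elements) + (self.max_degree + 1) + (self.max_h + 1) + (self.max_valence + 1) + 1


@dataclass(frozen=True)
class AtomRecord:
    element: str
    degree: int
    n_h: int
    implicit_valence: int
    is_aromatic: bool


@dataclass(frozen=True)
class BondRecord:
    a: int
    b: int
    order: str
    is_conjugated: bool
    is_in_ring: bool


@dataclass
class MoleculeGraph:
    """Heavy-atom molecular graph in canonical atom order."""

    mol_id: str
    atoms: list[AtomRecord]
    bonds: list[BondRecord]
    smiles: str = ""
    _rdmol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, j: int) -> list[tuple[int, int]]:
        """Neighbors of atom ``j`` as (atom index, bond index) pairs, ascending."""
        out = []
        for bi, bond in enumerate(self.bonds):
            if bond.a == j:
                out.append((bond.b, bi))
            elif bond.b == j:
                out.append((bond.a, bi))
        return sorted(out)

    def rdkit_mol(self) -> Chem.Mol:
        if self._rdmol is None:
            self._rdmol = Chem.MolFromSmiles(self.smiles)
        return self._rdmol


@dataclass
class AtomFeatureMatrix:
    values: np.ndarray  # (n_atoms, d_1)
    encoding: EncodingSpec


@dataclass
class LabelMatrix:
    """Dense N x M binary drug-ADR association matrix."""

    drugs: list[str]
    adrs: list[str]
    y: np.ndarray
    adr_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.y.shape != (len(self.drugs), len(self.adrs)):
            raise ChemIOError(
                f"label matrix shape {self.y.shape} does not match "
                f"{len(self.drugs)} drugs x {len(self.adrs)} ADRs"
            )
        if len(set(self.drugs)) != len(self.drugs):
            raise ChemIOError("duplicate drug ids in LabelMatrix")
        if len(set(self.adrs)) != len(self.adrs):
            raise ChemIOError("duplicate ADR ids in LabelMatrix")
        bad = set(np.unique(self.y)) - {0, 1}
        if bad:
            raise ChemIOError(f"label matrix entries must be 0/1, found {sorted(bad)}")

    @property
    def n_associations(self) -> int:
        return int(self.y.sum())

    def to_tsv(self, path) -> None:
        rows = []
        names = self.adr_names or self.adrs
        di, ai = np.nonzero(self.y)
        for d, a in zip(di, ai):
            rows.append((self.drugs[d], self.adrs[a], "PT", names[a]))
        pd.DataFrame(rows, columns=["drug_id", "adr_id", "term_type", "adr_name"]).to_csv(
            path, sep="\t", index=False, header=False
        )


def parse_molecule(smiles: str, mol_id: str | None = None, strip_salts: bool = False) -> MoleculeGraph:
    """Parse a SMILES string into a canonical-order heavy-atom graph.

    Multi-fragment inputs (salts) are rejected unless ``strip_salts`` is set,
    in which case the largest fragment (by heavy-atom count) is kept.  Atoms
    are renumbered by RDKit canonical rank so that any SMILES alias of the
    same molecule yields the same graph.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemIOError(f"malformed SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        if not strip_salts:
            raise ChemIOError(f"multi-fragment SMILES (use strip_salts to keep largest): {smiles!r}")
        mol = max(frags, key=lambda m: m.GetNumAtoms())
    order = list(np.argsort(list(Chem.CanonicalRankAtoms(mol, breakTies=True))))
    mol = Chem.RenumberAtoms(mol, [int(i) for i in order])
    Chem.SanitizeMol(mol)

    atoms = []
    for atom in mol.GetAtoms():
        atoms.append(
            AtomRecord(
                element=atom.GetSymbol(),
                degree=atom.GetDegree(),
                n_h=atom.GetTotalNumHs(),
                implicit_valence=atom.GetImplicitValence(),
                is_aromatic=atom.GetIsAromatic(),
            )
        )
    bonds = []
    for bond in mol.GetBonds():
        order_name = _RDKIT_BOND_ORDER.get(bond.GetBondType())
        if order_name is None:
            raise ChemIOError(f"unsupported bond type {bond.GetBondType()} in {smiles!r}")
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bonds.append(
            BondRecord(
                a=min(a, b),
                b=max(a, b),
                order=order_name,
                is_conjugated=bond.GetIsConjugated(),
                is_in_ring=bond.IsInRing(),
            )
        )
    bonds.sort(key=lambda bd: (bd.a, bd.b))
    return MoleculeGraph(
        mol_id=mol_id if mol_id is not None else smiles,
        atoms=atoms,
        bonds=bonds,
        smiles=Chem.MolToSmiles(mol),
        _rdmol=mol,
    )


def parse_sdf(path, strip_salts: bool = False) -> list[MoleculeGraph]:
    """Read an SDF (V2000) file into canonical molecule graphs."""
    out = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            raise ChemIOError(f"unparseable record {i} in {path}")
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        out.append(parse_molecule(Chem.MolToSmiles(mol), mol_id=mol_id, strip_salts=strip_salts))
    return out


def atom_features(mol: MoleculeGraph, encoding: EncodingSpec | None = None) -> AtomFeatureMatrix:
    """Raw layer-1 features: one row of concatenated one-hot blocks per atom."""
    enc = encoding or EncodingSpec()
    n = mol.n_atoms
    X = np.zeros((n, enc.n_features), dtype=np.float64)
    n_el = len(enc.elements)
    off_deg = n_el
    off_h = off_deg + enc.max_degree + 1
    off_val = off_h + enc.max_h + 1
    off_arom = off_val + enc.max_valence + 1
    for j, atom in enumerate(mol.atoms):
        try:
            ei = enc.elements.index(atom.element)
        except ValueError:
            raise ChemIOError(
                f"element {atom.element!r} of {mol.mol_id} not in encoding vocabulary {enc.elements}"
            ) from None
        if atom.degree > enc.max_degree:
            raise ChemIOError(f"atom degree {atom.degree} exceeds encoding range {enc.max_degree}")
        if atom.n_h > enc.max_h:
            raise ChemIOError(f"H count {atom.n_h} exceeds encoding range {enc.max_h}")
        if atom.implicit_valence > enc.max_valence:
            raise ChemIOError(
                f"implicit valence {atom.implicit_valence} exceeds encoding range {enc.max_valence}"
            )
        X[j, ei] = 1.0
        X[j, off_deg + atom.degree] = 1.0
        X[j, off_h + atom.n_h] = 1.0
        X[j, off_val + atom.implicit_valence] = 1.0
        X[j, off_arom] = float(atom.is_aromatic)
    return AtomFeatureMatrix(values=X, encoding=enc)


def bond_features(mol: MoleculeGraph) -> np.ndarray:
    """Per-bond feature rows: one-hot order + conjugated flag + in-ring flag."""
    B = np.zeros((len(mol.bonds), N_BOND_FEATURES), dtype=np.float64)
    for i, bond in enumerate(mol.bonds):
        B[i, BOND_ORDERS.index(bond.order)] = 1.0
        B[i, 4] = float(bond.is_conjugated)
        B[i, 5] = float(bond.is_in_ring)
    return B


def read_smiles_file(path, strip_salts: bool = False) -> list[MoleculeGraph]:
    """Read a SMILES file: one molecule per line, optional whitespace-separated id."""
    mols = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{i}"
            mols.append(parse_molecule(smiles, mol_id=mol_id, strip_salts=strip_salts))
    return mols


_LABEL_COLUMNS = ["drug_id", "adr_id", "term_type", "adr_name"]


def read_labels(tsv_path, term_type_filter: str = "PT") -> LabelMatrix:
    """Read a SIDER-style TSV into a binary label matrix.

    Expects four tab-separated columns (drug id, ADR concept id, MedDRA term
    type, ADR name), with or without a header row.  Only rows whose term type
    equals ``term_type_filter`` are kept; duplicate associations collapse.
    """
    df = pd.read_csv(tsv_path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 4:
        raise ChemIOError(
            f"label file {tsv_path} has {df.shape[1]} columns; "
            f"expected at least 4 ({', '.join(_LABEL_COLUMNS)})"
        )
    df = df.iloc[:, :4]
    df.columns = _LABEL_COLUMNS
    if df.iloc[0].tolist() == _LABEL_COLUMNS:
        df = df.iloc[1:]
    kept = df[df["term_type"] == term_type_filter]
    if kept.empty:
        raise ChemIOError(
            f"no rows with term type {term_type_filter!r} in {tsv_path} "
            f"(seen: {sorted(df['term_type'].unique())})"
        )
    drugs = sorted(df["drug_id"].unique())
    adr_first = kept.drop_duplicates("adr_id")
    adrs = sorted(adr_first["adr_id"])
    name_of = dict(zip(adr_first["adr_id"], adr_first["adr_name"]))
    di = {d: i for i, d in enumerate(drugs)}
    ai = {a: i for i, a in enumerate(adrs)}
    y = np.zeros((len(drugs), len(adrs)), dtype=np.int8)
    y[kept["drug_id"].map(di).to_numpy(), kept["adr_id"].map(ai).to_numpy()] = 1
    labels = LabelMatrix(drugs=drugs, adrs=adrs, y=y, adr_names=[name_of[a] for a in adrs])
    logger.info(
        "read %d drugs, %d %s ADRs, %d associations from %s",
        len(drugs), len(adrs), term_type_filter, labels.n_associations, tsv_path,
    )
    return labels


def filter_rare_adrs(labels: LabelMatrix, min_positive: int = 11) -> LabelMatrix:
    """Drop ADR columns with fewer than ``min_positive`` positive drugs.

    The SIDER convention keeps ADRs with more than 10 positive drugs, i.e.
    ``min_positive=11``.  Drugs are never dropped, even if left all-zero.
    """
    if min_positive < 1:
        raise ChemIOError("min_positive must be >= 1")
    keep = labels.y.sum(axis=0) >= min_positive
    if not keep.any():
        raise ChemIOError(f"no ADR has >= {min_positive} positive drugs; matrix would be empty")
    out = LabelMatrix(
        drugs=list(labels.drugs),
        adrs=[a for a, k in zip(labels.adrs, keep) if k],
        y=labels.y[:, keep],
        adr_names=[a for a, k in zip(labels.adr_names, keep) if k] if labels.adr_names else None,
    )
    logger.info(
        "kept %d/%d ADRs with >= %d positives (%d associations)",
        len(out.adrs), len(labels.adrs), min_positive, out.n_associations,
    )
    return out
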