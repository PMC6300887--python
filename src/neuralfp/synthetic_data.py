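"""Seeded SIDER-like synthetic corpora with known ground truth.

Molecules are assembled from small drug-like scaffolds plus random
substituents, so every molecule is valence-correct and parseable.  Binary
ADR labels are driven by planted causal motifs (by default, specific
substituents on an aromatic ring): a molecule containing the motif of ADR m
is positive with probability ``p_signal``, otherwise with ``p_noise``.
The planted motif map is returned as ground truth so that training,
back-tracing, association statistics and biclustering can all be validated
end to end without external data.

Default condition: 400 molecules, 5 ADRs, p_signal=0.9, p_noise=0.05.
Scaffold and substituent weights are fixed so that each planted motif is
present in roughly a quarter to a third of the corpus — enough positives for
both model training and well-populated contingency tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem_io import LabelMatrix, MoleculeGraph, parse_molecule


# (name, SMILES); aromatic scaffolds are upweighted so halogen-on-aromatic
# motifs reach useful prevalence
DEFAULT_SCAFFOLDS: tuple[tuple[str, str, float], ...] = (
    ("benzene", "c1ccccc1", 0.30),
    ("pyridine", "c1ccncc1", 0.20),
    ("furan", "c1ccoc1", 0.20),
    ("cyclohexane", "C1CCCCC1", 0.10),
    ("propane", "CCC", 0.05),
    ("butane", "CCCC", 0.05),
    ("pentane", "CCCCC", 0.05),
    ("hexane", "CCCCCC", 0.05),
)

# (SMILES fragment attached by a single bond, sampling weight)
DEFAULT_SUBSTITUENTS: tuple[tuple[str, float], ...] = (
    ("F", 0.25),
    ("Cl", 0.20),
    ("Br", 0.15),
    ("O", 0.10),    # hydroxyl
    ("N", 0.10),    # amino
    ("C=O", 0.10),  # formyl
    ("OC", 0.10),   # methoxy
)

DEFAULT_MOTIFS: dict[str, str] = {
    "ADR0": "cF",
    "ADR1": "cCl",
    "ADR2": "cBr",
    "ADR3": "cN",
    "ADR4": "cO",
}


@dataclass
class SyntheticSpec:
    n_molecules: int = 400
    scaffolds: tuple[tuple[str, str, float], ...] = DEFAULT_SCAFFOLDS
    substituents: tuple[tuple[str, float], ...] = DEFAULT_SUBSTITUENTS
    n_adrs: int = 5
    motifs: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    p_signal: float = 0.9
    p_noise: float = 0.05
    max_substituents: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_noise < self.p_signal <= 1):
            raise ValueError("need 0 <= p_noise < p_signal <= 1")
        if self.n_adrs > len(self.motifs):
            raise ValueError(f"only {len(self.motifs)} motifs for {self.n_adrs} ADRs")
        for adr, smarts in self.motifs.items():
            if Chem.MolFromSmarts(smarts) is None:
                raise ValueError(f"invalid motif SMARTS for {adr}: {smarts!r}")


def _attachment_sites(mol: Chem.Mol) -> list[int]:
    """Scaffold atoms that can accept one more single-bonded substituent."""
    sites = []
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C":
            continue  # keep heteroatoms of pyridine/furan unsubstituted
        if atom.GetTotalNumHs() >= 1:
            sites.append(atom.GetIdx())
    return sites


def _attach(mol: Chem.Mol, site: int, fragment: str) -> Chem.Mol | None:
    rw = Chem.RWMol(mol)
    frag = Chem.MolFromSmiles(fragment)
    amap = {}
    for atom in frag.GetAtoms():
        amap[atom.GetIdx()] = rw.AddAtom(Chem.Atom(atom.GetAtomicNum()))
    for bond in frag.GetBonds():
        rw.AddBond(amap[bond.GetBeginAtomIdx()], amap[bond.GetEndAtomIdx()], bond.GetBondType())
    rw.AddBond(site, amap[0], Chem.BondType.SINGLE)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:  # noqa: BLE001 - invalid valence: caller retries elsewhere
        return None
    return out


def generate_molecules(spec: SyntheticSpec) -> list[tuple[str, str]]:
    """Generate (id, canonical SMILES) pairs, reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    scaff_smiles = [s for _, s, _ in spec.scaffolds]
    scaff_w = np.array([w for _, _, w in spec.scaffolds], dtype=float)
    scaff_w /= scaff_w.sum()
    sub_smiles = [s for s, _ in spec.substituents]
    sub_w = np.array([w for _, w in spec.substituents], dtype=float)
    sub_w /= sub_w.sum()
    # 0..max substituents; skew toward substituted molecules so planted motifs
    # are reasonably prevalent
    n_sub_choices = np.arange(spec.max_substituents + 1)
    n_sub_w = np.array([0.1] + [0.9 / spec.max_substituents] * spec.max_substituents)

    out = []
    for i in range(spec.n_molecules):
        mol = Chem.MolFromSmiles(scaff_smiles[rng.choice(len(scaff_smiles), p=scaff_w)])
        n_subs = int(rng.choice(n_sub_choices, p=n_sub_w))
        for _ in range(n_subs):
            sites = _attachment_sites(mol)
            if not sites:
                break
            site = int(sites[rng.integers(len(sites))])
            frag = sub_smiles[rng.choice(len(sub_smiles), p=sub_w)]
            cand = _attach(mol, site, frag)
            if cand is not None:
                mol = cand
        out.append((f"D{i:04d}", Chem.MolToSmiles(mol)))
    return out


def assign_labels(
    molecules: list[tuple[str, str]], spec: SyntheticSpec
) -> tuple[LabelMatrix, dict[str, str]]:
    """Bernoulli labels from planted motifs; returns the truth map too."""
    rng = np.random.default_rng([spec.seed, 1])
    adrs = list(spec.motifs)[: spec.n_adrs]
    queries = {adr: Chem.MolFromSmarts(spec.motifs[adr]) for adr in adrs}
    rdmols = {mid: Chem.MolFromSmiles(smi) for mid, smi in molecules}
    y = np.zeros((len(molecules), len(adrs)), dtype=np.int8)
    for i, (mid, _smi) in enumerate(molecules):
        for j, adr in enumerate(adrs):
            p = spec.p_signal if rdmols[mid].HasSubstructMatch(queries[adr]) else spec.p_noise
            y[i, j] = int(rng.random() < p)
    labels = LabelMatrix(
        drugs=[mid for mid, _ in molecules], adrs=adrs, y=y,
        adr_names=[f"synthetic ADR {a}" for a in adrs],
    )
    return labels, {adr: spec.motifs[adr] for adr in adrs}


def generate_corpus(spec: SyntheticSpec):
    """Molecules (parsed), labels and motif truth in one call."""
    pairs = generate_molecules(spec)
    labels, truth = assign_labels(pairs, spec)
    mols: list[MoleculeGraph] = [parse_molecule(smi, mol_id=mid) for mid, smi in pairs]
    return mols, labels, truth


def make_bicluster_truth(
    n_rows: int = 24,
    n_cols: int = 18,
    blocks: list[tuple[list[int], list[int]]] | None = None,
    eps: float = 0.05,
    seed: int = 0,
):
    """Block-structured binary matrix with Bernoulli flip noise.

    Default truth: two disjoint all-ones blocks on a zero background.
    Returns (matrix, blocks).
    """
    if blocks is None:
        blocks = [
            (list(range(0, n_rows // 3)), list(range(0, n_cols // 3))),
            (list(range(n_rows // 2, n_rows // 2 + n_rows // 3)),
             list(range(n_cols // 2, n_cols // 2 + n_cols // 3))),
        ]
    rng = np.random.default_rng([seed, 2])
    A = np.zeros((n_rows, n_cols), dtype=np.int8)
    for rows, cols in blocks:
        A[np.ix_(rows, cols)] = 1
    if eps > 0:
        flips = rng.random(A.shape) < eps
        A = np.where(flips, 1 - A, A).astype(np.int8)
    return A, blocks
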