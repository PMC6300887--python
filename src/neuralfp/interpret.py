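"""Back-trace trained models to atom-centered substructures.

Fingerprint bits are ranked by their (linearized) head weight; for a top
bit, the per-(atom, level) softmax write activations from the forward pass
locate where in which molecules the bit is written, and the atom-centered
neighborhood of radius equal to the write level is extracted as a canonical
SMARTS pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chem_io import MoleculeGraph
from .neural_fingerprint import fingerprint
from .predictor import ADRModel

logger = logging.getLogger(__name__)


@dataclass
class SubstructureHit:
    smarts: str
    source_mol: str
    center_atom: int
    radius: int
    bit: int
    activation: float
    head_weight: float


def bit_importances(model: ADRModel) -> np.ndarray:
    """Signed per-bit head contribution.

    Linear head: the weight vector itself.  Hidden-layer head: first-order
    path-summed contribution sum_h W1[k,h] * W2[h] (batch-norm scale folded
    in), a linearization of the bit's effect on the logit.
    """
    head = model.head
    if not head.hidden_units:
        return head.w.copy()
    scale = head.W2
    if head.batch_norm:
        scale = head.gamma / np.sqrt(head.bn_var + 1e-5) * head.W2
    return head.W1 @ scale


def top_bits(model: ADRModel, n: int) -> list[tuple[int, float]]:
    """Top-n bits by |importance|, descending; ties broken by bit index."""
    imp = bit_importances(model)
    K = len(imp)
    if n > K:
        logger.warning("requested %d bits but fingerprint has %d; clipping", n, K)
        n = K
    order = sorted(range(K), key=lambda k: (-abs(imp[k]), k))
    return [(k, float(imp[k])) for k in order[:n]]


def atom_activations(model: ADRModel, mol: MoleculeGraph, bit: int) -> list[tuple[int, int, float]]:
    """Per-(atom, level) softmax write values for one bit."""
    if bit >= model.fp_params.K:
        raise ValueError(f"bit {bit} out of range for K={model.fp_params.K}")
    _, act = fingerprint(mol, model.fp_params, return_activations=True)
    out = []
    for a in range(act.shape[0]):
        for li, level in enumerate(model.fp_params.write_levels):
            out.append((a, level, float(act[a, li, bit])))
    return out


def extract_substructure(mol: MoleculeGraph, center_atom: int, radius: int) -> str:
    """Canonical SMARTS of the induced subgraph within ``radius`` bonds of center.

    Elements, aromaticity and bond orders are preserved (charges and stereo
    are not part of the raw features and are dropped).
    """
    rdmol = mol.rdkit_mol()
    if radius < 0:
        raise ValueError("radius must be >= 0")
    dists = Chem.GetDistanceMatrix(rdmol)
    atoms = [int(i) for i in range(rdmol.GetNumAtoms()) if dists[center_atom][i] <= radius]
    return Chem.MolFragmentToSmiles(rdmol, atomsToUse=atoms, canonical=True, allBondsExplicit=True)


def smarts_to_query(smarts: str) -> Chem.Mol:
    q = Chem.MolFromSmarts(smarts)
    if q is None:
        raise ValueError(f"invalid SMARTS: {smarts!r}")
    return q


def collect_substructures(
    model: ADRModel,
    molecules: list[MoleculeGraph],
    top_n_bits: int = 10,
    per_bit_atoms: int = 5,
    threshold: float | None = None,
) -> list[SubstructureHit]:
    """Back-trace the model over a molecule set.

    For each of the top bits, scan the molecules the model predicts positive
    (falling back to the 10 highest-scored molecules when none cross the
    threshold), take the ``per_bit_atoms`` highest-activation (atom, level)
    pairs, extract the centered substructures and deduplicate by canonical
    SMARTS, keeping the maximal activation per pattern.
    """
    if not molecules:
        return []
    thr = model.config.threshold if threshold is None else threshold
    probs = model.predict_proba(molecules)
    pos_idx = [i for i, p in enumerate(probs) if p >= thr]
    if not pos_idx:
        pos_idx = list(np.argsort(-probs)[:10])
        logger.warning("no molecule predicted positive at %.2f; using top-10 scored", thr)

    # one forward pass with activations per candidate molecule
    acts = {}
    for i in pos_idx:
        _, act = fingerprint(molecules[i], model.fp_params, return_activations=True)
        acts[i] = act

    levels = model.fp_params.write_levels
    best: dict[str, SubstructureHit] = {}
    for bit, weight in top_bits(model, top_n_bits):
        candidates = []  # (activation, mol index, atom, level)
        for i in pos_idx:
            act = acts[i]
            for a in range(act.shape[0]):
                for li, level in enumerate(levels):
                    candidates.append((float(act[a, li, bit]), i, a, level))
        candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
        for activation, i, a, level in candidates[:per_bit_atoms]:
            smarts = extract_substructure(molecules[i], a, level)
            hit = SubstructureHit(
                smarts=smarts, source_mol=molecules[i].mol_id, center_atom=a,
                radius=level, bit=bit, activation=activation, head_weight=weight,
            )
            prev = best.get(smarts)
            if prev is None or activation > prev.activation:
                best[smarts] = hit
    return sorted(best.values(), key=lambda h: (-h.activation, h.smarts))


def hits_to_rows(hits: list[SubstructureHit]) -> list[dict]:
    return [
        {
            "bit": h.bit, "head_weight": h.head_weight, "smarts": h.smarts,
            "source_mol": h.source_mol, "center_atom": h.center_atom,
            "radius": h.radius, "activation": h.activation,
        }
        for h in hits
    ]
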