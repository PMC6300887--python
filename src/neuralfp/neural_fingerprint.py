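"""Differentiable attention-based neural fingerprints.

A molecule's atoms carry one-hot raw features (layer 0).  Each of R
convolution layers concatenates an atom's features with its neighbors'
features and bond features, applies a degree-specific dense filter and a
smoothing nonlinearity, producing representations of atom-centered
substructures of growing radius.  At every level 0..R each atom writes a
softmax "attention" distribution over the K fingerprint bits; summing the
writes over atoms and levels gives the fixed-length fingerprint z.

Because every per-atom write is a probability vector, sum(z) equals
n_atoms * n_write_levels for any weights — a mass-conservation invariant
used throughout the tests.

Everything here is plain NumPy with hand-written reverse-mode gradients;
molecules are packed into flat arrays grouped by atom degree so a whole
minibatch runs as a handful of dense matrix products.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

from .chem_io import (
    EncodingSpec,
    MoleculeGraph,
    N_BOND_FEATURES,
    atom_features,
    bond_features,
)

MAX_FILTER_DEGREE = 5  # one filter per degree 1..5; degree 0 reuses filter 1


class FingerprintError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class FingerprintParams:
    """All learnable weights of the fingerprint network.

    H[l][deg] is the filter for atoms of degree ``deg`` at layer ``l``
    (0-based), of shape (d_l + deg*(d_l + 6), d_{l+1}).  F[l] maps level-l
    atom features to write logits over the K bits.  b[l] is a per-layer bias
    vector (a vector subsumes the scalar bias of the original formulation).
    """

    R: int
    K: int
    dims: list[int]  # d_1..d_{R+1}
    H: list[dict[int, np.ndarray]]
    b: list[np.ndarray]
    F: list[np.ndarray]
    activation: str = "tanh"
    write_levels: tuple[int, ...] = ()
    encoding: EncodingSpec = field(default_factory=EncodingSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.write_levels:
            self.write_levels = tuple(range(self.R + 1))
        for mats in self.H:
            for m in mats.values():
                if not np.all(np.isfinite(m)):
                    raise FingerprintError("non-finite filter weights")

    @property
    def n_write_levels(self) -> int:
        return len(self.write_levels)

    def copy(self) -> "FingerprintParams":
        return FingerprintParams(
            R=self.R,
            K=self.K,
            dims=list(self.dims),
            H=[{d: m.copy() for d, m in layer.items()} for layer in self.H],
            b=[v.copy() for v in self.b],
            F=[m.copy() for m in self.F],
            activation=self.activation,
            write_levels=self.write_levels,
            encoding=self.encoding,
            seed=self.seed,
        )

    # -- flat parameter access used by the optimizer and gradient checks ----

    def keys(self) -> list[tuple]:
        ks: list[tuple] = []
        for l in range(self.R):
            for deg in range(1, MAX_FILTER_DEGREE + 1):
                ks.append(("H", l, deg))
            ks.append(("b", l))
        for l in range(self.R + 1):
            ks.append(("F", l))
        return ks

    def get(self, key: tuple) -> np.ndarray:
        if key[0] == "H":
            return self.H[key[1]][key[2]]
        if key[0] == "b":
            return self.b[key[1]]
        return self.F[key[1]]

    def save(self, path) -> None:
        """Write a single-archive checkpoint: matrices + JSON header."""
        header = {
            "R": self.R,
            "K": self.K,
            "dims": self.dims,
            "activation": self.activation,
            "write_levels": list(self.write_levels),
            "seed": self.seed,
            "encoding": {
                "elements": list(self.encoding.elements),
                "max_degree": self.encoding.max_degree,
                "max_h": self.encoding.max_h,
                "max_valence": self.encoding.max_valence,
            },
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("header.json", json.dumps(header))
            for key in self.keys():
                buf = io.BytesIO()
                np.save(buf, self.get(key))
                zf.writestr(".".join(str(k) for k in key) + ".npy", buf.getvalue())

    @classmethod
    def load(cls, path) -> "FingerprintParams":
        with zipfile.ZipFile(path) as zf:
            header = json.loads(zf.read("header.json"))
            enc = EncodingSpec(
                elements=tuple(header["encoding"]["elements"]),
                max_degree=header["encoding"]["max_degree"],
                max_h=header["encoding"]["max_h"],
                max_valence=header["encoding"]["max_valence"],
            )
            R = header["R"]
            H: list[dict[int, np.ndarray]] = [dict() for _ in range(R)]
            b: list[np.ndarray] = [None] * R  # type: ignore[list-item]
            F: list[np.ndarray] = [None] * (R + 1)  # type: ignore[list-item]
            for name in zf.namelist():
                if not name.endswith(".npy"):
                    continue
                arr = np.load(io.BytesIO(zf.read(name)))
                parts = name[:-4].split(".")
                if parts[0] == "H":
                    H[int(parts[1])][int(parts[2])] = arr
                elif parts[0] == "b":
                    b[int(parts[1])] = arr
                elif parts[0] == "F":
                    F[int(parts[1])] = arr
        return cls(
            R=R,
            K=header["K"],
            dims=header["dims"],
            H=H,
            b=b,
            F=F,
            activation=header["activation"],
            write_levels=tuple(header["write_levels"]),
            encoding=enc,
            seed=header["seed"],
        )


@dataclass
class Fingerprint:
    z: np.ndarray  # (K,)


def init_params(
    R: int,
    K: int,
    encoding: EncodingSpec | None = None,
    hidden_dims: list[int] | None = None,
    seed: int = 0,
    activation: str = "tanh",
    write_levels: tuple[int, ...] | None = None,
) -> FingerprintParams:
    """Draw fingerprint weights from a 1/sqrt(fan-in)-scaled normal."""
    if R < 1 or K < 1:
        raise FingerprintError(f"R and K must be positive, got R={R}, K={K}")
    enc = encoding or EncodingSpec()
    d1 = enc.n_features
    dims = [d1] + (hidden_dims if hidden_dims is not None else [d1] * R)
    if len(dims) != R + 1:
        raise FingerprintError(f"need {R} hidden dims, got {len(dims) - 1}")
    if any(d < 1 for d in dims):
        raise FingerprintError("non-positive layer dimension")
    rng = np.random.default_rng(seed)
    H: list[dict[int, np.ndarray]] = []
    b: list[np.ndarray] = []
    for l in range(R):
        layer = {}
        for deg in range(1, MAX_FILTER_DEGREE + 1):
            fan_in = dims[l] + deg * (dims[l] + N_BOND_FEATURES)
            layer[deg] = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, dims[l + 1]))
        H.append(layer)
        b.append(np.zeros(dims[l + 1]))
    F = [
        rng.normal(0.0, 1.0 / np.sqrt(dims[l]), size=(dims[l], K))
        for l in range(R + 1)
    ]
    return FingerprintParams(
        R=R, K=K, dims=dims, H=H, b=b, F=F,
        activation=activation,
        write_levels=tuple(write_levels) if write_levels is not None else tuple(range(R + 1)),
        encoding=enc, seed=seed,
    )


# ---------------------------------------------------------------------------
# Packing molecules into degree-grouped flat arrays


@dataclass
class FeaturizedMolecule:
    mol_id: str
    n_atoms: int
    X0: np.ndarray  # (n_atoms, d_1)
    # per-degree: (local atom indices, neighbor indices (g, deg), bond features (g, deg*6))
    groups: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]


def featurize_molecule(mol: MoleculeGraph, encoding: EncodingSpec | None = None) -> FeaturizedMolecule:
    enc = encoding or EncodingSpec()
    by_degree: dict[int, list[int]] = {}
    nbrs = [mol.neighbors(j) for j in range(mol.n_atoms)]
    for j, nb in enumerate(nbrs):
        deg = len(nb)
        if deg > MAX_FILTER_DEGREE:
            raise FingerprintError(
                f"atom {j} of {mol.mol_id} has degree {deg}: no filter for degree > {MAX_FILTER_DEGREE}"
            )
        by_degree.setdefault(deg, []).append(j)
    X0 = atom_features(mol, enc).values
    B = bond_features(mol)
    groups = {}
    for deg, atom_idx in sorted(by_degree.items()):
        g = len(atom_idx)
        nbr_idx = np.zeros((g, deg), dtype=np.intp)
        bond = np.zeros((g, deg * N_BOND_FEATURES))
        for r, j in enumerate(atom_idx):
            for k, (n, bi) in enumerate(nbrs[j]):  # canonical: ascending atom index
                nbr_idx[r, k] = n
                bond[r, k * N_BOND_FEATURES : (k + 1) * N_BOND_FEATURES] = B[bi]
        groups[deg] = (np.asarray(atom_idx, dtype=np.intp), nbr_idx, bond)
    return FeaturizedMolecule(mol_id=mol.mol_id, n_atoms=mol.n_atoms, X0=X0, groups=groups)


@dataclass
class PackedGraphs:
    """A batch of molecules flattened into shared arrays."""

    n_mols: int
    n_atoms: int
    X0: np.ndarray  # (A, d_1)
    mol_index: np.ndarray  # (A,) molecule id per atom
    atom_offsets: np.ndarray  # (n_mols + 1,)
    groups: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]

    @classmethod
    def pack(cls, feats: list[FeaturizedMolecule]) -> "PackedGraphs":
        offsets = np.zeros(len(feats) + 1, dtype=np.intp)
        for i, f in enumerate(feats):
            offsets[i + 1] = offsets[i] + f.n_atoms
        A = int(offsets[-1])
        X0 = np.concatenate([f.X0 for f in feats], axis=0)
        mol_index = np.repeat(np.arange(len(feats), dtype=np.intp), [f.n_atoms for f in feats])
        degs = sorted({d for f in feats for d in f.groups})
        groups = {}
        for deg in degs:
            ai, ni, bo = [], [], []
            for i, f in enumerate(feats):
                if deg in f.groups:
                    a, n, bnd = f.groups[deg]
                    ai.append(a + offsets[i])
                    ni.append(n + offsets[i])
                    bo.append(bnd)
            groups[deg] = (
                np.concatenate(ai),
                np.concatenate(ni, axis=0),
                np.concatenate(bo, axis=0),
            )
        return cls(n_mols=len(feats), n_atoms=A, X0=X0, mol_index=mol_index,
                   atom_offsets=offsets, groups=groups)


# ---------------------------------------------------------------------------
# Forward / backward


def _activation_fns(name: str):
    if name == "tanh":
        return np.tanh, lambda out, pre: 1.0 - out * out
    if name == "relu":
        return lambda u: np.maximum(u, 0.0), lambda out, pre: (pre > 0).astype(float)
    raise FingerprintError(f"unknown activation {name!r}")


@dataclass
class ForwardCache:
    X: list[np.ndarray]  # per level 0..R: (A, d_l)
    pre: list[dict[int, np.ndarray]]  # per layer, per degree: pre-activations U
    V: list[dict[int, np.ndarray]]  # per layer, per degree: concatenated inputs
    writes: dict[int, np.ndarray]  # per write level: (A, K) softmax contributions


def forward(packed: PackedGraphs, params: FingerprintParams) -> tuple[np.ndarray, ForwardCache]:
    """Run the fingerprint network over a packed batch.

    Returns (Z, cache): Z of shape (n_mols, K); cache holds everything the
    backward pass and the interpretation module need.
    """
    f, _ = _activation_fns(params.activation)
    dims = params.dims
    X = [packed.X0]
    pre: list[dict[int, np.ndarray]] = []
    V: list[dict[int, np.ndarray]] = []
    for l in range(params.R):
        Xl = X[l]
        d = dims[l]
        Xn = np.zeros((packed.n_atoms, dims[l + 1]))
        pre_l: dict[int, np.ndarray] = {}
        V_l: dict[int, np.ndarray] = {}
        for deg, (atom_idx, nbr_idx, bond) in packed.groups.items():
            if deg == 0:
                # isolated atom: reuse the degree-1 filter with a zero neighbor block
                v = np.concatenate(
                    [Xl[atom_idx], np.zeros((len(atom_idx), d + N_BOND_FEATURES))], axis=1
                )
                Hmat = params.H[l][1]
            else:
                parts = [Xl[atom_idx]]
                for k in range(deg):
                    parts.append(Xl[nbr_idx[:, k]])
                    parts.append(bond[:, k * N_BOND_FEATURES : (k + 1) * N_BOND_FEATURES])
                v = np.concatenate(parts, axis=1)
                Hmat = params.H[l][deg]
            u = v @ Hmat + params.b[l]
            Xn[atom_idx] = f(u)
            pre_l[deg] = u
            V_l[deg] = v
        if not np.all(np.isfinite(Xn)):
            raise FingerprintError(f"non-finite activations at layer {l}")
        X.append(Xn)
        pre.append(pre_l)
        V.append(V_l)

    Z = np.zeros((packed.n_mols, params.K))
    writes: dict[int, np.ndarray] = {}
    for l in params.write_levels:
        logits = X[l] @ params.F[l]
        logits -= logits.max(axis=1, keepdims=True)
        C = np.exp(logits)
        C /= C.sum(axis=1, keepdims=True)
        writes[l] = C
        np.add.at(Z, packed.mol_index, C)
    return Z, ForwardCache(X=X, pre=pre, V=V, writes=writes)


def backward(
    packed: PackedGraphs,
    params: FingerprintParams,
    cache: ForwardCache,
    dZ: np.ndarray,
) -> dict[tuple, np.ndarray]:
    """Reverse-mode gradients of sum(dZ * Z) w.r.t. all fingerprint weights."""
    _, fprime = _activation_fns(params.activation)
    dims = params.dims
    grads: dict[tuple, np.ndarray] = {k: np.zeros_like(params.get(k)) for k in params.keys()}
    dX = [np.zeros_like(x) for x in cache.X]

    for l, C in cache.writes.items():
        dC = dZ[packed.mol_index]
        s = (dC * C).sum(axis=1, keepdims=True)
        dlogits = C * (dC - s)
        grads[("F", l)] += cache.X[l].T @ dlogits
        dX[l] += dlogits @ params.F[l].T

    for l in range(params.R - 1, -1, -1):
        d = dims[l]
        for deg, (atom_idx, nbr_idx, _bond) in packed.groups.items():
            out = cache.X[l + 1][atom_idx]
            dU = dX[l + 1][atom_idx] * fprime(out, cache.pre[l][deg])
            eff_deg = max(deg, 1)
            grads[("H", l, eff_deg)] += cache.V[l][deg].T @ dU
            grads[("b", l)] += dU.sum(axis=0)
            dV = dU @ params.H[l][eff_deg].T
            dX[l][atom_idx] += dV[:, :d]
            for k in range(deg):
                start = d + k * (d + N_BOND_FEATURES)
                np.add.at(dX[l], nbr_idx[:, k], dV[:, start : start + d])
    return grads


# ---------------------------------------------------------------------------
# Single-molecule conveniences


def neighbor_concat(X_l: np.ndarray, mol: MoleculeGraph, j: int, layer_bonds: np.ndarray | None = None) -> np.ndarray:
    """Concatenate atom j's features with each neighbor's features + bond features.

    Reference implementation of the expansion step used by the packed forward
    pass; neighbor order is canonical ascending atom index.
    """
    nb = mol.neighbors(j)
    if len(nb) > MAX_FILTER_DEGREE:
        raise FingerprintError(f"no filter for degree {len(nb)}")
    B = layer_bonds if layer_bonds is not None else bond_features(mol)
    parts = [X_l[j]]
    for n, bi in nb:
        parts.append(X_l[n])
        parts.append(B[bi])
    return np.concatenate(parts)


def layer_update(X_l: np.ndarray, mol: MoleculeGraph, params: FingerprintParams, l: int) -> np.ndarray:
    """One convolution layer on a single molecule (loop form, used as reference)."""
    f, _ = _activation_fns(params.activation)
    d = X_l.shape[1]
    B = bond_features(mol)
    rows = []
    for j in range(mol.n_atoms):
        deg = len(mol.neighbors(j))
        v = neighbor_concat(X_l, mol, j, B)
        if deg == 0:
            v = np.concatenate([v, np.zeros(d + N_BOND_FEATURES)])
        rows.append(f(v @ params.H[l][max(deg, 1)] + params.b[l]))
    out = np.vstack(rows)
    if not np.all(np.isfinite(out)):
        raise FingerprintError(f"non-finite activations at layer {l}")
    return out


def write_contribution(X_l: np.ndarray, F_l: np.ndarray) -> np.ndarray:
    """Per-atom softmax write over the K fingerprint bits; rows sum to 1."""
    logits = X_l @ F_l
    logits = logits - logits.max(axis=1, keepdims=True)
    C = np.exp(logits)
    return C / C.sum(axis=1, keepdims=True)


def fingerprint(
    mol: MoleculeGraph,
    params: FingerprintParams,
    return_activations: bool = False,
):
    """Fingerprint one molecule.

    With ``return_activations`` also returns the (n_atoms, n_write_levels, K)
    tensor of per-atom softmax writes used by the interpretation module.
    """
    packed = PackedGraphs.pack([featurize_molecule(mol, params.encoding)])
    Z, cache = forward(packed, params)
    fp = Fingerprint(z=Z[0])
    if not return_activations:
        return fp
    act = np.stack([cache.writes[l] for l in params.write_levels], axis=1)
    return fp, act


def fingerprint_gradients(
    mol: MoleculeGraph,
    params: FingerprintParams,
    upstream: np.ndarray,
) -> dict[tuple, np.ndarray]:
    """Gradients of dot(upstream, z) w.r.t. all fingerprint parameters."""
    packed = PackedGraphs.pack([featurize_molecule(mol, params.encoding)])
    _, cache = forward(packed, params)
    return backward(packed, params, cache, np.asarray(upstream)[None, :])
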