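"""SMILES-derived drug representations.

Three representations of a compound are used across the framework:

* a molecular graph with per-atom and per-bond feature vectors, consumed by
  the graph-attention encoder (the learnable drug representation);
* extended-connectivity fingerprints (ECFP), the precomputed baseline
  representation used by the base model preset and the elastic-net control;
* Bemis-Murcko scaffolds, the grouping key for leakage-free drug splits.

The encoder follows the AttentiveFP recipe: a few rounds of attention-weighted
neighbour aggregation with a gated recurrent state update per atom, then a
molecule-level "super node" that attends over atoms with the same update rule.
Its final state, linearly projected, is the drug latent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

from ._autodiff import Tensor, concat, no_grad, segment_sum, softmax_over_segments

RDLogger.DisableLog("rdApp.*")
logger = logging.getLogger("mmdrp")

__all__ = [
    "MolecularGraph", "featurize_smiles", "ecfp", "murcko_scaffold",
    "AttentiveFPEncoder", "ATOM_FEATURE_NAMES",
]

_ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "other"]
_HYBRID = ["SP", "SP2", "SP3", "SP3D", "SP3D2", "other"]
_DEGREES = list(range(6))
_H_COUNTS = list(range(5))
_BOND_TYPES = ["SINGLE", "DOUBLE", "TRIPLE", "AROMATIC"]
_STEREO = ["STEREONONE", "STEREOZ", "STEREOE", "other"]

ATOM_FEATURE_NAMES: list[str] = (
    [f"element={e}" for e in _ELEMENTS]
    + [f"degree={d}" for d in _DEGREES]
    + ["formal_charge"]
    + [f"hybridization={h}" for h in _HYBRID]
    + ["aromatic"]
    + [f"num_h={h}" for h in _H_COUNTS]
)

BOND_FEATURE_NAMES: list[str] = (
    [f"bond={b}" for b in _BOND_TYPES]
    + ["conjugated", "in_ring"]
    + [f"stereo={s}" for s in _STEREO]
)


def _one_hot(value, choices) -> list[float]:
    vec = [0.0] * len(choices)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0  # trailing "other" bucket
    return vec


@dataclass
class MolecularGraph:
    """Undirected molecular graph over heavy atoms.

    Each bond is stored once; consumers expand it symmetrically.
    """

    atom_features: np.ndarray          # (n_atoms, n_atom_features)
    bonds: list[tuple[int, int]]       # each bond once, (i, j) with i, j valid
    bond_features: np.ndarray          # (n_bonds, n_bond_features)
    smiles: str                        # canonical SMILES of origin
    atom_symbols: list[str] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES does not parse: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise ValueError(f"SMILES describes an empty molecule: {smiles!r}")
    return mol


def featurize_smiles(smiles: str) -> MolecularGraph:
    """Parse SMILES into a :class:`MolecularGraph` (hydrogens implicit).

    The atom feature layout is fixed and documented in
    :data:`ATOM_FEATURE_NAMES`; out-of-vocabulary elements map to the
    trailing ``other`` bucket with a logged warning.
    """
    mol = _mol_from_smiles(smiles)
    atom_rows: list[list[float]] = []
    symbols: list[str] = []
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        if symbol not in _ELEMENTS:
            logger.warning("out-of-vocabulary element %r in %r mapped to 'other'",
                           symbol, smiles)
        row = (
            _one_hot(symbol, _ELEMENTS)
            + _one_hot(atom.GetDegree(), _DEGREES)
            + [float(atom.GetFormalCharge())]
            + _one_hot(str(atom.GetHybridization()), _HYBRID)
            + [1.0 if atom.GetIsAromatic() else 0.0]
            + _one_hot(atom.GetTotalNumHs(), _H_COUNTS)
        )
        atom_rows.append(row)
        symbols.append(symbol)
    bonds: list[tuple[int, int]] = []
    bond_rows: list[list[float]] = []
    for bond in mol.GetBonds():
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        bond_rows.append(
            _one_hot(str(bond.GetBondType()), _BOND_TYPES)
            + [1.0 if bond.GetIsConjugated() else 0.0,
               1.0 if bond.IsInRing() else 0.0]
            + _one_hot(str(bond.GetStereo()), _STEREO)
        )
    n_bf = len(BOND_FEATURE_NAMES)
    return MolecularGraph(
        atom_features=np.asarray(atom_rows, dtype=np.float64),
        bonds=bonds,
        bond_features=(np.asarray(bond_rows, dtype=np.float64)
                       if bond_rows else np.zeros((0, n_bf))),
        smiles=Chem.MolToSmiles(mol),
        atom_symbols=symbols,
    )


def ecfp(smiles: str, radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    """Extended-connectivity (Morgan) fingerprint as a {0,1} vector."""
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprintAsNumPy(mol)
    return fp.astype(np.float64)


def murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis-Murcko scaffold SMILES.

    Acyclic molecules have an empty scaffold; they map to
    ``ACYCLIC:<canonical smiles>`` so each forms its own group in
    scaffold-based splits.
    """
    mol = _mol_from_smiles(smiles)
    scaffold = MurckoScaffold.MurckoScaffoldSmiles(mol=mol)
    if scaffold == "":
        return f"ACYCLIC:{Chem.MolToSmiles(mol)}"
    return scaffold


# ---------------------------------------------------------------------------
# graph-attention encoder
# ---------------------------------------------------------------------------

class _GRUCell:
    """Gated recurrent update h' = (1-z)*h + z*htilde."""

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        def w(n_in, n_out):
            return Tensor.param(rng.normal(0.0, 1.0 / np.sqrt(n_in), (n_in, n_out)))

        self.Wz, self.Uz = w(input_dim, hidden_dim), w(hidden_dim, hidden_dim)
        self.Wr, self.Ur = w(input_dim, hidden_dim), w(hidden_dim, hidden_dim)
        self.Wh, self.Uh = w(input_dim, hidden_dim), w(hidden_dim, hidden_dim)
        self.bz = Tensor.param(np.zeros(hidden_dim))
        self.br = Tensor.param(np.zeros(hidden_dim))
        self.bh = Tensor.param(np.zeros(hidden_dim))

    def params(self) -> list[Tensor]:
        return [self.Wz, self.Uz, self.Wr, self.Ur, self.Wh, self.Uh,
                self.bz, self.br, self.bh]

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        z = (x @ self.Wz + h @ self.Uz + self.bz).sigmoid()
        r = (x @ self.Wr + h @ self.Ur + self.br).sigmoid()
        htilde = (x @ self.Wh + (r * h) @ self.Uh + self.bh).tanh()
        return (1.0 - z) * h + z * htilde


class AttentiveFPEncoder:
    """Attention-based molecular graph encoder producing a drug latent.

    ``k_atom_rounds`` rounds of atom-level message passing (attention over
    bonded neighbours, bond features folded into the neighbour message,
    shared GRU state update) followed by ``t_mol_rounds`` rounds in which a
    virtual super node attends over all atoms. Deterministic given
    parameters; dropout applies only when ``train=True`` and an RNG is
    supplied.
    """

    def __init__(self, hidden_dim: int = 64, latent_dim: int = 32,
                 k_atom_rounds: int = 2, t_mol_rounds: int = 2,
                 dropout: float = 0.1, seed: int = 0):
        self.hidden_dim = hidden_dim
        self.latent_dim = latent_dim
        self.k_atom_rounds = k_atom_rounds
        self.t_mol_rounds = t_mol_rounds
        self.dropout = dropout
        rng = np.random.default_rng(seed)
        n_af, n_bf = len(ATOM_FEATURE_NAMES), len(BOND_FEATURE_NAMES)

        def w(n_in, n_out):
            return Tensor.param(rng.normal(0.0, 1.0 / np.sqrt(n_in), (n_in, n_out)))

        h = hidden_dim
        self.W_atom, self.b_atom = w(n_af, h), Tensor.param(np.zeros(h))
        self.W_nei, self.b_nei = w(h + n_bf, h), Tensor.param(np.zeros(h))
        self.w_align, self.b_align = w(2 * h, 1), Tensor.param(np.zeros(1))
        self.W_ctx = w(h, h)
        self.gru_atom = _GRUCell(h, h, rng)
        self.w_malign, self.b_malign = w(2 * h, 1), Tensor.param(np.zeros(1))
        self.W_mctx = w(h, h)
        self.gru_mol = _GRUCell(h, h, rng)
        self.W_out, self.b_out = w(h, latent_dim), Tensor.param(np.zeros(latent_dim))

    def params(self) -> list[Tensor]:
        ps = [self.W_atom, self.b_atom, self.W_nei, self.b_nei,
              self.w_align, self.b_align, self.W_ctx,
              self.w_malign, self.b_malign, self.W_mctx,
              self.W_out, self.b_out]
        return ps + self.gru_atom.params() + self.gru_mol.params()

    # -- forward --------------------------------------------------------------
    def _edges(self, graph: MolecularGraph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Directed edge arrays (src, dst, bond features); isolated atoms get a
        zero-featured self-loop so their context reduces to self."""
        n_bf = graph.bond_features.shape[1] if graph.bond_features.size else len(BOND_FEATURE_NAMES)
        src, dst, feats = [], [], []
        degree = np.zeros(graph.n_atoms, dtype=int)
        for (i, j), bf in zip(graph.bonds, graph.bond_features):
            src += [i, j]
            dst += [j, i]
            feats += [bf, bf]
            degree[i] += 1
            degree[j] += 1
        for v in np.nonzero(degree == 0)[0]:
            src.append(v)
            dst.append(v)
            feats.append(np.zeros(n_bf))
        return (np.asarray(src, dtype=np.intp), np.asarray(dst, dtype=np.intp),
                np.asarray(feats, dtype=np.float64))

    def forward(self, graph: MolecularGraph, atom_input: Tensor | None = None,
                train: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        """Encode one molecule; returns a ``(1, latent_dim)`` tensor.

        ``atom_input`` lets callers substitute a differentiable leaf tensor of
        atom features (used by integrated-gradients attribution).
        """
        if graph.n_atoms == 0:
            raise ValueError("cannot encode an empty molecular graph")
        x = atom_input if atom_input is not None else Tensor(graph.atom_features)
        src, dst, bond_feats = self._edges(graph)
        bf = Tensor(bond_feats)
        n = graph.n_atoms

        h = (x @ self.W_atom + self.b_atom).leaky_relu()
        for _ in range(self.k_atom_rounds):
            nei = concat([h.take(src), bf], axis=1)
            nei = (nei @ self.W_nei + self.b_nei).leaky_relu()
            scores = (concat([h.take(dst), nei], axis=1) @ self.w_align
                      + self.b_align).leaky_relu()
            alpha = softmax_over_segments(scores, dst, n)
            ctx = segment_sum(alpha * (nei @ self.W_ctx), dst, n)
            h = self.gru_atom(ctx, h)
            h = self._maybe_dropout(h, train, rng)

        s = h.sum(axis=0, keepdims=True)
        ones = np.zeros(n, dtype=np.intp)  # all atoms -> segment 0
        for _ in range(self.t_mol_rounds):
            s_rows = s.take(ones)
            scores = (concat([s_rows, h], axis=1) @ self.w_malign
                      + self.b_malign).leaky_relu()
            alpha = softmax_over_segments(scores, ones, 1)
            ctx = segment_sum(alpha * (h @ self.W_mctx), ones, 1)
            s = self.gru_mol(ctx, s)
        return s @ self.W_out + self.b_out

    def _maybe_dropout(self, h: Tensor, train: bool,
                       rng: np.random.Generator | None) -> Tensor:
        if not train or self.dropout <= 0.0 or rng is None:
            return h
        keep = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
        return h * Tensor(keep)

    def forward_batch(self, graphs: list[MolecularGraph], train: bool = False,
                      rng: np.random.Generator | None = None) -> Tensor:
        """Encode many molecules as one disjoint graph; returns (n_mols, d).

        Equivalent to stacking :meth:`forward` outputs (within float
        round-off) but with one set of matrix ops over all atoms, which is
        what makes training on a drug panel cheap.
        """
        if not graphs:
            raise ValueError("empty molecule list")
        atom_blocks, srcs, dsts, feats, mol_of_atom = [], [], [], [], []
        offset = 0
        for g, graph in enumerate(graphs):
            if graph.n_atoms == 0:
                raise ValueError("cannot encode an empty molecular graph")
            atom_blocks.append(graph.atom_features)
            s, d, f = self._edges(graph)
            srcs.append(s + offset)
            dsts.append(d + offset)
            feats.append(f)
            mol_of_atom.append(np.full(graph.n_atoms, g, dtype=np.intp))
            offset += graph.n_atoms
        x = Tensor(np.vstack(atom_blocks))
        src = np.concatenate(srcs)
        dst = np.concatenate(dsts)
        bf = Tensor(np.vstack(feats))
        mol_of_atom = np.concatenate(mol_of_atom)
        n_atoms, n_mols = offset, len(graphs)

        h = (x @ self.W_atom + self.b_atom).leaky_relu()
        for _ in range(self.k_atom_rounds):
            nei = concat([h.take(src), bf], axis=1)
            nei = (nei @ self.W_nei + self.b_nei).leaky_relu()
            scores = (concat([h.take(dst), nei], axis=1) @ self.w_align
                      + self.b_align).leaky_relu()
            alpha = softmax_over_segments(scores, dst, n_atoms)
            ctx = segment_sum(alpha * (nei @ self.W_ctx), dst, n_atoms)
            h = self.gru_atom(ctx, h)
            h = self._maybe_dropout(h, train, rng)

        s = segment_sum(h, mol_of_atom, n_mols)
        for _ in range(self.t_mol_rounds):
            s_rows = s.take(mol_of_atom)
            scores = (concat([s_rows, h], axis=1) @ self.w_malign
                      + self.b_malign).leaky_relu()
            alpha = softmax_over_segments(scores, mol_of_atom, n_mols)
            ctx = segment_sum(alpha * (h @ self.W_mctx), mol_of_atom, n_mols)
            s = self.gru_mol(ctx, s)
        return s @ self.W_out + self.b_out

    def encode(self, smiles_or_graph) -> np.ndarray:
        """Convenience: SMILES or graph in, latent vector (numpy) out."""
        graph = (smiles_or_graph if isinstance(smiles_or_graph, MolecularGraph)
                 else featurize_smiles(smiles_or_graph))
        with no_grad():
            return self.forward(graph).data[0]
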