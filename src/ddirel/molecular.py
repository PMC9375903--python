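"""Molecular graphs, r-radius subgraph fingerprints, and the additive
message-passing encoder (MGNN).

SMILES parsing is delegated to RDKit; atoms are renumbered into RDKit's
canonical order so vertex indices (and hence fingerprint assignment) are
reproducible across runs.  Each heavy atom gets an r-radius subgraph
signature -- a canonical encoding of its element together with the
sorted multiset of (bond type, neighbour signature) pairs within r hops
-- looked up in a trainable vocabulary (unknown signatures map to a
reserved UNK id at inference).

The MGNN updates per-atom vectors additively,

    m_i^l = m_i^{l-1} + sum_{j in N_i} ReLU(W_hidden^{l-1} m_j^{l-1} + b),

sums the atom vectors after L steps and applies a ReLU-affine readout to
give the fixed-size molecular feature H^mol.  Plain-numpy reference
functions (``mgnn_step``, ``mgnn_readout``) implement one step each; the
trainable :class:`MGNNEncoder` runs the same arithmetic on autodiff
tensors and is cross-checked against them in the tests.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import nn

logger = logging.getLogger(__name__)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MolecularGraph",
    "FingerprintVocabulary",
    "smiles_to_graph",
    "atom_signature",
    "assign_fingerprints",
    "mgnn_step",
    "mgnn_readout",
    "MGNNEncoder",
]

_BOND_SYMBOL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}

UNK_SIGNATURE = "<unk>"


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom graph: element symbols, undirected typed bonds, and
    (after :func:`assign_fingerprints`) per-vertex fingerprint ids."""

    symbols: tuple  # element symbol per atom
    bonds: tuple  # tuple of ((i, j, bond_symbol)), i < j
    smiles: str
    fingerprint_ids: tuple = ()

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def neighbors(self) -> list:
        """Adjacency list of (neighbor index, bond symbol) pairs."""
        adj = [[] for _ in range(self.n_atoms)]
        for i, j, sym in self.bonds:
            adj[i].append((j, sym))
            adj[j].append((i, sym))
        return adj

    def adjacency_matrix(self) -> np.ndarray:
        a = np.zeros((self.n_atoms, self.n_atoms))
        for i, j, _ in self.bonds:
            a[i, j] = a[j, i] = 1.0
        return a


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a canonical heavy-atom graph."""
    if not smiles:
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    order = tuple(Chem.CanonicalRankAtoms(mol, breakTies=True))
    # order[i] = canonical position of atom i; invert for RenumberAtoms
    inverse = [0] * len(order)
    for i, pos in enumerate(order):
        inverse[pos] = i
    mol = Chem.RenumberAtoms(mol, inverse)
    symbols = tuple(atom.GetSymbol() for atom in mol.GetAtoms())
    bonds = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        sym = _BOND_SYMBOL.get(bond.GetBondType(), "-")
        bonds.append((min(i, j), max(i, j), sym))
    return MolecularGraph(
        symbols=symbols, bonds=tuple(sorted(bonds)), smiles=smiles
    )


def atom_signature(graph: MolecularGraph, index: int, radius: int = 1) -> str:
    """Canonical signature of the r-radius subgraph rooted at ``index``.

    Radius 0 is the element symbol; radius r nests the sorted multiset of
    (bond symbol, neighbour signature at radius r-1) pairs.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return graph.symbols[index]
    adj = graph.neighbors()

    def sig(i: int, r: int) -> str:
        if r == 0:
            return graph.symbols[i]
        parts = sorted(f"{bond}{sig(nbr, r - 1)}" for nbr, bond in adj[i])
        return f"{graph.symbols[i]}({','.join(parts)})"

    return sig(index, radius)


class FingerprintVocabulary:
    """Dense signature -> id mapping; id 0 is reserved for unknowns."""

    def __init__(self, radius: int = 1):
        self.radius = radius
        self._ids = {UNK_SIGNATURE: 0}

    def __len__(self):
        return len(self._ids)

    def __contains__(self, signature):
        return signature in self._ids

    @property
    def unk_id(self) -> int:
        return 0

    def id_for(self, signature: str, train: bool = True) -> int:
        if signature not in self._ids:
            if not train:
                return self.unk_id
            self._ids[signature] = len(self._ids)
        return self._ids[signature]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"radius": self.radius, "signatures": self._ids}, fh)

    @classmethod
    def from_json(cls, path) -> "FingerprintVocabulary":
        with open(path) as fh:
            blob = json.load(fh)
        vocab = cls(radius=blob["radius"])
        vocab._ids = {sig: int(i) for sig, i in blob["signatures"].items()}
        return vocab


def assign_fingerprints(
    graph: MolecularGraph,
    vocab: FingerprintVocabulary,
    radius: int = 1,
    train: bool = True,
) -> MolecularGraph:
    """Attach fingerprint ids to every atom of the graph."""
    ids = tuple(
        vocab.id_for(atom_signature(graph, i, radius), train=train)
        for i in range(graph.n_atoms)
    )
    return replace(graph, fingerprint_ids=ids)


# ---------------------------------------------------------------------
# numpy reference message passing

def mgnn_step(graph: MolecularGraph, m: np.ndarray, w_hidden: np.ndarray,
              b_hidden: np.ndarray) -> np.ndarray:
    """One additive message-passing update (reference implementation)."""
    m = np.asarray(m, dtype=float)
    if m.shape[0] != graph.n_atoms:
        raise ValueError("one vector per atom required")
    messages = np.maximum(m @ np.asarray(w_hidden).T + np.asarray(b_hidden), 0.0)
    return m + graph.adjacency_matrix() @ messages


def mgnn_readout(graph: MolecularGraph, m: np.ndarray, w_output: np.ndarray,
                 b_output: np.ndarray) -> np.ndarray:
    """ReLU(W_out @ sum_i m_i + b_out): order-invariant molecular vector."""
    m = np.asarray(m, dtype=float)
    if graph.n_atoms == 0 or m.shape[0] == 0:
        raise ValueError("empty molecular graph")
    return np.maximum(np.asarray(w_output) @ m.sum(axis=0) + np.asarray(b_output), 0.0)


# ---------------------------------------------------------------------
# trainable encoder

class MGNNEncoder:
    """Trainable molecular encoder: fingerprint embeddings + L additive
    message-passing steps + sum-pool readout.

    One shared encoder serves both drugs of a pair.  Drug names missing
    from the name->SMILES table (or with unparsable SMILES) fall back to a
    dedicated zero-initialised learnable unknown-structure vector.
    """

    def __init__(
        self,
        vocab: FingerprintVocabulary,
        d_m: int = 64,
        n_steps: int = 2,
        vocab_capacity: int = 256,
        seed: int = 0,
    ):
        self.vocab = vocab
        self.d_m = d_m
        self.n_steps = n_steps
        rng = np.random.default_rng(seed)
        self.capacity = max(vocab_capacity, len(vocab) + 1)
        self.embedding = nn.parameter(rng, (self.capacity, d_m), scale=0.1)
        self.w_hidden = [
            nn.parameter(rng, (d_m, d_m), scale=0.1) for _ in range(n_steps)
        ]
        self.b_hidden = [nn.zeros_param((d_m,)) for _ in range(n_steps)]
        self.w_output = nn.parameter(rng, (d_m, d_m), scale=0.1)
        self.b_output = nn.zeros_param((d_m,))
        self.unknown_vector = nn.zeros_param((d_m,))
        self._graph_cache: dict = {}

    @property
    def params(self) -> list:
        return (
            [self.embedding, self.w_output, self.b_output, self.unknown_vector]
            + self.w_hidden
            + self.b_hidden
        )

    def _prepare(self, smiles: str, train: bool):
        if smiles not in self._graph_cache:
            graph = smiles_to_graph(smiles)
            graph = assign_fingerprints(
                graph, self.vocab, radius=self.vocab.radius, train=train
            )
            if max(graph.fingerprint_ids, default=0) >= self.capacity:
                raise ValueError("fingerprint vocabulary exceeded embedding capacity")
            self._graph_cache[smiles] = graph
        return self._graph_cache[smiles]

    def encode_smiles(self, smiles: str, train: bool = True) -> nn.Tensor:
        graph = self._prepare(smiles, train)
        m = self.embedding.take(list(graph.fingerprint_ids))
        adj = graph.adjacency_matrix()
        for step in range(self.n_steps):
            messages = (m @ self.w_hidden[step].T + self.b_hidden[step]).relu()
            m = m + nn.as_tensor(adj) @ messages
        return (self.w_output @ m.sum(axis=0) + self.b_output).relu()

    def encode_drug(self, name: str, lookup: dict, train: bool = True) -> nn.Tensor:
        """Name -> molecular feature vector; unknown names or bad SMILES
        yield the learnable unknown-structure vector."""
        smiles = lookup.get(name)
        if smiles is None:
            logger.warning("drug %r not in SMILES table; unknown-structure vector", name)
            return self.unknown_vector
        try:
            return self.encode_smiles(smiles, train=train)
        except ValueError:
            logger.warning("SMILES for %r failed to parse; unknown-structure vector", name)
            return self.unknown_vector
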