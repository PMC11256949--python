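"""Perturbation encoders: molecular-graph attention, genetic one-hot, dose.

A drug given as SMILES is parsed into a molecular graph (one node per heavy
atom, one undirected edge per bond) and pushed through two graph-attention
layers followed by a fully connected projection; mean pooling over atoms
yields the latent perturbation vector. Genetic perturbations go through a
single affine map of a one-hot target-gene encoding. An optional dose is
folded in by elementwise multiplication with a learned dose embedding.

The attention score between a node k and a first-order neighbor l is the
softmax (over N(k) plus k itself) of exp(elu(a . (W h_k || W h_l))); the
updated node embedding is ReLU of the attention-weighted sum of projected
neighbors, including the self term.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from ._nn import Linear, Module, Tensor, as_tensor

__all__ = [
    "DrugGraph",
    "AttentionParams",
    "PerturbationEmbedding",
    "Featurization",
    "GATLayer",
    "DrugEncoder",
    "GeneticEncoder",
    "DoseNet",
    "smiles_to_graph",
    "attention_scores",
    "gat_layer",
    "encode_drug",
    "encode_genetic",
    "apply_dose",
    "EncoderError",
]

DEFAULT_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B")


class EncoderError(ValueError):
    pass


@dataclasses.dataclass
class DrugGraph:
    """Molecular graph: per-atom features plus an undirected edge list."""

    node_features: np.ndarray  # |V| x F
    edges: list[tuple[int, int]]
    node_count: int

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=np.float64)
        if self.node_count < 1:
            raise EncoderError("graph must have at least one node")
        if self.node_features.shape[0] != self.node_count:
            raise EncoderError("node_features row count must equal node_count")
        for k, l in self.edges:
            if not (0 <= k < self.node_count and 0 <= l < self.node_count):
                raise EncoderError(f"edge ({k},{l}) outside [0,{self.node_count})")

    def adjacency_with_self(self) -> np.ndarray:
        """0/1 mask of N(k) plus the node itself."""
        A = np.eye(self.node_count)
        for k, l in self.edges:
            A[k, l] = 1.0
            A[l, k] = 1.0
        return A


@dataclasses.dataclass
class AttentionParams:
    W: np.ndarray  # F_out x F_in
    a: np.ndarray  # 2 * F_out

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        self.a = np.asarray(self.a, dtype=np.float64)
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.a))):
            raise EncoderError("attention parameters must be finite")
        if self.a.shape[0] != 2 * self.W.shape[0]:
            raise EncoderError(
                f"a must have length 2*F_out={2 * self.W.shape[0]}, got {self.a.shape[0]}"
            )


@dataclasses.dataclass
class PerturbationEmbedding:
    vector: np.ndarray
    perturbation_id: str = ""

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)


@dataclasses.dataclass(frozen=True)
class Featurization:
    """Atom featurization config: one-hot element + degree + aromaticity + charge."""

    elements: tuple[str, ...] = DEFAULT_ELEMENTS
    include_degree: bool = True
    include_aromaticity: bool = True
    include_formal_charge: bool = True

    @property
    def width(self) -> int:
        w = len(self.elements) + 1  # +1 for "other" element bucket
        if self.include_degree:
            w += 1
        if self.include_aromaticity:
            w += 1
        if self.include_formal_charge:
            w += 1
        return w

    def atom_features(self, atom) -> np.ndarray:
        vec = np.zeros(self.width)
        symbol = atom.GetSymbol()
        try:
            vec[self.elements.index(symbol)] = 1.0
        except ValueError:
            vec[len(self.elements)] = 1.0
        i = len(self.elements) + 1
        if self.include_degree:
            vec[i] = float(atom.GetDegree())
            i += 1
        if self.include_aromaticity:
            vec[i] = 1.0 if atom.GetIsAromatic() else 0.0
            i += 1
        if self.include_formal_charge:
            vec[i] = float(atom.GetFormalCharge())
        return vec


def smiles_to_graph(smiles: str, featurization: Optional[Featurization] = None) -> DrugGraph:
    """Parse a SMILES string into a featurized molecular graph."""
    from rdkit import Chem

    feat = featurization or Featurization()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise EncoderError(f"unparseable SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    if n == 0:
        raise EncoderError(f"SMILES yields an empty molecule: {smiles!r}")
    features = np.stack([feat.atom_features(mol.GetAtomWithIdx(i)) for i in range(n)])
    edges = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    return DrugGraph(node_features=features, edges=edges, node_count=n)


# ---------------------------------------------------------------------------
# attention math (pure-array reference interface)
# ---------------------------------------------------------------------------


def _attention_tensor(g: DrugGraph, h: Tensor, W: Tensor, a: Tensor) -> Tensor:
    """|V| x |V| attention matrix on the autodiff graph."""
    n = g.node_count
    if h.shape[0] != n:
        raise EncoderError(f"h has {h.shape[0]} rows for a {n}-node graph")
    if h.shape[1] != W.shape[1]:
        raise EncoderError(
            f"embedding width {h.shape[1]} does not match W input width {W.shape[1]}"
        )
    Wh = h @ W.T  # n x F_out
    f_out = W.shape[0]
    src = Wh @ a[:f_out].reshape(f_out, 1)  # n x 1, contribution of h_k
    dst = Wh @ a[f_out:].reshape(f_out, 1)  # n x 1, contribution of h_l
    logits = src + dst.T  # logits[k, l] = a . (Wh_k || Wh_l)
    scores = logits.elu().exp()
    mask = g.adjacency_with_self()
    masked = scores * mask
    denom = masked.sum(axis=1, keepdims=True)
    return masked / denom


def attention_scores(g: DrugGraph, h: np.ndarray, p: AttentionParams) -> np.ndarray:
    """Neighborhood-normalized attention scores; zero outside N(k) and k."""
    alpha = _attention_tensor(
        g, as_tensor(np.asarray(h, dtype=np.float64)), as_tensor(p.W), as_tensor(p.a)
    )
    return alpha.data


def gat_layer(g: DrugGraph, h: np.ndarray, p: AttentionParams) -> np.ndarray:
    """One graph-attention update: ReLU of attention-weighted projected neighbors."""
    ht = as_tensor(np.asarray(h, dtype=np.float64))
    Wt, at = as_tensor(p.W), as_tensor(p.a)
    alpha = _attention_tensor(g, ht, Wt, at)
    out = (alpha @ (ht @ Wt.T)).relu()
    return out.data


# ---------------------------------------------------------------------------
# trainable modules
# ---------------------------------------------------------------------------


class GATLayer(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        bound = np.sqrt(6.0 / in_dim)
        self.W = Tensor(rng.uniform(-bound, bound, size=(out_dim, in_dim)), requires_grad=True)
        self.a = Tensor(rng.uniform(-0.1, 0.1, size=2 * out_dim), requires_grad=True)

    def __call__(self, g: DrugGraph, h: Tensor) -> Tensor:
        alpha = _attention_tensor(g, h, self.W, self.a)
        return (alpha @ (h @ self.W.T)).relu()


class DrugEncoder(Module):
    """Two GAT layers, mean pooling over atoms, fully connected projection to L."""

    def __init__(
        self,
        feature_dim: int,
        latent_dim: int,
        hidden_dims: tuple[int, int] = (64, 64),
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        self.gat1 = GATLayer(feature_dim, hidden_dims[0], rng=rng)
        self.gat2 = GATLayer(hidden_dims[0], hidden_dims[1], rng=rng)
        self.proj = Linear(hidden_dims[1], latent_dim, rng=rng)
        self.latent_dim = latent_dim

    def forward(self, g: DrugGraph) -> Tensor:
        if g.node_count == 0:
            raise EncoderError("cannot encode an empty graph")
        h = as_tensor(g.node_features)
        h = self.gat1(g, h)
        h = self.gat2(g, h)
        pooled = h.mean(axis=0, keepdims=True)  # d_j = (1/|V|) sum_k h_k
        return self.proj(pooled).reshape(self.latent_dim)

    def __call__(self, g: DrugGraph) -> Tensor:
        return self.forward(g)


class GeneticEncoder(Module):
    """One-layer fully connected map from a one-hot target gene to latent space."""

    def __init__(
        self,
        vocabulary: Sequence[str],
        latent_dim: int,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        self.vocabulary = list(vocabulary)
        self.index = {g: i for i, g in enumerate(self.vocabulary)}
        self.fc = Linear(len(self.vocabulary), latent_dim, rng=rng)
        self.latent_dim = latent_dim

    def forward(self, target_gene: str) -> Tensor:
        if target_gene not in self.index:
            raise EncoderError(
                f"unknown target gene {target_gene!r} "
                f"(vocabulary has {len(self.vocabulary)} entries)"
            )
        onehot = np.zeros((1, len(self.vocabulary)))
        onehot[0, self.index[target_gene]] = 1.0
        return self.fc(as_tensor(onehot)).reshape(self.latent_dim)

    def __call__(self, target_gene: str) -> Tensor:
        return self.forward(target_gene)


class DoseNet(Module):
    """Affine map of log10(dose) to a latent-length embedding, softplus output."""

    def __init__(self, latent_dim: int, rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.fc = Linear(1, latent_dim, rng=rng)
        self.latent_dim = latent_dim

    def embedding(self, dose: float) -> Tensor:
        if not np.isfinite(dose):
            raise EncoderError("dose must be finite")
        if dose < 0:
            raise EncoderError(f"dose must be nonnegative, got {dose}")
        t = np.log10(dose + 1e-12)
        return self.fc(as_tensor([[t]])).softplus().reshape(self.latent_dim)

    def __call__(self, d: Tensor, dose: float) -> Tensor:
        return d * self.embedding(dose)


# ---------------------------------------------------------------------------
# functional wrappers returning PerturbationEmbedding
# ---------------------------------------------------------------------------


def encode_drug(g: DrugGraph, model, perturbation_id: str = "") -> PerturbationEmbedding:
    """Encode a drug graph through the model's GAT encoder (eval semantics)."""
    enc = model.drug_encoder if hasattr(model, "drug_encoder") else model
    return PerturbationEmbedding(enc.forward(g).data, perturbation_id)


def encode_genetic(target_gene: str, model) -> PerturbationEmbedding:
    enc = model.genetic_encoder if hasattr(model, "genetic_encoder") else model
    return PerturbationEmbedding(enc.forward(target_gene).data, target_gene)


def apply_dose(d: PerturbationEmbedding, dose: Optional[float], model) -> PerturbationEmbedding:
    """Elementwise product with the learned dose embedding; absent dose is a no-op."""
    if dose is None:
        return d
    net = model.dose_net if hasattr(model, "dose_net") else model
    emb = net.embedding(float(dose)).data
    return PerturbationEmbedding(d.vector * emb, d.perturbation_id)
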