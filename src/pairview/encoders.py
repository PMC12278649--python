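"""The projector: eight modality-specific encoders mapping heterogeneous drug
payloads into a shared d_hid-dimensional space, plus the context encoders
(cell line, xenograft time, interaction type).

Each encoder ends in one linear transformation layer into the shared space, so
modalities with very different raw structure (token sequence, molecular graph,
gene set, fixed vector, ontology node) become directly comparable points.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import nn
from .data import ModalityId, PPINetwork

logger = logging.getLogger("pairview")

CLS_TOKEN = "[CLS]"
UNK_TOKEN = "[UNK]"

# Token grammar: bracket atoms as single tokens, two-letter organic-subset
# atoms (Cl, Br), ring-closure digits (incl. %nn), bonds/branches, aromatic
# one-letter atoms.  Anything else becomes a single-character token that the
# vocabulary maps to UNK.
_SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|\d|[BCNOPSFI]|[bcnops]|[=#$:/\\().+-])"
)


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into grammar tokens and append the CLS marker."""
    if not smiles:
        raise ValueError("empty SMILES string")
    tokens, pos = [], 0
    while pos < len(smiles):
        m = _SMILES_TOKEN_RE.match(smiles, pos)
        if m:
            tokens.append(m.group(0))
            pos = m.end()
        else:
            tokens.append(smiles[pos])  # unknown char; vocab maps it to UNK
            pos += 1
    tokens.append(CLS_TOKEN)
    return tokens


class SmilesVocabulary:
    """Frozen token -> index map built from a training corpus; unseen tokens
    map to UNK at predict time."""

    def __init__(self, tokens):
        uniq = sorted(set(tokens) - {CLS_TOKEN, UNK_TOKEN})
        self.index = {UNK_TOKEN: 0, CLS_TOKEN: 1}
        for t in uniq:
            self.index[t] = len(self.index)

    def __len__(self):
        return len(self.index)

    def encode(self, tokens) -> np.ndarray:
        unk = self.index[UNK_TOKEN]
        return np.array([self.index.get(t, unk) for t in tokens], dtype=np.intp)

    @classmethod
    def from_smiles(cls, smiles_iter) -> "SmilesVocabulary":
        toks = []
        for s in smiles_iter:
            toks.extend(tokenize_smiles(s))
        return cls(toks)

    def to_dict(self) -> dict:
        return dict(self.index)

    @classmethod
    def from_dict(cls, d: dict) -> "SmilesVocabulary":
        v = cls([])
        v.index = {str(k): int(i) for k, i in d.items()}
        return v


def sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(0, dim, 2)[None, :]
    angle = pos / np.power(10000.0, i / dim)
    out = np.zeros((length, dim))
    out[:, 0::2] = np.sin(angle)
    out[:, 1::2] = np.cos(angle[:, : out[:, 1::2].shape[1]])
    return out


class SmilesEncoder:
    """Transformer encoder over SMILES tokens; the contextual embedding at the
    CLS position, passed through one transformation layer, is the modality
    embedding."""

    def __init__(self, vocab: SmilesVocabulary, dim: int, n_layers: int,
                 out_dim: int, rng: np.random.Generator,
                 n_heads: int = 2, max_len: int = 128):
        if dim % n_heads != 0:
            raise ValueError("encoder dim must be divisible by n_heads")
        self.vocab = vocab
        self.dim, self.n_heads, self.max_len = dim, n_heads, max_len
        self.embed = nn.parameter(rng.normal(0.0, 0.02, size=(len(vocab), dim)))
        self.layers = []
        for _ in range(n_layers):
            self.layers.append({
                "wq": nn.Linear(dim, dim, rng), "wk": nn.Linear(dim, dim, rng),
                "wv": nn.Linear(dim, dim, rng), "wo": nn.Linear(dim, dim, rng),
                "ff1": nn.Linear(dim, 2 * dim, rng), "ff2": nn.Linear(2 * dim, dim, rng),
                "g1": nn.parameter(np.ones(dim)), "b1": nn.parameter(np.zeros(dim)),
                "g2": nn.parameter(np.ones(dim)), "b2": nn.parameter(np.zeros(dim)),
            })
        self.out = nn.Linear(dim, out_dim, rng)

    def parameters(self):
        ps = [self.embed] + self.out.parameters()
        for l in self.layers:
            for key in ("wq", "wk", "wv", "wo", "ff1", "ff2"):
                ps.extend(l[key].parameters())
            ps.extend([l["g1"], l["b1"], l["g2"], l["b2"]])
        return ps

    def __call__(self, token_ids: np.ndarray) -> nn.Tensor:
        if len(token_ids) > self.max_len:
            logger.warning("SMILES sequence length %d exceeds max %d; truncating",
                           len(token_ids), self.max_len)
            token_ids = np.concatenate([token_ids[: self.max_len - 1], token_ids[-1:]])
        L = len(token_ids)
        x = self.embed.take_rows(token_ids) + nn.constant(
            sinusoidal_positions(L, self.dim))
        dk = self.dim // self.n_heads
        for l in self.layers:
            q, k, v = l["wq"](x), l["wk"](x), l["wv"](x)
            if self.n_heads == 1:
                att = nn.softmax((q @ k.T) * (1.0 / np.sqrt(dk)), axis=-1)
                mixed = att @ v
            else:
                heads = []
                for h in range(self.n_heads):
                    sl = slice(h * dk, (h + 1) * dk)
                    qh = q @ nn.constant(_slice_eye(self.dim, sl))
                    kh = k @ nn.constant(_slice_eye(self.dim, sl))
                    vh = v @ nn.constant(_slice_eye(self.dim, sl))
                    att = nn.softmax((qh @ kh.T) * (1.0 / np.sqrt(dk)), axis=-1)
                    heads.append(att @ vh)
                mixed = nn.concat(heads, axis=1)
            x = nn.layer_norm(x + l["wo"](mixed), l["g1"], l["b1"])
            x = nn.layer_norm(x + l["ff2"](l["ff1"](x).relu()), l["g2"], l["b2"])
        cls = x.take_rows(np.array([L - 1]))  # CLS is the trailing token
        return self.out(cls).reshape(-1)

    def encode_batch(self, sequences: list[np.ndarray]) -> nn.Tensor:
        """Encode several token sequences in one pass.

        Sequences are packed into one block-diagonal attention problem (tokens
        attend only within their own sequence), which is numerically identical
        to encoding each sequence separately.  Returns (n_sequences, out_dim).
        """
        seqs = []
        for ids in sequences:
            if len(ids) > self.max_len:
                logger.warning("SMILES sequence length %d exceeds max %d; truncating",
                               len(ids), self.max_len)
                ids = np.concatenate([ids[: self.max_len - 1], ids[-1:]])
            seqs.append(ids)
        lengths = [len(s) for s in seqs]
        offsets = np.cumsum([0] + lengths)
        total = offsets[-1]
        pos = np.concatenate([sinusoidal_positions(L, self.dim) for L in lengths])
        x = self.embed.take_rows(np.concatenate(seqs)) + nn.constant(pos)
        block_mask = np.full((total, total), -np.inf)
        for a, b in zip(offsets[:-1], offsets[1:]):
            block_mask[a:b, a:b] = 0.0
        mask = nn.constant(block_mask)
        dk = self.dim // self.n_heads
        for l in self.layers:
            q, k, v = l["wq"](x), l["wk"](x), l["wv"](x)
            if self.n_heads == 1:
                att = nn.softmax((q @ k.T) * (1.0 / np.sqrt(dk)) + mask, axis=-1)
                mixed = att @ v
            else:
                heads = []
                for h in range(self.n_heads):
                    sl = slice(h * dk, (h + 1) * dk)
                    qh = q @ nn.constant(_slice_eye(self.dim, sl))
                    kh = k @ nn.constant(_slice_eye(self.dim, sl))
                    vh = v @ nn.constant(_slice_eye(self.dim, sl))
                    att = nn.softmax((qh @ kh.T) * (1.0 / np.sqrt(dk)) + mask,
                                     axis=-1)
                    heads.append(att @ vh)
                mixed = nn.concat(heads, axis=1)
            x = nn.layer_norm(x + l["wo"](mixed), l["g1"], l["b1"])
            x = nn.layer_norm(x + l["ff2"](l["ff1"](x).relu()), l["g2"], l["b2"])
        cls_rows = x.take_rows(offsets[1:] - 1)
        return self.out(cls_rows)


def _slice_eye(dim: int, sl: slice) -> np.ndarray:
    return np.eye(dim)[:, sl]


# ---------------------------------------------------------------------------
# molecular graphs
# ---------------------------------------------------------------------------

@dataclass
class MolGraph:
    """Featurized molecular graph: per-atom features and adjacency."""

    features: np.ndarray   # (n_atoms, n_feat)
    adjacency: np.ndarray  # (n_atoms, n_atoms), symmetric 0/1


DEGREES = tuple(range(7))
CHARGES = (-2, -1, 0, 1, 2)


def smiles_to_graph(smiles: str, element_vocab: list[str]) -> MolGraph:
    """Convert a SMILES string to a featurized graph via RDKit.

    Atom features: element one-hot over `element_vocab` + other, degree 0-6,
    formal charge -2..+2, aromatic flag.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(f"unparseable or empty molecule: {smiles!r}")
    n = mol.GetNumAtoms()
    n_elem = len(element_vocab) + 1
    feats = np.zeros((n, n_elem + len(DEGREES) + len(CHARGES) + 1))
    elem_idx = {e: i for i, e in enumerate(element_vocab)}
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        feats[i, elem_idx.get(atom.GetSymbol(), n_elem - 1)] = 1.0
        feats[i, n_elem + min(atom.GetDegree(), 6)] = 1.0
        charge = int(np.clip(atom.GetFormalCharge(), -2, 2))
        feats[i, n_elem + len(DEGREES) + CHARGES.index(charge)] = 1.0
        feats[i, -1] = float(atom.GetIsAromatic())
    adj = np.zeros((n, n))
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[a, b] = adj[b, a] = 1.0
    return MolGraph(feats, adj)


class GraphEncoder:
    """Message-passing encoder; graph embedding is one transformation layer
    over the concatenation of mean- and max-pooled node embeddings, which
    makes the output exactly permutation invariant."""

    def __init__(self, n_feat: int, dim: int, n_layers: int, out_dim: int,
                 rng: np.random.Generator):
        self.proj = nn.Linear(n_feat, dim, rng)
        self.layers = [
            {"self": nn.Linear(dim, dim, rng), "nei": nn.Linear(dim, dim, rng)}
            for _ in range(n_layers)
        ]
        self.out = nn.Linear(2 * dim, out_dim, rng)

    def parameters(self):
        ps = self.proj.parameters() + self.out.parameters()
        for l in self.layers:
            ps.extend(l["self"].parameters())
            ps.extend(l["nei"].parameters())
        return ps

    def __call__(self, graph: MolGraph) -> nn.Tensor:
        if graph.features.shape[0] == 0:
            raise ValueError("empty molecular graph")
        deg = graph.adjacency.sum(axis=1, keepdims=True)
        ahat = nn.constant(graph.adjacency / np.maximum(deg, 1.0))
        h = self.proj(nn.constant(graph.features)).relu()
        for l in self.layers:
            h = (l["self"](h) + l["nei"](ahat @ h)).relu()
        pooled = nn.concat([h.mean(axis=0), h.max(axis=0)], axis=0)
        return self.out(pooled)

    def encode_batch(self, graphs: list[MolGraph]) -> nn.Tensor:
        """Encode several molecular graphs in one block-diagonal message-passing
        pass; identical to per-graph encoding.  Returns (n_graphs, out_dim)."""
        sizes = [g.features.shape[0] for g in graphs]
        if min(sizes) == 0:
            raise ValueError("empty molecular graph")
        offsets = np.cumsum([0] + sizes)
        total = offsets[-1]
        feats = np.concatenate([g.features for g in graphs])
        adj = np.zeros((total, total))
        for g, a, b in zip(graphs, offsets[:-1], offsets[1:]):
            adj[a:b, a:b] = g.adjacency
        deg = adj.sum(axis=1, keepdims=True)
        ahat = nn.constant(adj / np.maximum(deg, 1.0))
        h = self.proj(nn.constant(feats)).relu()
        for l in self.layers:
            h = (l["self"](h) + l["nei"](ahat @ h)).relu()
        mean_sel = np.zeros((len(graphs), total))
        for i, (a, b) in enumerate(zip(offsets[:-1], offsets[1:])):
            mean_sel[i, a:b] = 1.0 / (b - a)
        means = nn.constant(mean_sel) @ h
        maxes = nn.concat([h.take_rows(np.arange(a, b)).max(axis=0).reshape(1, -1)
                           for a, b in zip(offsets[:-1], offsets[1:])], axis=0)
        return self.out(nn.concat([means, maxes], axis=1))


# ---------------------------------------------------------------------------
# gene sets (drug targets & cell-line contexts)
# ---------------------------------------------------------------------------

class GeneEmbeddingTable:
    """Learnable per-gene embeddings, shared between the drug-target encoder
    and the cell-line context encoder."""

    def __init__(self, genes, dim: int, rng: np.random.Generator,
                 init_scale: float = 1.0):
        self.genes = sorted(set(genes))
        self.index = {g: i for i, g in enumerate(self.genes)}
        self.dim = dim
        # unit-scale init keeps pooled gene-set vectors comparable in
        # magnitude to the other modality embeddings
        self.table = nn.parameter(
            rng.normal(0.0, init_scale, size=(len(self.genes), dim)))

    def parameters(self):
        return [self.table]

    def __contains__(self, gene):
        return gene in self.index


def expand_target_genes(targets, ppi: PPINetwork, k_g: int) -> frozenset:
    """Union of targets with each target's up-to-k_g strongest PPI neighbors
    (ties broken by lexicographic gene id); genes absent from the network
    contribute only themselves."""
    if not targets:
        raise ValueError("empty target gene set")
    if k_g < 0:
        raise ValueError("k_g must be >= 0")
    expanded = set(targets)
    for g in targets:
        neigh = ppi.neighbors(g)
        ranked = sorted(neigh, key=lambda n: (-ppi.edge_weight(g, n), n))
        expanded.update(ranked[:k_g])
    return frozenset(expanded)


def encode_gene_set(genes, table: GeneEmbeddingTable, transform: nn.Linear,
                    pool: str = "mean") -> nn.Tensor:
    """Permutation-invariant pooling of gene embeddings followed by one
    transformation layer.  Unknown genes are dropped with a warning; a fully
    unknown set pools to the zero vector."""
    idx = [table.index[g] for g in sorted(genes) if g in table.index]
    unknown = len(list(genes)) - len(idx)
    if unknown:
        logger.warning("%d gene(s) absent from the embedding table", unknown)
    if not idx:
        logger.warning("gene set entirely unknown; pooled vector is zero")
        pooled = nn.constant(np.zeros(table.dim))
    else:
        rows = table.table.take_rows(np.array(idx, dtype=np.intp))
        pooled = rows.mean(axis=0) if pool == "mean" else rows.sum(axis=0)
    return transform(pooled)


# ---------------------------------------------------------------------------
# 2D-3D contrastive alignment
# ---------------------------------------------------------------------------

def infonce(scores: nn.Tensor) -> nn.Tensor:
    """Mean InfoNCE over rows of an (N, N) score matrix whose diagonal holds
    the matched pairs."""
    n = scores.shape[0]
    diag = (scores * nn.constant(np.eye(n))).sum(axis=1)
    return (nn.logsumexp(scores, axis=1) - diag).mean()


def infonce_2d3d(z2d: nn.Tensor, z3d: nn.Tensor, score_fn=None) -> nn.Tensor:
    """Symmetric InfoNCE aligning paired 2D and 3D embeddings: both matching
    directions averaged with weight 1/2.  Nonnegative in expectation; equals
    log N when all pairwise scores coincide."""
    n = z2d.shape[0]
    if n < 2:
        raise ValueError("contrastive alignment needs a batch of >= 2 pairs")
    scores = score_fn(z2d, z3d) if score_fn is not None else z2d @ z3d.T
    return 0.5 * infonce(scores) + 0.5 * infonce(scores.T)


def hashed_text_vector(text: str, dim: int = 32) -> np.ndarray:
    """Deterministic hashed bag-of-tokens featurizer for drug descriptions.

    Stands behind the pluggable text-modality input when no precomputed
    description embedding is supplied; identical descriptions always map to
    identical vectors.
    """
    import hashlib

    vec = np.zeros(dim)
    for token in re.findall(r"[a-z0-9]+", text.lower()):
        h = hashlib.sha256(token.encode()).digest()
        bucket = int.from_bytes(h[:4], "little") % dim
        sign = 1.0 if h[4] % 2 == 0 else -1.0
        vec[bucket] += sign
    return vec


# ---------------------------------------------------------------------------
# ontology embeddings: random walk with restart + SVD
# ---------------------------------------------------------------------------

def rwr_node_profiles(graph: nx.Graph, alpha: float = 0.5, tol: float = 1e-6,
                      max_iter: int = 100) -> tuple[list[str], np.ndarray]:
    """Per-seed stationary random-walk-with-restart distributions.

    Iterates t <- (1 - alpha) W t + alpha e_j with W the column-stochastic
    walk matrix (column j = uniform over j's neighbors), so every profile is
    a probability vector at every iteration.  Isolated nodes restart onto
    themselves.  Returns (sorted node list, matrix with row j = profile of
    seed j).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("restart probability must lie in (0, 1)")
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((n, n))
    for u, v in graph.edges():
        if u == v:
            continue
        W[idx[u], idx[v]] = 1.0
        W[idx[v], idx[u]] = 1.0
    colsum = W.sum(axis=0)
    isolated = np.where(colsum == 0)[0]
    for i in isolated:
        logger.info("isolated node %r: self-restart profile", nodes[i])
        W[i, i] = 1.0
    colsum = W.sum(axis=0)
    W = W / colsum
    T = np.eye(n)  # columns are the current profiles t_j
    for _ in range(max_iter):
        T_new = (1.0 - alpha) * (W @ T) + alpha * np.eye(n)
        if np.abs(T_new - T).sum(axis=0).max() < tol:
            T = T_new
            break
        T = T_new
    return nodes, T.T  # row j = stationary profile of seed j


@dataclass
class OntologyEmbeddingTable:
    """Cached SVD factorization of the stacked RWR profile matrix."""

    nodes: list
    vectors: np.ndarray  # (n_nodes, dim)
    alpha: float
    dim: int

    def vector(self, node_id: str) -> np.ndarray:
        return self.vectors[self.nodes.index(node_id)]

    def __contains__(self, node_id):
        return node_id in self.nodes


def ontology_embeddings(graph: nx.Graph, alpha: float = 0.5, dim: int = 16,
                        tol: float = 1e-6, max_iter: int = 100) -> OntologyEmbeddingTable:
    """Node embeddings from the SVD of the RWR profile matrix: node j's vector
    is (sigma_i * V[j, i]) over the top `dim` singular directions, with each
    right singular vector's largest-magnitude entry made positive so the
    factorization is deterministic."""
    nodes, P = rwr_node_profiles(graph, alpha=alpha, tol=tol, max_iter=max_iter)
    if dim > len(nodes):
        raise ValueError(f"embedding dim {dim} exceeds node count {len(nodes)}")
    _, S, Vt = np.linalg.svd(P, full_matrices=False)
    V = Vt.T
    for i in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, i]))
        if V[j, i] < 0:
            V[:, i] = -V[:, i]
    vectors = V[:, :dim] * S[:dim]
    return OntologyEmbeddingTable(nodes, vectors, alpha, dim)


# ---------------------------------------------------------------------------
# context features
# ---------------------------------------------------------------------------

def overexpressed_genes(tpm: dict | "object", th: float) -> frozenset:
    """Genes whose TPM meets or exceeds the over-expression threshold."""
    items = tpm.items() if hasattr(tpm, "items") else tpm.iteritems()
    return frozenset(g for g, v in items if float(v) >= th)


def one_hop_expand(genes, ppi: PPINetwork) -> frozenset:
    out = set(genes)
    for g in genes:
        out.update(ppi.neighbors(g))
    return frozenset(out)


def cell_line_context(tpm, th: float, ppi: PPINetwork,
                      table: GeneEmbeddingTable, transform: nn.Linear,
                      pool: str = "mean") -> nn.Tensor:
    """Cell-line context vector: over-expressed gene set (TPM >= TH) expanded
    by one hop on the PPI network, then encoded with the shared gene table."""
    over = overexpressed_genes(tpm, th)
    if not over:
        logger.warning("no gene reaches the over-expression threshold %g; "
                       "context vector is the transform of the zero pool", th)
        return transform(nn.constant(np.zeros(table.dim)))
    expanded = one_hop_expand(over, ppi)
    return encode_gene_set(expanded, table, transform, pool=pool)


def time_embedding(t: int, dhid: int) -> np.ndarray:
    """Sinusoidal day-index embedding: entry 2i = sin(t / 10000^(2i/dhid)),
    entry 2i+1 = cos(same).  Squared norm is dhid/2 for every t."""
    if dhid % 2 != 0:
        raise ValueError("time embedding requires an even dimension")
    if t < 0:
        raise ValueError("time must be nonnegative")
    i = np.arange(dhid // 2)
    angle = t / np.power(10000.0, 2 * i / dhid)
    out = np.empty(dhid)
    out[0::2] = np.sin(angle)
    out[1::2] = np.cos(angle)
    return out


class InteractionTypeTable:
    """Learnable embedding per drug-drug interaction type."""

    def __init__(self, type_ids, dim: int, rng: np.random.Generator):
        self.type_ids = sorted(set(type_ids))
        self.index = {t: i for i, t in enumerate(self.type_ids)}
        self.table = nn.parameter(rng.normal(0.0, 0.1, size=(len(self.type_ids), dim)))

    def parameters(self):
        return [self.table]

    def __call__(self, type_id: str) -> nn.Tensor:
        if type_id not in self.index:
            raise KeyError(f"unknown interaction type {type_id!r}")
        return self.table.take_rows(np.array([self.index[type_id]])).reshape(-1)
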