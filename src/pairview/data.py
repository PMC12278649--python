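"""Domain types, file readers/writers, configuration and the seeded-RNG contract.

Tables are plain TSV; multi-valued cells (gene sets, embedding vectors) use a
semicolon-separated inline dialect so a whole fixture fits in single text
files.  Missing cells mean the modality is absent for that drug — absence is
recorded, never imputed.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("pairview")

SIDE_EFFECT_DIM = 27   # side-effect indicator length (SIDER side-effect classes)
SENSITIVITY_DIM = 60   # drug-response profile length (NCI-60 cell-line panel)


class ModalityId(enum.Enum):
    """The eight drug modalities, in canonical enumeration order."""

    SMILES = "smiles"
    GRAPH_2D = "graph_2d"
    TARGET = "target"
    GEOM_3D = "geom_3d"
    TEXT = "text"
    ONTOLOGY = "ontology"
    SIDE_EFFECTS = "side_effects"
    SENSITIVITY = "sensitivity"


MODALITIES: tuple[ModalityId, ...] = tuple(ModalityId)
_MODALITY_INDEX = {m: i for i, m in enumerate(MODALITIES)}


def modality_order(m: ModalityId) -> int:
    return _MODALITY_INDEX[m]


@dataclass
class DrugRecord:
    """A drug id plus whatever subset of the eight modality payloads exists."""

    drug_id: str
    payloads: dict[ModalityId, object] = field(default_factory=dict)

    def __post_init__(self):
        if not self.payloads:
            raise ValueError(f"drug {self.drug_id!r}: at least one payload required")
        for m, v in self.payloads.items():
            if not isinstance(m, ModalityId):
                raise ValueError(f"drug {self.drug_id!r}: bad payload key {m!r}")
        se = self.payloads.get(ModalityId.SIDE_EFFECTS)
        if se is not None and len(se) != SIDE_EFFECT_DIM:
            raise ValueError(
                f"drug {self.drug_id!r}: side-effect vector length {len(se)} != {SIDE_EFFECT_DIM}")
        sv = self.payloads.get(ModalityId.SENSITIVITY)
        if sv is not None and len(sv) != SENSITIVITY_DIM:
            raise ValueError(
                f"drug {self.drug_id!r}: sensitivity vector length {len(sv)} != {SENSITIVITY_DIM}")

    def has(self, m: ModalityId) -> bool:
        return m in self.payloads


@dataclass
class TripletRecord:
    """(drug A, drug B, context, label); context is a cell line, xenograft
    model (optionally with a day index) or an interaction type."""

    drug_a: str
    drug_b: str
    context_id: str
    label: float
    time_days: Optional[int] = None

    def __post_init__(self):
        if self.time_days is not None and self.time_days < 0:
            raise ValueError("time_days must be nonnegative")

    def pair_key(self) -> tuple[str, str]:
        """Canonical (lexicographic) unordered drug-pair key."""
        return tuple(sorted((self.drug_a, self.drug_b)))


class PPINetwork:
    """Undirected gene-gene interaction network with optional edge weights."""

    def __init__(self, graph: nx.Graph):
        loops = list(nx.selfloop_edges(graph))
        if loops:
            graph = graph.copy()
            graph.remove_edges_from(loops)
            logger.info("dropped %d self-loop(s) from network", len(loops))
        self.graph = graph

    @property
    def genes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def neighbors(self, gene: str) -> list[str]:
        if gene not in self.graph:
            return []
        return list(self.graph.neighbors(gene))

    def edge_weight(self, u: str, v: str) -> float:
        return float(self.graph.edges[u, v].get("weight", 1.0))

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


@dataclass
class ExpressionMatrix:
    """Gene x context expression matrix with its normalization unit."""

    values: pd.DataFrame  # rows: gene ids, columns: context ids
    unit: str             # "TPM" or "FPKM"

    def __post_init__(self):
        if self.unit not in ("TPM", "FPKM"):
            raise ValueError(f"unknown expression unit {self.unit!r}")
        if (self.values.values < 0).any():
            raise ValueError("expression matrix contains negative values")

    def column(self, context_id: str) -> pd.Series:
        return self.values[context_id]


@dataclass
class RunConfig:
    """All tunable knobs; every source of randomness flows from `seed`."""

    hidden_dim: int = 512           # d_hid, shared embedding width
    smiles_layers: int = 6
    smiles_dim: int = 512
    smiles_heads: int = 4
    graph_layers: int = 6
    graph_dim: int = 384
    gene_dim: int = 64              # learnable gene-embedding width
    top_k: int = 8                  # retained views in the aggregator
    lambda_aux: float = 0.01
    lambda_infonce: float = 0.01
    lambda_mse: float = 0.01
    r_sampled_pairs: int = 2        # modality pairs sampled per batch
    batch_size: int = 128
    steps: int = 100_000
    warmup_steps: int = 4_000
    learning_rate: float = 1e-4
    learning_rate_grid: tuple = (1e-5, 5e-5, 8e-5, 1e-4, 5e-4)
    poly_decay_power: float = 1.0
    dropout: float = 0.0
    weight_decay: float = 0.0
    polyak_frac: float = 0.0  # average parameters over the last fraction of steps
    th_overexpressed: float = 400.0  # TPM threshold for the over-expressed set
    k_g: int = 5                    # PPI neighbors per target gene
    rwr_alpha: float = 0.5
    rwr_tol: float = 1e-6
    rwr_max_iter: int = 100
    ontology_dim: int = 16
    gene_pool: str = "mean"         # "mean" or "sum" pooling over gene sets
    shortcut_mode: str = "topk_mean"  # or "sum_over_k"
    seed: int = 0

    def __post_init__(self):
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        for name in ("lambda_aux", "lambda_infonce", "lambda_mse"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.hidden_dim % 2 != 0:
            raise ValueError("hidden_dim must be even (sin/cos time-embedding pairs)")
        if self.gene_pool not in ("mean", "sum"):
            raise ValueError("gene_pool must be 'mean' or 'sum'")
        if self.shortcut_mode not in ("topk_mean", "sum_over_k"):
            raise ValueError("shortcut_mode must be 'topk_mean' or 'sum_over_k'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "learning_rate_grid" in raw:
            raw["learning_rate_grid"] = tuple(raw["learning_rate_grid"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["learning_rate_grid"] = list(d["learning_rate_grid"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["learning_rate_grid"] = list(d["learning_rate_grid"])
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


# ---------------------------------------------------------------------------
# inline vector dialect
# ---------------------------------------------------------------------------

def format_vector(v) -> str:
    return ";".join(repr(float(x)) for x in np.asarray(v).ravel())


def parse_vector(cell: str) -> np.ndarray:
    return np.array([float(x) for x in str(cell).split(";") if x != ""])


def format_gene_set(genes) -> str:
    return ";".join(sorted(genes))


def parse_gene_set(cell: str) -> frozenset:
    return frozenset(g for g in str(cell).split(";") if g)


# ---------------------------------------------------------------------------
# drug tables
# ---------------------------------------------------------------------------

_DRUG_COLUMNS = {
    ModalityId.SMILES: "smiles",
    ModalityId.GRAPH_2D: "graph_2d",
    ModalityId.TARGET: "targets",
    ModalityId.GEOM_3D: "geom_3d",
    ModalityId.TEXT: "text",
    ModalityId.ONTOLOGY: "ontology",
    ModalityId.SIDE_EFFECTS: "side_effects",
    ModalityId.SENSITIVITY: "sensitivity",
}


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_drug_table(path) -> list[DrugRecord]:
    """Read a drug table (TSV/CSV, header row, `drug_id` + `smiles` required).

    Empty cells yield absent payloads.  Duplicate drug ids and malformed
    fixed-length vectors are errors naming the offending row.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if "drug_id" not in df.columns or "smiles" not in df.columns:
        raise ValueError(f"{path}: drug table needs 'drug_id' and 'smiles' columns")
    dupes = df["drug_id"][df["drug_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate drug_id(s): {sorted(set(dupes))}")
    records = []
    for i, row in df.iterrows():
        payloads: dict[ModalityId, object] = {}
        for modality, col in _DRUG_COLUMNS.items():
            cell = row.get(col, "")
            if col not in df.columns or cell == "":
                continue
            try:
                if modality in (ModalityId.SMILES, ModalityId.GRAPH_2D,
                                ModalityId.TEXT, ModalityId.ONTOLOGY):
                    payloads[modality] = str(cell)
                elif modality == ModalityId.TARGET:
                    payloads[modality] = parse_gene_set(cell)
                else:
                    payloads[modality] = parse_vector(cell)
            except ValueError as exc:
                raise ValueError(f"{path}: row {i} ({row['drug_id']}): {exc}") from exc
        try:
            records.append(DrugRecord(row["drug_id"], payloads))
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return records


def write_drug_table(records: list[DrugRecord], path) -> None:
    rows = []
    for rec in records:
        row = {"drug_id": rec.drug_id}
        for modality, col in _DRUG_COLUMNS.items():
            v = rec.payloads.get(modality)
            if v is None:
                row[col] = ""
            elif modality == ModalityId.TARGET:
                row[col] = format_gene_set(v)
            elif modality in (ModalityId.GEOM_3D, ModalityId.SIDE_EFFECTS,
                              ModalityId.SENSITIVITY):
                row[col] = format_vector(v)
            else:
                row[col] = str(v)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# triplet tables
# ---------------------------------------------------------------------------

def read_triplet_table(path, drug_ids: Optional[set] = None) -> list[TripletRecord]:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    needed = {"drug_a", "drug_b", "context_id", "label"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: triplet table missing columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        if drug_ids is not None:
            for col in ("drug_a", "drug_b"):
                if row[col] not in drug_ids:
                    raise ValueError(f"{path}: row {i}: unknown drug {row[col]!r}")
        t = row.get("time_days", "")
        out.append(TripletRecord(
            row["drug_a"], row["drug_b"], row["context_id"],
            float(row["label"]),
            time_days=int(t) if t != "" else None))
    return out


def write_triplet_table(triplets: list[TripletRecord], path) -> None:
    rows = [{
        "drug_a": t.drug_a, "drug_b": t.drug_b, "context_id": t.context_id,
        "label": repr(t.label),
        "time_days": "" if t.time_days is None else t.time_days,
    } for t in triplets]
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path, unit: str) -> ExpressionMatrix:
    """Read a gene x context TSV (gene ids as row labels); values must be
    nonnegative and both label axes present."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.isnull().any() or df.columns.isnull().any():
        raise ValueError(f"{path}: missing gene or context labels")
    if df.isnull().values.any():
        raise ValueError(f"{path}: missing values in expression matrix")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), unit)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def read_edge_list(path) -> PPINetwork:
    """Read a whitespace-separated two-column edge list (optional third weight
    column) into an undirected network; self-loops are dropped and counted."""
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
            u, v = parts[0], parts[1]
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
                g.add_edge(u, v, weight=w)
            else:
                g.add_edge(u, v)
    return PPINetwork(g)


def write_edge_list(net: PPINetwork, path) -> None:
    with open(path, "w") as fh:
        for u, v, attrs in sorted(net.graph.edges(data=True)):
            if "weight" in attrs:
                fh.write(f"{u}\t{v}\t{attrs['weight']!r}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def read_gene_pairs(path) -> set[tuple[str, str]]:
    """Read directed gene pairs (e.g. an SDL network: overactive, essential)."""
    pairs = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            if parts[0] == parts[1]:
                raise ValueError(f"{path}:{lineno}: self-pair {parts[0]!r}")
            pairs.add((parts[0], parts[1]))
    return pairs


def write_gene_pairs(pairs, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")
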