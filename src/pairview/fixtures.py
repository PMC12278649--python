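"""Deterministic generators for every input the framework consumes.

The generators are pure functions of (spec, seed): drug tables with a tiny
valence-safe SMILES grammar, preferential-attachment PPI networks, random
ontology trees, SDL pair lists, lognormal expression matrices, labeled
triplets with a planted two-modality rule, and exponential-growth xenograft
trajectories.  The planted rule — synergy iff drug A's sensitivity profile is
high AND drug B targets a gene over-expressed in the context — spans two
modalities, so single-modality ablations measurably underperform the fused
model on recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .data import (SENSITIVITY_DIM, SIDE_EFFECT_DIM, DrugRecord,
                   ExpressionMatrix, ModalityId, PPINetwork, TripletRecord,
                   write_drug_table, write_edge_list, write_expression_matrix,
                   write_gene_pairs, write_triplet_table)


def _default_missingness() -> dict:
    rates = {m: 0.1 for m in ModalityId}
    rates[ModalityId.SMILES] = 0.0   # SMILES is present for every drug
    rates[ModalityId.GRAPH_2D] = 0.0  # carried with SMILES
    return rates


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic-fixture bundle."""

    n_drugs: int = 12
    n_contexts: int = 6
    n_genes: int = 40
    n_classes: int = 8          # ontology tree size
    n_triplets: int = 480       # ~60% of the ordered pair-context space
    n_sdl_pairs: int = 30
    geom_dim: int = 8           # precomputed 3D-embedding payload length
    missingness: dict = field(default_factory=_default_missingness)
    planted_rule: str = "sens_and_target"
    noise_rate: float = 0.02
    th_overexpressed: float = 400.0
    seed: int = 0

    def __post_init__(self):
        for m, r in self.missingness.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missingness rate for {m} outside [0, 1]")
        self.missingness[ModalityId.SMILES] = 0.0
        if self.n_drugs < 2:
            raise ValueError("need at least two drugs")
        if self.n_genes < 5:
            raise ValueError("need at least five genes")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng((self.seed, 977, stream))


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:03d}" for i in range(n)]


_TEXT_VOCAB = ["kinase", "inhibitor", "antimetabolite", "alkylating", "agent",
               "taxane", "platinum", "antibody", "hormone", "topoisomerase",
               "selective", "receptor", "antagonist", "analog"]

_CHAIN_ATOMS = ["C", "C", "C", "N", "O"]  # C-weighted draw keeps valence safe


def _random_smiles(rng: np.random.Generator) -> str:
    """A valence-safe SMILES from a closed grammar: linear/branched chains and
    single rings over C/N/O with single bonds only."""
    kind = rng.choice(["linear", "branched", "ring"])
    if kind == "ring":
        size = int(rng.integers(5, 7))
        middle = "".join(rng.choice(_CHAIN_ATOMS) for _ in range(size - 2))
        smiles = "C1" + middle + "C1"
        if rng.random() < 0.5:
            smiles += "C" * int(rng.integers(1, 4))
        return smiles
    length = int(rng.integers(4, 10))
    atoms = [str(rng.choice(_CHAIN_ATOMS)) for _ in range(length)]
    atoms[0] = "C"
    if kind == "branched":
        spots = [i for i in range(1, length - 1) if atoms[i] == "C"]
        if spots:
            i = int(rng.choice(spots))
            atoms[i] = atoms[i] + "(" + str(rng.choice(["C", "O", "N"])) + ")"
    return "".join(atoms)


@dataclass
class DrugFixture:
    records: list[DrugRecord]
    # latent per-drug truth, computed before missingness is applied
    sens_mean: dict[str, float]
    targets: dict[str, frozenset]


def gen_drugs(spec: FixtureSpec) -> DrugFixture:
    """Drug table with all eight modality payloads, dropped i.i.d. at the
    per-modality missingness rates (SMILES never dropped)."""
    rng = spec.rng(stream=1)
    genes = _gene_ids(spec.n_genes)
    records, sens_mean, targets = [], {}, {}
    for i in range(spec.n_drugs):
        did = f"d{i:03d}"
        mu = rng.normal(0.0, 1.0)
        sens = mu + rng.normal(0.0, 0.3, SENSITIVITY_DIM)
        tg = frozenset(rng.choice(genes, size=int(rng.integers(2, 5)),
                                  replace=False).tolist())
        smiles = _random_smiles(rng)
        payloads = {
            ModalityId.SMILES: smiles,
            ModalityId.GRAPH_2D: smiles,  # structure string; graph built at encode time
            ModalityId.TARGET: tg,
            ModalityId.GEOM_3D: rng.normal(0.0, 1.0, spec.geom_dim),
            ModalityId.TEXT: " ".join(rng.choice(_TEXT_VOCAB,
                                                 size=int(rng.integers(2, 4)),
                                                 replace=False).tolist()),
            ModalityId.ONTOLOGY: f"class_{int(rng.integers(spec.n_classes)):02d}",
            ModalityId.SIDE_EFFECTS: (rng.random(SIDE_EFFECT_DIM) < 0.2).astype(float),
            ModalityId.SENSITIVITY: sens,
        }
        sens_mean[did] = float(np.mean(sens))
        targets[did] = tg
        # apply missingness after latent truth is recorded
        kept = {}
        for m, v in payloads.items():
            if rng.random() >= spec.missingness.get(m, 0.0):
                kept[m] = v
        if ModalityId.SMILES not in kept:  # enforced invariant
            kept[ModalityId.SMILES] = payloads[ModalityId.SMILES]
        records.append(DrugRecord(did, kept))
    return DrugFixture(records, sens_mean, targets)


@dataclass
class NetworkFixture:
    ppi: PPINetwork
    ontology: nx.Graph
    sdl_pairs: set[tuple[str, str]]


def gen_networks(spec: FixtureSpec) -> NetworkFixture:
    """PPI from seeded preferential attachment, ontology as a random rooted
    tree over synthetic classes, SDL pairs sampled from ordered gene pairs."""
    rng = spec.rng(stream=2)
    genes = _gene_ids(spec.n_genes)
    ba = nx.barabasi_albert_graph(spec.n_genes, 2,
                                  seed=int(rng.integers(2 ** 31)))
    ppi = PPINetwork(nx.relabel_nodes(ba, dict(enumerate(genes))))
    onto = nx.Graph()
    onto.add_node("class_00")
    for i in range(1, spec.n_classes):
        parent = int(rng.integers(i))
        onto.add_edge(f"class_{i:02d}", f"class_{parent:02d}")
    sdl = set()
    while len(sdl) < min(spec.n_sdl_pairs,
                         spec.n_genes * (spec.n_genes - 1)):
        a, b = rng.choice(spec.n_genes, size=2, replace=False)
        sdl.add((genes[a], genes[b]))
    return NetworkFixture(ppi, onto, sdl)


def gen_expression(spec: FixtureSpec, unit: str = "TPM",
                   prefix: str = "c") -> ExpressionMatrix:
    """Lognormal expression over the gene panel; roughly 30% of values clear
    the over-expression threshold of 400.  Column sums are not forced to 1e6:
    the panel is a subset of a transcriptome, as in real subsampled data."""
    rng = spec.rng(stream=3 if unit == "TPM" else 4)
    genes = _gene_ids(spec.n_genes)
    contexts = [f"{prefix}{i:02d}" for i in range(spec.n_contexts)]
    vals = rng.lognormal(mean=np.log(240.0), sigma=1.0,
                         size=(spec.n_genes, spec.n_contexts))
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=contexts), unit)


def planted_label(drug_a: str, drug_b: str, context: str,
                  fixture: DrugFixture, expression: ExpressionMatrix,
                  spec: FixtureSpec) -> int:
    """Noise-free planted rule: synergy iff drug A's latent mean sensitivity
    exceeds the cohort median AND drug B targets a gene over-expressed in the
    context."""
    med = float(np.median(list(fixture.sens_mean.values())))
    high_a = fixture.sens_mean[drug_a] > med
    over = set(expression.values.index[
        expression.values[context] >= spec.th_overexpressed])
    hits_b = bool(fixture.targets[drug_b] & over)
    return int(high_a and hits_b)


def gen_triplets(spec: FixtureSpec, fixture: DrugFixture,
                 expression: ExpressionMatrix) -> list[TripletRecord]:
    """Labeled triplets: the planted rule determines labels, then each label
    flips independently at the noise rate."""
    rng = spec.rng(stream=5)
    contexts = list(expression.values.columns)
    drug_ids = [d.drug_id for d in fixture.records]
    space = [(a, b, c) for a in drug_ids for b in drug_ids if a != b
             for c in contexts]
    n = min(spec.n_triplets, len(space))
    chosen = rng.choice(len(space), size=n, replace=False)
    out = []
    for i in sorted(chosen):
        a, b, c = space[i]
        label = planted_label(a, b, c, fixture, expression, spec)
        if rng.random() < spec.noise_rate:
            label = 1 - label
        out.append(TripletRecord(a, b, c, float(label)))
    return out


XENO_DAYS = (0, 3, 7, 10, 14, 17, 21)


def gen_xenograft(spec: FixtureSpec, n_models: int = 4,
                  noise_sigma: float = 0.05):
    """Tumor-volume trajectories: Vol_t = Vol_0 exp((g - e) t) with
    model-specific growth g, pair-specific effect e and multiplicative
    lognormal noise, sampled at the standard day grid."""
    from .tasks import XenograftTrajectory

    rng = spec.rng(stream=6)
    drug_ids = [f"d{i:03d}" for i in range(spec.n_drugs)]
    out = []
    for mi in range(n_models):
        model_id = f"x{mi:02d}"
        growth = rng.uniform(0.05, 0.15)
        for _ in range(3):  # pairs per model
            a, b = rng.choice(len(drug_ids), size=2, replace=False)
            a, b = drug_ids[a], drug_ids[b]
            effect = rng.uniform(0.0, 0.25)
            points = []
            for t in XENO_DAYS:
                vol = 100.0 * np.exp((growth - effect) * t)
                if t > 0 and noise_sigma > 0:
                    vol *= rng.lognormal(0.0, noise_sigma)
                points.append((t, (vol - 100.0) / 100.0))
            points[0] = (0, 0.0)
            out.append(XenograftTrajectory(model_id, a, b, points))
    return out


def write_fixture_bundle(spec: FixtureSpec, outdir) -> dict:
    """Write the complete fixture bundle (drug table, networks, expression,
    triplets, trajectories, SDL pairs) as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    drugs = gen_drugs(spec)
    nets = gen_networks(spec)
    expr = gen_expression(spec)
    triplets = gen_triplets(spec, drugs, expr)
    trajectories = gen_xenograft(spec)

    write_drug_table(drugs.records, outdir / "drugs.tsv")
    write_edge_list(nets.ppi, outdir / "ppi.tsv")
    with open(outdir / "ontology.tsv", "w") as fh:
        for u, v in sorted(nets.ontology.edges()):
            fh.write(f"{u}\t{v}\n")
    write_gene_pairs(nets.sdl_pairs, outdir / "sdl_pairs.tsv")
    write_expression_matrix(expr, outdir / "expression_tpm.tsv")
    write_triplet_table(triplets, outdir / "triplets.tsv")
    rows = []
    for traj in trajectories:
        for t, dv in traj.points:
            rows.append({"model_id": traj.model_id, "drug_a": traj.drug_a,
                         "drug_b": traj.drug_b, "day": t, "delta_vol": repr(dv)})
    pd.DataFrame(rows).to_csv(outdir / "xenograft.tsv", sep="\t", index=False)
    return {"drugs": len(drugs.records), "triplets": len(triplets),
            "positives": int(sum(t.label for t in triplets)),
            "trajectories": len(trajectories)}
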