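"""The full drug-pair prediction model.

Wires the eight modality encoders (projector), the view augmentor, the shared
per-view head and the top-k aggregator into one trainable object covering the
three tasks: cell-line synergy classification, xenograft tumor-volume
regression (with an optional day-index time embedding) and typed drug-drug
interaction classification.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from . import encoders, nn, views
from .data import (MODALITIES, DrugRecord, ExpressionMatrix, ModalityId,
                   PPINetwork, RunConfig, TripletRecord)

logger = logging.getLogger("pairview")


@dataclass
class ForwardResult:
    """Everything a training step needs from one batch forward pass."""

    y_star: nn.Tensor                 # (n_batch,) aggregated predictions
    dense: nn.Tensor                  # (n_batch, 64) per-view predictions, invalid = 0
    valid: np.ndarray                 # boolean (n_batch, 64)
    # ViewKey -> (triplet rows, slice into the packed view arrays)
    per_key: dict = field(default_factory=dict)
    zhat_all: nn.Tensor | None = None   # (sum of valid views, 2 d_hid)
    preds_all: nn.Tensor | None = None  # (sum of valid views,)

    def view_embeddings(self, key) -> tuple[np.ndarray, nn.Tensor]:
        rows, sl = self.per_key[key]
        return rows, self.zhat_all.take_rows(np.arange(sl.start, sl.stop))

    def view_predictions(self, key) -> tuple[np.ndarray, nn.Tensor]:
        rows, sl = self.per_key[key]
        return rows, self.preds_all.take_rows(np.arange(sl.start, sl.stop))


class DrugCombinationModel:
    """Multi-modal drug-pair predictor with view augmentation.

    Parameters
    ----------
    drugs : list of DrugRecord
    config : RunConfig
    ppi : PPINetwork used for target expansion and cell-line contexts.
    ontology : optional ontology graph (networkx); enables the ontology
        modality for drugs carrying a node-id payload.
    expression : optional ExpressionMatrix (TPM) defining cell-line /
        xenograft-model contexts.
    task : "synergy" (binary), "xenograft" (regression, optional time), or
        "ddi" (binary per interaction type).
    interaction_types : required for the ddi task.
    restrict_modalities : optional subset of ModalityId; availability is
        intersected with it (single-modality ablations).
    use_placeholders : assign a learnable embedding to a missing modality
        instead of dropping its views — the single-modality-study convention,
        so ablated models still see every drug.
    """

    def __init__(self, drugs: list[DrugRecord], config: RunConfig,
                 ppi: PPINetwork,
                 ontology: Optional[nx.Graph] = None,
                 expression: Optional[ExpressionMatrix] = None,
                 task: str = "synergy",
                 interaction_types=None,
                 restrict_modalities=None,
                 use_placeholders: bool = False,
                 aligned_2d_encoder=None):
        if task not in ("synergy", "xenograft", "ddi"):
            raise ValueError(f"unknown task {task!r}")
        if task == "ddi" and not interaction_types:
            raise ValueError("ddi task requires interaction_types")
        if task != "ddi" and expression is None:
            raise ValueError(f"{task} task requires an expression matrix")
        self.config = config
        self.task = task
        self.ppi = ppi
        self.drugs = {d.drug_id: d for d in drugs}
        self.restrict = frozenset(restrict_modalities) if restrict_modalities else None
        self.aligned_2d_encoder = aligned_2d_encoder
        rng = config.rng(stream=1)
        dhid = config.hidden_dim

        # --- projector -----------------------------------------------------
        smiles_payloads = [d.payloads[ModalityId.SMILES] for d in drugs
                           if d.has(ModalityId.SMILES)]
        self.vocab = encoders.SmilesVocabulary.from_smiles(smiles_payloads)
        self.smiles_encoder = encoders.SmilesEncoder(
            self.vocab, config.smiles_dim, config.smiles_layers, dhid, rng,
            n_heads=config.smiles_heads)
        self._token_cache: dict[str, np.ndarray] = {}

        self.element_vocab = self._element_vocab(drugs)
        n_feat = (len(self.element_vocab) + 1 + len(encoders.DEGREES)
                  + len(encoders.CHARGES) + 1)
        self.graph_encoder = encoders.GraphEncoder(
            n_feat, config.graph_dim, config.graph_layers, dhid, rng)
        self._graph_cache: dict[str, encoders.MolGraph] = {}

        genes = set(ppi.genes)
        for d in drugs:
            genes.update(d.payloads.get(ModalityId.TARGET, ()))
        if expression is not None:
            genes.update(expression.values.index)
        self.gene_table = encoders.GeneEmbeddingTable(genes, config.gene_dim, rng)
        self.target_transform = nn.Linear(config.gene_dim, dhid, rng)
        self.cellline_transform = nn.Linear(config.gene_dim, dhid, rng)

        self._expanded_targets = {}
        for d in drugs:
            tg = d.payloads.get(ModalityId.TARGET)
            if tg:
                self._expanded_targets[d.drug_id] = encoders.expand_target_genes(
                    tg, ppi, config.k_g)

        geom_dims = {len(d.payloads[ModalityId.GEOM_3D]) for d in drugs
                     if d.has(ModalityId.GEOM_3D)}
        if len(geom_dims) > 1:
            raise ValueError("inconsistent 3D-embedding payload lengths")
        self._geom_dim = geom_dims.pop() if geom_dims else dhid
        self.geom_transform = nn.Linear(self._geom_dim, dhid, rng)

        text_dims = {len(d.payloads[ModalityId.TEXT]) for d in drugs
                     if d.has(ModalityId.TEXT)
                     and not isinstance(d.payloads[ModalityId.TEXT], str)}
        self._text_dim = text_dims.pop() if text_dims else 32
        self.text_transform = nn.Linear(self._text_dim, dhid, rng)

        self.ontology_table = None
        if ontology is not None and ontology.number_of_nodes() > 0:
            dim = min(config.ontology_dim, ontology.number_of_nodes())
            self.ontology_table = encoders.ontology_embeddings(
                ontology, alpha=config.rwr_alpha, dim=dim,
                tol=config.rwr_tol, max_iter=config.rwr_max_iter)
            self.ontology_transform = nn.Linear(dim, dhid, rng)
        else:
            self.ontology_transform = None

        self.sides_transform = nn.Linear(27, dhid, rng)
        self.sens_transform = nn.Linear(60, dhid, rng)

        self.use_placeholders = bool(use_placeholders)
        self.placeholders = {}
        if self.use_placeholders:
            self.placeholders = {
                m: nn.parameter(rng.normal(0.0, 0.1, size=(dhid,)))
                for m in MODALITIES}

        # --- contexts ------------------------------------------------------
        self.expression = expression
        self._context_gene_sets: dict[str, frozenset] = {}
        if expression is not None:
            for ctx in expression.values.columns:
                over = encoders.overexpressed_genes(
                    expression.values[ctx], config.th_overexpressed)
                self._context_gene_sets[ctx] = (
                    encoders.one_hop_expand(over, ppi) if over else frozenset())
        self.type_table = None
        if task == "ddi":
            self.type_table = encoders.InteractionTypeTable(
                interaction_types, dhid, rng)

        # --- augmentor / heads / aggregator --------------------------------
        self.augmentor = views.Augmentor(dhid, rng, dropout=config.dropout,
                                         with_context=(task != "ddi"))
        if task == "ddi":
            self.head = views.DDIHead(dhid, rng, dropout=config.dropout)
        else:
            self.head = views.SynergyHead(dhid, rng, dropout=config.dropout,
                                          classify=(task != "xenograft"))
        self.aggregator = views.Aggregator(len(views.ALL_VIEW_KEYS), rng,
                                           shortcut_mode=config.shortcut_mode)

    # ------------------------------------------------------------------ #
    @staticmethod
    def _element_vocab(drugs) -> list[str]:
        from rdkit import Chem

        elems = set()
        for d in drugs:
            s = d.payloads.get(ModalityId.SMILES) or d.payloads.get(ModalityId.GRAPH_2D)
            if not s:
                continue
            mol = Chem.MolFromSmiles(s)
            if mol is not None:
                elems.update(a.GetSymbol() for a in mol.GetAtoms())
        return sorted(elems)

    def parameters(self) -> list[nn.Tensor]:
        ps = (self.smiles_encoder.parameters() + self.graph_encoder.parameters()
              + self.gene_table.parameters()
              + self.target_transform.parameters()
              + self.cellline_transform.parameters()
              + self.geom_transform.parameters()
              + self.text_transform.parameters()
              + self.sides_transform.parameters()
              + self.sens_transform.parameters()
              + self.augmentor.parameters() + self.head.parameters()
              + self.aggregator.parameters())
        if self.ontology_transform is not None:
            ps += self.ontology_transform.parameters()
        if self.type_table is not None:
            ps += self.type_table.parameters()
        ps += [self.placeholders[m] for m in MODALITIES
               if m in self.placeholders]
        return ps

    # ------------------------------------------------------------------ #
    def availability(self, drug_id: str) -> tuple[ModalityId, ...]:
        """Modalities usable for a drug: explicit payloads, a molecular graph
        derivable from SMILES, and the 3D view when a precomputed vector or an
        alignment-trained 2D encoder exists."""
        if self.use_placeholders:
            avail = set(MODALITIES)
        else:
            avail = {m for m in MODALITIES if self._has_real(drug_id, m)}
        if self.restrict is not None:
            avail &= self.restrict
        return tuple(m for m in MODALITIES if m in avail)

    def _has_real(self, drug_id: str, m: ModalityId) -> bool:
        """Whether the modality is computable from actual data (payload or a
        derivation rule), as opposed to a learnable placeholder."""
        d = self.drugs[drug_id]
        has_structure = (d.has(ModalityId.SMILES) or d.has(ModalityId.GRAPH_2D))
        if m == ModalityId.GRAPH_2D:
            return has_structure
        if m == ModalityId.GEOM_3D:
            return d.has(m) or (self.aligned_2d_encoder is not None
                                and has_structure)
        if m == ModalityId.ONTOLOGY:
            return (d.has(m) and self.ontology_table is not None
                    and d.payloads[m] in self.ontology_table)
        return d.has(m)

    def _mol_graph(self, drug_id: str) -> encoders.MolGraph:
        if drug_id not in self._graph_cache:
            d = self.drugs[drug_id]
            s = d.payloads.get(ModalityId.GRAPH_2D) or d.payloads[ModalityId.SMILES]
            self._graph_cache[drug_id] = encoders.smiles_to_graph(s, self.element_vocab)
        return self._graph_cache[drug_id]

    def modality_embedding(self, drug_id: str, m: ModalityId) -> nn.Tensor:
        """Embedding of one modality of one drug (eval path, no dropout)."""
        d = self.drugs[drug_id]
        if m == ModalityId.SMILES:
            if drug_id not in self._token_cache:
                self._token_cache[drug_id] = self.vocab.encode(
                    encoders.tokenize_smiles(d.payloads[m]))
            return self.smiles_encoder(self._token_cache[drug_id])
        if m == ModalityId.GRAPH_2D:
            return self.graph_encoder(self._mol_graph(drug_id))
        if m == ModalityId.TARGET:
            return encoders.encode_gene_set(
                self._expanded_targets[drug_id], self.gene_table,
                self.target_transform, pool=self.config.gene_pool)
        if m == ModalityId.GEOM_3D:
            if d.has(m):
                return self.geom_transform(nn.constant(np.asarray(d.payloads[m])))
            if self.aligned_2d_encoder is not None:
                z2d = self.aligned_2d_encoder(self._mol_graph(drug_id))
                return self.geom_transform(z2d)
            raise KeyError(f"drug {drug_id!r}: 3D view unavailable")
        if m == ModalityId.TEXT:
            payload = d.payloads[m]
            vec = (encoders.hashed_text_vector(payload, self._text_dim)
                   if isinstance(payload, str) else np.asarray(payload))
            return self.text_transform(nn.constant(vec))
        if m == ModalityId.ONTOLOGY:
            vec = self.ontology_table.vector(d.payloads[m])
            return self.ontology_transform(nn.constant(vec))
        if m == ModalityId.SIDE_EFFECTS:
            return self.sides_transform(nn.constant(np.asarray(d.payloads[m], float)))
        if m == ModalityId.SENSITIVITY:
            return self.sens_transform(nn.constant(np.asarray(d.payloads[m], float)))
        raise KeyError(m)

    def _modality_matrix(self, m: ModalityId, drug_list: list[str]) -> nn.Tensor:
        """Stacked embeddings (len(drug_list), d_hid) for one modality, using
        the batched encoder paths where they exist.  In placeholder mode,
        drugs lacking the modality receive its learnable placeholder row."""
        if self.use_placeholders:
            have = [d for d in drug_list if self._has_real(d, m)]
            if len(have) < len(drug_list):
                ph = self.placeholders[m].reshape(1, -1)
                if not have:
                    return ph + nn.constant(
                        np.zeros((len(drug_list), self.config.hidden_dim)))
                base = nn.concat([self._modality_matrix(m, have), ph], axis=0)
                hmap = {d: i for i, d in enumerate(have)}
                idx = np.array([hmap.get(d, len(have)) for d in drug_list],
                               dtype=np.intp)
                return base.take_rows(idx)
        if m == ModalityId.SMILES:
            seqs = []
            for did in drug_list:
                if did not in self._token_cache:
                    self._token_cache[did] = self.vocab.encode(
                        encoders.tokenize_smiles(
                            self.drugs[did].payloads[ModalityId.SMILES]))
                seqs.append(self._token_cache[did])
            return self.smiles_encoder.encode_batch(seqs)
        if m == ModalityId.GRAPH_2D:
            return self.graph_encoder.encode_batch(
                [self._mol_graph(d) for d in drug_list])
        if m == ModalityId.GEOM_3D and self.aligned_2d_encoder is None:
            mat = np.stack([np.asarray(self.drugs[d].payloads[m], float)
                            for d in drug_list])
            return self.geom_transform(nn.constant(mat))
        if m == ModalityId.TEXT:
            rows = []
            for did in drug_list:
                payload = self.drugs[did].payloads[m]
                rows.append(encoders.hashed_text_vector(payload, self._text_dim)
                            if isinstance(payload, str)
                            else np.asarray(payload, float))
            return self.text_transform(nn.constant(np.stack(rows)))
        if m == ModalityId.ONTOLOGY:
            mat = np.stack([self.ontology_table.vector(
                self.drugs[d].payloads[m]) for d in drug_list])
            return self.ontology_transform(nn.constant(mat))
        if m == ModalityId.SIDE_EFFECTS:
            mat = np.stack([np.asarray(self.drugs[d].payloads[m], float)
                            for d in drug_list])
            return self.sides_transform(nn.constant(mat))
        if m == ModalityId.SENSITIVITY:
            mat = np.stack([np.asarray(self.drugs[d].payloads[m], float)
                            for d in drug_list])
            return self.sens_transform(nn.constant(mat))
        # TARGET (variable-size gene sets) and the aligned-3D path: per drug
        return nn.concat([self.modality_embedding(d, m).reshape(1, -1)
                          for d in drug_list], axis=0)

    def context_vector(self, context_id: str, time_days: Optional[int] = None) -> nn.Tensor:
        if self.task == "ddi":
            return self.type_table(context_id)
        if context_id not in self._context_gene_sets:
            raise KeyError(f"unknown context {context_id!r}")
        gene_set = self._context_gene_sets[context_id]
        if gene_set:
            c = encoders.encode_gene_set(gene_set, self.gene_table,
                                         self.cellline_transform,
                                         pool=self.config.gene_pool)
        else:
            logger.warning("context %r has no over-expressed genes", context_id)
            c = self.cellline_transform(nn.constant(np.zeros(self.gene_table.dim)))
        if self.task == "xenograft" and time_days is not None:
            c = c + nn.constant(
                encoders.time_embedding(time_days, self.config.hidden_dim))
        return c

    # ------------------------------------------------------------------ #
    def forward_batch(self, triplets: list[TripletRecord], train: bool = False,
                      rng: Optional[np.random.Generator] = None) -> ForwardResult:
        cfg = self.config
        n = len(triplets)
        for t in triplets:
            for did in (t.drug_a, t.drug_b):
                if did not in self.drugs:
                    raise KeyError(f"unknown drug {did!r}")
                if not self.availability(did):
                    raise ValueError(f"drug {did!r} has no available modality")

        drug_ids = sorted({t.drug_a for t in triplets} | {t.drug_b for t in triplets})
        drug_row = {d: i for i, d in enumerate(drug_ids)}
        avail = {d: set(self.availability(d)) for d in drug_ids}

        # per-modality embedding matrix over the drugs that have it
        z_mats: dict[ModalityId, tuple[nn.Tensor, dict]] = {}
        for m in MODALITIES:
            having = [d for d in drug_ids if m in avail[d]]
            if not having:
                continue
            z_mats[m] = (self._modality_matrix(m, having),
                         {d: i for i, d in enumerate(having)})

        ctx_keys = sorted({(t.context_id, t.time_days) for t in triplets},
                          key=lambda x: (x[0], -1 if x[1] is None else x[1]))
        ctx_row = {k: i for i, k in enumerate(ctx_keys)}
        C = nn.concat([self.context_vector(cid, td).reshape(1, -1)
                       for cid, td in ctx_keys], axis=0)

        idx_c = np.array([ctx_row[(t.context_id, t.time_days)] for t in triplets])

        # stack every modality matrix so all views become one gather + matmul
        mods_present = [m for m in MODALITIES if m in z_mats]
        offsets = {}
        run = 0
        for m in mods_present:
            offsets[m] = run
            run += z_mats[m][0].shape[0]
        Z_all = nn.concat([z_mats[m][0] for m in mods_present], axis=0)

        # vectorized per-key row selection: precompute per-modality drug-row
        # lookups for the A and B slots of every triplet
        a_rows_by_mod, b_rows_by_mod = {}, {}
        for m in mods_present:
            mmap = z_mats[m][1]
            a_rows_by_mod[m] = np.array(
                [mmap.get(t.drug_a, -1) for t in triplets], dtype=np.intp)
            b_rows_by_mod[m] = np.array(
                [mmap.get(t.drug_b, -1) for t in triplets], dtype=np.intp)

        per_key = {}
        valid = np.zeros((n, len(views.ALL_VIEW_KEYS)), dtype=bool)
        ga, gb, gc, trip_rows, key_cols = [], [], [], [], []
        cursor = 0
        for kidx, (ma, mb) in enumerate(views.ALL_VIEW_KEYS):
            if ma not in z_mats or mb not in z_mats:
                continue
            ra, rb = a_rows_by_mod[ma], b_rows_by_mod[mb]
            rows = np.flatnonzero((ra >= 0) & (rb >= 0))
            if rows.size == 0:
                continue
            ga.append(offsets[ma] + ra[rows])
            gb.append(offsets[mb] + rb[rows])
            gc.append(idx_c[rows])
            trip_rows.append(rows)
            key_cols.append(np.full(rows.size, kidx, dtype=np.intp))
            valid[rows, kidx] = True
            per_key[(ma, mb)] = (rows, slice(cursor, cursor + rows.size))
            cursor += rows.size

        ga, gb, gc = (np.concatenate(x) for x in (ga, gb, gc))
        trip_rows, key_cols = np.concatenate(trip_rows), np.concatenate(key_cols)
        za = Z_all.take_rows(ga)
        zb = Z_all.take_rows(gb)
        c_rows = C.take_rows(gc)
        if self.task == "ddi":
            zhat = self.augmentor(nn.concat([za, zb], axis=1), rng=rng, train=train)
            preds = self.head(zhat, c_rows, rng=rng, train=train)
        else:
            zhat = self.augmentor(nn.concat([za, zb, c_rows], axis=1),
                                  rng=rng, train=train)
            preds = self.head(zhat, rng=rng, train=train)

        dense = nn.scatter_vector(preds, trip_rows, key_cols,
                                  (n, len(views.ALL_VIEW_KEYS)))
        y_star = self.aggregator(dense, valid, cfg.top_k,
                                 classify=(self.task != "xenograft"))
        return ForwardResult(y_star, dense, valid, per_key,
                             zhat_all=zhat, preds_all=preds)

    def predict(self, triplets: list[TripletRecord],
                batch_size: Optional[int] = None) -> np.ndarray:
        """Aggregated predictions in eval mode (deterministic)."""
        out = []
        bs = batch_size or max(1, self.config.batch_size)
        for i in range(0, len(triplets), bs):
            res = self.forward_batch(triplets[i:i + bs], train=False)
            out.append(np.atleast_1d(res.y_star.data))
        return np.concatenate(out) if out else np.array([])

    # ------------------------------------------------------------------ #
    def save(self, path) -> None:
        params = self.parameters()
        arrays = {f"p{i}": p.data for i, p in enumerate(params)}
        meta = {"task": self.task, "config_hash": self.config.config_hash(),
                "n_params": len(params), "vocab": self.vocab.to_dict()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    def load_parameters(self, path) -> None:
        with np.load(path) as blob:
            meta = json.loads(bytes(blob["__meta__"]).decode())
            params = self.parameters()
            if meta["n_params"] != len(params):
                raise ValueError("checkpoint does not match this model architecture")
            if meta["task"] != self.task:
                raise ValueError(f"checkpoint task {meta['task']!r} != {self.task!r}")
            for i, p in enumerate(params):
                arr = blob[f"p{i}"]
                if arr.shape != p.data.shape:
                    raise ValueError(f"parameter {i} shape mismatch")
                p.data = arr.astype(np.float64)
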