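"""Projector tests: tokenizer grammar, encoder invariants (shape, determinism,
permutation invariance), RWR/SVD ontology embeddings, context features."""

import re

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairview import nn
from pairview.data import PPINetwork
from pairview.encoders import (CLS_TOKEN, GeneEmbeddingTable, GraphEncoder,
                               InteractionTypeTable, SmilesEncoder,
                               SmilesVocabulary, cell_line_context,
                               encode_gene_set, expand_target_genes,
                               hashed_text_vector, infonce_2d3d, MolGraph,
                               ontology_embeddings, rwr_node_profiles,
                               smiles_to_graph, time_embedding,
                               tokenize_smiles)


class TestTokenizer:
    def test_simple_chain(self):
        assert tokenize_smiles("CCO") == ["C", "C", "O", CLS_TOKEN]

    def test_two_letter_atom_is_one_token(self):
        assert tokenize_smiles("CCl") == ["C", "Cl", CLS_TOKEN]
        assert tokenize_smiles("CBr") == ["C", "Br", CLS_TOKEN]

    def test_aromatic_ring_token_count(self):
        toks = tokenize_smiles("c1ccccc1")
        assert len(toks) == 9 and toks[-1] == CLS_TOKEN

    def test_bracket_atom_single_token(self):
        assert tokenize_smiles("[NH4+]")[0] == "[NH4+]"

    def test_empty_string_rejected(self):
        with pytest.raises(ValueError):
            tokenize_smiles("")

    @given(st.text(alphabet="CNOclnos()=#123[]+-BrF", min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_regex_oracle(self, s):
        # independent oracle: findall over the same closed grammar
        oracle = re.compile(
            r"\[[^\]]+\]|Br|Cl|%\d{2}|\d|[BCNOPSFI]|[bcnops]|[=#$:/\\().+-]|.")
        assert tokenize_smiles(s)[:-1] == oracle.findall(s)

    def test_unknown_characters_map_to_unk(self):
        vocab = SmilesVocabulary.from_smiles(["CCO"])
        ids = vocab.encode(tokenize_smiles("CXO"))
        assert ids[1] == vocab.index["[UNK]"]


class TestSmilesEncoder:
    def _encoder(self, dhid=16, seed=0):
        vocab = SmilesVocabulary.from_smiles(["CCO", "CCN", "C1CCCCC1"])
        rng = np.random.default_rng(seed)
        return vocab, SmilesEncoder(vocab, 8, 1, dhid, rng, n_heads=1)

    def test_eval_mode_deterministic(self):
        vocab, enc = self._encoder()
        ids = vocab.encode(tokenize_smiles("CCO"))
        assert np.array_equal(enc(ids).data, enc(ids).data)

    @pytest.mark.parametrize("dhid", [16, 512])
    def test_output_length_is_dhid(self, dhid):
        vocab, enc = self._encoder(dhid=dhid)
        out = enc(vocab.encode(tokenize_smiles("CCN")))
        assert out.shape == (dhid,) and np.all(np.isfinite(out.data))

    def test_distinct_strings_collide_with_probability_zero(self, rng):
        vocab, enc = self._encoder(seed=3)
        seen = []
        strings = ["C" * n + tail for n in range(1, 11) for tail in ("O", "N")]
        for s in strings:
            seen.append(enc(vocab.encode(tokenize_smiles(s))).data)
        for i in range(len(seen)):
            for j in range(i + 1, len(seen)):
                assert not np.allclose(seen[i], seen[j])

    def test_overlong_sequence_truncated_with_warning(self, caplog):
        vocab, enc = self._encoder()
        enc.max_len = 5
        out = enc(vocab.encode(tokenize_smiles("C" * 30)))
        assert out.shape == (16,)
        assert any("truncat" in r.message for r in caplog.records)


class TestGraphEncoder:
    def _graph_encoder(self, seed=0):
        return GraphEncoder(n_feat=20, dim=8, n_layers=2, out_dim=16,
                            rng=np.random.default_rng(seed))

    def test_single_atom_mean_equals_max_pool(self):
        enc = self._graph_encoder()
        g = MolGraph(np.eye(20)[:1], np.zeros((1, 1)))
        # with one node, mean-pool == max-pool == the node embedding
        h = enc.proj(nn.constant(g.features)).relu()
        for l in enc.layers:
            h = (l["self"](h) + l["nei"](nn.constant(np.zeros((1, 1))) @ h)).relu()
        expected = enc.out(nn.concat([h.reshape(-1), h.reshape(-1)], axis=0))
        assert np.allclose(enc(g).data, expected.data)

    def test_permutation_invariance_exact(self, rng):
        enc = self._graph_encoder()
        feats = np.eye(20)[rng.integers(0, 20, size=6)]
        adj = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0), (1, 4)]:
            adj[i, j] = adj[j, i] = 1
        base = enc(MolGraph(feats, adj)).data
        for _ in range(5):
            perm = rng.permutation(6)
            g2 = MolGraph(feats[perm], adj[np.ix_(perm, perm)])
            assert np.allclose(enc(g2).data, base, atol=1e-12)

    def test_isomorphic_relabeled_molecules_equal(self):
        enc = GraphEncoder(n_feat=16, dim=8, n_layers=2, out_dim=16,
                           rng=np.random.default_rng(1))
        # same molecule written with different atom orderings
        g1 = smiles_to_graph("OCC", ["C", "O"])
        g2 = smiles_to_graph("CCO", ["C", "O"])
        perm_free = sorted(map(tuple, g1.features.tolist()))
        assert perm_free == sorted(map(tuple, g2.features.tolist()))
        assert np.allclose(enc(g1).data, enc(g2).data, atol=1e-10)

    def test_empty_graph_rejected(self):
        enc = self._graph_encoder()
        with pytest.raises(ValueError):
            enc(MolGraph(np.zeros((0, 20)), np.zeros((0, 0))))


class TestTargetExpansion:
    def _net(self, edges):
        g = nx.Graph()
        g.add_weighted_edges_from(edges)
        return PPINetwork(g)

    def test_k_zero_is_identity(self):
        net = self._net([("t", "a", 1.0)])
        assert expand_target_genes({"t"}, net, 0) == {"t"}

    def test_star_with_fewer_neighbors_than_k(self):
        net = self._net([("T", "n1", 1.0), ("T", "n2", 1.0), ("T", "n3", 1.0)])
        assert expand_target_genes({"T"}, net, 5) == {"T", "n1", "n2", "n3"}

    def test_matches_bruteforce_sorted_neighbor_oracle(self, rng):
        g = nx.gnm_random_graph(25, 60, seed=11)
        for u, v in g.edges:
            g.edges[u, v]["weight"] = float(rng.random())
        g = nx.relabel_nodes(g, {i: f"g{i:02d}" for i in g.nodes})
        net = PPINetwork(g)
        targets = {"g03", "g10", "g24"}
        got = expand_target_genes(targets, net, 2)
        expected = set(targets)
        for t in targets:
            ranked = sorted(g.neighbors(t),
                            key=lambda n: (-g.edges[t, n]["weight"], n))
            expected.update(ranked[:2])
        assert got == expected

    def test_gene_absent_from_network_contributes_itself(self):
        net = self._net([("a", "b", 1.0)])
        assert expand_target_genes({"zz"}, net, 3) == {"zz"}


class TestGeneSetEncoder:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        table = GeneEmbeddingTable([f"g{i}" for i in range(12)], 6, rng)
        return table, nn.Linear(6, 10, rng)

    def test_singleton_is_transform_of_its_embedding(self):
        table, lin = self._setup()
        out = encode_gene_set({"g3"}, table, lin)
        expected = lin(table.table.take_rows([table.index["g3"]]).reshape(-1))
        assert np.allclose(out.data, expected.data)

    def test_order_invariance(self):
        table, lin = self._setup()
        assert np.allclose(encode_gene_set(["g1", "g2"], table, lin).data,
                           encode_gene_set(["g2", "g1"], table, lin).data)

    def test_matches_bruteforce_mean_oracle(self):
        table, lin = self._setup(seed=4)
        genes = [f"g{i}" for i in range(10)]
        acc = np.zeros(6)
        for g in genes:  # independent loop-based mean
            acc += table.table.data[table.index[g]]
        expected = lin(nn.constant(acc / len(genes)))
        assert np.allclose(encode_gene_set(genes, table, lin).data,
                           expected.data, atol=1e-12)

    def test_all_unknown_pools_to_zero(self, caplog):
        table, lin = self._setup()
        out = encode_gene_set({"nope"}, table, lin)
        assert np.allclose(out.data, lin(nn.constant(np.zeros(6))).data)


class TestInfoNCE2D3D:
    @pytest.mark.parametrize("n", [2, 4, 8])
    def test_uniform_scores_give_log_n(self, n):
        z = nn.constant(np.zeros((n, 4)))  # all pairwise scores equal (0)
        assert float(infonce_2d3d(z, z).data) == pytest.approx(np.log(n))

    def test_strongly_matched_loss_approaches_zero(self):
        z = nn.constant(np.eye(4) * 50.0)
        assert float(infonce_2d3d(z, z).data) < 1e-6

    def test_matches_double_loop_oracle(self, rng):
        a, b = rng.normal(size=(4, 5)), rng.normal(size=(4, 5))
        s = a @ b.T
        # brute-force evaluation of the symmetric InfoNCE
        def direction(mat):
            tot = 0.0
            for i in range(4):
                tot += -np.log(np.exp(mat[i, i]) / np.exp(mat[i]).sum())
            return tot / 4
        expected = 0.5 * direction(s) + 0.5 * direction(s.T)
        got = float(infonce_2d3d(nn.constant(a), nn.constant(b)).data)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_batch_of_one_rejected(self):
        with pytest.raises(ValueError):
            infonce_2d3d(nn.constant(np.ones((1, 3))), nn.constant(np.ones((1, 3))))


class TestHashedText:
    def test_identical_descriptions_identical_vectors(self):
        assert np.array_equal(hashed_text_vector("kinase inhibitor"),
                              hashed_text_vector("kinase inhibitor"))

    def test_matches_independent_hash_reimplementation(self):
        import hashlib

        text, dim = "selective EGFR kinase inhibitor", 32
        expected = np.zeros(dim)
        for tok in text.lower().split():  # alnum tokens here
            h = hashlib.sha256(tok.encode()).digest()
            expected[int.from_bytes(h[:4], "little") % dim] += (
                1.0 if h[4] % 2 == 0 else -1.0)
        assert np.array_equal(hashed_text_vector(text, dim), expected)


class TestRWR:
    def test_single_node_profile_is_one(self):
        g = nx.Graph(); g.add_node("a")
        nodes, P = rwr_node_profiles(g)
        assert nodes == ["a"] and np.allclose(P, [[1.0]])

    def test_two_node_path_fixed_point(self):
        g = nx.path_graph(2)
        _, P = rwr_node_profiles(g, alpha=0.5, tol=1e-12, max_iter=500)
        # analytic fixed point: t = 0.5 W t + 0.5 e  ->  (2/3, 1/3)
        assert np.allclose(P[0], [2 / 3, 1 / 3], atol=1e-9)
        assert np.allclose(P[1], [1 / 3, 2 / 3], atol=1e-9)

    def test_profiles_are_probability_vectors_each_iteration(self):
        g = nx.gnm_random_graph(10, 18, seed=3)
        for it in (1, 2, 5, 50):
            _, P = rwr_node_profiles(g, alpha=0.4, tol=0.0, max_iter=it)
            assert np.all(P >= -1e-15)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_fixed_point_satisfies_recurrence(self):
        g = nx.gnm_random_graph(10, 20, seed=5)
        nodes, P = rwr_node_profiles(g, alpha=0.5, tol=1e-10, max_iter=1000)
        A = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
        W = A / A.sum(axis=0)
        for j in range(len(nodes)):
            t = P[j]
            resid = (1 - 0.5) * W @ t + 0.5 * np.eye(len(nodes))[j] - t
            assert np.abs(resid).sum() < 1e-8


class TestOntologyEmbeddings:
    def _twin_graph(self):
        # a and b are twins: same neighbor set {c}, no edge between them
        g = nx.Graph()
        g.add_edges_from([("a", "c"), ("b", "c"), ("c", "d"), ("d", "e")])
        return g

    def test_twin_nodes_are_geometrically_exchangeable(self):
        g = self._twin_graph()
        table = ontology_embeddings(g, alpha=0.5, dim=5)
        ia, ib = table.nodes.index("a"), table.nodes.index("b")
        va, vb = table.vectors[ia], table.vectors[ib]
        assert np.linalg.norm(va) == pytest.approx(np.linalg.norm(vb), rel=1e-8)
        for other in ("c", "d", "e"):
            vo = table.vectors[table.nodes.index(other)]
            assert np.linalg.norm(va - vo) == pytest.approx(
                np.linalg.norm(vb - vo), rel=1e-6, abs=1e-8)

    def test_full_rank_svd_reconstructs_profiles(self):
        g = nx.gnm_random_graph(8, 14, seed=2)
        nodes, P = rwr_node_profiles(g, alpha=0.5, tol=1e-12, max_iter=2000)
        U, S, Vt = np.linalg.svd(P, full_matrices=False)
        assert np.allclose(U @ np.diag(S) @ Vt, P, atol=1e-8)
        table = ontology_embeddings(g, alpha=0.5, dim=len(nodes), tol=1e-12,
                                    max_iter=2000)
        # Gram identity: embeddings reproduce P^T P exactly at full rank
        assert np.allclose(table.vectors @ table.vectors.T, P.T @ P, atol=1e-8)

    def test_captured_variance_matches_singular_values(self):
        g = nx.cycle_graph(6)
        _, P = rwr_node_profiles(g, alpha=0.5, tol=1e-12, max_iter=2000)
        S = np.linalg.svd(P, compute_uv=False)
        table = ontology_embeddings(g, alpha=0.5, dim=2, tol=1e-12, max_iter=2000)
        captured = np.sum(table.vectors ** 2)
        assert captured == pytest.approx(np.sum(S[:2] ** 2), rel=1e-8)

    def test_dim_exceeding_nodes_rejected(self):
        with pytest.raises(ValueError):
            ontology_embeddings(nx.path_graph(3), dim=5)


class TestContextFeatures:
    def test_overexpression_threshold_is_inclusive(self):
        import pandas as pd

        tpm = pd.Series({"g0": 500.0, "g1": 100.0, "g2": 400.0})
        from pairview.encoders import overexpressed_genes

        assert overexpressed_genes(tpm, 400.0) == {"g0", "g2"}

    def test_no_ppi_edges_keeps_set_unchanged(self):
        from pairview.encoders import one_hop_expand

        net = PPINetwork(nx.empty_graph(0, create_using=nx.Graph))
        assert one_hop_expand({"g0"}, net) == {"g0"}

    def test_one_hop_on_chain(self):
        g = nx.Graph()
        g.add_edges_from([("g0", "g1"), ("g1", "g2")])
        from pairview.encoders import one_hop_expand

        assert one_hop_expand({"g0"}, PPINetwork(g)) == {"g0", "g1"}

    def test_empty_overexpressed_set_gives_zero_pool(self, caplog):
        import pandas as pd

        rng = np.random.default_rng(0)
        table = GeneEmbeddingTable(["g0"], 4, rng)
        lin = nn.Linear(4, 6, rng)
        net = PPINetwork(nx.Graph())
        out = cell_line_context(pd.Series({"g0": 1.0}), 400.0, net, table, lin)
        assert np.allclose(out.data, lin(nn.constant(np.zeros(4))).data)


class TestTimeEmbedding:
    def test_t_zero_alternates_zero_one(self):
        v = time_embedding(0, 8)
        assert np.array_equal(v, [0, 1, 0, 1, 0, 1, 0, 1])

    def test_squared_norm_is_half_dim(self, rng):
        for t in rng.integers(0, 100, size=20):
            v = time_embedding(int(t), 512)
            assert np.sum(v * v) == pytest.approx(256.0)

    def test_t_one_first_pair(self):
        v = time_embedding(1, 512)
        assert v[0] == pytest.approx(np.sin(1), abs=1e-6)
        assert v[1] == pytest.approx(np.cos(1), abs=1e-6)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            time_embedding(3, 7)


class TestInteractionTypes:
    def test_lookup_and_unknown_type(self, rng):
        table = InteractionTypeTable(["t1", "t2", "t3"], 8, rng)
        v = table("t2")
        assert v.shape == (8,)
        assert np.array_equal(v.data, table("t2").data)
        with pytest.raises(KeyError):
            table("nope")

    def test_rows_distinct_after_random_init(self, rng):
        table = InteractionTypeTable([f"t{i}" for i in range(20)], 8, rng)
        assert len({tuple(r) for r in table.table.data.round(12)}) == 20
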