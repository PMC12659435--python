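"""Retrieval against exhaustive oracles; confidence; ppm clustering."""

import numpy as np
import pytest

from fluorospec import retrieval
from fluorospec.chem import MoleculeRecord
from fluorospec.retrieval import (
    CandidateHit,
    EmbeddingIndex,
    build_index,
    cluster_by_precursor,
    confidence_score,
    retrieve_topk,
)
from fluorospec.spectra import EmptyInputError, SpectrumRecord


def synthetic_record(i: int, is_pfas: bool = False) -> MoleculeRecord:
    """A structurally meaningless record for geometry-only tests."""
    return MoleculeRecord(
        source_smiles=f"M{i}", canonical_smiles=f"MOL{i:05d}",
        inchikey2d=f"K{i:013d}", formula=f"C{i}", monoisotopic_mass=100.0 + i,
        is_pfas=is_pfas, smiles_tokens=("C",))


def synthetic_index(n: int, dim: int, rng, duplicates: int = 0) -> EmbeddingIndex:
    emb = rng.standard_normal((n, dim)).astype(np.float32)
    for d in range(duplicates):  # planted exact ties
        emb[n - 1 - d] = emb[d]
    records = tuple(synthetic_record(i, is_pfas=(i % 5 == 0)) for i in range(n))
    return EmbeddingIndex(embeddings=emb, records=records)


def oracle_ranking(query, index, k):
    """Brute-force MSE scan with the documented tie order."""
    dists = [float(np.mean((e - query) ** 2)) for e in index.embeddings]
    order = sorted(range(len(index)),
                   key=lambda i: (dists[i], index.records[i].canonical_smiles))
    return [(index.records[i].canonical_smiles, dists[i]) for i in order[:k]]


class TestRetrieveTopK:
    def test_matches_exhaustive_oracle_with_ties(self, rng):
        index = synthetic_index(200, 8, rng, duplicates=3)
        for _ in range(25):
            query = rng.standard_normal(8).astype(np.float32)
            hits = retrieve_topk(query, index, k=20)
            assert [(h.record.canonical_smiles, h.distance) for h in hits] \
                == oracle_ranking(query, index, 20)
            assert [h.rank for h in hits] == list(range(1, 21))
            dists = [h.distance for h in hits]
            assert dists == sorted(dists)

    def test_self_query_rank_one_distance_zero(self, rng):
        index = synthetic_index(50, 8, rng)
        hits = retrieve_topk(index.embeddings[7], index, k=5)
        assert hits[0].record.canonical_smiles == "MOL00007"
        assert hits[0].distance == 0.0

    def test_small_index_clamps_k(self, rng):
        index = synthetic_index(30, 4, rng)
        assert len(retrieve_topk(rng.standard_normal(4), index, k=100)) == 30

    def test_errors(self, rng):
        index = synthetic_index(10, 4, rng)
        with pytest.raises(ValueError):
            retrieve_topk(rng.standard_normal(5), index, k=3)
        with pytest.raises(ValueError):
            retrieve_topk(rng.standard_normal(4), index, k=0)

    def test_hand_set_coordinates(self):
        emb = np.array([[0, 0], [1, 0], [0, 2], [3, 3], [0.5, 0]],
                       dtype=np.float32)
        records = tuple(synthetic_record(i) for i in range(5))
        index = EmbeddingIndex(embeddings=emb, records=records)
        hits = retrieve_topk(np.zeros(2, dtype=np.float32), index, k=5)
        assert [h.record.canonical_smiles[-1] for h in hits] \
            == ["0", "4", "1", "2", "3"]


class TestBuildIndex:
    def test_duplicates_indexed_once(self, memorizing_ae):
        model, library, _ = memorizing_ae
        doubled = list(library) + list(library)
        index = build_index(doubled, model)
        assert len(index) == len({r.canonical_smiles for r in library})

    def test_rebuild_identical(self, memorizing_ae):
        model, library, _ = memorizing_ae
        a = build_index(library, model)
        b = build_index(library, model)
        assert np.array_equal(a.embeddings, b.embeddings)

    def test_empty_library(self, memorizing_ae):
        with pytest.raises(EmptyInputError):
            build_index([], memorizing_ae[0])


class TestConfidence:
    @pytest.mark.parametrize("n_pfas,expected", [(20, 100.0), (10, 50.0),
                                                 (0, 0.0)])
    def test_fraction(self, n_pfas, expected):
        hits = [CandidateHit(synthetic_record(i, is_pfas=(i < n_pfas)),
                             0.1, i + 1) for i in range(20)]
        assert confidence_score(hits) == expected

    def test_order_invariant(self):
        hits = [CandidateHit(synthetic_record(i, is_pfas=(i % 3 == 0)),
                             0.1, i + 1) for i in range(9)]
        assert confidence_score(hits) == confidence_score(hits[::-1])

    def test_empty(self):
        with pytest.raises(EmptyInputError):
            confidence_score([])


def oracle_clusters(masses, tol_ppm):
    """O(n^2) pairwise relation + connected components via networkx."""
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(len(masses)))
    for i in range(len(masses)):
        for j in range(i + 1, len(masses)):
            rel = abs(masses[i] - masses[j]) / max(masses[i], masses[j]) * 1e6
            if rel <= tol_ppm:
                g.add_edge(i, j)
    return sorted(sorted(c) for c in nx.connected_components(g))


def records_from_masses(masses):
    return [SpectrumRecord(precursor_mz=float(m), adduct=None, ion_mode=None,
                           collision_energy=None, peaks=(), source_id=str(i))
            for i, m in enumerate(masses)]


class TestClusterByPrecursor:
    def test_simple_example(self):
        clusters = cluster_by_precursor(
            records_from_masses([500.0000, 500.0020, 900.0]))
        assert sorted(map(sorted, clusters)) == [[0, 1], [2]]

    def test_transitive_chain_joins(self):
        clusters = cluster_by_precursor(
            records_from_masses([500.0000, 500.0022, 500.0044]))
        assert sorted(map(sorted, clusters)) == [[0, 1, 2]]

    def test_empty(self):
        assert cluster_by_precursor([]) == []

    def test_matches_brute_force_on_random_masses(self, rng):
        masses = np.round(rng.uniform(100, 999, size=300), 4)
        # plant a tight chain
        masses[:5] = [400.0000, 400.0018, 400.0036, 400.0054, 400.0072]
        records = records_from_masses(masses)
        ours = sorted(sorted(c) for c in cluster_by_precursor(records))
        assert ours == oracle_clusters(list(masses), 5.0)

    def test_partition_covers_all(self, rng):
        masses = rng.uniform(100, 999, size=200)
        clusters = cluster_by_precursor(records_from_masses(masses))
        flat = sorted(i for c in clusters for i in c)
        assert flat == list(range(200))
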