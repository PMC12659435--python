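"""MCS triple vs exhaustive oracle; fingerprint stats; retrieval scoring."""

import itertools

import networkx as nx
import numpy as np
import pytest
from networkx.algorithms import isomorphism
from rdkit import Chem

from fluorospec import metrics
from fluorospec.chem import prepare_molecule
from fluorospec.retrieval import AnnotationResult, CandidateHit
from fluorospec.spectra import EmptyInputError

# 12 molecules, each <= 12 heavy atoms: small PFAS, common solvents,
# aromatics -- representative of retrieval candidates at desk scale.
MCS_FIXTURE = [
    "OC(=O)C(F)(F)F",        # trifluoroacetic acid
    "OS(=O)(=O)C(F)(F)F",    # triflic acid
    "OC(=O)C(F)(F)C(F)(F)F", # perfluoropropanoic acid
    "CCO",                   # ethanol
    "COC",                   # dimethyl ether
    "CC(=O)O",               # acetic acid
    "c1ccccc1",              # benzene
    "Cc1ccccc1",             # toluene
    "c1ccncc1",              # pyridine
    "CCCCO",                 # butanol
    "FC(F)(F)CO",            # trifluoroethanol
    "CCOC(C)=O",             # ethyl acetate
]


def mol_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), el=atom.GetSymbol(), ring=atom.IsInRing())
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(),
                   order=str(bond.GetBondType()), ring=bond.IsInRing())
    return g


def oracle_mcs_atoms(smiles_a: str, smiles_b: str) -> int:
    """Exhaustive maximum common connected induced substructure size.

    Enumerates connected induced subgraphs of the smaller molecule from
    largest to smallest and tests induced-subgraph isomorphism into the
    other under element / ring-membership / bond-order matching.
    """
    ga = mol_graph(Chem.MolFromSmiles(smiles_a))
    gb = mol_graph(Chem.MolFromSmiles(smiles_b))
    if len(ga) > len(gb):
        ga, gb = gb, ga
    node_match = lambda x, y: x["el"] == y["el"] and x["ring"] == y["ring"]
    edge_match = lambda x, y: x["order"] == y["order"] and x["ring"] == y["ring"]
    for size in range(len(ga), 0, -1):
        for nodes in itertools.combinations(ga.nodes, size):
            sub = ga.subgraph(nodes)
            if not nx.is_connected(sub):
                continue
            matcher = isomorphism.GraphMatcher(gb, sub, node_match=node_match,
                                               edge_match=edge_match)
            if matcher.subgraph_is_isomorphic():
                return size
    return 0


class TestMcsMetrics:
    def test_identity_pairs_are_exactly_one(self):
        for smiles in MCS_FIXTURE:
            rec = prepare_molecule(smiles)
            assert metrics.mcs_metrics(rec, rec) == (1.0, 1.0, 1.0)

    def test_ethane_vs_propane(self):
        ethane, propane = prepare_molecule("CC"), prepare_molecule("CCC")
        ratio, tanimoto, overlap = metrics.mcs_metrics(ethane, propane)
        assert (ratio, overlap) == (1.0, 1.0)
        assert tanimoto == pytest.approx(2 / 3)

    def test_methane_vs_water_no_common_atom(self):
        assert metrics.mcs_metrics(prepare_molecule("C"),
                                   prepare_molecule("O")) == (0.0, 0.0, 0.0)

    def test_all_fixture_pairs_match_exhaustive_oracle(self):
        records = {s: prepare_molecule(s) for s in MCS_FIXTURE}
        for sa, sb in itertools.combinations(MCS_FIXTURE, 2):
            ra, rb = records[sa], records[sb]
            a_r = Chem.MolFromSmiles(sa).GetNumAtoms()
            a_p = Chem.MolFromSmiles(sb).GetNumAtoms()
            a_mcs = oracle_mcs_atoms(sa, sb)
            expected = (
                a_mcs / a_r,
                a_mcs / (a_r + a_p - a_mcs) if a_mcs else 0.0,
                a_mcs / min(a_r, a_p),
            )
            got = metrics.mcs_metrics(ra, rb)
            assert got == pytest.approx(expected), (sa, sb)

    def test_triple_inequalities(self):
        records = [prepare_molecule(s) for s in MCS_FIXTURE]
        for ra, rb in itertools.combinations(records, 2):
            ratio, tanimoto, overlap = metrics.mcs_metrics(ra, rb)
            assert tanimoto <= overlap + 1e-12
            assert 0 <= ratio <= 1 and 0 <= tanimoto <= 1 and 0 <= overlap <= 1


class TestFingerprintStats:
    def test_self_similarity(self):
        rec = prepare_molecule("OC(=O)C(F)(F)F")
        assert metrics.fingerprint_similarity_stats(rec, [rec]) == (1.0, 1.0, 1.0)

    def test_permutation_invariance(self):
        ref = prepare_molecule("CCO")
        candidates = [prepare_molecule(s) for s in ("CCCO", "CC(=O)O", "CCN")]
        assert metrics.fingerprint_similarity_stats(ref, candidates) \
            == pytest.approx(
                metrics.fingerprint_similarity_stats(ref, candidates[::-1]))

    def test_average_between_min_and_max(self):
        ref = prepare_molecule("CCO")
        candidates = [prepare_molecule(s) for s in ("CCCO", "c1ccccc1", "CCO")]
        avg, top, bottom = metrics.fingerprint_similarity_stats(ref, candidates)
        assert bottom <= avg <= top
        assert top == 1.0  # identical candidate present

    def test_empty_candidates(self):
        with pytest.raises(EmptyInputError):
            metrics.fingerprint_similarity_stats(prepare_molecule("CCO"), [])


def make_result(sid, candidate_records, distances=None):
    hits = tuple(
        CandidateHit(rec, 0.0 if distances is None else distances[i], i + 1)
        for i, rec in enumerate(candidate_records))
    conf = 100.0 * sum(h.record.is_pfas for h in hits) / len(hits)
    return AnnotationResult(spectrum_id=sid, hits=hits, confidence_score=conf)


@pytest.fixture(scope="module")
def molecules():
    return {name: prepare_molecule(s) for name, s in {
        "ethanol": "CCO",
        "acetate": "CC(=O)O",
        "propanol": "CCCO",
    }.items()}


class TestEvaluateRetrieval:

    def test_hand_computed_table(self, molecules):
        truth_mol = molecules["ethanol"]
        other = molecules["acetate"]
        same_formula = prepare_molecule("COC")  # C2H6O like ethanol
        # compound A (ethanol): 4 spectra, 1 with the molecule in top-k
        results = {
            "a1": make_result("a1", [truth_mol, other]),
            "a2": make_result("a2", [other, same_formula]),   # formula only
            "a3": make_result("a3", [other, other]),
            "a4": make_result("a4", [other, other]),
            # compound B (propanol): 1 spectrum, never retrieved
            "b1": make_result("b1", [other, other]),
        }
        truth = {sid: truth_mol for sid in ("a1", "a2", "a3", "a4")}
        truth["b1"] = molecules["propanol"]
        report = metrics.evaluate_retrieval(results, truth)
        assert report.molecule_accuracy == 50.0        # 1 of 2 compounds
        assert report.molecule_accuracy_spectra == 20.0  # 1 of 5 spectra
        assert report.formula_accuracy == 50.0
        assert report.formula_accuracy_spectra == 40.0   # a1 + a2
        row = {r.compound_key: r for r in report.per_compound}
        assert row[truth_mol.inchikey2d].annotation_accuracy == 25.0
        assert row[truth_mol.inchikey2d].n_spectra == 4

    def test_formula_match_does_not_imply_molecule_match(self, molecules):
        same_formula = prepare_molecule("COC")
        results = {"s": make_result("s", [same_formula])}
        truth = {"s": molecules["ethanol"]}
        report = metrics.evaluate_retrieval(results, truth)
        assert report.molecule_accuracy == 0.0
        assert report.formula_accuracy == 100.0

    def test_orphan_spectrum_rejected(self, molecules):
        results = {"x": make_result("x", [molecules["ethanol"]])}
        with pytest.raises(metrics.MissingTruthError):
            metrics.evaluate_retrieval(results, {})


class TestDatasetConfidence:
    def test_strict_all_rule(self):
        pfas = prepare_molecule("OC(=O)C(F)(F)C(F)(F)F")
        organic = prepare_molecule("CCO")
        all_pfas = make_result("p", [pfas, pfas])
        one_miss = make_result("q", [pfas, organic])  # 50% confidence
        assert metrics.dataset_confidence_level([all_pfas] * 3) == 100.0
        assert metrics.dataset_confidence_level(
            [all_pfas, all_pfas, all_pfas, one_miss]) == 75.0

    def test_high_confidence_still_excluded(self):
        pfas = prepare_molecule("OC(=O)C(F)(F)C(F)(F)F")
        organic = prepare_molecule("CCO")
        res = make_result("r", [pfas] * 19 + [organic])
        assert res.confidence_score == 95.0
        assert metrics.dataset_confidence_level([res]) == 0.0

    def test_empty(self):
        with pytest.raises(EmptyInputError):
            metrics.dataset_confidence_level([])
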