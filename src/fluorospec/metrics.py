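"""Evaluation metrics: retrieval accuracy, MCS triple, fingerprint stats.

Accuracy metrics over a retrieval run:

* MA / FA -- percent of unique compounds for which at least one of their
  spectra places the correct molecule / molecular formula in the top-k
  candidates;
* MAS / FAS -- the same at the level of individual spectra;
* per-compound annotation accuracy -- correct spectra / total spectra;
* dataset confidence level -- percent of spectra whose *every* candidate
  is PFAS.

Structural similarity between a reference and a predicted molecule is
quantified by the maximum common substructure (MCS) under atom-type,
bond-order and ring-membership matching: with a_MCS, a_r, a_p the heavy
atom counts of the MCS, reference and prediction,

    ratio   = a_MCS / a_r
    overlap = a_MCS / min(a_r, a_p)
    tanimoto = a_MCS / (a_r + a_p - a_MCS)

and by Tanimoto similarity of 2048-bit path-based (RDKit) fingerprints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFMCS

from .chem import MoleculeRecord
from .retrieval import AnnotationResult
from .spectra import EmptyInputError

FINGERPRINT_BITS = 2048


class DegenerateMoleculeError(ValueError):
    pass


class MissingTruthError(KeyError):
    pass


def _mol(record: MoleculeRecord) -> Chem.Mol:
    mol = Chem.MolFromSmiles(record.canonical_smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise DegenerateMoleculeError(f"empty molecule: {record.canonical_smiles!r}")
    return mol


def mcs_metrics(reference: MoleculeRecord,
                predicted: MoleculeRecord) -> tuple[float, float, float]:
    """(ratio, tanimoto, overlap) of the maximum common substructure.

    Atom counts are heavy-atom counts; matching requires identical
    elements, bond orders and ring membership for both atoms and bonds.
    When the best common substructure is a single atom (no common bond),
    the count is 1 if the two molecules share an (element, ring-membership)
    atom class, else 0.
    """
    ref, pred = _mol(reference), _mol(predicted)
    a_r, a_p = ref.GetNumAtoms(), pred.GetNumAtoms()
    if a_r == 1 or a_p == 1:
        a_mcs = _single_atom_mcs(ref, pred)
    else:
        result = rdFMCS.FindMCS(
            [ref, pred],
            atomCompare=rdFMCS.AtomCompare.CompareElements,
            bondCompare=rdFMCS.BondCompare.CompareOrder,
            ringMatchesRingOnly=True,
            timeout=30,
        )
        a_mcs = result.numAtoms
        if a_mcs <= 0:
            a_mcs = _single_atom_mcs(ref, pred)
    ratio = a_mcs / a_r
    overlap = a_mcs / min(a_r, a_p)
    tanimoto = a_mcs / (a_r + a_p - a_mcs) if a_mcs else 0.0
    return ratio, tanimoto, overlap


def _single_atom_mcs(ref: Chem.Mol, pred: Chem.Mol) -> int:
    ref_classes = {(a.GetSymbol(), a.IsInRing()) for a in ref.GetAtoms()}
    pred_classes = {(a.GetSymbol(), a.IsInRing()) for a in pred.GetAtoms()}
    return 1 if ref_classes & pred_classes else 0


def _fingerprint(record: MoleculeRecord):
    return Chem.RDKFingerprint(_mol(record), fpSize=FINGERPRINT_BITS)


def fingerprint_similarity_stats(
    reference: MoleculeRecord,
    candidates: Sequence[MoleculeRecord],
) -> tuple[float, float, float]:
    """(average, maximum, minimum) Tanimoto similarity to the candidates."""
    if not candidates:
        raise EmptyInputError("no candidate molecules")
    ref_fp = _fingerprint(reference)
    sims = [DataStructs.TanimotoSimilarity(ref_fp, _fingerprint(c)) for c in candidates]
    return float(np.mean(sims)), float(max(sims)), float(min(sims))


@dataclass(frozen=True)
class CompoundRow:
    compound_key: str
    n_spectra: int
    n_correct: int
    annotation_accuracy: float  # percent
    confidence_level: float  # percent of spectra with all-PFAS candidates
    mean_confidence: float  # mean per-spectrum confidence score


@dataclass(frozen=True)
class MetricReport:
    molecule_accuracy: float  # MA, percent of compounds
    formula_accuracy: float  # FA
    molecule_accuracy_spectra: float  # MAS, percent of spectra
    formula_accuracy_spectra: float  # FAS
    n_compounds: int
    n_spectra: int
    per_compound: tuple[CompoundRow, ...]

    def to_dict(self) -> dict:
        return {
            "molecule_accuracy": self.molecule_accuracy,
            "formula_accuracy": self.formula_accuracy,
            "molecule_accuracy_spectra": self.molecule_accuracy_spectra,
            "formula_accuracy_spectra": self.formula_accuracy_spectra,
            "n_compounds": self.n_compounds,
            "n_spectra": self.n_spectra,
        }

    def write_tsv(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("compound_key\tn_spectra\tn_correct\tannotation_accuracy"
                     "\tconfidence_level\tmean_confidence\n")
            for row in self.per_compound:
                fh.write(f"{row.compound_key}\t{row.n_spectra}\t{row.n_correct}"
                         f"\t{row.annotation_accuracy:.1f}\t{row.confidence_level:.1f}"
                         f"\t{row.mean_confidence:.1f}\n")


def evaluate_retrieval(
    results: Mapping[str, AnnotationResult],
    truth: Mapping[str, MoleculeRecord],
) -> MetricReport:
    """Score a retrieval run against per-spectrum ground truth.

    A molecule match is candidate ``inchikey2d == truth inchikey2d``
    (stereo-free identity); a formula match is equality of Hill formula
    strings.  MA/FA apply the at-least-one-spectrum rule per unique truth
    compound; MAS/FAS count individual spectra.
    """
    if not results:
        raise EmptyInputError("no annotation results")
    for sid in results:
        if sid not in truth:
            raise MissingTruthError(f"no truth entry for spectrum {sid!r}")
    mol_hit_spectra = 0
    formula_hit_spectra = 0
    by_compound: dict[str, list[tuple[bool, bool, AnnotationResult]]] = {}
    for sid, res in results.items():
        true_rec = truth[sid]
        keys = {h.record.inchikey2d for h in res.hits}
        formulas = {h.record.formula for h in res.hits}
        mol_ok = true_rec.inchikey2d in keys
        formula_ok = true_rec.formula in formulas
        mol_hit_spectra += mol_ok
        formula_hit_spectra += formula_ok
        by_compound.setdefault(true_rec.inchikey2d, []).append((mol_ok, formula_ok, res))
    n_spectra = len(results)
    n_compounds = len(by_compound)
    ma = 100.0 * sum(any(m for m, _, _ in rows) for rows in by_compound.values()) / n_compounds
    fa = 100.0 * sum(any(f for _, f, _ in rows) for rows in by_compound.values()) / n_compounds
    rows = []
    for key in sorted(by_compound):
        entries = by_compound[key]
        n = len(entries)
        n_correct = sum(m for m, _, _ in entries)
        all_pfas = sum(all(h.record.is_pfas for h in res.hits) for _, _, res in entries)
        mean_conf = float(np.mean([res.confidence_score for _, _, res in entries]))
        rows.append(CompoundRow(
            compound_key=key,
            n_spectra=n,
            n_correct=n_correct,
            annotation_accuracy=100.0 * n_correct / n,
            confidence_level=100.0 * all_pfas / n,
            mean_confidence=mean_conf,
        ))
    return MetricReport(
        molecule_accuracy=ma,
        formula_accuracy=fa,
        molecule_accuracy_spectra=100.0 * mol_hit_spectra / n_spectra,
        formula_accuracy_spectra=100.0 * formula_hit_spectra / n_spectra,
        n_compounds=n_compounds,
        n_spectra=n_spectra,
        per_compound=tuple(rows),
    )


def dataset_confidence_level(results: Sequence[AnnotationResult]) -> float:
    """Percent of spectra whose every candidate is PFAS (strict-all rule).

    A spectrum with a 95% confidence score (19/20 PFAS candidates) does
    not count: the rule requires all candidates to be PFAS.
    """
    if not results:
        raise EmptyInputError("no annotation results")
    strict = sum(1 for res in results if res.hits
                 and all(h.record.is_pfas for h in res.hits))
    return 100.0 * strict / len(results)


def compound_similarity_table(
    results: Mapping[str, AnnotationResult],
    truth: Mapping[str, MoleculeRecord],
) -> list[dict]:
    """Per-compound MCS / fingerprint similarity summary.

    For each spectrum the average, max and min similarity between the true
    molecule and all its candidates is computed; spectra of one compound
    are then averaged, mirroring two-level (within-compound, then across-
    compound) reporting.
    """
    per_compound: dict[str, list[dict]] = {}
    for sid, res in results.items():
        true_rec = truth[sid]
        mcs_vals = [mcs_metrics(true_rec, h.record) for h in res.hits]
        fps_avg, fps_max, fps_min = fingerprint_similarity_stats(
            true_rec, [h.record for h in res.hits])
        row = {
            "mcs_ratio": float(np.mean([v[0] for v in mcs_vals])),
            "mcs_tanimoto": float(np.mean([v[1] for v in mcs_vals])),
            "mcs_overlap": float(np.mean([v[2] for v in mcs_vals])),
            "fps_avg": fps_avg, "fps_max": fps_max, "fps_min": fps_min,
        }
        per_compound.setdefault(true_rec.inchikey2d, []).append(row)
    table = []
    for key in sorted(per_compound):
        rows = per_compound[key]
        entry = {"compound_key": key, "n_spectra": len(rows)}
        for field in rows[0]:
            entry[field] = float(np.mean([r[field] for r in rows]))
        table.append(entry)
    return table
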