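"""Latent-space candidate retrieval, confidence scoring and clustering.

An :class:`EmbeddingIndex` holds one molecular embedding per unique
canonical structure.  A query spectrum embedding retrieves its k nearest
molecules by mean squared error; the fraction of PFAS among the retrieved
candidates is the spectrum's annotation confidence score.  Spectra left
unmatched in nontargeted screening can be grouped by precursor mass at a
ppm tolerance (single-linkage over the pairwise relation, i.e. connected
components -- note a chain of pairwise-close precursors can join spectra
whose end-to-end difference exceeds the tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .chem import MoleculeRecord
from .models import SmilesAutoencoder, SpectrumEncoder, encode_molecules, encode_spectra
from .spectra import (
    EmptyInputError,
    SpectrumRecord,
    TokenizedSpectrum,
    preprocess_spectrum,
    tokenize_spectrum,
)

DEFAULT_TOP_K = 20
DEFAULT_PPM_TOL = 5.0
#: confidence (in %) at or above which a spectrum is called PFAS
PFAS_CONFIDENCE_THRESHOLD = 90.0
#: relaxed threshold used when screening clusters
CLUSTER_CONFIDENCE_THRESHOLD = 80.0


@dataclass(frozen=True)
class CandidateHit:
    record: MoleculeRecord
    distance: float  # mean squared error in latent space
    rank: int


@dataclass(frozen=True)
class AnnotationResult:
    spectrum_id: str
    hits: tuple[CandidateHit, ...]
    confidence_score: float  # percent of hits classified as PFAS

    @property
    def is_pfas_call(self) -> bool:
        return self.confidence_score >= PFAS_CONFIDENCE_THRESHOLD


@dataclass(frozen=True)
class EmbeddingIndex:
    embeddings: np.ndarray  # (n, d) float32
    records: tuple[MoleculeRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def dim(self) -> int:
        return self.embeddings.shape[1]


def build_index(library: Sequence[MoleculeRecord],
                model: SmilesAutoencoder) -> EmbeddingIndex:
    """Embed a molecule library, one entry per unique canonical structure."""
    if not library:
        raise EmptyInputError("empty molecule library")
    unique: dict[str, MoleculeRecord] = {}
    for rec in library:
        unique.setdefault(rec.canonical_smiles, rec)
    records = tuple(unique.values())
    return EmbeddingIndex(embeddings=encode_molecules(records, model), records=records)


def retrieve_topk(query: np.ndarray, index: EmbeddingIndex,
                  k: int = DEFAULT_TOP_K) -> list[CandidateHit]:
    """The k nearest index entries by MSE, ascending distance.

    Ties are broken by lexicographic canonical SMILES; fewer than k entries
    means all are returned.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    query = np.asarray(query, dtype=np.float32).reshape(-1)
    if query.shape[0] != index.dim:
        raise ValueError(f"query dim {query.shape[0]} != index dim {index.dim}")
    dists = np.mean((index.embeddings - query) ** 2, axis=1)
    order = sorted(range(len(index)),
                   key=lambda i: (dists[i], index.records[i].canonical_smiles))
    return [
        CandidateHit(record=index.records[i], distance=float(dists[i]), rank=r + 1)
        for r, i in enumerate(order[:k])
    ]


def confidence_score(hits: Sequence[CandidateHit]) -> float:
    """Percent of candidate hits classified as PFAS."""
    if not hits:
        raise EmptyInputError("no candidate hits")
    return 100.0 * sum(1 for h in hits if h.record.is_pfas) / len(hits)


def annotate_spectra(
    spectra: Sequence[SpectrumRecord],
    encoder: SpectrumEncoder,
    index: EmbeddingIndex,
    k: int = DEFAULT_TOP_K,
    max_peaks: int = 100,
    with_losses: bool = True,
) -> list[AnnotationResult]:
    """Embed, retrieve and score a batch of spectra."""
    tokenized: list[TokenizedSpectrum] = []
    for rec in spectra:
        prepped = preprocess_spectrum(rec, max_peaks=max_peaks, with_losses=with_losses)
        tokenized.append(tokenize_spectrum(prepped, max_peaks=max_peaks,
                                           max_len=encoder.config.max_spectrum_len - 1))
    queries = encode_spectra(tokenized, encoder)
    results = []
    for rec, query in zip(spectra, queries):
        hits = tuple(retrieve_topk(query, index, k=k))
        results.append(AnnotationResult(
            spectrum_id=rec.source_id,
            hits=hits,
            confidence_score=confidence_score(hits),
        ))
    return results


def cluster_by_precursor(spectra: Sequence[SpectrumRecord],
                         tol_ppm: float = DEFAULT_PPM_TOL) -> list[list[int]]:
    """Partition spectra into precursor-mass clusters at a ppm tolerance.

    Two spectra are related when ``abs(pm1 - pm2) / max(pm1, pm2) * 1e6 <=
    tol_ppm`` (inclusive); clusters are the connected components of that
    relation.  Because the relation is an interval condition on sorted
    masses, components equal runs of consecutively-related sorted
    precursors.  Returns lists of input indices; deterministic.
    """
    n = len(spectra)
    if n == 0:
        return []
    masses = np.array([s.precursor_mz for s in spectra], dtype=float)
    if np.any(~np.isfinite(masses)) or np.any(masses <= 0):
        raise ValueError("every spectrum needs a positive precursor m/z")
    order = np.argsort(masses, kind="stable")
    clusters: list[list[int]] = [[int(order[0])]]
    for prev, cur in zip(order[:-1], order[1:]):
        lo, hi = masses[prev], masses[cur]
        if (hi - lo) / hi * 1e6 <= tol_ppm:
            clusters[-1].append(int(cur))
        else:
            clusters.append([int(cur)])
    return [sorted(c) for c in clusters]


def write_annotations(results: Sequence[AnnotationResult], path,
                      truth_mass: Optional[dict] = None) -> None:
    """Per-spectrum candidate table: one row per (spectrum, rank).

    Columns mirror the screening report: formula, molecular weight,
    latent distance, PFAS flag, per-spectrum confidence and (when a truth
    table is supplied) the mass difference to the true molecule.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("spectrum_id\trank\tcanonical_smiles\tformula\tmw\tdistance"
                 "\tis_pfas\tconfidence_score\tmw_diff\n")
        for res in results:
            for hit in res.hits:
                mw_diff = ""
                if truth_mass and res.spectrum_id in truth_mass:
                    mw_diff = f"{hit.record.monoisotopic_mass - truth_mass[res.spectrum_id]:.4f}"
                fh.write(
                    f"{res.spectrum_id}\t{hit.rank}\t{hit.record.canonical_smiles}"
                    f"\t{hit.record.formula}\t{hit.record.monoisotopic_mass:.4f}"
                    f"\t{hit.distance:.6f}\t{hit.record.is_pfas}"
                    f"\t{res.confidence_score:.1f}\t{mw_diff}\n"
                )
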