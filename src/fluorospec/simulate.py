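"""Synthetic molecule libraries and simulated [M-H]- MS2 spectra.

Real training data for spectrum-to-structure retrieval lives in licensed
spectral libraries; this module generates a desk-scale stand-in with known
ground truth so that every pipeline stage is trainable and testable
offline.

The molecule generator emits two populations:

* PFAS -- homologous perfluoroalkyl series (carboxylic and sulfonic
  acids, fluorotelomer alcohols/acids/sulfonates, sulfonamides, perfluoro
  ether acids and diacids with chain lengths 1..12), all of which satisfy
  the OECD classifier by construction;
* background -- random small organics over C/N/O/S (optionally Cl/Br,
  never F), none of which satisfy it.

The fragmenter cleaves every acyclic single bond homolytically, keeps the
heavier side as the anion (m/z = fragment monoisotopic mass - 1.007276)
and assigns intensities proportional to fragment heavy-atom count.  These
rules are deliberately simple: the goal is a deterministic, structure-
linked peak pattern sufficient for retrieval learning, not chemical
realism.  Because fragment and complementary-loss masses sum to the
neutral parent mass, neutral-loss augmentation recovers the complementary
fragment of every cleavage -- the same rationale loss features have on
real spectra.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger

from .chem import MoleculeRecord, prepare_molecule, MoleculeRejection

# candidate SMILES from the random grammar may be invalid; rejections are
# handled, so keep RDKit quiet (matchms re-enables RDKit logging on import)
RDLogger.DisableLog("rdApp.error")
from .spectra import PROTON_MASS, Peak, SpectrumRecord, write_spectra

logger = logging.getLogger(__name__)

DEFAULT_RICHNESS = 6
DEFAULT_NOISE_SD = 0.002  # Da; ~5 ppm at m/z 400, typical HRMS accuracy

_PT = Chem.GetPeriodicTable()
_H_MASS = _PT.GetMostCommonIsotopeMass("H")


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------


def _perfluoro_chain(n: int) -> str:
    """SMILES fragment F-(CF2)n- written head-first."""
    return "C(F)(F)" * n + "F"


def _pfas_pool() -> list[str]:
    """Homologous PFAS families, chain lengths 1..12."""
    pool: list[str] = []
    for n in range(1, 13):
        chain = _perfluoro_chain(n)
        pool.append(f"OC(=O){chain}")              # perfluoro carboxylic acid
        pool.append(f"OS(=O)(=O){chain}")          # perfluoro sulfonic acid
        pool.append(f"OCC{chain}")                 # n:2 fluorotelomer alcohol
        pool.append(f"OS(=O)(=O)CC{chain}")        # n:2 fluorotelomer sulfonic acid
        pool.append(f"NS(=O)(=O){chain}")          # perfluoro sulfonamide
        pool.append(f"OC(=O)CC{chain}")            # n:2 fluorotelomer carboxylic acid
        pool.append("OC(=O)" + "C(F)(F)" * n + "C(=O)O")  # perfluoro diacid
    for n1 in range(1, 5):                         # perfluoro ether acids
        for n2 in range(1, 7):
            pool.append("OC(=O)" + "C(F)(F)" * n1 + "O" + _perfluoro_chain(n2))
    return pool


_BACKBONE_ATOMS = ["C", "C", "C", "C", "C", "N", "O", "S"]
_TERMINALS = ["", "O", "N", "=O", "Cl", "Br"]


def _random_background_smiles(rng: np.random.Generator) -> str:
    """A random small organic: branched heavy-atom chain, no fluorine."""
    length = int(rng.integers(3, 13))
    parts: list[str] = []
    for _ in range(length):
        parts.append(str(rng.choice(_BACKBONE_ATOMS)))
        if rng.random() < 0.25:
            branch = str(rng.choice(["C", "O", "N", "C(C)", "CO"]))
            parts.append(f"({branch})")
    tail = str(rng.choice(_TERMINALS))
    if tail == "=O":
        # attach a carbonyl only to a carbon backbone terminus
        return "".join(parts) + ("(=O)O" if parts[-1] == "C" else "O")
    return "".join(parts) + tail


def generate_library(n_pfas: int, n_background: int, seed: int = 0
                     ) -> list[MoleculeRecord]:
    """Deterministic synthetic library of PFAS and background molecules.

    Every record passes the cleaning filters; PFAS records all classify as
    PFAS and background records never do; canonical structures are unique.
    """
    if n_pfas < 0 or n_background < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    records: list[MoleculeRecord] = []
    seen: set[str] = set()

    pfas_candidates = []
    for smi in _pfas_pool():
        try:
            rec = prepare_molecule(smi)
        except MoleculeRejection:
            continue
        if rec.canonical_smiles in seen or not rec.is_pfas:
            continue
        seen.add(rec.canonical_smiles)
        pfas_candidates.append(rec)
    if n_pfas > len(pfas_candidates):
        raise ValueError(
            f"at most {len(pfas_candidates)} distinct PFAS available, asked for {n_pfas}")
    idx = rng.permutation(len(pfas_candidates))[:n_pfas]
    records.extend(pfas_candidates[i] for i in sorted(idx))

    n_done, attempts = 0, 0
    while n_done < n_background:
        attempts += 1
        if attempts > 200 * max(n_background, 1):
            raise RuntimeError("background generator failed to converge")
        smi = _random_background_smiles(rng)
        try:
            rec = prepare_molecule(smi)
        except MoleculeRejection:
            continue
        if rec.canonical_smiles in seen or rec.is_pfas:
            continue
        seen.add(rec.canonical_smiles)
        records.append(rec)
        n_done += 1
    return records


# ---------------------------------------------------------------------------
# fragmentation simulator
# ---------------------------------------------------------------------------


def _atom_side_masses_and_sizes(mol: Chem.Mol) -> list[tuple[float, int]]:
    """Neutral mass and heavy-atom count of the heavier side of every
    acyclic single-bond cleavage."""
    n_atoms = mol.GetNumAtoms()
    atom_mass = np.array([
        _PT.GetMostCommonIsotopeMass(a.GetSymbol()) + a.GetTotalNumHs() * _H_MASS
        for a in mol.GetAtoms()
    ])
    adjacency = [[] for _ in range(n_atoms)]
    for bond in mol.GetBonds():
        adjacency[bond.GetBeginAtomIdx()].append((bond.GetEndAtomIdx(), bond.GetIdx()))
        adjacency[bond.GetEndAtomIdx()].append((bond.GetBeginAtomIdx(), bond.GetIdx()))
    out: list[tuple[float, int]] = []
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        # BFS on one side with the bond removed
        start, banned = bond.GetBeginAtomIdx(), bond.GetIdx()
        side = {start}
        queue = [start]
        while queue:
            a = queue.pop()
            for nb, bidx in adjacency[a]:
                if bidx == banned or nb in side:
                    continue
                side.add(nb)
                queue.append(nb)
        m1 = float(atom_mass[list(side)].sum())
        m2 = float(atom_mass.sum() - m1)
        if m1 >= m2:
            out.append((m1, len(side)))
        else:
            out.append((m2, n_atoms - len(side)))
    return out


def simulate_spectrum(record: MoleculeRecord, richness: int = DEFAULT_RICHNESS,
                      noise_sd: float = DEFAULT_NOISE_SD, seed: int = 0,
                      source_id: Optional[str] = None) -> SpectrumRecord:
    """Simulate one negative-mode [M-H]- MS2 spectrum of a known parent.

    Up to ``richness`` most-massive unique fragments are kept; intensities
    are proportional to fragment heavy-atom count with the base peak at 1;
    Gaussian m/z jitter of ``noise_sd`` Da is added to fragment peaks (the
    precursor is taken as calibrated).  Collision energy is drawn uniformly
    in [10, 50] eV.  A molecule with no acyclic single bond yields only the
    precursor-derived peak.  Deterministic per seed.
    """
    if record.monoisotopic_mass >= 1000:
        raise ValueError("parent mass must be below 1000 Da")
    rng = np.random.default_rng(seed)
    mol = Chem.MolFromSmiles(record.canonical_smiles)
    precursor_mz = record.monoisotopic_mass - PROTON_MASS
    fragments = _atom_side_masses_and_sizes(mol)
    unique: dict[float, int] = {}
    for mass, size in fragments:
        key = round(mass, 6)
        if key not in unique or size > unique[key]:
            unique[key] = size
    chosen = sorted(unique.items(), key=lambda kv: -kv[0])[:richness]
    peaks: list[Peak] = []
    if chosen:
        top_size = max(size for _, size in chosen)
        for mass, size in chosen:
            mz = mass - PROTON_MASS + float(rng.normal(0.0, noise_sd)) if noise_sd > 0 \
                else mass - PROTON_MASS
            peaks.append(Peak(mz=mz, intensity=size / top_size))
    else:
        peaks.append(Peak(mz=precursor_mz, intensity=1.0))
    peaks.sort(key=lambda p: p.mz)
    collision_energy = float(rng.uniform(10.0, 50.0))
    return SpectrumRecord(
        precursor_mz=precursor_mz,
        adduct="[M-H]-",
        ion_mode="negative",
        collision_energy=collision_energy,
        peaks=tuple(peaks),
        compound_key=record.inchikey2d,
        source_id=source_id or f"sim-{record.inchikey2d}-{seed}",
    )


def simulate_spectra(library: Sequence[MoleculeRecord], spectra_per_compound: int,
                     seed: int = 0, richness: int = DEFAULT_RICHNESS,
                     noise_sd: float = DEFAULT_NOISE_SD) -> list[SpectrumRecord]:
    """Simulate several spectra per library molecule with derived seeds."""
    seeds = np.random.SeedSequence(seed).generate_state(
        len(library) * spectra_per_compound) % (2**31 - 1)
    out = []
    i = 0
    for mol_idx, rec in enumerate(library):
        for rep in range(spectra_per_compound):
            out.append(simulate_spectrum(
                rec, richness=richness, noise_sd=noise_sd, seed=int(seeds[i]),
                source_id=f"sim-{mol_idx:05d}-{rep}"))
            i += 1
    return out


def make_fixtures(library: Sequence[MoleculeRecord], spectra_per_compound: int,
                  seed: int, out_mgf, out_truth,
                  richness: int = DEFAULT_RICHNESS,
                  noise_sd: float = DEFAULT_NOISE_SD) -> int:
    """Write an MGF of simulated spectra plus a spectrum-level truth TSV.

    Returns the number of spectra written; truth rows are keyed by the
    MGF TITLE fields.
    """
    spectra = simulate_spectra(library, spectra_per_compound, seed=seed,
                               richness=richness, noise_sd=noise_sd)
    write_spectra(spectra, out_mgf, fmt="mgf")
    truth_rows = []
    i = 0
    for mol_idx, rec in enumerate(library):
        for rep in range(spectra_per_compound):
            truth_rows.append((spectra[i].source_id, rec))
            i += 1
    Path(out_truth).parent.mkdir(parents=True, exist_ok=True)
    with open(out_truth, "wt", encoding="utf-8") as fh:
        fh.write("spectrum_id\tcanonical_smiles\tinchikey2d\tformula\n")
        for sid, rec in truth_rows:
            fh.write(f"{sid}\t{rec.canonical_smiles}\t{rec.inchikey2d}\t{rec.formula}\n")
    return len(spectra)


def read_truth_table(path) -> dict[str, dict[str, str]]:
    """spectrum_id -> {canonical_smiles, inchikey2d, formula}."""
    out: dict[str, dict[str, str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            fields = dict(zip(header, line.rstrip("\n").split("\t")))
            out[fields["spectrum_id"]] = fields
    return out
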