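"""Molecule ingestion, cleaning, canonicalization and PFAS classification.

A molecule enters the pipeline as a raw SMILES string and leaves as a
:class:`MoleculeRecord`: a salt-free, stereo-free canonical SMILES together
with its 2D InChIKey (connectivity hash), Hill formula, monoisotopic mass,
SMILES token sequence and an OECD-rule PFAS flag.

Filtering rules applied by :func:`prepare_molecule`:

* the SMILES must parse;
* disconnected structures (a ``.`` in the SMILES, e.g. salts) are rejected;
* only the elements C, N, H, O, P, S, Cl, Br, F, I, B are allowed;
* the monoisotopic mass must be below 1000 Da;
* the canonical SMILES must tokenize to at most 110 tokens.

The PFAS flag implements the revised OECD definition: the molecule must
contain a perfluorinated methyl (-CF3) or methylene (-CF2-) group whose
carbon carries no H, Cl, Br or I.  For tetravalent carbon this is
equivalent to a single predicate: some carbon has at least two fluorine
neighbours and no H/Cl/Br/I attached (implicit hydrogens included).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.rdMolDescriptors import CalcMolFormula

# RDKit is chatty about unparseable input; rejections are reported through
# MoleculeRejection instead.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

logger = logging.getLogger(__name__)

ALLOWED_ELEMENTS = frozenset({"C", "N", "H", "O", "P", "S", "Cl", "Br", "F", "I", "B"})
MAX_SMILES_TOKENS = 110
MAX_MONOISOTOPIC_MASS = 1000.0  # Da
STEREO_MARKERS = ("@", "/", "\\")

#: rejection reason codes used by prepare_molecule
REJECTION_REASONS = (
    "unparseable",
    "disconnected",
    "disallowed-element",
    "too-heavy",
    "too-long",
)


class MoleculeRejection(ValueError):
    """A molecule failed one of the library cleaning rules.

    Attributes
    ----------
    reason : str
        One of :data:`REJECTION_REASONS`.
    smiles : str
        The offending input SMILES.
    """

    def __init__(self, reason: str, smiles: str, detail: str = ""):
        self.reason = reason
        self.smiles = smiles
        msg = f"{reason}: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class KeyGenerationError(RuntimeError):
    """The standard InChIKey could not be generated for a structure."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A cleaned molecule ready for training, indexing and evaluation."""

    source_smiles: str
    canonical_smiles: str
    inchikey2d: str
    formula: str
    monoisotopic_mass: float
    is_pfas: bool
    smiles_tokens: tuple[str, ...]

    def __post_init__(self):
        if len(self.inchikey2d) != 14:
            raise ValueError(f"inchikey2d must have 14 characters: {self.inchikey2d!r}")


def tokenize_smiles(smiles: str) -> list[str]:
    """Lex a SMILES string into tokens.

    The two-letter element symbols ``Cl`` and ``Br`` are single tokens;
    every other character is its own token.  Joining the tokens reproduces
    the input exactly.
    """
    tokens: list[str] = []
    i = 0
    n = len(smiles)
    while i < n:
        pair = smiles[i : i + 2]
        if pair in ("Cl", "Br"):
            tokens.append(pair)
            i += 2
        else:
            tokens.append(smiles[i])
            i += 1
    return tokens


def _mol_from_canonical(canonical_smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(canonical_smiles)
    if mol is None:  # pragma: no cover - records always hold valid SMILES
        raise ValueError(f"invalid canonical SMILES on record: {canonical_smiles!r}")
    return mol


def _classify_pfas_mol(mol: Chem.Mol) -> bool:
    # OECD predicate on each carbon: >=2 F neighbours, zero attached
    # H/Cl/Br/I (implicit hydrogens count as attached H).
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C":
            continue
        neighbours = atom.GetNeighbors()
        n_fluorine = sum(1 for nb in neighbours if nb.GetSymbol() == "F")
        if n_fluorine < 2:
            continue
        if atom.GetTotalNumHs() > 0:
            continue
        if any(nb.GetSymbol() in ("Cl", "Br", "I", "H") for nb in neighbours):
            continue
        return True
    return False


def prepare_molecule(raw_smiles: str) -> MoleculeRecord:
    """Clean and canonicalize one raw SMILES into a :class:`MoleculeRecord`.

    Stereochemistry and salt information are removed before
    canonicalization.  Raises :class:`MoleculeRejection` naming the first
    violated rule; the operation is idempotent on its own canonical output.
    """
    if not raw_smiles or not raw_smiles.strip():
        raise MoleculeRejection("unparseable", raw_smiles, "empty input")
    raw_smiles = raw_smiles.strip()
    if "." in raw_smiles:
        raise MoleculeRejection("disconnected", raw_smiles)
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        raise MoleculeRejection("unparseable", raw_smiles)
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in ALLOWED_ELEMENTS:
            raise MoleculeRejection(
                "disallowed-element", raw_smiles, f"element {atom.GetSymbol()}"
            )
    Chem.RemoveStereochemistry(mol)
    canonical = Chem.MolToSmiles(mol, isomericSmiles=False, canonical=True)
    if "." in canonical:  # pragma: no cover - guarded by the raw-text check
        raise MoleculeRejection("disconnected", raw_smiles)
    mass = Descriptors.ExactMolWt(mol)
    if mass >= MAX_MONOISOTOPIC_MASS:
        raise MoleculeRejection("too-heavy", raw_smiles, f"{mass:.4f} Da")
    tokens = tuple(tokenize_smiles(canonical))
    if len(tokens) > MAX_SMILES_TOKENS:
        raise MoleculeRejection("too-long", raw_smiles, f"{len(tokens)} tokens")
    key = Chem.MolToInchiKey(mol)
    if not key:
        raise KeyGenerationError(f"no standard InChIKey for {canonical!r}")
    return MoleculeRecord(
        source_smiles=raw_smiles,
        canonical_smiles=canonical,
        inchikey2d=key[:14],
        formula=CalcMolFormula(mol),
        monoisotopic_mass=mass,
        is_pfas=_classify_pfas_mol(mol),
        smiles_tokens=tokens,
    )


def randomize_smiles(record: MoleculeRecord, seed: int) -> str:
    """Return a randomized (non-canonical) SMILES for the record's molecule.

    The output always canonicalizes back to ``record.canonical_smiles``;
    the same seed yields the same string.
    """
    mol = _mol_from_canonical(record.canonical_smiles)
    # RDKit treats seed <= 0 as "unseeded"; fold into the positive range.
    rdkit_seed = (int(seed) % 2147483646) + 1
    return Chem.MolToRandomSmilesVect(mol, 1, randomSeed=rdkit_seed)[0]


def inchikey2d(record: MoleculeRecord) -> str:
    """First 14 characters of the standard InChIKey (connectivity hash).

    Stereoisomers of one skeleton map to the same key because records are
    stereo-stripped before key generation.
    """
    mol = _mol_from_canonical(record.canonical_smiles)
    key = Chem.MolToInchiKey(mol)
    if not key:
        raise KeyGenerationError(f"no standard InChIKey for {record.canonical_smiles!r}")
    return key[:14]


def formula_and_mass(record: MoleculeRecord) -> tuple[str, float]:
    """Hill-notation formula (implicit H counted) and monoisotopic mass in Da."""
    mol = _mol_from_canonical(record.canonical_smiles)
    return CalcMolFormula(mol), Descriptors.ExactMolWt(mol)


def classify_pfas(record: MoleculeRecord) -> bool:
    """Apply the OECD PFAS predicate to the record's structure."""
    return _classify_pfas_mol(_mol_from_canonical(record.canonical_smiles))


# ---------------------------------------------------------------------------
# Library file I/O: one SMILES per line, optional tab-separated identifier.
# ---------------------------------------------------------------------------


def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read a one-SMILES-per-line library; returns (smiles, identifier) pairs.

    An optional second tab-separated column is used as the identifier;
    otherwise the line number is used.  Blank lines and ``#`` comments are
    skipped.
    """
    entries: list[tuple[str, str]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            ident = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            entries.append((smiles, ident))
    return entries


def prepare_library(
    smiles_entries: Iterable[str | tuple[str, str]],
) -> tuple[list[MoleculeRecord], dict[str, int]]:
    """Clean a library, deduplicating by canonical SMILES.

    Returns the accepted records and a histogram of rejection reasons.
    Rejected molecules are logged with their violated rule.
    """
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    rejections: dict[str, int] = {}
    for entry in smiles_entries:
        smiles = entry[0] if isinstance(entry, tuple) else entry
        try:
            rec = prepare_molecule(smiles)
        except MoleculeRejection as exc:
            rejections[exc.reason] = rejections.get(exc.reason, 0) + 1
            logger.warning("rejected %r: %s", smiles, exc.reason)
            continue
        if rec.canonical_smiles in seen:
            continue
        seen.add(rec.canonical_smiles)
        records.append(rec)
    return records, rejections


def write_library(records: Sequence[MoleculeRecord], path, sidecar: bool = True) -> None:
    """Write a cleaned library as SMILES lines plus an optional TSV sidecar."""
    with open(path, "wt", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f"{rec.canonical_smiles}\t{rec.inchikey2d}\n")
    if sidecar:
        sidecar_path = str(path) + ".tsv"
        with open(sidecar_path, "wt", encoding="utf-8") as fh:
            fh.write("canonical_smiles\tinchikey2d\tformula\tmass\tis_pfas\n")
            for rec in records:
                fh.write(
                    f"{rec.canonical_smiles}\t{rec.inchikey2d}\t{rec.formula}"
                    f"\t{rec.monoisotopic_mass:.4f}\t{rec.is_pfas}\n"
                )
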