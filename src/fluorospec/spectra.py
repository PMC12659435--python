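"""MS2 spectrum I/O, validity filtering and peak tokenization.

Spectra are read from MGF or MSP files into :class:`SpectrumRecord`
objects, filtered by the screening validity criteria (precursor m/z below
1000, negative mode, [M-H]- adduct, collision energy between 10 and
50 eV), normalized, augmented with neutral-loss features and finally
tokenized at 0.01-Da resolution for the spectral encoder.

Neutral losses: fragmentation only shows the charged fragment of each
cleavage; the complementary uncharged piece is recovered as a "loss"
peak at ``precursor_mz - fragment_mz`` carrying the fragment's relative
intensity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
from matchms import Spectrum as _MatchmsSpectrum
from matchms.exporting import save_as_mgf, save_as_msp
from matchms.importing import load_from_mgf, load_from_msp

logger = logging.getLogger(__name__)

PROTON_MASS = 1.007276  # Da, [M-H]- arithmetic
MAX_PRECURSOR_MZ = 1000.0
COLLISION_ENERGY_RANGE = (10.0, 50.0)  # eV, inclusive
MZ_RESOLUTION_TOKENS = 100  # tokens per Da -> 0.01 Da resolution
MAX_MZ_TOKEN = 100000

#: strings accepted (case/whitespace-insensitively) as the [M-H]- adduct
_MH_ADDUCT_ALIASES = {"[m-h]-", "[m-h]1-", "m-h", "[m-h]-1"}


class SpectraIOError(IOError):
    """File-level problem while reading spectra."""


class EmptyInputError(ValueError):
    """An operation received no usable input."""


class DegenerateSpectrumError(ValueError):
    """All peak intensities are zero."""


class MzRangeError(ValueError):
    """An m/z value falls outside the tokenizable range (0, 1000]."""


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    is_loss: bool = False

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be non-negative, got {self.intensity}")


@dataclass(frozen=True)
class SpectrumRecord:
    """One MS2 acquisition.

    ``peaks`` holds fragment peaks sorted by ascending m/z; after
    :func:`add_loss_features` the loss peaks follow the fragments, each
    group sorted by ascending m/z.
    """

    precursor_mz: Optional[float]
    adduct: Optional[str]
    ion_mode: Optional[str]
    collision_energy: Optional[float]
    peaks: tuple[Peak, ...]
    compound_key: Optional[str] = None
    source_id: str = ""
    extra: dict = field(default_factory=dict, compare=False)

    @property
    def fragment_peaks(self) -> tuple[Peak, ...]:
        return tuple(p for p in self.peaks if not p.is_loss)

    @property
    def loss_peaks(self) -> tuple[Peak, ...]:
        return tuple(p for p in self.peaks if p.is_loss)


@dataclass(frozen=True)
class TokenizedSpectrum:
    """Integer token sequence ready for the spectral encoder.

    ``tokens[i] = round(mz_i * 100)`` (half away from zero), so each token
    identifies a 0.01-Da bin; ``segment_flags`` distinguishes fragment from
    loss tokens.
    """

    tokens: tuple[int, ...]
    intensities: tuple[float, ...]
    segment_flags: tuple[Literal["fragment", "loss"], ...]

    def __post_init__(self):
        if not (len(self.tokens) == len(self.intensities) == len(self.segment_flags)):
            raise ValueError("tokens, intensities and segment_flags must align")


def _parse_float(value) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, (tuple, list)) and value:
        return _parse_float(value[0])
    try:
        return float(str(value).strip())
    except ValueError:
        return None


def _metadata_to_record(meta: dict, mz: np.ndarray, intensities: np.ndarray,
                        fallback_id: str) -> Optional[SpectrumRecord]:
    precursor = _parse_float(
        meta.get("precursor_mz", meta.get("precursormz", meta.get("pepmass")))
    )
    if precursor is None or precursor <= 0:
        return None
    adduct = meta.get("adduct") or meta.get("precursor_type") or meta.get("precursortype")
    ion_mode = meta.get("ionmode") or meta.get("ion_mode") or meta.get("ionization_mode")
    ce_raw = meta.get("collision_energy", meta.get("collisionenergy", meta.get("ce")))
    # Ramped / compound CE strings stay unparsed (None) and are later
    # rejected as missing-metadata.
    collision_energy = _parse_float(ce_raw)
    if collision_energy is None and ce_raw is not None:
        logger.warning("unparseable collision energy %r", ce_raw)
    compound_key = meta.get("compound_key")
    if compound_key is None and meta.get("inchikey"):
        compound_key = str(meta["inchikey"])[:14]
    source_id = str(meta.get("title") or meta.get("compound_name") or meta.get("name")
                    or fallback_id)
    order = np.argsort(mz, kind="stable")
    peaks = tuple(
        Peak(float(m), float(i))
        for m, i in zip(mz[order], intensities[order])
        if m > 0 and i >= 0
    )
    known = {"precursor_mz", "precursormz", "pepmass", "adduct", "precursor_type",
             "precursortype", "ionmode", "ion_mode", "ionization_mode",
             "collision_energy", "collisionenergy", "ce", "compound_key",
             "inchikey", "title", "compound_name", "name", "num_peaks", "num peaks",
             "charge"}
    extra = {k: v for k, v in meta.items() if k not in known}
    return SpectrumRecord(
        precursor_mz=precursor,
        adduct=str(adduct) if adduct is not None else None,
        ion_mode=str(ion_mode).strip().lower() if ion_mode is not None else None,
        collision_energy=collision_energy,
        peaks=peaks,
        compound_key=str(compound_key) if compound_key else None,
        source_id=source_id,
        extra=extra,
    )


def read_spectra(path, fmt: Optional[Literal["mgf", "msp"]] = None) -> list[SpectrumRecord]:
    """Read all spectra from an MGF or MSP file.

    Unparseable entries (e.g. missing precursor m/z) are skipped with a
    logged warning; a file yielding zero parseable spectra raises
    :class:`EmptyInputError`.
    """
    path = Path(path)
    if not path.exists():
        raise SpectraIOError(f"no such file: {path}")
    if fmt is None:
        fmt = "msp" if path.suffix.lower() == ".msp" else "mgf"
    loader = load_from_msp if fmt == "msp" else load_from_mgf
    records: list[SpectrumRecord] = []
    skipped = 0
    for i, spec in enumerate(loader(str(path), metadata_harmonization=False)):
        if spec is None:
            skipped += 1
            continue
        rec = _metadata_to_record(
            dict(spec.metadata), spec.peaks.mz, spec.peaks.intensities,
            fallback_id=f"{path.stem}_{i}",
        )
        if rec is None:
            skipped += 1
            logger.warning("skipping spectrum %d of %s: no precursor m/z", i, path)
            continue
        records.append(rec)
    if skipped:
        logger.warning("%s: skipped %d unparseable spectra", path, skipped)
    if not records:
        raise EmptyInputError(f"no parseable spectra in {path}")
    return records


def write_spectra(records: Sequence[SpectrumRecord], path,
                  fmt: Optional[Literal["mgf", "msp"]] = None) -> None:
    """Write spectra to MGF or MSP (UTF-8, m/z with >= 4 decimals).

    Only fragment peaks are written: neutral-loss peaks are an in-memory
    augmentation, recomputable from the precursor, and have no place in an
    acquisition file.
    """
    path = Path(path)
    if fmt is None:
        fmt = "msp" if path.suffix.lower() == ".msp" else "mgf"
    specs = []
    for rec in records:
        frag = sorted(rec.fragment_peaks, key=lambda p: p.mz)
        meta = {
            "precursor_mz": f"{rec.precursor_mz:.4f}" if rec.precursor_mz else None,
            "adduct": rec.adduct,
            "ionmode": rec.ion_mode,
            "collision_energy": (f"{rec.collision_energy:.4f}"
                                 if rec.collision_energy is not None else None),
            "title": rec.source_id,
            "compound_key": rec.compound_key,
        }
        meta = {k: v for k, v in meta.items() if v is not None}
        meta.update(rec.extra)
        specs.append(_MatchmsSpectrum(
            mz=np.array([round(p.mz, 6) for p in frag], dtype=float),
            intensities=np.array([p.intensity for p in frag], dtype=float),
            metadata=meta,
            metadata_harmonization=False,
        ))
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.exists():
        path.unlink()  # matchms appends to existing files
    if fmt == "msp":
        save_as_msp(specs, str(path), style="nist")
    else:
        save_as_mgf(specs, str(path))


def normalize_adduct(adduct: Optional[str]) -> Optional[str]:
    """Map adduct spelling variants onto '[M-H]-'; None when unrecognized."""
    if adduct is None:
        return None
    key = "".join(str(adduct).split()).lower()
    if key in _MH_ADDUCT_ALIASES:
        return "[M-H]-"
    return None


def filter_spectrum(rec: SpectrumRecord) -> Optional[str]:
    """Apply the screening validity criteria; None = accept.

    On rejection, returns the first failed criterion: 'precursor-range',
    'ion-mode', 'adduct', 'missing-metadata' (absent or ramped collision
    energy) or 'collision-energy'.  Bounds are inclusive: CE of exactly 10
    or 50 eV is accepted.
    """
    if rec.precursor_mz is None or rec.precursor_mz <= 0:
        return "missing-metadata"
    if rec.precursor_mz >= MAX_PRECURSOR_MZ:
        return "precursor-range"
    if rec.ion_mode is None or rec.ion_mode.strip().lower() != "negative":
        return "ion-mode"
    if normalize_adduct(rec.adduct) != "[M-H]-":
        return "adduct"
    if rec.collision_energy is None:
        return "missing-metadata"
    lo, hi = COLLISION_ENERGY_RANGE
    if not (lo <= rec.collision_energy <= hi):
        return "collision-energy"
    return None


def normalize_intensities(peaks: Sequence[Peak]) -> list[Peak]:
    """Scale intensities so the base peak is 1.0; order preserved."""
    if not peaks:
        raise EmptyInputError("cannot normalize an empty peak list")
    top = max(p.intensity for p in peaks)
    if top <= 0:
        raise DegenerateSpectrumError("all intensities are zero")
    return [replace(p, intensity=p.intensity / top) for p in peaks]


def add_loss_features(rec: SpectrumRecord) -> SpectrumRecord:
    """Append neutral-loss peaks: mz = precursor - fragment, same intensity.

    Loss peaks with non-positive m/z are dropped; fragment peaks are left
    untouched.  The result holds fragments (ascending m/z) followed by
    losses (ascending m/z).
    """
    if rec.precursor_mz is None:
        raise ValueError("record has no precursor m/z")
    fragments = sorted(rec.fragment_peaks, key=lambda p: p.mz)
    losses = [
        Peak(mz=rec.precursor_mz - p.mz, intensity=p.intensity, is_loss=True)
        for p in fragments
        if rec.precursor_mz - p.mz > 0
    ]
    losses.sort(key=lambda p: p.mz)
    return replace(rec, peaks=tuple(fragments) + tuple(losses))


def mz_to_token(mz: float) -> int:
    """Token id for an m/z value: round(mz * 100), half away from zero.

    Decimal-exact so that e.g. 50.005 maps to 5001 rather than falling on
    the binary-float side of the midpoint.
    """
    token = int(
        (Decimal(repr(float(mz))) * MZ_RESOLUTION_TOKENS).quantize(0, ROUND_HALF_UP)
    )
    if token < 0 or token > MAX_MZ_TOKEN:
        raise MzRangeError(f"m/z {mz} outside tokenizable range (0, 1000]")
    return token


def token_to_mz(token: int) -> float:
    """Centre m/z of a token's 0.01-Da bin."""
    return token / MZ_RESOLUTION_TOKENS


def tokenize_spectrum(rec: SpectrumRecord, max_peaks: int = 100,
                      max_len: int = 256) -> TokenizedSpectrum:
    """Turn a preprocessed spectrum into an aligned token/intensity sequence.

    Fragment peaks are capped to the ``max_peaks`` most intense before loss
    augmentation (losses are regenerated from the kept fragments when the
    record carries loss features, which is equivalent to filtering them
    since a loss is a deterministic function of its fragment).  Fragments
    come first sorted by ascending m/z, then losses sorted by ascending
    m/z; the sequence is truncated at ``max_len``.
    """
    if rec.precursor_mz is None:
        raise ValueError("record has no precursor m/z")
    fragments = list(rec.fragment_peaks)
    if not fragments:
        raise EmptyInputError("spectrum has no fragment peaks")
    has_losses = any(p.is_loss for p in rec.peaks)
    if len(fragments) > max_peaks:
        by_intensity = sorted(fragments, key=lambda p: (-p.intensity, p.mz))
        fragments = by_intensity[:max_peaks]
    fragments.sort(key=lambda p: p.mz)
    entries: list[tuple[int, float, str]] = [
        (mz_to_token(p.mz), p.intensity, "fragment") for p in fragments
    ]
    if has_losses:
        losses = [
            Peak(mz=rec.precursor_mz - p.mz, intensity=p.intensity, is_loss=True)
            for p in fragments
            if rec.precursor_mz - p.mz > 0
        ]
        losses.sort(key=lambda p: p.mz)
        entries.extend((mz_to_token(p.mz), p.intensity, "loss") for p in losses)
    entries = entries[:max_len]
    tokens, intensities, flags = zip(*entries)
    return TokenizedSpectrum(tokens=tokens, intensities=intensities, segment_flags=flags)


def detokenize(ts: TokenizedSpectrum) -> list[float]:
    """Recover the rounded (0.01-Da) m/z values of a tokenized spectrum."""
    return [token_to_mz(t) for t in ts.tokens]


def match_precursor_ppm(observed: float, theoretical: float, tol_ppm: float = 5.0) -> bool:
    """True iff |observed - theoretical| / theoretical * 1e6 <= tol_ppm.

    The denominator is always the theoretical mass, so the relation is only
    approximately symmetric; the bound is inclusive.
    """
    if observed <= 0 or theoretical <= 0:
        raise ValueError("masses must be positive")
    return abs(observed - theoretical) / theoretical * 1e6 <= tol_ppm


def preprocess_spectrum(rec: SpectrumRecord, max_peaks: int = 100,
                        with_losses: bool = True) -> SpectrumRecord:
    """Normalize intensities, cap fragments, optionally add loss features."""
    fragments = sorted(rec.fragment_peaks, key=lambda p: p.mz)
    fragments = normalize_intensities(fragments)
    if len(fragments) > max_peaks:
        fragments = sorted(fragments, key=lambda p: (-p.intensity, p.mz))[:max_peaks]
        fragments.sort(key=lambda p: p.mz)
    rec = replace(rec, peaks=tuple(fragments))
    if with_losses:
        rec = add_loss_features(rec)
    return rec
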