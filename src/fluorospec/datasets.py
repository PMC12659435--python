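"""Compound-level dataset partitioning and per-compound spectrum balancing.

Splits are made at the level of the 2D InChIKey so that all spectra of one
compound (including stereoisomer duplicates, which share the key) travel
together -- the standard defence against compound leakage between training
and test sets.  Spectrum counts per compound are then balanced to a fixed
threshold: under-represented compounds are replicated and topped up by
sampling without replacement, over-represented ones are subsampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .spectra import SpectrumRecord


class UnlabeledRecordError(ValueError):
    """A spectrum record carries no compound_key."""


class TooFewCompoundsError(ValueError):
    """Fewer distinct compounds than non-empty splits requested."""


@dataclass(frozen=True)
class CompoundSplit:
    train: tuple[SpectrumRecord, ...]
    val: tuple[SpectrumRecord, ...]
    test: tuple[SpectrumRecord, ...]
    assignment: dict  # compound_key -> 'train' | 'val' | 'test'

    def manifest_rows(self) -> list[tuple[str, str, int]]:
        """(compound_key, split, n_spectra) rows for the audit TSV."""
        counts: dict[tuple[str, str], int] = {}
        for name, part in (("train", self.train), ("val", self.val), ("test", self.test)):
            for rec in part:
                counts[(rec.compound_key, name)] = counts.get((rec.compound_key, name), 0) + 1
        return sorted((key, split, n) for (key, split), n in counts.items())


def group_by_compound(records: Sequence[SpectrumRecord]) -> dict[str, list[SpectrumRecord]]:
    grouped: dict[str, list[SpectrumRecord]] = {}
    for rec in records:
        if not rec.compound_key:
            raise UnlabeledRecordError(f"spectrum {rec.source_id!r} has no compound_key")
        grouped.setdefault(rec.compound_key, []).append(rec)
    return grouped


def split_by_compound(
    records: Sequence[SpectrumRecord],
    fractions: tuple[float, float, float] = (0.9, 0.0, 0.1),
    seed: int = 0,
) -> CompoundSplit:
    """Partition spectra into train/val/test at the compound level.

    The distinct compound keys are shuffled deterministically and cut at
    the rounded cumulative fractions, so split sizes match the fractions at
    the compound level within rounding.  No key ever appears in two splits.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if any(f < 0 for f in fractions):
        raise ValueError(f"fractions must be non-negative, got {fractions}")
    grouped = group_by_compound(records)
    keys = sorted(grouped)
    n = len(keys)
    n_nonzero = sum(1 for f in fractions if f > 0)
    if n < n_nonzero:
        raise TooFewCompoundsError(f"{n} compounds for {n_nonzero} non-empty splits")
    rng = np.random.default_rng(seed)
    keys = [keys[i] for i in rng.permutation(n)]
    cut1 = round(fractions[0] * n)
    cut2 = round((fractions[0] + fractions[1]) * n)
    parts = {"train": keys[:cut1], "val": keys[cut1:cut2], "test": keys[cut2:]}
    # rounding must not starve a non-empty split
    for name, frac in zip(("train", "val", "test"), fractions):
        if frac > 0 and not parts[name]:
            donor = max(parts, key=lambda p: len(parts[p]))
            parts[name].append(parts[donor].pop())
    assignment = {k: name for name, ks in parts.items() for k in ks}
    collect = lambda ks: tuple(rec for k in sorted(ks) for rec in grouped[k])
    return CompoundSplit(
        train=collect(parts["train"]),
        val=collect(parts["val"]),
        test=collect(parts["test"]),
        assignment=assignment,
    )


def train_val_split(records: Sequence[SpectrumRecord], val_fraction: float = 0.1,
                    seed: int = 0) -> tuple[tuple[SpectrumRecord, ...], tuple[SpectrumRecord, ...]]:
    """Carve a validation set out of a training set by the same keyed split."""
    split = split_by_compound(records, (1.0 - val_fraction, 0.0, val_fraction), seed=seed)
    return split.train, split.test


def oversample(
    records_by_compound: Mapping[str, Sequence[SpectrumRecord]],
    threshold: int = 50,
    seed: int = 0,
) -> dict[str, list[SpectrumRecord]]:
    """Balance every compound to exactly ``threshold`` spectra.

    Under-represented compounds are replicated ``floor(threshold / n)``
    times and the remainder drawn without replacement; over-represented
    compounds keep a uniform random subset of size ``threshold``.
    Deterministic for a fixed seed (compounds processed in sorted key
    order).
    """
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    rng = np.random.default_rng(seed)
    balanced: dict[str, list[SpectrumRecord]] = {}
    for key in sorted(records_by_compound):
        spectra = list(records_by_compound[key])
        n = len(spectra)
        if n == 0:
            raise ValueError(f"compound {key!r} has no spectra")
        if n == threshold:
            balanced[key] = spectra
        elif n > threshold:
            idx = rng.choice(n, size=threshold, replace=False)
            balanced[key] = [spectra[i] for i in sorted(idx)]
        else:
            reps, remainder = divmod(threshold, n)
            out = spectra * reps
            if remainder:
                idx = rng.choice(n, size=remainder, replace=False)
                out.extend(spectra[i] for i in sorted(idx))
            balanced[key] = out
    return balanced


def write_split_manifest(split: CompoundSplit, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("compound_key\tsplit\tn_spectra\n")
        for key, name, n in split.manifest_rows():
            fh.write(f"{key}\t{name}\t{n}\n")
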