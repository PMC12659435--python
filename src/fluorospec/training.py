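"""Two-phase training: autoencoder pretraining, then spectral alignment.

Phase 1 trains the SMILES autoencoder unsupervised: every epoch each
molecule contributes a freshly randomized SMILES as input and its
canonical token sequence as target (plus the canonical identity pair,
which anchors the canonical serialization the retrieval index is built
from).  Phase 2 freezes the autoencoder and trains the spectral encoder to
minimize the mean squared error between its spectrum embeddings and the
molecular embeddings E_a of the true parent compounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import autograd as ag
from .chem import MoleculeRecord, randomize_smiles, tokenize_smiles
from .models import (
    EOS_ID,
    Adam,
    ModelConfig,
    SmilesAutoencoder,
    SmilesVocab,
    SpectrumEncoder,
    batch_spectra,
    pad_id_batch,
)
from .spectra import TokenizedSpectrum

logger = logging.getLogger(__name__)


class EmptyTrainingSetError(ValueError):
    pass


@dataclass
class LossHistory:
    epochs: list[int]
    train_loss: list[float]
    val_loss: list[Optional[float]]

    def smoothed(self) -> list[float]:
        """Running minimum of the training loss (monotone non-increasing)."""
        out, best = [], float("inf")
        for x in self.train_loss:
            best = min(best, x)
            out.append(best)
        return out

    def write_csv(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("epoch,train_loss,val_loss\n")
            for e, tr, va in zip(self.epochs, self.train_loss, self.val_loss):
                fh.write(f"{e},{tr:.6f},{'' if va is None else f'{va:.6f}'}\n")


def _length_sorted_batches(n_items: int, lengths: Sequence[int], batch_size: int,
                           rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffle, then group by length to limit padding; batch order shuffled."""
    order = rng.permutation(n_items)
    order = order[np.argsort(np.asarray(lengths)[order], kind="stable")]
    batches = [order[i:i + batch_size] for i in range(0, n_items, batch_size)]
    rng.shuffle(batches)
    return batches


def train_autoencoder(
    library: Sequence[MoleculeRecord],
    config: ModelConfig,
    epochs: int,
    seed: int = 0,
    batch_size: int = 32,
    lr: float = 2e-3,
    lr_min_fraction: float = 0.1,
    grad_clip: float = 1.0,
    include_canonical: bool = True,
    log_every: int = 0,
) -> tuple[SmilesAutoencoder, LossHistory]:
    """Pretrain the SMILES autoencoder on a molecule library.

    The learning rate follows a cosine decay from ``lr`` to
    ``lr * lr_min_fraction`` over the epochs; gradients are clipped to a
    global norm of ``grad_clip``.  Fully reproducible for a fixed seed;
    with ``epochs == 0`` the untrained (seed-initialized) model and an
    empty history are returned.
    """
    if not library:
        raise EmptyTrainingSetError("empty molecule library")
    rng = np.random.default_rng(seed)
    vocab = SmilesVocab.build(library)
    model = SmilesAutoencoder(config, vocab,
                              rng=np.random.default_rng(config.seed))
    optimizer = Adam(model.parameters(), lr=lr)
    canonical_ids = [vocab.encode(list(r.smiles_tokens)) + [EOS_ID] for r in library]
    history = LossHistory([], [], [])
    for epoch in range(epochs):
        if epochs > 1:
            cos = 0.5 * (1.0 + np.cos(np.pi * epoch / (epochs - 1)))
            optimizer.lr = lr * (lr_min_fraction + (1.0 - lr_min_fraction) * cos)
        pairs: list[tuple[list[int], list[int]]] = []
        for i, rec in enumerate(library):
            rand = randomize_smiles(rec, seed=int(rng.integers(0, 2**31 - 1)))
            rand_ids = vocab.encode(tokenize_smiles(rand)) + [EOS_ID]
            pairs.append((rand_ids, canonical_ids[i]))
            if include_canonical:
                pairs.append((canonical_ids[i], canonical_ids[i]))
        lengths = [len(p[0]) for p in pairs]
        total, count = 0.0, 0
        for batch_idx in _length_sorted_batches(len(pairs), lengths, batch_size, rng):
            in_ids, in_mask = pad_id_batch([pairs[i][0] for i in batch_idx])
            tgt_ids, tgt_mask = pad_id_batch([pairs[i][1] for i in batch_idx])
            optimizer.zero_grad()
            loss = model.teacher_forcing_loss(in_ids, in_mask, tgt_ids, tgt_mask)
            loss.backward()
            optimizer.clip_grad_norm(grad_clip)
            optimizer.step()
            total += loss.item() * len(batch_idx)
            count += len(batch_idx)
        epoch_loss = total / count
        history.epochs.append(epoch)
        history.train_loss.append(epoch_loss)
        history.val_loss.append(None)
        if log_every and epoch % log_every == 0:
            logger.info("AE epoch %d loss %.4f", epoch, epoch_loss)
    return model, history


def reconstruction_accuracy(model: SmilesAutoencoder,
                            library: Sequence[MoleculeRecord]) -> float:
    """Fraction of molecules whose canonical encoding greedy-decodes exactly."""
    if not library:
        raise EmptyTrainingSetError("empty molecule library")
    seqs = [model.vocab.encode(list(r.smiles_tokens)) + [EOS_ID] for r in library]
    correct = 0
    for lo in range(0, len(library), 64):
        chunk = seqs[lo:lo + 64]
        ids, mask = pad_id_batch(chunk)
        latent = model.encode_np(ids, mask)
        decoded = model.decode_greedy_np(latent)
        for rec, ids_out in zip(library[lo:lo + 64], decoded):
            if model.vocab.decode(ids_out) == list(rec.smiles_tokens):
                correct += 1
    return correct / len(library)


def randomized_decode_accuracy(model: SmilesAutoencoder,
                               library: Sequence[MoleculeRecord],
                               seed: int = 0) -> float:
    """Fraction of molecules whose *randomized* SMILES decodes to the canonical form."""
    if not library:
        raise EmptyTrainingSetError("empty molecule library")
    rng = np.random.default_rng(seed)
    correct = 0
    for lo in range(0, len(library), 64):
        chunk = library[lo:lo + 64]
        seqs = []
        for rec in chunk:
            rand = randomize_smiles(rec, seed=int(rng.integers(0, 2**31 - 1)))
            seqs.append(model.vocab.encode(tokenize_smiles(rand)) + [EOS_ID])
        ids, mask = pad_id_batch(seqs)
        decoded = model.decode_greedy_np(model.encode_np(ids, mask))
        for rec, ids_out in zip(chunk, decoded):
            if model.vocab.decode(ids_out) == list(rec.smiles_tokens):
                correct += 1
    return correct / len(library)


def train_spectral_encoder(
    pairs: Sequence[tuple[TokenizedSpectrum, np.ndarray]],
    config: ModelConfig,
    epochs: int,
    seed: int = 0,
    batch_size: int = 32,
    lr: float = 1e-3,
    val_pairs: Optional[Sequence[tuple[TokenizedSpectrum, np.ndarray]]] = None,
    patience: int = 10,
    log_every: int = 0,
) -> tuple[SpectrumEncoder, LossHistory]:
    """Align the spectral encoder to frozen molecular embeddings by MSE.

    ``pairs`` are (tokenized spectrum, E_a target) tuples; the targets come
    from a trained autoencoder, which is never touched here.  Early
    stopping on validation MSE with the given patience when ``val_pairs``
    is provided (the best-so-far weights are restored).
    """
    if not pairs:
        raise EmptyTrainingSetError("no alignment pairs")
    d = config.latent_dim
    for _, target in pairs:
        if np.asarray(target).shape != (d,):
            raise ValueError(f"target latent dimension {np.asarray(target).shape} != ({d},)")
    rng = np.random.default_rng(seed)
    model = SpectrumEncoder(config, rng=np.random.default_rng(config.seed + 1))
    optimizer = Adam(model.parameters(), lr=lr)
    targets = np.stack([np.asarray(t, dtype=np.float32) for _, t in pairs])
    spectra = [ts for ts, _ in pairs]
    lengths = [len(ts.tokens) for ts in spectra]
    history = LossHistory([], [], [])
    best_val, best_state, since_best = float("inf"), None, 0
    for epoch in range(epochs):
        total, count = 0.0, 0
        for batch_idx in _length_sorted_batches(len(pairs), lengths, batch_size, rng):
            ids, intens, segs, mask = batch_spectra([spectra[i] for i in batch_idx],
                                                    config.max_spectrum_len)
            optimizer.zero_grad()
            pred = model.forward(ids, intens, segs, mask)
            loss = ag.mse(pred, ag.Tensor(targets[batch_idx]))
            loss.backward()
            optimizer.step()
            total += loss.item() * len(batch_idx)
            count += len(batch_idx)
        epoch_loss = total / count
        val_loss = None
        if val_pairs:
            val_loss = evaluate_alignment_mse(model, val_pairs)
            if val_loss < best_val - 1e-9:
                best_val, best_state, since_best = val_loss, model.state_dict(), 0
            else:
                since_best += 1
        history.epochs.append(epoch)
        history.train_loss.append(epoch_loss)
        history.val_loss.append(val_loss)
        if log_every and epoch % log_every == 0:
            logger.info("encoder epoch %d train %.5f val %s", epoch, epoch_loss, val_loss)
        if val_pairs and since_best >= patience:
            logger.info("early stopping at epoch %d (best val %.5f)", epoch, best_val)
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def evaluate_alignment_mse(model: SpectrumEncoder,
                           pairs: Sequence[tuple[TokenizedSpectrum, np.ndarray]]) -> float:
    """Mean squared error of E_s against E_a targets over a pair set."""
    total = 0.0
    for lo in range(0, len(pairs), 64):
        chunk = pairs[lo:lo + 64]
        ids, intens, segs, mask = batch_spectra([ts for ts, _ in chunk],
                                                model.config.max_spectrum_len)
        pred = model.encode_np(ids, intens, segs, mask)
        tgt = np.stack([np.asarray(t, dtype=np.float32) for _, t in chunk])
        total += float(((pred - tgt) ** 2).mean(axis=1).sum())
    return total / len(pairs)
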