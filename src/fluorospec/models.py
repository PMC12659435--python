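"""The two neural components sharing one chemical latent space.

* :class:`SmilesAutoencoder` -- a GRU sequence-to-sequence model trained to
  translate randomized SMILES into canonical SMILES.  The encoder's final
  hidden state is projected to a ``latent_dim`` vector: the chemical
  latent code E_a of the molecule.

* :class:`SpectrumEncoder` -- attention layers whose queries and keys are
  rotated by intensity-RoPE (see :mod:`fluorospec.nn`), their outputs
  stacked into a single-channel 2-D map consumed by a stack of (1, k)
  convolutions with per-layer kernel sizes, pooled and projected to the
  same ``latent_dim``: the spectrum embedding E_s.

Both models are deterministic in inference; all initialization randomness
flows from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import autograd as ag
from .autograd import DTYPE, Tensor
from .chem import MoleculeRecord
from .nn import (
    Adam,  # noqa: F401  (re-exported for training)
    Linear,
    Module,
    gru_forward_np,
    init_normal,
    rope_cache,
    rotation_pair_matrix,
)
from .spectra import MAX_MZ_TOKEN, TokenizedSpectrum


class VocabError(KeyError):
    """A token is not present in the model vocabulary."""


class LengthError(ValueError):
    """An input sequence exceeds the model's maximum length."""


class ShapeError(ValueError):
    """Tensor dimensions do not match the model configuration."""


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters shared by the autoencoder and spectral encoder.

    Defaults are desk-scale: small enough to train on one CPU in minutes
    while exercising every architectural element (GRU autoencoder, two
    attention layers with intensity-RoPE, an 11-layer convolution stack).
    """

    latent_dim: int = 64
    embed_dim: int = 64
    gru_hidden: int = 192
    gru_layers: int = 1
    attn_layers: int = 2
    attn_heads: int = 4
    d_model: int = 64
    ffn_dim: int = 128
    cnn_layers: int = 11
    cnn_kernel_sizes: tuple[int, ...] = (1, 3, 5, 7, 9, 11, 13, 15, 17, 19, 21)
    cnn_channels: int = 16
    vocab_size_spectrum: int = MAX_MZ_TOKEN + 1  # one token per 0.01-Da bin
    rope_scale: float = 100.0
    rope_base: float = 10000.0
    max_smiles_len: int = 110
    max_spectrum_len: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim <= 0:
            raise ValueError("latent_dim must be positive")
        if self.cnn_layers != len(self.cnn_kernel_sizes):
            raise ValueError("cnn_layers must equal len(cnn_kernel_sizes)")
        if self.d_model % self.attn_heads:
            raise ValueError("d_model must be divisible by attn_heads")
        if (self.d_model // self.attn_heads) % 2:
            raise ValueError("head dimension must be even for rotary encoding")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cnn_kernel_sizes"] = list(d["cnn_kernel_sizes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["cnn_kernel_sizes"] = tuple(d["cnn_kernel_sizes"])
        return cls(**d)


# ---------------------------------------------------------------------------
# SMILES vocabulary
# ---------------------------------------------------------------------------

#: tokens any randomized serialization may need beyond those in the
#: canonical forms (extra ring-closure digits, branch/bond punctuation)
_BASE_SMILES_TOKENS = tuple("()=#+-[]H123456789%") + ("Cl", "Br")

PAD_ID, SOS_ID, EOS_ID = 0, 1, 2


@dataclass(frozen=True)
class SmilesVocab:
    tokens: tuple[str, ...]  # includes the three specials at ids 0..2
    index: dict = field(default_factory=dict, compare=False, repr=False)

    @classmethod
    def build(cls, records: Sequence[MoleculeRecord]) -> "SmilesVocab":
        symbols = set(_BASE_SMILES_TOKENS)
        for rec in records:
            symbols.update(rec.smiles_tokens)
        tokens = ("<pad>", "<sos>", "<eos>") + tuple(sorted(symbols))
        return cls(tokens=tokens, index={t: i for i, t in enumerate(tokens)})

    def __post_init__(self):
        if not self.index:
            object.__setattr__(self, "index", {t: i for i, t in enumerate(self.tokens)})

    def __len__(self) -> int:
        return len(self.tokens)

    def encode(self, smiles_tokens: Sequence[str]) -> list[int]:
        try:
            return [self.index[t] for t in smiles_tokens]
        except KeyError as exc:
            raise VocabError(f"token {exc.args[0]!r} not in vocabulary") from None

    def decode(self, ids: Sequence[int]) -> list[str]:
        out = []
        for i in ids:
            if i == EOS_ID:
                break
            if i in (PAD_ID, SOS_ID):
                continue
            out.append(self.tokens[i])
        return out


def pad_id_batch(seqs: Sequence[Sequence[int]], pad: int = PAD_ID
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad integer sequences; returns (ids (B, T), mask (B, T))."""
    T = max(len(s) for s in seqs)
    ids = np.full((len(seqs), T), pad, dtype=np.int64)
    mask = np.zeros((len(seqs), T), dtype=DTYPE)
    for i, s in enumerate(seqs):
        ids[i, :len(s)] = s
        mask[i, :len(s)] = 1.0
    return ids, mask


# ---------------------------------------------------------------------------
# SMILES autoencoder
# ---------------------------------------------------------------------------


class SmilesAutoencoder(Module):
    """GRU encoder/decoder translating randomized to canonical SMILES."""

    def __init__(self, config: ModelConfig, vocab: SmilesVocab,
                 rng: Optional[np.random.Generator] = None):
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.config = config
        self.vocab = vocab
        V, E, H, d = len(vocab), config.embed_dim, config.gru_hidden, config.latent_dim
        gs = 1.0 / np.sqrt(H)
        xs = 1.0 / np.sqrt(E)
        self.embedding = init_normal(rng, (V, E), 0.1)
        self.enc_wx = init_normal(rng, (E, 3 * H), xs)
        self.enc_wh = init_normal(rng, (H, 3 * H), gs)
        self.enc_bx = Tensor(np.zeros(3 * H, dtype=DTYPE), requires_grad=True)
        self.enc_bh = Tensor(np.zeros(3 * H, dtype=DTYPE), requires_grad=True)
        self.to_latent = Linear(rng, H, d)
        self.from_latent = Linear(rng, d, H)
        self.dec_wx = init_normal(rng, (E, 3 * H), xs)
        self.dec_wh = init_normal(rng, (H, 3 * H), gs)
        self.dec_bx = Tensor(np.zeros(3 * H, dtype=DTYPE), requires_grad=True)
        self.dec_bh = Tensor(np.zeros(3 * H, dtype=DTYPE), requires_grad=True)
        # latent is injected at every decoder step (added to the token
        # embedding), not only via the initial hidden state: the code must
        # steer the whole sequence, and this shortens the gradient path.
        self.latent_to_input = Linear(rng, d, E)
        self.out = Linear(rng, H, V)

    # -- training-graph paths ---------------------------------------------
    def encode_batch(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        """Latent codes for a padded id batch (graph-building path)."""
        B, T = ids.shape
        h = Tensor(np.zeros((B, self.config.gru_hidden), dtype=DTYPE))
        for t in range(T):
            x_t = ag.embedding(self.embedding, ids[:, t])
            h = ag.gru_step(x_t, h, self.enc_wx, self.enc_wh,
                            self.enc_bx, self.enc_bh, mask=mask[:, t])
        return self.to_latent(h)

    def teacher_forcing_loss(self, in_ids: np.ndarray, in_mask: np.ndarray,
                             tgt_ids: np.ndarray, tgt_mask: np.ndarray) -> Tensor:
        """Per-token cross entropy of decoding targets from encoded inputs."""
        latent = self.encode_batch(in_ids, in_mask)
        h = self.from_latent(latent).tanh()
        ctx = self.latent_to_input(latent)
        B, T = tgt_ids.shape
        dec_in = np.concatenate(
            [np.full((B, 1), SOS_ID, dtype=np.int64), tgt_ids[:, :-1]], axis=1)
        states = []
        for t in range(T):
            x_t = ag.embedding(self.embedding, dec_in[:, t]) + ctx
            h = ag.gru_step(x_t, h, self.dec_wx, self.dec_wh,
                            self.dec_bx, self.dec_bh, mask=tgt_mask[:, t])
            states.append(h)
        hs = ag.stack(states, axis=1).reshape(B * T, self.config.gru_hidden)
        logits = self.out(hs)
        return ag.cross_entropy_logits(logits, tgt_ids.reshape(-1),
                                       mask=tgt_mask.reshape(-1))

    # -- inference paths (pure NumPy) -------------------------------------
    def encode_np(self, ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
        B, T = ids.shape
        h = np.zeros((B, self.config.gru_hidden), dtype=DTYPE)
        for t in range(T):
            x_t = self.embedding.data[ids[:, t]]
            h_new = gru_forward_np(x_t, h, self.enc_wx.data, self.enc_wh.data,
                                   self.enc_bx.data, self.enc_bh.data)
            m = mask[:, t].reshape(-1, 1)
            h = m * h_new + (1.0 - m) * h
        return h @ self.to_latent.weight.data + self.to_latent.bias.data

    def decode_greedy_np(self, latent: np.ndarray) -> list[list[int]]:
        """Greedy decoding until <eos> or max_smiles_len tokens."""
        if latent.ndim != 2 or latent.shape[1] != self.config.latent_dim:
            raise ShapeError(
                f"latent must be (B, {self.config.latent_dim}), got {latent.shape}")
        B = latent.shape[0]
        latent = latent.astype(DTYPE)
        h = np.tanh(latent @ self.from_latent.weight.data + self.from_latent.bias.data)
        ctx = latent @ self.latent_to_input.weight.data + self.latent_to_input.bias.data
        tokens = np.full(B, SOS_ID, dtype=np.int64)
        done = np.zeros(B, dtype=bool)
        outputs: list[list[int]] = [[] for _ in range(B)]
        for _ in range(self.config.max_smiles_len):
            x_t = self.embedding.data[tokens] + ctx
            h = gru_forward_np(x_t, h, self.dec_wx.data, self.dec_wh.data,
                               self.dec_bx.data, self.dec_bh.data)
            logits = h @ self.out.weight.data + self.out.bias.data
            tokens = logits.argmax(axis=1)
            for i in range(B):
                if not done[i]:
                    if tokens[i] == EOS_ID:
                        done[i] = True
                    else:
                        outputs[i].append(int(tokens[i]))
            if done.all():
                break
        return outputs


def encode_molecule(tokens: Sequence[str], model: SmilesAutoencoder) -> np.ndarray:
    """Chemical latent code E_a for one SMILES token sequence."""
    if len(tokens) > model.config.max_smiles_len:
        raise LengthError(f"{len(tokens)} tokens exceed {model.config.max_smiles_len}")
    ids = model.vocab.encode(tokens) + [EOS_ID]
    batch, mask = pad_id_batch([ids])
    return model.encode_np(batch, mask)[0]


def encode_molecules(records: Sequence[MoleculeRecord], model: SmilesAutoencoder,
                     batch_size: int = 64) -> np.ndarray:
    """E_a matrix (n, latent_dim) for a list of records."""
    out = np.empty((len(records), model.config.latent_dim), dtype=DTYPE)
    for lo in range(0, len(records), batch_size):
        chunk = records[lo:lo + batch_size]
        seqs = [model.vocab.encode(list(r.smiles_tokens)) + [EOS_ID] for r in chunk]
        ids, mask = pad_id_batch(seqs)
        out[lo:lo + len(chunk)] = model.encode_np(ids, mask)
    return out


def decode_molecule(code: np.ndarray, model: SmilesAutoencoder) -> list[str]:
    """Greedy-decode a latent code to a SMILES token sequence."""
    code = np.asarray(code, dtype=DTYPE)
    if code.ndim != 1 or code.shape[0] != model.config.latent_dim:
        raise ShapeError(f"expected a {model.config.latent_dim}-vector, got {code.shape}")
    ids = model.decode_greedy_np(code.reshape(1, -1))[0]
    return model.vocab.decode(ids)


# ---------------------------------------------------------------------------
# spectral encoder
# ---------------------------------------------------------------------------

SPEC_PAD_ID, SPEC_CLS_ID, SPEC_SEP_ID = 0, 1, 2
_N_SPEC_SPECIALS = 3
SEG_CLS, SEG_FRAGMENT, SEG_LOSS = 0, 1, 2


def batch_spectra(spectra: Sequence[TokenizedSpectrum], max_len: int
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pack tokenized spectra into padded model inputs.

    Returns (ids, intensities, segments, mask), each (B, L).  A CLS token
    with intensity 0 is prepended; raw 0.01-Da bin tokens are shifted past
    the special ids.
    """
    for ts in spectra:
        if len(ts.tokens) + 1 > max_len:
            raise LengthError(f"spectrum of {len(ts.tokens)} tokens exceeds {max_len - 1}")
    L = max(len(ts.tokens) for ts in spectra) + 1
    B = len(spectra)
    ids = np.full((B, L), SPEC_PAD_ID, dtype=np.int64)
    intens = np.zeros((B, L), dtype=DTYPE)
    segs = np.zeros((B, L), dtype=np.int64)
    mask = np.zeros((B, L), dtype=DTYPE)
    for i, ts in enumerate(spectra):
        n = len(ts.tokens)
        ids[i, 0] = SPEC_CLS_ID
        segs[i, 0] = SEG_CLS
        mask[i, 0] = 1.0
        ids[i, 1:n + 1] = np.asarray(ts.tokens) + _N_SPEC_SPECIALS
        intens[i, 1:n + 1] = ts.intensities
        segs[i, 1:n + 1] = [SEG_FRAGMENT if f == "fragment" else SEG_LOSS
                            for f in ts.segment_flags]
        mask[i, 1:n + 1] = 1.0
    return ids, intens, segs, mask


class _AttentionBlock(Module):
    """Self-attention with intensity-RoPE, then a feed-forward sublayer."""

    def __init__(self, rng, d_model: int, heads: int, ffn_dim: int):
        self.heads = heads
        self.head_dim = d_model // heads
        self.wq = Linear(rng, d_model, d_model)
        self.wk = Linear(rng, d_model, d_model)
        self.wv = Linear(rng, d_model, d_model)
        self.wo = Linear(rng, d_model, d_model)
        self.ln1_g = Tensor(np.ones(d_model, dtype=DTYPE), requires_grad=True)
        self.ln1_b = Tensor(np.zeros(d_model, dtype=DTYPE), requires_grad=True)
        self.ffn1 = Linear(rng, d_model, ffn_dim)
        self.ffn2 = Linear(rng, ffn_dim, d_model)
        self.ln2_g = Tensor(np.ones(d_model, dtype=DTYPE), requires_grad=True)
        self.ln2_b = Tensor(np.zeros(d_model, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor, cos: np.ndarray, sin: np.ndarray,
                 mask_bias: np.ndarray, rot: Tensor) -> Tensor:
        B, L, D = x.shape
        hd = self.head_dim

        def to_heads(t: Tensor) -> Tensor:
            return t.reshape(B, L, self.heads, hd).transpose((0, 2, 1, 3))

        q = to_heads(self.wq(x))
        k = to_heads(self.wk(x))
        v = to_heads(self.wv(x))
        cos_t, sin_t = Tensor(cos), Tensor(sin)
        q = q * cos_t + (q @ rot) * sin_t
        k = k * cos_t + (k @ rot) * sin_t
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(hd))
        scores = scores + Tensor(mask_bias)
        attn = ag.softmax(scores, axis=-1)
        ctx = (attn @ v).transpose((0, 2, 1, 3)).reshape(B, L, D)
        x = ag.layer_norm(x + self.wo(ctx), self.ln1_g, self.ln1_b)
        x = ag.layer_norm(x + self.ffn2(self.ffn1(x).relu()), self.ln2_g, self.ln2_b)
        return x


class SpectrumEncoder(Module):
    """Attention + convolution spectral encoder producing E_s."""

    def __init__(self, config: ModelConfig, rng: Optional[np.random.Generator] = None):
        if rng is None:
            rng = np.random.default_rng(config.seed + 1)
        self.config = config
        D = config.d_model
        V = config.vocab_size_spectrum + _N_SPEC_SPECIALS
        self.embedding = init_normal(rng, (V, D), 0.1)
        self.embedding.sparse = True  # 100k-row table: sparse optimizer updates
        self.seg_embedding = init_normal(rng, (3, D), 0.1)
        self.blocks = [
            _AttentionBlock(rng, D, config.attn_heads, config.ffn_dim)
            for _ in range(config.attn_layers)
        ]
        c = config.cnn_channels
        self.conv_weights = []
        self.conv_biases = []
        c_in = D  # map channels = model features; rows = attention layers
        for k in config.cnn_kernel_sizes:
            scale = 1.0 / np.sqrt(c_in * k)
            self.conv_weights.append(init_uniform_conv(rng, (c, c_in, k), scale))
            self.conv_biases.append(Tensor(np.zeros(c, dtype=DTYPE), requires_grad=True))
            c_in = c
        self.out = Linear(rng, c * config.attn_layers + config.attn_layers * D,
                          config.latent_dim)
        self._rot = Tensor(rotation_pair_matrix(D // config.attn_heads))

    def forward(self, ids: np.ndarray, intensities: np.ndarray,
                segments: np.ndarray, mask: np.ndarray) -> Tensor:
        cfg = self.config
        B, L = ids.shape
        if not (intensities.shape == segments.shape == mask.shape == (B, L)):
            raise ShapeError("ids, intensities, segments and mask must align")
        if L > cfg.max_spectrum_len:
            raise LengthError(f"sequence of {L} exceeds {cfg.max_spectrum_len}")
        if ids.max(initial=0) >= self.embedding.shape[0]:
            raise VocabError(f"token id {int(ids.max())} outside spectral vocabulary")
        x = ag.embedding(self.embedding, ids) + ag.embedding(self.seg_embedding, segments)
        head_dim = cfg.d_model // cfg.attn_heads
        cos, sin = rope_cache(intensities, head_dim, cfg.rope_scale, cfg.rope_base)
        cos = cos[:, None]  # (B, 1, L, hd) broadcast over heads
        sin = sin[:, None]
        mask_bias = ((1.0 - mask) * -1e9).astype(DTYPE)[:, None, None, :]
        layer_outputs = []
        for block in self.blocks:
            x = block(x, cos, sin, mask_bias, self._rot)
            layer_outputs.append(x)
        # 2-D map: rows = attention layers, cols = sequence, channels = features
        fmap = ag.stack([t.transpose((0, 2, 1)) for t in layer_outputs], axis=2)
        mask_cols = Tensor(mask[:, None, None, :])
        fmap = fmap * mask_cols  # zero padded columns so pooling ignores them
        for w, b in zip(self.conv_weights, self.conv_biases):
            fmap = ag.conv_rows(fmap, w, b).relu()
            fmap = fmap * mask_cols
        lengths = mask.sum(axis=1).astype(DTYPE)
        inv_len = Tensor(1.0 / lengths.reshape(B, 1, 1))
        pooled_conv = (fmap.sum(axis=3) * inv_len).reshape(B, -1)    # (B, c*n)
        attn_cat = ag.concat(layer_outputs, axis=-1)                 # (B, L, n*D)
        attn_cat = attn_cat * Tensor(mask[:, :, None])
        pooled_attn = attn_cat.sum(axis=1) * Tensor(1.0 / lengths.reshape(B, 1))
        return self.out(ag.concat([pooled_conv, pooled_attn], axis=-1))

    def encode_np(self, ids: np.ndarray, intensities: np.ndarray,
                  segments: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Inference path: run the graph and return the values."""
        return self.forward(ids, intensities, segments, mask).data.copy()


def init_uniform_conv(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.uniform(-scale, scale, size=shape).astype(DTYPE),
                  requires_grad=True)


def encode_spectrum(ts: TokenizedSpectrum, model: SpectrumEncoder) -> np.ndarray:
    """Spectrum embedding E_s for one tokenized spectrum."""
    ids, intens, segs, mask = batch_spectra([ts], model.config.max_spectrum_len)
    return model.encode_np(ids, intens, segs, mask)[0]


def encode_spectra(spectra: Sequence[TokenizedSpectrum], model: SpectrumEncoder,
                   batch_size: int = 64) -> np.ndarray:
    out = np.empty((len(spectra), model.config.latent_dim), dtype=DTYPE)
    for lo in range(0, len(spectra), batch_size):
        chunk = spectra[lo:lo + batch_size]
        ids, intens, segs, mask = batch_spectra(chunk, model.config.max_spectrum_len)
        out[lo:lo + len(chunk)] = model.encode_np(ids, intens, segs, mask)
    return out


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_autoencoder(model: SmilesAutoencoder, path) -> None:
    meta = json.dumps({"config": model.config.to_dict(),
                       "vocab": list(model.vocab.tokens)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.state_dict())


def load_autoencoder(path) -> SmilesAutoencoder:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = SmilesAutoencoder(ModelConfig.from_dict(meta["config"]),
                              SmilesVocab(tokens=tuple(meta["vocab"])))
    model.load_state_dict(state)
    return model


def save_spectrum_encoder(model: SpectrumEncoder, path) -> None:
    meta = json.dumps({"config": model.config.to_dict()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.state_dict())


def load_spectrum_encoder(path) -> SpectrumEncoder:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = SpectrumEncoder(ModelConfig.from_dict(meta["config"]))
    model.load_state_dict(state)
    return model
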