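"""Model contracts: shapes, determinism, vocabulary, checkpoints."""

import numpy as np
import pytest

from fluorospec import models
from fluorospec.models import (
    ModelConfig,
    SmilesVocab,
    SpectrumEncoder,
    batch_spectra,
    encode_molecule,
    decode_molecule,
    encode_spectrum,
)
from fluorospec.spectra import TokenizedSpectrum


def make_tokenized(tokens, intensities=None):
    n = len(tokens)
    return TokenizedSpectrum(
        tokens=tuple(tokens),
        intensities=tuple(intensities or [1.0] * n),
        segment_flags=tuple(["fragment"] * n),
    )


class TestModelConfig:
    def test_kernel_count_invariant(self):
        with pytest.raises(ValueError):
            ModelConfig(cnn_layers=3, cnn_kernel_sizes=(1, 3))

    def test_latent_positive(self):
        with pytest.raises(ValueError):
            ModelConfig(latent_dim=0)

    def test_round_trip_dict(self):
        cfg = ModelConfig(latent_dim=32, cnn_layers=2, cnn_kernel_sizes=(1, 3))
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


class TestSmilesVocab:
    def test_build_and_encode(self, tiny_library):
        vocab = SmilesVocab.build(tiny_library)
        rec = tiny_library[0]
        ids = vocab.encode(rec.smiles_tokens)
        assert vocab.decode(ids) == list(rec.smiles_tokens)

    def test_unknown_token_raises(self, tiny_library):
        vocab = SmilesVocab.build(tiny_library)
        with pytest.raises(models.VocabError):
            vocab.encode(["@"])


class TestAutoencoderContracts:
    def test_encode_deterministic_and_shaped(self, memorizing_ae):
        model, library, _ = memorizing_ae
        rec = library[0]
        one = encode_molecule(rec.smiles_tokens, model)
        two = encode_molecule(rec.smiles_tokens, model)
        assert np.array_equal(one, two)
        assert one.shape == (model.config.latent_dim,)

    def test_over_length_rejected(self, memorizing_ae):
        model, library, _ = memorizing_ae
        with pytest.raises(models.LengthError):
            encode_molecule(["C"] * 111, model)

    def test_decode_total_on_zero_vector(self, memorizing_ae):
        model, _, _ = memorizing_ae
        tokens = decode_molecule(np.zeros(model.config.latent_dim), model)
        assert isinstance(tokens, list)
        assert len(tokens) <= 110

    def test_decode_dimension_mismatch(self, memorizing_ae):
        model, _, _ = memorizing_ae
        with pytest.raises(models.ShapeError):
            decode_molecule(np.zeros(model.config.latent_dim + 1), model)

    def test_memorized_molecule_round_trips(self, memorizing_ae):
        model, library, _ = memorizing_ae
        hits = 0
        for rec in library:
            code = encode_molecule(rec.smiles_tokens, model)
            if decode_molecule(code, model) == list(rec.smiles_tokens):
                hits += 1
        assert hits / len(library) >= 0.9

    def test_augmented_forms_embed_closer_than_other_molecules(self, memorizing_ae):
        from fluorospec.chem import randomize_smiles, tokenize_smiles
        model, library, _ = memorizing_ae
        codes = np.stack([encode_molecule(r.smiles_tokens, model) for r in library])
        inter = [float(np.mean((codes[i] - codes[j]) ** 2))
                 for i in range(len(library)) for j in range(i + 1, len(library))]
        median_inter = np.median(inter)
        closer = 0
        for i, rec in enumerate(library):
            rand_tokens = tokenize_smiles(randomize_smiles(rec, seed=5))
            rand_code = encode_molecule(rand_tokens, model)
            if float(np.mean((rand_code - codes[i]) ** 2)) < median_inter:
                closer += 1
        assert closer / len(library) >= 0.9


@pytest.fixture(scope="module")
def encoder(tiny_config):
    return SpectrumEncoder(tiny_config, rng=np.random.default_rng(5))


class TestSpectrumEncoderContracts:
    def test_deterministic_and_shaped(self, encoder):
        ts = make_tokenized([5000, 12000, 44431], [0.2, 1.0, 0.6])
        one = encode_spectrum(ts, encoder)
        two = encode_spectrum(ts, encoder)
        assert np.array_equal(one, two)
        assert one.shape == (encoder.config.latent_dim,)

    def test_batching_preserves_singleton_result(self, encoder):
        a = make_tokenized([5000, 12000], [0.5, 1.0])
        b = make_tokenized([700, 1400, 2100, 2800], [0.1, 0.4, 0.7, 1.0])
        batch = models.encode_spectra([a, b], encoder)
        assert np.allclose(batch[0], encode_spectrum(a, encoder), atol=1e-5)
        assert np.allclose(batch[1], encode_spectrum(b, encoder), atol=1e-5)

    def test_length_overflow(self, encoder):
        ts = make_tokenized(list(range(1, encoder.config.max_spectrum_len + 1)))
        with pytest.raises(models.LengthError):
            encode_spectrum(ts, encoder)

    def test_misaligned_inputs_rejected(self, encoder):
        ids = np.zeros((1, 4), dtype=np.int64)
        with pytest.raises(models.ShapeError):
            encoder.forward(ids, np.zeros((1, 3)), np.zeros((1, 4)),
                            np.ones((1, 4)))

    def test_token_outside_vocabulary(self, encoder):
        ids = np.array([[encoder.embedding.shape[0] + 5]])
        with pytest.raises(models.VocabError):
            encoder.forward(ids, np.ones((1, 1)), np.zeros((1, 1), dtype=int),
                            np.ones((1, 1)))


class TestBatchSpectra:
    def test_layout(self):
        ts = make_tokenized([5000, 100000], [0.5, 1.0])
        ids, intens, segs, mask = batch_spectra([ts], max_len=16)
        assert ids[0, 0] == models.SPEC_CLS_ID
        assert list(ids[0, 1:3]) == [5003, 100003]  # shifted past specials
        assert intens[0, 0] == 0.0  # CLS carries zero intensity
        assert mask[0].sum() == 3


class TestCheckpoints:
    def test_autoencoder_round_trip(self, memorizing_ae, tmp_path):
        model, library, _ = memorizing_ae
        path = tmp_path / "ae.npz"
        models.save_autoencoder(model, path)
        back = models.load_autoencoder(path)
        rec = library[0]
        assert np.array_equal(encode_molecule(rec.smiles_tokens, model),
                              encode_molecule(rec.smiles_tokens, back))

    def test_spectrum_encoder_round_trip(self, tiny_config, tmp_path):
        enc = SpectrumEncoder(tiny_config, rng=np.random.default_rng(2))
        path = tmp_path / "enc.npz"
        models.save_spectrum_encoder(enc, path)
        back = models.load_spectrum_encoder(path)
        ts = make_tokenized([123, 456], [0.3, 1.0])
        assert np.array_equal(encode_spectrum(ts, enc), encode_spectrum(ts, back))
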