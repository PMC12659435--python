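"""The desk-scale end-to-end retrieval benchmark with known ground truth.

One function runs the whole study under fixed conditions: generate a
500-molecule library (100 PFAS homologues + 400 background organics),
pretrain the SMILES autoencoder on 300 of them, align the spectral
encoder on simulated spectra of 250 compounds (8 replicates each), then
annotate one held-out replicate per trained compound against the full
500-molecule index and score retrieval and PFAS confidence.  All
randomness derives from a single seed.

Problem sizes are desk-scale by design: large enough that top-20 /
500-candidate retrieval is far from chance (4%), small enough to run on
one CPU in minutes.
"""

from __future__ import annotations

import logging
import time
from typing import Optional

import numpy as np

from .chem import MoleculeRecord
from .metrics import dataset_confidence_level, evaluate_retrieval
from .models import ModelConfig, SmilesAutoencoder, encode_molecules
from .retrieval import (
    PFAS_CONFIDENCE_THRESHOLD,
    annotate_spectra,
    build_index,
)
from .simulate import simulate_spectra, generate_library
from .training import (
    randomized_decode_accuracy,
    reconstruction_accuracy,
    train_autoencoder,
    train_spectral_encoder,
)
from .spectra import preprocess_spectrum, tokenize_spectrum

logger = logging.getLogger(__name__)

#: study conditions of the desk-scale benchmark
BENCHMARK_CONDITIONS = dict(
    n_pfas=100,
    n_background=400,
    n_ae_train=300,
    n_encoder_compounds=250,
    spectra_per_compound=8,
    ae_epochs=550,
    encoder_epochs=40,
    top_k=20,
)


def _derived_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def run_benchmark(seed: int, conditions: Optional[dict] = None,
                  ae: Optional[SmilesAutoencoder] = None) -> dict:
    """Run the full two-phase training + retrieval study; returns metrics.

    ``conditions`` may override :data:`BENCHMARK_CONDITIONS` (used by unit
    tests to shrink the problem; the defaults are the reported study).  A
    pre-trained autoencoder can be injected to split the run across test
    fixtures.
    """
    cond = dict(BENCHMARK_CONDITIONS)
    if conditions:
        cond.update(conditions)
    (lib_seed, shuffle_seed, ae_seed, enc_seed, train_sim_seed,
     test_sim_seed, eval_seed) = _derived_seeds(seed, 7)

    t0 = time.time()
    library = generate_library(cond["n_pfas"], cond["n_background"], seed=lib_seed)
    order = np.random.default_rng(shuffle_seed).permutation(len(library))
    ae_train = [library[i] for i in order[:cond["n_ae_train"]]]
    encoder_compounds = [library[i] for i in order[:cond["n_encoder_compounds"]]]

    config = ModelConfig(seed=ae_seed % 100000)
    if ae is None:
        ae, _ = train_autoencoder(ae_train, config, epochs=cond["ae_epochs"],
                                  seed=ae_seed, batch_size=64,
                                  lr=3e-3, lr_min_fraction=0.04)
    else:
        config = ae.config
    recon = reconstruction_accuracy(ae, ae_train)
    rand_decode = randomized_decode_accuracy(ae, ae_train, seed=eval_seed)
    logger.info("AE done (%.0fs): recon %.3f, randomized %.3f",
                time.time() - t0, recon, rand_decode)

    index = build_index(library, ae)
    targets = encode_molecules(encoder_compounds, ae)
    target_by_key = {rec.inchikey2d: targets[i]
                     for i, rec in enumerate(encoder_compounds)}

    train_specs = simulate_spectra(encoder_compounds, cond["spectra_per_compound"],
                                   seed=train_sim_seed)
    test_specs = simulate_spectra(encoder_compounds, 1, seed=test_sim_seed)

    def make_pairs(specs):
        pairs = []
        for s in specs:
            prepped = preprocess_spectrum(s)
            ts = tokenize_spectrum(prepped, max_len=config.max_spectrum_len - 1)
            pairs.append((ts, target_by_key[s.compound_key]))
        return pairs

    t1 = time.time()
    encoder, history = train_spectral_encoder(
        make_pairs(train_specs), config, epochs=cond["encoder_epochs"],
        seed=enc_seed, batch_size=32)
    logger.info("encoder done (%.0fs): final MSE %.5f",
                time.time() - t1, history.train_loss[-1])

    results = annotate_spectra(test_specs, encoder, index, k=cond["top_k"])
    truth_by_key = {rec.inchikey2d: rec for rec in encoder_compounds}
    results_map = {r.spectrum_id: r for r in results}
    truth_map: dict[str, MoleculeRecord] = {
        r.spectrum_id: truth_by_key[s.compound_key]
        for r, s in zip(results, test_specs)
    }
    report = evaluate_retrieval(results_map, truth_map)
    pfas_results = [r for r, s in zip(results, test_specs)
                    if truth_by_key[s.compound_key].is_pfas]
    mean_pfas_conf = float(np.mean([r.confidence_score for r in pfas_results]))
    pfas_call_rate = 100.0 * np.mean(
        [r.confidence_score >= PFAS_CONFIDENCE_THRESHOLD for r in pfas_results])
    return {
        "ae_reconstruction_accuracy": 100.0 * recon,
        "ae_randomized_decode_accuracy": 100.0 * rand_decode,
        "molecule_accuracy": report.molecule_accuracy,
        "formula_accuracy": report.formula_accuracy,
        "molecule_accuracy_spectra": report.molecule_accuracy_spectra,
        "formula_accuracy_spectra": report.formula_accuracy_spectra,
        "mean_confidence_pfas_spectra": mean_pfas_conf,
        "pfas_call_rate": float(pfas_call_rate),
        "dataset_confidence_level_pfas": dataset_confidence_level(pfas_results),
        "n_library": len(library),
        "n_ae_train": len(ae_train),
        "n_test_spectra": len(test_specs),
        "n_pfas_test_spectra": len(pfas_results),
        "encoder_final_mse": history.train_loss[-1] if history.train_loss else None,
        "runtime_s": time.time() - t0,
    }
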