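# Methods

## Problem setting

Nontargeted screening for per- and polyfluoroalkyl substances (PFAS) in
environmental samples produces thousands of tandem (MS2) spectra whose
parent compounds are unknown. Library search fails for the long tail of
PFAS derivatives that have no reference spectrum. `fluorospec` follows the
spectrum-to-structure retrieval strategy: instead of predicting a structure
from a spectrum directly, both molecules and spectra are projected into one
*chemical latent space*, and candidates for an unknown spectrum are the
molecules whose embeddings lie nearest to the spectrum embedding.

The screening decision does not require the exact structure: if the
nearest candidates are overwhelmingly PFAS, the spectrum is called PFAS.
That call is quantified by the **confidence score** — the percentage of
the top-k candidates classified as PFAS under the revised OECD structural
definition (a perfluorinated −CF3 or −CF2− group whose carbon bears no
H/Cl/Br/I).

## Model

**Molecular embeddings (E_a).** A GRU sequence-to-sequence autoencoder is
pretrained unsupervised to translate randomized SMILES serializations into
the canonical SMILES of the same molecule. The encoder's final hidden
state is projected linearly to a `latent_dim`-vector, the chemical latent
code E_a. Randomized-to-canonical translation (rather than plain copying)
forces the code to represent the molecule, not the serialization. The
decoder receives the latent both through its initial hidden state and
added to every input token embedding; the second path proved necessary
for exact free-running reconstruction of long sequences.

**Spectrum embeddings (E_s).** Peaks are tokenized at 0.01-Da resolution
(token id = `round(100 * m/z)`, half away from zero; finer resolution
would multiply the vocabulary tenfold). For each fragment peak a
neutral-loss peak at `precursor − m/z` with the fragment's relative
intensity is appended, recovering the uncharged half of each cleavage.
The token sequence (fragments ascending by m/z, then losses ascending,
with a per-token segment flag and a zero-intensity CLS token) enters a
stack of self-attention layers whose queries and keys are rotated by
**intensity-modulated rotary encoding**: the rotary position index is
replaced by `intensity × rope_scale`, so the pre-softmax interaction of
two peaks depends only on their intensity difference and the (already
canonicalized) sequence order carries no information. The attention-layer
outputs are arranged as a 2-D map — rows = attention layers, columns =
sequence positions, model features as channels — and passed through 11
convolution layers with (1, k) kernels, k = 1, 3, …, 21, aggregating
local m/z context at increasing scales. Masked mean-pooling of the final
map, concatenated with mean-pooled attention features, is projected to
`latent_dim`.

**Alignment.** With the autoencoder frozen, the spectral encoder is
trained to minimize the mean squared error between E_s and the E_a of the
spectrum's parent molecule. Retrieval then ranks library molecules by MSE
to the query embedding; ties break lexicographically on canonical SMILES
so rankings are reproducible.

## Data preparation rules

* Molecules: salt/stereo stripping, rejection of disconnected SMILES,
  element whitelist {C, N, H, O, P, S, Cl, Br, F, I, B}, monoisotopic
  mass < 1000 Da, ≤ 110 SMILES tokens. Tokenization treats `Cl`/`Br` as
  single tokens and every other character as one token.
* Spectra: precursor m/z < 1000, negative mode, adduct normalizing to
  [M−H]⁻, collision energy in [10, 50] eV (inclusive; ramped CE strings
  are rejected as missing metadata). Intensities are base-peak
  normalized.
* Dataset handling: train/test partitions are made at the compound level
  on the first 14 InChIKey characters (InChIKey2D), so stereoisomers and
  repeated acquisitions of one compound never straddle a split. Spectrum
  counts per compound can be balanced to a threshold (default 50):
  under-represented compounds are replicated `floor(threshold/n)` times
  plus a remainder sampled without replacement; over-represented ones are
  subsampled. The synthetic corpus used in the tests is already flat, so
  the desk-scale pipeline leaves balancing off by default; the operation
  matters for unbalanced real libraries and is fully tested.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `latent_dim` | 64 | shared embedding dimension of E_a and E_s |
| `gru_hidden` | 192 | GRU state; 128 converged in loss but miscounted long C(F)(F) repeats in free-running decoding, 192 reconstructs reliably |
| `attn_layers` / `attn_heads` | 2 / 4 | desk-scale attention stack |
| `d_model` / `ffn_dim` | 64 / 128 | attention width / feed-forward width |
| `cnn_layers`, kernels | 11, (1,k) k=1..21 odd | local m/z aggregation at increasing scales |
| `cnn_channels` | 16 | convolution width |
| `rope_scale` | 100 | maps intensity [0,1] onto the angular range that integer positions 0–100 would occupy |
| `max_peaks` | 100 | fragment-peak cap (by intensity) before loss augmentation |
| `max_spectrum_len` | 256 | token-sequence cap |
| top-k | 20 | candidates retrieved per spectrum |
| ppm tolerance | 5 | precursor matching and clustering |
| confidence thresholds | 90 / 80 % | PFAS call / relaxed cluster screening |
| collision energy | 10–50 eV | validity window, inclusive |
| AE training | 550 epochs, Adam, lr 3e-3 cosine→0.04×, grad-clip 1.0, batch 64 | converges the 300-molecule study on one CPU in minutes |
| encoder training | 40 epochs, Adam, lr 1e-3, batch 32 | aligns E_s to E_a on the simulated corpus |

All training is float32 NumPy on a small reverse-mode autodiff engine
written for this package (`autograd.py`); the GRU cell, embedding lookup,
softmax cross-entropy, layer norm and row convolution are fused ops with
hand-derived gradients, checked against finite differences in the test
suite. The 100 001-row spectral-token embedding uses sparse (touched-row)
Adam updates.

## Synthetic data generator

Licensed spectral libraries cannot ship with the package, so the tests
and the benchmark use a generator with exact ground truth:

* **Library**: PFAS as homologous perfluoroalkyl series (carboxylic and
  sulfonic acids, fluorotelomer alcohols/acids/sulfonates, sulfonamides,
  ether acids, diacids; chain lengths 1–12) — all OECD-positive by
  construction; background as random small organics over C/N/O/S/Cl/Br
  with no fluorine — all OECD-negative. Default mix 100 PFAS / 400
  background.
* **Spectra**: each acyclic single bond is cleaved homolytically; the
  heavier side is kept as the anion (m/z = fragment monoisotopic mass −
  1.007276), the `richness` = 6 most massive unique fragments are
  retained, intensities are proportional to fragment heavy-atom count
  (base peak 1), fragment m/z gets Gaussian jitter of 0.002 Da (≈5 ppm at
  m/z 400), collision energy is drawn uniformly in [10, 50] eV, and the
  precursor is the exact [M−H]⁻ m/z (survey-scan calibration assumed).
  3 replicates per compound in the fixture files; 8 replicates for
  encoder training in the benchmark.

These rules are deliberately simple. They guarantee mass conservation
(fragment + complementary loss = neutral parent), so loss augmentation
recovers complementary fragments exactly as intended, and they give every
molecule a deterministic, structure-linked peak pattern — sufficient for
retrieval learning. They do **not** emulate collision-energy-dependent
fragmentation, rearrangements, isotope envelopes, co-isolation, matrix
effects, or adducts other than [M−H]⁻. Passing the end-to-end tests
therefore demonstrates that the architecture and training machinery can
learn a spectrum→structure mapping with these statistics; it does not
certify accuracy on real instrument data.

## Evaluation metrics

* **MA / FA**: percent of unique compounds with at least one spectrum
  placing the correct molecule / Hill formula in the top-k candidates.
  **MAS / FAS**: the same per spectrum. Molecule identity is InChIKey2D
  equality (stereo-free, consistent with the stereo stripping).
* **Annotation accuracy** (per compound): correct spectra / total.
* **Confidence score** (per spectrum): percent of candidates that are
  PFAS. **Dataset confidence level**: percent of spectra whose *every*
  candidate is PFAS (strict-all rule; 19/20 does not count).
* **MCS ratio / overlap / Tanimoto**: heavy-atom counts of the maximum
  common substructure under element + bond-order matching with
  ring-membership correspondence (rdFMCS). When the best common
  substructure is a single atom, rdFMCS reports zero atoms; a shared
  (element, ring-membership) atom class then counts as 1. Hydrogens are
  implicit in the structures and excluded from all counts. An exhaustive
  induced-subgraph oracle in the tests verifies all fixture pairs.
* **Fingerprint similarity**: Tanimoto over 2048-bit path-based RDKit
  fingerprints; per-spectrum average/max/min, then averaged within and
  across compounds when tabulated per compound.

## Numerical and design choices

* Spectrum tokenization uses decimal-exact rounding (via the shortest
  float repr), so `50.005 → 5001` rather than falling on the binary side
  of the midpoint; de-tokenization returns `token / 100`.
* ppm matching always divides by the theoretical mass and is inclusive at
  the bound; precursor clustering uses `|Δm| / max(m1, m2) ≤ 5 ppm` and
  takes connected components (single linkage), which on sorted masses
  reduces to linking consecutive pairs — a chain of pairwise-close
  precursors can therefore join spectra whose end-to-end gap exceeds the
  tolerance (documented behaviour, tested against a brute-force oracle).
* Losses share the fragment token vocabulary and are distinguished by a
  segment embedding; fragments-then-losses ordering is canonical, chosen
  for reproducibility since intensity-driven attention makes order
  non-semantic.
* Oversampling order: full replication first, then the remainder without
  replacement, processed in sorted key order under one seeded generator.
* The molecule-weight cutoff uses monoisotopic mass, matching the
  precursor m/z < 1000 spectral filter.
* Autoencoder training pairs each molecule's fresh randomized SMILES with
  its canonical target every epoch *and* includes the canonical→canonical
  identity pair, anchoring the serialization the retrieval index embeds.
* All randomness flows from one run seed through `numpy` SeedSequences;
  reruns with the same configuration are byte-identical.

## Desk-scale benchmark

`scripts/acceptance.py` (and the end-to-end tests) run one fixed study:
500-molecule library (100 PFAS / 400 background), autoencoder trained on
300 of them, spectral encoder trained on 8 simulated replicates of 250
compounds, evaluation on 1 held-out replicate per trained compound against
the full 500-molecule index with k = 20. Problem sizes were chosen so the
whole study runs on one CPU in minutes while keeping top-20/500 retrieval
far from the 4 % chance level.

## Known limitations

* The fragmenter's chemistry is schematic (see above); measured accuracy
  numbers characterize the synthetic study, not instrument data.
* Training at full literature scale (10⁸ molecules, 10⁵ spectra) is out
  of scope; the NumPy engine is built for desk-scale problems.
* Retrieval is an exhaustive scan — exact and fast to ~10⁵ molecules, but
  no approximate index is provided.
* Only the [M−H]⁻ adduct is modelled end to end; other adducts are
  rejected by the validity filter rather than corrected.
* Greedy decoding only; the decoder is used as an embedding quality gate,
  not as a structure generator.
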