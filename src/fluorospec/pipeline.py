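"""Stage orchestration: the training and inference workflow on disk.

Stages (in dependency order): ``prepare-molecules`` -> ``fixtures`` ->
``train-ae`` -> ``embed-db`` -> ``train-encoder`` -> ``annotate`` ->
``evaluate`` and ``cluster``.  Every stage writes a JSON manifest
(seed, config hash, SHA-256 of each input, outputs) so a run can be
audited and reproduced exactly; a missing upstream artifact raises
:class:`DependencyError` naming the stage that should have produced it.

Configuration is one YAML document; every screening threshold is
surfaced with its standard value as the default (precursor < 1000 Da,
collision energy 10-50 eV, spectrum-balancing threshold 50, top-20
retrieval, 5 ppm precursor tolerance, 90% / 80% confidence calls).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import chem, datasets, retrieval, simulate, training
from .metrics import dataset_confidence_level, evaluate_retrieval
from .models import (
    ModelConfig,
    load_autoencoder,
    load_spectrum_encoder,
    save_autoencoder,
    save_spectrum_encoder,
    encode_molecules,
)
from .retrieval import EmbeddingIndex, annotate_spectra, cluster_by_precursor
from .spectra import SpectrumRecord, filter_spectrum, read_spectra

logger = logging.getLogger(__name__)

STAGES = ("prepare-molecules", "fixtures", "train-ae", "embed-db",
          "train-encoder", "annotate", "evaluate", "cluster")

DEFAULT_CONFIG = {
    "seed": 42,
    "library": {"n_pfas": 100, "n_background": 400, "path": None},
    "fixtures": {"spectra_per_compound": 3, "richness": 6, "noise_sd": 0.002},
    "ae": {"epochs": 150, "train_fraction": 0.6, "batch_size": 64, "lr": 2e-3},
    "encoder": {"epochs": 40, "batch_size": 32, "lr": 1e-3,
                "holdout": "replicate", "val_fraction": 0.1,
                "oversample_threshold": None, "patience": 10},
    "model": {},  # ModelConfig overrides
    "annotate": {"topk": 20, "max_peaks": 100},
    "cluster": {"ppm": 5.0, "min_confidence": 80.0},
    "thresholds": {"pfas_confidence": 90.0, "oversample": 50},
}


class DependencyError(RuntimeError):
    """An upstream stage artifact is missing."""

    def __init__(self, stage: str, path: Path):
        super().__init__(f"stage {stage!r} requires missing artifact {path}; "
                         f"run the producing stage first")
        self.stage = stage


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: Optional[str] = None) -> dict:
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    with open(path, "rt", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    """Runs the workflow stages inside one working directory."""

    def __init__(self, config: dict, workdir):
        self.config = config
        self.workdir = Path(workdir)
        self.workdir.mkdir(parents=True, exist_ok=True)
        (self.workdir / "manifests").mkdir(exist_ok=True)

    # -- artifact paths ----------------------------------------------------
    @property
    def molecules_path(self) -> Path:
        return self.workdir / "molecules.smi"

    @property
    def spectra_path(self) -> Path:
        return self.workdir / "spectra.mgf"

    @property
    def truth_path(self) -> Path:
        return self.workdir / "truth.tsv"

    @property
    def ae_path(self) -> Path:
        return self.workdir / "autoencoder.npz"

    @property
    def index_path(self) -> Path:
        return self.workdir / "index.npz"

    @property
    def encoder_path(self) -> Path:
        return self.workdir / "encoder.npz"

    @property
    def annotations_path(self) -> Path:
        return self.workdir / "annotations.tsv"

    @property
    def metrics_path(self) -> Path:
        return self.workdir / "metrics.json"

    @property
    def clusters_path(self) -> Path:
        return self.workdir / "clusters.tsv"

    # -- helpers -----------------------------------------------------------
    def _require(self, stage: str, *paths: Path) -> None:
        for path in paths:
            if not path.exists():
                raise DependencyError(stage, path)

    def _manifest(self, stage: str, inputs: list[Path], outputs: list[Path],
                  stage_config) -> None:
        payload = {
            "stage": stage,
            "seed": self.config["seed"],
            "config_hash": hashlib.sha256(
                json.dumps(stage_config, sort_keys=True).encode()).hexdigest(),
            "inputs": {str(p.name): _sha256(p) for p in inputs},
            "outputs": [str(p.name) for p in outputs],
        }
        out = self.workdir / "manifests" / f"{stage}.json"
        with open(out, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    def _model_config(self) -> ModelConfig:
        overrides = dict(self.config.get("model") or {})
        overrides.setdefault("seed", self.config["seed"])
        if "cnn_kernel_sizes" in overrides:
            overrides["cnn_kernel_sizes"] = tuple(overrides["cnn_kernel_sizes"])
        return ModelConfig(**overrides)

    def _load_library(self, stage: str) -> list[chem.MoleculeRecord]:
        self._require(stage, self.molecules_path)
        records, _ = chem.prepare_library(chem.read_smiles_file(self.molecules_path))
        return records

    def _load_valid_spectra(self, stage: str) -> list[SpectrumRecord]:
        self._require(stage, self.spectra_path)
        spectra = read_spectra(self.spectra_path)
        return [s for s in spectra if filter_spectrum(s) is None]

    def _encoder_split(self, spectra: list[SpectrumRecord]
                       ) -> tuple[list[SpectrumRecord], list[SpectrumRecord]]:
        """Training vs held-out spectra per the configured holdout mode."""
        mode = self.config["encoder"]["holdout"]
        if mode == "compound":
            split = datasets.split_by_compound(spectra, (0.9, 0.0, 0.1),
                                               seed=self.config["seed"])
            return list(split.train), list(split.test)
        # replicate mode: last spectrum of every compound held out
        grouped = datasets.group_by_compound(spectra)
        train, test = [], []
        for key in sorted(grouped):
            members = sorted(grouped[key], key=lambda s: s.source_id)
            if len(members) == 1:
                train.extend(members)
            else:
                train.extend(members[:-1])
                test.append(members[-1])
        return train, test

    # -- stages ------------------------------------------------------------
    def prepare_molecules(self) -> None:
        cfg = self.config["library"]
        if cfg.get("path"):
            entries = chem.read_smiles_file(cfg["path"])
            records, rejected = chem.prepare_library(entries)
            logger.info("library: %d accepted, rejections %s", len(records), rejected)
        else:
            records = simulate.generate_library(
                cfg["n_pfas"], cfg["n_background"], seed=self.config["seed"])
        chem.write_library(records, self.molecules_path)
        self._manifest("prepare-molecules", [], [self.molecules_path], cfg)

    def fixtures(self) -> None:
        cfg = self.config["fixtures"]
        library = self._load_library("fixtures")
        n = simulate.make_fixtures(
            library, cfg["spectra_per_compound"], seed=self.config["seed"],
            out_mgf=self.spectra_path, out_truth=self.truth_path,
            richness=cfg["richness"], noise_sd=cfg["noise_sd"])
        logger.info("wrote %d simulated spectra", n)
        self._manifest("fixtures", [self.molecules_path],
                       [self.spectra_path, self.truth_path], cfg)

    def train_ae(self) -> None:
        cfg = self.config["ae"]
        library = self._load_library("train-ae")
        rng = np.random.default_rng(self.config["seed"])
        order = rng.permutation(len(library))
        n_train = max(1, int(round(cfg["train_fraction"] * len(library))))
        train = [library[i] for i in order[:n_train]]
        model, history = training.train_autoencoder(
            train, self._model_config(), epochs=cfg["epochs"],
            seed=self.config["seed"], batch_size=cfg["batch_size"], lr=cfg["lr"])
        save_autoencoder(model, self.ae_path)
        history.write_csv(self.workdir / "ae_loss.csv")
        self._manifest("train-ae", [self.molecules_path],
                       [self.ae_path, self.workdir / "ae_loss.csv"], cfg)

    def embed_db(self) -> None:
        self._require("embed-db", self.ae_path)
        library = self._load_library("embed-db")
        model = load_autoencoder(self.ae_path)
        index = retrieval.build_index(library, model)
        np.savez(self.index_path, embeddings=index.embeddings,
                 smiles=np.array([r.canonical_smiles for r in index.records]))
        self._manifest("embed-db", [self.molecules_path, self.ae_path],
                       [self.index_path], {})

    def _load_index(self, stage: str) -> EmbeddingIndex:
        self._require(stage, self.index_path)
        with np.load(self.index_path, allow_pickle=False) as data:
            embeddings = data["embeddings"]
            smiles = [str(s) for s in data["smiles"]]
        records = tuple(chem.prepare_molecule(s) for s in smiles)
        return EmbeddingIndex(embeddings=embeddings, records=records)

    def train_encoder(self) -> None:
        cfg = self.config["encoder"]
        self._require("train-encoder", self.ae_path, self.truth_path)
        ae = load_autoencoder(self.ae_path)
        spectra = self._load_valid_spectra("train-encoder")
        train, _ = self._encoder_split(spectra)
        if cfg.get("oversample_threshold"):
            grouped = datasets.group_by_compound(train)
            balanced = datasets.oversample(grouped, cfg["oversample_threshold"],
                                           seed=self.config["seed"])
            train = [s for key in sorted(balanced) for s in balanced[key]]
        train_core, val = datasets.train_val_split(
            train, cfg["val_fraction"], seed=self.config["seed"]) \
            if cfg["val_fraction"] else (tuple(train), ())
        truth = simulate.read_truth_table(self.truth_path)
        mol_records = {}
        for row in truth.values():
            mol_records.setdefault(row["inchikey2d"], row["canonical_smiles"])
        records_by_key = {k: chem.prepare_molecule(s) for k, s in mol_records.items()}
        keys = sorted(records_by_key)
        targets = encode_molecules([records_by_key[k] for k in keys], ae)
        target_by_key = dict(zip(keys, targets))
        model_cfg = self._model_config()

        def make_pairs(specs):
            out = []
            for s in specs:
                prepped = retrieval.preprocess_spectrum(
                    s, max_peaks=self.config["annotate"]["max_peaks"])
                ts = retrieval.tokenize_spectrum(
                    prepped, max_peaks=self.config["annotate"]["max_peaks"],
                    max_len=model_cfg.max_spectrum_len - 1)
                out.append((ts, target_by_key[s.compound_key]))
            return out

        encoder, history = training.train_spectral_encoder(
            make_pairs(train_core), model_cfg, epochs=cfg["epochs"],
            seed=self.config["seed"], batch_size=cfg["batch_size"], lr=cfg["lr"],
            val_pairs=make_pairs(val) if val else None, patience=cfg["patience"])
        save_spectrum_encoder(encoder, self.encoder_path)
        history.write_csv(self.workdir / "encoder_loss.csv")
        self._manifest("train-encoder",
                       [self.spectra_path, self.truth_path, self.ae_path],
                       [self.encoder_path, self.workdir / "encoder_loss.csv"], cfg)

    def annotate(self) -> list[retrieval.AnnotationResult]:
        cfg = self.config["annotate"]
        self._require("annotate", self.encoder_path)
        index = self._load_index("annotate")
        encoder = load_spectrum_encoder(self.encoder_path)
        spectra = self._load_valid_spectra("annotate")
        _, held_out = self._encoder_split(spectra)
        results = annotate_spectra(held_out, encoder, index, k=cfg["topk"],
                                   max_peaks=cfg["max_peaks"])
        truth = simulate.read_truth_table(self.truth_path) \
            if self.truth_path.exists() else {}
        truth_mass = {}
        for sid, row in truth.items():
            truth_mass[sid] = chem.prepare_molecule(row["canonical_smiles"]).monoisotopic_mass
        retrieval.write_annotations(results, self.annotations_path,
                                    truth_mass=truth_mass or None)
        self._manifest("annotate",
                       [self.spectra_path, self.encoder_path, self.index_path],
                       [self.annotations_path], cfg)
        return results

    def evaluate(self) -> dict:
        self._require("evaluate", self.annotations_path, self.truth_path)
        results = self._read_annotations()
        truth_rows = simulate.read_truth_table(self.truth_path)
        truth = {sid: chem.prepare_molecule(row["canonical_smiles"])
                 for sid, row in truth_rows.items() if sid in results}
        report = evaluate_retrieval(results, truth)
        all_results = list(results.values())
        pfas_results = [r for sid, r in results.items() if truth[sid].is_pfas]
        payload = report.to_dict()
        payload["dataset_confidence_level"] = dataset_confidence_level(all_results)
        payload["mean_confidence_pfas_spectra"] = (
            float(np.mean([r.confidence_score for r in pfas_results]))
            if pfas_results else None)
        payload["n_pfas_spectra"] = len(pfas_results)
        with open(self.metrics_path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        report.write_tsv(self.workdir / "per_compound.tsv")
        self._manifest("evaluate", [self.annotations_path, self.truth_path],
                       [self.metrics_path, self.workdir / "per_compound.tsv"], {})
        return payload

    def _read_annotations(self) -> dict[str, retrieval.AnnotationResult]:
        """Rebuild AnnotationResult objects from the annotations TSV."""
        rows: dict[str, list[dict]] = {}
        with open(self.annotations_path, "rt", encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                fields = dict(zip(header, line.rstrip("\n").split("\t")))
                rows.setdefault(fields["spectrum_id"], []).append(fields)
        results = {}
        cache: dict[str, chem.MoleculeRecord] = {}
        for sid, hit_rows in rows.items():
            hits = []
            for fields in sorted(hit_rows, key=lambda f: int(f["rank"])):
                smi = fields["canonical_smiles"]
                if smi not in cache:
                    cache[smi] = chem.prepare_molecule(smi)
                hits.append(retrieval.CandidateHit(
                    record=cache[smi], distance=float(fields["distance"]),
                    rank=int(fields["rank"])))
            results[sid] = retrieval.AnnotationResult(
                spectrum_id=sid, hits=tuple(hits),
                confidence_score=retrieval.confidence_score(hits))
        return results

    def cluster(self) -> list[list[int]]:
        cfg = self.config["cluster"]
        spectra = self._load_valid_spectra("cluster")
        clusters = cluster_by_precursor(spectra, tol_ppm=cfg["ppm"])
        confidences: dict[str, float] = {}
        if self.annotations_path.exists():
            for sid, res in self._read_annotations().items():
                confidences[sid] = res.confidence_score
        with open(self.clusters_path, "wt", encoding="utf-8") as fh:
            fh.write("cluster_id\tspectrum_id\tprecursor_mz\tconfidence\tpfas_cluster\n")
            for cid, members in enumerate(clusters):
                member_conf = [confidences.get(spectra[i].source_id) for i in members]
                is_pfas_cluster = any(
                    c is not None and c >= cfg["min_confidence"] for c in member_conf)
                for i, conf in zip(members, member_conf):
                    fh.write(f"{cid}\t{spectra[i].source_id}"
                             f"\t{spectra[i].precursor_mz:.4f}"
                             f"\t{'' if conf is None else f'{conf:.1f}'}"
                             f"\t{is_pfas_cluster}\n")
        self._manifest("cluster", [self.spectra_path], [self.clusters_path], cfg)
        return clusters

    # -- driver ------------------------------------------------------------
    def run(self, stages: Optional[list[str]] = None) -> None:
        stages = list(stages or STAGES)
        for stage in stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
            logger.info("running stage %s", stage)
            getattr(self, stage.replace("-", "_"))()


def run_pipeline(config_path: Optional[str], workdir,
                 stages: Optional[list[str]] = None) -> Pipeline:
    pipeline = Pipeline(load_config(config_path), workdir)
    pipeline.run(stages)
    return pipeline
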