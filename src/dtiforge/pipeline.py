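"""End-to-end orchestration: featurize -> CNN -> fuse -> ELM -> evaluate.

Per cross-validation fold the pipeline

1. standardizes the 20 x 20 protein matrices with training-fold
   statistics and trains the CNN feature extractor on the training
   pairs only (interaction labels as the supervision signal);
2. extracts the penultimate-layer features Gamma for both folds with
   the frozen network;
3. fuses each pair's protein features with its drug fingerprint by
   concatenation, standardizes the fused vectors (training-fold mean
   and sd — the random-projection ELM hidden layer is scale
   sensitive), and fits the ELM by minimum-norm least squares;
4. scores the test fold; label 1 iff the positive-minus-negative
   output margin is > 0.

Test-fold labels are never visible to any training stage: the trainer
callback receives only training-fold indices and labels.

Two descriptor routes are available: the CNN route above and a 2DPCA
route (eigenbasis of the training matrices' image covariance,
projection flattened), used for ablation-style comparisons with the
classifier held fixed.  An "early" fusion mode instead embeds the
fingerprint alongside the protein matrix as a second input channel of
the CNN (zero-padded 30 x 30 grids) and feeds Gamma directly to the
ELM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cnn import CNNConfig, build_cnn, cnn_extract_batch, cnn_train
from .datasets import (
    GoldStandardDataset,
    InteractionPair,
    positive_pairs,
    sample_negatives,
)
from .descriptors import (
    FP_NBITS,
    Fingerprint,
    PSSM,
    load_fingerprint_table,
    load_pssm_dir,
    pssm_to_fixed,
    two_dpca_basis,
)
from .elm import ELMModel, elm_decide, elm_predict, elm_train
from .errors import ShapeError
from .evaluation import CVResult, five_fold_cv
from .datasets import load_gold_standard

__all__ = [
    "PipelineConfig",
    "PipelineRun",
    "FittedPipeline",
    "assemble_pairs",
    "featurize_pairs",
    "run_pipeline",
    "fit_full",
    "rank_candidates",
]

_EARLY_GRID = 30  # early-fusion input grid side; 881 fingerprint bits fit in 30x30


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    ``seed`` drives every stochastic stage (negative sampling, CV
    shuffle, per-fold CNN initialization and ELM hidden layer) through
    fixed offsets, so a run is reproducible from this one integer.
    """

    descriptor: str = "cnn"            # "cnn" | "2dpca"
    fusion: str = "late"               # "late" | "early"
    cnn: CNNConfig = field(default_factory=CNNConfig)
    n_2dpca_components: int = 6
    elm_n_hidden: int | None = None    # None -> min(1000, 10 L)
    elm_activation: str = "sigmoid"
    seed: int = 0
    stratified: bool = False
    resample_negatives_per_fold: bool = False
    # optional external inputs (used by the CLI)
    pairs_path: str | None = None
    fp_path: str | None = None
    pssm_dir: str | None = None

    def validate(self) -> None:
        if self.descriptor not in ("cnn", "2dpca"):
            raise ShapeError(f"unknown descriptor {self.descriptor!r}")
        if self.fusion not in ("late", "early"):
            raise ShapeError(f"unknown fusion mode {self.fusion!r}")
        if self.descriptor == "2dpca" and self.fusion == "early":
            raise ShapeError("early fusion requires the cnn descriptor")

    def to_dict(self) -> dict:
        return {
            "descriptor": self.descriptor,
            "fusion": self.fusion,
            "cnn": {
                "layers": [list(s) for s in self.cnn.layers],
                "input_shape": list(self.cnn.input_shape),
                "theta": self.cnn.theta,
                "epsilon": self.cnn.epsilon,
                "epochs": self.cnn.epochs,
                "seed": self.cnn.seed,
                "activation": self.cnn.activation,
                "pooling": self.cnn.pooling,
            },
            "n_2dpca_components": self.n_2dpca_components,
            "elm_n_hidden": self.elm_n_hidden,
            "elm_activation": self.elm_activation,
            "seed": self.seed,
            "stratified": self.stratified,
            "resample_negatives_per_fold": self.resample_negatives_per_fold,
        }


@dataclass
class PipelineRun:
    """CV outcome plus a reproducibility log (seeds, resolved config)."""

    cv_result: CVResult
    log: dict


# --- sample assembly ------------------------------------------------------


def assemble_pairs(
    ds: GoldStandardDataset, negatives: list[InteractionPair]
) -> tuple[list[InteractionPair], np.ndarray]:
    """Positives (sorted) + provided negatives, with the label vector."""
    pairs = positive_pairs(ds) + list(negatives)
    labels = np.array([p.label for p in pairs], dtype=int)
    return pairs, labels


def featurize_pairs(
    pairs: list[InteractionPair],
    fingerprints: dict[str, Fingerprint],
    pssms: dict[str, PSSM],
    fusion: str = "late",
) -> tuple[np.ndarray, np.ndarray]:
    """Raw per-pair inputs: protein images and fingerprint bit rows.

    Late fusion: images are (n, 1, 20, 20) protein matrices and the
    fingerprint matrix is kept separate for post-CNN concatenation.
    Early fusion: images are (n, 2, 30, 30) — channel 0 the zero-padded
    protein matrix, channel 1 the fingerprint reshaped into the grid.
    """
    mat_cache = {tid: pssm_to_fixed(p) for tid, p in pssms.items()}
    fps = np.stack([fingerprints[p.drug_id].bits for p in pairs]).astype(float)
    if fusion == "late":
        images = np.stack([mat_cache[p.target_id] for p in pairs])[:, None]
    else:
        n = len(pairs)
        images = np.zeros((n, 2, _EARLY_GRID, _EARLY_GRID))
        pad = np.zeros(_EARLY_GRID * _EARLY_GRID)
        for i, p in enumerate(pairs):
            images[i, 0, :20, :20] = mat_cache[p.target_id]
            grid = pad.copy()
            grid[:FP_NBITS] = fps[i]
            images[i, 1] = grid.reshape(_EARLY_GRID, _EARLY_GRID)
    return images, fps


class _Standardizer:
    """Per-coordinate z-scoring with training statistics.

    With ``unit_scale`` the z-scored vector is additionally divided by
    sqrt(d).  The ELM hidden layer projects features through
    uniform(-1, 1) weights, so pre-activations on raw z-scored
    d-dimensional input have sd ~ sqrt(d/3) and saturate the sigmoid
    into a pure random-sign hash; the sqrt(d) conditioning keeps them
    O(1), where the hidden layer is far more expressive.
    """

    def __init__(self, X: np.ndarray, unit_scale: bool = False):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd < 1e-8, 1.0, sd)
        self.scale = 1.0 / math.sqrt(X[0].size) if unit_scale else 1.0

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd * self.scale


@dataclass
class FittedPipeline:
    """Frozen per-fold (or full-data) model: extractor + ELM + scalers."""

    cfg: PipelineConfig
    image_scaler: _Standardizer
    extractor: object                  # CNNModel or 2DPCA basis ndarray
    feature_scaler: _Standardizer
    elm: ELMModel

    def _protein_features(self, images: np.ndarray) -> np.ndarray:
        z = self.image_scaler(images)
        if self.cfg.descriptor == "cnn":
            return cnn_extract_batch(self.extractor, z)
        return (z[:, 0] @ self.extractor).reshape(len(images), -1)

    def score(self, images: np.ndarray, fps: np.ndarray) -> np.ndarray:
        """Continuous decision margin per pair (label 1 iff > 0)."""
        gamma = self._protein_features(images)
        fused = gamma if self.cfg.fusion == "early" \
            else np.concatenate([gamma, fps], axis=1)
        out = elm_predict(self.elm, self.feature_scaler(fused))
        _, margin = elm_decide(out, positive_column=1)
        return margin


def _fit(
    cfg: PipelineConfig,
    images: np.ndarray,
    fps: np.ndarray,
    y: np.ndarray,
    stage_seed: int,
) -> FittedPipeline:
    image_scaler = _Standardizer(images)
    z = image_scaler(images)
    if cfg.descriptor == "cnn":
        cnn_cfg = CNNConfig(
            layers=list(cfg.cnn.layers),
            input_shape=images.shape[1:],
            theta=cfg.cnn.theta,
            epsilon=cfg.cnn.epsilon,
            epochs=cfg.cnn.epochs,
            seed=cfg.cnn.seed + stage_seed,
            activation=cfg.cnn.activation,
            pooling=cfg.cnn.pooling,
        )
        extractor = cnn_train(build_cnn(cnn_cfg), (z, y))
        gamma = cnn_extract_batch(extractor, z)
    else:
        extractor = two_dpca_basis([m for m in z[:, 0]], cfg.n_2dpca_components)
        gamma = (z[:, 0] @ extractor).reshape(len(images), -1)

    fused = gamma if cfg.fusion == "early" else np.concatenate([gamma, fps], axis=1)
    feature_scaler = _Standardizer(fused, unit_scale=True)
    onehot = np.zeros((len(y), 2))
    onehot[np.arange(len(y)), y] = 1.0
    # keep the hidden layer under-parameterized: the exact-interpolation
    # regime N ~ L fits the training noise and collapses test AUC
    n_hidden = cfg.elm_n_hidden
    if n_hidden is None:
        n_hidden = min(500, max(10, len(y) // 2))
    elm = elm_train(
        feature_scaler(fused),
        onehot,
        n_hidden=n_hidden,
        seed=cfg.seed + 1000 + stage_seed,
        activation=cfg.elm_activation,
    )
    return FittedPipeline(cfg, image_scaler, extractor, feature_scaler, elm)


def run_pipeline(
    cfg: PipelineConfig,
    dataset: GoldStandardDataset | None = None,
    fingerprints: dict[str, Fingerprint] | None = None,
    pssms: dict[str, PSSM] | None = None,
) -> PipelineRun:
    """Five-fold cross-validate the full pipeline.

    Inputs may be passed in memory or, when omitted, loaded from the
    paths in ``cfg``.  The balanced negative set is sampled once from
    the non-positive cross-product (seed ``cfg.seed``); with
    ``resample_negatives_per_fold`` negatives are re-drawn per fold
    (sensitivity analysis) — the CV split is then over a fresh sample
    each fold, so only fold reports, not the split, stay comparable.
    """
    cfg.validate()
    if dataset is None:
        if not (cfg.pairs_path and cfg.fp_path and cfg.pssm_dir):
            raise ShapeError("either in-memory inputs or all three paths required")
        dataset = load_gold_standard(cfg.pairs_path)
        fingerprints = load_fingerprint_table(cfg.fp_path)
        pssms = load_pssm_dir(cfg.pssm_dir, dataset.target_ids)

    def build_samples(neg_seed: int):
        negatives = sample_negatives(dataset, seed=neg_seed)
        pairs, labels = assemble_pairs(dataset, negatives)
        images, fps = featurize_pairs(pairs, fingerprints, pssms, cfg.fusion)
        return pairs, labels, images, fps

    pairs, labels, images, fps = build_samples(cfg.seed)

    fold_counter = {"i": 0}

    def trainer(idx_train, y_train):
        fold = fold_counter["i"]
        fold_counter["i"] += 1
        if cfg.resample_negatives_per_fold:
            _, _, imgs, f = build_samples(cfg.seed + 7919 * (fold + 1))
        else:
            imgs, f = images, fps
        fitted = _fit(cfg, imgs[idx_train], f[idx_train], y_train, stage_seed=fold)

        def scorer(idx_test):
            return fitted.score(imgs[idx_test], f[idx_test])

        return scorer

    cv = five_fold_cv(
        np.arange(len(labels)), labels, trainer,
        seed=cfg.seed, stratified=cfg.stratified,
    )
    log = {
        "config": cfg.to_dict(),
        "seeds": {
            "master": cfg.seed,
            "negative_sampling": cfg.seed,
            "cv_shuffle": cfg.seed,
            "cnn_init_per_fold": [cfg.cnn.seed + f for f in range(5)],
            "elm_per_fold": [cfg.seed + 1000 + f for f in range(5)],
        },
        "dataset": {
            "name": dataset.name,
            "n_drugs": dataset.n_drugs,
            "n_targets": dataset.n_targets,
            "n_positives": len(dataset.positives),
            "n_samples": int(len(labels)),
        },
    }
    return PipelineRun(cv_result=cv, log=log)


def fit_full(
    cfg: PipelineConfig,
    dataset: GoldStandardDataset,
    fingerprints: dict[str, Fingerprint],
    pssms: dict[str, PSSM],
) -> FittedPipeline:
    """Train one model on all positives + one sampled negative set."""
    cfg.validate()
    negatives = sample_negatives(dataset, seed=cfg.seed)
    pairs, labels = assemble_pairs(dataset, negatives)
    images, fps = featurize_pairs(pairs, fingerprints, pssms, cfg.fusion)
    return _fit(cfg, images, fps, labels, stage_seed=0)


def rank_candidates(
    fitted: FittedPipeline,
    dataset: GoldStandardDataset,
    fingerprints: dict[str, Fingerprint],
    pssms: dict[str, PSSM],
    k: int = 10,
) -> list[tuple[str, str, float]]:
    """Score every non-positive pair; return the k best.

    Returns (drug_id, target_id, score) rows sorted by descending
    score, ties broken lexicographically by (drug_id, target_id).  If
    fewer than k unknown pairs exist, all are returned.
    """
    unknown = [
        InteractionPair(drug_id=d, target_id=t, label=0)
        for d in dataset.drug_ids
        for t in dataset.target_ids
        if (d, t) not in dataset.positives
    ]
    if not unknown:
        return []
    images, fps = featurize_pairs(unknown, fingerprints, pssms, fitted.cfg.fusion)
    scores = fitted.score(images, fps)
    rows = sorted(
        zip((p.drug_id for p in unknown), (p.target_id for p in unknown), scores),
        key=lambda r: (-r[2], r[0], r[1]),
    )
    return [(d, t, float(s)) for d, t, s in rows[: max(k, 0)]]
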