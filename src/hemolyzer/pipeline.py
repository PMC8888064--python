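"""End-to-end orchestration: generate → preprocess → augment → extend →
extract → train → evaluate.

The train/test split happens before any augmentation, and both geometric and
adversarial expansion touch the training pool only — the test manifest never
contains a synthesized or transformed image, so reported accuracy is free of
leakage.  Every stage draws from its own named seed, making a whole run a
pure function of (config, seeds).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize
from sklearn.metrics import confusion_matrix

from . import elm, gan as gan_mod
from .features import default_backbone, extract_features
from .geometric import AugmentConfig, augment_batch
from .phantoms import LabeledImage, sample_dataset
from .preprocess import equalize

__all__ = [
    "SplitSpec",
    "PipelineConfig",
    "split_dataset",
    "extend_training_pool",
    "evaluate",
    "run_pipeline",
]


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(items: list, spec: SplitSpec) -> tuple[list, list]:
    """Disjoint train/test partition; |train| = round(train_fraction·N).

    With stratification the split is applied per class (round-half-up within
    each class); a class with fewer than 2 items cannot be stratified.
    """
    if not items:
        raise ValueError("empty manifest")
    rng = np.random.default_rng(spec.seed)
    labels = np.array([it.label for it in items])
    train_idx: list[int] = []
    if spec.stratified:
        for lab in np.unique(labels):
            idx = np.nonzero(labels == lab)[0]
            if idx.size < 2:
                raise ValueError(f"class {lab} has {idx.size} item(s); cannot stratify")
            perm = rng.permutation(idx)
            n_train = _round_half_up(spec.train_fraction * idx.size)
            train_idx.extend(perm[:n_train])
    else:
        perm = rng.permutation(len(items))
        n_train = _round_half_up(spec.train_fraction * len(items))
        train_idx.extend(perm[:n_train])
    train_set = set(train_idx)
    train = [items[i] for i in sorted(train_set)]
    test = [items[i] for i in range(len(items)) if i not in train_set]
    return train, test


def extend_training_pool(train_items: list, generated_items: list) -> list:
    """Concatenate accepted synthesized samples onto the training pool."""
    return list(train_items) + list(generated_items)


def evaluate(predictions, truth, n_classes: int = 3) -> dict:
    """Overall accuracy, per-class recall and the confusion matrix.

    ``confusion[i][j]`` counts items of true class i predicted as class j.
    """
    predictions = np.asarray(predictions, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth lengths differ")
    cm = confusion_matrix(truth, predictions, labels=list(range(n_classes)))
    row_sums = cm.sum(axis=1)
    recall = [
        float(cm[i, i] / row_sums[i]) if row_sums[i] else float("nan")
        for i in range(n_classes)
    ]
    return {
        "accuracy": float(np.mean(predictions == truth)),
        "per_class_recall": recall,
        "confusion": cm.tolist(),
    }


@dataclass
class PipelineConfig:
    """Configuration of a full run; every random stage has a named seed."""

    n_per_class: int = 300
    resolution: tuple[int, int] = (72, 128)
    train_fraction: float = 0.8
    equalize: bool = True
    augment: AugmentConfig | None = None  # None disables the geometric stage
    gan_per_class: int = 0  # 0 disables adversarial extension
    gan_epochs: int = 120
    gan_resolution: tuple[int, int] = (36, 64)
    hidden_nodes: int = elm.DEFAULT_HIDDEN_NODES
    alpha: float = elm.DEFAULT_ALPHA
    #: when set, the ridge level is chosen by k-fold CV on the training
    #: features (at the configured hidden-node count) instead of ``alpha``
    alpha_candidates: tuple | None = elm.DEFAULT_ALPHA_CANDIDATES
    cv_folds: int | None = 4
    cv_candidates: tuple | None = None  # set to run a hidden-node sweep
    data_seed: int = 0
    split_seed: int = 1
    augment_seed: int = 2
    gan_seed: int = 3
    backbone_seed: int = 4
    elm_seed: int = 5


def _equalize_items(items: list[LabeledImage]) -> list[LabeledImage]:
    return [LabeledImage(image=equalize(it.image), label=it.label) for it in items]


def _gan_extend(train: list[LabeledImage], cfg: PipelineConfig) -> list[LabeledImage]:
    """Train one GAN per class on downscaled training images and synthesize."""
    out: list[LabeledImage] = []
    gh, gw = cfg.gan_resolution
    h, w = cfg.resolution
    for lab in (0, 1, 2):
        cls = [it.image for it in train if it.label == lab]
        if not cls:
            continue
        small = np.stack(
            [resize(im.astype(float) / 255.0, (gh, gw), anti_aliasing=True) for im in cls]
        )
        tcfg = gan_mod.GanTrainConfig(
            epochs=cfg.gan_epochs, batch_size=min(16, len(cls)),
            seed=cfg.gan_seed + lab, latent_dim=16, hidden_dim=64,
        )
        model = gan_mod.train(small, tcfg)
        samples = gan_mod.sample_and_filter(
            model, cfg.gan_per_class, seed=cfg.gan_seed + 100 + lab,
            filter_band=(0.0, 1.0), min_foreground=0.05,
        )
        for s in samples:
            big = resize(s, (h, w), anti_aliasing=False)
            img = np.clip(np.rint(big * 255.0), 0, 255).astype(np.uint8)
            out.append(LabeledImage(image=img, label=lab))
    return out


def run_pipeline(cfg: PipelineConfig, images: list[LabeledImage] | None = None):
    """Execute the full protocol and return (manifest, metrics).

    ``images`` overrides the phantom-generation stage with an existing
    labeled dataset.  The manifest records per-stage counts and origins; the
    metrics dict carries accuracy, per-class recall, the confusion matrix,
    optional cross-validation results and stage timings.
    """
    manifest: list[dict] = []
    timings: dict[str, float] = {}

    def stage(name):
        timings[name] = time.perf_counter()

    def done(name, **counts):
        timings[name] = time.perf_counter() - timings[name]
        manifest.append({"stage": name, **counts})

    stage("generate")
    if images is None:
        images = sample_dataset(cfg.n_per_class, cfg.data_seed, cfg.resolution)
    done("generate", n=len(images))

    stage("split")
    train, test = split_dataset(images, SplitSpec(cfg.train_fraction, cfg.split_seed))
    done("split", n_train=len(train), n_test=len(test))

    if cfg.equalize:
        stage("equalize")
        train, test = _equalize_items(train), _equalize_items(test)
        done("equalize", n_train=len(train), n_test=len(test))

    n_real_train = len(train)
    if cfg.augment is not None:
        stage("augment")
        aug_cfg = cfg.augment
        if aug_cfg.seed != cfg.augment_seed:
            aug_cfg = AugmentConfig(**{**aug_cfg.__dict__, "seed": cfg.augment_seed})
        augmented = augment_batch(train, aug_cfg)
        train = extend_training_pool(train, augmented)
        done("augment", n_added=len(augmented), n_train=len(train))

    if cfg.gan_per_class > 0:
        stage("gan")
        generated = _gan_extend(train[:n_real_train], cfg)
        train = extend_training_pool(train, generated)
        done("gan", n_added=len(generated), n_train=len(train))

    stage("extract")
    backbone = default_backbone(seed=cfg.backbone_seed)
    F_train = extract_features(train, backbone)
    F_test = extract_features(test, backbone)
    y_train = np.array([it.label for it in train])
    y_test = np.array([it.label for it in test])
    done("extract", n_features=F_train.shape[1])

    metrics: dict = {}
    alpha = cfg.alpha
    if cfg.alpha_candidates and cfg.cv_folds:
        stage("select_alpha")
        a_table, alpha = elm.select_alpha(
            F_train, y_train, hidden_nodes=cfg.hidden_nodes,
            candidates=cfg.alpha_candidates, k=cfg.cv_folds, seed=cfg.elm_seed,
        )
        metrics["alpha_table"] = a_table
        metrics["alpha_selected"] = alpha
        metrics["cv_accuracy"] = max(acc for _, acc in a_table)
        done("select_alpha", n_candidates=len(a_table))

    if cfg.cv_candidates:
        stage("sweep")
        table, best = elm.sweep_hidden_nodes(
            F_train, y_train, candidates=cfg.cv_candidates,
            k=cfg.cv_folds or 4, seed=cfg.elm_seed, alpha=alpha,
        )
        metrics["cv_table"] = table
        metrics["cv_best_hidden_nodes"] = best
        done("sweep", n_candidates=len(table))
        hidden_nodes = best
    else:
        hidden_nodes = cfg.hidden_nodes
        if cfg.cv_folds and "cv_accuracy" not in metrics:
            stage("cv")
            table, _ = elm.sweep_hidden_nodes(
                F_train, y_train, candidates=[hidden_nodes],
                k=cfg.cv_folds, seed=cfg.elm_seed, alpha=alpha,
            )
            metrics["cv_accuracy"] = table[0][1]
            done("cv", folds=cfg.cv_folds)

    stage("train")
    model = elm.fit(
        F_train, y_train, hidden_nodes=hidden_nodes, alpha=alpha, seed=cfg.elm_seed
    )
    done("train", hidden_nodes=hidden_nodes)

    stage("evaluate")
    pred = elm.predict(F_test, model)
    metrics.update(evaluate(pred, y_test))
    done("evaluate", n_test=len(test))

    metrics["timings"] = {k: round(v, 3) for k, v in timings.items()}
    metrics["counts"] = {
        "train_final": len(train),
        "train_real": n_real_train,
        "test": len(test),
    }
    return manifest, metrics
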