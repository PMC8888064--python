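"""Disk formats: PNG images with manifest CSVs, feature CSVs, model files."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .elm import ElmModel
from .gan import GanModel
from .phantoms import LabeledImage

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_features_csv",
    "read_features_csv",
    "save_elm",
    "load_elm",
    "save_gan",
    "load_gan",
]


def write_dataset(images: list[LabeledImage], outdir, origins=None) -> Path:
    """Write PNGs named ``<label>_<index>.png`` plus a ``manifest.csv``.

    The manifest has columns ``path,label`` (and ``origin`` when given:
    real / geom / gan).  Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, item in enumerate(images):
        name = f"{item.label}_{i}.png"
        iio.imwrite(outdir / name, item.image)
        row = {"path": name, "label": item.label}
        if origins is not None:
            row["origin"] = origins[i]
        rows.append(row)
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(manifest_path) -> list[LabeledImage]:
    """Load images listed in a ``path,label`` manifest CSV."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    out = []
    for _, row in df.iterrows():
        img = iio.imread(base / row["path"])
        out.append(LabeledImage(image=np.asarray(img), label=int(row["label"])))
    return out


def write_features_csv(F: np.ndarray, labels, path) -> None:
    """Feature matrix to CSV: ``image_id`` and ``label`` columns plus f0..fL−1."""
    df = pd.DataFrame(F, columns=[f"f{i}" for i in range(F.shape[1])])
    df.insert(0, "label", np.asarray(labels, dtype=int))
    df.insert(0, "image_id", np.arange(F.shape[0]))
    df.to_csv(path, index=False)


def read_features_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    labels = df["label"].to_numpy(dtype=int)
    F = df.drop(columns=["image_id", "label"]).to_numpy(dtype=float)
    return F, labels


def save_elm(model: ElmModel, path) -> None:
    """ELM to a .npz array container plus a .json metadata sidecar."""
    path = Path(path)
    arrays = {"W": model.W, "b": model.b}
    if model.beta is not None:
        arrays["beta"] = model.beta
    if model.feature_mean is not None:
        arrays["feature_mean"] = model.feature_mean
        arrays["feature_std"] = model.feature_std
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "alpha": model.alpha,
        "n_classes": model.n_classes,
        "hidden_nodes": model.hidden_nodes,
        "activation": "sigmoid",
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_elm(path) -> ElmModel:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return ElmModel(
        W=data["W"],
        b=data["b"],
        alpha=float(meta["alpha"]),
        beta=data["beta"] if "beta" in data else None,
        n_classes=int(meta["n_classes"]),
        feature_mean=data["feature_mean"] if "feature_mean" in data else None,
        feature_std=data["feature_std"] if "feature_std" in data else None,
    )


def save_gan(model: GanModel, path) -> None:
    path = Path(path)
    arrays = {f"gen_{k}": v for k, v in model.gen.items()}
    arrays.update({f"disc_{k}": v for k, v in model.disc.items()})
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "latent_dim": model.latent_dim,
        "image_shape": list(model.image_shape),
        "history": model.history,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_gan(path) -> GanModel:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    gen = {k[4:]: data[k] for k in data.files if k.startswith("gen_")}
    disc = {k[5:]: data[k] for k in data.files if k.startswith("disc_")}
    return GanModel(
        gen=gen,
        disc=disc,
        latent_dim=int(meta["latent_dim"]),
        image_shape=tuple(meta["image_shape"]),
        history=meta.get("history", {}),
    )
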