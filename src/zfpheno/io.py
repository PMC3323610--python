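"""Image, manifest, feature-table and model-bundle I/O plus well parsing.

Images arrive as 16-bit grayscale TIFF or 8-bit PNG/JPEG, one well per
file; 16-bit intensities map to 8 bits by round(v / 257).  Manifests,
feature tables and reports are plain comma-separated tables.  Trained
models persist as a versioned joblib bundle carrying the classifier, the
subset code, the normalizer and training metadata so recognition of new
images always reuses training-set statistics.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .classify import TrainedClassifier
from .descriptors import EdgeConfig, GrayImage, extract, subset_blocks

__all__ = [
    "read_image",
    "write_image",
    "parse_well",
    "well_name",
    "read_manifest",
    "write_manifest",
    "feature_table",
    "split_features",
    "save_model",
    "load_model",
    "MODEL_FORMAT_VERSION",
]

MODEL_FORMAT_VERSION = 1

MANIFEST_COLUMNS = ("image_id", "path", "plate_id", "well_id", "label")

_WELL_RE = re.compile(r"^([A-H])([1-9]|1[0-2])$")


def parse_well(well_id: str) -> tuple[int, int]:
    """Map a 96-well id to 0-based (row, col): A1 -> (0, 0), H12 -> (7, 11)."""
    m = _WELL_RE.match(well_id)
    if not m:
        raise ValueError(f"invalid 96-well id {well_id!r} (expected A1..H12)")
    return ord(m.group(1)) - ord("A"), int(m.group(2)) - 1


def well_name(row: int, col: int) -> str:
    """Inverse of :func:`parse_well`."""
    if not (0 <= row <= 7 and 0 <= col <= 11):
        raise ValueError(f"well coordinates ({row}, {col}) outside a 96-well plate")
    return f"{chr(ord('A') + row)}{col + 1}"


def read_image(path: str | Path) -> GrayImage:
    """Load a single-channel well image as an 8-bit :class:`GrayImage`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return GrayImage(arr, source_depth=8)
    if arr.dtype == np.uint16:
        return GrayImage(np.rint(arr / 257.0).astype(np.uint8), source_depth=16)
    raise ValueError(f"{path}: unsupported pixel dtype {arr.dtype}")


def write_image(path: str | Path, img: GrayImage) -> None:
    """Write an 8-bit image losslessly (PNG or TIFF by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img.pixels)
    else:
        Image.fromarray(img.pixels).save(path)


# ---------------------------------------------------------------------------
# manifests and feature tables
# ---------------------------------------------------------------------------


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns and c != "label"]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a plate manifest (unique ids, valid well ids)."""
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in ("image_id", "path", "plate_id", "well_id") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {missing}")
    if df["image_id"].duplicated().any():
        dupes = df.loc[df["image_id"].duplicated(), "image_id"].tolist()
        raise ValueError(f"duplicate image ids in manifest: {dupes[:5]}")
    for well in df["well_id"]:
        parse_well(str(well))
    return df


def feature_table(
    manifest: pd.DataFrame,
    images: Mapping[str, GrayImage],
    subset: str = "111111",
    cfg: EdgeConfig | None = None,
) -> pd.DataFrame:
    """Per-image descriptor rows: image_id, well, label, then components."""
    rows = []
    names: list[str] | None = None
    for rec in manifest.itertuples(index=False):
        img = images[rec.image_id]
        vec = extract(img, subset, cfg)
        if names is None:
            names = vec.component_names
        rows.append(
            [rec.image_id, rec.well_id, getattr(rec, "label", "")] + list(vec.values)
        )
    return pd.DataFrame(rows, columns=["image_id", "well", "label"] + (names or []))


def split_features(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Split a feature table into (metadata, X, y)."""
    meta_cols = [c for c in ("image_id", "well", "label") if c in features.columns]
    comp_cols = [c for c in features.columns if c not in meta_cols]
    meta = features[meta_cols]
    y = features["label"].to_numpy(dtype=str) if "label" in features.columns else np.array([])
    return meta, features[comp_cols], y


# ---------------------------------------------------------------------------
# model bundles
# ---------------------------------------------------------------------------


def save_model(model: TrainedClassifier, path: str | Path) -> None:
    """Persist a trained classifier as a versioned bundle."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "classifier": model}, path)


def load_model(path: str | Path) -> TrainedClassifier:
    """Load a model bundle, refusing unknown format versions."""
    bundle = joblib.load(path)
    version = bundle.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model bundle {path} has format version {version}; "
            f"this build reads version {MODEL_FORMAT_VERSION}"
        )
    return bundle["classifier"]


def subset_columns(columns: Sequence[str], subset: str) -> list[str]:
    """Feature-table columns belonging to the blocks of a subset code."""
    prefixes = tuple(f"{name}_" for name in subset_blocks(subset))
    return [c for c in columns if c.startswith(prefixes)]
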