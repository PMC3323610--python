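"""Feature normalization and edge-count quality triage.

Descriptor components have wildly different dynamic ranges (quantized
edge bins in [0, 7] next to pixel counts up to width x height), so every
component is Z-scored with statistics learned on the training set only.
Images are triaged before modelling: an image whose MPEG-7 edge count
reaches the threshold (default 170) is dominated by particle deposits or
debris and is routed to the stress partition rather than discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .descriptors import EdgeConfig, GrayImage, count_edges

__all__ = ["Normalizer", "QCReport", "qc_filter", "DEFAULT_EDGE_THRESHOLD"]

#: Edge-count threshold separating good-quality from stress images.
DEFAULT_EDGE_THRESHOLD = 170


@dataclass
class Normalizer:
    """Per-component Z-score parameters (c - mu) / sigma.

    ``sigma`` is the population (divide-by-n) standard deviation of the
    training set.  Constant components (sigma = 0) transform to 0.
    """

    mean: np.ndarray
    std: np.ndarray
    names: tuple[str, ...]

    @classmethod
    def fit(cls, train: pd.DataFrame | np.ndarray) -> "Normalizer":
        """Learn component means and population SDs from training rows."""
        if isinstance(train, pd.DataFrame):
            names = tuple(train.columns)
            x = train.to_numpy(dtype=float)
        else:
            x = np.asarray(train, dtype=float)
            if x.ndim != 2:
                raise ValueError("expected a 2-D feature matrix")
            names = tuple(f"c{i}" for i in range(x.shape[1]))
        if x.shape[0] < 2:
            raise ValueError(f"need at least 2 training rows, got {x.shape[0]}")
        return cls(mean=x.mean(axis=0), std=x.std(axis=0, ddof=0), names=names)

    def transform(
        self, x: pd.DataFrame | pd.Series | np.ndarray
    ) -> pd.DataFrame | pd.Series | np.ndarray:
        """Apply z = (c - mu) / sigma componentwise; sigma = 0 maps to 0."""
        if isinstance(x, pd.DataFrame):
            self._check_names(x.columns)
            z = self._z(x.to_numpy(dtype=float))
            return pd.DataFrame(z, index=x.index, columns=x.columns)
        if isinstance(x, pd.Series):
            self._check_names(x.index)
            return pd.Series(self._z(x.to_numpy(dtype=float)), index=x.index)
        arr = np.asarray(x, dtype=float)
        vec = arr.ndim == 1
        arr = np.atleast_2d(arr)
        if arr.shape[1] != len(self.names):
            raise ValueError(
                f"feature dimension {arr.shape[1]} does not match the "
                f"{len(self.names)} fitted components"
            )
        z = self._z(arr)
        return z[0] if vec else z

    def inverse(self, z: np.ndarray) -> np.ndarray:
        """Map standardized values back: c = z * sigma + mu."""
        return np.asarray(z, dtype=float) * self.std + self.mean

    def _z(self, arr: np.ndarray) -> np.ndarray:
        safe = np.where(self.std > 0, self.std, 1.0)
        z = (arr - self.mean) / safe
        z[..., self.std == 0] = 0.0
        return z

    def _check_names(self, cols: Sequence[str]) -> None:
        missing = [n for n in self.names if n not in set(cols)]
        extra = [c for c in cols if c not in set(self.names)]
        if missing or extra:
            msg = []
            if missing:
                msg.append(f"missing components: {missing[:8]}")
            if extra:
                msg.append(f"unknown components: {extra[:8]}")
            raise ValueError("; ".join(msg))
        if list(cols) != list(self.names):
            raise ValueError("component order does not match fitted components")

    # -- serialization (human-readable, kept next to the model bundle) ----

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"component": self.names, "mean": self.mean, "std": self.std})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Normalizer":
        return cls(
            mean=df["mean"].to_numpy(dtype=float),
            std=df["std"].to_numpy(dtype=float),
            names=tuple(df["component"]),
        )


# ---------------------------------------------------------------------------
# quality triage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCReport:
    """Edge-count quality verdict for one image."""

    image_id: str
    edge_count: int
    verdict: str  # "good" or "stress"
    threshold: int

    def __post_init__(self) -> None:
        expected = "good" if self.edge_count < self.threshold else "stress"
        if self.verdict != expected:
            raise ValueError("verdict inconsistent with edge count and threshold")


def qc_filter(
    images: Iterable[tuple[str, GrayImage]],
    threshold: int = DEFAULT_EDGE_THRESHOLD,
    cfg: EdgeConfig | None = None,
) -> list[QCReport]:
    """Partition images into good / stress by edge count.

    An image is ``good`` iff its edge count is strictly below the
    threshold.  Nothing is deleted; stress images are kept for external
    validation of a trained model.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    cfg = cfg or EdgeConfig()
    reports = []
    for image_id, img in images:
        n = count_edges(img, cfg)
        verdict = "good" if n < threshold else "stress"
        reports.append(QCReport(image_id, n, verdict, threshold))
    if not reports:
        warnings.warn("qc_filter received no images", stacklevel=2)
    return reports


def qc_table(reports: Sequence[QCReport]) -> pd.DataFrame:
    """QC reports as a table (image_id, edge_count, verdict, threshold)."""
    return pd.DataFrame(
        {
            "image_id": [r.image_id for r in reports],
            "edge_count": [r.edge_count for r in reports],
            "verdict": [r.verdict for r in reports],
            "threshold": [r.threshold for r in reports],
        }
    )
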