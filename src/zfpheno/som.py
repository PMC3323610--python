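"""Self-organizing-map phenotype mapping and cluster-quality scoring.

A rectangular SOM is batch-trained on standardized descriptor vectors
without using labels.  Each image then maps to its best-matching cell
(minimum Euclidean distance) and cells are colored
[R, G, B] = [N_dead, N_hatched, N_unhatched] / N, so homogeneous cells
are pure red (dead), green (hatched) or blue (unhatched) and empty cells
are white.  Codebook vectors are grouped into primary clusters by
k-means; cluster quality against known labels is scored like a confusion
matrix, with user-specified metaclusters merged first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .classify import CLASSES

__all__ = [
    "SOMGrid",
    "CellStats",
    "ClusterQuality",
    "train_som",
    "map_images",
    "cluster_cells",
    "cluster_quality",
    "cluster_quality_from_table",
    "render_map",
]

#: RGB channel order of the cell coloring (R = dead, G = hatched, B = unhatched).
RGB_CLASS_ORDER: tuple[str, ...] = ("dead", "hatched", "unhatched")


@dataclass
class SOMGrid:
    """A trained map: ``codebook[r, c]`` is the cell (r, c) prototype."""

    codebook: np.ndarray  # (rows, cols, dim)
    seed: int
    n_epochs: int
    radius_init: float
    radius_final: float

    @property
    def rows(self) -> int:
        return self.codebook.shape[0]

    @property
    def cols(self) -> int:
        return self.codebook.shape[1]

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    @property
    def dim(self) -> int:
        return self.codebook.shape[2]

    def flat(self) -> np.ndarray:
        return self.codebook.reshape(self.n_cells, self.dim)


@dataclass(frozen=True)
class CellStats:
    """Per-cell image counts and the derived RGB color."""

    row: int
    col: int
    counts: Mapping[str, int]

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def rgb(self) -> tuple[float, float, float]:
        if self.n == 0:
            return (1.0, 1.0, 1.0)  # empty cell: white
        return tuple(self.counts.get(c, 0) / self.n for c in RGB_CLASS_ORDER)


def _grid_coords(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)


def train_som(
    X,
    grid_shape: tuple[int, int] = (15, 15),
    seed: int = 0,
    n_epochs: int = 50,
    radius_init: float | None = None,
    radius_final: float = 1.0,
) -> SOMGrid:
    """Batch-train a SOM with a Gaussian neighborhood.

    Codebooks are initialized from seeded random data rows.  Each epoch
    assigns every sample to its best-matching cell and replaces each
    codebook by the neighborhood-weighted mean of all samples; the
    neighborhood radius decays linearly from ``radius_init`` (default
    max(grid)/2) to ``radius_final``.  Fully deterministic per seed.
    """
    Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Xm = np.atleast_2d(Xm)
    rows, cols = grid_shape
    if rows < 1 or cols < 1:
        raise ValueError(f"degenerate SOM grid {grid_shape}")
    n_cells = rows * cols
    n = Xm.shape[0]
    if n < n_cells:
        warnings.warn(
            f"{n} samples for {n_cells} SOM cells; many cells will stay empty",
            stacklevel=2,
        )
    if radius_init is None:
        radius_init = max(rows, cols) / 2.0
    rng = np.random.default_rng(seed)
    codebook = Xm[rng.integers(0, n, size=n_cells)].astype(float).copy()
    coords = _grid_coords(rows, cols)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    sq_norm_x = (Xm**2).sum(1)
    for epoch in range(n_epochs):
        frac = epoch / max(n_epochs - 1, 1)
        sigma = radius_init + frac * (radius_final - radius_init)
        d2 = sq_norm_x[:, None] - 2.0 * Xm @ codebook.T + (codebook**2).sum(1)[None, :]
        bmu = np.argmin(d2, axis=1)
        h = np.exp(-grid_d2 / (2.0 * sigma**2))  # (cells, cells)
        weights = h[bmu]                          # (n, cells)
        denom = weights.sum(axis=0)
        numer = weights.T @ Xm
        update = denom > 1e-12
        codebook[update] = numer[update] / denom[update, None]
    return SOMGrid(
        codebook=codebook.reshape(rows, cols, -1),
        seed=seed,
        n_epochs=n_epochs,
        radius_init=float(radius_init),
        radius_final=float(radius_final),
    )


def bmu_cells(som: SOMGrid, X) -> np.ndarray:
    """Flat best-matching-cell index for every row of ``X``."""
    Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Xm = np.atleast_2d(Xm)
    if Xm.shape[1] != som.dim:
        raise ValueError(f"feature dimension {Xm.shape[1]} != codebook dimension {som.dim}")
    flat = som.flat()
    d2 = (Xm**2).sum(1)[:, None] - 2.0 * Xm @ flat.T + (flat**2).sum(1)[None, :]
    return np.argmin(d2, axis=1)


def map_images(
    som: SOMGrid, X, labels: Sequence[str] | None = None
) -> tuple[list[CellStats], np.ndarray]:
    """Assign images to cells and compute per-cell counts and colors.

    Returns the per-cell stats (all cells, row-major) and the flat cell
    index of each image.
    """
    bmu = bmu_cells(som, X)
    n = len(bmu)
    labs = np.asarray(labels) if labels is not None else np.array(["unlabeled"] * n)
    stats = []
    for cell in range(som.n_cells):
        members = labs[bmu == cell]
        counts = {c: int(np.sum(members == c)) for c in CLASSES}
        if labels is None:
            counts = {"unlabeled": int(len(members))}
        stats.append(CellStats(row=cell // som.cols, col=cell % som.cols, counts=counts))
    assert sum(s.n for s in stats) == n
    return stats, bmu


def cell_table(stats: Sequence[CellStats]) -> pd.DataFrame:
    """Cell stats as a table (row, col, per-class counts, N, r, g, b)."""
    rows = []
    for s in stats:
        r, g, b = s.rgb
        rec = {"row": s.row, "col": s.col}
        rec.update({f"n_{c}": s.counts.get(c, 0) for c in CLASSES})
        rec.update({"N": s.n, "r": r, "g": g, "b": b})
        rows.append(rec)
    return pd.DataFrame(rows)


def cluster_cells(som: SOMGrid, k: int = 4, seed: int = 0) -> np.ndarray:
    """k-means clustering of the codebook vectors, one id per cell (flat).

    Ten seeded restarts; cluster ids are relabeled by the lexicographic
    order of the cluster centroids so the labeling is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > som.n_cells:
        raise ValueError(f"k={k} exceeds the {som.n_cells} cells")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(som.flat())
    order = np.lexsort(km.cluster_centers_.T[::-1])  # sort centroids lexicographically
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[raw]


@dataclass(frozen=True)
class ClusterQuality:
    """Cluster-by-phenotype table with merge-aware precision / recall.

    ``average_quality`` is the fraction (percent) of images that fall in
    a cluster whose majority phenotype matches their own.
    """

    table: pd.DataFrame                       # merged clusters x phenotypes
    assigned: dict[str, str]                  # merged cluster -> majority phenotype
    precision: dict[str, float]               # per merged cluster, percent
    recall: dict[str, float | None]           # per phenotype, percent
    average_quality: float
    ambiguous: tuple[str, ...] = field(default_factory=tuple)


def _merge_table(table: pd.DataFrame, merges: Sequence[Sequence[object]]) -> pd.DataFrame:
    merged = table.copy()
    for group in merges:
        group = list(group)
        missing = [g for g in group if g not in merged.index]
        if missing:
            raise ValueError(f"merge refers to unknown clusters: {missing}")
        name = "+".join(str(g) for g in group)
        combined = merged.loc[group].sum(axis=0)
        merged = merged.drop(index=group)
        merged.loc[name] = combined
    return merged


def cluster_quality_from_table(
    table: pd.DataFrame, merges: Sequence[Sequence[object]] = ()
) -> ClusterQuality:
    """Score a cluster-by-phenotype count table (rows = clusters).

    Each (merged) cluster is assigned its majority phenotype (ties go to
    phenotype column order and are flagged); cluster precision is the
    majority fraction, phenotype recall the fraction of that phenotype
    captured by its assigned cluster(s), and the average quality the
    overall correctly-grouped fraction.
    """
    merged = _merge_table(table, merges)
    phenos = list(table.columns)
    assigned: dict[str, str] = {}
    precision: dict[str, float] = {}
    ambiguous: list[str] = []
    correct = 0
    for cluster, row in merged.iterrows():
        top = row.max()
        winners = [p for p in phenos if row[p] == top]
        if len(winners) > 1:
            ambiguous.append(str(cluster))
        assigned[str(cluster)] = winners[0]
        total = int(row.sum())
        precision[str(cluster)] = 100.0 * top / total if total else 0.0
        correct += int(top)
    recall: dict[str, float | None] = {}
    for p in phenos:
        col_total = int(merged[p].sum())
        captured = sum(
            int(merged.loc[cl, p]) for cl in merged.index if assigned[str(cl)] == p
        )
        recall[p] = 100.0 * captured / col_total if col_total else None
    total_images = int(merged.to_numpy().sum())
    return ClusterQuality(
        table=merged,
        assigned=assigned,
        precision=precision,
        recall=recall,
        average_quality=100.0 * correct / total_images,
        ambiguous=tuple(ambiguous),
    )


def cluster_quality(
    cell_clusters: np.ndarray,
    image_cells: np.ndarray,
    labels: Sequence[str],
    merges: Sequence[Sequence[object]] = (),
    classes: Sequence[str] = CLASSES,
) -> ClusterQuality:
    """Score SOM clusters against known phenotype labels.

    ``cell_clusters`` gives the cluster id of every cell (flat index) and
    ``image_cells`` the best-matching cell of every image, as returned by
    :func:`cluster_cells` and :func:`map_images`.
    """
    labs = np.asarray(labels)
    img_cluster = np.asarray(cell_clusters)[np.asarray(image_cells)]
    ids = sorted(set(img_cluster.tolist()))
    table = pd.DataFrame(
        {p: [int(np.sum((img_cluster == c) & (labs == p))) for c in ids] for p in classes},
        index=ids,
    )
    return cluster_quality_from_table(table, merges)


def render_map(stats: Sequence[CellStats], path: str, cell_px: int = 24) -> None:
    """Render the colored cell map (one rectangle per cell) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = max(s.row for s in stats) + 1
    cols = max(s.col for s in stats) + 1
    img = np.ones((rows, cols, 3))
    for s in stats:
        img[s.row, s.col] = s.rgb
    fig, ax = plt.subplots(figsize=(cols * cell_px / 72, rows * cell_px / 72))
    ax.imshow(img, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
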