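"""Shared fixtures: toy images and brute-force descriptor oracles.

The oracles here recompute every descriptor with naive per-pixel loops,
independent of the vectorized implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from zfpheno.descriptors import _EDGE_FILTERS, EdgeConfig, GrayImage


def bounds(n: int, k: int) -> list[int]:
    """Partition boundaries: equal floor-size parts, remainder to the last."""
    base = n // k
    edges = [i * base for i in range(k)] + [n]
    return edges


def oracle_edge_counts(img: GrayImage, cfg: EdgeConfig) -> np.ndarray:
    """Loop-based edge classification of every image-block; (16, 5) counts."""
    px = img.pixels.astype(float)
    h, w = px.shape
    counts = np.zeros((16, 5), dtype=int)
    hb, wb = bounds(h, 4), bounds(w, 4)
    for br in range(4):
        for bc in range(4):
            block = px[hb[br] : hb[br + 1], wb[bc] : wb[bc + 1]]
            ib_r = bounds(block.shape[0], cfg.grid)
            ib_c = bounds(block.shape[1], cfg.grid)
            for ir in range(cfg.grid):
                for ic in range(cfg.grid):
                    ib = block[ib_r[ir] : ib_r[ir + 1], ib_c[ic] : ib_c[ic + 1]]
                    mr = ib.shape[0] // 2
                    mc = ib.shape[1] // 2
                    a = [
                        ib[:mr, :mc].mean(),
                        ib[:mr, mc:].mean(),
                        ib[mr:, :mc].mean(),
                        ib[mr:, mc:].mean(),
                    ]
                    strengths = [abs(sum(f * v for f, v in zip(filt, a))) for filt in _EDGE_FILTERS]
                    m = max(strengths)
                    if m > cfg.threshold:
                        counts[4 * br + bc, strengths.index(m)] += 1
    return counts


def oracle_lehd_freq(img: GrayImage, cfg: EdgeConfig) -> np.ndarray:
    return oracle_edge_counts(img, cfg) / (cfg.grid * cfg.grid)


def oracle_block_means(img: GrayImage, k: int = 8) -> np.ndarray:
    """Per-pixel mean intensity of each k x k partition block."""
    px = img.pixels.astype(float)
    hb, wb = bounds(px.shape[0], k), bounds(px.shape[1], k)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            out[i, j] = px[hb[i] : hb[i + 1], wb[j] : wb[j + 1]].mean()
    return out


def oracle_dct2(m: np.ndarray) -> np.ndarray:
    """Direct double-sum orthonormal 2-D DCT-II of an 8x8 matrix."""
    n = 8
    out = np.zeros((n, n))
    for u in range(n):
        for v in range(n):
            cu = np.sqrt(1.0 / n) if u == 0 else np.sqrt(2.0 / n)
            cv = np.sqrt(1.0 / n) if v == 0 else np.sqrt(2.0 / n)
            s = 0.0
            for x in range(n):
                for y in range(n):
                    s += (
                        m[x, y]
                        * np.cos((2 * x + 1) * u * np.pi / (2 * n))
                        * np.cos((2 * y + 1) * v * np.pi / (2 * n))
                    )
            out[u, v] = cu * cv * s
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy16(rng) -> GrayImage:
    """Seeded random 16x16 image (use EdgeConfig(grid=2) with it)."""
    return GrayImage(rng.integers(0, 256, size=(16, 16), dtype=np.uint8))


@pytest.fixture
def toy_cfg() -> EdgeConfig:
    return EdgeConfig(grid=2, threshold=11.0)


@pytest.fixture
def img128(rng) -> GrayImage:
    """Seeded random 128x128 image usable with the default edge config."""
    return GrayImage(rng.integers(0, 256, size=(128, 128), dtype=np.uint8))


def constant_image(value: int, shape=(64, 64)) -> GrayImage:
    return GrayImage(np.full(shape, value, dtype=np.uint8))


@pytest.fixture
def blobs3(rng):
    """Three well-separated Gaussian blobs with phenotype labels."""
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    X = np.vstack([c + 0.3 * rng.standard_normal((30, 2)) for c in centers])
    y = np.array(["hatched"] * 30 + ["unhatched"] * 30 + ["dead"] * 30)
    return X, y
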