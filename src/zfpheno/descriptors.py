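"""Grayscale image descriptors for well-plate embryo images.

Six vectorial descriptors summarize one 8-bit grayscale well image:

==========  ====  =========================================================
block       dim   summary
==========  ====  =========================================================
LEHD         80   local edge histogram: 5 edge-type frequencies in each of
                  the 4x4 image blocks (MPEG-7 edge histogram convention)
GSEHD        80   global and semi-global edge histograms: the same 5 edge
                  frequencies aggregated over 16 groups of blocks
CHD          16   16-bin intensity histogram (bin width 16)
SCD           8   Haar-transform-encoded 8-bin intensity histogram
RCD          64   representative color: mean intensity of each 8x8 block
CLD          15   color layout: first 15 zig-zag coefficients of the 2-D
                  DCT of the 8x8 representative-color matrix
==========  ====  =========================================================

The full concatenation LEHD -> GSEHD -> CHD -> SCD -> RCD -> CLD has 263
components.  A 6-bit subset code over {LEHD, GSEHD, CHD, SCD, RCD, CLD}
("111111" = all six) selects which blocks are present.

Edge detection follows the MPEG-7 XM convention: each of the 16 image
blocks is tiled by an 8x8 grid of image-blocks; every image-block is split
2x2 into sub-block means (a0, a1; a2, a3) and filtered with the five
edge kernels; the strongest response is assigned iff it exceeds a
threshold.  The total number of assigned image-blocks is the edge count
used for image-quality triage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.fft import dctn

__all__ = [
    "BLOCK_ORDER",
    "BLOCK_DIMS",
    "GrayImage",
    "EdgeConfig",
    "AggregationLayout",
    "DescriptorBlock",
    "DescriptorVector",
    "subset_blocks",
    "blocks_to_subset",
    "subset_dimension",
    "compute_lehd",
    "compute_gsehd",
    "compute_cld",
    "compute_rcd",
    "compute_chd",
    "compute_scd_gray",
    "count_edges",
    "extract",
    "haar_forward",
    "haar_inverse",
]

#: Fixed block order used for subset codes and concatenation.
BLOCK_ORDER: tuple[str, ...] = ("LEHD", "GSEHD", "CHD", "SCD", "RCD", "CLD")

#: Component count of each descriptor block.
BLOCK_DIMS: dict[str, int] = {
    "LEHD": 80,
    "GSEHD": 80,
    "CHD": 16,
    "SCD": 8,
    "RCD": 64,
    "CLD": 15,
}

EDGE_TYPES: tuple[str, ...] = (
    "vertical",
    "horizontal",
    "fwd_diagonal",
    "bwd_diagonal",
    "undirectional",
)

_SQRT2 = np.sqrt(2.0)

# MPEG-7 edge filter coefficients applied to the 2x2 sub-block means
# (a0, a1, a2, a3) in row-major order.
_EDGE_FILTERS = np.array(
    [
        [1.0, -1.0, 1.0, -1.0],       # vertical
        [1.0, 1.0, -1.0, -1.0],       # horizontal
        [_SQRT2, 0.0, 0.0, -_SQRT2],  # 45 degree (forward diagonal)
        [0.0, _SQRT2, -_SQRT2, 0.0],  # 135 degree (backward diagonal)
        [2.0, -2.0, -2.0, 2.0],       # non-directional
    ]
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrayImage:
    """An 8-bit grayscale well image.

    Parameters
    ----------
    pixels
        2-D integer array with values in [0, 255]; row-major, origin at the
        top-left corner.
    source_depth
        Bit depth of the file the image came from (8 or 16).  16-bit
        sources are expected to have been mapped to 8 bits already.
    """

    pixels: np.ndarray
    source_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D single-channel image, got shape {px.shape}")
        if px.shape[0] < 16:
            raise ValueError(f"image height {px.shape[0]} < 16: block partitions degenerate")
        if px.shape[1] < 16:
            raise ValueError(f"image width {px.shape[1]} < 16: block partitions degenerate")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError(f"pixel dtype must be integer, got {px.dtype}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("pixel intensities must lie in [0, 255]")
        if self.source_depth not in (8, 16):
            raise ValueError(f"source_depth must be 8 or 16, got {self.source_depth}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class EdgeConfig:
    """Parameters of the MPEG-7 edge classification.

    ``grid`` is the per-image-block grid inside each of the 16 histogram
    blocks (``grid x grid`` image-blocks, 8 by default, i.e. 1024
    image-blocks per image); ``threshold`` is the minimum filter response
    for an image-block to count as an edge.
    """

    grid: int = 8
    threshold: float = 11.0

    def __post_init__(self) -> None:
        if self.grid < 1:
            raise ValueError("grid must be >= 1")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


def _default_groups() -> tuple[tuple[int, ...], ...]:
    rows = [tuple(range(4 * r, 4 * r + 4)) for r in range(4)]
    cols = [tuple(range(c, 16, 4)) for c in range(4)]
    quadrants = [
        (0, 1, 4, 5),      # top-left
        (2, 3, 6, 7),      # top-right
        (8, 9, 12, 13),    # bottom-left
        (10, 11, 14, 15),  # bottom-right
    ]
    center = (5, 6, 9, 10)
    top_half = tuple(range(8))
    bottom_half = tuple(range(8, 16))
    return (
        tuple(range(16)),  # global
        *rows,
        *cols,
        *quadrants,
        center,
        top_half,
        bottom_half,
    )


@dataclass(frozen=True)
class AggregationLayout:
    """Groups of 4x4-grid blocks whose edge histograms are aggregated.

    The default layout has 16 groups — the whole image, the 4 rows, the
    4 columns, the 4 corner quadrants, the centre 2x2, and the top and
    bottom halves — giving the 80-dimensional global/semi-global
    histogram.  Blocks are indexed 0–15 row-major over the 4x4 grid.
    """

    groups: tuple[tuple[int, ...], ...] = field(default_factory=_default_groups)

    def __post_init__(self) -> None:
        for g, members in enumerate(self.groups):
            if len(members) == 0:
                raise ValueError(f"aggregation group {g} is empty")
            bad = [b for b in members if not 0 <= b <= 15]
            if bad:
                raise ValueError(
                    f"aggregation group {g} contains indices outside the 4x4 "
                    f"block grid: {bad}"
                )


@dataclass(frozen=True)
class DescriptorBlock:
    """One named descriptor block and its ordered components."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in BLOCK_DIMS:
            raise ValueError(f"unknown descriptor block {self.name!r}")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def dimension(self) -> int:
        return len(self.values)

    def component_names(self) -> list[str]:
        return [f"{self.name}_{i}" for i in range(self.dimension)]


@dataclass(frozen=True)
class DescriptorVector:
    """Concatenation of descriptor blocks in the fixed block order."""

    blocks: tuple[DescriptorBlock, ...]
    subset_code: str

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([b.values for b in self.blocks])

    @property
    def component_names(self) -> list[str]:
        names: list[str] = []
        for b in self.blocks:
            names.extend(b.component_names())
        return names

    @property
    def dimension(self) -> int:
        return sum(b.dimension for b in self.blocks)


# ---------------------------------------------------------------------------
# subset codes
# ---------------------------------------------------------------------------


def _validate_code(code: str) -> str:
    if len(code) != 6 or any(c not in "01" for c in code):
        raise ValueError(f"subset code must be a 6-character binary string, got {code!r}")
    return code


def subset_blocks(code: str) -> tuple[str, ...]:
    """Block names selected by a 6-bit subset code (order LEHD..CLD)."""
    _validate_code(code)
    if code == "000000":
        raise ValueError('subset code "000000" selects no descriptors')
    return tuple(name for name, bit in zip(BLOCK_ORDER, code) if bit == "1")


def blocks_to_subset(names: Sequence[str]) -> str:
    """Inverse of :func:`subset_blocks`."""
    unknown = [n for n in names if n not in BLOCK_ORDER]
    if unknown:
        raise ValueError(f"unknown descriptor blocks: {unknown}")
    return "".join("1" if name in names else "0" for name in BLOCK_ORDER)


def subset_dimension(code: str) -> int:
    return sum(BLOCK_DIMS[name] for name in subset_blocks(code))


# ---------------------------------------------------------------------------
# partition helpers
# ---------------------------------------------------------------------------


def _bounds(n: int, k: int) -> np.ndarray:
    """Boundaries of ``k`` contiguous intervals covering [0, n).

    Intervals have equal length ``n // k``; the remainder (< k pixels) is
    absorbed by the last interval.
    """
    base = n // k
    if base < 1:
        raise ValueError(f"cannot split extent {n} into {k} parts")
    edges = np.arange(k + 1) * base
    edges[-1] = n
    return edges


def _integral(px: np.ndarray) -> np.ndarray:
    """Zero-padded 2-D cumulative sum for O(1) rectangle sums."""
    s = np.zeros((px.shape[0] + 1, px.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(px, axis=0, dtype=np.float64), axis=1, out=s[1:, 1:])
    return s


def _rect_means(s: np.ndarray, rb: np.ndarray, cb: np.ndarray) -> np.ndarray:
    """Mean intensity of every rectangle of a boundary grid.

    ``s`` is the integral image; ``rb``/``cb`` are sorted boundary arrays.
    Returns an array of shape (len(rb)-1, len(cb)-1).
    """
    r0, r1 = rb[:-1], rb[1:]
    c0, c1 = cb[:-1], cb[1:]
    total = (
        s[np.ix_(r1, c1)] - s[np.ix_(r0, c1)] - s[np.ix_(r1, c0)] + s[np.ix_(r0, c0)]
    )
    area = np.outer(r1 - r0, c1 - c0)
    return total / area


def _subblock_bounds(extent: int, grid: int) -> np.ndarray:
    """Boundaries of the 2*grid sub-block intervals along one block axis.

    The block extent is first split into ``grid`` image-blocks (remainder
    to the last) and each image-block is then split in two the same way.
    """
    ib = _bounds(extent, grid)
    out = [0]
    for lo, hi in zip(ib[:-1], ib[1:]):
        mid = lo + (hi - lo) // 2
        out.extend((int(mid), int(hi)))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# edge histograms
# ---------------------------------------------------------------------------


def _edge_counts(img: GrayImage, cfg: EdgeConfig) -> np.ndarray:
    """Raw per-block edge-type counts, shape (16, 5).

    Entry (b, t) is the number of image-blocks of 4x4-grid block ``b``
    (row-major) assigned to edge type ``t``.
    """
    px = img.pixels
    h, w = px.shape
    g = cfg.grid
    # each image-block needs a 2x2 sub-block split
    if h < 4 * g * 2:
        raise ValueError(f"image height {h} too small for a 4x{g}x2 partition")
    if w < 4 * g * 2:
        raise ValueError(f"image width {w} too small for a 4x{g}x2 partition")

    s = _integral(px)
    hb = _bounds(h, 4)
    wb = _bounds(w, 4)
    counts = np.zeros((16, 5), dtype=np.int64)
    for br in range(4):
        rb = _subblock_bounds(int(hb[br + 1] - hb[br]), g) + int(hb[br])
        for bc in range(4):
            cb = _subblock_bounds(int(wb[bc + 1] - wb[bc]), g) + int(wb[bc])
            m = _rect_means(s, rb, cb)
            a0 = m[0::2, 0::2]
            a1 = m[0::2, 1::2]
            a2 = m[1::2, 0::2]
            a3 = m[1::2, 1::2]
            sub = np.stack([a0, a1, a2, a3], axis=-1)  # (g, g, 4)
            strength = np.abs(sub @ _EDGE_FILTERS.T)   # (g, g, 5)
            best = np.argmax(strength, axis=-1)
            peak = np.max(strength, axis=-1)
            assigned = peak > cfg.threshold
            block = 4 * br + bc
            for t in range(5):
                counts[block, t] = int(np.sum(assigned & (best == t)))
    return counts


def _lehd_frequencies(img: GrayImage, cfg: EdgeConfig) -> np.ndarray:
    """Pre-quantization relative edge frequencies, shape (16, 5)."""
    counts = _edge_counts(img, cfg)
    return counts / float(cfg.grid * cfg.grid)


def quantize_frequency(f: np.ndarray) -> np.ndarray:
    """Map a relative frequency in [0, 1] to an integer bin in [0, 7]."""
    return np.minimum(np.floor(8.0 * np.asarray(f)), 7).astype(np.int64)


def compute_lehd(img: GrayImage, cfg: EdgeConfig | None = None) -> DescriptorBlock:
    """Local edge histogram: 16 blocks x 5 edge types, quantized to [0, 7].

    Components are ordered block-major (block 0..15 row-major; within a
    block: vertical, horizontal, forward-diagonal, backward-diagonal,
    undirectional).
    """
    cfg = cfg or EdgeConfig()
    freq = _lehd_frequencies(img, cfg)
    return DescriptorBlock("LEHD", quantize_frequency(freq).ravel())


def compute_gsehd(
    img: GrayImage,
    cfg: EdgeConfig | None = None,
    layout: AggregationLayout | None = None,
) -> DescriptorBlock:
    """Global and semi-global edge histogram over block aggregates.

    For every aggregation group the member blocks' pre-quantization edge
    frequencies are averaged per edge type and then quantized.  The
    default 16-group layout yields 80 components ordered group-major
    (global, rows top→bottom, columns left→right, corner quadrants
    TL/TR/BL/BR, centre 2x2, top half, bottom half).
    """
    cfg = cfg or EdgeConfig()
    layout = layout or AggregationLayout()
    freq = _lehd_frequencies(img, cfg)
    agg = np.stack([freq[list(members)].mean(axis=0) for members in layout.groups])
    return DescriptorBlock("GSEHD", quantize_frequency(agg).ravel())


def count_edges(img: GrayImage, cfg: EdgeConfig | None = None) -> int:
    """Total number of image-blocks classified as any edge type.

    This is the pre-histogram edge count used for quality triage (images
    with many edges are dominated by particle deposits or debris).
    """
    cfg = cfg or EdgeConfig()
    return int(_edge_counts(img, cfg).sum())


# ---------------------------------------------------------------------------
# color descriptors
# ---------------------------------------------------------------------------


def _representative_colors(img: GrayImage) -> np.ndarray:
    """8x8 matrix of per-block mean intensities."""
    s = _integral(img.pixels)
    rb = _bounds(img.height, 8)
    cb = _bounds(img.width, 8)
    return _rect_means(s, rb, cb)


def compute_rcd(img: GrayImage) -> DescriptorBlock:
    """Representative color: the 64 block means, row-major, in [0, 255]."""
    return DescriptorBlock("RCD", _representative_colors(img).ravel())


def _zigzag_indices(n: int = 15) -> list[tuple[int, int]]:
    """First ``n`` (row, col) positions of the 8x8 zig-zag scan."""
    order: list[tuple[int, int]] = []
    for d in range(15):
        cells = [(d - j, j) for j in range(d + 1) if 0 <= d - j < 8 and 0 <= j < 8]
        if d % 2 == 1:
            cells.reverse()  # odd anti-diagonals are walked downward
        order.extend(cells)
    return order[:n]


_ZIGZAG_15 = _zigzag_indices(15)


def compute_cld(img: GrayImage) -> DescriptorBlock:
    """Color layout: first 15 zig-zag DCT coefficients of the block means.

    The 8x8 representative-color matrix is transformed with the
    orthonormal 2-D DCT-II; coefficients are kept unquantized (Z-score
    normalization downstream handles scale).
    """
    coeff = dctn(_representative_colors(img), norm="ortho")
    return DescriptorBlock("CLD", np.array([coeff[r, c] for r, c in _ZIGZAG_15]))


def compute_chd(img: GrayImage) -> DescriptorBlock:
    """16-bin intensity histogram; bin i counts pixels in [16i, 16i+15]."""
    hist = np.bincount(img.pixels.ravel() >> 4, minlength=16)
    return DescriptorBlock("CHD", hist.astype(float))


def haar_forward(x: np.ndarray) -> np.ndarray:
    """Full averaging Haar transform of a power-of-two-length vector.

    Each level maps pairs to their average and half-difference; output is
    the overall average followed by the detail coefficients from coarsest
    to finest.  Exactly invertible by :func:`haar_inverse`.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n & (n - 1):
        raise ValueError(f"length must be a power of two, got {n}")
    details: list[np.ndarray] = []
    while len(x) > 1:
        details.append((x[0::2] - x[1::2]) / 2.0)
        x = (x[0::2] + x[1::2]) / 2.0
    return np.concatenate([x] + details[::-1])


def haar_inverse(coeff: np.ndarray) -> np.ndarray:
    """Inverse of :func:`haar_forward`."""
    coeff = np.asarray(coeff, dtype=float)
    n = len(coeff)
    if n & (n - 1):
        raise ValueError(f"length must be a power of two, got {n}")
    x = coeff[:1]
    pos = 1
    while pos < n:
        d = coeff[pos : 2 * pos]
        out = np.empty(2 * pos)
        out[0::2] = x + d
        out[1::2] = x - d
        x = out
        pos *= 2
    return x


def compute_scd_gray(img: GrayImage) -> DescriptorBlock:
    """Scalable color for grayscale: Haar-encoded 8-bin histogram.

    The intensity histogram (bin width 32) is normalized to relative
    frequencies and passed through the full 3-level Haar transform;
    the 8 coefficients are returned with the overall average first.
    """
    hist = np.bincount(img.pixels.ravel() >> 5, minlength=8).astype(float)
    rel = hist / hist.sum()
    return DescriptorBlock("SCD", haar_forward(rel))


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

_COMPUTE = {
    "LEHD": lambda img, cfg, layout: compute_lehd(img, cfg),
    "GSEHD": lambda img, cfg, layout: compute_gsehd(img, cfg, layout),
    "CHD": lambda img, cfg, layout: compute_chd(img),
    "SCD": lambda img, cfg, layout: compute_scd_gray(img),
    "RCD": lambda img, cfg, layout: compute_rcd(img),
    "CLD": lambda img, cfg, layout: compute_cld(img),
}


def extract(
    img: GrayImage,
    subset: str = "111111",
    cfg: EdgeConfig | None = None,
    layout: AggregationLayout | None = None,
) -> DescriptorVector:
    """Extract the descriptor blocks selected by ``subset``.

    Blocks are concatenated in the fixed order LEHD -> GSEHD -> CHD ->
    SCD -> RCD -> CLD; component names carry the block prefix and index
    (``LEHD_0`` ... ``CLD_14``).  The edge-frequency grid is computed once
    and shared between LEHD and GSEHD.
    """
    names = subset_blocks(subset)
    cfg = cfg or EdgeConfig()
    blocks: list[DescriptorBlock] = []
    freq: np.ndarray | None = None
    for name in names:
        if name in ("LEHD", "GSEHD"):
            if freq is None:
                freq = _lehd_frequencies(img, cfg)
            if name == "LEHD":
                blocks.append(DescriptorBlock("LEHD", quantize_frequency(freq).ravel()))
            else:
                lay = layout or AggregationLayout()
                agg = np.stack(
                    [freq[list(members)].mean(axis=0) for members in lay.groups]
                )
                blocks.append(DescriptorBlock("GSEHD", quantize_frequency(agg).ravel()))
        else:
            blocks.append(_COMPUTE[name](img, cfg, layout))
    return DescriptorVector(tuple(blocks), subset)
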