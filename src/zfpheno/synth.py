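"""Seeded synthetic well-plate images with known phenotype labels.

The generator emulates the statistical structure of bright-field
zebrafish-embryo well images at 72 h post exposure: a light background,
one organism per well, particle-deposit speckle noise, thin
chorion-fragment arcs, a mild illumination gradient and optical blur.
Three morphologies are rendered procedurally:

hatched
    a curved, elongated larva of random orientation and position,
    possibly clipped at the frame edge;
unhatched
    a bright circular chorion ring enclosing a curled dark embryo;
dead
    a dense dark opaque circular mass with an irregular boundary.

Everything is deterministic under a seed; the generator never looks at
other images.  Rendering is deliberately schematic — controllable
difficulty, not photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, polygon

from .classify import CLASSES
from .descriptors import GrayImage

__all__ = [
    "PhenotypeSpec",
    "NoiseSpec",
    "DEFAULT_SPECS",
    "DEFAULT_NOISE",
    "ZERO_NOISE",
    "STRESS_NOISE_MULTIPLIER",
    "generate_image",
    "generate_plate",
    "add_noise",
]

#: Nominal well-image shape (height, width) in pixels.
IMAGE_SHAPE: tuple[int, int] = (520, 696)

#: Background intensity of a clean well.
BACKGROUND = 200

#: Stress images use noise counts >= this multiple of the clean defaults.
STRESS_NOISE_MULTIPLIER = 4.0


@dataclass(frozen=True)
class PhenotypeSpec:
    """Geometry and intensity ranges of one phenotype morphology.

    ``size_range`` is the larva length for hatched and the outer radius
    for unhatched/dead, in pixels.  Intensity ranges are kept inside a
    single 16-wide histogram bin so clean images show clearly separated
    intensity modes.
    """

    label: str
    size_range: tuple[float, float]
    intensity_range: tuple[float, float]
    ring_intensity_range: tuple[float, float] = (226.0, 238.0)
    ring_width_range: tuple[float, float] = (5.0, 9.0)
    background: int = BACKGROUND

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"unknown phenotype label {self.label!r}")


# Zebrafish morphology at 72 h is stereotyped: chorion diameter and larva
# length vary by a few percent, and each tissue has a characteristic
# optical density.  Sizes therefore vary narrowly and every structure's
# intensity stays inside one 16-wide histogram bin (dead mass: bin 3,
# larva body: bin 4, curled embryo: bin 5, background: bin 12, chorion
# ring: bin 14).
DEFAULT_SPECS: dict[str, PhenotypeSpec] = {
    "hatched": PhenotypeSpec("hatched", size_range=(300.0, 340.0), intensity_range=(68.0, 78.0)),
    "unhatched": PhenotypeSpec("unhatched", size_range=(88.0, 98.0), intensity_range=(84.0, 94.0)),
    "dead": PhenotypeSpec("dead", size_range=(72.0, 82.0), intensity_range=(52.0, 60.0)),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Well-image noise model.

    ``particle_count`` dark speckles emulate nanoparticle deposits,
    ``fragment_count`` thin arcs emulate chorion fragments; a linear
    illumination gradient of the given amplitude and a Gaussian blur
    complete the model.  The all-zero spec leaves an image untouched.
    """

    particle_count: int = 40
    particle_intensity: tuple[float, float] = (40.0, 90.0)
    particle_radius: tuple[float, float] = (1.0, 3.0)
    fragment_count: int = 3
    fragment_intensity: tuple[float, float] = (120.0, 160.0)
    gradient_amplitude: float = 10.0
    blur_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.particle_count < 0 or self.fragment_count < 0:
            raise ValueError("noise counts must be non-negative")
        if self.gradient_amplitude < 0 or self.blur_sigma < 0:
            raise ValueError("gradient amplitude and blur sigma must be non-negative")

    @property
    def is_zero(self) -> bool:
        return (
            self.particle_count == 0
            and self.fragment_count == 0
            and self.gradient_amplitude == 0
            and self.blur_sigma == 0
        )

    def scale(self, factor: float) -> "NoiseSpec":
        """Multiply the noise *amounts* (counts, gradient) by ``factor``."""
        return replace(
            self,
            particle_count=int(round(self.particle_count * factor)),
            fragment_count=int(round(self.fragment_count * factor)),
            gradient_amplitude=self.gradient_amplitude * factor,
        )


DEFAULT_NOISE = NoiseSpec()
ZERO_NOISE = NoiseSpec(
    particle_count=0, fragment_count=0, gradient_amplitude=0.0, blur_sigma=0.0
)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _stamp_disk(canvas: np.ndarray, cy: float, cx: float, r: float, value: float) -> None:
    rr, cc = disk((cy, cx), max(r, 1.0), shape=canvas.shape)
    canvas[rr, cc] = value


def _render_hatched(canvas: np.ndarray, spec: PhenotypeSpec, rng: np.random.Generator) -> None:
    h, w = canvas.shape
    length = rng.uniform(*spec.size_range)
    body_val = rng.uniform(*spec.intensity_range)
    # centerline = circular arc; bend is the total turn angle
    bend = rng.uniform(0.4, 1.4)
    arc_r = length / bend
    theta0 = rng.uniform(0, 2 * np.pi)
    # allow placement near the border so the larva may be clipped
    cy = rng.uniform(0.15 * h, 0.85 * h)
    cx = rng.uniform(0.15 * w, 0.85 * w)
    head_r = rng.uniform(11.0, 16.0)
    tail_r = 4.0
    ts = np.linspace(0.0, 1.0, 140)
    ang = theta0 + bend * ts
    ys = cy + arc_r * (np.sin(ang) - np.sin(theta0))
    xs = cx + arc_r * (np.cos(ang) - np.cos(theta0))
    radii = head_r * (1 - ts) + tail_r * ts
    for y, x, r in zip(ys, xs, radii):
        _stamp_disk(canvas, y, x, r, body_val)
    # enlarged head/yolk blob; same optical density as the body so the
    # larva contributes a single intensity mode
    _stamp_disk(canvas, ys[0], xs[0], head_r * 1.2, body_val)


def _render_unhatched(canvas: np.ndarray, spec: PhenotypeSpec, rng: np.random.Generator) -> None:
    h, w = canvas.shape
    R = rng.uniform(*spec.size_range)
    if 2 * R > min(h, w) - 20:
        raise ValueError(f"chorion radius {R:.0f} px does not fit the {h}x{w} frame")
    ring_w = rng.uniform(*spec.ring_width_range)
    ring_val = rng.uniform(*spec.ring_intensity_range)
    embryo_val = rng.uniform(*spec.intensity_range)
    cy = rng.uniform(R + 10, h - R - 10)
    cx = rng.uniform(R + 10, w - R - 10)
    # bright chorion ring (annulus); interior stays at background
    rr, cc = disk((cy, cx), R, shape=canvas.shape)
    outside = (rr - cy) ** 2 + (cc - cx) ** 2 >= (R - ring_w) ** 2
    canvas[rr[outside], cc[outside]] = ring_val
    # curled embryo: thick arc inside the chorion
    phi0 = rng.uniform(0, 2 * np.pi)
    span = rng.uniform(3.6, 4.6)
    orbit = 0.45 * R
    body_r = 0.26 * R
    for phi in np.linspace(phi0, phi0 + span, 80):
        _stamp_disk(canvas, cy + orbit * np.sin(phi), cx + orbit * np.cos(phi), body_r, embryo_val)


def _render_dead(canvas: np.ndarray, spec: PhenotypeSpec, rng: np.random.Generator) -> None:
    h, w = canvas.shape
    R = rng.uniform(*spec.size_range)
    if 2 * R > min(h, w) - 20:
        raise ValueError(f"mass radius {R:.0f} px does not fit the {h}x{w} frame")
    val = rng.uniform(*spec.intensity_range)
    margin = 1.3 * R + 10
    cy = rng.uniform(margin, h - margin)
    cx = rng.uniform(margin, w - margin)
    theta = np.linspace(0, 2 * np.pi, 240, endpoint=False)
    wobble = np.zeros_like(theta)
    for harmonic in (2, 3, 5):
        wobble += rng.uniform(0.02, 0.06) * np.cos(harmonic * theta + rng.uniform(0, 2 * np.pi))
    radius = R * (1.0 + wobble)
    rr, cc = polygon(cy + radius * np.sin(theta), cx + radius * np.cos(theta), shape=canvas.shape)
    canvas[rr, cc] = val


_RENDERERS = {
    "hatched": _render_hatched,
    "unhatched": _render_unhatched,
    "dead": _render_dead,
}


def _apply_noise(canvas: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = canvas.shape
    out = canvas.astype(float)
    if noise.gradient_amplitude > 0:
        psi = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        proj = (xx * np.cos(psi) + yy * np.sin(psi)) / np.hypot(h, w)
        out += noise.gradient_amplitude * 2.0 * (proj - proj.mean())
    # speckles are drawn one at a time so a lower particle count produces
    # a prefix of the same deposit sequence under the same seed
    for _ in range(noise.particle_count):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        r = rng.uniform(*noise.particle_radius)
        val = rng.uniform(*noise.particle_intensity)
        _stamp_disk(out, cy, cx, r, val)
    for _ in range(noise.fragment_count):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        arc_r = rng.uniform(40.0, 130.0)
        phi0 = rng.uniform(0, 2 * np.pi)
        span = rng.uniform(0.5, 2.0)
        val = rng.uniform(*noise.fragment_intensity)
        for phi in np.linspace(phi0, phi0 + span, int(arc_r * span)):
            _stamp_disk(out, cy + arc_r * np.sin(phi), cx + arc_r * np.cos(phi), 1.2, val)
    if noise.blur_sigma > 0:
        out = gaussian_filter(out, noise.blur_sigma)
    return out


def _finish(canvas: np.ndarray, source_depth: int = 8) -> GrayImage:
    return GrayImage(np.clip(np.rint(canvas), 0, 255).astype(np.uint8), source_depth)


def generate_image(
    spec: PhenotypeSpec | str,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    shape: tuple[int, int] = IMAGE_SHAPE,
) -> tuple[GrayImage, str]:
    """Render one labeled well image; identical seed, identical bytes."""
    if isinstance(spec, str):
        spec = DEFAULT_SPECS[spec]
    noise = DEFAULT_NOISE if noise is None else noise
    rng = np.random.default_rng(seed)
    canvas = np.full(shape, float(spec.background))
    _RENDERERS[spec.label](canvas, spec, rng)
    if not noise.is_zero:
        canvas = _apply_noise(canvas, noise, rng)
    return _finish(canvas), spec.label


def add_noise(img: GrayImage, noise: NoiseSpec, seed: int = 0) -> GrayImage:
    """Apply the noise model to an existing image (zero spec: identity)."""
    if noise.is_zero:
        return GrayImage(img.pixels.copy(), img.source_depth)
    rng = np.random.default_rng(seed)
    return _finish(_apply_noise(img.pixels.astype(float), noise, rng), img.source_depth)


# ---------------------------------------------------------------------------
# plate generation
# ---------------------------------------------------------------------------

_WELLS = [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]


def generate_plate(
    n_per_class: int,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    n_stress_per_class: int = 0,
    stress_multiplier: float = STRESS_NOISE_MULTIPLIER,
    specs: dict[str, PhenotypeSpec] | None = None,
    shape: tuple[int, int] = IMAGE_SHAPE,
) -> tuple[pd.DataFrame, dict[str, GrayImage]]:
    """Generate a balanced labeled plate (plus an optional stress partition).

    Wells are filled A1..H12 across as many 96-well plates as needed.
    The stress partition reuses the same morphologies with noise amounts
    multiplied by ``stress_multiplier``.  Returns the manifest (image_id,
    path, plate_id, well_id, label, partition) and the images keyed by id.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    noise = DEFAULT_NOISE if noise is None else noise
    specs = specs or DEFAULT_SPECS
    labels = [CLASSES[i % 3] for i in range(3 * n_per_class)]
    partitions = ["train"] * len(labels)
    if n_stress_per_class:
        labels += [CLASSES[i % 3] for i in range(3 * n_stress_per_class)]
        partitions += ["stress"] * (3 * n_stress_per_class)
    seeds = np.random.SeedSequence(seed).generate_state(len(labels)) & 0x7FFFFFFF
    stress_noise = noise.scale(stress_multiplier)
    rows = []
    images: dict[str, GrayImage] = {}
    for i, (label, part) in enumerate(zip(labels, partitions)):
        image_id = f"img{i:04d}"
        img, _ = generate_image(
            specs[label],
            stress_noise if part == "stress" else noise,
            seed=int(seeds[i]),
            shape=shape,
        )
        images[image_id] = img
        rows.append(
            {
                "image_id": image_id,
                "path": "",
                "plate_id": f"P{i // 96 + 1:02d}",
                "well_id": _WELLS[i % 96],
                "label": label,
                "partition": part,
            }
        )
    return pd.DataFrame(rows), images
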