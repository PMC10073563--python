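"""Seeded synthetic brain phantoms with ground-truth tumor masks.

Each phantom is a 256x256 8-bit image: a dark background, an elliptical
"brain" with smoothed Gaussian texture, a smooth multiplicative bias field
(the intensity-inhomogeneity artifact the retinex enhancement exists to
remove, modeled as a random-direction planar ramp — MR bias fields are
conventionally near-polynomial in smoothness), per-pixel Gaussian noise,
and 0-3 bright elliptical "tumors" whose texture differs from brain tissue
in both mean intensity and correlation length, so that texture descriptors
— not just raw intensity — carry class signal.

A corpus mimics a small clinical atlas: a healthy:pathological imbalance of
roughly 1:4 (as in a 45/190 collection), pathological images carrying one to
three tumors.  Identical spec + seed reproduces a phantom bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "generate_phantom", "generate_corpus"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise of one phantom.

    ``tumor_contrast`` is the mean intensity added inside tumors over the
    brain mean; ``illumination_amp`` is the relative amplitude of the
    low-frequency multiplicative field; ``texture_scale`` is the Gaussian
    smoothing length (pixels) of the within-brain texture.
    """

    size: tuple[int, int] = (256, 256)
    n_tumors: int = 1
    tumor_axes: tuple[float, float] = (10.0, 30.0)
    tumor_contrast: float = 80.0
    brain_mean: float = 110.0
    background: float = 20.0
    noise_sigma: float = 8.0
    illumination_amp: float = 0.2
    texture_scale: float = 3.0
    texture_amp: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_tumors <= 3:
            raise ValueError("n_tumors must be in 0..3")
        lo, hi = self.tumor_axes
        if lo < 2 or hi < lo:
            raise ValueError("tumor_axes must satisfy 2 <= lo <= hi")


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
) -> np.ndarray:
    rows, cols = np.mgrid[: shape[0], : shape[1]].astype(np.float64)
    dy, dx = rows - center[0], cols - center[1]
    c, s = np.cos(angle), np.sin(angle)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _smooth_noise(rng: np.random.Generator, shape, scale: float, amp: float) -> np.ndarray:
    """Zero-mean Gaussian field smoothed to correlation length ``scale`` and
    rescaled to standard deviation ``amp``."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), scale)
    sd = field.std()
    return field * (amp / sd) if sd > 0 else field


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, int]:
    """Generate one phantom; returns ``(image, tumor_mask, label)`` with
    label +1 if any tumor is present, else -1.

    Raises
    ------
    RuntimeError
        If a tumor cannot be placed inside the brain without overlap after
        100 attempts.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    cy, cx = h / 2.0, w / 2.0

    # brain ellipse: fills most of the frame, mild random eccentricity
    brain_axes = (
        0.36 * w * rng.uniform(0.92, 1.05),
        0.44 * h * rng.uniform(0.92, 1.05),
    )
    brain_angle = rng.uniform(-0.15, 0.15)
    brain = _ellipse_mask((h, w), (cy, cx), brain_axes, brain_angle)

    image = np.full((h, w), spec.background, dtype=np.float64)
    texture = _smooth_noise(rng, (h, w), spec.texture_scale, spec.texture_amp)
    image[brain] = spec.brain_mean + texture[brain]

    # tumors: bright ellipses with shorter-range texture, wholly inside brain
    tumor_mask = np.zeros((h, w), dtype=bool)
    eroded_brain = ndimage.binary_erosion(brain, iterations=5)
    tumor_texture = _smooth_noise(rng, (h, w), spec.texture_scale / 2.0, spec.texture_amp)
    for _ in range(spec.n_tumors):
        for _attempt in range(100):
            axes = tuple(rng.uniform(*spec.tumor_axes, size=2))
            angle = rng.uniform(0, np.pi)
            ty = rng.uniform(cy - brain_axes[1], cy + brain_axes[1])
            tx = rng.uniform(cx - brain_axes[0], cx + brain_axes[0])
            cand = _ellipse_mask((h, w), (ty, tx), axes, angle)
            inside = not (cand & ~eroded_brain).any()
            # keep tumors separated so component counts match n_tumors
            grown = ndimage.binary_dilation(cand, iterations=3)
            if inside and not (grown & tumor_mask).any():
                tumor_mask |= cand
                image[cand] = (
                    spec.brain_mean + spec.tumor_contrast + tumor_texture[cand]
                )
                break
        else:
            raise RuntimeError("could not place a tumor inside the brain")

    # multiplicative bias: planar ramp of relative amplitude illumination_amp
    # across the half-frame, in a random direction
    phi = rng.uniform(0.0, 2.0 * np.pi)
    rows, cols = np.mgrid[:h, :w].astype(np.float64)
    ramp = ((cols - cx) * np.cos(phi) + (rows - cy) * np.sin(phi)) / (max(h, w) / 2.0)
    image *= 1.0 + spec.illumination_amp * ramp
    image += rng.normal(0.0, spec.noise_sigma, size=(h, w))
    image = np.clip(np.floor(image + 0.5), 0, 255).astype(np.uint8)

    label = 1 if spec.n_tumors > 0 else -1
    return image, tumor_mask.astype(np.uint8), label


def generate_corpus(
    n_healthy: int = 45,
    n_pathological: int = 190,
    spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray, int]]:
    """Deterministic corpus of phantoms: ``n_healthy`` with no tumors, then
    ``n_pathological`` with 1-3 tumors each (count drawn per image).

    Per-image seeds are derived from ``seed`` so the corpus is reproducible
    and individual images are independent.
    """
    if min(n_healthy, n_pathological) < 0:
        raise ValueError("counts must be nonnegative")
    master = np.random.default_rng(seed)
    corpus = []
    for i in range(n_healthy + n_pathological):
        image_seed = int(master.integers(0, 2**31 - 1))
        n_tumors = 0 if i < n_healthy else int(master.integers(1, 4))
        corpus.append(
            generate_phantom(replace(spec, n_tumors=n_tumors, seed=image_seed))
        )
    return corpus
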