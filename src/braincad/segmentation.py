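"""Maximum-entropy (Kapur) thresholding and morphological cleanup.

The Kapur criterion picks the grey level ``t`` that maximizes the sum of the
Shannon entropies of the foreground (levels ``<= t``) and background (levels
``> t``) intensity distributions, each renormalized to a probability
distribution over its own side.  The binarized image is then opened with a
disk structuring element and small connected components are removed, which
suppresses the speckle that entropy thresholding leaves behind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .image_io import IntensityHistogram, _validate_integer_image, to_histogram

__all__ = [
    "ThresholdResult",
    "MorphParams",
    "kapur_entropy",
    "max_entropy_threshold",
    "apply_threshold",
    "morphological_cleanup",
    "segment",
]


@dataclass(frozen=True)
class ThresholdResult:
    """Diagnostics of a maximum-entropy threshold search.

    Attributes
    ----------
    t_opt
        Selected grey level: the smallest maximizer of the total entropy.
    entropy_curve
        ``entropy_curve[t]`` is the total entropy ``H(t)`` in nats, ``nan``
        where one side of the split is empty.
    h_max
        The maximum total entropy, ``H(t_opt)``.
    t_norm
        ``h_max / 255`` — the entropy normalized by the maximum intensity.
        Reported for completeness; it is an entropy value, not a grey level,
        and plays no role in masking.
    """

    t_opt: int
    entropy_curve: np.ndarray = field(repr=False)
    h_max: float
    t_norm: float


@dataclass(frozen=True)
class MorphParams:
    """Disk radius of the morphological opening and the minimum surviving
    connected-component area (8-connectivity), in pixels.

    The radius must stay below the semi-minor axis of the smallest lesion
    that should survive (opening deletes anything that cannot contain the
    disk); with lesions down to ~10 px half-width, radius 8 is the safe end
    of the supported 8-12 range.
    """

    disk_radius: int = 8
    min_object_area: int = 50

    def __post_init__(self) -> None:
        if not 8 <= self.disk_radius <= 12:
            raise ValueError("disk_radius must lie in [8, 12]")
        if self.min_object_area < 0:
            raise ValueError("min_object_area must be nonnegative")


def kapur_entropy(hist: IntensityHistogram, t: int) -> float:
    """Total entropy ``H(t) = H1(t) + H2(t)`` in nats for split level ``t``.

    ``H1`` is the Shannon entropy of the foreground distribution
    ``p(k)/P1(t)`` over ``k <= t`` and ``H2`` that of the background over
    ``k > t``.  Levels with ``p(k) = 0`` contribute nothing.

    Raises
    ------
    ValueError
        If either side of the split has zero total probability.
    """
    p = hist.probabilities
    p1 = float(p[: t + 1].sum())
    p2 = float(p[t + 1 :].sum())
    if p1 <= 0.0 or p2 <= 0.0:
        raise ValueError(f"split at t={t} leaves an empty side (P1={p1}, P2={p2})")

    def _side_entropy(side: np.ndarray, total: float) -> float:
        q = side[side > 0] / total
        return float(-(q * np.log(q)).sum())

    return _side_entropy(p[: t + 1], p1) + _side_entropy(p[t + 1 :], p2)


def max_entropy_threshold(hist: IntensityHistogram) -> ThresholdResult:
    """Search all valid split levels and return the entropy-maximizing one.

    Valid levels are those with nonzero probability mass on both sides; ties
    are broken toward the smallest level so the result is deterministic.

    Raises
    ------
    ValueError
        If the histogram has fewer than two occupied levels.
    """
    p = hist.probabilities
    nonzero = np.flatnonzero(hist.counts)
    if nonzero.size < 2:
        raise ValueError("histogram has a single occupied level; nothing to threshold")

    curve = np.full(256, np.nan)
    cum = np.cumsum(p)
    for t in range(nonzero[0], nonzero[-1]):
        if cum[t] <= 0.0 or cum[t] >= 1.0:
            continue
        curve[t] = kapur_entropy(hist, t)
    valid = np.flatnonzero(~np.isnan(curve))
    h_max = float(np.nanmax(curve))
    # smallest level attaining the maximum; ties (e.g. runs of empty levels)
    # are compared with a small tolerance against summation-order noise
    t_opt = int(valid[curve[valid] >= h_max - 1e-12][0])
    return ThresholdResult(
        t_opt=t_opt, entropy_curve=curve, h_max=h_max, t_norm=h_max / 255.0
    )


def apply_threshold(image: np.ndarray, t: int) -> np.ndarray:
    """Binarize: foreground (1) where the pixel intensity is strictly
    greater than ``t`` (tumors are bright on T2 after enhancement)."""
    arr = _validate_integer_image(image)
    return (arr > t).astype(np.uint8)


def morphological_cleanup(mask: np.ndarray, params: MorphParams = MorphParams()) -> np.ndarray:
    """Binary opening with a disk, then removal of small components.

    Opening (erosion followed by dilation) deletes structures that cannot
    contain the disk; the area filter then drops surviving 8-connected
    components smaller than ``min_object_area`` pixels.  The result is always
    a subset of the input foreground, and the operation is idempotent.
    """
    arr = np.asarray(mask).astype(bool)
    opened = ndimage.binary_opening(arr, structure=disk(params.disk_radius))
    labels, n = ndimage.label(opened, structure=np.ones((3, 3), dtype=int))
    if n:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < params.min_object_area)
        opened &= ~np.isin(labels, small[small > 0])
    return opened.astype(np.uint8)


def segment(
    image: np.ndarray, morph: MorphParams = MorphParams()
) -> tuple[np.ndarray, ThresholdResult]:
    """Full segmentation: histogram → maximum-entropy threshold → binarize →
    morphological cleanup.  Returns the final mask and threshold diagnostics."""
    hist = to_histogram(image)
    result = max_entropy_threshold(hist)
    raw_mask = apply_threshold(image, result.t_opt)
    return morphological_cleanup(raw_mask, morph), result


def count_components(mask: np.ndarray) -> int:
    """Number of 8-connected foreground components."""
    _, n = ndimage.label(np.asarray(mask) > 0, structure=np.ones((3, 3), dtype=int))
    return int(n)
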