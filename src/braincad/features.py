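"""Non-local binary pattern (NLBP) texture descriptor.

Classic LBP thresholds a circular neighborhood against its *own* central
pixel, so every code is a purely local statement.  NLBP replaces the central
reference with a handful of global *anchor* intensities: the intensities of
all central pixels are sorted, split into ``M`` equal intervals, and each
interval's mean becomes one anchor.  Every pixel's circular neighborhood is
then thresholded against every anchor, tying local patterns to the global
intensity distribution and capturing long-range structure that plain LBP
misses.

The circular bit pattern is summarized by the extended rotation-invariant
uniform (eriu2) encoding: patterns with at most two 0/1 transitions around
the circle map to their bit-sum (codes ``0..K``), patterns with exactly 4,
6, 8 or 10 transitions get one dedicated code each (``K+1..K+4``), and
everything else falls into a catch-all (``K+5``) — ``K+6`` codes per anchor
in total.  The descriptor is the concatenation over anchors of the per-anchor
code histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NLBPParams",
    "AnchorSet",
    "NLBPFeature",
    "compute_anchors",
    "sample_neighborhood",
    "eriu2_code",
    "nlbp_features",
    "feature_names",
]


@dataclass(frozen=True)
class NLBPParams:
    """Sampling radius ``r``, circle sample count ``K`` and anchor count ``M``.

    With the defaults (r=5, K=24, M=4) the descriptor has 4·30 = 120 bins.
    """

    radius: int = 5
    neighbors: int = 24
    anchors: int = 4

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.neighbors < 4:
            raise ValueError("neighbors must be >= 4")
        if self.anchors < 1:
            raise ValueError("anchors must be >= 1")

    @property
    def n_codes(self) -> int:
        return self.neighbors + 6

    @property
    def n_features(self) -> int:
        return self.anchors * self.n_codes


@dataclass(frozen=True)
class AnchorSet:
    """Sorted central-pixel intensities and the ``M`` interval-mean anchors."""

    sorted_centrals: np.ndarray
    anchor_intensities: np.ndarray


@dataclass(frozen=True)
class NLBPFeature:
    """Concatenated per-anchor eriu2 code histograms.

    ``histogram`` holds raw counts (each anchor block sums to the number of
    central pixels); ``normalized`` divides each block by its total.
    """

    histogram: np.ndarray
    normalized: np.ndarray
    params: NLBPParams


def _central_index(shape: tuple[int, int], r: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/col index grids of all pixels at distance >= r from every border."""
    h, w = shape
    if h < 2 * r + 1 or w < 2 * r + 1:
        raise ValueError(f"image {shape} too small for radius {r}")
    rows = np.arange(r, h - r)
    cols = np.arange(r, w - r)
    return np.meshgrid(rows, cols, indexing="ij")


def compute_anchors(
    image: np.ndarray, mask: np.ndarray | None, M: int, radius: int = 5
) -> AnchorSet:
    """Sort the central-pixel intensities and average ``M`` equal intervals.

    Central pixels are those at distance at least ``radius`` from every
    border, intersected with ``mask`` when one is given.  The sorted sequence
    is cut into ``M`` chunks of ``floor(N/M)`` entries; anchor ``m`` is the
    mean of chunk ``m``.  Up to ``M-1`` trailing entries are discarded by the
    floor.
    """
    arr = np.asarray(image, dtype=np.float64)
    rr, cc = _central_index(arr.shape, radius)
    values = arr[rr, cc]
    if mask is not None:
        sel = np.asarray(mask)[rr, cc] > 0
        values = values[sel]
    values = np.sort(values.ravel())
    N = values.size
    if N < M:
        raise ValueError(f"only {N} central pixels for {M} anchors")
    chunk = N // M
    anchors = values[: M * chunk].reshape(M, chunk).mean(axis=1)
    return AnchorSet(sorted_centrals=values, anchor_intensities=anchors)


def _circle_offsets(r: int, K: int) -> np.ndarray:
    """(K, 2) array of (row, col) offsets: k=0 along +column, counter-clockwise."""
    k = np.arange(K)
    theta = 2.0 * np.pi * k / K
    # row axis points down, so counter-clockwise on screen is -sin on rows
    return np.stack([-r * np.sin(theta), r * np.cos(theta)], axis=1)


def sample_neighborhood(
    image: np.ndarray, row: int, col: int, r: int, K: int
) -> np.ndarray:
    """Bilinearly sample ``K`` points on the radius-``r`` circle at (row, col)."""
    arr = np.asarray(image, dtype=np.float64)
    h, w = arr.shape
    if not (r <= row < h - r and r <= col < w - r):
        raise ValueError(f"center ({row}, {col}) closer than r={r} to a border")
    out = np.empty(K)
    for k, (dy, dx) in enumerate(_circle_offsets(r, K)):
        y, x = row + dy, col + dx
        y0, x0 = int(np.floor(y)), int(np.floor(x))
        fy, fx = y - y0, x - x0
        y1, x1 = (y0 + 1 if fy > 0 else y0), (x0 + 1 if fx > 0 else x0)
        out[k] = (
            arr[y0, x0] * (1 - fy) * (1 - fx)
            + arr[y0, x1] * (1 - fy) * fx
            + arr[y1, x0] * fy * (1 - fx)
            + arr[y1, x1] * fy * fx
        )
    return out


def eriu2_code(bits: np.ndarray, K: int) -> int:
    """eriu2 code of one circular bit pattern (see module docstring)."""
    b = np.asarray(bits).astype(np.int64).ravel()
    if b.size != K:
        raise ValueError(f"expected {K} bits, got {b.size}")
    U = int(abs(b[-1] - b[0]) + np.abs(np.diff(b)).sum())
    return _code_from_U(int(b.sum()), U, K)


def _code_from_U(bit_sum: int, U: int, K: int) -> int:
    if U <= 2:
        return bit_sum
    if U == 4:
        return K + 1
    if U == 6:
        return K + 2
    if U == 8:
        return K + 3
    if U == 10:
        return K + 4
    return K + 5


def _sample_all(image: np.ndarray, r: int, K: int) -> np.ndarray:
    """Bilinear circle samples for every central pixel at once.

    Returns shape ``(n_rows, n_cols, K)`` over the interior grid.  Because
    each circle point is a *constant* fractional offset from its center, one
    offset corresponds to one bilinearly weighted combination of four shifted
    views of the image, which vectorizes the sampling.
    """
    arr = np.asarray(image, dtype=np.float64)
    h, w = arr.shape
    nr, nc = h - 2 * r, w - 2 * r
    out = np.empty((nr, nc, K))
    for k, (dy, dx) in enumerate(_circle_offsets(r, K)):
        y0, x0 = int(np.floor(dy)), int(np.floor(dx))
        fy, fx = dy - y0, dx - x0
        top, left = r + y0, r + x0
        # at lattice-aligned offsets the +1 neighbor has zero weight; reuse
        # the base slice so the view never leaves the array
        oy1, ox1 = (1 if fy > 0 else 0), (1 if fx > 0 else 0)

        def view(oy: int, ox: int) -> np.ndarray:
            return arr[top + oy : top + oy + nr, left + ox : left + ox + nc]

        out[:, :, k] = (
            view(0, 0) * (1 - fy) * (1 - fx)
            + view(0, ox1) * (1 - fy) * fx
            + view(oy1, 0) * fy * (1 - fx)
            + view(oy1, ox1) * fy * fx
        )
    return out


def nlbp_features(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    params: NLBPParams = NLBPParams(),
) -> NLBPFeature:
    """NLBP descriptor of an image (optionally restricted by a segmentation).

    When a mask is given, intensities outside it are zeroed before anchoring
    and coding — the descriptor then characterizes the segmented region
    against a silenced background, and an empty mask legitimately yields the
    all-background signature.  Central pixels are always the full interior
    grid, so the feature length is independent of the mask.
    """
    r, K, M = params.radius, params.neighbors, params.anchors
    arr = np.asarray(image, dtype=np.float64)
    if mask is not None:
        if np.asarray(mask).shape != arr.shape:
            raise ValueError("mask shape must match image shape")
        arr = np.where(np.asarray(mask) > 0, arr, 0.0)

    anchors = compute_anchors(arr, None, M, radius=r).anchor_intensities
    samples = _sample_all(arr, r, K)  # (nr, nc, K)
    n_central = samples.shape[0] * samples.shape[1]

    counts = np.empty((M, K + 6), dtype=np.int64)
    for m, anchor in enumerate(anchors):
        # f(d) = 1 iff d >= 0, with a tolerance absorbing bilinear round-off
        # (the four interpolation weights sum to 1 only to ~1e-16)
        bits = (samples >= anchor - 1e-9).astype(np.int64)
        bit_sum = bits.sum(axis=2)
        trans = np.abs(np.diff(bits, axis=2)).sum(axis=2) + np.abs(
            bits[:, :, -1] - bits[:, :, 0]
        )
        codes = np.where(
            trans <= 2,
            bit_sum,
            np.where(
                trans == 4,
                K + 1,
                np.where(
                    trans == 6,
                    K + 2,
                    np.where(trans == 8, K + 3, np.where(trans == 10, K + 4, K + 5)),
                ),
            ),
        )
        counts[m] = np.bincount(codes.ravel(), minlength=K + 6)

    normalized = counts / n_central
    return NLBPFeature(
        histogram=counts.ravel().copy(),
        normalized=normalized.ravel(),
        params=params,
    )


def feature_names(params: NLBPParams = NLBPParams()) -> list[str]:
    """Column names ``a<m>_c<code>`` matching the concatenated histogram."""
    return [
        f"a{m}_c{c}" for m in range(params.anchors) for c in range(params.n_codes)
    ]
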