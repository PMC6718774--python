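"""Cell-body (ROI) detection on a reference frame.

The detector is a classic blob pipeline: linear contrast stretch to
``[0, 1]``, Gaussian denoise (``sigma_n``), difference-of-Gaussians
band-pass (``sigma_a``, ``sigma_b``), a strict brightness threshold, and
connected-component clustering with a minimum-size filter.  Cell bodies
appear as bright blobs against a darker background, and the DOG response
is maximal for structures near the pass band of the two Gaussian scales.

All convolutions are separable (1-D kernel along rows, then columns) with
reflect border handling; kernels are truncated at ``ceil(3*sigma)`` and
renormalized to unit sum so constant regions are preserved exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "GaussianKernel",
    "SegmentationParams",
    "ROI",
    "ROISet",
    "stretch_contrast",
    "gaussian_kernel_1d",
    "gaussian_blur",
    "dog_filter",
    "threshold_binary",
    "label_components",
    "detect_rois",
    "merge_manual_rois",
]


@dataclass(frozen=True)
class GaussianKernel:
    """Separable 1-D Gaussian kernel: weights symmetric, summing to 1."""

    sigma: float
    radius: int
    weights: np.ndarray

    @classmethod
    def from_sigma(cls, sigma: float) -> "GaussianKernel":
        if sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {sigma}")
        # 3-sigma truncation keeps >99.7% of the mass; renormalize the rest.
        radius = int(np.ceil(3.0 * sigma))
        x = np.arange(-radius, radius + 1, dtype=float)
        w = np.exp(-(x**2) / (2.0 * sigma**2))
        w /= w.sum()
        return cls(sigma=float(sigma), radius=radius, weights=w)


@dataclass(frozen=True)
class SegmentationParams:
    """User parameters of the blob detector.

    sigma_n : denoising blur scale (px); sigma_a/sigma_b : DOG scales (px);
    th : brightness threshold applied to the raw DOG response; connectivity :
    4 or 8 pixel adjacency; min_size_px : smallest cluster kept.
    """

    sigma_n: float = 1.0
    sigma_a: float = 2.0
    sigma_b: float = 6.0
    th: float = 0.1
    connectivity: int = 8
    min_size_px: int = 4

    def __post_init__(self) -> None:
        if self.sigma_n <= 0 or self.sigma_a <= 0 or self.sigma_b <= 0:
            raise ValueError("all sigmas must be > 0")
        if self.sigma_a == self.sigma_b:
            raise ValueError("sigma_a == sigma_b gives a degenerate (zero) detector")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_size_px < 1:
            raise ValueError("min_size_px must be >= 1")


@dataclass(frozen=True)
class ROI:
    """One detected cell body: a connected cluster of pixels.

    ``pixels`` is an ``(N, 2)`` integer array of (row, col) coordinates,
    sorted lexicographically; the centroid is their arithmetic mean.
    """

    id: int
    pixels: np.ndarray
    centroid: tuple[float, float]
    area_px: int

    @classmethod
    def from_pixels(cls, roi_id: int, pixels: np.ndarray | Sequence[tuple[int, int]]) -> "ROI":
        pixels = np.asarray(pixels, dtype=np.int64).reshape(-1, 2)
        if len(pixels) == 0:
            raise ValueError("ROI must contain at least one pixel")
        order = np.lexsort((pixels[:, 1], pixels[:, 0]))
        pixels = pixels[order]
        centroid = (float(pixels[:, 0].mean()), float(pixels[:, 1].mean()))
        return cls(id=int(roi_id), pixels=pixels, centroid=centroid, area_px=len(pixels))

    @property
    def pixel_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(map(tuple, self.pixels.tolist()))


class ROISet:
    """An ordered collection of ROIs over one frame geometry.

    Pixel sets are pairwise disjoint; ids are unique but need not be
    contiguous (manual editing can leave gaps).
    """

    def __init__(self, rois: Sequence[ROI] = (), shape: tuple[int, int] | None = None):
        rois = list(rois)
        ids = [r.id for r in rois]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ROI ids")
        self._rois = rois
        self.shape = tuple(shape) if shape is not None else None

    def __len__(self) -> int:
        return len(self._rois)

    def __iter__(self) -> Iterator[ROI]:
        return iter(self._rois)

    def __getitem__(self, roi_id: int) -> ROI:
        for r in self._rois:
            if r.id == roi_id:
                return r
        raise KeyError(roi_id)

    @property
    def ids(self) -> list[int]:
        return [r.id for r in self._rois]

    def compacted(self) -> "ROISet":
        """Relabel ROIs to the contiguous id set {1..K}, preserving order."""
        rois = [
            ROI.from_pixels(k, roi.pixels) for k, roi in enumerate(self._rois, start=1)
        ]
        return ROISet(rois, shape=self.shape)


# ---------------------------------------------------------------------------
# Filters


def stretch_contrast(frame: np.ndarray) -> np.ndarray:
    """Linear contrast stretch to [0, 1]: (O - min O) / (max O - min O).

    A constant frame has no contrast to stretch; it maps to all zeros and a
    warning is emitted.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    lo, hi = frame.min(), frame.max()
    if hi == lo:
        warnings.warn("constant frame: contrast stretch returns all zeros")
        return np.zeros_like(frame)
    return (frame - lo) / (hi - lo)


def gaussian_kernel_1d(sigma: float) -> np.ndarray:
    """Normalized 1-D Gaussian weights truncated at ceil(3*sigma)."""
    return GaussianKernel.from_sigma(sigma).weights


def gaussian_blur(frame: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian blur: 1-D convolution along rows then columns.

    Reflect border handling avoids the dark rim zero padding would create
    near image edges; the normalized kernel preserves constant frames
    exactly.
    """
    kernel = gaussian_kernel_1d(sigma)
    frame = np.asarray(frame, dtype=float)
    out = ndimage.convolve1d(frame, kernel, axis=0, mode="reflect")
    out = ndimage.convolve1d(out, kernel, axis=1, mode="reflect")
    return out


def dog_filter(frame: np.ndarray, sigma_a: float, sigma_b: float) -> np.ndarray:
    """Difference of Gaussians: blur(frame, sigma_a) - blur(frame, sigma_b).

    The response is signed; for bright blobs on a dark background with
    ``sigma_a < sigma_b`` the blob centers respond positively.
    """
    return gaussian_blur(frame, sigma_a) - gaussian_blur(frame, sigma_b)


def threshold_binary(frame: np.ndarray, th: float) -> np.ndarray:
    """Binary mask of pixels strictly brighter than the threshold."""
    return np.asarray(frame) > th


_STRUCTURE = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def label_components(
    mask: np.ndarray, connectivity: int = 8, min_size_px: int = 1
) -> ROISet:
    """Cluster a binary mask into maximal connected components.

    Components smaller than ``min_size_px`` pixels are dropped; surviving
    clusters are labeled 1..K in scan order.  The labeling is iterative
    (no recursion), so arbitrarily large blobs are safe.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    labeled, n = ndimage.label(mask, structure=_STRUCTURE[connectivity])
    rois = []
    next_id = 1
    for lab in range(1, n + 1):
        pixels = np.argwhere(labeled == lab)
        if len(pixels) < min_size_px:
            continue
        rois.append(ROI.from_pixels(next_id, pixels))
        next_id += 1
    return ROISet(rois, shape=mask.shape)


def detect_rois(stack, reference_frame_index: int, params: SegmentationParams) -> ROISet:
    """Run the full detector on one reference frame of a stack.

    Pipeline: stretch_contrast -> gaussian_blur(sigma_n) ->
    dog_filter(sigma_a, sigma_b) -> threshold_binary(th) ->
    label_components.  The DOG response is compared to ``th`` raw (no
    re-normalization), so ``th`` is calibrated against DOG amplitudes,
    which for stretched input lie well inside [-1, 1].
    """
    frames = stack.frames if hasattr(stack, "frames") else np.asarray(stack)
    if frames.ndim == 2:
        frames = frames[None]
    if not (0 <= reference_frame_index < frames.shape[0]):
        raise IndexError(
            f"reference frame {reference_frame_index} out of range [0, {frames.shape[0]})"
        )
    frame = frames[reference_frame_index]
    stretched = stretch_contrast(frame)
    denoised = gaussian_blur(stretched, params.sigma_n)
    response = dog_filter(denoised, params.sigma_a, params.sigma_b)
    mask = threshold_binary(response, params.th)
    return label_components(mask, params.connectivity, params.min_size_px)


def merge_manual_rois(
    auto: ROISet,
    add: np.ndarray | None = None,
    remove: Sequence[int] = (),
    connectivity: int = 8,
) -> ROISet:
    """Apply manual edits to an automatically detected ROISet.

    ``remove`` lists ids to drop (unknown id -> KeyError).  ``add`` is a
    label grid of new clusters; each distinct label becomes a fresh ROI
    appended after the surviving automatic ones.  Disjointness is restored
    by subtracting the added pixels from any overlapping automatic ROI
    (an automatic ROI fully covered by additions disappears).
    """
    known = set(auto.ids)
    for rid in remove:
        if rid not in known:
            raise KeyError(f"unknown ROI id {rid}")
    kept = [r for r in auto if r.id not in set(remove)]

    added_pixels: set[tuple[int, int]] = set()
    new_rois: list[np.ndarray] = []
    if add is not None:
        add = np.asarray(add)
        if auto.shape is not None and tuple(add.shape) != tuple(auto.shape):
            raise ValueError("added mask geometry does not match the ROISet")
        for label in np.unique(add):
            if label == 0:
                continue
            pixels = np.argwhere(add == label)
            new_rois.append(pixels)
            added_pixels.update(map(tuple, pixels.tolist()))

    out: list[ROI] = []
    next_id = 1
    for roi in kept:
        if added_pixels:
            remaining = [p for p in roi.pixels.tolist() if tuple(p) not in added_pixels]
            if not remaining:
                continue
            out.append(ROI.from_pixels(next_id, np.array(remaining)))
        else:
            out.append(ROI.from_pixels(next_id, roi.pixels))
        next_id += 1
    for pixels in new_rois:
        out.append(ROI.from_pixels(next_id, pixels))
        next_id += 1
    return ROISet(out, shape=auto.shape)
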