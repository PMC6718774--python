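import numpy as np
import pytest

from caflux.segmentation import ROI, ROISet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def roi_from_coords(roi_id, coords):
    return ROI.from_pixels(roi_id, np.array(coords))


def roiset_from_grid(grid):
    """Build an ROISet from a small integer label grid (test helper)."""
    grid = np.asarray(grid)
    rois = [
        ROI.from_pixels(int(lab), np.argwhere(grid == lab))
        for lab in np.unique(grid)
        if lab != 0
    ]
    return ROISet(rois, shape=grid.shape)


# --- independent oracles used across test modules ---------------------------


def direct_gaussian_blur_2d(frame, sigma):
    """Brute-force 2-D Gaussian convolution: the full (non-separable)
    truncated 2-D kernel applied with symmetric (reflect) padding."""
    radius = int(np.ceil(3.0 * sigma))
    x = np.arange(-radius, radius + 1, dtype=float)
    k2 = np.exp(-(x[:, None] ** 2 + x[None, :] ** 2) / (2.0 * sigma**2))
    k2 /= k2.sum()
    padded = np.pad(np.asarray(frame, dtype=float), radius, mode="symmetric")
    windows = np.lib.stride_tricks.sliding_window_view(padded, k2.shape)
    return np.einsum("ijkl,kl->ij", windows, k2)


def flood_fill_labels(mask, connectivity):
    """Reference connected-component labeling by explicit-stack flood fill."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    labels = np.zeros((h, w), dtype=int)
    current = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                current += 1
                stack = [(r0, c0)]
                labels[r0, c0] = current
                while stack:
                    r, c = stack.pop()
                    for dr, dc in steps:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = current
                            stack.append((rr, cc))
    return labels


def partition_of(labels):
    """Set-of-frozensets view of a labeling, for order-independent comparison."""
    return {
        frozenset(map(tuple, np.argwhere(labels == lab).tolist()))
        for lab in np.unique(labels)
        if lab != 0
    }
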