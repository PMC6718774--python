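"""Movie and mask I/O plus tabular export.

Fluorescence movies arrive as numbered single-frame image files (PNG, JPG,
BMP, GIF, single-page TIFF) or as a video container.  All downstream
analysis runs on an :class:`ImageStack`: an ordered ``(T, H, W)`` array of
real-valued intensities together with the temporal (frames per second) and
spatial (micrometers per pixel) calibration.

Every writer in this module has a matching reader and the pair is a
lossless identity for values within the declared precision, so CSV files
double as the inter-stage contract of the pipeline.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .segmentation import ROI, ROISet

__all__ = [
    "ImageStack",
    "load_stack",
    "load_video",
    "load_label_mask",
    "write_label_mask",
    "rois_to_label_mask",
    "label_mask_to_rois",
    "write_traces_csv",
    "read_traces_csv",
    "write_spikes_csv",
    "read_spikes_csv",
    "write_edges_csv",
    "read_edges_csv",
    "write_rois_csv",
    "write_correlations_csv",
    "write_adjacency_csv",
]

# Rec. 601 luminance weights for color -> gray reduction.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ImageStack:
    """Ordered grayscale frames with spatial and temporal calibration.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)``, real-valued intensities ``>= 0``.
    fps
        Acquisition rate in frames per second, strictly positive.
    um_per_px
        Pixel pitch in micrometers, strictly positive.
    """

    frames: np.ndarray
    fps: float
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) array with T >= 1")
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if self.um_per_px <= 0:
            raise ValueError(f"um_per_px must be > 0, got {self.um_per_px}")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height_px(self) -> int:
        return self.frames.shape[1]

    @property
    def width_px(self) -> int:
        return self.frames.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of a single frame."""
        return self.frames.shape[1:]

    def frame(self, index: int) -> np.ndarray:
        return self.frames[index]


def _to_gray(img: np.ndarray) -> np.ndarray:
    """Reduce a decoded image to one grayscale channel (Rec. 601 luminance)."""
    img = np.asarray(img)
    if img.ndim == 2:
        return img.astype(float)
    if img.ndim == 3 and img.shape[2] in (3, 4):
        return img[:, :, :3].astype(float) @ _LUMA
    if img.ndim == 3 and img.shape[2] == 1:
        return img[:, :, 0].astype(float)
    raise ValueError(f"unsupported image shape {img.shape}")


def _read_frame(path: str | os.PathLike) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
        if img.ndim == 3 and img.shape[0] > 1 and img.shape[-1] not in (1, 3, 4):
            raise ValueError(
                f"{path} looks like a multi-page TIFF stack; "
                "supply one file per frame instead"
            )
    else:
        img = iio.imread(path)
    return _to_gray(img)


def load_stack(
    paths: Sequence[str | os.PathLike], fps: float, um_per_px: float = 1.0
) -> ImageStack:
    """Load an ordered sequence of single-frame image files.

    Frames are kept in the order given; color inputs are reduced to one
    channel with Rec. 601 luminance; intensities are preserved as reals.

    Raises
    ------
    ValueError
        If no paths are given, the frames disagree in shape, or the
        calibration is non-positive.
    FileNotFoundError
        If any path does not exist.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("no input files given")
    frames = [_read_frame(p) for p in paths]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"frames have mixed dimensions: {sorted(shapes)}")
    return ImageStack(np.stack(frames), fps=fps, um_per_px=um_per_px)


def load_video(
    path: str | os.PathLike,
    fps_override: float | None = None,
    um_per_px: float = 1.0,
) -> ImageStack:
    """Load a multi-frame video container (AVI/MP4/... need imageio-ffmpeg).

    Frame order is preserved.  The container's own rate is used when it is
    available; otherwise, or when ``fps_override`` is given, that value wins.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frames = [_to_gray(f) for f in iio.imiter(path)]
    except FileNotFoundError:
        raise
    except Exception as exc:  # undecodable container or missing plugin
        raise ValueError(f"cannot decode video {path}: {exc}") from exc
    if not frames:
        raise ValueError(f"no frames decoded from {path}")
    fps = fps_override
    if fps is None:
        try:
            meta = iio.immeta(path)
            fps = float(meta.get("fps", 0)) or None
        except Exception:
            fps = None
    if fps is None:
        fps = 1.0
    return ImageStack(np.stack(frames), fps=fps, um_per_px=um_per_px)


# ---------------------------------------------------------------------------
# Label masks


def rois_to_label_mask(rois: ROISet, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Render an ROISet as a label grid: 0 = background, k = ROI id k."""
    if shape is None:
        shape = rois.shape
    if shape is None:
        raise ValueError("shape required when the ROISet carries none")
    mask = np.zeros(shape, dtype=np.uint16)
    for roi in rois:
        if roi.id > 65535:
            raise ValueError("more than 65535 ROIs cannot be stored in a 16-bit mask")
        rr, cc = roi.pixels[:, 0], roi.pixels[:, 1]
        if (rr >= shape[0]).any() or (cc >= shape[1]).any():
            raise ValueError(f"ROI {roi.id} has pixels outside shape {shape}")
        mask[rr, cc] = roi.id
    return mask


def label_mask_to_rois(mask: np.ndarray) -> ROISet:
    """Rebuild an ROISet from a label grid (ids taken from the labels)."""
    mask = np.asarray(mask)
    rois = []
    for label in np.unique(mask):
        if label == 0:
            continue
        pixels = np.argwhere(mask == label)
        rois.append(ROI.from_pixels(int(label), pixels))
    return ROISet(rois, shape=mask.shape)


def write_label_mask(
    rois: ROISet, path: str | os.PathLike, shape: tuple[int, int] | None = None
) -> None:
    """Write an ROISet as a 16-bit label image (TIFF or PNG by extension)."""
    mask = rois_to_label_mask(rois, shape)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, mask)
    else:
        iio.imwrite(path, mask)


def load_label_mask(path: str | os.PathLike) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        mask = tifffile.imread(path)
    else:
        mask = iio.imread(path)
    return np.asarray(mask).astype(np.int64)


# ---------------------------------------------------------------------------
# CSV writers.  Dialect: comma separator, "." decimal, header row, UTF-8,
# frame index as an integer first column.  Floats carry 12 significant
# decimal digits so write -> read round-trips within 1e-12 relative error.

_FLOAT_FMT = "%.12g"


def _frame_table(values: dict[int, np.ndarray], n_frames: int, offset: int = 0) -> pd.DataFrame:
    df = pd.DataFrame(
        {f"roi_{rid}": np.asarray(v, dtype=float) for rid, v in values.items()}
    )
    df.insert(0, "frame", np.arange(offset, offset + n_frames))
    return df


def write_traces_csv(traces: dict[int, np.ndarray], path: str | os.PathLike) -> None:
    """Write per-ROI brightness (or rate) traces, one row per frame."""
    if not traces:
        raise ValueError("no traces to write")
    lengths = {len(v) for v in traces.values()}
    if len(lengths) != 1:
        raise ValueError("traces have unequal lengths")
    _frame_table(traces, lengths.pop()).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_traces_csv(path: str | os.PathLike) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    return {
        int(c[len("roi_"):]): df[c].to_numpy(dtype=float)
        for c in df.columns
        if c.startswith("roi_")
    }


def write_spikes_csv(spikes: dict[int, np.ndarray], path: str | os.PathLike) -> None:
    """Write binary spike vectors as a frame x ROI matrix."""
    if not spikes:
        raise ValueError("no spike trains to write")
    lengths = {len(v) for v in spikes.values()}
    if len(lengths) != 1:
        raise ValueError("spike trains have unequal lengths")
    df = pd.DataFrame({f"roi_{rid}": np.asarray(v, dtype=int) for rid, v in spikes.items()})
    df.insert(0, "frame", np.arange(len(df)))
    df.to_csv(path, index=False)


def read_spikes_csv(path: str | os.PathLike) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    return {
        int(c[len("roi_"):]): df[c].to_numpy(dtype=int)
        for c in df.columns
        if c.startswith("roi_")
    }


_EDGE_COLUMNS = ["source_roi", "target_roi", "best_lag", "correlation", "distance_um", "delay_s"]


def write_edges_csv(edges: Iterable, path: str | os.PathLike) -> None:
    """Write network edges: one row per directed connection."""
    rows = [
        {
            "source_roi": e.source_roi,
            "target_roi": e.target_roi,
            "best_lag": e.best_lag,
            "correlation": e.correlation,
            "distance_um": e.distance_um,
            "delay_s": e.delay_s,
        }
        for e in edges
    ]
    pd.DataFrame(rows, columns=_EDGE_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_edges_csv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_rois_csv(rois: ROISet, path: str | os.PathLike) -> None:
    rows = [
        {
            "id": r.id,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
            "area_px": r.area_px,
        }
        for r in rois
    ]
    pd.DataFrame(rows, columns=["id", "centroid_row", "centroid_col", "area_px"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_correlations_csv(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the (pair, lag, value) cross-correlation table."""
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_adjacency_csv(adjacency: np.ndarray, roi_ids: Sequence[int], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        np.asarray(adjacency, dtype=int),
        index=list(roi_ids),
        columns=[str(i) for i in roi_ids],
    )
    df.to_csv(path, index_label="roi")
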