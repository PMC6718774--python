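"""Synthetic calcium-imaging movies with known ground truth.

Cells are rendered as 2-D Gaussian blobs on a dark background.  Each cell
carries a constant baseline brightness plus a calcium activity signal:
every spike adds an instant-rise, single-exponential-decay transient
(the dominant shape of fluorescence-indicator transients).  Spikes arise
as independent Bernoulli draws per frame, optionally scripted per cell,
and can propagate along planted directed edges: a source spike triggers a
target spike a fixed number of frames later with a set probability, which
lets every reconstruction stage be validated against a known network.
Sensor noise is additive Gaussian.

All randomness derives from one master seed through named substreams
(placement, spiking, propagation, noise), keyed per cell, so the output
is a pure function of the spec and growing ``n_cells`` does not reshuffle
the cells already present.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import ImageStack
from .segmentation import ROI, ROISet

__all__ = ["SyntheticSpec", "GroundTruth", "generate_movie", "generate_traces"]

# substream tags (kept small; combined with the master seed)
_PLACE, _SPIKE, _EDGE, _NOISE, _TRACE_NOISE, _BASE = 0, 1, 2, 3, 4, 5


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic movie.

    n_cells : number of cells; ids are 1..n_cells.
    height_px, width_px : frame geometry.
    n_frames : movie length in frames.
    blob_sigma_px : spatial scale of the Gaussian cell body.
    baseline_range : per-cell resting brightness drawn uniformly from this
        interval (arbitrary intensity units).
    amplitude : brightness added by one spike at its peak.
    decay_frames : e-folding time of the transient decay, in frames.
    spike_rate : intrinsic spike probability per cell per frame.
    noise_sigma : std of the additive Gaussian sensor noise.
    edges : planted directed connections (source_id, target_id,
        lag_frames, transmission_probability).
    scripted_spikes : optional {cell_id: [frames]} overriding the
        Bernoulli draws for those cells (propagation still applies).
    centers : optional {cell_id: (row, col)} pinning cell positions
        (cells not listed are placed randomly).
    allow_overlap : when False (default) cell supports must not overlap;
        placement retries up to ``max_place_tries`` times per cell.
    """

    n_cells: int = 20
    height_px: int = 128
    width_px: int = 128
    n_frames: int = 200
    blob_sigma_px: float = 3.0
    baseline_range: tuple[float, float] = (40.0, 100.0)
    amplitude: float = 60.0
    decay_frames: float = 3.0
    spike_rate: float = 0.02
    noise_sigma: float = 2.0
    edges: tuple[tuple[int, int, int, float], ...] = ()
    scripted_spikes: Mapping[int, Sequence[int]] | None = None
    centers: Mapping[int, tuple[float, float]] | None = None
    allow_overlap: bool = False
    max_place_tries: int = 2000
    fps: float = 10.0
    um_per_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.blob_sigma_px <= 0 or self.decay_frames <= 0:
            raise ValueError("blob_sigma_px and decay_frames must be > 0")
        if not 0.0 <= self.spike_rate <= 1.0:
            raise ValueError("spike_rate must lie in [0, 1]")
        if self.noise_sigma < 0 or self.amplitude < 0:
            raise ValueError("noise_sigma and amplitude must be >= 0")
        for src, dst, lag, prob in self.edges:
            if not (1 <= src <= self.n_cells and 1 <= dst <= self.n_cells):
                raise ValueError(f"edge ({src}->{dst}) references an unknown cell")
            if lag < 0:
                raise ValueError("edge lag must be >= 0")
            if not 0.0 <= prob <= 1.0:
                raise ValueError("transmission probability must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually rendered."""

    label_mask: np.ndarray
    rois: ROISet
    spike_frames: dict[int, np.ndarray]
    baselines: dict[int, float]
    edges: tuple[tuple[int, int, int, float], ...]
    centers: dict[int, tuple[float, float]]


def _rng(spec: SyntheticSpec, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=key))


def _support_radius(spec: SyntheticSpec) -> int:
    return int(np.ceil(3.0 * spec.blob_sigma_px))


def _mask_radius(spec: SyntheticSpec) -> float:
    # ground-truth ROI support: within 2 sigma of the center
    return 2.0 * spec.blob_sigma_px


def _place_cells(spec: SyntheticSpec) -> dict[int, tuple[float, float]]:
    margin = _support_radius(spec)
    if spec.height_px <= 2 * margin or spec.width_px <= 2 * margin:
        raise ValueError("frame too small for the blob size")
    min_sep = 2.0 * margin
    centers: dict[int, tuple[float, float]] = {}
    pinned = dict(spec.centers or {})
    for cell in range(1, spec.n_cells + 1):
        if cell in pinned:
            centers[cell] = (float(pinned[cell][0]), float(pinned[cell][1]))
            continue
        rng = _rng(spec, _PLACE, cell)
        for _ in range(spec.max_place_tries):
            r = rng.uniform(margin, spec.height_px - 1 - margin)
            c = rng.uniform(margin, spec.width_px - 1 - margin)
            if spec.allow_overlap or all(
                np.hypot(r - r0, c - c0) >= min_sep for r0, c0 in centers.values()
            ):
                centers[cell] = (r, c)
                break
        else:
            raise RuntimeError(
                f"could not place cell {cell} without overlap after "
                f"{spec.max_place_tries} tries"
            )
    return centers


def _draw_spikes(spec: SyntheticSpec) -> dict[int, np.ndarray]:
    """Intrinsic + propagated spikes per cell, as sorted frame arrays."""
    spiking: dict[int, set[int]] = {}
    scripted = dict(spec.scripted_spikes or {})
    for cell in range(1, spec.n_cells + 1):
        if cell in scripted:
            frames = {int(f) for f in scripted[cell] if 0 <= f < spec.n_frames}
        else:
            rng = _rng(spec, _SPIKE, cell)
            frames = set(np.flatnonzero(rng.random(spec.n_frames) < spec.spike_rate))
        spiking[cell] = frames

    # propagate along planted edges, event by event in (frame, cell) order
    out_edges: dict[int, list[tuple[int, int, int, float]]] = {}
    edge_rngs = {}
    for k, (src, dst, lag, prob) in enumerate(spec.edges):
        out_edges.setdefault(src, []).append((k, dst, lag, prob))
        edge_rngs[k] = _rng(spec, _EDGE, k)
    if out_edges:
        heap = [(int(f), cell) for cell, fr in spiking.items() for f in fr]
        heapq.heapify(heap)
        seen = set(heap)
        while heap:
            frame, cell = heapq.heappop(heap)
            for k, dst, lag, prob in out_edges.get(cell, ()):  # noqa: B020
                target_frame = frame + lag
                if target_frame >= spec.n_frames:
                    continue
                if edge_rngs[k].random() < prob:
                    if target_frame not in spiking[dst]:
                        spiking[dst].add(target_frame)
                        if (target_frame, dst) not in seen:
                            heapq.heappush(heap, (target_frame, dst))
                            seen.add((target_frame, dst))
    return {cell: np.array(sorted(fr), dtype=int) for cell, fr in spiking.items()}


def _baselines(spec: SyntheticSpec) -> dict[int, float]:
    lo, hi = spec.baseline_range
    return {
        cell: float(_rng(spec, _BASE, cell).uniform(lo, hi))
        for cell in range(1, spec.n_cells + 1)
    }


def _activity(spec: SyntheticSpec, frames: np.ndarray) -> np.ndarray:
    """Transient amplitude over time: instant rise, exponential decay."""
    a = np.zeros(spec.n_frames)
    pulse = np.zeros(spec.n_frames)
    pulse[frames] = spec.amplitude
    decay = np.exp(-1.0 / spec.decay_frames)
    for n in range(spec.n_frames):
        a[n] = (a[n - 1] * decay if n > 0 else 0.0) + pulse[n]
    return a


def generate_movie(spec: SyntheticSpec) -> tuple[ImageStack, GroundTruth]:
    """Render the full movie and its ground truth.

    Identical spec (including seed) gives a bit-identical movie.
    """
    centers = _place_cells(spec)
    spikes = _draw_spikes(spec)
    baselines = _baselines(spec)

    rows = np.arange(spec.height_px)[:, None]
    cols = np.arange(spec.width_px)[None, :]
    movie = np.zeros((spec.n_frames, spec.height_px, spec.width_px))
    label_mask = np.zeros((spec.height_px, spec.width_px), dtype=np.uint16)
    mask_r2 = _mask_radius(spec) ** 2

    for cell in range(1, spec.n_cells + 1):
        r0, c0 = centers[cell]
        d2 = (rows - r0) ** 2 + (cols - c0) ** 2
        blob = np.exp(-d2 / (2.0 * spec.blob_sigma_px**2))
        intensity = baselines[cell] + _activity(spec, spikes[cell])
        movie += intensity[:, None, None] * blob[None, :, :]
        label_mask[d2 <= mask_r2] = cell

    if spec.noise_sigma > 0:
        noise = _rng(spec, _NOISE).normal(0.0, spec.noise_sigma, movie.shape)
        movie = movie + noise
    np.clip(movie, 0.0, None, out=movie)

    rois = ROISet(
        [
            ROI.from_pixels(cell, np.argwhere(label_mask == cell))
            for cell in range(1, spec.n_cells + 1)
        ],
        shape=label_mask.shape,
    )
    truth = GroundTruth(
        label_mask=label_mask,
        rois=rois,
        spike_frames=spikes,
        baselines=baselines,
        edges=spec.edges,
        centers=centers,
    )
    return ImageStack(movie, fps=spec.fps, um_per_px=spec.um_per_px), truth


def generate_traces(spec: SyntheticSpec) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Trace-only fast path: per-cell brightness traces with the same
    kinetics and additive noise, skipping the spatial rendering.

    Returns ``({cell: b}, {cell: spike_frames})``.
    """
    spikes = _draw_spikes(spec)
    baselines = _baselines(spec)
    traces: dict[int, np.ndarray] = {}
    for cell in range(1, spec.n_cells + 1):
        b = baselines[cell] + _activity(spec, spikes[cell])
        if spec.noise_sigma > 0:
            b = b + _rng(spec, _TRACE_NOISE, cell).normal(
                0.0, spec.noise_sigma, spec.n_frames
            )
        traces[cell] = b
    return traces, spikes
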