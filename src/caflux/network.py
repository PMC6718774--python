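"""Lagged cross-correlation and constrained network reconstruction.

Functional coupling between two ROIs is scored by the lagged Pearson
cross-correlation of their activity signals (brightness ``b``, rate of
change ``r``, or spike vector ``s``).  A directed communication network
is then reconstructed under physiological constraints: a minimum
correlation (similar spiking patterns), a maximum centroid distance
(neurites have finite length), and a maximum response delay (converted to
a frame-lag window through the acquisition rate).  The lag at which the
correlation peaks decides the direction: the leading cell points to the
following one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .segmentation import ROI, ROISet
from .timeseries import SpikeTrain

__all__ = [
    "CorrelationSpec",
    "NetworkParams",
    "Edge",
    "NetworkGraph",
    "xcorr",
    "correlation_table",
    "heatmap_values",
    "centroid_distance_um",
    "reconstruct_network",
    "adjacency",
    "spatiotemporal_map_data",
]


@dataclass(frozen=True)
class CorrelationSpec:
    """Which signal to correlate and over which lag window.

    signal : 'b' (brightness), 'r' (rate of change) or 's' (spike vector).
    tau_max : lags -tau_max..tau_max are evaluated.
    """

    signal: str = "s"
    tau_max: int = 5

    def __post_init__(self) -> None:
        if self.signal not in ("b", "r", "s"):
            raise ValueError("signal must be one of 'b', 'r', 's'")
        if self.tau_max < 0:
            raise ValueError("tau_max must be >= 0")


@dataclass(frozen=True)
class NetworkParams:
    """Physiological constraints on reconstructed connections.

    min_corr : correlation must exceed this (strict), range [0, 1].
    max_dist_um : centroid distance must not exceed this.
    max_delay_s : response delay must not exceed this; the admissible lag
        window is ``floor(max_delay_s * fps)`` frames.
    """

    min_corr: float = 0.25
    max_dist_um: float = 208.0
    max_delay_s: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_corr <= 1.0:
            raise ValueError("min_corr must lie in [0, 1]")
        if self.max_dist_um <= 0:
            raise ValueError("max_dist_um must be > 0")
        if self.max_delay_s < 0:
            raise ValueError("max_delay_s must be >= 0")

    def max_lag_frames(self, fps: float) -> int:
        return int(np.floor(self.max_delay_s * fps))


@dataclass(frozen=True)
class Edge:
    """A directed connection source -> target at the best admissible lag."""

    source_roi: int
    target_roi: int
    best_lag: int
    correlation: float
    distance_um: float
    delay_s: float


@dataclass(frozen=True)
class NetworkGraph:
    """Reconstructed communication network over a ROI set."""

    roi_ids: tuple[int, ...]
    edges: tuple[Edge, ...]

    def adjacency_matrix(self) -> np.ndarray:
        """Binary K x K matrix: entry (i, j) = 1 iff edge roi_i -> roi_j."""
        index = {rid: k for k, rid in enumerate(self.roi_ids)}
        adj = np.zeros((len(self.roi_ids), len(self.roi_ids)), dtype=int)
        for e in self.edges:
            adj[index[e.source_roi], index[e.target_roi]] = 1
        return adj

    def edge_set(self) -> set[tuple[int, int]]:
        return {(e.source_roi, e.target_roi) for e in self.edges}

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.roi_ids)
        for e in self.edges:
            g.add_edge(
                e.source_roi,
                e.target_roi,
                lag=e.best_lag,
                correlation=e.correlation,
                distance_um=e.distance_um,
                delay_s=e.delay_s,
            )
        return g


def _as_signal(x) -> np.ndarray:
    if isinstance(x, SpikeTrain):
        x = x.s
    return np.asarray(x, dtype=float)


def xcorr(f, g, tau: int) -> float:
    """Normalized Pearson cross-correlation of f against g at lag tau.

    ``f`` is shifted by ``tau`` frames: the sum runs over
    ``f[n - tau] * g[n]`` for the overlapping index range, with each
    series centred by its full-length mean and scaled by its full-length
    norm.  A positive tau therefore means f's past matches g's present —
    f leads.  A constant series has zero norm; the correlation is
    reported as 0.0 with a warning.
    """
    f = _as_signal(f)
    g = _as_signal(g)
    if len(f) != len(g):
        raise ValueError("series must have equal length")
    n = len(f)
    tau = int(tau)
    if abs(tau) >= n:
        raise ValueError(f"|tau|={abs(tau)} must be smaller than the series length {n}")
    fc = f - f.mean()
    gc = g - g.mean()
    nf = np.linalg.norm(fc)
    ng = np.linalg.norm(gc)
    if nf == 0.0 or ng == 0.0:
        warnings.warn("constant series: cross-correlation undefined, reporting 0")
        return 0.0
    if tau >= 0:
        prod = fc[: n - tau] * gc[tau:]
    else:
        prod = fc[-tau:] * gc[: n + tau]
    return float(prod.sum() / (nf * ng))


def _signals_from(data, kind: str) -> dict[int, np.ndarray]:
    """Normalize a trace/train mapping to {roi_id: 1-D float array}."""
    out: dict[int, np.ndarray] = {}
    for rid, v in data.items():
        if kind == "s" and isinstance(v, SpikeTrain):
            out[rid] = v.s.astype(float)
        else:
            out[rid] = _as_signal(v)
    return out


def correlation_table(
    data: Mapping[int, object], spec: CorrelationSpec | None = None
) -> pd.DataFrame:
    """Cross-correlation for all ordered ROI pairs over the lag window.

    Returns a tidy frame with columns (roi_a, roi_b, lag, correlation).
    At lag 0 the implied matrix is symmetric with unit diagonal for
    non-constant signals.
    """
    if spec is None:
        spec = CorrelationSpec()
    signals = _signals_from(data, spec.signal)
    ids = sorted(signals)
    if len(ids) < 2:
        raise ValueError("need at least 2 ROIs to correlate")
    rows = []
    for a in ids:
        for b in ids:
            for tau in range(-spec.tau_max, spec.tau_max + 1):
                rows.append(
                    {
                        "roi_a": a,
                        "roi_b": b,
                        "lag": tau,
                        "correlation": xcorr(signals[a], signals[b], tau),
                    }
                )
    return pd.DataFrame(rows, columns=["roi_a", "roi_b", "lag", "correlation"])


def heatmap_values(data: Mapping[int, object], kind: str = "s") -> dict[int, float]:
    """Per-ROI activity scalar, normalized to [0, 1] by the maximum.

    kind 'b': mean brightness over frames; 'r': mean absolute rate of
    change; 's': spike count.  An all-zero collection maps to all zeros.
    """
    if kind not in ("b", "r", "s"):
        raise ValueError("kind must be one of 'b', 'r', 's'")
    raw: dict[int, float] = {}
    for rid, v in data.items():
        if kind == "s":
            s = v.s if isinstance(v, SpikeTrain) else np.asarray(v)
            raw[rid] = float(np.sum(s))
        elif kind == "b":
            raw[rid] = float(np.mean(_as_signal(v)))
        else:
            raw[rid] = float(np.mean(np.abs(_as_signal(v))))
    top = max(raw.values(), default=0.0)
    if top == 0.0:
        return {rid: 0.0 for rid in raw}
    return {rid: val / top for rid, val in raw.items()}


def centroid_distance_um(roi_a: ROI, roi_b: ROI, um_per_px: float) -> float:
    """Euclidean distance between ROI centroids, scaled to micrometers."""
    if um_per_px <= 0:
        raise ValueError("um_per_px must be > 0")
    dr = roi_a.centroid[0] - roi_b.centroid[0]
    dc = roi_a.centroid[1] - roi_b.centroid[1]
    return float(np.hypot(dr, dc) * um_per_px)


def _best_lag(f: np.ndarray, g: np.ndarray, max_lag: int) -> tuple[int, float]:
    """Peak correlation over |tau| <= max_lag; ties broken toward the
    smallest |tau|, then the positive lag."""
    best_tau, best_val = 0, -np.inf
    # visit lags in tie-break priority order: 0, +1, -1, +2, -2, ...
    order = [0]
    for k in range(1, max_lag + 1):
        order.extend([k, -k])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tau in order:
            val = xcorr(f, g, tau)
            if val > best_val:
                best_tau, best_val = tau, val
    return best_tau, best_val


def reconstruct_network(
    rois: ROISet,
    signals: Mapping[int, object],
    net_params: NetworkParams | None = None,
    fps: float = 1.0,
    um_per_px: float = 1.0,
    spec: CorrelationSpec | None = None,
) -> NetworkGraph:
    """Reconstruct the directed communication network among the ROIs.

    For each unordered ROI pair the cross-correlation is evaluated over
    all admissible lags ``|tau| <= floor(max_delay_s * fps)`` and its peak
    located (tie -> smallest |tau|, then positive tau).  An edge is
    created iff the peak correlation strictly exceeds ``min_corr`` and
    the centroid distance does not exceed ``max_dist_um``.  A nonzero
    peak lag orients the edge from the leading to the following ROI; a
    zero-lag peak yields two reciprocal edges (an undirected link).
    """
    if net_params is None:
        net_params = NetworkParams()
    if spec is None:
        spec = CorrelationSpec()
    sig = _signals_from(signals, spec.signal)
    ids = [rid for rid in rois.ids if rid in sig]
    max_lag = net_params.max_lag_frames(fps)
    edges: list[Edge] = []
    for idx_a in range(len(ids)):
        for idx_b in range(idx_a + 1, len(ids)):
            a, b = ids[idx_a], ids[idx_b]
            dist = centroid_distance_um(rois[a], rois[b], um_per_px)
            if dist > net_params.max_dist_um:
                continue
            tau, val = _best_lag(sig[a], sig[b], max_lag)
            if not val > net_params.min_corr:
                continue
            lag = abs(tau)
            delay = lag / fps
            if tau > 0:
                pairs = [(a, b)]
            elif tau < 0:
                pairs = [(b, a)]
            else:
                pairs = [(a, b), (b, a)]
            for src, dst in pairs:
                edges.append(
                    Edge(
                        source_roi=src,
                        target_roi=dst,
                        best_lag=lag,
                        correlation=val,
                        distance_um=dist,
                        delay_s=delay,
                    )
                )
    return NetworkGraph(roi_ids=tuple(ids), edges=tuple(edges))


def adjacency(graph: NetworkGraph) -> np.ndarray:
    """Binary adjacency matrix of the reconstructed network."""
    return graph.adjacency_matrix()


def spatiotemporal_map_data(
    trains: Mapping[int, SpikeTrain], rois: ROISet
) -> pd.DataFrame:
    """Per-ROI (centroid, spike_count, n_avg) for the spatiotemporal map.

    Only ROIs with at least one detected spike appear: circle size tracks
    the spike count, color the mean spike frame.
    """
    rows = []
    for rid, train in trains.items():
        if train.spike_count == 0:
            continue
        roi = rois[rid]
        rows.append(
            {
                "roi_id": rid,
                "centroid_row": roi.centroid[0],
                "centroid_col": roi.centroid[1],
                "spike_count": train.spike_count,
                "n_avg": train.n_avg,
            }
        )
    return pd.DataFrame(
        rows, columns=["roi_id", "centroid_row", "centroid_col", "spike_count", "n_avg"]
    )
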