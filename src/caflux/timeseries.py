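"""Per-ROI brightness traces and calcium-spike detection.

Cells differ widely in resting brightness, so detection runs on the rate
of change ``r[n] = b[n] - b[n-1]`` of the mean ROI brightness rather than
on the brightness itself: any constant baseline cancels out.

Spikes are flagged by an influence-limited sliding-window z-score.  A
window of the ``l`` most recent *filtered* rate samples provides a local
mean ``mu_l`` and population standard deviation ``sigma_l``; frame ``n``
is a spike when the rate both exceeds an absolute floor ``th_r`` and
deviates from the local mean by more than ``th_z`` local standard
deviations.  Samples that fire (or show an equally extreme negative
excursion, i.e. a spike's falling edge) enter the window only partially,
mixed with weight ``i`` into the previous filtered value, so a burst of
activity cannot inflate the running statistics and mask later spikes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "SpikeParams",
    "SpikeDetectionState",
    "SpikeTrain",
    "extract_traces",
    "rate_of_change",
    "detect_spikes",
    "filter_active",
    "spike_summary",
]


@dataclass(frozen=True)
class SpikeParams:
    """Detector parameters.

    l : window length in frames (>= 2).
    influence : mixing weight i in [0, 1] limiting how much a detected
        spike contaminates the running mean/std estimates.
    th_z : z-score threshold (> 0).
    th_r : absolute rate-of-change floor, in brightness units per frame.
    min_spikes : minimum spike count for a ROI to be kept in the analysis.

    Defaults are the published operating point for low-noise footage:
    l=10, th_z=5, i=0.50, th_r=0.100.
    """

    l: int = 10
    influence: float = 0.50
    th_z: float = 5.0
    th_r: float = 0.100
    min_spikes: int = 0

    def __post_init__(self) -> None:
        if self.l < 2:
            raise ValueError("window length l must be >= 2")
        if not 0.0 <= self.influence <= 1.0:
            raise ValueError("influence must lie in [0, 1]")
        if self.th_z <= 0:
            raise ValueError("th_z must be > 0")
        if self.min_spikes < 0:
            raise ValueError("min_spikes must be >= 0")


@dataclass(frozen=True)
class SpikeDetectionState:
    """Intermediate detector traces, aligned to the rate vector r.

    mu_l[n]/sigma_l[n] are the windowed mean/std used to score r[n]
    (NaN during warm-up); r_f is the influence-filtered rate; z the
    z-score vector (NaN during warm-up, +inf under the zero-sigma rule).
    """

    mu_l: np.ndarray
    sigma_l: np.ndarray
    r_f: np.ndarray
    z: np.ndarray


@dataclass(frozen=True)
class SpikeTrain:
    """Binary spike vector for one ROI, aligned to the rate vector."""

    roi_id: int
    s: np.ndarray

    @property
    def spike_count(self) -> int:
        return int(self.s.sum())

    @property
    def spike_frames(self) -> np.ndarray:
        """Frame numbers of the spikes (frame axis of the brightness trace)."""
        # s[j] scores r[j] = b[j+1] - b[j+1-1]; index j is brightness frame j+1.
        return np.flatnonzero(self.s) + 1

    @property
    def n_avg(self) -> float | None:
        """Mean spike frame, or None when the train is empty."""
        if self.spike_count == 0:
            return None
        return float(self.spike_frames.mean())


def extract_traces(stack, rois) -> dict[int, np.ndarray]:
    """Mean brightness per ROI per frame: b[n] = mean over the ROI's pixels."""
    frames = stack.frames if hasattr(stack, "frames") else np.asarray(stack)
    traces: dict[int, np.ndarray] = {}
    for roi in rois:
        if roi.area_px == 0:
            raise ValueError(f"ROI {roi.id} is empty")
        rr, cc = roi.pixels[:, 0], roi.pixels[:, 1]
        if rr.max() >= frames.shape[1] or cc.max() >= frames.shape[2]:
            raise ValueError(f"ROI {roi.id} has pixels outside the frame bounds")
        traces[roi.id] = frames[:, rr, cc].mean(axis=1)
    return traces


def rate_of_change(b: np.ndarray) -> np.ndarray:
    """First difference of a brightness trace: r[n] = b[n] - b[n-1].

    The result has length ``len(b) - 1`` and is indexed from frame 1.
    """
    b = np.asarray(b, dtype=float)
    if b.ndim != 1 or len(b) < 2:
        raise ValueError("trace must be 1-D with at least 2 samples")
    return np.diff(b)


def _z_at(r_n: float, mu: float, sigma: float) -> float:
    if sigma > 0:
        return (r_n - mu) / sigma
    # Zero local dispersion: any positive deviation is infinitely many
    # standard deviations out; no deviation or a negative one scores 0.
    return math.inf if r_n > mu else 0.0


def detect_spikes(
    r: np.ndarray, params: SpikeParams | None = None, roi_id: int = 0
) -> tuple[SpikeTrain, SpikeDetectionState]:
    """Run the influence-limited sliding-window z-score detector on a rate trace.

    For each n >= l (0-based index into ``r``), the window holds the l
    filtered samples ``r_f[n-l .. n-1]``; with its mean ``mu`` and
    population standard deviation ``sigma`` (1/l normalization),

        z[n] = (r[n] - mu) / sigma
        s[n] = 1  iff  r[n] > th_r  and  z[n] > th_z

    The filtered series updates as ``r_f[n] = i*r[n] + (1-i)*r_f[n-1]``
    when the sample fired or when its negative excursion is equally
    extreme ((-r[n] - 2*mu)/sigma > th_z); otherwise ``r_f[n] = r[n]``.
    The first l samples are warm-up: no detection, ``r_f = r``.
    """
    if params is None:
        params = SpikeParams()
    r = np.asarray(r, dtype=float)
    if r.ndim != 1:
        raise ValueError("rate trace must be 1-D")
    n_samples = len(r)
    l = params.l
    if l >= n_samples:
        raise ValueError(f"window length l={l} must be shorter than the trace ({n_samples})")

    i = params.influence
    s = np.zeros(n_samples, dtype=np.int8)
    r_f = np.empty(n_samples)
    mu_l = np.full(n_samples, np.nan)
    sigma_l = np.full(n_samples, np.nan)
    z = np.full(n_samples, np.nan)

    r_f[:l] = r[:l]
    for n in range(l, n_samples):
        window = r_f[n - l : n]
        mu = window.mean()
        sigma = window.std()  # population (1/l) normalization
        mu_l[n] = mu
        sigma_l[n] = sigma
        z[n] = _z_at(r[n], mu, sigma)
        fired = (r[n] > params.th_r) and (z[n] > params.th_z)
        s[n] = 1 if fired else 0
        if sigma > 0:
            negative_excursion = (-r[n] - 2.0 * mu) / sigma > params.th_z
        else:
            negative_excursion = (-r[n] - 2.0 * mu) > 0
        if fired or negative_excursion:
            r_f[n] = i * r[n] + (1.0 - i) * r_f[n - 1]
        else:
            r_f[n] = r[n]

    train = SpikeTrain(roi_id=roi_id, s=s)
    state = SpikeDetectionState(mu_l=mu_l, sigma_l=sigma_l, r_f=r_f, z=z)
    return train, state


def detect_spikes_all(
    traces: Mapping[int, np.ndarray], params: SpikeParams | None = None
) -> dict[int, SpikeTrain]:
    """Convenience: rate_of_change + detect_spikes over a trace dictionary."""
    trains = {}
    for rid, b in traces.items():
        train, _ = detect_spikes(rate_of_change(b), params, roi_id=rid)
        trains[rid] = train
    return trains


def filter_active(
    trains: Iterable[SpikeTrain], min_spikes: int
) -> list[SpikeTrain]:
    """Keep only trains with at least ``min_spikes`` detected spikes."""
    return [t for t in trains if t.spike_count >= min_spikes]


def spike_summary(train: SpikeTrain) -> tuple[int, float | None]:
    """(spike_count, mean spike frame); the mean is None for empty trains."""
    return train.spike_count, train.n_avg
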