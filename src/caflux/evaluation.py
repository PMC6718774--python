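"""Scoring of detected ROIs and spike trains against ground truth.

Segmentation is scored by pixel-overlap matching between detected ROIs
and reference (manually drawn or synthetic) cells.  A detected ROI that
overlaps exactly one reference cell is a candidate true positive; one
that overlaps none is a false positive; one spanning several cells is a
merge error and is bookkept separately — merged detections count toward
neither TP nor FN, because conflating the two error modes would reward
under- and over-segmentation alike.  Per reference cell, only the
largest-overlap candidate is the true positive; redundant candidates are
false positives.

Scores:  TPR (sensitivity) = TP / P,  PPV = TP / (TP + FP),
recall = TP / (TP + FN),  with P the number of reference cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import ROISet

__all__ = [
    "MatchCounts",
    "Scores",
    "match_rois",
    "segmentation_scores",
    "match_spikes",
]


@dataclass(frozen=True)
class MatchCounts:
    """TP/FP/FN bookkeeping; ``merged`` counts detections spanning several
    reference cells, ``merged_covered`` the reference cells reachable only
    through such detections."""

    P: int
    TP: int
    FP: int
    FN: int
    merged: int = 0
    merged_covered: int = 0


@dataclass(frozen=True)
class Scores:
    """tpr/ppv/recall in [0, 1]; None where the denominator is zero."""

    tpr: float | None
    ppv: float | None
    recall: float | None


@dataclass(frozen=True)
class RoiMatchResult:
    counts: MatchCounts
    # detected id -> classification: ('tp', truth_id) | ('fp', None) | ('merged', None)
    assignment: dict[int, tuple[str, int | None]]
    # truth id -> 'tp' | 'fn' | 'merged_covered'
    truth_status: dict[int, str]


def match_rois(
    detected: ROISet, truth: ROISet, min_overlap_px: int = 1
) -> RoiMatchResult:
    """Match detected ROIs to reference cells by pixel overlap.

    Two regions "overlap" when they share at least ``min_overlap_px``
    pixels.  Classification:

    * detected overlapping >= 2 reference cells -> merged;
    * detected overlapping 0 -> FP;
    * per reference cell, among its single-cell detections the one with
      the largest overlap (tie -> lowest detected id) is the TP, any
      others are FP;
    * reference cell with no overlapping detection at all -> FN;
    * reference cell touched only by merged detections -> merged_covered
      (neither TP nor FN).
    """
    if (
        detected.shape is not None
        and truth.shape is not None
        and tuple(detected.shape) != tuple(truth.shape)
    ):
        raise ValueError("detected and truth ROI sets live on different geometries")
    if min_overlap_px < 1:
        raise ValueError("min_overlap_px must be >= 1")

    truth_pixels = {t.id: t.pixel_set for t in truth}
    overlaps: dict[int, dict[int, int]] = {}  # det id -> {truth id: shared px}
    for d in detected:
        dpix = d.pixel_set
        hits = {}
        for tid, tpix in truth_pixels.items():
            shared = len(dpix & tpix)
            if shared >= min_overlap_px:
                hits[tid] = shared
        overlaps[d.id] = hits

    assignment: dict[int, tuple[str, int | None]] = {}
    truth_candidates: dict[int, list[tuple[int, int]]] = {t.id: [] for t in truth}
    truth_touched_by_merged: set[int] = set()
    merged = 0
    for did in sorted(overlaps):
        hits = overlaps[did]
        if len(hits) == 0:
            assignment[did] = ("fp", None)
        elif len(hits) >= 2:
            assignment[did] = ("merged", None)
            merged += 1
            truth_touched_by_merged.update(hits)
        else:
            (tid, shared), = hits.items()
            truth_candidates[tid].append((did, shared))

    tp = 0
    truth_status: dict[int, str] = {}
    for tid in sorted(truth_candidates):
        candidates = truth_candidates[tid]
        if candidates:
            # largest overlap wins; tie -> lowest detected id
            winner = min(candidates, key=lambda c: (-c[1], c[0]))[0]
            assignment[winner] = ("tp", tid)
            tp += 1
            truth_status[tid] = "tp"
            for did, _ in candidates:
                if did != winner:
                    assignment[did] = ("fp", None)
        elif tid in truth_touched_by_merged:
            truth_status[tid] = "merged_covered"
        else:
            truth_status[tid] = "fn"

    fp = sum(1 for kind, _ in assignment.values() if kind == "fp")
    fn = sum(1 for st in truth_status.values() if st == "fn")
    merged_covered = sum(1 for st in truth_status.values() if st == "merged_covered")
    counts = MatchCounts(
        P=len(truth),
        TP=tp,
        FP=fp,
        FN=fn,
        merged=merged,
        merged_covered=merged_covered,
    )
    return RoiMatchResult(counts=counts, assignment=assignment, truth_status=truth_status)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def segmentation_scores(counts: MatchCounts) -> Scores:
    """tpr = TP/P, ppv = TP/(TP+FP), recall = TP/(TP+FN)."""
    return Scores(
        tpr=_ratio(counts.TP, counts.P),
        ppv=_ratio(counts.TP, counts.TP + counts.FP),
        recall=_ratio(counts.TP, counts.TP + counts.FN),
    )


def match_spikes(
    detected_frames: np.ndarray,
    truth_frames: np.ndarray,
    tolerance_frames: int = 1,
) -> MatchCounts:
    """Match detected spike frames to reference spike frames.

    A detection within ``tolerance_frames`` of an unmatched reference
    spike is a TP.  Matching is a sorted two-pointer sweep, which attains
    the maximum-cardinality matching for this interval-tolerance
    structure.  Unmatched detections are FP, unmatched reference spikes FN.

    Inputs are frame-index lists; a SpikeTrain or a boolean spike vector
    is converted to frame indices first.
    """
    from .timeseries import SpikeTrain

    if isinstance(detected_frames, SpikeTrain):
        det = detected_frames.spike_frames
    else:
        det = np.asarray(detected_frames)
        if det.dtype == bool:
            det = np.flatnonzero(det)
    det = np.sort(det.astype(int))
    tru = np.sort(np.asarray(truth_frames, dtype=int))
    if tolerance_frames < 0:
        raise ValueError("tolerance_frames must be >= 0")

    i = j = tp = 0
    while i < len(tru) and j < len(det):
        if abs(det[j] - tru[i]) <= tolerance_frames:
            tp += 1
            i += 1
            j += 1
        elif det[j] < tru[i] - tolerance_frames:
            j += 1
        else:
            i += 1
    return MatchCounts(
        P=len(tru),
        TP=tp,
        FP=len(det) - tp,
        FN=len(tru) - tp,
    )
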