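"""End-to-end pipeline: load -> segment -> traces -> spikes -> network -> export.

Each stage writes its result as CSV into the output directory, so the
stages can also be run (and inspected) independently; the CSVs are the
inter-stage contract.  The run is deterministic: identical inputs and
configuration give byte-identical outputs, and the resolved configuration
is echoed alongside them.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np

from . import io as cio
from . import network as cnet
from . import segmentation as cseg
from . import timeseries as cts
from .config import RunConfig

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger("caflux")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage(name):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %-12s done in %.3f s", name, time.perf_counter() - t0)
            return result

        return wrapped

    return decorator


@_stage("load")
def _load(config: RunConfig, stack):
    if stack is not None:
        return stack
    if config.video:
        return cio.load_video(config.video, fps_override=config.fps, um_per_px=config.um_per_px)
    if not config.frames:
        raise ValueError("config provides neither frames nor video")
    return cio.load_stack(list(config.frames), fps=config.fps, um_per_px=config.um_per_px)


def run_pipeline(config: RunConfig, stack=None, out_dir: str | Path | None = None) -> Path:
    """Run every stage and write the artifact directory.

    ``stack`` may be passed directly (e.g. a synthetic movie) to bypass
    file loading.  Returns the output directory path.  A movie in which
    no ROI survives segmentation still succeeds: downstream tables are
    written empty and a warning is logged.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))

        stack = _load(config, stack)

        rois = _segment(config, stack)
        cio.write_rois_csv(rois, out / "rois.csv")
        cio.write_label_mask(rois, out / "mask.tiff", shape=stack.shape)
        if len(rois) == 0:
            logger.warning("no ROIs detected; writing empty downstream tables")
            _write_empty(out)
            return out

        traces = _traces(stack, rois)
        cio.write_traces_csv(traces, out / "traces.csv")
        rates = {rid: cts.rate_of_change(b) for rid, b in traces.items()}
        cio.write_traces_csv(rates, out / "rates.csv")

        trains = _spikes(config, rates)
        cio.write_spikes_csv({rid: t.s for rid, t in trains.items()}, out / "spikes.csv")

        kept = cts.filter_active(trains.values(), config.spikes.min_spikes)
        kept_trains = {t.roi_id: t for t in kept}
        logger.info("%d/%d ROIs pass the min-spike filter", len(kept), len(trains))

        table, graph = _network(config, stack, rois, traces, rates, kept_trains)
        if table is not None:
            cio.write_correlations_csv(table, out / "correlations.csv")
        else:
            (out / "correlations.csv").write_text("roi_a,roi_b,lag,correlation\n")
        cio.write_edges_csv(graph.edges, out / "edges.csv")
        cio.write_adjacency_csv(graph.adjacency_matrix(), graph.roi_ids, out / "adjacency.csv")
        logger.info("network: %d ROIs, %d edges", len(graph.roi_ids), len(graph.edges))
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()


@_stage("segment")
def _segment(config: RunConfig, stack):
    return cseg.detect_rois(stack, config.reference_frame, config.segmentation)


@_stage("traces")
def _traces(stack, rois):
    return cts.extract_traces(stack, rois)


@_stage("spikes")
def _spikes(config: RunConfig, rates):
    trains = {}
    for rid, r in rates.items():
        train, _ = cts.detect_spikes(r, config.spikes, roi_id=rid)
        trains[rid] = train
    return trains


@_stage("network")
def _network(config: RunConfig, stack, rois, traces, rates, trains):
    signal = config.correlation.signal
    if signal == "b":
        signals = traces
    elif signal == "r":
        signals = rates
    else:
        signals = trains
    kept_rois = cseg.ROISet([r for r in rois if r.id in signals], shape=rois.shape)
    table = None
    if len(signals) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # silent (constant) ROIs score 0
            table = cnet.correlation_table(signals, config.correlation)
    graph = cnet.reconstruct_network(
        kept_rois,
        signals,
        config.network,
        fps=stack.fps,
        um_per_px=stack.um_per_px,
        spec=config.correlation,
    )
    return table, graph


def _write_empty(out: Path) -> None:
    (out / "traces.csv").write_text("frame\n")
    (out / "rates.csv").write_text("frame\n")
    (out / "spikes.csv").write_text("frame\n")
    (out / "correlations.csv").write_text("roi_a,roi_b,lag,correlation\n")
    (out / "edges.csv").write_text("source_roi,target_roi,best_lag,correlation,distance_um,delay_s\n")
    (out / "adjacency.csv").write_text("roi\n")
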