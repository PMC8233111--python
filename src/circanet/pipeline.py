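"""End-to-end orchestration of the analysis stages.

``RunConfig`` carries every numeric parameter of the pipeline with its
standard defaults (7.5-SD artifact threshold, 0.9-s buffers, 1.5-40 Hz artifact band,
0.5-55 Hz connectivity band, 500 permutation iterations at the 95th
percentile, 11,000-epoch x 1,000-iteration state bootstrap, 300-s windows in
30-s steps, 10-200-s stability windows, 5-point minute bins, 11:00-13:00 vs
23:00-01:00 day/night pools) plus a reduced "demo" profile for quick runs.
``run_pipeline`` executes preprocess -> connectivity -> aggregation ->
graphs -> states -> circadian on one recording and writes CSV/JSON artifacts
plus a parameter echo.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate, circadian, connectivity, graphs, states
from .hypnogram import Hypnogram
from .io import dump_json
from .preprocess import preprocess
from .recording import Recording

logger = logging.getLogger("circanet")


@dataclass
class RunConfig:
    """All stage parameters with the pipeline's standard defaults."""

    artifact_threshold_sd: float = 7.5
    artifact_buffer_s: float = 0.9
    artifact_band: tuple = (1.5, 40.0)
    connectivity_band: tuple = (0.5, 55.0)
    rereference: bool = True
    max_lag_ms: float = 200.0
    null_iters: int = 500
    alpha_percentile: float = 95.0
    n_samp: int = 11_000
    n_boot: int = 1_000
    window_s: int = 300
    step_s: int = 30
    stability_sizes: tuple = (10, 30, 60, 120, 200)
    min_bin_count: int = 5
    day_minutes: tuple = circadian.DAY_MINUTES
    night_minutes: tuple = circadian.NIGHT_MINUTES
    circadian_n_boot: int = 1000
    seed: int = 0

    @classmethod
    def demo(cls, **overrides) -> "RunConfig":
        """Reduced-scale profile for quick end-to-end runs."""
        cfg = cls(null_iters=200, n_samp=1000, n_boot=100, circadian_n_boot=500)
        return replace(cfg, **overrides)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class PipelineResult:
    """Everything the pipeline computed for one recording."""

    tensor: connectivity.EpochTensor
    series: aggregate.NetworkSeries
    Q_w: np.ndarray | None
    Q_s: np.ndarray | None
    metrics: dict
    state_model: states.StateModel | None
    state_labels: states.StateLabels | None
    stability: dict
    circadian_timecourses: pd.DataFrame
    day_night: dict
    config: RunConfig = field(default_factory=RunConfig)


def run_pipeline(recording: Recording, hypnogram: Hypnogram,
                 config: RunConfig | None = None,
                 outdir=None) -> PipelineResult:
    """Run every stage on one recording; optionally write artifacts."""
    cfg = config or RunConfig()
    logger.info("pipeline config: %s", asdict(cfg))
    t0 = time.time()

    epochs = preprocess(recording, rereference=cfg.rereference)
    logger.info("preprocess: %d/%d valid epochs (%.1fs)",
                epochs.n_valid, epochs.n_epochs, time.time() - t0)

    max_lag = int(round(cfg.max_lag_ms / 1000.0 * epochs.fs))
    nulls = connectivity.build_all_nulls(
        epochs, n_iter=cfg.null_iters, seed=cfg.seed, max_lag=max_lag,
        percentile=cfg.alpha_percentile)
    tensor = connectivity.epoch_networks(epochs, nulls, max_lag=max_lag)
    logger.info("connectivity: %d pairs x %d epochs (%.1fs)",
                tensor.n_pairs, tensor.n_epochs, time.time() - t0)

    n_w, n_s = tensor.state_counts(hypnogram)
    Q_w = Q_s = None
    metrics = {}
    if n_w > 0 and n_s > 0:
        Q_w = aggregate.state_average(tensor, hypnogram, "wake",
                                      n_samp=cfg.n_samp, n_boot=cfg.n_boot,
                                      seed=cfg.seed)
        Q_s = aggregate.state_average(tensor, hypnogram, "sleep",
                                      n_samp=cfg.n_samp, n_boot=cfg.n_boot,
                                      seed=cfg.seed)
        for name, W in (("wake", Q_w), ("sleep", Q_s)):
            gm = graphs.graph_metrics(W)
            metrics[name] = {
                "strength_top10": aggregate.proportional_strength(W, 0.10),
                "mean_strength": aggregate.proportional_strength(W, 1.0),
                "mean_degree": gm.mean_degree,
                "mean_clustering": gm.mean_clustering,
                "char_path_length": gm.char_path_length,
            }

    series = aggregate.windowed_series(tensor, window_s=cfg.window_s,
                                       step_s=cfg.step_s)

    state_model = state_labels = None
    if series.usable.sum() >= 10:
        state_model, state_labels = states.decompose_states(
            series, hypnogram=hypnogram, seed=cfg.seed)

    stability = {}
    for st, n_state in (("wake", n_w), ("sleep", n_s)):
        if n_state >= 2 * min(cfg.stability_sizes):
            stability[st] = aggregate.stability_curve(
                tensor, hypnogram, st, sizes=cfg.stability_sizes)

    tcs = []
    for metric in circadian.METRICS:
        tc = circadian.metric_timecourse(series, hypnogram, metric,
                                         clock_start=recording.clock_start)
        tcs.append(tc)
    timecourses = pd.concat(tcs, ignore_index=True) if tcs else pd.DataFrame()

    day_night = {}
    for st in ("wake", "sleep"):
        for metric in circadian.METRICS:
            sub = timecourses[timecourses["metric"] == metric]
            day, night = circadian.select_pools(
                sub, st, day=cfg.day_minutes, night=cfg.night_minutes,
                window_s=cfg.window_s)
            if len(day) and len(night):
                day_night[(st, metric)] = circadian.day_night_test(
                    day, night, n_boot=cfg.circadian_n_boot, seed=cfg.seed)

    result = PipelineResult(tensor=tensor, series=series, Q_w=Q_w, Q_s=Q_s,
                            metrics=metrics, state_model=state_model,
                            state_labels=state_labels, stability=stability,
                            circadian_timecourses=timecourses,
                            day_night=day_night, config=cfg)
    logger.info("pipeline done in %.1fs", time.time() - t0)
    if outdir is not None:
        write_artifacts(result, recording, outdir)
    return result


def _network_frame(W: np.ndarray, labels: list) -> pd.DataFrame:
    return pd.DataFrame(W, index=labels, columns=labels)


def write_artifacts(result: PipelineResult, recording: Recording, outdir) -> None:
    """Persist the pipeline outputs as CSV/JSON under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    labels = result.tensor.labels
    dump_json(asdict(result.config), out / "config_echo.json")
    result.tensor.index_frame().to_csv(out / "tensor_index.csv", index=False)
    if result.Q_w is not None:
        _network_frame(result.Q_w, labels).to_csv(out / "network_wake.csv")
        _network_frame(result.Q_s, labels).to_csv(out / "network_sleep.csv")
        dump_json(result.metrics, out / "graph_metrics.json")
    result.series.to_frame().to_csv(out / "windowed_series.csv", index=False)
    if result.state_model is not None:
        dump_json(result.state_model.to_dict(), out / "state_model.json")
    if result.state_labels is not None:
        result.state_labels.frame.to_csv(out / "state_labels.csv", index=False)
        dump_json({"correspondence_pct": result.state_labels.correspondence_pct},
                  out / "state_correspondence.json")
    if result.stability:
        rows = [{"state": st, "window_s": n, "mean_corr": v}
                for st, curve in result.stability.items()
                for n, v in curve.items()]
        pd.DataFrame(rows).to_csv(out / "stability.csv", index=False)
    if not result.circadian_timecourses.empty:
        result.circadian_timecourses.to_csv(out / "circadian_timecourses.csv",
                                            index=False)
        profile = circadian.build_profile(result.circadian_timecourses,
                                          min_count=result.config.min_bin_count)
        profile.to_csv(out / "circadian_profile.csv", index=False)
    if result.day_night:
        dump_json({f"{st}_{metric}": vars(t)
                   for (st, metric), t in result.day_night.items()},
                  out / "day_night_tests.json")
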