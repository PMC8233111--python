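"""Shared synthetic cohort for the analysis scripts.

Simulates a small cohort of subjects (4-channel, 6-hr recordings with
staggered wall-clock start times so the group covers the full 24-hr clock),
runs preprocessing and per-epoch connectivity once per subject, and caches
the binary tensors under scratch/ so the numbered scripts can be re-run
cheaply and in any order.
"""

from __future__ import annotations

import pickle
from datetime import datetime
from pathlib import Path

from circanet import connectivity, preprocess, simdata

SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "cohort"
RESULTS = Path(__file__).resolve().parent.parent / "results"

N_SUBJECTS = 6
N_CHANNELS = 4
FS = 125.0
DURATION_S = 6 * 3600
NULL_ITERS = 200
SEED = 2024


def subject_config(k: int) -> simdata.SimulationConfig:
    """Subject k's generator settings; clock starts staggered by 4 hours."""
    return simdata.SimulationConfig(
        n_channels=N_CHANNELS, fs=FS, duration=DURATION_S,
        clock_start=datetime(2018, 1, 1, (8 + 4 * k) % 24, 0),
        seed=SEED + k, bout_mean_wake=1800, bout_mean_sleep=1800,
        circadian_amplitude=0.3, artifact_rate=2.0)


def load_subject(k: int) -> dict:
    """Simulate/analyze subject k, or load the cached result."""
    SCRATCH.mkdir(parents=True, exist_ok=True)
    cache = SCRATCH / f"subject_{k:02d}.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    cfg = subject_config(k)
    schedule = simdata.generate_schedule(cfg)
    recording, truth = simdata.generate_recording(cfg, schedule)
    epochs = preprocess.preprocess(recording, rereference=False)
    nulls = connectivity.build_all_nulls(epochs, n_iter=NULL_ITERS,
                                         seed=cfg.seed)
    tensor = connectivity.epoch_networks(epochs, nulls)
    subject = {"k": k, "config": cfg, "schedule": schedule, "truth": truth,
               "clock_start": cfg.clock_start, "tensor": tensor,
               "n_valid": int(tensor.valid.sum())}
    with open(cache, "wb") as fh:
        pickle.dump(subject, fh)
    return subject


def load_cohort() -> list:
    return [load_subject(k) for k in range(N_SUBJECTS)]
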