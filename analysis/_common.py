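"""Shared helpers for the numbered analysis drivers.

The synthetic cohort is fully determined by its seed, so each driver
regenerates the recordings it needs instead of shuttling hundreds of
megabytes of time series between steps; only compact result tables are
written under results/.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from nirsconn import connectivity as conn
from nirsconn import preprocess as pp
from nirsconn import synthetic_data as sd

RESULTS = Path(__file__).resolve().parents[1] / "results"


def parse_args(description, **extra):
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=17)
    for name, kwargs in extra.items():
        parser.add_argument(f"--{name}", **kwargs)
    return parser.parse_args()


def default_cohort(seed):
    cfg = sd.SimulationConfig(seed=seed)
    subjects, truth = sd.simulate_cohort(cfg)
    return cfg, subjects, truth


def preprocessed_resting(subjects, config=None):
    config = config or pp.PreprocessConfig()
    return {s.subject_id: pp.preprocess_recording(s.resting, config)
            for s in subjects}


def subject_matrices(series_by_id, subjects):
    mats = {g: [] for g in sd.GROUPS}
    by_id = {}
    for s in subjects:
        m = conn.whole_brain_matrix(series_by_id[s.subject_id])
        mats[s.group].append(m)
        by_id[s.subject_id] = m
    return mats, by_id


def outdir(name):
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
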