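"""End-to-end orchestration: simulate -> preprocess -> localize -> connect
-> graph -> stats, with one root seed and a machine-readable report.

The report is a plain dict (JSON-serializable) with one section per
analysis stage plus a QC log; rerunning with the same configuration and
seed reproduces it exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import graph_metrics as gm
from . import group_stats as gs
from . import localizer_glm as lg
from . import preprocess as pp
from . import synthetic_data as sd
from .errors import NoSeedError, QCError

log = logging.getLogger("nirsconn")


@dataclass
class PipelineConfig:
    simulation: sd.SimulationConfig = field(default_factory=sd.SimulationConfig)
    preprocessing: pp.PreprocessConfig = field(default_factory=pp.PreprocessConfig)
    localizer_alpha: float = 0.05
    s_grid_step: float = 0.01
    sweep_fdr_q: float = 0.05
    regression_fdr_q: float = 0.10
    n_rewires: int = 100
    normalized_s_step: float = 0.05  # grid for the rewiring-based curves

    def s_grid(self) -> np.ndarray:
        return np.round(np.arange(self.s_grid_step, 1.0 + 1e-9,
                                  self.s_grid_step), 10)

    def normalized_s_grid(self) -> np.ndarray:
        return np.round(np.arange(self.normalized_s_step, 1.0 + 1e-9,
                                  self.normalized_s_step), 10)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = sd.SimulationConfig(**raw.get("simulation", {}))
        pre = pp.PreprocessConfig(**raw.get("preprocessing", {}))
        extra = {k: v for k, v in raw.items()
                 if k not in ("simulation", "preprocessing")}
        return cls(simulation=sim, preprocessing=pre, **extra)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def run_pipeline(config: PipelineConfig | None = None,
                 seed: int | None = None,
                 out_dir=None) -> dict:
    """Execute the four analysis stages on a simulated cohort.

    Stage order: (1) interhemispheric correlations, (2) seed-based and
    whole-brain correlation analyses, (3) graph-theory network analysis,
    (4) linear regression of anxiety on seed connectivity.  Returns the
    report dict; with ``out_dir`` it is also written as ``report.json``.
    """
    config = config or PipelineConfig()
    if seed is not None:
        config.simulation.seed = int(seed)
    sim = config.simulation
    montage = sim.montage
    report = {"config": {"seed": sim.seed,
                         "n_hd": sim.n_hd, "n_cg": sim.n_cg,
                         "s_grid_step": config.s_grid_step,
                         "localizer_alpha": config.localizer_alpha},
              "qc": {"excluded_channels": {}, "notes": []}}

    log.info("simulating cohort (seed=%d)", sim.seed)
    subjects, truth = sd.simulate_cohort(sim)
    meta = sd.metadata_table(subjects)

    log.info("preprocessing %d subjects", len(subjects))
    rest_series, task_series = {}, {}
    for s in subjects:
        rest = pp.preprocess_recording(s.resting, config.preprocessing)
        task = pp.preprocess_recording(s.task, config.preprocessing)
        rest_series[s.subject_id], task_series[s.subject_id] = rest, task
        excluded = [rest.channel_ids[i] for i in range(rest.n_channels)
                    if not rest.valid_channels[i]]
        if excluded:
            report["qc"]["excluded_channels"][s.subject_id] = excluded

    # --- stage: localizer -> seeds -------------------------------------
    log.info("stage localizer: per-channel GLM on the task session")
    betas = []
    for s in subjects:
        ts = task_series[s.subject_id]
        trimmed_events = pp.trim_initial(
            s.task, trim_rest_s=config.preprocessing.trim_rest_s,
            trim_task_s=config.preprocessing.trim_task_s).events
        X, names = lg.build_design_matrix(
            trimmed_events, ts.n_samples / ts.sampling_rate_hz,
            ts.sampling_rate_hz)
        X[:, 1:] = pp.filter_columns(X[:, 1:], ts.sampling_rate_hz,
                                     config.preprocessing.band_task_hz)
        act = lg.fit_glm(ts, X, names, normalize=False)
        row = {c: np.nan for c in montage.channel_ids}
        row.update({c: b for c, b in zip(act.channel_ids, act.beta)})
        betas.append([row[c] for c in montage.channel_ids])
    group_act = lg.group_activation(np.asarray(betas), montage.channel_ids)
    try:
        seeds = lg.select_seeds(group_act, montage, alpha=config.localizer_alpha)
    except NoSeedError:
        log.error("localizer found no significant channel; halting at stage 2")
        raise
    report["localizer"] = {
        "tstat": dict(zip(group_act.channel_ids, group_act.tstat)),
        "pvalue": dict(zip(group_act.channel_ids, group_act.pvalue)),
        "seeds_left": list(seeds.seeds_left),
        "seeds_right": list(seeds.seeds_right)}

    # --- stage 1: interhemispheric correlations ------------------------
    log.info("stage 1: interhemispheric correlations")
    inter = {g: [] for g in sd.GROUPS}
    for s in subjects:
        inter[s.group].append(
            conn.interhemispheric_correlation(rest_series[s.subject_id], montage))
    inter_tables = {g: conn.group_interhemispheric(v) for g, v in inter.items()}
    inter_tests = {}
    for sig in ("HbO", "Hb"):
        for roi in ("overall", "lOFC", "mOFC"):
            a = conn.subject_roi_values(inter["HD"], sig, roi)
            b = conn.subject_roi_values(inter["CG"], sig, roi)
            res = gs.welch_ttest(a[np.isfinite(a)], b[np.isfinite(b)],
                                 label=f"{sig}/{roi}")
            inter_tests[f"{sig}/{roi}"] = res.as_dict()
    report["interhemispheric"] = {
        "group_means": {g: t.reset_index().to_dict("records")
                        for g, t in inter_tables.items()},
        "group_tests": inter_tests}

    # --- stage 2: seed-based + whole-brain connectivity -----------------
    log.info("stage 2: seed-based and whole-brain correlation analyses")
    subj_mats = {g: [] for g in sd.GROUPS}
    for s in subjects:
        subj_mats[s.group].append(
            conn.whole_brain_matrix(rest_series[s.subject_id], "HbO"))
    group_mats = {g: conn.group_mean_matrix(m) for g, m in subj_mats.items()}
    seed_maps = {}
    for seed_ch in seeds.all_seeds():
        for g in sd.GROUPS:
            seed_maps[f"{g}/seed_{seed_ch}"] = conn.group_seed_map(
                subj_mats[g], seed_ch).to_dict()
    cg_graph = conn.threshold_absolute(group_mats["CG"], top_fraction=0.05)
    report["connectivity"] = {
        "group_matrices_r": {g: m.values_r for g, m in group_mats.items()},
        "seed_maps_z": seed_maps,
        "cg_top5_cutoff_edges": sorted(
            [ (group_mats["CG"].channel_labels[i],
               group_mats["CG"].channel_labels[j]) for i, j in cg_graph.edge_set()])}

    # --- stage 3: graph-theory network analysis -------------------------
    log.info("stage 3: graph metrics over the sparsity grid")
    sweep = gm.sparsity_sweep(group_mats, config.s_grid(), subj_mats,
                              fdr_q=config.sweep_fdr_q)
    norm = gm.normalized_curves(group_mats["HD"], group_mats["CG"],
                                config.normalized_s_grid(),
                                n_rewires=config.n_rewires,
                                seed=sim.seed + 1)
    strengths = pd.DataFrame(
        {s.subject_id: pd.Series(
            gm.nodal_strength(m).strength, index=m.channel_labels)
         for g in sd.GROUPS
         for s, m in zip([x for x in subjects if x.group == g], subj_mats[g])}).T
    groups_series = pd.Series({s.subject_id: s.group for s in subjects})
    strength_cmp = gs.compare_nodal_strength(strengths, groups_series)
    report["graph"] = {
        "group_curves": {g: c.reset_index().to_dict("records")
                         for g, c in sweep.group_curves.items()},
        "significant_ranges": sweep.significant_ranges,
        "normalized": {f"{mode}/{idx}": norm[(mode, idx)].to_dict()
                       for mode, idx in norm.columns},
        "nodal_strength_comparison": strength_cmp.reset_index().to_dict("records")}

    # --- stage 4: regression of anxiety on seed connectivity ------------
    log.info("stage 4: anxiety regression (FDR %g)", config.regression_fdr_q)
    cohort = meta.copy()
    all_mats = {s.subject_id: m for g in sd.GROUPS
                for s, m in zip([x for x in subjects if x.group == g], subj_mats[g])}
    regression = {}
    for seed_ch in (seeds.primary_left, seeds.primary_right):
        targets = [c for c in montage.channel_ids
                   if c not in (seed_ch,)]
        for t in targets:
            col = f"z_{seed_ch}_{t}"
            cohort[col] = [
                all_mats[sid].values_z[all_mats[sid].index_of(seed_ch),
                                       all_mats[sid].index_of(t)]
                for sid in cohort.index]
        table = gs.regress_anxiety_on_connectivity(
            cohort, seed_ch, targets, fdr_q=config.regression_fdr_q)
        regression[f"seed_{seed_ch}"] = table.reset_index().to_dict("records")
    report["regression"] = regression
    report["metadata"] = meta.reset_index().to_dict("records")
    report["ground_truth"] = {
        "anxiety_edge": list(truth.anxiety_edge),
        "true_anxiety_slope": truth.true_anxiety_slope,
        "subject_edge_z": truth.subject_edge_z}

    report = _jsonable(report)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1,
                                                    sort_keys=True))
        log.info("report written to %s", out / "report.json")
    return report


def report_hash(report: dict) -> str:
    import hashlib
    blob = json.dumps(report, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
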