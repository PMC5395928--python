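"""Fit the task GLM per channel and select the resting-state seed channels.

Per subject, HbO from the task session is regressed on the HRF-convolved
block regressor (band-pass matched to the data); subject betas are
combined by a one-sample t-test per channel, and the most significant
channel per hemisphere plus its partner forms the seed set.  Writes
results/localizer/group_tmap.tsv and seeds.json.
"""

import json

import numpy as np
import pandas as pd
from _common import default_cohort, outdir, parse_args

from nirsconn import localizer_glm as lg
from nirsconn import preprocess as pp


def main():
    args = parse_args(__doc__)
    cfg, subjects, _ = default_cohort(args.seed)
    pcfg = pp.PreprocessConfig()
    betas = []
    for s in subjects:
        ts = pp.preprocess_recording(s.task, pcfg)
        events = pp.trim_initial(s.task).events
        X, names = lg.build_design_matrix(events, ts.n_samples
                                          / ts.sampling_rate_hz,
                                          ts.sampling_rate_hz)
        X[:, 1:] = pp.filter_columns(X[:, 1:], ts.sampling_rate_hz,
                                     pcfg.band_task_hz)
        act = lg.fit_glm(ts, X, names)
        row = dict.fromkeys(cfg.montage.channel_ids, np.nan)
        row.update(dict(zip(act.channel_ids, act.beta)))
        betas.append([row[c] for c in cfg.montage.channel_ids])
    group = lg.group_activation(np.asarray(betas), cfg.montage.channel_ids)
    seeds = lg.select_seeds(group, cfg.montage)
    out = outdir("localizer")
    tmap = pd.DataFrame({"channel": group.channel_ids, "beta": group.beta,
                         "t": group.tstat, "p": group.pvalue}).set_index("channel")
    tmap.to_csv(out / "group_tmap.tsv", sep="\t")
    (out / "seeds.json").write_text(json.dumps(
        {"left": list(seeds.seeds_left), "right": list(seeds.seeds_right)},
        indent=1))
    print(tmap.round(4))
    print(f"\nseeds: left {seeds.seeds_left}, right {seeds.seeds_right} "
          f"(planted active channels: {cfg.task_active_channels})")
    print(f"wrote {out}/group_tmap.tsv and seeds.json")


if __name__ == "__main__":
    main()
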