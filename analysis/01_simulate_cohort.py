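"""Simulate the two-group resting/task cohort and record its ground truth.

Writes the per-subject metadata table and the planted parameters
(coupling matrices, anxiety edge and slope, artifact log) under
results/cohort/.  Recordings themselves are regenerated deterministically
by later steps from the same seed.
"""

import json

from _common import default_cohort, outdir, parse_args

from nirsconn import synthetic_data as sd


def main():
    args = parse_args(__doc__)
    cfg, subjects, truth = default_cohort(args.seed)
    out = outdir("cohort")
    meta = sd.metadata_table(subjects)
    meta.to_csv(out / "metadata.tsv", sep="\t")
    truth.to_json(out / "ground_truth.json")
    (out / "config.json").write_text(json.dumps(
        {"seed": cfg.seed, "n_hd": cfg.n_hd, "n_cg": cfg.n_cg,
         "duration_rest_s": cfg.duration_rest_s,
         "duration_task_s": cfg.duration_task_s,
         "interhemispheric_rho": cfg.interhemispheric_rho,
         "anxiety_link": [list(cfg.anxiety_link[0]), cfg.anxiety_link[1],
                          cfg.anxiety_link[2]]}, indent=1))
    print(f"cohort of {len(subjects)} subjects "
          f"({cfg.n_hd} HD, {cfg.n_cg} CG), seed {cfg.seed}")
    print(f"group STAI means: "
          f"HD {meta[meta.group == 'HD'].stai.mean():.1f}, "
          f"CG {meta[meta.group == 'CG'].stai.mean():.1f}")
    print(f"planted anxiety edge {truth.anxiety_edge} "
          f"slope {truth.true_anxiety_slope}")
    print(f"wrote {out}/metadata.tsv, ground_truth.json, config.json")


if __name__ == "__main__":
    main()
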