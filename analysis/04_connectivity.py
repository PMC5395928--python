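"""Interhemispheric, seed-based, and whole-brain connectivity of the cohort.

Writes the interhemispheric summary with group comparisons, the group
mean correlation matrices, the top-5% control-group network edges, and
the seed z-maps under results/connectivity/.
"""

import json

import numpy as np
import pandas as pd
from _common import (default_cohort, outdir, parse_args,
                     preprocessed_resting, subject_matrices)

from nirsconn import connectivity as conn
from nirsconn import group_stats as gs
from nirsconn import montage_io as mio
from nirsconn import synthetic_data as sd


def main():
    args = parse_args(__doc__)
    cfg, subjects, truth = default_cohort(args.seed)
    series = preprocessed_resting(subjects)
    out = outdir("connectivity")

    inter = {g: [] for g in sd.GROUPS}
    for s in subjects:
        inter[s.group].append(conn.interhemispheric_correlation(
            series[s.subject_id], cfg.montage))
    rows = []
    for sig in ("HbO", "Hb"):
        for roi in ("overall", "lOFC", "mOFC"):
            a = conn.subject_roi_values(inter["HD"], sig, roi)
            b = conn.subject_roi_values(inter["CG"], sig, roi)
            t = gs.welch_ttest(a[np.isfinite(a)], b[np.isfinite(b)])
            rows.append({"signal": sig, "roi": roi,
                         "hd_mean": np.nanmean(a), "cg_mean": np.nanmean(b),
                         "t": t.tstat, "p": t.pvalue})
    table = pd.DataFrame(rows)
    table.to_csv(out / "interhemispheric.tsv", sep="\t", index=False,
                 float_format="%.4f")

    mats, _ = subject_matrices(series, subjects)
    group_mats = {g: conn.group_mean_matrix(m) for g, m in mats.items()}
    for g, m in group_mats.items():
        mio.write_connectivity(m.values_r, out / f"group_{g}_r.tsv",
                               labels=m.channel_labels, mask=m.mask)
    cg_graph = conn.threshold_absolute(group_mats["CG"], top_fraction=0.05)
    edges = sorted((group_mats["CG"].channel_labels[i],
                    group_mats["CG"].channel_labels[j])
                   for i, j in cg_graph.edge_set())
    seed_maps = {f"seed_{s}": conn.group_seed_map(mats["HD"], s).round(4).to_dict()
                 for s in (11, 12, 4, 1)}
    (out / "seed_maps_hd.json").write_text(json.dumps(seed_maps, indent=1))
    (out / "cg_top5_edges.json").write_text(json.dumps(edges))

    print(table.round(3).to_string(index=False))
    planted = {g: cfg.interhemispheric_rho[g] for g in sd.GROUPS}
    print(f"\nplanted interhemispheric rho: {planted}")
    print(f"CG top-5% network keeps {cg_graph.n_edges} edges: {edges}")
    print(f"wrote tables under {out}")


if __name__ == "__main__":
    main()
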