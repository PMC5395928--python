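# nirsconn

Resting-state functional connectivity of the orbitofrontal cortex (OFC)
from functional near-infrared spectroscopy (fNIRS), built as a tested,
end-to-end analysis pipeline and exercised on synthetic two-group cohorts
(8 heroin-dependent subjects vs 7 controls) with known ground truth.

The pipeline covers, in order:

1. **Preprocessing** — two-wavelength optical density (690/830 nm, 50 Hz,
   12 channels over the OFC at 30 mm source-detector separation) is
   converted to oxy-/deoxyhemoglobin concentration changes via the
   modified Beer-Lambert law `ΔOD_λ = (ε_λ,HbO ΔHbO + ε_λ,Hb ΔHb)·L·DPF_λ`,
   then trimmed, band-passed (rest: 0.01–0.1 Hz; task: 0.012–0.18 Hz),
   detrended, motion-corrected by spline interpolation and by
   correlation-based signal improvement (CBSI:
   `HbO′ = (HbO − α·Hb)/2`, `Hb′ = −HbO′/α`, `α = sd(HbO)/sd(Hb)`), and
   screened by a channel SNR rule.
2. **Task localizer** — a per-channel GLM with a canonical double-gamma
   HRF selects the most significantly activated channel per hemisphere
   (plus its partner channel) as resting-state seeds.
3. **Connectivity** — interhemispheric correlations between mirrored
   channel pairs, seed-based maps, and whole-brain 12×12 Pearson
   matrices; all correlations are Fisher-transformed (`z = arctanh r`)
   before statistics, and group matrices are subject averages in z-space.
4. **Graph topology** — matrices are thresholded into binary graphs over
   the full sparsity range `S` (keep the `round(S·N(N−1)/2)` strongest
   edges, or an absolute rule such as the top 5% of connections);
   clustering coefficient `Cp`, characteristic path length `Lp`, local and
   global efficiency `Eloc`, `Eglob` are profiled per threshold, with
   group comparisons FDR-controlled over the sweep.  Small-world indices
   `γ, λ, γE, λE` and `sw = γ/λ` are computed against two references:
   degree-preserving random rewirings (traditional) or the control group's
   network at the same sparsity (group-referenced).
5. **Group statistics** — Welch two-sample tests for demographics and
   nodal strength, and the anxiety regression
   `STAI ~ z(seed, target) + age + IQ + education + cigarettes`
   with Benjamini–Hochberg control at FDR 10% over the target family.

Who it is for: researchers analyzing optical neuroimaging connectivity
who want a small, fully reproducible reference implementation of this
workflow, with a generator that plants known effects (interhemispheric
coupling difference, task activations, an anxiety–connectivity slope) so
every stage can be validated by parameter recovery.

## Worked example

```bash
cd analysis
python 01_simulate_cohort.py --seed 17
python 03_localize_seeds.py  --seed 17
python 04_connectivity.py    --seed 17
python 06_anxiety_regression.py --seed 17
```

prints (abridged, actual output):

```
cohort of 15 subjects (8 HD, 7 CG), seed 17
planted anxiety edge (11, 6) slope 20.0

seeds: left (11, 12), right (4, 1) (planted active channels: (4, 11))

planted interhemispheric rho: {'HD': 0.85, 'CG': 0.6}
CG top-5% network keeps 3 edges: [(1, 12), (2, 11), (6, 7)]

planted edge (11,6) slope 20.0: estimate 18.64 +- 7.67 (q=0.418)
nodal strength: 12/12 channels differ between groups at p<0.05
```

Reading this: the localizer recovered exactly the planted active
channels with their partners; the interhemispheric group contrast
(planted 0.85 vs 0.60) drives strongly significant group tests (the
`04` table); the top-5% rule keeps `floor(0.05·66) = 3` edges and finds
the strongest mirrored pairs.  The anxiety slope estimate (18.6 ± 7.7
against a planted 20) is within one standard error, while its FDR
q-value in this single cohort is not below 0.1 — with n = 15 and five
regressors, single-cohort FDR detection has roughly 60% power, and the
decisive check is the replicate-combined evidence computed by the
acceptance script and test suite (combined q ≈ 1e-18 over six cohorts).

The same run is available as one command (`nirsconn run --out run_dir
--seed 17`), which writes a machine-readable `report.json` covering all
four analysis stages plus a QC log.

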