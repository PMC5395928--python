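# Methods

This note documents the models, parameter choices and numerical decisions
behind `nirsconn`, and what the synthetic-cohort experiments do and do not
demonstrate.

## Probe model

Twelve measurement channels cover the orbitofrontal cortex: channels 1–4
right lateral OFC, 5–6 right medial OFC, 7–8 left medial OFC, 9–12 left
lateral OFC, at 30 mm source-detector separation and 50 Hz sampling with
two wavelengths (690, 830 nm).  The optode layout is mirror-symmetric
about the midline; since no explicit pairing table exists, the geometric
mirror is used: {1↔12, 2↔11, 3↔10, 4↔9, 5↔8, 6↔7}.  Channel labels are
1-based externally and converted to 0-based indices only at the I/O
boundary.  A separate within-hemisphere *partner* table (11↔12, 4↔1, and
the analogous adjacent pairs) governs how a localizer seed is paired with
its companion channel; it is configurable.

## Optical model

The modified Beer-Lambert inversion uses literature molar extinction
coefficients (cm⁻¹/mM): 690 nm → (0.2762, 2.0520) and 830 nm →
(0.9740, 0.6930) for (HbO, Hb), a differential pathlength factor of 6.0
at both wavelengths, and the 30 mm geometric pathlength.  Concentrations
are expressed in micromolar.  The 2×2 system is solved exactly per
sample; its condition number (~3) is checked and a singular extinction
table is rejected.  The forward model in the simulator uses the same
matrix, so forward-then-inverse is exact to machine precision.

## Preprocessing chain

Fixed order for resting data: trim the first 120 s (30 s for task) →
MBLL → zero-phase band-pass → linear detrend → spline motion correction →
CBSI → channel QC.  Each step appends itself with parameters to the
series' provenance list.

* **Band-pass**: 4th-order Butterworth applied forward-backward
  (`sosfiltfilt`), rest band 0.01–0.1 Hz, task band 0.012–0.18 Hz.
  Zero-phase filtering preserves inter-channel correlation structure,
  which is the analysis target.
* **Spline motion correction**: samples are flagged when their amplitude
  exceeds 5 robust (MAD-based) standard deviations of the channel, or
  when the first difference exceeds 5 robust standard deviations of the
  differenced series; flags are padded by 0.25 s and merged across gaps
  under 0.5 s.  Flagged segments are rebuilt with a shape-preserving
  (PCHIP) spline through the surrounding samples, and the baseline offset
  across each segment is subtracted from the remainder of the series so
  step artifacts do not persist.  If flags cover more than half a
  channel, the recording is rejected.  Note the chain order places this
  step after the band-pass, where raw spikes have already been strongly
  attenuated; the step is most effective on unfiltered series and is
  unit-tested there.
* **CBSI**: with α = sd(HbO)/sd(Hb) per channel, HbO′ = (HbO − α·Hb)/2
  and Hb′ = −HbO′/α.  By construction corr(HbO′, Hb′) = −1; a consequence
  worth noting is that after CBSI the Hb channel carries no information
  beyond HbO (all Hb-based correlations equal the HbO-based ones).
  Analyses that need an independent Hb reference should run the chain
  with `motion="spline"`.  Whether CBSI applies to resting data, task
  data, or both is configurable (`motion` ∈ {spline, cbsi, both, none});
  the default applies both steps to all sessions.
* **Channel QC**: signal intensity is the temporal standard deviation per
  channel.  A channel is masked when its intensity lies more than k = 5
  standard deviations below the mean intensity of the *other* channels
  (leave-one-out), for HbO or Hb.  The leave-one-out form is required for
  the rule to behave sensibly: a dead channel inflates the pooled spread
  enough that a plain z-score never reaches −5.  Masks propagate: masked
  channels appear as NA rows/columns in matrices, their mirror pairs drop
  out of interhemispheric aggregates, and group averages use the
  available subjects.

## Connectivity

Subject-level matrices are pairwise Pearson correlations of the
preprocessed HbO series (Hb supported as a reference signal).  All
statistics operate on Fisher z = arctanh(r); degenerate |r| ≈ 1 edges are
capped at r = 0.9999 with a warning.  Group matrices are the mean of
subject z-matrices (variance-stabilized averaging), back-transformed for
display.  Thresholding keeps positive correlations only.  Two rules:
an absolute cutoff (r > r*) or top fraction (floor(q·N(N−1)/2) strongest
edges), and a relative sparsity S (round(S·N(N−1)/2) strongest edges).
Ties break by ascending channel-pair order, making edge sets nested
across S.

## Graph metrics

Binary graphs at every threshold.  Cp is the mean local clustering
(degree < 2 nodes contribute 0); Lp averages shortest-path lengths over
*reachable* ordered pairs (the disconnected-pair fraction is reported
separately), which keeps Lp finite across the whole sparsity range while
Eglob = mean 1/d handles disconnection natively.  Eloc is the mean global
efficiency of each node's neighborhood subgraph.  Note that under nested
edge growth Eglob is monotone but Cp is not (a triangle gaining a pendant
edge drops from 1 to 7/12), so only the former is asserted as an
invariant.  The random reference uses 100 degree-preserving double-edge
swaps per graph (10× the edge count of swap attempts), seeded.  The
normalized indices γ, λ, γE, λE divide a target group's metrics either by
the rewired-null means (traditional) or by the control group's metrics at
the same sparsity (group-referenced); sw = γ/λ.  The sparsity sweep
compares groups per threshold with Welch t-tests across subjects and
controls the sweep at FDR 5% (Benjamini–Hochberg), distinct from the
regression module's 10% rule.

## Group statistics

Demographic comparisons use Welch's unequal-variance t-test, which
reproduces the published anxiety p-value (0.047) where the pooled-variance
form gives ≈ 0.052; the test accepts printed (mean, sd, n) summaries
directly.  The anxiety regression pools both groups into one sample
(matching a single population-level fit with group markers) and reports
the connectivity coefficient per target channel with BH-FDR at 10%; a
group main effect is available via `group_term=True`.  Methadone dose is
defined for the HD group only and is an optional covariate.  Nodal
strength (mean off-diagonal correlation per channel) is compared per
channel with Welch tests and the usual significance tiers (* p<0.05 to
**** p<0.0001).

## Synthetic cohorts

The generator's defaults are the study conditions: 8 vs 7 subjects, 660 s
resting and 180 s task recordings at 50 Hz, twelve channels, covariates
drawn from the published group means and standard deviations (truncated
to plausible ranges).

* **Latent signals.** Channels share unit-variance Gaussian signals
  restricted to 0.01–0.1 Hz, synthesized spectrally (independent complex
  Fourier coefficients on in-band bins).  Spectral synthesis is used
  instead of time-domain Butterworth filtering because the latter's
  ~100 s impulse response produces edge transients that triple the
  sampling error of correlation estimates at these durations.  Latents
  are mixed through the eigendecomposition square root of the target
  correlation matrix, making planted correlations analytic.
* **Coupling structure.** Group target matrices are built from three
  levels — baseline 0.55/0.35, within-ROI 0.70/0.50, and mirrored-pair
  (interhemispheric) 0.85/0.60 for the two groups — chosen to reproduce
  the reported interhemispheric contrast while keeping the matrix
  positive semidefinite.  Mirror couplings get per-subject Gaussian
  jitter (sd 0.05).  The anxiety-linked edge (11, 6) is drawn per subject
  from Uniform(0.10, 0.90): wide individual variation is what makes the
  covariate-adjusted regression of anxiety on that edge well conditioned
  at n = 15.  Perturbed matrices are projected to the nearest correlation
  matrix (alternating eigenvalue clipping / unit-diagonal), and the
  *projected* matrix is what the ground truth records; note the
  projection geometrically caps how far a single edge can stray from a
  strongly coupled neighborhood.
* **Hemoglobin and nuisance structure.** Hb = −HbO/3 plus independent
  band-limited noise at 15% of the HbO scale, giving Hb-based
  correlations attenuated relative to HbO as observed empirically.
  Physiological oscillations (cardiac ~1.1 Hz amplitude 0.2 µM,
  respiratory ~0.3 Hz 0.1 µM, Mayer ~0.095 Hz 0.05 µM, random phase per
  channel), white optical-density noise (sd 5·10⁻⁴), and Poisson motion
  events at 0.5/min (70% spikes of 5–15× the OD scale and ≤ 1 s, 30%
  baseline steps of 0.5–1.5×, hitting all channels) complete the model.
  HbO fluctuation scale is 0.5 µM.
* **Anxiety.** STAI = 70 + 20·z(edge) + 0.2·(cigarettes − 21) + N(0, 5),
  truncated to [40, 160]; slope and noise are configurable through
  `anxiety_link`.  The covariate effect sits on a *modeled* covariate so
  the adjusted regression removes it.
* **Task.** Three 15 s blocks at 40/85/130 s; active channels (default 4
  and 11) carry the HRF-convolved boxcar at 2 µM amplitude.
* **Determinism.** Every random stream derives from
  (seed, stream id, CRC32(subject id)); identical seeds reproduce
  cohorts bit-for-bit.

### What the synthetic experiments show — and what they do not

Passing recovery tests shows the pipeline correctly extracts planted
correlation structure, task activations, and anxiety–connectivity slopes
under realistic noise, motion and physiology at the study's sample sizes.
The generator does not emulate optics-level photon transport, anatomical
variability, scalp/superficial contamination, serially correlated
sensor drift, or group differences in *topology*: the default groups
differ in coupling level (which drives the interhemispheric, strength and
edge-count contrasts) but share the same ranking structure, so sparsity
thresholded graphs of the two default groups are similar and the sweep's
group tests are exercised instead with explicitly modular configurations.
Real-data effect sizes and artifact statistics may differ from these
choices.

## Problem sizes and statistical formulations

Monte-Carlo checks run at the study's own scale (n = 8 vs 7, 660 s
recordings): 50 replicate cohorts for detection/type-I rates and 12 for
slope recovery in the test suite, 25/6 in the acceptance script.  At
these sizes the single-cohort FDR detection of the planted anxiety slope
has ≈ 60% power (measured over 30 replicates), an intrinsic consequence
of slope 20/noise 5/df 9 and the geometric cap on single-edge variance;
the suite therefore asserts per-cohort estimate accuracy (within 2 SE)
plus replicate-combined significance (Stouffer over cohorts, BH over the
11-target family), and separately that null slopes stay non-significant
per cohort.

## Known limitations

* SNIRF support covers the amplitude/OD time-series layout this pipeline
  writes and reads (one data block, per-channel measurement lists); it is
  not a general-purpose SNIRF validator.
* Weighted graph metrics, partial correlations, dynamic connectivity and
  modularity analyses are out of scope.
* The GLM uses OLS with i.i.d. errors; single-subject t-values are
  anti-conservative under autocorrelated noise, which is why seed
  selection operates on the across-subject distribution of betas rather
  than single-subject t-maps.
* After CBSI, Hb duplicates HbO (see above); run `motion="spline"` when
  an independent Hb analysis is required.
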