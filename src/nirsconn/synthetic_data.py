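"""Synthetic two-group fNIRS cohorts with known ground truth.

The generator emulates the study conditions end to end: two groups (8
heroin-dependent, 7 control subjects), an 11-minute resting recording and a
~3-minute task recording per subject at 50 Hz, twelve channels over the
orbitofrontal cortex at two wavelengths.

Resting model: channels share band-limited (0.01-0.1 Hz) latent Gaussian
fluctuations mixed through the matrix square root of a target correlation
matrix, so the planted inter-channel correlation structure is analytic.
Deoxyhemoglobin is an attenuated, inverted copy of HbO plus independent
band-limited noise.  Physiological oscillations (cardiac ~1.1 Hz,
respiratory ~0.3 Hz, Mayer ~0.095 Hz), white sensor noise, and
Poisson-placed spike/step motion artifacts are added on top.
Concentrations are mapped to optical density through the same extinction
model the preprocessing chain inverts.

Anxiety scores are linearly tied to the Fisher-z value of one planted
connectivity edge, so the downstream regression is a well-posed recovery
problem with known slope.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from . import reference
from .errors import ConfigurationError
from .localizer_glm import task_regressor
from .montage_io import ProbeMontage, RawRecording, default_montage, write_recording
from .preprocess import OpticalModel, forward_optical_density

GROUPS = ("HD", "CG")

DEFAULT_COUPLING_LEVELS = {
    # (baseline off-diagonal r, within-ROI r, contralateral mirror-pair r)
    "HD": (0.55, 0.70, 0.85),
    "CG": (0.35, 0.50, 0.60),
}


def build_coupling(montage: ProbeMontage, base: float, within_roi: float,
                   mirror: float) -> np.ndarray:
    """Target correlation matrix from three coupling levels.

    Raises :class:`ConfigurationError` if the result is not positive
    semidefinite.
    """
    n = len(montage.channel_ids)
    R = np.full((n, n), base, dtype=float)
    for i, ci in enumerate(montage.channel_ids):
        for j, cj in enumerate(montage.channel_ids):
            if i == j:
                continue
            if montage.roi_map[ci] == montage.roi_map[cj]:
                R[i, j] = within_roi
            if montage.mirror_map[ci] == cj:
                R[i, j] = mirror
    np.fill_diagonal(R, 1.0)
    _check_psd(R)
    return R


def _check_psd(R: np.ndarray) -> None:
    R = np.asarray(R, dtype=float)
    if not np.allclose(R, R.T, atol=1e-10):
        raise ConfigurationError("coupling matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ConfigurationError("coupling matrix must have unit diagonal")
    w = np.linalg.eigvalsh(R)
    if w.min() < -1e-8:
        raise ConfigurationError(
            f"coupling matrix is not positive semidefinite (min eig {w.min():.3g})")


def nearest_correlation(R: np.ndarray, max_iter: int = 200) -> np.ndarray:
    """Project a symmetric matrix to the nearest correlation matrix.

    Alternating projection between the PSD cone and the unit-diagonal set;
    sufficient here because inputs are small perturbations of valid
    correlation matrices.
    """
    X = np.asarray(R, dtype=float).copy()
    X = (X + X.T) / 2
    for _ in range(max_iter):
        w, V = np.linalg.eigh(X)
        if w.min() >= -1e-12:
            break
        X = (V * np.clip(w, 0, None)) @ V.T
        d = np.sqrt(np.clip(np.diag(X), 1e-12, None))
        X = X / np.outer(d, d)
        np.fill_diagonal(X, 1.0)
    np.fill_diagonal(X, 1.0)
    return np.clip((X + X.T) / 2, -1.0, 1.0)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_hd: int = 8
    n_cg: int = 7
    duration_rest_s: float = 660.0
    duration_task_s: float = 180.0
    sampling_rate_hz: float = 50.0
    latent_band_hz: tuple = (0.01, 0.1)
    coupling_matrix_by_group: dict | None = None
    coupling_levels: dict = field(
        default_factory=lambda: dict(DEFAULT_COUPLING_LEVELS))
    interhemispheric_rho: dict = field(
        default_factory=lambda: {"HD": 0.85, "CG": 0.60})
    subject_rho_sd: float = 0.05
    artifact_rate_per_min: float = 0.5
    physio_amplitudes: dict = field(default_factory=lambda: {
        "cardiac": 0.20, "respiratory": 0.10, "mayer": 0.05})
    anxiety_link: tuple = ((11, 6), 20.0, 5.0)  # (edge, slope, noise_sd)
    anxiety_intercept: float = 70.0
    anxiety_cigarettes_coef: float = 0.2
    # subject-level distribution of the anxiety-linked edge correlation;
    # wide, so the regression of STAI on the edge is well conditioned
    edge_rho_range: tuple = (0.10, 0.90)
    spike_fraction: float = 0.7   # remaining artifacts are baseline steps
    hbo_sd_uM: float = 0.5
    hb_ratio: float = 1.0 / 3.0
    hb_noise_frac: float = 0.15
    od_noise_sd: float = 5e-4
    task_beta_uM: float = 2.0
    task_active_channels: tuple = (4, 11)
    task_events: tuple = ((40.0, 15.0, "gamble"),
                          (85.0, 15.0, "gamble"),
                          (130.0, 15.0, "gamble"))
    attenuated_channels: dict = field(default_factory=dict)  # subject_id -> [ch]
    seed: int = 0
    montage: ProbeMontage = field(default_factory=default_montage)
    optical_model: OpticalModel = field(default_factory=OpticalModel)

    def __post_init__(self):
        if self.duration_rest_s < 120.0 + 60.0:
            raise ConfigurationError("resting duration must exceed trim + 60 s")
        if self.duration_task_s < 30.0 + 60.0:
            raise ConfigurationError("task duration must exceed trim + 60 s")
        low, high = self.latent_band_hz
        if not 0 < low < high < self.sampling_rate_hz / 2:
            raise ConfigurationError("latent band must lie in (0, Nyquist)")
        for onset, dur, _ in self.task_events:
            if onset < 0 or onset + dur > self.duration_task_s:
                raise ConfigurationError(
                    f"task event at {onset}s does not fit the "
                    f"{self.duration_task_s}s task recording")

    def group_coupling(self, group: str) -> np.ndarray:
        if self.coupling_matrix_by_group is not None:
            R = np.asarray(self.coupling_matrix_by_group[group], dtype=float)
            _check_psd(R)
            return R
        base, within, _ = self.coupling_levels[group]
        mirror = self.interhemispheric_rho[group]
        return build_coupling(self.montage, base, within, mirror)

    def subject_ids(self) -> list:
        return ([f"HD{i + 1:02d}" for i in range(self.n_hd)]
                + [f"CG{i + 1:02d}" for i in range(self.n_cg)])

    def group_of(self, subject_id: str) -> str:
        return "HD" if subject_id.startswith("HD") else "CG"


def _rng_for(config: SimulationConfig, subject_id: str, stream: int):
    return np.random.default_rng(
        [int(config.seed), int(stream), zlib.crc32(subject_id.encode())])


def band_limited_noise(rng, n_samples: int, n_series: int, fs: float,
                       band) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to ``band`` (columns).

    Synthesized spectrally: independent complex-Gaussian Fourier
    coefficients on the in-band bins, zero elsewhere.  This is ideally
    band-limited filtered Gaussian noise without filter edge transients,
    so sample correlations of mixtures concentrate tightly around their
    targets.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ConfigurationError(f"band {band} contains no Fourier bin")
    spec = np.zeros((freqs.size, n_series), dtype=complex)
    spec[mask] = (rng.standard_normal((int(mask.sum()), n_series))
                  + 1j * rng.standard_normal((int(mask.sum()), n_series)))
    z = np.fft.irfft(spec, n=n_samples, axis=0)
    sd = z.std(axis=0)
    sd[sd == 0] = 1.0
    return z / sd


def subject_target_matrix(config: SimulationConfig, subject_id: str,
                          group: str) -> np.ndarray:
    """Per-subject planted correlation matrix (group structure + jitter).

    Mirror-pair couplings get Gaussian subject-level jitter; the anxiety
    edge is drawn uniformly from ``edge_rho_range`` so it varies widely
    across individuals.  The perturbed matrix is projected back to the
    nearest correlation matrix, which is what the ground truth records.
    """
    R = config.group_coupling(group).copy()
    rng = _rng_for(config, subject_id, stream=11)
    montage = config.montage
    if config.subject_rho_sd > 0:
        for (cr, cl) in montage.mirror_pairs():
            i, j = montage.index_of(cr), montage.index_of(cl)
            rho = np.clip(R[i, j] + rng.normal(0, config.subject_rho_sd),
                          -0.97, 0.97)
            R[i, j] = R[j, i] = rho
    (e1, e2), _, _ = config.anxiety_link
    i, j = montage.index_of(e1), montage.index_of(e2)
    if config.edge_rho_range is not None:
        R[i, j] = R[j, i] = rng.uniform(*config.edge_rho_range)
    return nearest_correlation(R)


def _mixed_latents(rng, R: np.ndarray, n_samples: int, fs: float, band):
    w, V = np.linalg.eigh(np.asarray(R, dtype=float))
    L = V * np.sqrt(np.clip(w, 0, None))
    Z = band_limited_noise(rng, n_samples, R.shape[0], fs, band)
    return Z @ L.T


def _physiology(rng, n_samples: int, n_channels: int, fs: float,
                amplitudes: dict) -> np.ndarray:
    t = np.arange(n_samples) / fs
    freq = {"cardiac": rng.normal(1.1, 0.1),
            "respiratory": rng.normal(0.30, 0.03),
            "mayer": rng.normal(0.095, 0.01)}
    out = np.zeros((n_samples, n_channels))
    for name, amp in amplitudes.items():
        f = abs(freq.get(name, 0.1))
        phases = rng.uniform(0, 2 * np.pi, n_channels)
        out += amp * np.sin(2 * np.pi * f * t[:, None] + phases[None, :])
    return out


def _apply_artifacts(rng, od: np.ndarray, fs: float, rate_per_min: float,
                     spike_fraction: float, subject_id: str,
                     log: list) -> np.ndarray:
    """Poisson-placed motion events hitting all channels at once.

    Spikes (<= 1 s, 5-15x the channel's OD standard deviation) dominate;
    the rest are small baseline steps (0.5-1.5x), the residual of seated
    resting recordings.
    """
    n, n_ch, n_wl = od.shape
    duration_min = n / fs / 60.0
    n_events = rng.poisson(rate_per_min * duration_min)
    if n_events == 0:
        return od
    od = od.copy()
    sd = od.std(axis=0)  # (channel, wavelength)
    t = np.arange(n)
    for _ in range(n_events):
        onset = rng.uniform(0.02, 0.95) * n / fs
        i0 = int(onset * fs)
        kind = "spike" if rng.random() < spike_fraction else "step"
        if kind == "spike":
            width = rng.uniform(0.1, 1.0) * fs
            shape = np.exp(-0.5 * ((t - i0) / (width / 4)) ** 2)
            for c in range(n_ch):
                amp = rng.uniform(5, 15) * rng.choice([-1, 1])
                for w in range(n_wl):
                    od[:, c, w] += amp * sd[c, w] * shape
        else:
            for c in range(n_ch):
                amp = rng.uniform(0.5, 1.5) * rng.choice([-1, 1])
                for w in range(n_wl):
                    od[i0:, c, w] += amp * sd[c, w]
        for c in range(n_ch):
            log.append((subject_id, c + 1, round(onset, 3), kind))
    return od


def _concentrations_to_recording(config, hbo, hb, subject_id, session,
                                 events, rng, log) -> RawRecording:
    od = forward_optical_density(hbo, hb, config.optical_model)
    for ch in config.attenuated_channels.get(subject_id, ()):
        idx = config.montage.index_of(ch)
        od[:, idx, :] *= 0.02
    od = od + rng.normal(0, config.od_noise_sd, od.shape)
    od = _apply_artifacts(rng, od, config.sampling_rate_hz,
                          config.artifact_rate_per_min, config.spike_fraction,
                          subject_id, log)
    return RawRecording(od, sampling_rate_hz=config.sampling_rate_hz,
                        wavelengths_nm=tuple(config.optical_model.wavelengths_nm),
                        session=session, events=list(events),
                        channel_ids=tuple(config.montage.channel_ids),
                        subject_id=subject_id)


def simulate_resting_recording(config: SimulationConfig, subject_id: str,
                               group: str | None = None,
                               artifact_log: list | None = None) -> RawRecording:
    """One resting-state recording; deterministic given (seed, subject_id)."""
    group = group or config.group_of(subject_id)
    R = subject_target_matrix(config, subject_id, group)
    rng = _rng_for(config, subject_id, stream=1)
    n = int(round(config.duration_rest_s * config.sampling_rate_hz))
    fs = config.sampling_rate_hz
    n_ch = R.shape[0]
    latents = _mixed_latents(rng, R, n, fs, config.latent_band_hz)
    hbo = config.hbo_sd_uM * latents
    hb_noise = band_limited_noise(rng, n, n_ch, fs, config.latent_band_hz)
    hb = -config.hb_ratio * hbo + (config.hb_noise_frac * config.hbo_sd_uM) * hb_noise
    physio = _physiology(rng, n, n_ch, fs, config.physio_amplitudes)
    hbo = hbo + physio
    hb = hb - 0.3 * physio
    log = artifact_log if artifact_log is not None else []
    return _concentrations_to_recording(config, hbo, hb, subject_id,
                                        "resting", [], rng, log)


def simulate_task_recording(config: SimulationConfig, subject_id: str,
                            group: str | None = None,
                            active_channels=None, beta_uM: float | None = None,
                            artifact_log: list | None = None) -> RawRecording:
    """One task recording with event-locked HRF responses on active channels."""
    group = group or config.group_of(subject_id)
    events = list(config.task_events)
    if not events:
        raise ConfigurationError("task simulation requires a non-empty event list")
    active = set(config.task_active_channels if active_channels is None
                 else active_channels)
    if not active <= set(config.montage.channel_ids):
        raise ConfigurationError(f"active channels {active} not in montage")
    beta = config.task_beta_uM if beta_uM is None else beta_uM
    rng = _rng_for(config, subject_id, stream=2)
    fs = config.sampling_rate_hz
    n = int(round(config.duration_task_s * fs))
    R = config.group_coupling(group)
    n_ch = R.shape[0]
    latents = _mixed_latents(rng, R, n, fs, config.latent_band_hz)
    hbo = config.hbo_sd_uM * latents
    hb_noise = band_limited_noise(rng, n, n_ch, fs, config.latent_band_hz)
    hb = -config.hb_ratio * hbo + (config.hb_noise_frac * config.hbo_sd_uM) * hb_noise
    regs = task_regressor(events, n, fs)
    response = sum(regs.values())
    for ch in active:
        idx = config.montage.index_of(ch)
        hbo[:, idx] += beta * response
        hb[:, idx] -= config.hb_ratio * beta * response
    physio = _physiology(rng, n, n_ch, fs, config.physio_amplitudes)
    hbo = hbo + physio
    hb = hb - 0.3 * physio
    log = artifact_log if artifact_log is not None else []
    return _concentrations_to_recording(config, hbo, hb, subject_id,
                                        "task", events, rng, log)


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class SubjectBundle:
    subject_id: str
    group: str
    resting: RawRecording
    task: RawRecording
    meta: dict


@dataclass
class GroundTruth:
    """Everything the simulator planted, for downstream recovery checks."""

    true_correlations: dict           # group -> group-level target matrix
    subject_matrices: dict            # subject_id -> planted matrix
    subject_edge_z: dict              # subject_id -> Fisher z of anxiety edge
    true_betas: dict                  # channel -> task response amplitude (uM)
    true_anxiety_slope: float
    anxiety_edge: tuple
    artifact_log: list
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "true_correlations": {g: np.asarray(m).tolist()
                                  for g, m in self.true_correlations.items()},
            "subject_matrices": {s: np.asarray(m).tolist()
                                 for s, m in self.subject_matrices.items()},
            "subject_edge_z": self.subject_edge_z,
            "true_betas": {str(k): v for k, v in self.true_betas.items()},
            "true_anxiety_slope": self.true_anxiety_slope,
            "anxiety_edge": list(self.anxiety_edge),
            "artifact_log": [list(e) for e in self.artifact_log],
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _truncnorm(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def simulate_cohort(config: SimulationConfig):
    """Full two-group cohort: recordings, metadata, and ground truth.

    STAI anxiety is generated as
    ``intercept + slope * z(edge) + cig_coef * (cigarettes - 21) + noise``
    where ``z(edge)`` is the Fisher z of the subject's planted anxiety-edge
    correlation, so the covariate-adjusted regression can recover the slope.
    """
    if config.n_hd < 2 or config.n_cg < 2:
        raise ConfigurationError("each group needs at least 2 subjects")
    montage = config.montage
    (e1, e2), slope, noise_sd = config.anxiety_link
    ei, ej = montage.index_of(e1), montage.index_of(e2)
    artifact_log: list = []
    subjects, subj_matrices, subj_edge_z = [], {}, {}
    for subject_id in config.subject_ids():
        group = config.group_of(subject_id)
        R = subject_target_matrix(config, subject_id, group)
        subj_matrices[subject_id] = R
        z_edge = float(np.arctanh(np.clip(R[ei, ej], -0.999999, 0.999999)))
        subj_edge_z[subject_id] = z_edge
        rest = simulate_resting_recording(config, subject_id, group,
                                          artifact_log=artifact_log)
        task = simulate_task_recording(config, subject_id, group,
                                       artifact_log=artifact_log)
        rng = _rng_for(config, subject_id, stream=3)
        meta = {"subject_id": subject_id, "group": group}
        for var in ("age", "education", "iq", "cigarettes", "smoking_years"):
            mean, sd = reference.COHORT_SUMMARY[var][group]
            lo, hi = reference.COVARIATE_RANGES[var]
            meta[var] = round(_truncnorm(rng, mean, sd, lo, hi), 1)
        stai = (config.anxiety_intercept + slope * z_edge
                + config.anxiety_cigarettes_coef * (meta["cigarettes"] - 21.0)
                + rng.normal(0, noise_sd))
        lo, hi = reference.COVARIATE_RANGES["stai"]
        meta["stai"] = round(float(np.clip(stai, lo, hi)), 1)
        meta["methadone_mg"] = (
            round(_truncnorm(rng, *reference.METHADONE_MG, 0.0, 120.0), 1)
            if group == "HD" else np.nan)
        subjects.append(SubjectBundle(subject_id, group, rest, task, meta))
    truth = GroundTruth(
        true_correlations={g: config.group_coupling(g) for g in GROUPS},
        subject_matrices=subj_matrices,
        subject_edge_z=subj_edge_z,
        true_betas={c: (config.task_beta_uM if c in config.task_active_channels
                        else 0.0) for c in montage.channel_ids},
        true_anxiety_slope=slope,
        anxiety_edge=(e1, e2),
        artifact_log=artifact_log,
        seed=config.seed)
    return subjects, truth


def metadata_table(subjects) -> pd.DataFrame:
    return pd.DataFrame([s.meta for s in subjects]).set_index("subject_id")


def write_cohort(subjects, truth: GroundTruth, out_dir,
                 dialect: str = "tsv") -> None:
    """Write a cohort as one recording file per subject/session plus
    metadata TSV and ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = "tsv" if dialect == "tsv" else "snirf"
    for s in subjects:
        write_recording(s.resting, out / f"{s.subject_id}_rest.{ext}", dialect)
        write_recording(s.task, out / f"{s.subject_id}_task.{ext}", dialect)
    metadata_table(subjects).to_csv(out / "metadata.tsv", sep="\t")
    truth.to_json(out / "ground_truth.json")
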