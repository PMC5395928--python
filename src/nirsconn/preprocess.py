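"""Optical-density to hemoglobin preprocessing chain.

The resting-state chain, in fixed order: initial trim -> modified
Beer-Lambert inversion -> zero-phase band-pass (0.01-0.1 Hz) -> linear
detrend -> spline motion correction -> correlation-based signal improvement
(CBSI) -> channel-level SNR exclusion.  The task chain uses a 30 s trim and
a 0.012-0.18 Hz band.  Every step appends to the series' provenance list.

Modified Beer-Lambert law (MBLL): at each wavelength lambda the measured
optical-density change is

    dOD_lambda = (eps_lambda,HbO * dHbO + eps_lambda,Hb * dHb) * L * DPF_lambda

with eps the molar extinction coefficients, L the source-detector
separation and DPF the differential pathlength factor.  With two
wavelengths this is a 2x2 linear system per sample, inverted exactly.

CBSI exploits the physiological anti-correlation of HbO and Hb: with
alpha = sd(HbO)/sd(Hb), the corrected signals are
HbO' = (HbO - alpha*Hb)/2 and Hb' = -HbO'/alpha, which are perfectly
anti-correlated by construction; motion, which moves HbO and Hb together,
cancels in the difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal

from .errors import FormatError, LengthError, ModelError, QCError
from .montage_io import RawRecording

# Molar extinction coefficients in cm^-1 / mM (HbO, Hb), literature values
# for the two standard CW-fNIRS wavelengths.
DEFAULT_EXTINCTION_CM_PER_MM = {
    690.0: (0.2762, 2.0520),
    830.0: (0.9740, 0.6930),
}
DEFAULT_DPF = 6.0


@dataclass(frozen=True)
class OpticalModel:
    """Extinction coefficients, DPF and geometry for the MBLL inversion.

    ``extinction_cm_per_mM[w]`` is the (HbO, Hb) row for wavelength index w;
    concentrations are expressed in micromolar.
    """

    wavelengths_nm: tuple = (690.0, 830.0)
    extinction_cm_per_mM: tuple = (
        DEFAULT_EXTINCTION_CM_PER_MM[690.0],
        DEFAULT_EXTINCTION_CM_PER_MM[830.0],
    )
    dpf: tuple = (DEFAULT_DPF, DEFAULT_DPF)
    pathlength_mm: float = 30.0

    def design(self) -> np.ndarray:
        """2x2 matrix A with dOD = A @ (dHbO_uM, dHb_uM)."""
        eps = np.asarray(self.extinction_cm_per_mM, dtype=float)
        if eps.shape != (len(self.wavelengths_nm), 2):
            raise ModelError("extinction table shape does not match wavelengths")
        L_cm = self.pathlength_mm / 10.0
        scale = L_cm * np.asarray(self.dpf, dtype=float)[:, None] * 1e-3  # uM
        A = eps * scale
        if np.linalg.cond(A) > 1e8:
            raise ModelError("extinction matrix is singular or near-singular")
        return A

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.design()))


def forward_optical_density(hbo_uM: np.ndarray, hb_uM: np.ndarray,
                            model: OpticalModel | None = None) -> np.ndarray:
    """Forward MBLL: concentration changes (time, channel) -> dOD (time, channel, wavelength)."""
    model = model or OpticalModel()
    A = model.design()
    conc = np.stack([np.asarray(hbo_uM, float), np.asarray(hb_uM, float)], axis=-1)
    return conc @ A.T


@dataclass
class HemoTimeSeries:
    """HbO/Hb concentration changes (micromolar) after preprocessing."""

    hbo: np.ndarray
    hb: np.ndarray
    sampling_rate_hz: float
    channel_ids: tuple
    valid_channels: np.ndarray = None
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hb = np.asarray(self.hb, dtype=float)
        if self.hbo.shape != self.hb.shape:
            raise FormatError("hbo and hb must share shape")
        if self.hbo.ndim != 2 or self.hbo.shape[1] != len(self.channel_ids):
            raise FormatError("series must be (time, channel) matching channel_ids")
        if self.valid_channels is None:
            self.valid_channels = np.ones(self.hbo.shape[1], dtype=bool)
        else:
            self.valid_channels = np.asarray(self.valid_channels, dtype=bool).copy()

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[1]

    def evolved(self, hbo=None, hb=None, step: str | None = None,
                valid=None) -> "HemoTimeSeries":
        out = HemoTimeSeries(
            hbo=self.hbo.copy() if hbo is None else hbo,
            hb=self.hb.copy() if hb is None else hb,
            sampling_rate_hz=self.sampling_rate_hz,
            channel_ids=self.channel_ids,
            valid_channels=self.valid_channels if valid is None else valid,
            provenance=list(self.provenance))
        if step:
            out.provenance.append(step)
        return out

    def signal(self, name: str) -> np.ndarray:
        if name == "HbO":
            return self.hbo
        if name == "Hb":
            return self.hb
        raise KeyError(name)


@dataclass(frozen=True)
class PreprocessConfig:
    band_rest_hz: tuple = (0.01, 0.1)
    band_task_hz: tuple = (0.012, 0.18)
    trim_rest_s: float = 120.0
    trim_task_s: float = 30.0
    qc_sd_multiplier: float = 5.0
    motion: str = "both"  # spline | cbsi | both | none
    spline_amp_sd: float = 5.0
    spline_deriv_sd: float = 5.0

    def __post_init__(self):
        for low, high in (self.band_rest_hz, self.band_task_hz):
            if not 0 < low < high:
                raise ValueError("band edges must satisfy 0 < low < high")
        if self.motion not in ("spline", "cbsi", "both", "none"):
            raise ValueError(f"unknown motion mode {self.motion!r}")


# ---------------------------------------------------------------------------
# Individual steps


def od_to_concentration(rec: RawRecording,
                        model: OpticalModel | None = None) -> HemoTimeSeries:
    """Invert the MBLL per sample and channel; output in micromolar."""
    if len(rec.wavelengths_nm) < 2:
        raise FormatError("two wavelengths required for hemoglobin conversion")
    model = model or OpticalModel(wavelengths_nm=tuple(rec.wavelengths_nm))
    if tuple(model.wavelengths_nm) != tuple(rec.wavelengths_nm):
        raise FormatError("optical model wavelengths do not match recording")
    A_inv = np.linalg.inv(model.design())
    conc = rec.optical_density @ A_inv.T  # (time, channel, [HbO, Hb])
    return HemoTimeSeries(
        hbo=conc[:, :, 0], hb=conc[:, :, 1],
        sampling_rate_hz=rec.sampling_rate_hz,
        channel_ids=tuple(rec.channel_ids),
        provenance=[f"od_to_concentration(dpf={model.dpf}, "
                    f"L={model.pathlength_mm}mm)"])


def _band_sos(band, fs):
    low, high = band
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band {band} outside (0, Nyquist={nyq})")
    return signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(series: HemoTimeSeries, band) -> HemoTimeSeries:
    """Zero-phase 4th-order Butterworth band-pass (applied forward-backward)."""
    sos = _band_sos(band, series.sampling_rate_hz)
    ntaps = 6 * sos.shape[0] + 3  # sosfiltfilt default pad length
    if series.n_samples <= 3 * ntaps:
        raise LengthError(
            f"series of {series.n_samples} samples too short for band-pass")
    hbo = signal.sosfiltfilt(sos, series.hbo, axis=0)
    hb = signal.sosfiltfilt(sos, series.hb, axis=0)
    return series.evolved(hbo=hbo, hb=hb,
                          step=f"bandpass(band={tuple(band)})")


def filter_columns(X: np.ndarray, fs: float, band) -> np.ndarray:
    """Zero-phase band-pass arbitrary regressor columns (same filter as
    :func:`bandpass`); used so GLM regressors see the filtering the data saw."""
    sos = _band_sos(band, fs)
    return signal.sosfiltfilt(sos, np.asarray(X, dtype=float), axis=0)


def detrend(series: HemoTimeSeries) -> HemoTimeSeries:
    """Remove the per-channel least-squares linear trend."""
    if series.n_samples < 3:
        raise LengthError("detrend needs at least 3 samples")
    hbo = signal.detrend(series.hbo, axis=0, type="linear")
    hb = signal.detrend(series.hb, axis=0, type="linear")
    return series.evolved(hbo=hbo, hb=hb, step="detrend(linear)")


def _robust_sd(x: np.ndarray) -> float:
    mad = np.median(np.abs(x - np.median(x)))
    return 1.4826 * mad if mad > 0 else float(np.std(x)) or 1.0


def _motion_flags(x: np.ndarray, fs: float, amp_sd: float,
                  deriv_sd: float, pad_s: float) -> np.ndarray:
    flags = np.zeros(x.shape[0], dtype=bool)
    rsd = _robust_sd(x)
    flags |= np.abs(x - np.median(x)) > amp_sd * rsd
    dx = np.diff(x)
    rsd_d = _robust_sd(dx)
    dflag = np.abs(dx) > deriv_sd * rsd_d
    flags[:-1] |= dflag
    flags[1:] |= dflag
    if flags.any():
        pad = max(1, int(round(pad_s * fs)))
        idx = np.flatnonzero(flags)
        for i in idx:
            flags[max(0, i - pad):i + pad + 1] = True
    return flags


def _segments(flags: np.ndarray, merge_gap: int):
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    segs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > merge_gap:
            segs.append((start, prev))
            start = i
        prev = i
    segs.append((start, prev))
    return segs


def _correct_channel(x: np.ndarray, segs, fs: float, window_s: float = 1.0):
    """Spline-interpolate flagged segments and remove segment-wise shifts."""
    x = x.copy()
    w = max(2, int(round(window_s * fs)))
    n = len(x)
    for s, e in segs:
        pre = x[max(0, s - w):s]
        post = x[e + 1:e + 1 + w]
        if pre.size and post.size:
            offset = float(np.median(post) - np.median(pre))
            x[e + 1:] -= offset
            post = x[e + 1:e + 1 + w]
        # rebuild the flagged span from surrounding good samples
        left_i = np.arange(max(0, s - w), s)
        right_i = np.arange(e + 1, min(n, e + 1 + w))
        support = np.concatenate([left_i, right_i])
        if support.size >= 2:
            interp = interpolate.PchipInterpolator(support, x[support])
            x[s:e + 1] = interp(np.arange(s, e + 1))
        elif support.size == 1:
            x[s:e + 1] = x[support[0]]
    return x


def spline_motion_correct(series: HemoTimeSeries, amp_sd: float = 5.0,
                          deriv_sd: float = 5.0, pad_s: float = 0.25,
                          merge_gap_s: float = 0.5) -> HemoTimeSeries:
    """Detect motion segments and repair them by spline interpolation.

    Detection flags samples whose amplitude exceeds ``amp_sd`` robust
    standard deviations from the channel median, or whose first difference
    exceeds ``deriv_sd`` robust standard deviations of the differenced
    series.  Flagged segments are replaced by a shape-preserving spline
    through the surrounding clean samples; the baseline shift across each
    segment (a step artifact) is subtracted from the remainder of the
    series.  Artifact-free channels are returned unchanged.
    """
    fs = series.sampling_rate_hz
    merge_gap = max(1, int(round(merge_gap_s * fs)))
    hbo, hb = series.hbo.copy(), series.hb.copy()
    n_flagged = 0
    for c in range(series.n_channels):
        flags = (_motion_flags(hbo[:, c], fs, amp_sd, deriv_sd, pad_s)
                 | _motion_flags(hb[:, c], fs, amp_sd, deriv_sd, pad_s))
        if flags.mean() > 0.5:
            raise QCError(
                f"motion flags cover {flags.mean():.0%} of channel "
                f"{series.channel_ids[c]}; recording unusable")
        segs = _segments(flags, merge_gap)
        if not segs:
            continue
        n_flagged += int(flags.sum())
        hbo[:, c] = _correct_channel(hbo[:, c], segs, fs)
        hb[:, c] = _correct_channel(hb[:, c], segs, fs)
    return series.evolved(
        hbo=hbo, hb=hb,
        step=f"spline_motion_correct(amp_sd={amp_sd}, deriv_sd={deriv_sd}, "
             f"flagged={n_flagged})")


def cbsi_correct(series: HemoTimeSeries) -> HemoTimeSeries:
    """Correlation-based signal improvement.

    Per channel, with alpha = sd(HbO)/sd(Hb):
    HbO' = (HbO - alpha*Hb)/2 and Hb' = -HbO'/alpha, so that
    corr(HbO', Hb') = -1 exactly.  Zero-variance channels are skipped with
    a warning.
    """
    hbo, hb = series.hbo.copy(), series.hb.copy()
    for c in range(series.n_channels):
        s_o, s_h = np.std(hbo[:, c]), np.std(hb[:, c])
        if s_o == 0 or s_h == 0:
            warnings.warn(
                f"CBSI skipped zero-variance channel {series.channel_ids[c]}")
            continue
        alpha = s_o / s_h
        corrected = (hbo[:, c] - alpha * hb[:, c]) / 2.0
        hbo[:, c] = corrected
        hb[:, c] = -corrected / alpha
    return series.evolved(hbo=hbo, hb=hb, step="cbsi_correct")


def qc_exclude_channels(series: HemoTimeSeries,
                        k: float = 5.0) -> HemoTimeSeries:
    """Mask channels with anomalously low signal intensity.

    Signal intensity is the temporal standard deviation of each channel.
    A channel is excluded when its intensity (for HbO or Hb) lies more than
    ``k`` standard deviations below the mean intensity of the *other*
    channels -- the signature of poor optode-scalp contact.
    """
    if series.n_channels < 2:
        raise QCError("QC exclusion needs at least 2 channels")
    valid = series.valid_channels.copy()
    for sig in (series.hbo, series.hb):
        intensity = np.std(sig, axis=0)
        for c in range(series.n_channels):
            if not valid[c]:
                continue
            others = np.array([intensity[j] for j in range(series.n_channels)
                               if j != c and series.valid_channels[j]])
            if others.size < 2:
                continue
            mu, sd = float(np.mean(others)), float(np.std(others, ddof=1))
            if sd == 0:
                if intensity[c] < mu:
                    valid[c] = False
            elif intensity[c] < mu - k * sd:
                valid[c] = False
    if not valid.any():
        raise QCError("all channels excluded by SNR rule")
    excluded = [series.channel_ids[i] for i in range(series.n_channels)
                if series.valid_channels[i] and not valid[i]]
    return series.evolved(step=f"qc_exclude_channels(k={k}, excluded={excluded})",
                          valid=valid)


def trim_initial(obj, session: str | None = None, trim_rest_s: float = 120.0,
                 trim_task_s: float = 30.0):
    """Drop the initial unstable portion: 120 s (rest) or 30 s (task).

    Works on :class:`RawRecording` (event onsets are shifted accordingly)
    and on :class:`HemoTimeSeries`.
    """
    if isinstance(obj, RawRecording):
        session = session or obj.session
        fs, n = obj.sampling_rate_hz, obj.n_samples
    else:
        if session is None:
            raise ValueError("session required when trimming a HemoTimeSeries")
        fs, n = obj.sampling_rate_hz, obj.n_samples
    trim_s = trim_rest_s if session == "resting" else trim_task_s
    cut = int(round(trim_s * fs))
    if cut >= n:
        raise LengthError(
            f"recording of {n / fs:.1f}s shorter than the {trim_s:.0f}s trim")
    if isinstance(obj, RawRecording):
        events = [(onset - trim_s, dur, cond) for onset, dur, cond in obj.events]
        return RawRecording(obj.optical_density[cut:], sampling_rate_hz=fs,
                            wavelengths_nm=obj.wavelengths_nm, session=obj.session,
                            events=events, channel_ids=obj.channel_ids,
                            subject_id=obj.subject_id)
    out = obj.evolved(hbo=obj.hbo[cut:], hb=obj.hb[cut:],
                      step=f"trim_initial({trim_s:.0f}s)")
    return out


# ---------------------------------------------------------------------------
# Full chains


def preprocess_recording(rec: RawRecording,
                         config: PreprocessConfig | None = None,
                         model: OpticalModel | None = None) -> HemoTimeSeries:
    """Run the full fixed-order chain for one recording."""
    config = config or PreprocessConfig()
    session = rec.session
    band = config.band_rest_hz if session == "resting" else config.band_task_hz
    rec = trim_initial(rec, session, config.trim_rest_s, config.trim_task_s)
    series = od_to_concentration(rec, model)
    series.provenance.insert(
        0, f"trim_initial({config.trim_rest_s if session == 'resting' else config.trim_task_s:.0f}s)")
    series = bandpass(series, band)
    series = detrend(series)
    if config.motion in ("spline", "both"):
        series = spline_motion_correct(series, config.spline_amp_sd,
                                       config.spline_deriv_sd)
    if config.motion in ("cbsi", "both"):
        series = cbsi_correct(series)
    series = qc_exclude_channels(series, config.qc_sd_multiplier)
    return series
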