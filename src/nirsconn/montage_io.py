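"""Probe geometry and on-disk formats.

The default montage is a 12-channel continuous-wave layout covering the
orbitofrontal cortex (OFC): three sources and eight detectors at 30 mm
separation, yielding four regions of interest (ROIs) -- the lateral OFC of
each hemisphere (four channels each) and the medial OFC of each hemisphere
(two channels each).  Channels are numbered 1..12, right hemisphere first.
The optode layout is anatomically mirror-symmetric about the midline, which
defines a contralateral partner for every channel; that pairing drives the
interhemispheric correlation analysis.

I/O covered here: a SNIRF-style HDF5 container and a plain TSV dialect for
two-wavelength optical-density recordings, YAML montage configuration, and
TSV connectivity matrices with "NA" sentinels for masked channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, MontageError, SamplingError

ROI_NAMES = ("lOFC-right", "mOFC-right", "mOFC-left", "lOFC-left")

DEFAULT_ROI_MAP = {
    1: "lOFC-right", 2: "lOFC-right", 3: "lOFC-right", 4: "lOFC-right",
    5: "mOFC-right", 6: "mOFC-right",
    7: "mOFC-left", 8: "mOFC-left",
    9: "lOFC-left", 10: "lOFC-left", 11: "lOFC-left", 12: "lOFC-left",
}

# Geometric mirror of the optode layout about the midline: channels are
# numbered lateral-to-medial on the right and medial-to-lateral on the left.
DEFAULT_MIRROR_MAP = {1: 12, 2: 11, 3: 10, 4: 9, 5: 8, 6: 7,
                      12: 1, 11: 2, 10: 3, 9: 4, 8: 5, 7: 6}

# Nominal source-detector wiring: one lateral source with four detectors per
# lateral OFC, one midline source with four detectors for the two medial OFCs.
DEFAULT_SD_PAIRS = {
    1: (1, 1), 2: (1, 2), 3: (1, 3), 4: (1, 4),
    5: (2, 3), 6: (2, 4), 7: (2, 5), 8: (2, 6),
    9: (3, 5), 10: (3, 6), 11: (3, 7), 12: (3, 8),
}

DEFAULT_WAVELENGTHS_NM = (690.0, 830.0)
DEFAULT_SAMPLING_RATE_HZ = 50.0


@dataclass(frozen=True)
class ProbeMontage:
    """Channel geometry, ROI membership and contralateral pairing."""

    channel_ids: tuple = tuple(range(1, 13))
    roi_map: dict = field(default_factory=lambda: dict(DEFAULT_ROI_MAP))
    mirror_map: dict = field(default_factory=lambda: dict(DEFAULT_MIRROR_MAP))
    source_detector_pairs: dict = field(default_factory=lambda: dict(DEFAULT_SD_PAIRS))
    separation_mm: float = 30.0

    def __post_init__(self):
        self.validate()

    # -- derived views -------------------------------------------------
    def hemisphere(self, channel: int) -> str:
        return "right" if self.roi_map[channel].endswith("right") else "left"

    def channels_in_roi(self, roi: str) -> tuple:
        return tuple(c for c in self.channel_ids if self.roi_map[c] == roi)

    def channels_in_hemisphere(self, hemi: str) -> tuple:
        return tuple(c for c in self.channel_ids if self.hemisphere(c) == hemi)

    def mirror_pairs(self) -> list:
        """Unordered (right, left) contralateral pairs, one per pairing."""
        pairs = []
        for c in self.channel_ids:
            m = self.mirror_map[c]
            if self.hemisphere(c) == "right":
                pairs.append((c, m))
        return sorted(pairs)

    def roi_of_pair(self, pair) -> str:
        """'lOFC' or 'mOFC' for a contralateral pair."""
        return self.roi_map[pair[0]].split("-")[0]

    def index_of(self, channel: int) -> int:
        """0-based array index of an external 1-based channel label."""
        return self.channel_ids.index(channel)

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        ids = set(self.channel_ids)
        if len(ids) != len(self.channel_ids):
            raise MontageError("duplicate channel ids")
        if set(self.roi_map) != ids:
            raise MontageError("roi_map does not cover exactly the channel ids")
        for c, roi in self.roi_map.items():
            if roi not in ROI_NAMES:
                raise MontageError(f"unknown ROI {roi!r} for channel {c}")
        if set(self.mirror_map) != ids:
            raise MontageError("mirror_map does not cover exactly the channel ids")
        for c in self.channel_ids:
            m = self.mirror_map[c]
            if m not in ids:
                raise MontageError(f"mirror of channel {c} is not a channel: {m}")
            if self.mirror_map[m] != c:
                raise MontageError(f"mirror_map is not an involution at channel {c}")
            if self.hemisphere(c) == self.hemisphere(m):
                raise MontageError(
                    f"mirror pair ({c}, {m}) does not cross the midline")
            if self.roi_of_pair((c, m)) != self.roi_map[m].split("-")[0]:
                raise MontageError(
                    f"mirror pair ({c}, {m}) crosses ROI families")
        if self.separation_mm <= 0:
            raise MontageError("separation_mm must be positive")


def default_montage() -> ProbeMontage:
    return ProbeMontage()


def load_montage(config_path) -> ProbeMontage:
    """Read a montage from YAML; omitted fields fall back to the default layout.

    Recognised keys: ``channels`` (list of ints), ``roi_map``, ``mirror_map``
    (int -> int), ``separation_mm``, ``source_detector_pairs``.
    """
    path = Path(config_path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise FormatError(f"cannot parse montage file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise FormatError(f"montage file {path} must contain a mapping")

    kwargs = {}
    if "channels" in raw:
        try:
            kwargs["channel_ids"] = tuple(int(c) for c in raw["channels"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"field 'channels' malformed: {exc}") from exc
    for key, attr in (("roi_map", "roi_map"),
                      ("mirror_map", "mirror_map"),
                      ("source_detector_pairs", "source_detector_pairs")):
        if key in raw:
            if not isinstance(raw[key], dict):
                raise FormatError(f"field {key!r} must be a mapping")
            try:
                if key == "source_detector_pairs":
                    kwargs[attr] = {int(c): tuple(int(x) for x in v)
                                    for c, v in raw[key].items()}
                elif key == "mirror_map":
                    kwargs[attr] = {int(c): int(v) for c, v in raw[key].items()}
                else:
                    kwargs[attr] = {int(c): str(v) for c, v in raw[key].items()}
            except (TypeError, ValueError) as exc:
                raise FormatError(f"field {key!r} malformed: {exc}") from exc
    if "separation_mm" in raw:
        try:
            kwargs["separation_mm"] = float(raw["separation_mm"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"field 'separation_mm' malformed: {exc}") from exc
    return ProbeMontage(**kwargs)


# ---------------------------------------------------------------------------
# Recordings


@dataclass
class RawRecording:
    """Two-wavelength optical-density time series for one session.

    ``optical_density`` has shape (samples, channels, wavelengths) and holds
    dimensionless changes in optical density.  ``events`` is a list of
    (onset_s, duration_s, condition) triples for task sessions, with onsets
    on the recording's own clock.
    """

    optical_density: np.ndarray
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    wavelengths_nm: tuple = DEFAULT_WAVELENGTHS_NM
    session: str = "resting"
    events: list = field(default_factory=list)
    channel_ids: tuple = tuple(range(1, 13))
    subject_id: str = ""

    def __post_init__(self):
        od = np.asarray(self.optical_density, dtype=float)
        if od.ndim != 3:
            raise FormatError("optical_density must be (time, channel, wavelength)")
        if od.shape[2] != len(self.wavelengths_nm):
            raise FormatError("wavelength axis does not match wavelengths_nm")
        if len(self.wavelengths_nm) < 2:
            raise FormatError("two wavelengths are required for hemoglobin conversion")
        if od.shape[1] != len(self.channel_ids):
            raise FormatError("channel axis does not match channel_ids")
        if self.sampling_rate_hz <= 0:
            raise SamplingError("sampling_rate_hz must be positive")
        self.optical_density = od

    @property
    def n_samples(self) -> int:
        return self.optical_density.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


def _tsv_column(channel: int, wavelength_nm: float) -> str:
    return f"ch{channel}-{wavelength_nm:g}"


def write_recording(rec: RawRecording, path, dialect: str = "tsv") -> None:
    """Serialize a recording; ``tsv`` or ``snirf`` dialect.

    The TSV dialect puts time (s) in the first column and one
    ``ch<label>-<wavelength>`` column per channel/wavelength.  Events, if
    any, go to a ``<path>.events.tsv`` sidecar.
    """
    path = Path(path)
    if dialect == "tsv":
        cols = {"time": rec.times()}
        for ci, c in enumerate(rec.channel_ids):
            for wi, wl in enumerate(rec.wavelengths_nm):
                cols[_tsv_column(c, wl)] = rec.optical_density[:, ci, wi]
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False,
                                  float_format="%.17g")
        if rec.events:
            ev = pd.DataFrame(rec.events, columns=["onset_s", "duration_s",
                                                   "condition"])
            ev.to_csv(path.with_suffix(path.suffix + ".events.tsv"),
                      sep="\t", index=False, float_format="%.17g")
    elif dialect == "snirf":
        _write_snirf(rec, path)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


def read_recording(path, dialect: str = "tsv", session: str | None = None) -> RawRecording:
    """Read a recording written by :func:`write_recording`.

    Verifies a uniform time base: successive time deltas may deviate from
    the nominal period by at most 1%.
    """
    path = Path(path)
    if dialect == "snirf":
        return _read_snirf(path, session=session)
    if dialect != "tsv":
        raise FormatError(f"unknown dialect {dialect!r}")

    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "time":
        raise FormatError("first TSV column must be 'time'")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise SamplingError("recording has fewer than 2 samples")
    dt = np.diff(t)
    period = np.median(dt)
    if period <= 0 or np.max(np.abs(dt - period)) > 0.01 * period:
        raise SamplingError("non-uniform time base in recording")
    rate = 1.0 / period

    channels, wavelengths = [], []
    for col in df.columns[1:]:
        if not col.startswith("ch") or "-" not in col:
            raise FormatError(f"unrecognised column {col!r}")
        ch_s, wl_s = col[2:].split("-", 1)
        try:
            ch, wl = int(ch_s), float(wl_s)
        except ValueError as exc:
            raise FormatError(f"unknown wavelength label in column {col!r}") from exc
        if ch not in channels:
            channels.append(ch)
        if wl not in wavelengths:
            wavelengths.append(wl)
    od = np.empty((len(df), len(channels), len(wavelengths)))
    for ci, c in enumerate(channels):
        for wi, wl in enumerate(wavelengths):
            col = _tsv_column(c, wl)
            if col not in df.columns:
                raise FormatError(f"missing column {col!r}")
            od[:, ci, wi] = df[col].to_numpy(dtype=float)

    events = []
    ev_path = path.with_suffix(path.suffix + ".events.tsv")
    if ev_path.exists():
        ev = pd.read_csv(ev_path, sep="\t")
        events = [(float(r.onset_s), float(r.duration_s), str(r.condition))
                  for r in ev.itertuples()]
    return RawRecording(od, sampling_rate_hz=rate,
                        wavelengths_nm=tuple(wavelengths),
                        session=session or ("task" if events else "resting"),
                        events=events, channel_ids=tuple(channels))


def _write_snirf(rec: RawRecording, path) -> None:
    n_ch = len(rec.channel_ids)
    n_wl = len(rec.wavelengths_nm)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        flat = rec.optical_density.reshape(rec.n_samples, n_ch * n_wl)
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=rec.times())
        k = 1
        for ci, c in enumerate(rec.channel_ids):
            for wi in range(n_wl):
                ml = data.create_group(f"measurementList{k}")
                src, det = DEFAULT_SD_PAIRS.get(c, (0, 0))
                ml.create_dataset("sourceIndex", data=src)
                ml.create_dataset("detectorIndex", data=det)
                ml.create_dataset("wavelengthIndex", data=wi + 1)
                ml.create_dataset("dataType", data=99999)
                ml.create_dataset("channelLabel", data=str(c))
                k += 1
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths_nm))
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("session", data=rec.session)
        meta.create_dataset("SubjectID", data=rec.subject_id or "unknown")
        for i, (onset, dur, cond) in enumerate(rec.events, start=1):
            stim = nirs.create_group(f"stim{i}")
            stim.create_dataset("name", data=cond)
            stim.create_dataset("data", data=np.asarray([[onset, dur, 1.0]]))


def _read_snirf(path, session=None) -> RawRecording:
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        data = nirs["data1"]
        t = np.asarray(data["time"])
        if len(t) < 2:
            raise SamplingError("recording has fewer than 2 samples")
        dt = np.diff(t)
        period = np.median(dt)
        if period <= 0 or np.max(np.abs(dt - period)) > 0.01 * period:
            raise SamplingError("non-uniform time base in SNIRF file")
        wavelengths = tuple(float(w) for w in np.asarray(nirs["probe/wavelengths"]))
        flat = np.asarray(data["dataTimeSeries"])
        channels, columns = [], {}
        for key in sorted((k for k in data.keys() if k.startswith("measurementList")),
                          key=lambda k: int(k[len("measurementList"):])):
            ml = data[key]
            label = int(np.asarray(ml["channelLabel"]).item().decode()
                        if isinstance(np.asarray(ml["channelLabel"]).item(), bytes)
                        else np.asarray(ml["channelLabel"]).item())
            wi = int(np.asarray(ml["wavelengthIndex"]).item()) - 1
            if wi < 0 or wi >= len(wavelengths):
                raise FormatError(f"unknown wavelength index in {key}")
            if label not in channels:
                channels.append(label)
            columns[(label, wi)] = int(key[len("measurementList"):]) - 1
        od = np.empty((flat.shape[0], len(channels), len(wavelengths)))
        for ci, c in enumerate(channels):
            for wi in range(len(wavelengths)):
                od[:, ci, wi] = flat[:, columns[(c, wi)]]
        events = []
        for key in sorted(k for k in nirs.keys() if k.startswith("stim")):
            stim = nirs[key]
            name = np.asarray(stim["name"]).item()
            if isinstance(name, bytes):
                name = name.decode()
            for row in np.asarray(stim["data"]).reshape(-1, 3):
                events.append((float(row[0]), float(row[1]), str(name)))
        events.sort()
        stored_session = None
        if "metaDataTags" in nirs and "session" in nirs["metaDataTags"]:
            stored_session = np.asarray(nirs["metaDataTags/session"]).item()
            if isinstance(stored_session, bytes):
                stored_session = stored_session.decode()
    return RawRecording(od, sampling_rate_hz=1.0 / period,
                        wavelengths_nm=wavelengths,
                        session=session or stored_session or "resting",
                        events=events, channel_ids=tuple(channels))


# ---------------------------------------------------------------------------
# Connectivity matrices


def write_connectivity(values: np.ndarray, path, labels=None,
                       mask=None) -> None:
    """Write a square labelled connectivity matrix as TSV.

    Masked channels (``mask[i] == False``) are serialized as ``NA`` across
    their row and column.  Asymmetric input is rejected.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise FormatError("connectivity matrix must be square")
    finite = np.isfinite(values)
    sym = np.where(finite & finite.T, values, 0.0)
    if not np.allclose(sym, sym.T, atol=1e-12, equal_nan=True):
        raise FormatError("connectivity matrix must be symmetric")
    n = values.shape[0]
    labels = list(labels) if labels is not None else list(range(1, n + 1))
    out = values.copy()
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        out[~mask, :] = np.nan
        out[:, ~mask] = np.nan
    df = pd.DataFrame(out, index=labels, columns=labels)
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g",
              index_label="channel")


def read_connectivity(path):
    """Read a TSV connectivity matrix; returns (values, labels, mask).

    A channel whose whole row is NA is reported as masked.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise FormatError("connectivity matrix must be square")
    labels = [int(x) for x in df.index]
    off = ~np.eye(len(labels), dtype=bool)
    mask = np.array([np.isfinite(values[i][off[i]]).any() or np.isfinite(values[i, i])
                     for i in range(len(labels))])
    return values, labels, mask
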