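"""Recording I/O: EDF and delimited-text readers, plus a minimal EDF writer.

The montage is fixed: four scalp electrodes F3, F4, P3, P4 recorded against a
common reference Cz at 250 Hz.  All in-memory signals are in microvolts (μV).
"""
from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

logger = logging.getLogger("fpcoma")

#: canonical channel order used throughout the package
CHANNELS = ("F3", "F4", "P3", "P4")

#: default minimum recording duration in seconds (30 min)
MIN_DURATION_S = 1800.0


@dataclass
class Recording:
    """A multichannel resting-state EEG recording in μV.

    Parameters
    ----------
    channels : tuple of str
        Channel labels, ordered; must contain F3, F4, P3, P4.
    samples : ndarray, shape (n_channels, n_samples)
        Signal in μV.
    fs : float
        Sampling rate in Hz.
    subject_id : str
        Opaque subject identifier.
    """

    channels: tuple
    samples: np.ndarray
    fs: float
    subject_id: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channels):
            raise ValueError("samples must be (n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channels.index(label)]


def _check_duration(rec: Recording, min_duration_s: float) -> None:
    if rec.duration_s < min_duration_s:
        raise ValueError(
            f"recording lasts {rec.duration_s:.1f} s, below the required "
            f"{min_duration_s:.0f} s minimum"
        )
    if rec.duration_s < MIN_DURATION_S:
        warnings.warn(
            f"recording of {rec.duration_s:.1f} s is shorter than the standard "
            f"30-min monitoring window; accepted under a relaxed minimum",
            stacklevel=3,
        )


def _resolve_channels(labels, channel_map=None):
    """Map raw labels to canonical F3/F4/P3/P4, returning index per channel."""
    channel_map = channel_map or {}
    canon = {}
    for i, lab in enumerate(labels):
        name = channel_map.get(lab, lab).upper().replace("EEG ", "").strip()
        canon[name] = i
    idx = []
    for ch in CHANNELS:
        if ch not in canon:
            raise ValueError(f"required channel {ch!r} not found in {list(labels)}")
        idx.append(canon[ch])
    return idx


def load_recording(path, format="edf", config=None, channel_map=None,
                   fs=None, subject_id=None, min_duration_s=MIN_DURATION_S) -> Recording:
    """Load an EEG recording from EDF or headerless delimited text.

    Parameters
    ----------
    path : str
        Input file.
    format : {"edf", "csv"}
    config : str or dict, optional
        Sidecar configuration for text input (YAML path or dict) with keys
        ``channels`` (column order), ``fs`` (Hz), ``unit_scale`` (multiplier
        converting stored values to μV, default 1.0) and optionally
        ``delimiter`` and ``subject_id``.
    channel_map : dict, optional
        Aliasing table mapping raw labels to canonical ones.
    fs : float, optional
        Sampling rate override when the header carries none.
    min_duration_s : float
        Recordings shorter than this are rejected.  Lower it to accept short
        recordings (a warning is still emitted below 30 min).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "edf":
        rec = _load_edf(path, channel_map, subject_id)
    elif format == "csv":
        rec = _load_csv(path, config, channel_map, fs, subject_id)
    else:
        raise ValueError(f"unknown format {format!r}")
    _check_duration(rec, min_duration_s)
    logger.info("loaded %s: fs=%g Hz, duration=%.1f s",
                rec.subject_id, rec.fs, rec.duration_s)
    return rec


def _load_edf(path, channel_map, subject_id):
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    idx = _resolve_channels(raw.ch_names, channel_map)
    # mne converts EEG to volts internally; recover μV
    data = raw.get_data()[idx] * 1e6
    return Recording(CHANNELS, data, float(raw.info["sfreq"]),
                     subject_id or os.path.splitext(os.path.basename(path))[0])


def _load_csv(path, config, channel_map, fs, subject_id):
    if isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config or {})
    labels = config.get("channels")
    if labels is None:
        raise ValueError("text input needs a sidecar config listing 'channels'")
    fs = fs or config.get("fs")
    if not fs:
        raise ValueError("sampling rate not readable: supply fs or config['fs']")
    unit_scale = float(config.get("unit_scale", 1.0))
    data = np.loadtxt(path, delimiter=config.get("delimiter", ","), ndmin=2)
    if data.shape[1] != len(labels):
        raise ValueError(
            f"{data.shape[1]} columns but {len(labels)} channel labels declared")
    idx = _resolve_channels(labels, channel_map)
    return Recording(CHANNELS, data.T[idx] * unit_scale, float(fs),
                     subject_id or config.get("subject_id")
                     or os.path.splitext(os.path.basename(path))[0])


def write_csv(rec: Recording, path, config_path=None) -> None:
    """Write a Recording as headerless CSV plus a YAML sidecar config."""
    np.savetxt(path, rec.samples.T, delimiter=",", fmt="%.6f")
    if config_path:
        with open(config_path, "w") as fh:
            yaml.safe_dump({"channels": list(rec.channels), "fs": rec.fs,
                            "unit_scale": 1.0, "subject_id": rec.subject_id}, fh)


def write_edf(rec: Recording, path) -> None:
    """Write a Recording as a standard 16-bit EDF file (1-second records).

    Values are quantized to the signed 16-bit range over a symmetric physical
    span, so round-tripped samples match to within the format's quantization
    step.  The trailing partial second, if any, is zero-padded.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    nchan = len(rec.channels)
    n = rec.samples.shape[1]
    n_records = int(np.ceil(n / fs))
    data = np.zeros((nchan, n_records * fs))
    data[:, :n] = rec.samples

    # integer physical span: written exactly in the 8-char header field, so
    # encoder and reader agree on the scale
    phys_max = float(int(np.max(np.abs(data))) + 1)
    dig_min, dig_max = -32768, 32767
    scale = dig_max / phys_max
    digital = np.clip(np.round(data * scale), dig_min, dig_max).astype("<i2")

    def pad(s, width):
        s = str(s)[:width]
        return s + " " * (width - len(s))

    header = "".join([
        pad("0", 8),                                   # version
        pad(rec.subject_id, 80),                       # patient id
        pad("fpcoma", 80),                             # recording id
        pad("01.01.20", 8), pad("00.00.00", 8),        # date, time
        pad(256 * (nchan + 1), 8),                     # header bytes
        pad("", 44),                                   # reserved
        pad(n_records, 8), pad("1", 8), pad(nchan, 4),
    ])
    sig = "".join([
        "".join(pad(ch, 16) for ch in rec.channels),
        "".join(pad("EEG", 80) for _ in rec.channels),           # transducer
        "".join(pad("uV", 8) for _ in rec.channels),             # unit
        "".join(pad(f"{-phys_max:.4g}", 8) for _ in rec.channels),
        "".join(pad(f"{phys_max:.4g}", 8) for _ in rec.channels),
        "".join(pad(dig_min, 8) for _ in rec.channels),
        "".join(pad(dig_max, 8) for _ in rec.channels),
        "".join(pad("", 80) for _ in rec.channels),              # prefiltering
        "".join(pad(fs, 8) for _ in rec.channels),
        "".join(pad("", 32) for _ in rec.channels),
    ])
    with open(path, "wb") as fh:
        fh.write((header + sig).encode("ascii"))
        for r in range(n_records):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())
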