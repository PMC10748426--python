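"""Epoching and preprocessing of frontoparietal EEG recordings.

A recording is cut into non-overlapping fixed-length epochs (2 min each),
every epoch is baseline-calibrated (per-channel mean removal), bandpass
filtered with a zero-phase 0.1-40 Hz fourth-order Butterworth, and rejected
if any sample on any channel exceeds 200 μV in absolute amplitude.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .io import Recording, CHANNELS


@dataclass
class Epoch:
    """One fixed-length window of a recording, in μV."""

    subject_id: str
    index: int
    samples: np.ndarray  # (n_channels, n_samples)
    fs: float
    channels: tuple = CHANNELS
    qc_status: str = "retained"
    qc_reason: str = ""

    def __post_init__(self):
        if self.qc_status == "rejected" and not self.qc_reason:
            raise ValueError("rejected epoch requires a qc_reason")

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channels.index(label)]


def partition_epochs(rec: Recording, epoch_s: float = 120.0) -> list[Epoch]:
    """Cut a recording into contiguous non-overlapping epochs of ``epoch_s``
    seconds starting at sample 0; the trailing remainder is discarded."""
    n_per = int(round(rec.fs * epoch_s))
    n_total = rec.samples.shape[1]
    if n_total < n_per:
        raise ValueError(
            f"recording of {n_total / rec.fs:.1f} s is shorter than one "
            f"{epoch_s:.0f}-s epoch")
    n_epochs = n_total // n_per
    return [
        Epoch(rec.subject_id, i, rec.samples[:, i * n_per:(i + 1) * n_per].copy(),
              rec.fs, tuple(rec.channels))
        for i in range(n_epochs)
    ]


def baseline_calibrate(e: Epoch) -> Epoch:
    """Remove the per-channel mean over the epoch (idempotent)."""
    return replace(e, samples=e.samples - e.samples.mean(axis=1, keepdims=True))


def bandpass_filter(e: Epoch, lo: float = 0.1, hi: float = 40.0,
                    order: int = 4) -> Epoch:
    """Zero-phase (forward-backward) Butterworth bandpass.

    ``order`` is the single-pass order; the effective attenuation after the
    forward-backward pass is doubled.  Reflect padding of one settling length
    suppresses edge transients.
    """
    nyq = e.fs / 2.0
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"upper edge {hi} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=e.fs, output="sos")
    # reflect-pad one settling length of the low edge to kill edge transients
    padlen = min(e.samples.shape[1] - 1, int(3 * e.fs / lo))
    out = signal.sosfiltfilt(sos, e.samples, axis=1, padtype="even",
                             padlen=padlen)
    return replace(e, samples=out)


def reject_artifacts(epochs: list[Epoch], amp_thresh: float = 200.0):
    """Reject epochs containing any sample with \\|amplitude\\| > ``amp_thresh`` μV.

    Returns ``(retained, qc_log)`` where ``qc_log`` is a DataFrame with one
    row per input epoch (subject_id, epoch_index, status, reason).  Raises if
    every epoch is rejected, since no features can then be computed.
    """
    retained, rows = [], []
    for e in epochs:
        over = np.abs(e.samples) > amp_thresh
        if over.any():
            ch_i, samp_i = np.unravel_index(np.argmax(over), over.shape)
            reason = (f"|amplitude| {abs(e.samples[ch_i, samp_i]):.1f} uV > "
                      f"{amp_thresh:g} uV on {e.channels[ch_i]} at sample {samp_i}")
            e = replace(e, qc_status="rejected", qc_reason=reason)
        else:
            retained.append(e)
        rows.append({"subject_id": e.subject_id, "epoch_index": e.index,
                     "status": e.qc_status, "reason": e.qc_reason})
    qc_log = pd.DataFrame(rows, columns=["subject_id", "epoch_index",
                                         "status", "reason"])
    if epochs and not retained:
        raise ValueError(
            f"all {len(epochs)} epochs rejected for subject "
            f"{epochs[0].subject_id}; no features computable")
    return retained, qc_log


def preprocess_recording(rec: Recording, epoch_s: float = 120.0,
                         lo: float = 0.1, hi: float = 40.0, order: int = 4,
                         amp_thresh: float = 200.0):
    """Full preprocessing chain: partition → calibrate → filter → reject.

    Returns ``(retained_epochs, qc_log)``.
    """
    epochs = partition_epochs(rec, epoch_s)
    epochs = [bandpass_filter(baseline_calibrate(e), lo, hi, order)
              for e in epochs]
    return reject_artifacts(epochs, amp_thresh)
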