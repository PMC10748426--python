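"""Quantitative EEG features for coma prognosis.

Per 2-min epoch and channel: 8 temporal features (burst suppression ratio,
RMS, Hjorth activity/mobility/complexity, kurtosis, skewness, Shannon
entropy), 16 frequency features (peak frequency f_m, δ/θ/α/β band powers, ten
band-power ratios, 95% spectral edge f_h), and 4 functional-connectivity
metrics (PCC, MI, PLV, PLI) for each of the 6 channel pairs — 48 features per
patient after aggregation.

Aggregation follows the montage design: temporal and frequency features take
the median across the four channels within an epoch, connectivity is computed
per pair; both are then averaged across all retained epochs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .preprocess import Epoch

#: frequency bands in Hz
BANDS = {"delta": (0.5, 4.0), "theta": (4.0, 8.0),
         "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}

#: the 6 unordered channel pairs, in conventional reporting order
PAIRS = (("F3", "F4"), ("P3", "P4"), ("F3", "P3"),
         ("F4", "P4"), ("F3", "P4"), ("F4", "P3"))

TEMPORAL_FEATURES = ("bsr", "rms", "activity", "mobility", "complexity",
                     "kurtosis", "skewness", "entropy")
FREQUENCY_FEATURES = ("f_m", "delta", "theta", "alpha", "beta",
                      "delta_total", "theta_total", "alpha_total", "beta_total",
                      "theta_delta", "alpha_delta", "beta_delta",
                      "alpha_theta", "beta_theta", "beta_alpha", "f_h")
CONNECTIVITY_METRICS = ("pcc", "mi", "plv", "pli")
CONNECTIVITY_FEATURES = tuple(f"{m}_{a}_{b}" for m in CONNECTIVITY_METRICS
                              for a, b in PAIRS)
FEATURE_NAMES = TEMPORAL_FEATURES + FREQUENCY_FEATURES + CONNECTIVITY_FEATURES


# ---------------------------------------------------------------- temporal

def burst_suppression_ratio(x, fs, supp_thresh=5.0, min_supp_s=0.5,
                            smooth_s=0.1):
    """Fraction of the epoch spent in the suppression state.

    The amplitude envelope (moving average of \\|x\\| over ``smooth_s`` seconds)
    must stay at or below ``supp_thresh`` μV for at least ``min_supp_s``
    seconds for a stretch to count as suppression.  Returns a value in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    win = max(1, int(round(smooth_s * fs)))
    env = np.convolve(np.abs(x), np.ones(win) / win, mode="same")
    supp = env <= supp_thresh
    min_run = max(1, int(round(min_supp_s * fs)))
    # run-length encode the suppression mask
    edges = np.flatnonzero(np.diff(supp.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges + 1, supp.size]
    total = 0
    for s, e in zip(starts, ends):
        if supp[s] and e - s >= min_run:
            total += e - s
    return total / supp.size


def shannon_entropy(x, bins=64):
    """Shannon entropy (nats) of the equal-width amplitude histogram."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def temporal_features(x, fs, supp_thresh=5.0, min_supp_s=0.5,
                      entropy_bins=64) -> dict:
    """All 8 temporal features for one epoch channel (NaN where undefined)."""
    x = np.asarray(x, dtype=float)
    var = x.var()
    out = {
        "bsr": burst_suppression_ratio(x, fs, supp_thresh, min_supp_s),
        "rms": float(np.sqrt(var)),
        "activity": float(var),
        "kurtosis": float(stats.kurtosis(x, fisher=False)) if var > 0 else np.nan,
        "skewness": float(stats.skew(x)) if var > 0 else np.nan,
        "entropy": shannon_entropy(x, entropy_bins),
    }
    if var > 0:
        d1 = np.diff(x) * fs
        mob = np.sqrt(d1.var() / var)
        out["mobility"] = float(mob)
        v1 = d1.var()
        if v1 > 0:
            d2 = np.diff(d1) * fs
            out["complexity"] = float(np.sqrt(d2.var() / v1) / mob)
        else:
            out["complexity"] = np.nan
    else:
        out["mobility"] = np.nan
        out["complexity"] = np.nan
    return out


# ---------------------------------------------------------------- spectral

@dataclass
class SpectralEstimate:
    """Welch PSD in μV²/Hz on a one-sided frequency grid."""

    freqs: np.ndarray
    psd: np.ndarray
    seg_s: float
    overlap: float


def power_spectrum(x, fs, seg_s=4.0, overlap=0.5) -> SpectralEstimate:
    """Welch periodogram: Hann windows of ``seg_s`` seconds, 50% overlap,
    density scaling (the integral over frequency approximates the variance)."""
    nperseg = min(int(round(seg_s * fs)), np.size(x))
    freqs, psd = signal.welch(np.asarray(x, dtype=float), fs=fs,
                              window="hann", nperseg=nperseg,
                              noverlap=int(round(nperseg * overlap)),
                              scaling="density")
    return SpectralEstimate(freqs, psd, seg_s, overlap)


def _band_power(s: SpectralEstimate, lo, hi):
    m = (s.freqs >= lo) & (s.freqs <= hi)
    if m.sum() < 2:
        return 0.0
    return float(np.trapezoid(s.psd[m], s.freqs[m]))


def frequency_features(s: SpectralEstimate, edge_fraction=0.95,
                       f_lo=0.5, f_hi=30.0) -> dict:
    """The 16 frequency features from one channel's PSD.

    Band powers are PSD integrals; total = δ+θ+α+β so that the four
    band-to-total ratios sum to one.  ``f_m`` is the frequency of the PSD
    maximum in [0.5, 30] Hz; ``f_h`` the spectral edge below which
    ``edge_fraction`` of the in-band power lies.
    """
    out = {name: _band_power(s, *band) for name, band in BANDS.items()}
    total = sum(out.values())
    ratios = [("delta_total", "delta", "total"), ("theta_total", "theta", "total"),
              ("alpha_total", "alpha", "total"), ("beta_total", "beta", "total"),
              ("theta_delta", "theta", "delta"), ("alpha_delta", "alpha", "delta"),
              ("beta_delta", "beta", "delta"), ("alpha_theta", "alpha", "theta"),
              ("beta_theta", "beta", "theta"), ("beta_alpha", "beta", "alpha")]
    vals = dict(out, total=total)
    for name, num, den in ratios:
        out[name] = vals[num] / vals[den] if vals[den] > 0 else np.nan

    inband = (s.freqs >= f_lo) & (s.freqs <= f_hi)
    f, p = s.freqs[inband], s.psd[inband]
    if total > 0 and f.size >= 2:
        out["f_m"] = float(f[np.argmax(p)])
        cum = np.concatenate([[0.0], np.cumsum(np.diff(f) * (p[1:] + p[:-1]) / 2)])
        out["f_h"] = float(np.interp(edge_fraction * cum[-1], cum, f))
    else:
        out["f_m"] = np.nan
        out["f_h"] = np.nan
    return out


# ------------------------------------------------------------ connectivity

def mutual_information(x, y, bins=64):
    """Plug-in mutual information (nats) from a 2-D amplitude histogram.

    Marginals are taken from the joint histogram, so the estimate is
    nonnegative up to float round-off; it is clipped at 0.
    """
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    mi = float((pxy[nz] * np.log(pxy[nz] / np.outer(px, py)[nz])).sum())
    return max(mi, 0.0)


def _instantaneous_phase(x):
    return np.angle(signal.hilbert(np.asarray(x, dtype=float)))


def phase_synchrony(phase_x, phase_y):
    """PLV and PLI from two instantaneous-phase series.

    PLV is the modulus of the mean unit phasor of the phase difference; PLI
    the modulus of the mean sign of the (wrapped) phase difference, which
    ignores zero-lag coupling.
    """
    dphi = phase_x - phase_y
    plv = float(np.abs(np.mean(np.exp(1j * dphi))))
    pli = float(np.abs(np.mean(np.sign(np.sin(dphi)))))
    return plv, pli


def connectivity_pair(x, y, mi_bins=64) -> dict:
    """PCC, MI, PLV and PLI between two epoch channels.

    Phases come from the analytic signal of each broadband-filtered channel.
    A constant channel leaves pcc/plv/pli undefined (NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("channels must have equal length")
    out = {"mi": mutual_information(x, y, mi_bins)}
    if x.var() == 0 or y.var() == 0:
        out.update(pcc=np.nan, plv=np.nan, pli=np.nan)
        return out
    out["pcc"] = float(np.corrcoef(x, y)[0, 1])
    plv, pli = phase_synchrony(_instantaneous_phase(x), _instantaneous_phase(y))
    out.update(plv=plv, pli=pli)
    return out


# -------------------------------------------------------------- per-epoch

def epoch_features(e: Epoch, supp_thresh=5.0, min_supp_s=0.5,
                   entropy_bins=64, edge_fraction=0.95) -> dict:
    """One epoch → the 48-entry feature dict.

    Temporal and frequency features are medians across the four channels;
    connectivity metrics are per-pair.  NaN marks undefined values.
    """
    per_ch_t = [temporal_features(e.samples[i], e.fs, supp_thresh, min_supp_s,
                                  entropy_bins)
                for i in range(len(e.channels))]
    per_ch_f = [frequency_features(power_spectrum(e.samples[i], e.fs),
                                   edge_fraction)
                for i in range(len(e.channels))]
    out = {}
    for name in TEMPORAL_FEATURES:
        vals = np.array([d[name] for d in per_ch_t])
        out[name] = np.nan if np.isnan(vals).all() else float(np.nanmedian(vals))
    for name in FREQUENCY_FEATURES:
        vals = np.array([d[name] for d in per_ch_f])
        out[name] = np.nan if np.isnan(vals).all() else float(np.nanmedian(vals))

    phases = {ch: _instantaneous_phase(e.channel(ch)) for ch in e.channels}
    for a, b in PAIRS:
        x, y = e.channel(a), e.channel(b)
        out[f"mi_{a}_{b}"] = mutual_information(x, y, entropy_bins)
        if x.var() == 0 or y.var() == 0:
            for m in ("pcc", "plv", "pli"):
                out[f"{m}_{a}_{b}"] = np.nan
        else:
            out[f"pcc_{a}_{b}"] = float(np.corrcoef(x, y)[0, 1])
            plv, pli = phase_synchrony(phases[a], phases[b])
            out[f"plv_{a}_{b}"] = plv
            out[f"pli_{a}_{b}"] = pli
    return out


@dataclass
class PatientFeatures:
    """Aggregated 48-feature vector for one patient plus metadata."""

    subject_id: str
    features: dict
    n_epochs_used: int
    n_missing: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_series(self) -> pd.Series:
        row = {"subject_id": self.subject_id, **self.features,
               "n_epochs_used": self.n_epochs_used, **self.metadata}
        return pd.Series(row)


def aggregate_patient_features(epoch_feature_dicts, subject_id="unknown",
                               metadata=None) -> PatientFeatures:
    """Average per-epoch feature dicts into one patient-level vector.

    Missing (NaN) per-epoch values are excluded from the mean; the count of
    epochs excluded per feature is recorded in ``n_missing``.  A feature
    missing in every epoch stays NaN and is flagged.
    """
    if not epoch_feature_dicts:
        raise ValueError("need at least one retained epoch")
    table = pd.DataFrame(epoch_feature_dicts)[list(FEATURE_NAMES)]
    means = table.mean(axis=0, skipna=True)
    missing = table.isna().sum()
    return PatientFeatures(
        subject_id=subject_id,
        features={k: (float(means[k]) if pd.notna(means[k]) else np.nan)
                  for k in FEATURE_NAMES},
        n_epochs_used=len(table),
        n_missing={k: int(missing[k]) for k in FEATURE_NAMES if missing[k] > 0},
        metadata=dict(metadata or {}),
    )


def extract_patient_features(recording, epoch_s=120.0, metadata=None,
                             **preprocess_kw) -> PatientFeatures:
    """Convenience chain: preprocess a Recording and aggregate its features."""
    from .preprocess import preprocess_recording

    retained, _ = preprocess_recording(recording, epoch_s=epoch_s,
                                       **preprocess_kw)
    return aggregate_patient_features([epoch_features(e) for e in retained],
                                      subject_id=recording.subject_id,
                                      metadata=metadata)
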