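"""Independent brute-force reference implementations of every feature.

These follow the feature definitions directly (explicit sums, loops, FFT
analytic signal built by hand) and share no code with the package; they
exist solely to cross-check the production implementations.
"""
import numpy as np
from scipy import signal as spsig


def analytic_signal(x):
    """Analytic signal via explicit one-sided spectrum doubling."""
    x = np.asarray(x, float)
    n = len(x)
    X = np.fft.fft(x)
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1:n // 2] = 2.0
    else:
        h[1:(n + 1) // 2] = 2.0
    return np.fft.ifft(X * h)


def rms(x):
    x = np.asarray(x, float)
    m = sum(x) / len(x)
    return np.sqrt(sum((v - m) ** 2 for v in x) / len(x))


def _var(x):
    m = np.mean(x)
    return np.mean((x - m) ** 2)


def mobility(x, fs):
    d = (x[1:] - x[:-1]) * fs
    return np.sqrt(_var(d) / _var(x))


def complexity(x, fs):
    d = (x[1:] - x[:-1]) * fs
    return mobility(d, fs) / mobility(x, fs)


def kurtosis(x):
    m = np.mean(x)
    s2 = np.mean((x - m) ** 2)
    return np.mean((x - m) ** 4) / s2 ** 2


def skewness(x):
    m = np.mean(x)
    s2 = np.mean((x - m) ** 2)
    return np.mean((x - m) ** 3) / s2 ** 1.5


def shannon_entropy(x, bins=64):
    counts, _ = np.histogram(x, bins=bins)
    total = counts.sum()
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * np.log(p)
    return h


def bsr(x, fs, thresh=5.0, min_supp_s=0.5, smooth_s=0.1):
    """Direct sample counting: moving-average envelope, qualifying runs."""
    x = np.asarray(x, float)
    n = len(x)
    win = max(1, int(round(smooth_s * fs)))
    ax = np.abs(x)
    # zero-padded centred moving average, matching 'same' convolution
    pad = np.concatenate([np.zeros(win), ax, np.zeros(win)])
    cs = np.cumsum(pad)
    left = win - (win - 1) // 2 - 1
    env = np.array([(cs[i + left + win] - cs[i + left]) / win
                    for i in range(n)])
    supp = env <= thresh
    min_run = max(1, int(round(min_supp_s * fs)))
    count = run = 0
    for i in range(n + 1):
        inside = i < n and supp[i]
        if inside:
            run += 1
        else:
            if run >= min_run:
                count += run
            run = 0
    return count / n


def band_power(freqs, psd, lo, hi):
    """Trapezoid integral of the PSD over [lo, hi], written out."""
    total = 0.0
    for i in range(len(freqs) - 1):
        f0, f1 = freqs[i], freqs[i + 1]
        if f0 >= lo and f1 <= hi:
            total += (f1 - f0) * (psd[i] + psd[i + 1]) / 2
    return total


def spectral_features(x, fs, edge_fraction=0.95):
    """Frequency features recomputed from a fresh Welch PSD."""
    nperseg = min(int(4 * fs), len(x))
    freqs, psd = spsig.welch(x, fs=fs, window="hann", nperseg=nperseg,
                             noverlap=nperseg // 2, scaling="density")
    bands = {"delta": (0.5, 4.0), "theta": (4.0, 8.0),
             "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}
    out = {k: band_power(freqs, psd, lo, hi) for k, (lo, hi) in bands.items()}
    total = sum(out.values())
    for name, num, den in (
            ("delta_total", "delta", None), ("theta_total", "theta", None),
            ("alpha_total", "alpha", None), ("beta_total", "beta", None),
            ("theta_delta", "theta", "delta"), ("alpha_delta", "alpha", "delta"),
            ("beta_delta", "beta", "delta"), ("alpha_theta", "alpha", "theta"),
            ("beta_theta", "beta", "theta"), ("beta_alpha", "beta", "alpha")):
        d = total if den is None else out[den]
        out[name] = out[num] / d if d > 0 else np.nan
    inb = [(f, p) for f, p in zip(freqs, psd) if 0.5 <= f <= 30.0]
    fi = np.array([f for f, _ in inb])
    pi = np.array([p for _, p in inb])
    out["f_m"] = fi[int(np.argmax(pi))]
    cum = [0.0]
    for i in range(len(fi) - 1):
        cum.append(cum[-1] + (fi[i + 1] - fi[i]) * (pi[i] + pi[i + 1]) / 2)
    cum = np.array(cum)
    out["f_h"] = float(np.interp(edge_fraction * cum[-1], cum, fi))
    return out


def pcc(x, y):
    mx, my = np.mean(x), np.mean(y)
    num = np.sum((x - mx) * (y - my)) / len(x)
    return num / np.sqrt(_var(x) * _var(y))


def mutual_information(x, y, bins=64):
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    total = joint.sum()
    px = joint.sum(axis=1) / total
    py = joint.sum(axis=0) / total
    mi = 0.0
    for i in range(bins):
        for j in range(bins):
            pij = joint[i, j] / total
            if pij > 0:
                mi += pij * np.log(pij / (px[i] * py[j]))
    return max(mi, 0.0)


def plv_pli(x, y):
    phx = np.angle(analytic_signal(x))
    phy = np.angle(analytic_signal(y))
    dphi = phx - phy
    plv = abs(np.mean(np.cos(dphi)) + 1j * np.mean(np.sin(dphi)))
    pli = abs(np.mean(np.sign(np.sin(dphi))))
    return plv, pli


def auc_concordance(probs, labels):
    """AUC as the fraction of concordant positive/negative pairs (+½ ties)."""
    pos = [p for p, l in zip(probs, labels) if l == 1]
    neg = [p for p, l in zip(probs, labels) if l == 0]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                conc += 1
            elif p == q:
                conc += 0.5
    return conc / total


def bh_stepup(pvals):
    """Benjamini-Hochberg adjusted p-values by the step-up recursion."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [None] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank)
        adj[i] = val
        prev = val
    return adj
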