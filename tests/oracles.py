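"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: plain loops
and boolean masks over explicit definitions, so they can arbitrate the
implementation.
"""

from __future__ import annotations

import math

import numpy as np


def brute_local_maxima(y) -> list[int]:
    """Indices strictly greater than both neighbouring runs; plateaus
    resolved to their leftmost point; endpoints excluded."""
    y = list(y)
    n = len(y)
    peaks: list[int] = []
    idx = 0
    while idx < n:
        k = idx
        while k + 1 < n and y[k + 1] == y[idx]:
            k += 1
        if idx > 0 and k < n - 1 and y[idx - 1] < y[idx] and y[k + 1] < y[idx]:
            peaks.append(idx)
        idx = k + 1
    return peaks


def brute_baseline(x, y, center, inner, outer):
    """(mu, sd, n) of the pooled flanking annuli, or None when a flank has
    fewer than 10 points. Population SD with the machine-epsilon floor."""
    x = np.asarray(x)
    y = np.asarray(y)
    left = (x >= center - outer) & (x <= center - inner)
    right = (x >= center + inner) & (x <= center + outer)
    if left.sum() < 10 or right.sum() < 10:
        return None
    vals = np.concatenate([y[left], y[right]])
    mu = float(vals.mean())
    sd = float(vals.std(ddof=0))
    floor = np.finfo(float).eps * max(1.0, abs(mu))
    if sd < floor:
        sd = floor
    return mu, sd, int(vals.size)


def brute_snr(x, y, center, inner, mu, sd) -> float:
    x = np.asarray(x)
    y = np.asarray(y)
    window = (x >= center - inner) & (x <= center + inner)
    return (float(y[window].max()) - mu) / sd


def brute_detect_peaks(x, y, min_snr, inner=0.15, outer=0.60):
    """(apex_index, snr) for every qualifying local maximum."""
    out = []
    for i in brute_local_maxima(y):
        base = brute_baseline(x, y, x[i], inner, outer)
        if base is None:
            continue
        mu, sd, _ = base
        snr = brute_snr(x, y, x[i], inner, mu, sd)
        if snr >= min_snr:
            out.append((i, snr))
    return out


def brute_confusion(labels_true, labels_pred):
    """(tp, fp, tn, fn) with positive class = abnormal, by explicit count."""
    tp = fp = tn = fn = 0
    for t, p in zip(labels_true, labels_pred, strict=True):
        if t == "abnormal" and p == "abnormal":
            tp += 1
        elif t == "abnormal" and p == "normal":
            fn += 1
        elif t == "normal" and p == "abnormal":
            fp += 1
        elif t == "normal" and p == "normal":
            tn += 1
        else:
            raise ValueError((t, p))
    return tp, fp, tn, fn


def gaussian_window_area(amp: float, sigma: float, halfwidth: float) -> float:
    """Closed-form integral of amp*exp(-x^2/(2 sigma^2)) over
    [-halfwidth, halfwidth]."""
    return amp * sigma * math.sqrt(2.0 * math.pi) * math.erf(
        halfwidth / (sigma * math.sqrt(2.0))
    )
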