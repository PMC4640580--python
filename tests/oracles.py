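"""Independent straight-line reference implementations used as test
oracles.  Deliberately naive: explicit loops, no vectorization, no shared
code with the package internals."""

import numpy as np


def ref_band_power(window_samples, fs, lo, hi):
    """Hann-tapered DFT periodogram summed over [lo, hi), one window."""
    x = np.asarray(window_samples, dtype=float)
    n = x.size
    x = x - x.mean()
    w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / n)
    xw = x * w
    total = 0.0
    for k in range(n // 2 + 1):
        X = 0.0 + 0.0j
        for i in range(n):
            X += xw[i] * np.exp(-2j * np.pi * k * i / n)
        p = abs(X) ** 2 / (fs * np.sum(w**2))
        if 0 < k < n / 2:
            p *= 2
        f = k * fs / n
        if lo <= f < hi:
            total += p
    return total


def ref_rate_series(event_times, duration):
    """Per-bin rate via midpoint interval lookup."""
    out = []
    for k in range(int(duration)):
        mid = k + 0.5
        val = np.nan
        for i in range(1, len(event_times)):
            if event_times[i - 1] < mid <= event_times[i]:
                val = 1.0 / (event_times[i] - event_times[i - 1])
                break
        out.append(val)
    return np.array(out)


def ref_circular_xcorr(a, b, lags):
    """O(L^2) double-loop circular cross-correlation."""
    L = len(a)
    out = []
    for tau in lags:
        s = 0.0
        for i in range(L):
            s += a[i] * b[(i + tau) % L]
        out.append(s / L)
    return np.array(out)


def ref_find_tau0(values, lags):
    """Exhaustive scan for argmax |C| with the smallest-|tau|-then-
    positive tie rule."""
    best = None
    for tau, c in zip(lags, values):
        key = (-abs(c), abs(tau), tau < 0)
        if best is None or key < best[0]:
            best = (key, tau)
    return int(best[1])


def ref_stability(taus, valid, window=5, min_agree=4, tol=1):
    """Exhaustive sliding-window / candidate-reference stability scan."""
    n = len(taus)
    stable = [False] * n
    for start in range(n - window + 1):
        if not all(valid[start:start + window]):
            continue
        w = taus[start:start + window]
        for r in range(int(min(w)) - tol, int(max(w)) + tol + 1):
            agreeing = [i for i in range(window) if abs(w[i] - r) <= tol]
            if len(agreeing) >= min_agree:
                for i in agreeing:
                    stable[start + i] = True
    return np.array(stable)


def ref_tds_pair(x, y, L=60, step=30):
    """Straight-line TDS pipeline: loops only.

    Returns (taus, valid, stable, pct).
    """
    N = len(x)
    n_seg = (N - L) // step + 1
    lags = list(range(-(L // 2), L - L // 2))
    taus, valid = [], []
    for v in range(n_seg):
        a = np.array(x[v * step:v * step + L], dtype=float)
        b = np.array(y[v * step:v * step + L], dtype=float)
        if (not np.all(np.isfinite(a)) or not np.all(np.isfinite(b))
                or a.std() == 0 or b.std() == 0):
            taus.append(0)
            valid.append(False)
            continue
        a = (a - a.mean()) / a.std()
        b = (b - b.mean()) / b.std()
        C = ref_circular_xcorr(a, b, lags)
        taus.append(ref_find_tau0(C, lags))
        valid.append(True)
    stable = ref_stability(taus, valid)
    n_valid = sum(valid)
    pct = float(stable.sum() / n_valid) if n_valid else 0.0
    return np.array(taus), np.array(valid), stable, pct
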