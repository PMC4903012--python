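"""Independent brute-force reference implementations used only by tests.

Each function here is written from the definitions with plain loops,
deliberately not sharing code with the package, so agreement between the
two routes is evidence of correctness.
"""

import math

import numpy as np


def time_domain_oracle(nn):
    """Loop-based time-domain HRV metrics from the definitions."""
    nn = list(map(float, nn))
    n = len(nn)
    avrr = sum(nn) / n
    sdrr = math.sqrt(sum((x - avrr) ** 2 for x in nn) / n)
    hr = [60.0 / x for x in nn]
    avg_hr = sum(hr) / n
    sd_hr = math.sqrt(sum((h - avg_hr) ** 2 for h in hr) / n)
    diffs = [nn[i + 1] - nn[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    nn50 = sum(1 for d in diffs if abs(d) > 0.050)
    pnn50 = 100.0 * nn50 / n
    return dict(avrr=avrr, sdrr=sdrr, avg_hr=avg_hr, sd_hr=sd_hr,
                rmssd=rmssd, nn50=nn50, pnn50=pnn50)


def geometric_oracle(nn, bin_width):
    """Triangular index and TINN by exhaustive scalar search."""
    nn = np.asarray(nn, dtype=float)
    lo = math.floor(nn.min() / bin_width) * bin_width
    nbins = int(math.ceil((nn.max() - lo) / bin_width)) + 1
    edges = [lo + bin_width * i for i in range(nbins + 1)]
    counts, _ = np.histogram(nn, bins=np.array(edges))
    counts = counts.tolist()
    kmode = max(range(nbins), key=lambda i: counts[i])
    peak = counts[kmode]
    tri = len(nn) / peak
    if sum(1 for c in counts if c > 0) == 1:
        return tri, 0.0
    centers = [(edges[i] + edges[i + 1]) / 2 for i in range(nbins)]
    ck = centers[kmode]
    best_err, best_width = float("inf"), 0.0
    for iN in range(0, kmode + 1):
        N = edges[iN]
        for iM in range(kmode + 1, nbins + 1):
            M = edges[iM]
            err = 0.0
            for j in range(nbins):
                c = centers[j]
                if N <= c < ck:
                    t = peak * (c - N) / (ck - N)
                elif c == ck:
                    t = float(peak)
                elif ck < c <= M:
                    t = peak * (M - c) / (M - ck)
                else:
                    t = 0.0
                err += (counts[j] - t) ** 2
            if err < best_err:
                best_err, best_width = err, M - N
    return tri, best_width


def welch_psd_oracle(y, fs, nperseg, noverlap):
    """Hand-rolled Welch PSD (hann window, constant detrend, one-sided)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    w = 0.5 * (1 - np.cos(2 * np.pi * np.arange(nperseg) / nperseg))
    step = nperseg - noverlap
    nseg = (n - nperseg) // step + 1
    scale = 1.0 / (fs * np.sum(w * w))
    acc = None
    for s in range(nseg):
        seg = y[s * step: s * step + nperseg]
        seg = seg - seg.mean()
        spec = np.fft.rfft(w * seg)
        p = (spec.real ** 2 + spec.imag ** 2) * scale
        p[1:] *= 2.0
        if nperseg % 2 == 0:
            p[-1] /= 2.0
        acc = p if acc is None else acc + p
    f = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return f, acc / nseg


def band_power_oracle(f, psd, lo, hi):
    """Trapezoid integration of the PSD over [lo, hi] by scalar loop."""
    pts = [(fi, pi) for fi, pi in zip(f, psd) if lo <= fi <= hi]
    total = 0.0
    for (f0, p0), (f1, p1) in zip(pts[:-1], pts[1:]):
        total += 0.5 * (p0 + p1) * (f1 - f0)
    return total


def auc_oracle(scores, outcomes):
    """Pairwise concordance count with half credit for ties."""
    pos = [s for s, y in zip(scores, outcomes) if y == 1]
    neg = [s for s, y in zip(scores, outcomes) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def hosmer_lemeshow_oracle(probs, y, groups=10):
    """Decile-based HL statistic with rank-chunk groups (distinct probs)."""
    order = sorted(range(len(probs)), key=lambda i: probs[i])
    size = len(probs) // groups
    stat = 0.0
    for g in range(groups):
        idx = order[g * size:(g + 1) * size] if g < groups - 1 else \
            order[(groups - 1) * size:]
        n_g = len(idx)
        obs = sum(y[i] for i in idx)
        exp = sum(probs[i] for i in idx)
        stat += (obs - exp) ** 2 / (exp * (1 - exp / n_g))
    return stat


def exhaustive_backward_sets(fit_block_p, blocks, p_remove=0.10):
    """All terminal variable sets reachable by any order of valid removals.

    ``fit_block_p(frozenset_of_vars)`` must return {var: LR p} for the model
    containing exactly those variable blocks.
    """
    results = set()
    seen = set()

    def recurse(state):
        if state in seen:
            return
        seen.add(state)
        pvals = fit_block_p(state)
        removable = [v for v, p in pvals.items() if p >= p_remove]
        if not removable or not state:
            results.add(state)
            return
        for v in removable:
            recurse(state - {v})

    recurse(frozenset(blocks))
    return results
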