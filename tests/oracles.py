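"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written directly from first principles / published
formulas, deliberately avoiding the code paths (and where practical the
library calls) used by the package itself.
"""

from __future__ import annotations

import math

import numpy as np


def collapse_oracle(reads_by_sample):
    """Hash-count collapse: {sequence: {sample: count}}."""
    out = {}
    for sid, seqs in reads_by_sample.items():
        for s in seqs:
            out.setdefault(s, {}).setdefault(sid, 0)
            out[s][sid] += 1
    return out


def trim_oracle(read, adapter, min_overlap=3, max_error_rate=0.1, min_insert=10):
    """Exhaustive suffix-vs-adapter-prefix scan."""
    best = None
    for i in range(len(read)):
        suffix = read[i:]
        m = min(len(suffix), len(adapter))
        if m < min_overlap:
            break
        mism = sum(1 for a, b in zip(suffix[:m], adapter[:m]) if a != b)
        if mism <= int(m * max_error_rate):
            best = i
            break
    if best is None:
        return read, "untrimmed"
    ins = read[:best]
    return ins, ("too_short" if len(ins) < min_insert else "trimmed")


def _quantile75(values):
    """Type-7 75th percentile, written out explicitly."""
    x = sorted(values)
    h = (len(x) - 1) * 0.75
    lo = int(math.floor(h))
    if lo + 1 >= len(x):
        return x[-1]
    return x[lo] + (h - lo) * (x[lo + 1] - x[lo])


def _ranks_average(values):
    """1-based ranks with ties averaged, by explicit counting."""
    out = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        out.append(less + (equal + 1) / 2.0)
    return out


def tmm_oracle(counts, lib_sizes=None, logratio_trim=0.3, sum_trim=0.05):
    """Weighted trimmed mean of M-values from the published formula.

    `counts` is a features x samples array-like. Returns factors with
    geometric mean 1.
    """
    x = [[float(v) for v in row] for row in counts]
    n_feat = len(x)
    n_samp = len(x[0])
    if lib_sizes is None:
        lib = [sum(x[i][j] for i in range(n_feat)) for j in range(n_samp)]
    else:
        lib = [float(v) for v in lib_sizes]

    f75 = [_quantile75([x[i][j] for i in range(n_feat)]) / lib[j] for j in range(n_samp)]
    mean75 = sum(f75) / n_samp
    ref = min(range(n_samp), key=lambda j: abs(f75[j] - mean75))

    factors = []
    for j in range(n_samp):
        ms, es, vs = [], [], []
        for i in range(n_feat):
            o, r = x[i][j], x[i][ref]
            if o <= 0 or r <= 0:
                continue
            po, pr = o / lib[j], r / lib[ref]
            ms.append(math.log2(po / pr))
            es.append((math.log2(po) + math.log2(pr)) / 2.0)
            vs.append((lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r))
        if not ms or max(abs(m) for m in ms) < 1e-6:
            factors.append(1.0)
            continue
        n = len(ms)
        lo_l = math.floor(n * logratio_trim) + 1
        hi_l = n + 1 - lo_l
        lo_s = math.floor(n * sum_trim) + 1
        hi_s = n + 1 - lo_s
        rm = _ranks_average(ms)
        re = _ranks_average(es)
        num = den = 0.0
        kept = False
        for k in range(n):
            if lo_l <= rm[k] <= hi_l and lo_s <= re[k] <= hi_s:
                num += ms[k] / vs[k]
                den += 1.0 / vs[k]
                kept = True
        factors.append(2.0 ** (num / den) if kept else 1.0)

    log_mean = sum(math.log(f) for f in factors) / n_samp
    return np.array([f / math.exp(log_mean) for f in factors])


def efron_negloglik(beta, times, events, x):
    """Negative Efron partial log-likelihood for a single covariate."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    eta = beta * x
    ll = 0.0
    for t in np.unique(times[events == 1]):
        d_idx = np.where((times == t) & (events == 1))[0]
        r_idx = np.where(times >= t)[0]
        d = len(d_idx)
        sum_r = np.exp(eta[r_idx]).sum()
        sum_d = np.exp(eta[d_idx]).sum()
        ll += eta[d_idx].sum()
        for k in range(d):
            ll -= math.log(sum_r - (k / d) * sum_d)
    return -ll


def km_oracle(times, events):
    """Product-limit estimate, returned as {event time: survival}."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    out = {}
    for t in np.unique(times[events == 1]):
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_at_risk
        out[float(t)] = s
    return out


def bh_oracle(pvals):
    """Benjamini-Hochberg from the definition (step-up with cummin)."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = min(1.0, running)
    return np.array(adj)
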