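"""Independent brute-force re-implementations used only as test oracles.

Deliberately naive (plain Python loops, no numpy vector ops) so they stay
independent of the implementations they check.
"""

from __future__ import annotations

import math


def brute_force_peaks(ribo_test, rna_test, ribo_ctrl, rna_ctrl):
    """Naive cNorm -> cDiff -> cMean -> T -> runs -> scores.

    All inputs are lists of per-replicate lists (n_reps x L). Returns a dict
    with cmean, meancov, stdmean, threshold and peaks [(s, e, score_mean,
    [score_rep...])].
    """
    n_reps = len(ribo_test)
    L = len(ribo_test[0])
    cdiff = []
    for i in range(n_reps):
        row = []
        for p in range(L):
            if rna_test[i][p] == 0 or rna_ctrl[i][p] == 0:
                row.append(None)
            else:
                row.append(ribo_test[i][p] / rna_test[i][p]
                           - ribo_ctrl[i][p] / rna_ctrl[i][p])
        cdiff.append(row)
    cmean = []
    for p in range(L):
        vals = [cdiff[i][p] for i in range(n_reps)]
        if any(v is None for v in vals):
            cmean.append(None)
            for i in range(n_reps):
                cdiff[i][p] = None
        else:
            cmean.append(sum(vals) / n_reps)
    defined = [v for v in cmean if v is not None]
    if not defined:
        return {"cmean": cmean, "meancov": None, "stdmean": None,
                "threshold": None, "peaks": []}
    meancov = sum(defined) / len(defined)
    stdmean = math.sqrt(sum((v - meancov) ** 2 for v in defined) / len(defined))
    threshold = meancov + 3 * stdmean

    peaks = []
    s = None
    for p in range(L + 1):
        above = p < L and cmean[p] is not None and cmean[p] > threshold
        if above and s is None:
            s = p
        elif not above and s is not None:
            peaks.append((s, p))
            s = None

    def score(vals):
        if threshold <= 0:
            return float("nan")
        return (sum(vals) / (len(vals) * threshold) - 1) * 100

    out = []
    for s, e in peaks:
        sm = score(cmean[s:e])
        sr = [score([cdiff[i][p] for p in range(s, e)]) for i in range(n_reps)]
        out.append((s, e, sm, sr))
    return {"cmean": cmean, "meancov": meancov, "stdmean": stdmean,
            "threshold": threshold, "peaks": out}


def brute_force_logistic_wald_p(y01_a, y01_b):
    """Bernoulli logistic fit of outcome on condition (b=1) by Newton
    iteration; returns the Wald p for the condition coefficient."""
    xs = [0.0] * len(y01_a) + [1.0] * len(y01_b)
    ys = list(y01_a) + list(y01_b)
    b0 = b1 = 0.0
    for _ in range(100):
        g0 = g1 = 0.0
        h00 = h01 = h11 = 0.0
        for x, y in zip(xs, ys):
            eta = b0 + b1 * x
            mu = 1.0 / (1.0 + math.exp(-eta))
            w = mu * (1 - mu)
            g0 += y - mu
            g1 += (y - mu) * x
            h00 += w
            h01 += w * x
            h11 += w * x * x
        det = h00 * h11 - h01 * h01
        if det == 0:
            return float("nan")
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        b0 += d0
        b1 += d1
        if abs(d0) < 1e-12 and abs(d1) < 1e-12:
            break
    det = h00 * h11 - h01 * h01
    var_b1 = h00 / det
    z = b1 / math.sqrt(var_b1)
    return math.erfc(abs(z) / math.sqrt(2.0))
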