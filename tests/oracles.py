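"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: pair enumeration for
rank statistics, exact rational arithmetic for the Hardy-Weinberg test, and
direct formula evaluation for the remaining metrics.
"""

import math
from fractions import Fraction

import numpy as np


def auroc_oracle(scores, labels):
    pairs = wins = 0
    for i, li in enumerate(labels):
        if li != 1:
            continue
        for j, lj in enumerate(labels):
            if lj != 0:
                continue
            pairs += 1
            if scores[i] > scores[j]:
                wins += 1
            elif scores[i] == scores[j]:
                wins += 0.5
    return wins / pairs if pairs else float("nan")


def tau_b_oracle(x, y):
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = x[i] - x[j], y[i] - y[j]
            if a == 0 and b == 0:
                continue
            if a == 0:
                tx += 1
            elif b == 0:
                ty += 1
            elif a * b > 0:
                conc += 1
            else:
                disc += 1
    den = math.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / den if den > 0 else float("nan")


def ranks_oracle(v):
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j < len(v) and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks


def pearson_oracle(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    den = math.sqrt(float((xc ** 2).sum()) * float((yc ** 2).sum()))
    return float((xc * yc).sum() / den) if den > 0 else float("nan")


def spearman_oracle(x, y):
    return pearson_oracle(ranks_oracle(x), ranks_oracle(y))


def mcc_oracle(tp, fp, tn, fn):
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    return (tp * tn - fp * fn) / math.sqrt(den) if den else 0.0


def nmse_oracle(pred, obs):
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    var = float(np.mean((obs - obs.mean()) ** 2))
    return float(np.mean((pred - obs) ** 2) / var) if var > 0 else float("nan")


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration of the conditional heterozygote distribution."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    if n_A == 0 or n_a == 0:
        return 1.0

    def prob(h):
        hom_A = (n_A - h) // 2
        hom_a = (n_a - h) // 2
        return (Fraction(math.factorial(n), math.factorial(hom_A) * math.factorial(h)
                         * math.factorial(hom_a))
                * Fraction(2 ** h)
                * Fraction(math.factorial(n_A) * math.factorial(n_a),
                           math.factorial(2 * n)))

    rare = min(n_A, n_a)
    probs = {h: prob(h) for h in range(rare % 2, rare + 1, 2)}
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))
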