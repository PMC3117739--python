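"""Deliberately naive straight-line radiobiology oracle.

A from-scratch re-implementation of the TCP / NTCP / P+ chain using
plain Python loops and ``math`` only — no numpy, no shared code with
the package.  Used to cross-validate the composed pipeline the way the
original tool was validated against a hand-built spreadsheet.

Input curves are plain lists: a cumulative DVH as ``(doses, volumes)``
with volumes in percent.
"""

import math


def naive_differential(doses, volumes):
    """Midpoint bins + terminal bin for any residual volume."""
    bins = []
    for i in range(len(doses) - 1):
        v = volumes[i] - volumes[i + 1]
        if v < 0:
            v = 0.0
        bins.append((0.5 * (doses[i] + doses[i + 1]), v))
    if volumes[-1] > 0:
        bins.append((doses[-1], volumes[-1]))
    return bins


def naive_ntd2(dose, n_fractions, alpha_beta):
    d_i = dose / n_fractions
    return dose * (alpha_beta + d_i) / (alpha_beta + 2.0)


def naive_tcp(doses, volumes, n_fractions, alpha, alpha_beta, clonogens):
    bins = naive_differential(doses, volumes)
    total = sum(v for _, v in bins)
    surv = 0.0
    for d, v in bins:
        ntd2 = naive_ntd2(d, n_fractions, alpha_beta)
        sf = math.exp(-alpha * ntd2 * (1.0 + 2.0 / alpha_beta))
        surv += (v / total) * sf
    return math.exp(-clonogens * surv)


def naive_ntcp(doses, volumes, n_fractions, alpha_beta, td50_whole, slope_m, n_exp,
               floor=0.0):
    bins = naive_differential(doses, volumes)
    total = sum(v for _, v in bins)
    ntd2_bins = [(naive_ntd2(d, n_fractions, alpha_beta), v) for d, v in bins]
    ntd2_max = 0.0
    for d, v in ntd2_bins:
        if v > floor and d > ntd2_max:
            ntd2_max = d
    veff = 0.0
    for d, v in ntd2_bins:
        veff += (v / total) * (d / ntd2_max) ** (1.0 / n_exp)
    td50 = td50_whole * veff ** (-n_exp)
    s = (ntd2_max - td50) / (slope_m * td50)
    return 0.5 * (1.0 + math.erf(s / math.sqrt(2.0)))


def naive_p_plus(tcp, ntcps):
    out = tcp
    for p in ntcps:
        out *= 1.0 - p
    return out
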