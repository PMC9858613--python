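"""Independent oracles: direct textbook-formula implementations.

These deliberately avoid the package's vectorised code paths — statistics
are accumulated cell by cell in plain Python loops — so they can serve as
an independent cross-check of the implementation.
"""

import math

import numpy as np


def mi_bits_oracle(table) -> float:
    """Plug-in MI in bits by direct term-by-term summation."""
    table = [[float(c) for c in row] for row in np.asarray(table)]
    n = sum(sum(row) for row in table)
    row_m = [sum(row) for row in table]
    col_m = [sum(row[j] for row in table) for j in range(len(table[0]))]
    mi = 0.0
    for i, row in enumerate(table):
        for j, o in enumerate(row):
            if o > 0:
                p = o / n
                mi += p * math.log2(p / ((row_m[i] / n) * (col_m[j] / n)))
    return mi


def g_oracle(table) -> float:
    """Likelihood-ratio statistic 2*sum O*ln(O/E) by direct summation."""
    table = [[float(c) for c in row] for row in np.asarray(table)]
    n = sum(sum(row) for row in table)
    row_m = [sum(row) for row in table]
    col_m = [sum(row[j] for row in table) for j in range(len(table[0]))]
    g = 0.0
    for i, row in enumerate(table):
        for j, o in enumerate(row):
            if o > 0:
                e = row_m[i] * col_m[j] / n
                g += o * math.log(o / e)
    return 2.0 * g


def chi2_oracle(table) -> float:
    """Pearson chi-square, no continuity correction, direct summation."""
    table = [[float(c) for c in row] for row in np.asarray(table)]
    n = sum(sum(row) for row in table)
    row_m = [sum(row) for row in table]
    col_m = [sum(row[j] for row in table) for j in range(len(table[0]))]
    chi2 = 0.0
    for i, row in enumerate(table):
        for j, o in enumerate(row):
            e = row_m[i] * col_m[j] / n
            if e > 0:
                chi2 += (o - e) ** 2 / e
    return chi2


def phi_oracle(table) -> float:
    table = np.asarray(table, dtype=float)
    return math.sqrt(chi2_oracle(table) / table.sum())


def cramers_v_oracle(table) -> float:
    table = np.asarray(table, dtype=float)
    r, c = table.shape
    return math.sqrt(chi2_oracle(table) / (table.sum() * (min(r, c) - 1)))


def entropy_bits_oracle(probs) -> float:
    return -sum(p * math.log2(p) for p in probs if p > 0)


def grid_scan_pairwise_joint(target_mi, px, py, resolution=1e-6):
    """Brute-force the 2x2 free parameter to an MI target.

    Scans the (1,1) cell over the positive-association bracket at the given
    resolution and returns the cells of the best-matching joint.
    """
    lo = px * py
    hi = min(px, py)
    p11 = np.arange(lo, hi + resolution, resolution)
    p11 = p11[p11 <= hi]
    cells = np.stack(
        [p11, px - p11, py - p11, 1 - px - py + p11], axis=1
    ).clip(min=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.stack([px * py, px * (1 - py), (1 - px) * py,
                       (1 - px) * (1 - py)])
        terms = np.where(cells > 0, cells * np.log2(cells / ex), 0.0)
    mi = terms.sum(axis=1)
    best = int(np.argmin(np.abs(mi - target_mi)))
    return {
        "p11": float(p11[best]),
        "mi": float(mi[best]),
    }


def tv_distance_oracle(p, q) -> float:
    return 0.5 * sum(abs(a - b) for a, b in zip(p, q))
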