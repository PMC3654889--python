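"""Independent brute-force reference implementations of the encoders.

Deliberately written as plain double loops over the definitions, with
no shared code with the package, so they can serve as oracles.
"""

import math

PROPS = range(6)


def ac_brute(seq, table, lg):
    """Auto covariance by direct double-loop evaluation."""
    L = len(seq)
    prof = [[float(table.iloc[table.index.get_loc(c), j]) for j in PROPS] for c in seq]
    out = []
    for j in PROPS:
        mean_j = sum(prof[i][j] for i in range(L)) / L
        for lag in range(1, lg + 1):
            s = 0.0
            for i in range(L - lag):
                s += (prof[i][j] - mean_j) * (prof[i + lag][j] - mean_j)
            out.append(s / (L - lag))
    return out


def mac_brute(seq, table, dmax):
    """Moran autocorrelation by direct evaluation of the sums."""
    L = len(seq)
    prof = [[float(table.iloc[table.index.get_loc(c), j]) for j in PROPS] for c in seq]
    out = []
    for j in PROPS:
        mean_j = sum(prof[i][j] for i in range(L)) / L
        var_j = sum((prof[i][j] - mean_j) ** 2 for i in range(L)) / L
        for d in range(1, dmax + 1):
            if var_j == 0:
                out.append(0.0)
                continue
            s = 0.0
            for i in range(L - d):
                s += (prof[i][j] - mean_j) * (prof[i + d][j] - mean_j)
            out.append((s / (L - d)) / var_j)
    return out


def ct_brute(seq, groups, relative=True):
    """Conjoint-triad tally by exhaustive sliding window."""
    L = len(seq)
    counts = {}
    for i in range(L - 2):
        triad = (groups[seq[i]], groups[seq[i + 1]], groups[seq[i + 2]])
        counts[triad] = counts.get(triad, 0) + 1
    out = []
    for g1 in range(1, 8):
        for g2 in range(1, 8):
            for g3 in range(1, 8):
                c = counts.get((g1, g2, g3), 0)
                out.append(c / (L - 2) if relative else float(c))
    return out


def regions_brute(seq):
    """The ten regions, recomputed independently from the convention."""
    L = len(seq)
    q1, q2, q3 = L // 4, L // 2, (3 * L) // 4
    h, t, e = math.ceil(L / 2), math.ceil(3 * L / 4), L // 8
    return [
        seq[0:q1], seq[q1:q2], seq[q2:q3], seq[q3:L],
        seq[0:q2], seq[q2:L],
        seq[q1 : q1 + h],
        seq[0:t], seq[L - t : L], seq[e : e + t],
    ]


def ctd_brute(region, groups):
    """Composition/transition/distribution of one region, by hand."""
    n = len(region)
    g = [groups[c] for c in region]
    comp = [100.0 * sum(1 for x in g if x == k) / n for k in range(1, 8)]
    trans = []
    for r in range(1, 8):
        for s in range(r + 1, 8):
            c = 0
            for i in range(n - 1):
                if (g[i], g[i + 1]) in ((r, s), (s, r)):
                    c += 1
            trans.append(100.0 * c / (n - 1) if n > 1 else 0.0)
    dist = []
    for k in range(1, 8):
        pos = [i + 1 for i, x in enumerate(g) if x == k]
        if not pos:
            dist.extend([0.0] * 5)
            continue
        marks = [1] + [math.ceil(q * len(pos) / 100) for q in (25, 50, 75, 100)]
        dist.extend(100.0 * pos[m - 1] / n for m in marks)
    return comp + trans + dist


def ld_brute(seq, groups):
    out = []
    for region in regions_brute(seq):
        out.extend(ctd_brute(region, groups))
    return out
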