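"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's dynamic programmes and vectorised
implementations: alignments are enumerated explicitly, indices computed
with plain loops, and distributions integrated numerically.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats


def enumerate_alignments(la: int, lb: int):
    """All monotone alignments from (0,0) to (la-1, lb-1).

    Steps: diagonal, repeat-left, repeat-right; every index of each
    sequence appears in at least one pair.
    """
    def extend(path):
        i, j = path[-1]
        if i == la - 1 and j == lb - 1:
            yield path
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < la and nj < lb:
                yield from extend(path + [(ni, nj)])

    yield from extend([(0, 0)])


def brute_mdtw(times_a, energies_a, times_b, energies_b, beta, time_scale, energy_scale):
    """Exhaustive minimum over all monotone alignments."""
    la, lb = len(times_a), len(times_b)
    best = np.inf
    for path in enumerate_alignments(la, lb):
        total = 0.0
        for i, j in path:
            de = (energies_a[i] - energies_b[j]) / energy_scale
            dt = (times_a[i] - times_b[j]) / time_scale
            total += de * de + beta * dt * dt
        best = min(best, total)
    return best


def brute_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    """Per-point silhouette by definition; singleton clusters contribute 0."""
    n = len(labels)
    uniq = sorted(set(labels.tolist()))
    s = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            s.append(0.0)
            continue
        a = sum(D[i, j] for j in own) / len(own)
        b = min(
            sum(D[i, j] for j in range(n) if labels[j] == c)
            / sum(1 for j in range(n) if labels[j] == c)
            for c in uniq
            if c != labels[i]
        )
        denom = max(a, b)
        s.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(s))


def brute_dunn(D: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    uniq = sorted(set(labels.tolist()))
    diam = 0.0
    for c in uniq:
        members = [i for i in range(n) if labels[i] == c]
        for x in members:
            for y in members:
                diam = max(diam, D[x, y])
    sep = np.inf
    for ci in uniq:
        for cj in uniq:
            if ci >= cj:
                continue
            for x in (i for i in range(n) if labels[i] == ci):
                for y in (j for j in range(n) if labels[j] == cj):
                    sep = min(sep, D[x, y])
    return sep / diam


def studentized_range_sf(q: float, k: int, df: float) -> float:
    """P(Q_{k,df} >= q) by direct numerical integration.

    Conditional on the scale s = sqrt(chi2_df/df), the range of k
    standard normals satisfies
      P(range < q s) = k * int phi(z) [Phi(z) - Phi(z - q s)]^(k-1) dz,
    which is integrated against the density of s.
    """
    def inner(s):
        def f(z):
            return stats.norm.pdf(z) * (
                stats.norm.cdf(z) - stats.norm.cdf(z - q * s)
            ) ** (k - 1)

        val, _ = integrate.quad(f, -8.0, 8.0, limit=200)
        return k * val

    def s_density(s):
        # density of sqrt(X/df), X ~ chi2(df)
        return stats.chi2.pdf(df * s * s, df) * 2.0 * df * s

    cdf, _ = integrate.quad(
        lambda s: s_density(s) * inner(s), 0.0, 10.0, limit=200
    )
    return 1.0 - cdf
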