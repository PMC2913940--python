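"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: the arc scan is a plain
double loop, the exact 3x2 test enumerates margin-fixed tables in rational
arithmetic, and the remaining oracles are textbook closed forms.
"""

from fractions import Fraction
from math import comb

import numpy as np

ARC_RTOL = 1e-10


def arc_scan_oracle(x, min_width=2):
    """Exhaustive double-loop maximal-arc scan with lexicographic ties."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    best = None
    for i in range(n):
        for j in range(i + min_width, n + 1):
            k = j - i
            if n - k < min_width:
                continue
            arc = x[i:j]
            comp = np.r_[x[:i], x[j:]]
            ss = ((arc - arc.mean()) ** 2).sum() + ((comp - comp.mean()) ** 2).sum()
            d = arc.mean() - comp.mean()
            den = np.sqrt(ss / (n - 2) * (1 / k + 1 / (n - k)))
            if den > 0:
                t = d / den
            else:
                t = np.inf * np.sign(d) if d != 0 else 0.0
            a = abs(t)
            if (
                best is None
                or a > best[3] * (1 + ARC_RTOL)
                or (a >= best[3] * (1 - ARC_RTOL) and (i, j) < (best[0], best[1]))
            ):
                best = (i, j, t, a)
    return best


def fisher_3x2_oracle(table, tie_rtol=Fraction(1, 10**7)):
    """Exact 3x2 conditional p by full rational enumeration of the margins."""
    t = np.asarray(table, dtype=int)
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    n_tot = int(t.sum())

    def prob(a, n10, b):
        return Fraction(comb(r[0], a) * comb(r[1], n10) * comb(r[2], b), comb(n_tot, c[0]))

    p_obs = prob(t[0, 0], t[1, 0], t[2, 0])
    total = Fraction(0)
    for a in range(min(r[0], c[0]) + 1):
        for b in range(min(r[2], c[0] - a) + 1):
            n10 = c[0] - a - b
            if 0 <= n10 <= r[1]:
                pr = prob(a, n10, b)
                if pr <= p_obs * (1 + tie_rtol):
                    total += pr
    return float(total)


def pooled_t_oracle(x, y):
    """Classic pooled two-sample t and its two-sided p (closed form)."""
    from scipy.stats import t as tdist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * tdist.sf(abs(t), nx + ny - 2)
    return t, p


def bh_oracle(p):
    """Benjamini-Hochberg step-up: min over the tail of p*m/rank."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def hypergeom_upper_tail_oracle(k_min, N, K, n):
    """P(X >= k_min) for hypergeometric X by explicit pmf summation."""
    total = Fraction(0)
    for x in range(max(k_min, 0), min(n, K) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
    return float(total)
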