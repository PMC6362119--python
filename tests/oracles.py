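"""Independent brute-force oracles used by the test suite.

Everything here is written directly from definitions (double loops over
strings, exact Fraction arithmetic), deliberately sharing no code with the
package implementations it checks.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

MISSING = set("N-")


def retained_sites(seqs: list[str]) -> list[int]:
    """Complete-deletion policy: sites free of N/- in every sequence."""
    L = len(seqs[0])
    return [j for j in range(L) if all(s[j] not in MISSING for s in seqs)]


def classify_sites_bf(seqs: list[str]) -> tuple[int, int, int, int]:
    keep = retained_sites(seqs)
    L = len(seqs[0])
    inv = sing = pinf = 0
    for j in keep:
        col = [s[j] for s in seqs]
        states = set(col)
        if len(states) == 1:
            inv += 1
        elif sum(col.count(x) >= 2 for x in states) >= 2:
            pinf += 1
        else:
            sing += 1
    return inv, sing, pinf, L - len(keep)


def haplotypes_bf(seqs: list[str]) -> dict[str, int]:
    keep = retained_sites(seqs)
    out: dict[str, int] = {}
    for s in seqs:
        key = "".join(s[j] for j in keep)
        out[key] = out.get(key, 0) + 1
    return out


def pi_bf(seqs: list[str]) -> float:
    """Mean per-site pairwise difference over all pairs, retained sites."""
    keep = retained_sites(seqs)
    n = len(seqs)
    if n < 2 or not keep:
        return 0.0
    tot = Fraction(0)
    for a, b in combinations(seqs, 2):
        tot += Fraction(sum(a[j] != b[j] for j in keep), len(keep))
    return float(tot / (n * (n - 1) // 2))


def h_bf(seqs: list[str]) -> float:
    n = len(seqs)
    if n < 2:
        return 0.0
    counts = haplotypes_bf(seqs).values()
    ssq = sum(Fraction(c, n) ** 2 for c in counts)
    return float(Fraction(n, n - 1) * (1 - ssq))


def segregating_bf(seqs: list[str]) -> int:
    return sum(len({s[j] for s in seqs}) > 1 for j in retained_sites(seqs))


def p_distance_bf(a: str, b: str, deletion: str, all_seqs: list[str]) -> float | None:
    if deletion == "complete":
        keep = retained_sites(all_seqs)
    else:
        keep = [j for j in range(len(a)) if a[j] not in MISSING and b[j] not in MISSING]
    if not keep:
        return None
    return sum(a[j] != b[j] for j in keep) / len(keep)


def diff_count_bf(a: str, b: str, keep: list[int]) -> int:
    return sum(a[j] != b[j] for j in keep)


def amova_bf(d: list[list[float]], groups: list[list[int]]):
    """Excoffier-Smouse-Quattro one-level decomposition, written straight
    from the sums over squared distances."""
    N = len(d)
    G = len(groups)
    ss_total = sum(d[i][j] ** 2 for i in range(N) for j in range(i + 1, N)) / N
    ss_within = 0.0
    for g in groups:
        ng = len(g)
        if ng > 1:
            ss_within += sum(d[i][j] ** 2 for i in g for j in g if i < j) / ng
    ss_among = ss_total - ss_within
    df_a, df_w = G - 1, N - G
    ms_a = ss_among / df_a
    ms_w = ss_within / df_w
    n_eff = (N - sum(len(g) ** 2 for g in groups) / N) / df_a
    sigma_a = (ms_a - ms_w) / n_eff
    sigma_w = ms_w
    phi = sigma_a / (sigma_a + sigma_w) if (sigma_a + sigma_w) != 0 else 0.0
    return ss_among, ss_within, sigma_a, sigma_w, phi


def sumstats_bf(seqs: list[str], pops: dict[str, list[int]], order: list[str]):
    """Summary-statistic vector from definitions (strings and loops)."""
    keep = retained_sites(seqs)
    vals: list[float] = []
    n = len(seqs)

    def mean_within(idx):
        pairs = [(i, j) for i, j in combinations(idx, 2)]
        if not pairs:
            return None
        return sum(diff_count_bf(seqs[i], seqs[j], keep) for i, j in pairs) / len(pairs)

    # pooled allele counts per retained site
    def col(j):
        return [seqs[i][j] for i in range(n)]

    seg_pooled = [j for j in keep if len(set(col(j))) > 1]
    for p in order:
        idx = pops[p]
        sub = ["".join(seqs[i][j] for j in keep) for i in idx]
        vals.append(float(len(set(sub))))
        vals.append(float(sum(len({seqs[i][j] for i in idx}) > 1 for j in keep)))
        mw = mean_within(idx)
        vals.append(float(mw) if mw is not None else 0.0)
        priv = 0
        for j in seg_pooled:
            c = col(j)
            states = sorted(set(c))
            major = max(states, key=lambda s: (c.count(s), -states.index(s)))
            minors = [s for s in states if s != major]
            if minors and all(
                all(i in idx for i in range(n) if seqs[i][j] == s) for s in minors
            ):
                priv += 1
        vals.append(float(priv))
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            ia, ib = pops[order[a]], pops[order[b]]
            hb = sum(diff_count_bf(seqs[i], seqs[j], keep) for i in ia for j in ib) / (
                len(ia) * len(ib))
            vals.append(hb)
            ws = [w for w in (mean_within(ia), mean_within(ib)) if w is not None]
            hw = sum(ws) / len(ws) if ws else 0.0
            vals.append(0.0 if hb <= 0 else 1.0 - hw / hb)
    return vals


from functools import lru_cache


@lru_cache(maxsize=None)
def stirling2_exact(k: int, j: int) -> int:
    if j in (0, k):
        return 1 if (j == k or k == 0) else 0
    if j > k or j < 0:
        return 0
    return j * stirling2_exact(k - 1, j) + stirling2_exact(k - 1, j - 1)


def parsimony_probability_exact(j: int, L: int, terms: int = 60) -> Fraction:
    """Exact-arithmetic probability of parsimony for j differences over L
    sites: geometric number of mutations (theta = j) with multinomial
    occupancy correction."""
    if j < 1:
        return Fraction(1)
    r = Fraction(j, j + 1)
    denom = Fraction(0)
    for k in range(j, j + terms + 1):
        denom += r ** (k - j) * Fraction(stirling2_exact(k, j), L ** (k - j))
    return 1 / denom


def parsimony_limit_exact(L: int, alpha: Fraction = Fraction(95, 100)) -> int:
    j = 1
    while parsimony_probability_exact(j + 1, L) >= alpha:
        j += 1
    return j
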