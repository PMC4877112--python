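"""Distance, codon-substitution and distribution-shape statistics.

Implements the evolutionary toolkit used to analyse element copies: p-distance
and Kimura two-parameter distance (optionally gamma-corrected), a sliding
conservation track over a multiple alignment, Nei-Gojobori synonymous /
nonsynonymous substitution counting with Jukes-Cantor correction, the
one-tailed Fisher test used to flag horizontal transfer (transposon dS lower
than host-gene dS), Hartigan's dip statistic with Monte-Carlo p-values, and
Kruskal-Wallis group comparison with rank-based pairwise follow-ups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from Bio.Data import CodonTable

_GAPS = set("-.")
_VALID = set("ACGT")
_PURINES = set("AG")

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)


def _aa(codon: str) -> str:
    return _TABLE.forward_table[codon]


@dataclass
class PairwiseDistanceResult:
    p: float
    d: float
    sites_used: int
    model: str  # {"p", "K2P", "K2P+G"}
    defined: bool = True
    transitions: int = 0
    transversions: int = 0


@dataclass
class CodonSubstitutionResult:
    S: float
    N: float
    Sd: float
    Nd: float
    codons_used: int

    @property
    def pS(self) -> float:
        return self.Sd / self.S

    @property
    def pN(self) -> float:
        return self.Nd / self.N

    @property
    def dS(self) -> float:
        """Jukes-Cantor-corrected synonymous rate; NaN when pS >= 3/4."""
        if self.pS >= 0.75:
            return float("nan")
        return -0.75 * math.log(1.0 - 4.0 * self.pS / 3.0)

    @property
    def dN(self) -> float:
        if self.pN >= 0.75:
            return float("nan")
        return -0.75 * math.log(1.0 - 4.0 * self.pN / 3.0)

    @property
    def dS_defined(self) -> bool:
        return self.pS < 0.75


@dataclass
class HTTestResult:
    table: list[list[int]]
    p_one_tailed: float
    verdict: str  # {"HT_supported", "not_supported"}
    alpha: float = 0.005


@dataclass
class DipTestResult:
    dip: float
    p: float
    n: int
    n_boot: int
    seed: int | None = None
    null_dips: np.ndarray | None = field(default=None, repr=False)


def _paired_sites(a: str, b: str):
    """Indices where both sequences carry an unambiguous base (pairwise deletion)."""
    for ca, cb in zip(a.upper(), b.upper()):
        if ca in _VALID and cb in _VALID:
            yield ca, cb


def p_distance(a: str, b: str) -> PairwiseDistanceResult:
    """Proportion of differing sites, pairwise deletion of gaps/ambiguities."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned (equal length)")
    sites = diffs = 0
    for ca, cb in _paired_sites(a, b):
        sites += 1
        diffs += ca != cb
    if sites == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    p = diffs / sites
    return PairwiseDistanceResult(p=p, d=p, sites_used=sites, model="p")


def k2p_distance(a: str, b: str, gamma_shape: float | None = 1.0) -> PairwiseDistanceResult:
    """Kimura two-parameter distance.

    ``gamma_shape`` of None (or inf) gives classic K2P,
    d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q); a finite shape ``a`` applies
    gamma-distributed rate variation across sites,
    d = (a/2)[(1-2P-Q)^(-1/a) - 1] + (a/4)[(1-2Q)^(-1/a) - 1].
    Out-of-domain inputs (saturation) are returned flagged undefined.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned (equal length)")
    sites = ts = tv = 0
    for ca, cb in _paired_sites(a, b):
        sites += 1
        if ca == cb:
            continue
        if (ca in _PURINES) == (cb in _PURINES):
            ts += 1
        else:
            tv += 1
    if sites == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    P, Q = ts / sites, tv / sites
    model = "K2P" if gamma_shape in (None, math.inf) else "K2P+G"
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return PairwiseDistanceResult(p=P + Q, d=float("nan"), sites_used=sites,
                                      model=model, defined=False,
                                      transitions=ts, transversions=tv)
    if model == "K2P":
        d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    else:
        ga = float(gamma_shape)
        d = (ga / 2.0) * (w1 ** (-1.0 / ga) - 1.0) + (ga / 4.0) * (w2 ** (-1.0 / ga) - 1.0)
    return PairwiseDistanceResult(p=P + Q, d=d, sites_used=sites, model=model,
                                  transitions=ts, transversions=tv)


def sliding_conservation(msa: list[str], window: int = 100) -> np.ndarray:
    """Mean pairwise identity per column, smoothed over a centered window.

    Per column: match=1, mismatch or gap-vs-base=0, gap-vs-gap pairs excluded.
    Columns where every pair is gap-vs-gap get score 0. The window is truncated
    at the alignment edges.
    """
    if len(msa) < 2:
        raise ValueError("need at least 2 aligned sequences")
    L = len(msa[0])
    if any(len(s) != L for s in msa):
        raise ValueError("alignment rows differ in length")
    seqs = [s.upper() for s in msa]
    col_scores = np.zeros(L)
    for c in range(L):
        chars = [s[c] for s in seqs]
        num = den = 0
        for x, y in itertools.combinations(chars, 2):
            if x in _GAPS and y in _GAPS:
                continue
            den += 1
            num += (x == y and x not in _GAPS)
        col_scores[c] = num / den if den else 0.0
    half = window // 2
    out = np.empty(L)
    csum = np.concatenate([[0.0], np.cumsum(col_scores)])
    for c in range(L):
        lo = max(0, c - half)
        hi = min(L, c + window - half)
        out[c] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def _codon_syn_fraction(codon: str) -> float:
    """Number of synonymous one-step changes / 3; stop-creating changes count
    as nonsynonymous (they stay in the denominator)."""
    syn = 0
    aa0 = _aa(codon)
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if mut not in _STOPS and _aa(mut) == aa0:
                syn += 1
    return syn / 3.0


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged with
    equal weights over all minimal substitution pathways; pathways passing
    through a stop codon are excluded unless every pathway does."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                blocked = True
                break
            if _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((blocked, sd, nd))
    valid = [(sd, nd) for blocked, sd, nd in paths if not blocked]
    if not valid:
        valid = [(sd, nd) for _, sd, nd in paths]
        # a blocked pathway's truncated step counts omit the remaining steps;
        # distribute them as nonsynonymous (the stop route is lethal)
        valid = [(sd, nd + (len(diff) - sd - nd)) for sd, nd in valid]
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


def nei_gojobori(cds_a: str, cds_b: str) -> CodonSubstitutionResult:
    """Nei-Gojobori synonymous/nonsynonymous counting for one aligned CDS pair.

    Codons containing gaps or ambiguities in either sequence are excluded
    pairwise; a trailing stop codon is dropped; internal stops are an error.
    Multi-substitution codons are averaged over all minimal pathways with equal
    weights.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("CDS pair must be aligned (equal length)")
    if len(a) % 3:
        raise ValueError("aligned length must be a multiple of 3")
    cod_a = [a[i:i + 3] for i in range(0, len(a), 3)]
    cod_b = [b[i:i + 3] for i in range(0, len(b), 3)]
    if cod_a and cod_a[-1] in _STOPS and cod_b[-1] in _STOPS:
        cod_a, cod_b = cod_a[:-1], cod_b[:-1]
    S = N = Sd = Nd = 0.0
    used = 0
    for idx, (ca, cb) in enumerate(zip(cod_a, cod_b)):
        if not (set(ca) <= _VALID and set(cb) <= _VALID):
            continue
        if ca in _STOPS or cb in _STOPS:
            raise ValueError(f"internal stop codon at codon {idx}")
        used += 1
        S += (_codon_syn_fraction(ca) + _codon_syn_fraction(cb)) / 2.0
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    if used == 0:
        raise ValueError("no comparable codons")
    N = 3.0 * used - S
    return CodonSubstitutionResult(S=S, N=N, Sd=Sd, Nd=Nd, codons_used=used)


def ht_fisher_test(te: CodonSubstitutionResult, gene: CodonSubstitutionResult,
                   alpha: float = 0.005) -> HTTestResult:
    """One-tailed Fisher exact test: is the transposon's synonymous-substitution
    proportion lower than the host gene's?

    The 2x2 table rows are (TE, gene), columns (synonymous differences,
    remaining synonymous sites), each rounded to integers. A significantly
    lower TE proportion supports horizontal transfer.
    """
    cells = [[round(te.Sd), round(te.S - te.Sd)],
             [round(gene.Sd), round(gene.S - gene.Sd)]]
    if round(te.S) <= 0 or round(gene.S) <= 0:
        raise ValueError("zero synonymous sites")
    if min(min(r) for r in cells) < 0:
        raise ValueError("negative cell in contingency table")
    _, p = stats.fisher_exact(cells, alternative="less")
    verdict = "HT_supported" if p < alpha else "not_supported"
    return HTTestResult(table=cells, p_one_tailed=float(p), verdict=verdict, alpha=alpha)


def pairwise_diversity(copies: list[str]) -> list[float]:
    """All n(n-1)/2 pairwise p-distances among aligned element copies."""
    if len(copies) < 2:
        raise ValueError("need at least 2 copies")
    return [p_distance(a, b).p for a, b in itertools.combinations(copies, 2)]


# --- Hartigan dip -----------------------------------------------------------

def _hull_touches(xs: np.ndarray, ys: np.ndarray, lower: bool) -> list[int]:
    """Indices of the lower (or upper) convex-hull vertices of (xs, ys),
    xs nondecreasing."""
    sgn = 1.0 if lower else -1.0
    hull: list[int] = []
    for i in range(len(xs)):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            cross = (xs[k] - xs[j]) * (sgn * (ys[i] - ys[j])) - \
                    (xs[i] - xs[j]) * (sgn * (ys[k] - ys[j]))
            if cross <= 0:
                hull.pop()
            else:
                break
        # vertical stacks: keep only the extreme point at equal x
        if hull and xs[hull[-1]] == xs[i]:
            if sgn * ys[i] <= sgn * ys[hull[-1]]:
                hull.pop()
            else:
                continue
        hull.append(i)
    return hull


def _interp(xs, ys, touches, xq: float) -> float:
    """Piecewise-linear interpolation of the hull at xq."""
    tx = [xs[t] for t in touches]
    ty = [ys[t] for t in touches]
    return float(np.interp(xq, tx, ty))


def dip_statistic(values) -> float:
    """Hartigan & Hartigan dip statistic: the smallest sup-distance between the
    empirical cdf and any unimodal distribution function.

    Computed by the iterative greatest-convex-minorant / least-concave-majorant
    search over shrinking modal intervals. For n values the statistic lies in
    [1/(2n), 1/4]; equally spaced (unimodal-uniform) data attain the minimum.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 1:
        raise ValueError("empty sample")
    if n == 1 or x[0] == x[-1]:
        return 1.0 / (2.0 * n)
    yl = np.arange(n) / n          # F(x_i-): lower step corners
    yu = np.arange(1, n + 1) / n   # F(x_i): upper step corners
    lo, hi = 0, n - 1
    D = 1.0 / n  # endpoint corner gap, always attainable
    while True:
        if x[hi] == x[lo] or hi - lo < 1:
            break
        idx = np.arange(lo, hi + 1)
        gcm = [lo + t for t in _hull_touches(x[idx], yl[idx], lower=True)]
        lcm = [lo + t for t in _hull_touches(x[idx], yu[idx], lower=False)]

        # largest gap between the two envelopes, measured at touch points
        best_gap = -1.0
        candidates: list[tuple[float, int, int]] = []
        for i in lcm:
            g = yu[i] - _interp(x, yl, gcm, x[i])
            # modal interval: gcm vertex at/left of x_i, through this lcm vertex
            ja = max((j for j in gcm if x[j] <= x[i]), default=gcm[0])
            candidates.append((g, ja, i))
        for j in gcm:
            g = _interp(x, yu, lcm, x[j]) - yl[j]
            ib = min((i for i in lcm if x[i] >= x[j]), default=lcm[-1])
            candidates.append((g, j, ib))
        best_gap = max(c[0] for c in candidates)
        if best_gap <= D + 1e-12:
            break
        # among max-gap candidates prefer the one shrinking the interval most
        pool = [c for c in candidates if c[0] >= best_gap - 1e-12]
        pool.sort(key=lambda c: ((c[1] - lo) + (hi - c[2])), reverse=True)
        _, new_lo, new_hi = pool[0]
        if (new_lo, new_hi) == (lo, hi):
            break
        # deviations of F from the envelopes on the discarded wings
        dl = max((yu[i] - _interp(x, yl, gcm, x[i]) for i in range(lo, new_lo + 1)),
                 default=0.0)
        du = max((_interp(x, yu, lcm, x[i]) - yl[i] for i in range(new_hi, hi + 1)),
                 default=0.0)
        D = max(D, dl, du)
        lo, hi = new_lo, new_hi
    return max(D / 2.0, 1.0 / (2.0 * n))


def dip_null_distribution(n: int, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo null dips from uniform(0,1) samples of size n."""
    return np.array([dip_statistic(rng.random(n)) for _ in range(n_boot)])


def dip_test(values, n_boot: int = 10000, seed: int | None = None,
             null_dips: np.ndarray | None = None) -> DipTestResult:
    """Dip test for unimodality; p is the Monte-Carlo fraction of uniform null
    samples (same n) with dip >= observed.

    A precomputed ``null_dips`` table (from :func:`dip_null_distribution`)
    may be supplied to amortise the null across many tests at the same n.
    """
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    if n < 4:
        raise ValueError("need at least 4 values")
    if n_boot < 100 and null_dips is None:
        raise ValueError("n_boot must be >= 100")
    d = dip_statistic(vals)
    if np.all(vals == vals[0]):
        return DipTestResult(dip=d, p=1.0, n=n, n_boot=0, seed=seed)
    if null_dips is None:
        rng = np.random.default_rng(seed)
        null_dips = dip_null_distribution(n, n_boot, rng)
    p = float(np.mean(null_dips >= d - 1e-15))
    return DipTestResult(dip=d, p=p, n=n, n_boot=len(null_dips), seed=seed,
                         null_dips=null_dips)


def group_compare(groups: dict[str, list[float]] | list[list[float]],
                  alpha: float = 0.05) -> dict:
    """Kruskal-Wallis test across groups plus pairwise rank-based follow-ups.

    Follow-ups are two-sided Mann-Whitney U tests with Holm correction (a
    rank-based stand-in for parametric post-hoc comparisons on these
    non-parametric data).
    """
    if isinstance(groups, dict):
        names = list(groups)
        data = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        names = [f"group{i}" for i in range(len(groups))]
        data = [np.asarray(g, dtype=float) for g in groups]
    if len(data) < 2 or any(len(g) < 2 for g in data):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.all(g == data[0][0]) for g in data):
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*data)
    pairs = []
    raw = []
    for (i, j) in itertools.combinations(range(len(data)), 2):
        if np.array_equal(data[i], data[j]):
            pu = 1.0
        else:
            _, pu = stats.mannwhitneyu(data[i], data[j], alternative="two-sided")
        pairs.append((names[i], names[j]))
        raw.append(float(pu))
    # Holm step-down
    order = np.argsort(raw)
    m = len(raw)
    adj = [0.0] * m
    running = 0.0
    for rank, k in enumerate(order):
        running = max(running, (m - rank) * raw[k])
        adj[k] = min(1.0, running)
    return {
        "H": float(H),
        "p": float(p),
        "significant": bool(p < alpha),
        "pairwise": [
            {"a": a, "b": b, "p_raw": pr, "p_holm": pa,
             "significant": bool(pa < alpha)}
            for (a, b), pr, pa in zip(pairs, raw, adj)
        ],
        "alpha": alpha,
    }
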