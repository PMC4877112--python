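"""Evolution statistics against enumeration, closed-form and LP oracles."""

import itertools
import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy.optimize import linprog

from baritone.evolution import (dip_null_distribution, dip_statistic, dip_test,
                                group_compare, ht_fisher_test, k2p_distance,
                                nei_gojobori, p_distance, pairwise_diversity,
                                sliding_conservation)

from conftest import random_seq

# --- independent Nei-Gojobori oracle ---------------------------------------

CODON_TABLE = {}
_BASES = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for i, c1 in enumerate(_BASES):
    for j, c2 in enumerate(_BASES):
        for k, c3 in enumerate(_BASES):
            CODON_TABLE[c1 + c2 + c3] = _AA[16 * i + 4 * j + k]


def ng_sites_oracle(codon):
    syn = 0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if CODON_TABLE[mut] != "*" and CODON_TABLE[mut] == CODON_TABLE[codon]:
                syn += 1
    return syn / 3.0


def ng_pathways_oracle(c1, c2):
    """Explicit enumeration of all substitution pathways between two codons."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    all_paths, valid = [], []
    for order in itertools.permutations(diff):
        cur, sd, nd, blocked = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if CODON_TABLE[nxt] == "*":
                blocked = True
                break
            sd += CODON_TABLE[cur] == CODON_TABLE[nxt]
            nd += CODON_TABLE[cur] != CODON_TABLE[nxt]
            cur = nxt
        if blocked:
            all_paths.append((sd, nd + (len(diff) - sd - nd)))
        else:
            path = (sd, nd)
            all_paths.append(path)
            valid.append(path)
    use = valid or all_paths
    return (sum(p[0] for p in use) / len(use), sum(p[1] for p in use) / len(use))


def random_cds_pair(rng, n_codons):
    codons = [c for c in CODON_TABLE if CODON_TABLE[c] != "*"]
    a = [rng.choice(codons)]
    b = [rng.choice(codons)]
    while len(a) < n_codons:
        ca = rng.choice(codons)
        cb = "".join(x if rng.random() < 0.8 else rng.choice(list("ACGT"))
                     for x in ca)
        if CODON_TABLE.get(cb) == "*":
            continue
        a.append(ca)
        b.append(cb)
    return "".join(a), "".join(b)


# --- exact Fisher oracle ----------------------------------------------------

def fisher_less_oracle(a, b, c, d):
    """One-tailed (less) Fisher p by exact hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    n1 = a + c
    N = r1 + r2
    denom = comb(N, n1)
    p = Fraction(0)
    for k in range(max(0, n1 - r2), min(r1, n1) + 1):
        if k <= a:
            p += Fraction(comb(r1, k) * comb(r2, n1 - k), denom)
    return float(p)


# --- exact dip oracle (LP over piecewise-linear unimodal cdfs) --------------

def dip_lp_oracle(values):
    x = np.sort(np.asarray(values, float))
    n = len(x)
    u, counts = np.unique(x, return_counts=True)
    m = len(u)
    cum = np.cumsum(counts) / n
    cum_lo = np.concatenate([[0.0], cum[:-1]])
    best = np.inf
    for t in range(m):
        nv = m + 2
        iD, imp = m + 1, m
        A, bv = [], []

        def band(ivar, *corner_vals):
            for v in corner_vals:
                row = np.zeros(nv); row[ivar] = 1; row[iD] = -1
                A.append(row); bv.append(v)
                row = np.zeros(nv); row[ivar] = -1; row[iD] = -1
                A.append(row); bv.append(-v)

        for k in range(m):
            if k != t:
                band(k, cum_lo[k], cum[k])
        band(t, cum_lo[t])   # left limit at the mode atom
        band(imp, cum[t])    # value after the jump
        chain = list(range(t + 1)) + [imp] + list(range(t + 1, m))
        for a2, b2 in zip(chain, chain[1:]):
            row = np.zeros(nv); row[a2] = 1; row[b2] = -1
            A.append(row); bv.append(0.0)

        def gv(k):
            return imp if k == t else k

        for k in range(1, m - 1):
            d1, d2 = u[k] - u[k - 1], u[k + 1] - u[k]
            if k + 1 <= t:
                row = np.zeros(nv)
                row[k + 1] -= 1 / d2; row[k] += 1 / d2 + 1 / d1; row[k - 1] -= 1 / d1
                A.append(row); bv.append(0.0)
            if k - 1 >= t:
                row = np.zeros(nv)
                row[gv(k + 1)] += 1 / d2; row[gv(k)] -= 1 / d2 + 1 / d1
                row[gv(k - 1)] += 1 / d1
                A.append(row); bv.append(0.0)
        c = np.zeros(nv); c[iD] = 1
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(bv),
                      bounds=[(0, 1)] * (m + 1) + [(0, None)], method="highs")
        if res.success:
            best = min(best, res.fun)
    return best


# --- tests ------------------------------------------------------------------

class TestPDistance:
    def test_identical(self):
        assert p_distance("A" * 100, "A" * 100).p == 0.0

    def test_quarter(self):
        assert p_distance("AAAA", "AAAT").p == 0.25

    def test_gap_exclusion(self):
        r = p_distance("AA-A", "AATA")
        assert r.sites_used == 3 and r.p == 0.0

    def test_no_sites_error(self):
        with pytest.raises(ValueError):
            p_distance("---", "AAA")


class TestK2P:
    def test_zero_distance(self):
        r = k2p_distance("ACGT" * 10, "ACGT" * 10, gamma_shape=None)
        assert r.d == 0.0

    def test_classic_closed_form(self):
        # P=0.1, Q=0.05 realised on 100 sites: 10 transitions, 5 transversions
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        r = k2p_distance(a, b, gamma_shape=None)
        expect = -0.5 * math.log(1 - 2 * 0.1 - 0.05) - 0.25 * math.log(1 - 2 * 0.05)
        assert r.d == pytest.approx(expect, abs=1e-12)

    def test_gamma_formula_and_limit(self):
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        P, Q = 0.1, 0.05
        for shape in (0.5, 1.0, 2.0):
            r = k2p_distance(a, b, gamma_shape=shape)
            expect = (shape / 2) * ((1 - 2 * P - Q) ** (-1 / shape) - 1) + \
                     (shape / 4) * ((1 - 2 * Q) ** (-1 / shape) - 1)
            assert r.d == pytest.approx(expect, abs=1e-12)
        assert k2p_distance(a, b, gamma_shape=1e6).d == pytest.approx(
            k2p_distance(a, b, gamma_shape=None).d, abs=1e-4)

    def test_saturation_flagged(self):
        r = k2p_distance("A" * 10, "G" * 10)
        assert not r.defined and math.isnan(r.d)


class TestSlidingConservation:
    def test_identical_sequences(self):
        track = sliding_conservation(["ACGT" * 5] * 3, window=4)
        assert np.allclose(track, 1.0)

    def test_everywhere_different(self):
        track = sliding_conservation(["AAAA", "CCCC"], window=2)
        assert np.allclose(track, 0.0)

    def test_hand_computed_toy(self):
        # columns:      match?  scores per column for 3 seqs (3 pairs):
        # col0 AAA -> 1.0 ; col1 AAC -> 1/3 ; col2 A-A -> gap-vs-base pairs:
        #   (A,-)=0,(A,A)=1,(-,A)=0 -> 1/3 ; col3 CCC -> 1.0 ; col4 ACG -> 0
        msa = ["AAACA", "AA-CC", "ACACG"]
        col = [1.0, 1 / 3, 1 / 3, 1.0, 0.0]
        track = sliding_conservation(msa, window=3)
        expect = [np.mean(col[max(0, i - 1):i + 2]) for i in range(5)]
        assert np.allclose(track, expect)


class TestNeiGojobori:
    def test_identical_cds(self):
        r = nei_gojobori("ATGAAACCC", "ATGAAACCC")
        assert r.Sd == 0 and r.Nd == 0 and r.dS == 0 and r.dN == 0

    def test_site_counts_conserved(self):
        rng = np.random.default_rng(0)
        a, b = random_cds_pair(rng, 30)
        r = nei_gojobori(a, b)
        assert r.S + r.N == pytest.approx(3 * r.codons_used)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = random_cds_pair(rng, 25)
        r1, r2 = nei_gojobori(a, b), nei_gojobori(b, a)
        assert r1.Sd == pytest.approx(r2.Sd) and r1.S == pytest.approx(r2.S)

    def test_matches_pathway_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a, b = random_cds_pair(rng, 30)
            r = nei_gojobori(a, b)
            S = sum(ng_sites_oracle(a[i:i + 3]) + ng_sites_oracle(b[i:i + 3])
                    for i in range(0, len(a), 3)) / 2
            sd = nd = 0.0
            for i in range(0, len(a), 3):
                s_, n_ = ng_pathways_oracle(a[i:i + 3], b[i:i + 3])
                sd += s_
                nd += n_
            assert r.S == pytest.approx(S)
            assert r.N == pytest.approx(3 * (len(a) // 3) - S)
            assert r.Sd == pytest.approx(sd)
            assert r.Nd == pytest.approx(nd)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            nei_gojobori("ATGTAACCC", "ATGTAACCC")

    def test_saturated_ds_flagged(self):
        # force pS high via fully divergent synonymous-rich codons is hard;
        # instead check the flag logic directly on the dataclass
        from baritone.evolution import CodonSubstitutionResult
        r = CodonSubstitutionResult(S=4.0, N=8.0, Sd=3.5, Nd=0.0, codons_used=4)
        assert not r.dS_defined and math.isnan(r.dS)


class TestHtFisher:
    def test_identical_counts_not_supported(self):
        r = nei_gojobori("ATGAAACCCGGG", "ATGAAGCCCGGG")
        res = ht_fisher_test(r, r)
        assert res.p_one_tailed >= 0.5 and res.verdict == "not_supported"

    def test_matches_enumeration_oracle_exhaustive(self):
        for N in range(1, 13):
            for a in range(N + 1):
                for b in range(N + 1 - a):
                    for c in range(N + 1 - a - b):
                        d = N - a - b - c
                        from scipy.stats import fisher_exact
                        p = fisher_exact([[a, b], [c, d]], alternative="less")[1]
                        assert p == pytest.approx(
                            fisher_less_oracle(a, b, c, d), rel=1e-9)

    def test_matches_enumeration_oracle_large_margins(self):
        from baritone.evolution import CodonSubstitutionResult as C
        rng = np.random.default_rng(3)
        for _ in range(100):
            a, b = int(rng.integers(0, 100)), int(rng.integers(1, 101))
            c, d = int(rng.integers(0, 100)), int(rng.integers(1, 101))
            te = C(S=float(a + b), N=1.0, Sd=float(a), Nd=0.0, codons_used=1)
            gene = C(S=float(c + d), N=1.0, Sd=float(c), Nd=0.0, codons_used=1)
            res = ht_fisher_test(te, gene)
            assert res.p_one_tailed == pytest.approx(
                fisher_less_oracle(a, b, c, d), rel=1e-9)

    def test_strong_contrast_supported(self):
        from baritone.evolution import CodonSubstitutionResult as C
        te = C(S=100.0, N=200.0, Sd=5.0, Nd=0.0, codons_used=100)
        gene = C(S=100.0, N=200.0, Sd=35.0, Nd=0.0, codons_used=100)
        res = ht_fisher_test(te, gene)
        assert res.p_one_tailed < 0.005 and res.verdict == "HT_supported"

    def test_zero_synonymous_sites_error(self):
        from baritone.evolution import CodonSubstitutionResult as C
        z = C(S=0.0, N=3.0, Sd=0.0, Nd=0.0, codons_used=1)
        with pytest.raises(ValueError):
            ht_fisher_test(z, z)


class TestPairwiseDiversity:
    def test_identical_copies(self):
        assert pairwise_diversity(["ACGT" * 5] * 4) == [0.0] * 6

    def test_count(self):
        rng = np.random.default_rng(4)
        copies = [random_seq(rng, 40) for _ in range(7)]
        assert len(pairwise_diversity(copies)) == 21

    def test_too_few(self):
        with pytest.raises(ValueError):
            pairwise_diversity(["ACGT"])


class TestDipStatistic:
    def test_equally_spaced_minimum(self):
        for n in (4, 10, 25):
            assert dip_statistic(np.arange(n)) == pytest.approx(1 / (2 * n))

    def test_identical_values_minimum(self):
        assert dip_statistic([3.0] * 8) == pytest.approx(1 / 16)

    def test_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            d = dip_statistic(rng.random(n))
            assert 1 / (2 * n) - 1e-12 <= d <= 0.25 + 1e-12

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        v = rng.normal(0, 1, 60)
        assert dip_statistic(v) == pytest.approx(dip_statistic(3.5 * v + 11.0),
                                                 abs=1e-12)

    def test_matches_exact_lp_oracle(self):
        rng = np.random.default_rng(7)
        for rep in range(60):
            kind = rep % 4
            n = int(rng.integers(4, 16))
            if kind == 0:
                v = rng.random(n)
            elif kind == 1:
                v = rng.normal(0, 1, n)
            elif kind == 2:
                v = np.concatenate([rng.normal(-4, .3, n // 2),
                                    rng.normal(4, .3, n - n // 2)])
            else:
                v = rng.integers(0, 4, n).astype(float)
            assert dip_statistic(v) == pytest.approx(dip_lp_oracle(v), abs=1e-7)


class TestDipTest:
    def test_all_identical_p_one(self):
        r = dip_test([2.0] * 10, n_boot=100, seed=0)
        assert r.p == 1.0

    def test_bimodal_rejected_unimodal_not(self):
        rng = np.random.default_rng(8)
        null = dip_null_distribution(100, 500, rng)
        bim = np.concatenate([rng.normal(0, 1, 50), rng.normal(10, 1, 50)])
        uni = rng.normal(0, 1, 100)
        assert dip_test(bim, null_dips=null).p < 0.05
        assert dip_test(uni, null_dips=null).p > 0.05

    def test_seed_reproducible(self):
        rng = np.random.default_rng(9)
        v = rng.random(30)
        assert dip_test(v, n_boot=200, seed=5).p == dip_test(v, n_boot=200, seed=5).p


class TestGroupCompare:
    def test_identical_groups(self):
        g = [[1.0, 2.0, 3.0]] * 3
        r = group_compare(g)
        assert r["p"] == pytest.approx(1.0) and not r["significant"]

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, 30)
        b = rng.normal(2, 1, 30)
        r = group_compare([list(a), list(b)])
        assert r["significant"]

    def test_h_matches_rank_formula(self):
        groups = [[1.0, 3.0, 5.0], [2.0, 4.0, 6.0], [7.0, 8.0, 9.0]]
        allv = sorted(v for g in groups for v in g)
        ranks = {v: i + 1 for i, v in enumerate(allv)}
        N = 9
        H = 12 / (N * (N + 1)) * sum(
            len(g) * (np.mean([ranks[v] for v in g]) - (N + 1) / 2) ** 2
            for g in groups)
        r = group_compare(groups)
        assert r["H"] == pytest.approx(H)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            group_compare([[1.0], [2.0, 3.0]])
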