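"""Element calling, classification, naming and redundancy removal."""

import math

import numpy as np
import pytest

from baritone.align import revcomp
from baritone.annotate import (Candidate, ElementAnnotation, ReferenceSet,
                               assign_name, classify_element, dedupe,
                               detect_tsd, merge_and_extend, naive_search,
                               reconstruct_consensus, screen_hits,
                               summarize_lengths)
from baritone.seqio import GenomeRecord, HomologyHit, Interval
from baritone.synthetic_data import derive_mite

from conftest import mutate_seq, random_seq


def _hit(evalue, ident=80.0, q_start=1, q_end=339, s_start=1000, s_end=2000):
    return HomologyHit("q", "s", ident, q_end - q_start + 1, 0, 0,
                       q_start, q_end, s_start, s_end, evalue, 500.0)


class TestScreenHits:
    def test_protein_mode_keeps_strong_full_coverage(self):
        kept = screen_hits([_hit(1e-130)], mode="protein")
        assert len(kept) == 1

    def test_protein_mode_drops_weak_evalue(self):
        assert screen_hits([_hit(1e-100)], mode="protein") == []

    def test_protein_mode_drops_partial_coverage(self):
        assert screen_hits([_hit(1e-130, q_end=200)], mode="protein") == []

    def test_mite_mode_relaxed(self):
        assert len(screen_hits([_hit(1e-25)], mode="mite")) == 1
        assert screen_hits([_hit(1e-10)], mode="mite") == []

    def test_nan_evalue_bypasses(self):
        assert len(screen_hits([_hit(float("nan"))], mode="protein")) == 1

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            screen_hits([], mode="bogus")


class TestNaiveSearch:
    def test_exact_copy_found_full_length(self):
        rng = np.random.default_rng(0)
        ref = random_seq(rng, 300)
        g = GenomeRecord(id="g", residues=random_seq(rng, 2000) + ref +
                         random_seq(rng, 2000))
        hits = naive_search(g, ref)
        assert hits, "no hit for an exact copy"
        best = max(hits, key=lambda h: h.aln_length)
        assert best.pct_identity == 100.0 and best.aln_length == 300
        assert math.isnan(best.evalue)

    def test_pure_n_genome_no_hits(self):
        g = GenomeRecord(id="g", residues="N" * 500)
        assert naive_search(g, "ACGT" * 10) == []

    def test_diverged_copy_identity_close_to_truth(self):
        rng = np.random.default_rng(1)
        ref = random_seq(rng, 400)
        copy = mutate_seq(ref, 0.10, rng)
        true_ident = 100 * sum(a == b for a, b in zip(ref, copy)) / 400
        g = GenomeRecord(id="g", residues=random_seq(rng, 1500) + copy +
                         random_seq(rng, 1500))
        hits = naive_search(g, ref)
        best = max(hits, key=lambda h: h.aln_length)
        assert abs(best.pct_identity - true_ident) <= 3.0

    def test_minus_strand_copy(self):
        rng = np.random.default_rng(2)
        ref = random_seq(rng, 300)
        g = GenomeRecord(id="g", residues=random_seq(rng, 1000) + revcomp(ref) +
                         random_seq(rng, 1000))
        hits = naive_search(g, ref)
        assert any(h.s_start > h.s_end for h in hits)


class TestMergeAndExtend:
    def _h(self, s, e):
        return HomologyHit("q", "g", 90.0, e - s, 0, 0, 1, e - s, s + 1, e,
                           float("nan"), 100.0)

    def test_nearby_hits_merge(self):
        g = GenomeRecord(id="g", residues="A" * 10000)
        cands = merge_and_extend([self._h(1000, 1500), self._h(1550, 2000)], g,
                                 max_gap=200)
        assert len(cands) == 1
        assert cands[0].interval.start == 600 and cands[0].interval.end == 2400

    def test_distant_hits_stay_separate(self):
        g = GenomeRecord(id="g", residues="A" * 20000)
        cands = merge_and_extend([self._h(1000, 1500), self._h(9000, 9500)], g)
        assert len(cands) == 2

    def test_contig_end_flagged(self):
        g = GenomeRecord(id="g", residues="A" * 3000)
        cands = merge_and_extend([self._h(10, 500)], g)
        assert cands[0].boundary_overlap

    def test_nested_split_bridged_by_large_gap(self):
        g = GenomeRecord(id="g", residues="A" * 20000)
        cands = merge_and_extend([self._h(1000, 1800), self._h(2900, 3600)], g,
                                 max_gap=2000)
        assert len(cands) == 1


class TestClassifyElement:
    def _setup(self, sir_template, category="autonomous", rng=None):
        from baritone.synthetic_data import ImplantSpec, implant
        spec = ImplantSpec(seed=17, genome_length=120_000,
                           n_copies={category: 1},
                           divergence=0.03)
        return implant(spec)

    def test_autonomous_template(self, sir_template):
        genome, truth, refs = self._setup(sir_template, "autonomous")
        t = truth[0]
        cand = Candidate(Interval(genome.id, max(0, t.interval.start - 400),
                                  t.interval.end + 400, "+"))
        ann = classify_element(cand, genome, refs)
        assert ann.category == "putatively_autonomous"

    def test_premature_stop_flips_to_inactive(self, sir_template):
        genome, truth, refs = self._setup(sir_template, "inactive")
        t = truth[0]
        cand = Candidate(Interval(genome.id, t.interval.start - 400,
                                  t.interval.end + 400, "+"))
        ann = classify_element(cand, genome, refs)
        assert ann.category == "inactive_full_length"

    def test_mite_template(self, sir_template):
        genome, truth, refs = self._setup(sir_template, "MITE")
        t = truth[0]
        cand = Candidate(Interval(genome.id, t.interval.start - 400,
                                  t.interval.end + 400, "+"))
        ann = classify_element(cand, genome, refs)
        assert ann.category == "MITE"

    def test_boundary_candidate_is_partial(self, sir_template):
        genome, truth, refs = self._setup(sir_template, "autonomous")
        t = truth[0]
        cand = Candidate(Interval(genome.id, t.interval.start - 400,
                                  t.interval.end + 400, "+"),
                         boundary_overlap=True)
        ann = classify_element(cand, genome, refs)
        assert ann.category == "partial"

    def test_deterministic_and_idempotent(self, sir_template):
        genome, truth, refs = self._setup(sir_template, "autonomous")
        t = truth[0]
        cand = Candidate(Interval(genome.id, t.interval.start - 400,
                                  t.interval.end + 400, "+"))
        a1 = classify_element(cand, genome, refs)
        a2 = classify_element(cand, genome, refs)
        assert a1.interval == a2.interval and a1.category == a2.category


class TestDetectTsd:
    def _genome(self, core):
        return GenomeRecord(id="g", residues=core)

    def test_ta_both_sides(self):
        g = self._genome("GCTA" + "CCCGGG" + "TAGC")
        assert detect_tsd(g, Interval("g", 4, 10)) == "TA"

    def test_absent(self):
        g = self._genome("GCGG" + "CCCGGG" + "TAGC")
        assert detect_tsd(g, Interval("g", 4, 10)) == "absent"

    def test_contig_start_unknown(self):
        g = self._genome("CCCGGGTAGC")
        assert detect_tsd(g, Interval("g", 0, 6)) == "unknown"


class TestAssignName:
    def test_subfamily_species(self):
        assert assign_name("Bari3", "Dmoj", set()) == "Bari3_Dmoj"

    def test_mite_with_family_index(self):
        assert assign_name("MITE", "Dsec", set(), is_mite=True,
                           mite_family_index=2) == "Bari_Dsec_MITE2"

    def test_mite_single_family_no_suffix(self):
        assert assign_name("MITE", "Dtak", set(), is_mite=True) == "Bari_Dtak_MITE"

    def test_uniqueness_enforced(self):
        existing = {"Bari1_Dmel"}
        n2 = assign_name("Bari1", "Dmel", existing)
        assert n2 != "Bari1_Dmel" and n2.startswith("Bari1_Dmel")

    def test_bad_species_code(self):
        with pytest.raises(ValueError):
            assign_name("Bari1", "Dm", set())


class TestDedupe:
    def _ann(self, g, start, end, name, category="truncated"):
        return ElementAnnotation(
            interval=Interval(g, start, end), species_code="Dmel",
            category=category, subfamily="Bari1", tir_type="SIR",
            dr_counts=(3, 3), tsd="TA", name=name)

    def test_identical_flanks_deduped(self):
        rng = np.random.default_rng(3)
        flank_l, elem, flank_r = (random_seq(rng, 200), random_seq(rng, 500),
                                  random_seq(rng, 200))
        res1 = flank_l + elem + flank_r
        g1 = GenomeRecord(id="c1", residues=res1)
        g2 = GenomeRecord(id="c2", residues=random_seq(rng, 50) + res1)
        anns = [self._ann("c1", 200, 700, "a"), self._ann("c2", 250, 750, "b")]
        kept = dedupe(anns, {"c1": g1, "c2": g2})
        assert len(kept) == 1

    def test_different_loci_kept(self):
        rng = np.random.default_rng(4)
        elem = random_seq(rng, 500)
        res = random_seq(rng, 300) + elem + random_seq(rng, 1000) + elem + \
            random_seq(rng, 300)
        g = GenomeRecord(id="c1", residues=res)
        anns = [self._ann("c1", 300, 800, "a"), self._ann("c1", 1800, 2300, "b")]
        assert len(dedupe(anns, {"c1": g})) == 2

    def test_partial_never_removed(self):
        rng = np.random.default_rng(5)
        res = random_seq(rng, 2000)
        g = GenomeRecord(id="c1", residues=res)
        anns = [self._ann("c1", 500, 900, "a"),
                self._ann("c1", 500, 900, "b", category="partial")]
        kept = dedupe(anns, {"c1": g})
        assert any(a.category == "partial" for a in kept)


class TestConsensus:
    def test_disjoint_deletions_recover_template(self):
        rng = np.random.default_rng(6)
        template = random_seq(rng, 60)
        a = template[:20] + "-" * 10 + template[30:]
        b = template[:40] + "-" * 10 + template[50:]
        assert reconstruct_consensus([a, b, template]) == template

    def test_identical_copies(self):
        assert reconstruct_consensus(["ACGT", "ACGT"]) == "ACGT"

    def test_majority_column(self):
        assert reconstruct_consensus(["AAAA", "AAAT", "AAAT"]) == "AAAT"

    def test_tie_broken_by_first_sequence(self):
        assert reconstruct_consensus(["AT", "AC"]) == "AT"


class TestSummarizeLengths:
    def _anns(self, lengths):
        return [ElementAnnotation(
            interval=Interval("c", 0, L), species_code="Dmel",
            category="truncated", subfamily="Bari1", tir_type="ND",
            dr_counts=(0, 0), tsd="unknown", name=f"e{i}")
            for i, L in enumerate(lengths)]

    def test_median_of_three(self):
        s = summarize_lengths(self._anns([17, 696, 4353]))
        assert s["median"] == 696 and s["min"] == 17 and s["max"] == 4353

    def test_single_element_iqr_zero(self):
        s = summarize_lengths(self._anns([100]))
        assert s["iqr"] == 0

    def test_empty_subset_error(self):
        with pytest.raises(ValueError):
            summarize_lengths(self._anns([5]), subset=lambda a: False)
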