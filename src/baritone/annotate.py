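"""Element calling and classification.

From homology hits (external tabular hits or the built-in word-seeded search)
to named, categorised element annotations: candidate merging, boundary
trimming, terminal-structure typing, ORF/transposase checks, MITE calling,
TA-target-site-duplication detection, redundancy removal and consensus
reconstruction.

Categories follow the element inventory logic of the Bari family:

* ``putatively_autonomous`` — two 3-DR termini bracketing an intact
  transposase ORF (>= 300 codons, >= 75% similarity to a reference
  transposase over the inter-terminal region).
* ``inactive_full_length`` — two 3-DR termini, no intact ORF.
* ``truncated`` — element chunk missing one or both termini.
* ``partial`` — overlaps a contig boundary (counted, not analysed further).
* ``MITE`` — short (<= 939 nt) two-termini element with at most one DR per
  terminus and no transposase homology in any frame.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .align import DEFAULT_SCORING, find_orfs, global_align, local_align, revcomp
from .seqio import GenomeRecord, HomologyHit, Interval
from .terminal_structure import TerminalStructureReport, terminal_report

logger = logging.getLogger(__name__)

#: protein-mode screening: tBLASTn-style thresholds
PROTEIN_EVALUE = 1e-120
PROTEIN_MIN_IDENTITY = 75.0
TRANSPOSASE_LEN = 339
#: relaxed nucleotide/MITE-mode threshold
MITE_EVALUE = 1e-20
#: MITEs in this family top out at 939 nt
MITE_MAX_LEN = 939
#: intact transposase ORF: at least this many codons
MIN_ORF_CODONS = 300


@dataclass
class ElementAnnotation:
    interval: Interval
    species_code: str
    category: str       # {putatively_autonomous, inactive_full_length, truncated, partial, MITE}
    subfamily: str      # {Bari1, Bari2, Bari3, MITE, ND}
    tir_type: str       # {SIR, LIR, ND}
    dr_counts: tuple[int, int]
    tsd: str            # {TA, absent, unknown}
    name: str
    notes: str = ""
    terminal: TerminalStructureReport | None = field(default=None, repr=False)

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class ReferenceSet:
    """Reference transposase proteins and element/termini nucleotide sequences."""

    proteins: dict[str, str]
    elements: dict[str, str]
    #: optional explicit subfamily per element label; else prefix of the label
    subfamilies: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.proteins or not self.elements:
            raise ValueError("need at least one protein and one nucleotide reference")

    def subfamily_of(self, label: str) -> str:
        if label in self.subfamilies:
            return self.subfamilies[label]
        for sf in ("Bari1", "Bari2", "Bari3"):
            if label.startswith(sf):
                return sf
        return "ND"

    def termini(self, label: str, window: int = 250) -> tuple[str, str]:
        seq = self.elements[label]
        w = min(window, len(seq) // 2)
        return seq[:w], seq[-w:]


def screen_hits(hits: list[HomologyHit], mode: str,
                protein_evalue: float = PROTEIN_EVALUE,
                min_identity: float = PROTEIN_MIN_IDENTITY,
                query_len: int = TRANSPOSASE_LEN,
                min_coverage: float = 1.0,
                relaxed_evalue: float = MITE_EVALUE) -> list[HomologyHit]:
    """Filter hits by mode-specific thresholds.

    protein mode keeps E < ``protein_evalue`` at > ``min_identity`` percent over
    the full query; mite/nucleotide modes use the relaxed E-value cutoff.
    Hits with NaN E-values (the built-in search) bypass the E-value test and are
    screened on identity alone.
    """
    if mode not in ("protein", "nucleotide", "mite"):
        raise ValueError(f"unknown screening mode {mode!r}")
    out = []
    for h in hits:
        no_e = math.isnan(h.evalue)
        if mode == "protein":
            cov = (h.q_end - h.q_start + 1) >= min_coverage * query_len
            if (no_e or h.evalue < protein_evalue) and h.pct_identity > min_identity and cov:
                out.append(h)
        else:
            if no_e or h.evalue < relaxed_evalue:
                out.append(h)
    return out


def _encode(seq: str) -> np.ndarray:
    tab = np.full(256, -1, dtype=np.int8)
    for i, c in enumerate("ACGT"):
        tab[ord(c)] = i
    return tab[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Base-4 codes of all k-mers; windows containing non-ACGT get -1."""
    if len(enc) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(enc, k).astype(np.int64)
    codes = win @ (4 ** np.arange(k - 1, -1, -1, dtype=np.int64))
    codes[np.any(win < 0, axis=1)] = -1
    return codes


def naive_search(genome: GenomeRecord, reference: str, word: int = 11,
                 min_pct: float = 70.0, cluster_gap: int = 250,
                 pad_frac: float = 0.25, min_len: int = 50) -> list[HomologyHit]:
    """Word-seeded homology search of one reference against one contig.

    Exact ``word``-mers shared with the reference (either orientation) are
    clustered, each cluster window is locally aligned against the reference and
    hits above ``min_pct`` identity are reported. E-values are NaN (screening of
    these hits uses identity, never E-value); bitscore carries the raw score.
    """
    reference = reference.upper()
    if len(reference) < word:
        raise ValueError("reference shorter than word size")
    g_codes = _kmer_codes(_encode(genome.residues), word)
    hits: list[HomologyHit] = []
    pad = int(len(reference) * pad_frac) + 50
    for strand, ref in (("+", reference), ("-", revcomp(reference))):
        r_codes = np.unique(_kmer_codes(_encode(ref), word))
        r_codes = r_codes[r_codes >= 0]
        if not len(r_codes):
            continue
        pos = np.nonzero(np.isin(g_codes, r_codes))[0]
        if not len(pos):
            continue
        # cluster seed positions into candidate windows
        breaks = np.nonzero(np.diff(pos) > cluster_gap)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s_i, e_i in zip(starts, ends):
            w_lo = max(0, int(pos[s_i]) - pad)
            w_hi = min(len(genome.residues), int(pos[e_i]) + word + pad)
            window = genome.residues[w_lo:w_hi]
            aln = local_align(window, ref)
            alen = aln.a_end - aln.a_start
            if alen < max(word, min_len) or aln.pct_identity < min_pct:
                continue
            g_start = w_lo + aln.a_start  # 0-based
            g_end = w_lo + aln.a_end
            if strand == "+":
                q_start, q_end = aln.b_start + 1, aln.b_end
                s_start, s_end = g_start + 1, g_end
            else:
                q_start = len(reference) - aln.b_end + 1
                q_end = len(reference) - aln.b_start
                s_start, s_end = g_end, g_start + 1  # reversed => minus strand
            mism = round(alen * (1 - aln.pct_identity / 100.0))
            hits.append(HomologyHit(
                query_id="ref", subject_id=genome.id,
                pct_identity=round(aln.pct_identity, 2), aln_length=alen,
                mismatches=mism, gap_opens=0,
                q_start=q_start, q_end=q_end, s_start=s_start, s_end=s_end,
                evalue=float("nan"), bitscore=aln.score,
            ))
    hits.sort(key=lambda h: (min(h.s_start, h.s_end), -h.bitscore))
    return hits


@dataclass
class Candidate:
    interval: Interval
    boundary_overlap: bool = False


def merge_and_extend(hits: list[HomologyHit], genome: GenomeRecord,
                     max_gap: int = 200, flank_pad: int = 400,
                     boundary_tol: int = 50) -> list[Candidate]:
    """Merge hits within ``max_gap`` into candidate element loci, padded by
    ``flank_pad`` for the terminal search; candidates reaching within
    ``boundary_tol`` of a contig end are flagged ``boundary_overlap``.

    Merging ignores hit strand: one locus yields hits in both orientations when
    references share inverted termini, and the element's orientation is decided
    later by the boundary-trimming alignment.
    """
    if not hits:
        return []
    ivs = sorted((h.subject_interval() for h in hits if h.subject_id == genome.id),
                 key=lambda iv: (iv.start, iv.end))
    out: list[Candidate] = []
    n = len(genome.residues)
    cur: Interval | None = None
    for iv in ivs + [None]:
        if cur is not None and (iv is None or iv.start - cur.end > max_gap):
            start = max(0, cur.start - flank_pad)
            end = min(n, cur.end + flank_pad)
            boundary = cur.start <= boundary_tol or cur.end >= n - boundary_tol
            out.append(Candidate(Interval(genome.id, start, end, "+"), boundary))
            cur = None
        if iv is None:
            break
        if cur is None:
            cur = iv
        else:
            cur = Interval(cur.seq_id, cur.start, max(cur.end, iv.end), "+")
    out.sort(key=lambda c: c.interval.start)
    return out


_BLOSUM = Align.substitution_matrices.load("BLOSUM62")


def _protein_aligner(mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = _BLOSUM
    al.open_gap_score = -11
    al.extend_gap_score = -1
    return al


def protein_similarity(a: str, b: str, mode: str = "global") -> float:
    """Percent of aligned columns with a positive substitution score."""
    a = a.replace("*", "X")
    b = b.replace("*", "X")
    if not a or not b:
        return 0.0
    al = _protein_aligner(mode)
    try:
        aln = next(iter(al.align(a, b)))
    except StopIteration:
        return 0.0
    sa, sb = str(aln[0]), str(aln[1])
    pos = cols = 0
    for ca, cb in zip(sa, sb):
        if ca == "-" and cb == "-":
            continue
        cols += 1
        if ca != "-" and cb != "-" and _BLOSUM[ca, cb] > 0:
            pos += 1
    return 100.0 * pos / cols if cols else 0.0


def _six_frame_peptides(seq: str, min_len: int = 30) -> list[str]:
    from Bio.Seq import Seq
    peps = []
    for s in (seq, revcomp(seq)):
        for f in range(3):
            sub = s[f:]
            sub = sub[:len(sub) - len(sub) % 3]
            if not sub:
                continue
            for pep in str(Seq(sub).translate()).split("*"):
                if len(pep) >= min_len:
                    peps.append(pep)
    return peps


def has_transposase_homology(seq: str, refs: ReferenceSet,
                             min_score: float = 60.0) -> bool:
    """Any frame encodes a peptide with a substantial local alignment to a
    reference transposase (raw BLOSUM62 score threshold; chance peptides from
    non-coding sequence score well below genuine transposase fragments)."""
    al = _protein_aligner("local")
    for pep in _six_frame_peptides(seq):
        for prot in refs.proteins.values():
            if al.score(pep.replace("*", "X"), prot.replace("*", "X")) >= min_score:
                return True
    return False


def _intact_orf(seq: str, report: TerminalStructureReport, refs: ReferenceSet,
                min_codons: int = MIN_ORF_CODONS,
                min_span: float = 0.8,
                min_similarity: float = PROTEIN_MIN_IDENTITY) -> tuple[bool, float]:
    """Is there a single ORF >= min_codons covering >= min_span of the
    inter-terminal region whose protein resembles a reference transposase?"""
    w = report.terminal_window
    inter_lo, inter_hi = w, len(seq) - w
    span_len = max(1, inter_hi - inter_lo)
    best_sim = 0.0
    for iv, prot in find_orfs(seq, min_aa=min_codons):
        ov = max(0, min(iv.end, inter_hi) - max(iv.start, inter_lo))
        if ov / span_len < min_span:
            continue
        for ref_prot in refs.proteins.values():
            sim = protein_similarity(prot, ref_prot)
            best_sim = max(best_sim, sim)
    return best_sim >= min_similarity, best_sim


def _assign_subfamily(seq: str, refs: ReferenceSet, window: int = 250) -> str:
    """Best nucleotide similarity of the terminal windows to reference termini."""
    w = min(window, len(seq) // 2)
    if w < 15:
        return "ND"
    left, right = seq[:w], seq[-w:]
    scores: dict[str, float] = {}
    for label in refs.elements:
        rl, rr = refs.termini(label, window)
        sim = max(local_align(left, rl).score, local_align(right, rr).score)
        sf = refs.subfamily_of(label)
        scores[sf] = max(scores.get(sf, 0.0), sim)
    if not scores:
        return "ND"
    ranked = sorted(scores.items(), key=lambda kv: -kv[1])
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return "ND"
    return ranked[0][0]


def detect_tsd(genome: GenomeRecord, interval: Interval) -> str:
    """TA iff the two bases immediately flanking the element on both sides are TA."""
    if interval.start < 2 or interval.end > len(genome.residues) - 2:
        return "unknown"
    up = genome.residues[interval.start - 2:interval.start]
    down = genome.residues[interval.end:interval.end + 2]
    return "TA" if up == "TA" and down == "TA" else "absent"


def trim_candidate(cand: Candidate, genome: GenomeRecord, refs: ReferenceSet,
                   min_identity: float = 60.0) -> tuple[Interval, str, float] | None:
    """Trim a padded candidate to element boundaries by the best local alignment
    against any reference element (either orientation). Returns the trimmed
    interval, best reference label and identity, or None when nothing aligns."""
    window = genome.residues[cand.interval.start:cand.interval.end]
    best = None
    for label, ref in refs.elements.items():
        for strand, r in (("+", ref), ("-", revcomp(ref))):
            aln = local_align(window, r)
            if aln.score > 0 and (best is None or aln.score > best[0]):
                best = (aln.score, aln, strand, label)
    if best is None:
        return None
    score, aln, strand, label = best
    if aln.pct_identity < min_identity:
        return None
    # local alignment clips diverged terminal bases. Two repairs: (1) X-drop
    # ungapped extension of both ends along the reference recovers the clipped
    # tail at an internal truncation; (2) when the alignment (nearly) reaches a
    # reference extremity, extrapolate to it so terminal arms stay anchored.
    ref = refs.elements[label]
    r = ref if strand == "+" else revcomp(ref)
    a_start, a_end = aln.a_start, aln.a_end
    b_start, b_end = aln.b_start, aln.b_end

    def _extend(gpos, rpos, step, xdrop=8):
        sc = best_sc = 0
        best_k = 0
        k = 0
        while True:
            g, rr = gpos + step * k, rpos + step * k
            if not (0 <= g < len(window) and 0 <= rr < len(r)):
                break
            sc += 1 if window[g] == r[rr] else -1
            k += 1
            if sc > best_sc:
                best_sc, best_k = sc, k
            elif sc < best_sc - xdrop:
                break
        return best_k

    k = _extend(a_end, b_end, +1)
    a_end += k
    b_end += k
    k = _extend(a_start - 1, b_start - 1, -1)
    a_start -= k
    b_start -= k

    lead, trail = b_start, len(r) - b_end
    if 0 < lead <= 12:
        a_start = max(0, a_start - lead)
    if 0 < trail <= 12:
        a_end = min(len(window), a_end + trail)
    lo = cand.interval.start + a_start
    hi = cand.interval.start + a_end
    iv = Interval(genome.id, lo, hi, strand)
    return iv, label, aln.pct_identity


def classify_element(cand: Candidate, genome: GenomeRecord, refs: ReferenceSet,
                     species_code: str | None = None,
                     mite_max_len: int = MITE_MAX_LEN) -> ElementAnnotation | None:
    """Classify one candidate locus into the element category tree."""
    species = species_code or genome.species_code
    trimmed = trim_candidate(cand, genome, refs)
    if trimmed is None:
        logger.info("candidate %s dropped: no reference homology", cand.interval)
        return None
    iv, ref_label, identity = trimmed
    seq = genome.extract(iv)

    if cand.boundary_overlap:
        return ElementAnnotation(
            interval=iv, species_code=species, category="partial",
            subfamily=_assign_subfamily(seq, refs), tir_type="ND",
            dr_counts=(0, 0), tsd=detect_tsd(genome, iv), name="",
            notes=f"boundary_overlap;ref={ref_label}",
        )

    try:
        report = terminal_report(seq)
    except ValueError:
        logger.info("candidate %s dropped: too short for terminal analysis", iv)
        return None

    dr_l, dr_r = report.dr_count_left, report.dr_count_right
    two_termini_3dr = (report.tir_type != "ND" and dr_l == 3 and dr_r == 3)
    notes = f"ref={ref_label}"

    if two_termini_3dr:
        intact, sim = _intact_orf(seq, report, refs)
        if intact:
            category = "putatively_autonomous"
            notes += f";tnp_sim={sim:.0f}"
        else:
            category = "inactive_full_length"
        subfamily = _assign_subfamily(seq, refs)
    elif (report.tir_type != "ND" and dr_l <= 1 and dr_r <= 1
          and len(seq) <= mite_max_len
          and not has_transposase_homology(seq, refs)):
        category = "MITE"
        parent = _assign_subfamily(seq, refs)
        subfamily = "MITE"
        if parent != "ND":
            notes += f";parent={parent}"
    else:
        category = "truncated"
        subfamily = _assign_subfamily(seq, refs)

    return ElementAnnotation(
        interval=iv, species_code=species, category=category,
        subfamily=subfamily, tir_type=report.tir_type,
        dr_counts=(dr_l, dr_r), tsd=detect_tsd(genome, iv),
        name="", notes=notes, terminal=report,
    )


def assign_name(subfamily: str, species_code: str, existing: set[str],
                is_mite: bool = False, mite_family_index: int | None = None) -> str:
    """Repbase-style binary nomenclature: Bari3 + Dmoj -> "Bari3_Dmoj";
    MITEs -> "Bari_Dsec_MITE2" (numeric suffix only when more than one family)."""
    if len(species_code) != 4:
        raise ValueError(f"species code must be 4 letters, got {species_code!r}")
    if is_mite or subfamily == "MITE":
        base = f"Bari_{species_code}_MITE"
        if mite_family_index is not None:
            base += str(mite_family_index)
    else:
        base = f"{subfamily}_{species_code}"
    if base not in existing:
        return base
    for i in range(2, 10000):
        cand = f"{base}.{i}"
        if cand not in existing:
            return cand
    raise ValueError(f"name collision could not be resolved for {base}")


def dedupe(annotations: list[ElementAnnotation], genomes: dict[str, GenomeRecord],
           flank_len: int = 100, min_flank_identity: float = 95.0) -> list[ElementAnnotation]:
    """Remove redundant annotations (same insertion reachable from overlapping
    contigs) by flanking-sequence comparison; partial elements are never removed,
    only flagged."""
    def flanks(a: ElementAnnotation) -> tuple[str, str] | None:
        g = genomes[a.interval.seq_id]
        lo, hi = a.interval.start, a.interval.end
        if lo < flank_len or hi + flank_len > len(g.residues):
            return None
        return (g.residues[lo - flank_len:lo], g.residues[hi:hi + flank_len])

    kept: list[ElementAnnotation] = []
    for a in sorted(annotations, key=lambda a: (a.interval.seq_id, a.interval.start)):
        fa = flanks(a)
        dup = False
        for b in kept:
            if a.category == "partial" or b.category == "partial":
                continue
            fb = flanks(b)
            if fa is None or fb is None:
                continue
            if (global_align(fa[0], fb[0]).pct_identity >= min_flank_identity
                    and global_align(fa[1], fb[1]).pct_identity >= min_flank_identity):
                dup = True
                break
        if dup:
            logger.info("dropped duplicate %s at %s", a.name, a.interval)
        else:
            kept.append(a)
    return kept


def reconstruct_consensus(msa: list[str]) -> str:
    """Column-wise majority-rule consensus; ties resolved by the earliest
    sequence carrying a tied character; all-gap and gap-majority columns drop."""
    if len(msa) < 2:
        raise ValueError("need >= 2 aligned sequences")
    L = len(msa[0])
    if any(len(s) != L for s in msa):
        raise ValueError("alignment rows differ in length")
    out = []
    for c in range(L):
        col = [s[c].upper() for s in msa]
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        best_n = max(counts.values())
        tied = {ch for ch, n in counts.items() if n == best_n}
        winner = next(ch for ch in col if ch in tied)
        if winner not in "-.":
            out.append(winner)
    return "".join(out)


def summarize_lengths(annotations: list[ElementAnnotation],
                      subset=None) -> dict[str, float]:
    """Median, IQR (linear-interpolation quartiles), min and max of lengths."""
    anns = [a for a in annotations if subset is None or subset(a)]
    if not anns:
        raise ValueError("empty subset")
    lengths = np.array([a.length for a in anns], dtype=float)
    q1, med, q3 = np.percentile(lengths, [25, 50, 75])
    return {"n": len(lengths), "median": float(med), "iqr": float(q3 - q1),
            "min": float(lengths.min()), "max": float(lengths.max())}


def annotate_genome(genome: GenomeRecord, refs: ReferenceSet,
                    word: int = 11, min_pct: float = 70.0,
                    max_gap: int = 200, flank_pad: int = 400,
                    species_code: str | None = None) -> list[ElementAnnotation]:
    """Full pipeline on one contig: built-in search with every nucleotide
    reference, screen, merge, classify, name, dedupe."""
    all_hits: list[HomologyHit] = []
    for label, ref in refs.elements.items():
        hits = naive_search(genome, ref, word=word, min_pct=min_pct)
        for h in hits:
            h.query_id = label
        all_hits.extend(screen_hits(hits, mode="nucleotide"))
    candidates = merge_and_extend(all_hits, genome, max_gap=max_gap, flank_pad=flank_pad)
    annotations: list[ElementAnnotation] = []
    names: set[str] = set()
    species = species_code or genome.species_code
    mite_anns = []
    for cand in candidates:
        ann = classify_element(cand, genome, refs, species_code=species)
        if ann is None:
            continue
        if ann.category == "MITE":
            mite_anns.append(ann)
        annotations.append(ann)
    single_mite_family = len({a.notes for a in mite_anns}) <= 1
    mite_idx = 0
    for ann in annotations:
        if ann.category == "MITE":
            mite_idx += 1
            fam = None if single_mite_family else 1
            ann.name = assign_name("MITE", species, names, is_mite=True,
                                   mite_family_index=fam)
        else:
            sf = ann.subfamily if ann.subfamily != "ND" else "Bari"
            ann.name = assign_name(sf, species, names)
        names.add(ann.name)
    return dedupe(annotations, {genome.id: genome})
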