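"""Pairwise alignment, dot-plot and ORF primitives.

Needleman-Wunsch / Smith-Waterman with affine gaps via Bio.Align.PairwiseAligner.
Default nucleotide scoring: match +1, mismatch -1, gap open -4, gap extend -1
(a gap of length L costs 4 + (L-1)). N is permitted but matches nothing, i.e. it
scores as a mismatch against every base including N; ambiguity codes other than
N are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .seqio import Interval

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: default scoring scheme: (match, mismatch, gap_open, gap_extend); gap penalties positive
DEFAULT_SCORING = (1.0, -1.0, 4.0, 1.0)

_ALPHABET = "ACGTN"


def _check_nt(s: str, what: str) -> None:
    bad = set(s) - set(_ALPHABET)
    if bad:
        raise ValueError(f"{what}: unsupported characters {sorted(bad)}")


def revcomp(a: str) -> str:
    """Reverse complement; N -> N."""
    _check_nt(a.upper(), "revcomp input")
    return a.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    pct_identity: float
    mode: str  # {"global", "local"}
    a_start: int = 0
    a_end: int = 0
    b_start: int = 0
    b_end: int = 0

    def __len__(self) -> int:
        return len(self.aligned_a)


@dataclass(frozen=True)
class DotPlotMatch:
    a_pos: int
    b_pos: int
    matches: int
    orientation: str  # {"direct", "inverted"}


def _substitution_matrix(match: float, mismatch: float):
    m = np.full((len(_ALPHABET), len(_ALPHABET)), mismatch)
    for i, c in enumerate("ACGT"):
        m[i, i] = match
    # N matches nothing, including itself
    arr = Align.substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    arr[:, :] = m
    return arr


def _make_aligner(scoring, mode: str) -> Align.PairwiseAligner:
    match, mismatch, gap_open, gap_extend = scoring
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _substitution_matrix(match, mismatch)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def _identity(aligned_a: str, aligned_b: str) -> float:
    cols = matches = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" and cb == "-":
            continue
        cols += 1
        if ca == cb and ca != "-" and ca != "N":
            matches += 1
    return 100.0 * matches / cols if cols else 0.0


def _from_biopython(aln, a: str, b: str, mode: str) -> PairwiseAlignment:
    sa, sb = str(aln[0]), str(aln[1])
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a):
        a0, a1 = int(blocks_a[0][0]), int(blocks_a[-1][1])
        b0, b1 = int(blocks_b[0][0]), int(blocks_b[-1][1])
    else:
        a0 = a1 = b0 = b1 = 0
    return PairwiseAlignment(
        aligned_a=sa, aligned_b=sb, score=float(aln.score),
        pct_identity=_identity(sa, sb), mode=mode,
        a_start=a0, a_end=a1, b_start=b0, b_end=b1,
    )


def global_align(a: str, b: str, scoring=DEFAULT_SCORING) -> PairwiseAlignment:
    """Optimal global (Needleman-Wunsch, affine-gap) alignment."""
    if not a or not b:
        raise ValueError("global_align: empty input sequence")
    a, b = a.upper(), b.upper()
    _check_nt(a, "sequence a")
    _check_nt(b, "sequence b")
    aligner = _make_aligner(scoring, "global")
    aln = next(iter(aligner.align(a, b)))
    return _from_biopython(aln, a, b, "global")


def local_align(a: str, b: str, scoring=DEFAULT_SCORING) -> PairwiseAlignment:
    """Optimal local (Smith-Waterman) alignment; empty alignment (score 0) allowed."""
    if not a or not b:
        raise ValueError("local_align: empty input sequence")
    a, b = a.upper(), b.upper()
    _check_nt(a, "sequence a")
    _check_nt(b, "sequence b")
    aligner = _make_aligner(scoring, "local")
    score = aligner.score(a, b)
    if score <= 0:
        return PairwiseAlignment("", "", 0.0, 0.0, "local")
    aln = next(iter(aligner.align(a, b)))
    return _from_biopython(aln, a, b, "local")


def dotplot(a: str, b: str, window: int = 13, stringency: int = 11) -> list[DotPlotMatch]:
    """All window pairs of ``a`` vs ``b`` with >= ``stringency`` matching positions.

    Both direct and inverted (b reverse-complemented) orientations are reported.
    The defaults reproduce a window-13 / stringency-11 dot-plot matrix.
    """
    if not (1 <= stringency <= window):
        raise ValueError("require window >= stringency >= 1")
    if len(a) < window or len(b) < window:
        raise ValueError("sequences shorter than window")
    a, b = a.upper(), b.upper()
    _check_nt(a, "sequence a")
    _check_nt(b, "sequence b")
    out: list[DotPlotMatch] = []
    for orientation, bb in (("direct", b), ("inverted", revcomp(b))):
        av = np.frombuffer(a.encode(), dtype=np.uint8)
        bv = np.frombuffer(bb.encode(), dtype=np.uint8)
        nn = ord("N")
        eq = (av[:, None] == bv[None, :]) & (av[:, None] != nn)
        # window sums along diagonals via cumulative sum on each diagonal
        na, nb = len(a), len(bb)
        for d in range(-(na - window), nb - window + 1):
            diag = np.diagonal(eq, offset=d).astype(np.int32)
            if len(diag) < window:
                continue
            csum = np.concatenate([[0], np.cumsum(diag)])
            wsum = csum[window:] - csum[:-window]
            for k in np.nonzero(wsum >= stringency)[0]:
                i = k if d >= 0 else k - d
                j = k + d if d >= 0 else k
                if orientation == "inverted":
                    # report b position in original (uncomplemented) coordinates
                    j = nb - (j + window)
                out.append(DotPlotMatch(int(i), int(j), int(wsum[k]), orientation))
    out.sort(key=lambda m: (m.orientation, m.a_pos, m.b_pos))
    return out


_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def find_orfs(seq: str, min_aa: int, seq_id: str = "seq") -> list[tuple[Interval, str]]:
    """All ATG-to-stop ORFs on both strands with protein length >= ``min_aa``.

    Every in-frame ATG opens its own ORF (nested starts are reported separately);
    the protein excludes the stop. Intervals are in plus-strand coordinates with a
    strand flag and cover start codon through stop codon inclusive.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = seq.upper()
    _check_nt(seq, "find_orfs input")
    n = len(seq)
    results = []
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            # positions of stops in this frame, scanned once
            i = frame
            starts: list[int] = []
            while i + 3 <= n:
                codon = s[i:i + 3]
                if codon == "ATG":
                    starts.append(i)
                elif codon in _STANDARD_TABLE.stop_codons:
                    for st in starts:
                        aa_len = (i - st) // 3
                        if aa_len >= min_aa:
                            prot = str(Seq(s[st:i]).translate())
                            if strand == "+":
                                iv = Interval(seq_id, st, i + 3, "+")
                            else:
                                iv = Interval(seq_id, n - (i + 3), n - st, "-")
                            results.append((iv, prot))
                    starts = []
                i += 3
    results.sort(key=lambda r: (r[0].start, r[0].end, r[0].strand))
    return results
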