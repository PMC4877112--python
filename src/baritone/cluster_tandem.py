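"""Tandem-array detection, junction typing and deletion-microhomology analysis.

The heterochromatic Bari1 cluster consists of head-to-tail element copies whose
inter-copy junctions characteristically lack the first two nucleotides (CA) of
the downstream copy. Recombination between monomers leaves deletions flanked by
short identical repeats (microhomology), and satellite abundance in the array
flanks orients the cluster with respect to the centromere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import global_align
from .annotate import ElementAnnotation
from .seqio import GenomeRecord, Interval


@dataclass
class JunctionReport:
    junction_type: str  # {"canonical", "CA_deleted", "other"}
    left_member: int
    right_member: int
    window: str  # junction sequence window


@dataclass
class TandemArray:
    members: list[ElementAnnotation]
    junctions: list[JunctionReport] = field(default_factory=list)
    satellite_counts: dict[str, int] = field(default_factory=dict)

    @property
    def interval(self) -> Interval:
        return Interval(self.members[0].interval.seq_id,
                        self.members[0].interval.start,
                        self.members[-1].interval.end,
                        self.members[0].interval.strand)


@dataclass
class MicrohomologyReport:
    deletion_length: int
    breakpoint: int          # deletion start in the canonical sequence
    homology: str            # maximal exact repeat at the breakpoints
    homology_length: int


def find_tandem_arrays(annotations: list[ElementAnnotation],
                       max_gap: int = 100,
                       min_member_len: int = 15) -> list[TandemArray]:
    """Maximal runs of >= 2 same-strand members with inter-member gaps <=
    ``max_gap`` on one contig. Members shorter than ``min_member_len`` are
    ignored; short terminal relics >= 15 nt do count (flagged by length)."""
    arrays: list[TandemArray] = []
    by_contig: dict[str, list[ElementAnnotation]] = {}
    for a in annotations:
        if len(a.interval) >= min_member_len:
            by_contig.setdefault(a.interval.seq_id, []).append(a)
    for anns in by_contig.values():
        anns.sort(key=lambda a: a.interval.start)
        run: list[ElementAnnotation] = []
        for a in anns + [None]:
            if run and (a is None
                        or a.interval.strand != run[-1].interval.strand
                        or a.interval.start - run[-1].interval.end > max_gap):
                if len(run) >= 2:
                    arrays.append(TandemArray(members=run))
                run = []
            if a is not None:
                run.append(a)
    return arrays


def classify_junctions(array: TandemArray, genome: GenomeRecord,
                       reference: str, window: int = 60) -> list[JunctionReport]:
    """Type each adjacent-pair junction of a tandem array.

    ``CA_deleted``: the downstream copy starts at reference position 2, its
    two reference-initial nucleotides absent. ``canonical``: the downstream
    copy carries the full reference start. Anything else: ``other``.
    Classification is orientation-invariant: minus-strand arrays are read in
    element orientation.
    """
    out = []
    minus = array.members[0].interval.strand == "-"
    pairs = list(zip(array.members, array.members[1:]))
    for k, (left, right) in enumerate(pairs):
        boundary = right.interval.start if not minus else left.interval.end
        w0 = max(0, boundary - window // 2)
        win = genome.residues[w0:boundary + window // 2]
        # downstream (in element orientation) copy start sequence
        if not minus:
            down = genome.extract(Interval(genome.id, right.interval.start,
                                           min(right.interval.end,
                                               right.interval.start + 12), "+"))
        else:
            down = genome.extract(Interval(genome.id,
                                           max(left.interval.start,
                                               left.interval.end - 12),
                                           left.interval.end, "-"))
        if down == reference[:len(down)]:
            jt = "canonical"
        elif down == reference[2:2 + len(down)]:
            jt = "CA_deleted"
        else:
            jt = "other"
        li, ri = (k, k + 1)
        out.append(JunctionReport(junction_type=jt, left_member=li,
                                  right_member=ri, window=win))
    array.junctions = out
    return out


def find_deletion_microhomology(canonical_seq: str,
                                deleted_seq: str,
                                min_deletion: int = 10) -> MicrohomologyReport:
    """Locate the single largest deletion of ``deleted_seq`` relative to
    ``canonical_seq`` and the maximal exact repeat flanking both breakpoints
    (the putative recombination substrate).

    The two inputs are globally aligned; the longest run of gap columns in the
    deleted sequence is the deletion. The microhomology is grown outward from
    the breakpoints while the sequence entering the deletion matches the
    sequence at its far end.
    """
    aln = global_align(canonical_seq, deleted_seq)
    best_len = best_start = 0
    run = start = 0
    pos_a = 0  # position in canonical
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if cb == "-" and ca != "-":
            if run == 0:
                start = pos_a
            run += 1
            if run > best_len:
                best_len, best_start = run, start
        else:
            run = 0
        if ca != "-":
            pos_a += 1
    if best_len < min_deletion:
        return MicrohomologyReport(0, 0, "", 0)
    # microhomology: canonical[d0:d1) deleted; compare outward around breakpoints
    d0, d1 = best_start, best_start + best_len
    right = 0
    while (d1 + right < len(canonical_seq)
           and canonical_seq[d0 + right] == canonical_seq[d1 + right]):
        right += 1
    left = 0
    while (d0 - left - 1 >= 0
           and canonical_seq[d0 - left - 1] == canonical_seq[d1 - left - 1]):
        left += 1
    hom = canonical_seq[d0 - left:d0 + right]
    return MicrohomologyReport(deletion_length=best_len, breakpoint=d0,
                               homology=hom, homology_length=len(hom))


def count_satellite(genome: GenomeRecord, motif: str, min_pct: float = 80.0,
                    region: Interval | None = None, word: int = 11) -> int:
    """Non-overlapping count of satellite-monomer matches at >= ``min_pct``
    identity, greedy left-to-right.

    Exact ``word``-mer seeds vote for candidate monomer starts (tandem copies
    produce one candidate per monomer, unlike cluster-based searches that would
    merge the whole block); candidates are verified by ungapped identity.
    """
    import numpy as np

    from .annotate import _encode, _kmer_codes

    motif = motif.upper()
    if len(motif) < 10:
        raise ValueError("satellite consensus must be >= 10 nt")
    seq = genome.residues if region is None else genome.extract(region)
    k = min(word, len(motif) // 2)
    g_codes = _kmer_codes(_encode(seq), k)
    m_codes = _kmer_codes(_encode(motif), k)
    code_to_offsets: dict[int, list[int]] = {}
    for off, c in enumerate(m_codes):
        if c >= 0:
            code_to_offsets.setdefault(int(c), []).append(off)
    votes: dict[int, int] = {}
    match_pos = np.nonzero(np.isin(g_codes, np.unique(m_codes[m_codes >= 0])))[0]
    for p in match_pos:
        for off in code_to_offsets.get(int(g_codes[p]), ()):
            s = int(p) - off
            if 0 <= s <= len(seq) - len(motif):
                votes[s] = votes.get(s, 0) + 1
    L = len(motif)
    cands = []
    for s in sorted(votes):
        window = seq[s:s + L]
        ident = 100.0 * sum(a == b for a, b in zip(window, motif)) / L
        if ident >= min_pct:
            cands.append((s, ident))
    count = 0
    cursor = -1
    for s, _ in cands:
        if s >= cursor:
            count += 1
            cursor = s + L
    return count


def flank_satellite_counts(array: TandemArray, genome: GenomeRecord,
                           satellites: dict[str, str], flank: int = 50_000,
                           min_pct: float = 80.0) -> dict[str, dict[str, int]]:
    """Satellite-family counts in the two flanks of an array (the computable
    core of centromere-proximity orientation arguments)."""
    iv = array.interval
    left = Interval(iv.seq_id, max(0, iv.start - flank), iv.start) \
        if iv.start > 0 else None
    right = Interval(iv.seq_id, iv.end, min(len(genome.residues), iv.end + flank)) \
        if iv.end < len(genome.residues) else None
    out: dict[str, dict[str, int]] = {"left": {}, "right": {}}
    for name, motif in satellites.items():
        out["left"][name] = count_satellite(genome, motif, min_pct, left) if left else 0
        out["right"][name] = count_satellite(genome, motif, min_pct, right) if right else 0
    array.satellite_counts = {n: out["left"][n] + out["right"][n] for n in satellites}
    return out
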