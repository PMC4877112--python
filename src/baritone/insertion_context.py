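"""Insertion-site composition and co-occurrence statistics.

Target-site analysis: oriented flank extraction, sequence logos (position
frequencies and information content), AT-richness. Co-occurrence analysis:
counts of unrelated TE superfamilies within cumulative distance windows
(0-500 ... 0-2500 bp) of element flanks, compared against random control
regions under a Poisson model — the repeat rate in controls provides the
expected value, the flank count is the observed value, and one-sided tail
probabilities call enrichment or depletion per superfamily and window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .align import revcomp
from .seqio import GenomeRecord, Interval, RepeatFeature

#: cumulative distance windows (bp) from the sequence origin
DEFAULT_WINDOWS = (500, 1000, 1500, 2000, 2500)


@dataclass
class Flank:
    interval: Interval
    sequence: str        # read on the element's strand (upstream ends at the
                         # element, downstream starts at it)
    side: str            # {"upstream", "downstream"} relative to element strand
    proximal: str        # which region edge touches the element: {"start","end"}
    element_name: str
    truncated: bool


@dataclass
class LogoMatrix:
    width: int
    freqs: np.ndarray    # (width, 4) over A,C,G,T
    info: np.ndarray     # bits per position
    n_sequences: int


@dataclass
class CooccurrenceRow:
    superfamily: str
    window: int
    observed: int
    expected: float
    p_enrich: float
    p_deplete: float
    call: str            # {"enriched", "depleted", "ns"}
    flagged: bool = False


def extract_flanks(genome: GenomeRecord, annotations, flank_len: int = 2500
                   ) -> list[Flank]:
    """Upstream/downstream flanks of each element, oriented so position 0 is
    element-proximal (minus-strand elements are reverse-complemented);
    truncated flanks are flagged."""
    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    n = len(genome.residues)
    out = []
    for a in annotations:
        iv = a.interval
        if iv.seq_id != genome.id:
            continue
        left_iv = Interval(genome.id, max(0, iv.start - flank_len), iv.start) \
            if iv.start > 0 else None
        right_iv = Interval(genome.id, iv.end, min(n, iv.end + flank_len)) \
            if iv.end < n else None
        # the genomic left flank touches the element at its own end, the right
        # flank at its own start; on the minus strand left/right swap roles and
        # sequences are reverse-complemented into element orientation
        if iv.strand == "+":
            triples = (("upstream", left_iv, "end"), ("downstream", right_iv, "start"))
        else:
            triples = (("upstream", right_iv, "start"), ("downstream", left_iv, "end"))
        for side, f_iv, prox in triples:
            if f_iv is None:
                continue
            seq = genome.residues[f_iv.start:f_iv.end]
            if iv.strand == "-":
                seq = revcomp(seq)
            out.append(Flank(interval=f_iv, sequence=seq, side=side,
                             proximal=prox, element_name=a.name,
                             truncated=len(f_iv) < flank_len))
    return out


def logo(flank_seqs: list[str], width: int) -> LogoMatrix:
    """Position frequency matrix and information content R_i = 2 - H_i bits
    (no small-sample correction). Requires at least four sequences."""
    if len(flank_seqs) < 4:
        raise ValueError("insufficient flanks: need at least 4 sequences")
    if any(len(s) < width for s in flank_seqs):
        raise ValueError(f"all sequences must be at least {width} nt")
    idx = {b: i for i, b in enumerate("ACGT")}
    counts = np.zeros((width, 4))
    for s in flank_seqs:
        for p, c in enumerate(s[:width].upper()):
            if c in idx:
                counts[p, idx[c]] += 1
    tot = counts.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1
    freqs = counts / tot
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.nansum(np.where(freqs > 0, freqs * np.log2(freqs), 0.0), axis=1)
    info = 2.0 - h
    return LogoMatrix(width=width, freqs=freqs, info=info,
                      n_sequences=len(flank_seqs))


def at_fraction(seqs: list[str] | str) -> float:
    """(A+T)/(A+C+G+T); N excluded. Error when no countable base remains."""
    if isinstance(seqs, str):
        seqs = [seqs]
    if not seqs:
        raise ValueError("empty input")
    at = acgt = 0
    for s in seqs:
        for c in s.upper():
            if c in "AT":
                at += 1
                acgt += 1
            elif c in "CG":
                acgt += 1
    if acgt == 0:
        raise ValueError("no A/C/G/T bases")
    return at / acgt


def sample_controls(genomes: list[GenomeRecord], n: int = 1000,
                    length: int = 2500, seed: int | None = None,
                    rng: np.random.Generator | None = None) -> list[Interval]:
    """Seeded uniform sampling of ``n`` non-overlapping, N-free control windows.

    Deterministic given the seed; raises (stating the deficit) when the
    genomes cannot host the requested windows.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    # candidate starts per genome, excluding windows containing N
    pool: list[tuple[int, int]] = []  # (genome index, start)
    for gi, g in enumerate(genomes):
        seq = g.residues
        if len(seq) < length:
            continue
        has_n = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("N")
        bad = np.convolve(has_n.astype(np.int32), np.ones(length, dtype=np.int32),
                          mode="valid") > 0
        for s in np.nonzero(~bad)[0]:
            pool.append((gi, int(s)))
    chosen: list[Interval] = []
    taken: dict[int, list[tuple[int, int]]] = {}
    order = rng.permutation(len(pool))
    for k in order:
        gi, s = pool[k]
        if any(s < e2 and s + length > s2 for s2, e2 in taken.get(gi, ())):
            continue
        taken.setdefault(gi, []).append((s, s + length))
        chosen.append(Interval(genomes[gi].id, s, s + length, "+"))
        if len(chosen) == n:
            break
    if len(chosen) < n:
        raise ValueError(
            f"insufficient eligible sequence: placed {len(chosen)} of {n} windows")
    return chosen


def nearest_repeat_distances(regions: list,
                             repeats: list[RepeatFeature]) -> list[dict]:
    """Distances of repeats from each region's origin.

    Regions are Intervals (origin = region start, the convention for random
    control scaffolds) or Flanks (origin = the element-proximal edge). Every
    repeat overlapping a region is recorded.
    """
    out = []
    for region in regions:
        if isinstance(region, Flank):
            iv, from_end = region.interval, region.proximal == "end"
        else:
            iv, from_end = region, False
        rows = []
        for rep in repeats:
            riv = rep.interval
            if not riv.overlaps(iv):
                continue
            if from_end:
                dist = max(0, iv.end - riv.end)
            else:
                dist = max(0, riv.start - iv.start)
            rows.append({"superfamily": rep.superfamily, "family": rep.family,
                         "distance": int(dist)})
        out.append({"region": iv, "repeats": rows})
    return out


def cooccurrence_test(flank_distances: list[dict], control_distances: list[dict],
                      n_flanks: int, n_controls: int,
                      alpha: float = 0.05,
                      windows: tuple[int, ...] = DEFAULT_WINDOWS,
                      superfamilies: list[str] | None = None
                      ) -> list[CooccurrenceRow]:
    """Poisson enrichment/depletion per superfamily and cumulative window.

    Expected count: lambda = (control count within w / n_controls) * n_flanks.
    p_enrich = P(X >= obs | lambda), p_deplete = P(X <= obs | lambda); both
    tails include the point mass, so p_enrich + p_deplete >= 1.
    """
    if n_controls < 100:
        raise ValueError("need n_controls >= 100")

    def tally(dist_rows):
        t: dict[tuple[str, int], int] = {}
        for row in dist_rows:
            for rep in row["repeats"]:
                for w in windows:
                    if rep["distance"] < w:
                        key = (rep["superfamily"], w)
                        t[key] = t.get(key, 0) + 1
        return t

    obs_t = tally(flank_distances)
    ctl_t = tally(control_distances)
    if superfamilies is None:
        superfamilies = sorted({sf for sf, _ in list(obs_t) + list(ctl_t)})
    rows = []
    for sf in superfamilies:
        for w in windows:
            obs = obs_t.get((sf, w), 0)
            lam = ctl_t.get((sf, w), 0) / n_controls * n_flanks
            flagged = False
            if lam == 0:
                if obs == 0:
                    rows.append(CooccurrenceRow(sf, w, 0, 0.0, 1.0, 1.0, "ns"))
                    continue
                # no control counts at all: report the resolution bound
                p_en = 1.0 / n_controls
                rows.append(CooccurrenceRow(sf, w, obs, 0.0, p_en, 1.0,
                                            "enriched" if p_en < alpha else "ns",
                                            flagged=True))
                continue
            p_en = float(stats.poisson.sf(obs - 1, lam))   # P(X >= obs)
            p_de = float(stats.poisson.cdf(obs, lam))      # P(X <= obs)
            if p_en < alpha:
                call = "enriched"
            elif p_de < alpha:
                call = "depleted"
            else:
                call = "ns"
            rows.append(CooccurrenceRow(sf, w, obs, lam, p_en, p_de, call, flagged))
    return rows


def signed_log10(row: CooccurrenceRow) -> float:
    """-log10 of the smaller tail, signed positive for enrichment and negative
    for depletion (the sign convention of relative-probability plots)."""
    if row.p_enrich <= row.p_deplete:
        return -math.log10(max(row.p_enrich, 1e-300))
    return math.log10(max(row.p_deplete, 1e-300))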