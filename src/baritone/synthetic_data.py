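"""Synthetic genomes with implanted ground-truth elements.

Generates Tc1-mariner-style templates (CA...TG termini, SIR or LIR terminal
architecture, three 18-nt direct repeats per terminus, a toy 339-codon
transposase CDS), derives MITEs by internal deletion between the Lo-Lm and
Rm-Ro direct repeats, and implants diverged copies into random genomes at TA
dinucleotides inside AT-rich loci with target-site duplication — so every
pipeline stage can be exercised against known truth.

Mutations are i.i.d. substitutions with a 2:1 transition:transversion bias.
All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import revcomp
from .annotate import ElementAnnotation, ReferenceSet
from .seqio import GenomeRecord, Interval

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")

#: transition partner of each base
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _rand_seq(rng: np.random.Generator, n: int, at: float = 0.5) -> str:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def mutate(seq: str, rate: float, rng: np.random.Generator,
           protect: list[tuple[int, int]] | None = None) -> str:
    """i.i.d. substitutions at ``rate`` with 2:1 ts:tv; optional protected spans."""
    chars = list(seq)
    mask = rng.random(len(chars)) < rate
    if protect:
        for lo, hi in protect:
            mask[lo:hi] = False
    for i in np.nonzero(mask)[0]:
        c = chars[i]
        if c not in _TRANSITION:
            continue
        if rng.random() < 2 / 3:
            chars[i] = _TRANSITION[c]
        else:
            tvs = [b for b in "ACGT" if b != c and b != _TRANSITION[c]]
            chars[i] = tvs[int(rng.integers(2))]
    return "".join(chars)


@dataclass
class TransposonTemplate:
    """A full-length synthetic element with known internal layout."""

    name: str
    subfamily: str
    tir_type: str              # {"SIR", "LIR"}
    sequence: str
    arm_len: int
    dr: str                    # the 18-nt direct-repeat motif
    dr_left: list[tuple[int, int]]   # Lo, Lm, Li spans (element coords)
    dr_right: list[tuple[int, int]]  # Ri, Rm, Ro spans (element coords, ascending)
    cds: tuple[int, int]       # CDS span incl. stop codon
    protein: str

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def lo_end(self) -> int:
        return self.dr_left[0][1]

    @property
    def ro_start(self) -> int:
        return self.dr_right[-1][0]


def _toy_cds(rng: np.random.Generator, n_aa: int) -> tuple[str, str]:
    """Random CDS of n_aa codons (ATG start, no internal stop) plus stop."""
    from Bio.Seq import Seq

    codons = ["ATG"]
    while len(codons) < n_aa:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    cds = "".join(codons)
    return cds, str(Seq(cds[:-3]).translate())


def make_template(subfamily: str = "Bari1", tir_type: str = "SIR",
                  length: int = 1726, seed: int = 0,
                  n_aa: int = 339, dr_len: int = 18,
                  terminal_window: int = 250) -> TransposonTemplate:
    """Build a synthetic full-length element.

    SIR templates get a 28-nt terminal arm; LIR templates a full-window
    (~250 nt) arm, i.e. the right terminus is the reverse complement of the
    left. Both carry three identical direct repeats per terminus (the family's
    DRs are highly similar to one another). The element starts with CA and ends
    with TG.
    """
    if tir_type not in ("SIR", "LIR"):
        raise ValueError("tir_type must be SIR or LIR")
    rng = np.random.default_rng(seed)
    cds, protein = _toy_cds(rng, n_aa)
    w = terminal_window
    min_len = 2 * w + len(cds) + 2
    if length < min_len:
        raise ValueError(f"length {length} incompatible: need >= {min_len}")

    arm_len = 28 if tir_type == "SIR" else w
    arm = "CA" + _rand_seq(rng, arm_len - 2)
    dr = _rand_seq(rng, dr_len)
    # DR slot starts within the terminal window (outer, middle, inner); the two
    # termini of a SIR element carry the DRs at offset positions, as the blocks
    # are shared in sequence, not in exact placement
    slot_starts = (38, 86, 134)
    slot_starts_right = slot_starts if tir_type == "LIR" else (44, 96, 146)

    def build_terminus(rng_local, starts) -> str:
        t = list(_rand_seq(rng_local, w))
        t[:arm_len] = list(arm)
        for s in starts:
            t[s:s + dr_len] = list(dr)
        return "".join(t)

    left = build_terminus(rng, slot_starts)
    if tir_type == "LIR":
        right = revcomp(left)
    else:
        right = revcomp(build_terminus(rng, slot_starts_right))

    pad_total = length - 2 * w - len(cds)
    pad1 = pad_total // 2
    pad2 = pad_total - pad1
    seq = left + _rand_seq(rng, pad1) + cds + _rand_seq(rng, pad2) + right
    assert len(seq) == length and seq.startswith("CA") and seq.endswith("TG")

    dr_left = [(s, s + dr_len) for s in slot_starts]
    # right DR spans in element coordinates (reverse-complemented layout)
    dr_right = sorted((length - (s + dr_len), length - s) for s in slot_starts_right)
    cds_start = w + pad1
    return TransposonTemplate(
        name=f"{subfamily}_synthetic", subfamily=subfamily, tir_type=tir_type,
        sequence=seq, arm_len=arm_len, dr=dr, dr_left=dr_left, dr_right=dr_right,
        cds=(cds_start, cds_start + len(cds)), protein=protein,
    )


def derive_mite(template: TransposonTemplate, filler_length: int = 0,
                seed: int = 0) -> str:
    """MITE by internal deletion between the Lo-Lm and Rm-Ro direct repeats:
    keeps the Lo-containing left stub and the Ro-containing right stub, joined
    directly or through random filler."""
    rng = np.random.default_rng(seed)
    left_stub = template.sequence[:template.lo_end]
    right_stub = template.sequence[template.ro_start:]
    filler = _rand_seq(rng, filler_length) if filler_length else ""
    return left_stub + filler + right_stub


@dataclass
class ImplantSpec:
    """Conditions for one synthetic-genome build.

    Copy categories: autonomous, inactive, truncated, MITE, partial.
    """

    seed: int
    genome_length: int = 1_000_000
    #: one partial per contig extremity; interior fragments would not be partial
    n_copies: dict[str, int] = field(default_factory=lambda: {
        "autonomous": 12, "inactive": 12, "truncated": 12, "MITE": 12, "partial": 2})
    divergence: float = 0.05
    at_background: float = 0.55
    at_rich_at: float = 0.70
    at_rich_fraction: float = 0.30
    mite_filler: int = 400
    species_code: str = "Dsyn"
    contig_id: str = "synth_contig_1"
    nested: int = 0  # copies receiving an unrelated nested insertion

    def __post_init__(self):
        if not 0 <= self.divergence <= 1:
            raise ValueError("divergence must be in [0,1]")


def _background_genome(rng: np.random.Generator, spec: ImplantSpec) -> tuple[str, list[tuple[int, int]]]:
    """Background sequence with AT-rich loci (blocks of 4-10 kb)."""
    n = spec.genome_length
    blocks = []
    pos = 0
    rich: list[tuple[int, int]] = []
    while pos < n:
        blk = int(rng.integers(4000, 10001))
        blk = min(blk, n - pos)
        is_rich = rng.random() < spec.at_rich_fraction
        at = spec.at_rich_at if is_rich else spec.at_background
        blocks.append(_rand_seq(rng, blk, at=at))
        if is_rich:
            rich.append((pos, pos + blk))
        pos += blk
    return "".join(blocks), rich


def _make_copy(category: str, template: TransposonTemplate, mite_seq: str,
               rate: float, rng: np.random.Generator) -> tuple[str, str]:
    """One diverged element copy; returns (sequence, notes)."""
    if category == "MITE":
        return mutate(mite_seq, rate, rng), ""
    seq = mutate(template.sequence, rate, rng)
    c0, c1 = template.cds
    # repair any mutation-created premature stop / broken start so that
    # "autonomous" means what it says
    codons = [seq[i:i + 3] for i in range(c0, c1 - 3, 3)]
    tmpl_codons = [template.sequence[i:i + 3] for i in range(c0, c1 - 3, 3)]
    repaired = [codons[0] if codons[0] == "ATG" else "ATG"]
    for cod, tc in zip(codons[1:], tmpl_codons[1:]):
        repaired.append(tc if cod in _STOPS else cod)
    seq = seq[:c0] + "".join(repaired) + seq[c1 - 3:]
    if category == "autonomous":
        return seq, ""
    if category == "inactive":
        k = int(rng.integers(len(repaired) // 4, 3 * len(repaired) // 4))
        stop_pos = c0 + 3 * k
        seq = seq[:stop_pos] + "TAA" + seq[stop_pos + 3:]
        return seq, "premature_stop"
    if category == "truncated":
        frac = float(rng.uniform(0.15, 0.55))
        cut = int(len(seq) * frac)
        if rng.random() < 0.5:
            return seq[cut:], f"left_truncation_{cut}"
        return seq[:-cut], f"right_truncation_{cut}"
    raise ValueError(f"unknown category {category!r}")


def implant(spec: ImplantSpec, template: TransposonTemplate | None = None,
            ) -> tuple[GenomeRecord, list[ElementAnnotation], ReferenceSet]:
    """Build a genome with implanted copies; returns (genome, truth, references).

    Every copy is inserted at a TA dinucleotide inside an AT-rich locus with the
    TA duplicated on both sides (target-site duplication). Truth annotations are
    in final genome coordinates. The reference set holds the implant templates
    (full element, MITE, transposase protein).
    """
    rng = np.random.default_rng(spec.seed)
    if template is None:
        template = make_template(seed=int(rng.integers(2**31)))
    mite_seq = derive_mite(template, filler_length=spec.mite_filler,
                           seed=int(rng.integers(2**31)))
    background, rich = _background_genome(rng, spec)

    # candidate TA sites inside AT-rich loci, well separated
    sites = []
    margin = len(template) + 3000
    for lo, hi in rich:
        p = lo + 100
        while p < hi - 100:
            if background[p:p + 2] == "TA":
                sites.append(p)
                p += margin
            else:
                p += 1
    sites = [s for s in sites if margin < s < len(background) - margin]
    rng.shuffle(sites)

    plan: list[tuple[str, str, str, str]] = []  # (category, seq, strand, notes)
    for category in ("autonomous", "inactive", "truncated", "MITE"):
        for _ in range(spec.n_copies.get(category, 0)):
            seq, notes = _make_copy(category, template, mite_seq,
                                    spec.divergence, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            plan.append((category, seq, strand, notes))
    n_interior = len(plan)
    if n_interior > len(sites):
        raise ValueError(f"genome too small: {n_interior} copies, {len(sites)} eligible sites")

    # nested insertions: mark the first `nested` autonomous copies
    inserts = []  # (position, full_inserted_seq, category, strand, elem_len, notes)
    for (category, seq, strand, notes), site in zip(plan, sites):
        elem = seq if strand == "+" else revcomp(seq)
        inserts.append([site, elem, category, strand, notes])
    inserts.sort(key=lambda t: -t[0])  # right to left keeps coordinates stable

    genome_seq = background
    truth_raw = []  # (start, end, category, strand, notes)
    for site, elem, category, strand, notes in inserts:
        # duplicate the TA: ...TA [elem] TA...
        genome_seq = genome_seq[:site + 2] + elem + genome_seq[site:]
        shift = len(elem) + 2
        truth_raw = [(s + shift if s >= site else s, e + shift if s >= site else e,
                      c, st, nt) for s, e, c, st, nt in truth_raw]
        truth_raw.append((site + 2, site + 2 + len(elem), category, strand, notes))

    # partial copies at the contig extremities (at most one per end)
    n_partial = min(2, spec.n_copies.get("partial", 0))
    for i in range(n_partial):
        seq, _ = _make_copy("autonomous", template, mite_seq, spec.divergence, rng)
        keep = int(len(seq) * rng.uniform(0.35, 0.6))
        if i % 2 == 0:  # element running off the contig start
            frag = seq[len(seq) - keep:]
            genome_seq = frag + genome_seq
            truth_raw = [(s + keep, e + keep, c, st, nt) for s, e, c, st, nt in truth_raw]
            truth_raw.append((0, keep, "partial", "+", "contig_start"))
        else:
            frag = seq[:keep]
            truth_raw.append((len(genome_seq), len(genome_seq) + keep, "partial", "+",
                              "contig_end"))
            genome_seq = genome_seq + frag

    genome = GenomeRecord(id=spec.contig_id, residues=genome_seq,
                          species_code=spec.species_code)
    truth: list[ElementAnnotation] = []
    cat_to_fields = {
        "autonomous": ("putatively_autonomous", template.subfamily, template.tir_type, (3, 3)),
        "inactive": ("inactive_full_length", template.subfamily, template.tir_type, (3, 3)),
        "truncated": ("truncated", template.subfamily, template.tir_type, (3, 3)),
        "MITE": ("MITE", "MITE", template.tir_type, (1, 1)),
        "partial": ("partial", template.subfamily, "ND", (0, 0)),
    }
    for k, (s, e, c, st, nt) in enumerate(sorted(truth_raw)):
        category, subfamily, tir, drs = cat_to_fields[c]
        truth.append(ElementAnnotation(
            interval=Interval(spec.contig_id, s, e, st),
            species_code=spec.species_code, category=category,
            subfamily=subfamily, tir_type=tir, dr_counts=drs,
            # a truncated copy lost one flank along with the cut end, so the
            # two-sided TA signature survives only on intact insertions
            tsd={"partial": "unknown", "truncated": "absent"}.get(c, "TA"),
            name=f"truth_{k}", notes=nt,
        ))
    refs = ReferenceSet(
        proteins={f"{template.subfamily}_tnp": template.protein},
        elements={template.name: template.sequence,
                  f"{template.name}_MITE": mite_seq},
        subfamilies={template.name: template.subfamily,
                     f"{template.name}_MITE": "MITE"},
    )
    return genome, truth, refs


def implant_cluster(genome: GenomeRecord, template: TransposonTemplate,
                    n_copies: int, junction: str = "CA_deleted",
                    satellite: tuple[str, int] | None = None,
                    seed: int = 0, position: int | None = None,
                    ) -> tuple[GenomeRecord, dict]:
    """Implant a head-to-tail tandem array (optionally flanked by a satellite
    block) into a genome; returns the new genome and a truth dict.

    ``junction="CA_deleted"`` drops the first two nucleotides (CA) of every
    downstream copy, the hallmark of the heterochromatic cluster junctions.
    """
    if n_copies < 2:
        raise ValueError("need n_copies >= 2")
    if junction not in ("canonical", "CA_deleted"):
        raise ValueError(f"unknown junction type {junction!r}")
    rng = np.random.default_rng(seed)
    monomer = template.sequence
    members = [monomer] + [
        monomer[2:] if junction == "CA_deleted" else monomer
        for _ in range(n_copies - 1)
    ]
    array = "".join(members)
    sat_block = ""
    sat_truth = None
    if satellite is not None:
        sat_seq, k = satellite
        sat_block = sat_seq * k
        sat_truth = {"monomer": sat_seq, "count": k}
    insert = array + sat_block
    pos = position if position is not None else int(
        rng.integers(1000, len(genome.residues) - 1000))
    new_seq = genome.residues[:pos] + insert + genome.residues[pos:]
    member_ivs = []
    cursor = pos
    for m in members:
        member_ivs.append(Interval(genome.id, cursor, cursor + len(m), "+"))
        cursor += len(m)
    truth = {
        "array_interval": Interval(genome.id, pos, pos + len(array), "+"),
        "members": member_ivs,
        "junction": junction,
        "n_junctions": n_copies - 1,
        "satellite": sat_truth,
        "satellite_interval": (Interval(genome.id, pos + len(array),
                                        pos + len(insert), "+")
                               if sat_block else None),
    }
    return GenomeRecord(id=genome.id, residues=new_seq,
                        species_code=genome.species_code), truth


def simulate_bursts(template_seq: str, n_copies: int, waves: int = 1,
                    rates: tuple[float, float] = (0.05, 0.01),
                    seed: int = 0) -> list[str]:
    """Element copies from one or two transposition waves.

    One wave: every copy mutated from the template at rates[0]. Two waves: half
    the copies are re-copied from one first-wave copy and mutated at rates[1],
    producing a multimodal pairwise-diversity distribution.
    """
    if n_copies < 8:
        raise ValueError("need n_copies >= 8")
    if waves not in (1, 2):
        raise ValueError("waves must be 1 or 2")
    rng = np.random.default_rng(seed)
    copies = [mutate(template_seq, rates[0], rng) for _ in range(n_copies)]
    if waves == 2:
        master = copies[0]
        half = n_copies // 2
        copies[half:] = [mutate(master, rates[1], rng) for _ in range(n_copies - half)]
    return copies
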