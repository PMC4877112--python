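"""Terminal inverted repeat (TIR) and direct repeat (DR) detection.

Bari-family termini come in two architectures: short inverted repeats (SIR,
around 28 nt) and long inverted repeats (LIR, roughly 250 nt). Both carry three
conserved ~18-nt direct repeats per terminus (slots Lo/Lm/Li on the left and
Ro/Rm/Ri on the right, reading outer to inner). The right terminus is always
reverse-complemented before DR comparison so all six slots read in one
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import global_align, local_align, revcomp
from .seqio import Interval

#: arm length (nt) at or above which a terminus is typed LIR rather than SIR
LIR_THRESHOLD = 60

LEFT_SLOTS = ("Lo", "Lm", "Li")
RIGHT_SLOTS = ("Ro", "Rm", "Ri")


@dataclass
class DirectRepeat:
    """One ~18-nt direct-repeat block.

    ``interval.seq_id`` is "left_terminus" or "right_terminus"; coordinates are
    relative to the terminal window, with the right window reverse-complemented
    (position 0 = outermost nucleotide of the element on either side).
    """

    slot: str
    interval: Interval
    sequence: str
    mismatches: int = 0


@dataclass
class TerminalStructureReport:
    left_terminal: Interval | None
    right_terminal: Interval | None
    tir_arm_length: int
    tir_similarity: float
    tir_type: str  # {"SIR", "LIR", "ND"}
    drs: list[DirectRepeat] = field(default_factory=list)
    dr_count_left: int = 0
    dr_count_right: int = 0
    #: span from Lo start to Li end (left terminus), None when < 2 DRs
    dr_span_left: int | None = None
    terminal_window: int = 250

    @property
    def label(self) -> str:
        """Structure label such as "SIR-3DR" or "LIR-1DR"."""
        n = max(self.dr_count_left, self.dr_count_right)
        return f"{self.tir_type}-{n}DR"


def find_terminal_ir(
    element_seq: str,
    max_arm: int = 400,
    min_arm: int = 20,
    min_pct: float = 60.0,
    xdrop: int = 12,
) -> tuple[tuple[Interval, Interval], float] | None:
    """Best terminal inverted-repeat arm pair, or None if nothing qualifies.

    A TIR arm is anchored at the element extremities: the first base of the
    element pairs with the last. The left prefix is compared position-by-position
    with the reverse complement of the right suffix (match +1, mismatch or N -1);
    extension stops once the running score falls more than ``xdrop`` below its
    maximum, and the arm ends at the highest-scoring prefix (ties broken toward
    the longest arm). The arm qualifies if it spans at least ``min_arm``
    positions at >= ``min_pct`` identity.

    An unanchored search would happily chain the short arm of a SIR element with
    the direct repeats shared between its termini into one long, low-identity
    "arm"; anchoring plus the X-drop cutoff is what keeps SIR arms short.
    """
    seq = element_seq.upper()
    n = len(seq)
    if n < 2 * min_arm:
        raise ValueError(f"element length {n} < 2*min_arm")
    w = min(max_arm, n // 2)
    left_w = seq[:w]
    right_w_rc = revcomp(seq[n - w:])
    score = 0
    best = -1
    best_k = -1
    for k in range(w):
        hit = left_w[k] == right_w_rc[k] and left_w[k] != "N"
        score += 1 if hit else -1
        if score >= best:
            best, best_k = score, k
        elif score < best - xdrop:
            break
    arm = best_k + 1
    if arm < 1:
        return None
    matches = (arm + best) // 2
    identity = 100.0 * matches / arm
    if arm < min_arm or identity < min_pct:
        return None
    left_iv = Interval("element", 0, arm, "+")
    right_iv = Interval("element", n - arm, n, "-")
    return (left_iv, right_iv), identity


def classify_tir_type(arm_length: int, lir_threshold: int = LIR_THRESHOLD) -> str:
    if arm_length < 1:
        raise ValueError("arm_length must be >= 1")
    return "SIR" if arm_length < lir_threshold else "LIR"


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def _occurrences(terminus: str, motif: str, max_mismatch: int,
                 exclude: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Non-overlapping best occurrences of motif (Hamming <= max_mismatch).

    A window is excluded only when more than half of it falls inside an
    exclusion zone (a chance-extended arm may graze the outer DR slot)."""
    L, k = len(terminus), len(motif)
    cands = []
    for i in range(L - k + 1):
        if any(min(i + k, e) - max(i, s) > k // 2 for s, e in exclude):
            continue
        mm = _hamming(terminus[i:i + k], motif)
        if mm <= max_mismatch:
            cands.append((mm, i))
    cands.sort()
    chosen: list[tuple[int, int]] = []
    for mm, i in cands:
        if all(abs(i - j) >= k for _, j in chosen):
            chosen.append((mm, i))
    chosen.sort(key=lambda c: c[1])
    return chosen


def detect_drs(
    left_terminus: str,
    right_terminus: str,
    dr_len: int = 18,
    max_mismatch: int = 4,
    seed_len: int = 8,
    exclude_left: list[tuple[int, int]] | None = None,
    exclude_right: list[tuple[int, int]] | None = None,
) -> list[DirectRepeat]:
    """Direct-repeat blocks shared between the two terminal windows.

    ``right_terminus`` must already be reverse-complemented (element-internal
    orientation). Exact common ``seed_len``-mers between the windows seed
    candidate ``dr_len`` blocks (kept at <= ``max_mismatch`` mismatches); each
    candidate motif is then re-scanned against both windows and the motif with
    the most (capped at 3 per terminus) non-overlapping occurrences wins. Up to
    three blocks per terminus are reported, slots assigned outer to inner.
    """
    left = left_terminus.upper()
    right = right_terminus.upper()
    if len(left) < dr_len or len(right) < dr_len:
        raise ValueError("terminal window shorter than dr_len")
    excl_l = exclude_left or []
    excl_r = exclude_right or []

    # seed: exact common seed_len-mers
    index: dict[str, list[int]] = {}
    for i in range(len(left) - seed_len + 1):
        index.setdefault(left[i:i + seed_len], []).append(i)
    seed_pairs: list[tuple[int, int]] = []
    for j in range(len(right) - seed_len + 1):
        for i in index.get(right[j:j + seed_len], ()):
            seed_pairs.append((i, j))

    # extend each seed to the best dr_len window containing it
    motifs: dict[str, tuple[int, int, int]] = {}  # motif -> (mismatches, i, j)
    for i, j in seed_pairs:
        best = None
        for off in range(dr_len - seed_len + 1):
            li, rj = i - off, j - off
            if li < 0 or rj < 0 or li + dr_len > len(left) or rj + dr_len > len(right):
                continue
            mm = _hamming(left[li:li + dr_len], right[rj:rj + dr_len])
            if mm <= max_mismatch and (best is None or mm < best[0]):
                best = (mm, li, rj)
        if best is not None:
            motif = left[best[1]:best[1] + dr_len]
            if motif not in motifs or best < motifs[motif]:
                motifs[motif] = best
    if not motifs:
        return []

    # pick the motif with the most supported occurrences on both termini
    scored = []
    for motif, (mm, i, j) in motifs.items():
        occ_l = _occurrences(left, motif, max_mismatch, excl_l)
        occ_r = _occurrences(right, motif, max_mismatch, excl_r)
        if not occ_l or not occ_r:
            continue
        score = (min(len(occ_l), 3) + min(len(occ_r), 3),
                 -mm, -i)  # multiplicity, then seed quality, then leftmost
        scored.append((score, motif, occ_l, occ_r))
    if not scored:
        return []
    scored.sort(key=lambda t: t[0], reverse=True)
    _, motif, occ_l, occ_r = scored[0]

    # refine: the chosen motif is one diverged instance; rescanning with the
    # column-majority consensus of all found instances recovers slots that sit
    # just past the mismatch cap relative to a single instance
    for _ in range(2):
        inst = [left[p:p + dr_len] for _, p in occ_l] + \
               [right[p:p + dr_len] for _, p in occ_r]
        if len(inst) < 2:
            break
        cons = "".join(max("ACGT", key=lambda b: sum(s[c] == b for s in inst))
                       for c in range(dr_len))
        if cons == motif:
            break
        motif = cons
        occ_l = _occurrences(left, motif, max_mismatch, excl_l)
        occ_r = _occurrences(right, motif, max_mismatch, excl_r)

    # clean families (instances nearly identical) should not accrete chance
    # near-matches at the full mismatch cap: bound the accepted divergence by
    # what the family itself shows
    mms = sorted(mm for mm, _ in occ_l + occ_r)
    if len(mms) >= 2:
        thr = min(max_mismatch, mms[len(mms) // 2] + 3)
        occ_l = [(mm, p) for mm, p in occ_l if mm <= thr]
        occ_r = [(mm, p) for mm, p in occ_r if mm <= thr]

    drs: list[DirectRepeat] = []
    for (occs, slots, term, name) in (
        (occ_l[:3], LEFT_SLOTS, left, "left_terminus"),
        (occ_r[:3], RIGHT_SLOTS, right, "right_terminus"),
    ):
        for slot, (mm, pos) in zip(slots, occs):
            drs.append(DirectRepeat(
                slot=slot,
                interval=Interval(name, pos, pos + dr_len, "+"),
                sequence=term[pos:pos + dr_len],
                mismatches=mm,
            ))
    return drs


def terminal_report(
    element_seq: str,
    terminal_window: int = 250,
    dr_len: int = 18,
    max_mismatch: int = 4,
    lir_threshold: int = LIR_THRESHOLD,
    min_arm: int = 20,
    min_pct: float = 60.0,
) -> TerminalStructureReport:
    """Full terminal-structure report: TIR arms, SIR/LIR type, DR slots.

    The similarity reported is the global-alignment percent identity of the two
    terminal windows (right reverse-complemented) for LIR-type elements, or of
    the SIR arms for SIR-type elements.
    """
    seq = element_seq.upper()
    n = len(seq)
    if n < 2 * min_arm:
        raise ValueError(f"element too short ({n} nt) for terminal analysis")
    w = min(terminal_window, n // 2)
    left_w = seq[:w]
    right_w_rc = revcomp(seq[n - w:])

    ir = find_terminal_ir(seq, max_arm=400, min_arm=min_arm, min_pct=min_pct)
    if ir is None:
        tir_type = "ND"
        arm_len = 0
        left_iv = right_iv = None
        arm_sim = 0.0
    else:
        (left_iv, right_iv), arm_sim = ir
        arm_len = len(left_iv)
        tir_type = classify_tir_type(arm_len, lir_threshold)

    window_sim = global_align(left_w, right_w_rc).pct_identity
    tir_similarity = arm_sim if tir_type == "SIR" else window_sim

    # a short SIR arm is itself a shared terminal block: keep it out of the DR
    # slots; LIR arms span the whole window and contain the DRs, so no exclusion
    excl_l: list[tuple[int, int]] = []
    excl_r: list[tuple[int, int]] = []
    if tir_type == "SIR" and left_iv is not None and right_iv is not None:
        excl_l = [(left_iv.start, left_iv.end)]
        excl_r = [(n - right_iv.end, n - right_iv.start)]  # rc-window coords

    drs = []
    if w >= dr_len:
        drs = detect_drs(left_w, right_w_rc, dr_len=dr_len, max_mismatch=max_mismatch,
                         exclude_left=excl_l, exclude_right=excl_r)
        if not drs and (excl_l or excl_r):
            # short elements whose arm engulfs the outer DR (e.g. zero-filler
            # MITEs are palindromes): retry without the arm exclusion
            drs = detect_drs(left_w, right_w_rc, dr_len=dr_len, max_mismatch=max_mismatch)
    left_drs = [d for d in drs if d.slot in LEFT_SLOTS]
    right_drs = [d for d in drs if d.slot in RIGHT_SLOTS]
    span = None
    if len(left_drs) >= 2:
        span = left_drs[-1].interval.end - left_drs[0].interval.start
    return TerminalStructureReport(
        left_terminal=left_iv,
        right_terminal=right_iv,
        tir_arm_length=arm_len,
        tir_similarity=tir_similarity,
        tir_type=tir_type,
        drs=drs,
        dr_count_left=len(left_drs),
        dr_count_right=len(right_drs),
        dr_span_left=span,
        terminal_window=w,
    )
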