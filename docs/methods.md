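# Methods

`baritone` annotates and analyses Bari-family transposons — Tc1-mariner DNA
transposons of drosophilids — and ships a synthetic-genome generator that lets
every stage be validated against known ground truth. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Element model

A full-length Bari-like element begins with `CA`, ends with `TG`, and carries a
terminal inverted repeat (TIR) at each extremity: either a *short* inverted
repeat (SIR, ≈28 nt, the Bari1 architecture) or a *long* one (LIR, ≈250 nt, the
Bari2/Bari3 architecture). Both architectures carry three conserved ~18-nt
direct repeats (DRs) within the terminal 250 nt of each side — slots Lo/Lm/Li
on the left and Ro/Rm/Ri on the right, reading outer → inner — which are the
transposase binding sites. A central ORF encodes a ~339-aa transposase.
Insertion targets a TA dinucleotide, duplicated on both sides (TSD).

Categories assigned by the classifier:

| category | definition |
|---|---|
| `putatively_autonomous` | two 3-DR termini bracketing an intact ORF (≥300 codons spanning ≥80% of the inter-terminal region, ≥75% similarity to a reference transposase) |
| `inactive_full_length` | two 3-DR termini, no intact ORF |
| `truncated` | element chunk missing termini |
| `partial` | overlaps a contig boundary; counted but not analysed further |
| `MITE` | ≤939 nt, TIR present, ≤1 DR per terminus, no transposase homology in any reading frame |

## Terminal-structure detection

**TIR arms** are found by *anchored* X-drop extension: the element's first base
must pair with its last, so the left prefix is compared base-by-base with the
reverse complement of the right suffix (match +1, mismatch −1, N always
mismatches); extension stops when the running score drops more than 12 below
its maximum, and the arm ends at the best-scoring prefix (ties go to the longer
arm). Anchoring is essential: an unanchored local alignment chains a SIR arm
with the DRs shared between the two termini into one long, ~60%-identity
pseudo-arm. The SIR/LIR boundary is an arm length of 60 nt (configurable);
the literature gives exemplars near 28 nt and 250 nt but no threshold.
The scan is substitution-only — it will shorten arms containing indels. That
matches the generator (which introduces substitutions only) and is the main
known limitation on real, indel-bearing copies.

**DR slots** are detected self-referentially — shared ~18-nt blocks between an
element's own two termini (right terminus reverse-complemented first so all six
slots read in one orientation) — because published DR consensus sequences are
figure-only. Pipeline: exact common 8-mers seed candidate 18-nt blocks
(≤4 mismatches); the candidate motif with the most non-overlapping occurrences
on both termini wins (the three DR slots of one terminus are highly similar to
one another, which is exactly the discriminating signal); the motif is then
refined by column-majority consensus over its occurrences and re-scanned, which
recovers slots that sit just past the mismatch cap relative to any single
diverged instance. Finally, clean families (near-identical instances) do not
accrete chance near-matches: the accepted mismatch count is bounded by the
family's own median + 3. Eight-mer seeds rather than longer ones are needed
because both termini of a diverged copy have mutated independently — at 5%
per-copy divergence the two DR instances differ at ~10% of positions, and the
probability of a long shared exact word drops quickly. For SIR elements the
arm itself is a shared terminal block and is excluded from DR candidacy
(unless it engulfs the outer slot, as in zero-filler MITE palindromes, where
the exclusion is dropped); LIR arms span the whole window and contain the DRs,
so no exclusion applies.

## Element calling

Candidate loci come either from external 12-column tabular hits (screened at
the study's printed thresholds: E < 10⁻¹²⁰ and >75% identity over the full
339-aa transposase for protein searches, E < 10⁻²⁰ for the relaxed MITE/
nucleotide mode) or from the built-in word-seeded search (exact 11-mers,
clustered, verified by local alignment; its hits carry NaN E-values and are
screened on identity — desk-scale stand-in for an external search engine, with
hits ≥50 aligned nt to suppress chance seeds). Hits within 200 nt merge into
one candidate regardless of strand — one locus legitimately produces hits in
both orientations when references share inverted termini — padded by 400 nt
for the terminal search.

Boundary trimming aligns the padded candidate locally against each reference
element in both orientations and keeps the best; two repairs recover the bases
local alignment clips: X-drop (8) ungapped extension of both alignment ends
along the reference, and extrapolation to the reference extremity whenever the
alignment ends within 12 nt of it. Residual ambiguity of a few nt remains at
internal truncation cuts whose final bases are mutated — the exact cut
coordinate is then not identifiable from sequence, which is why the recovery
benchmark asks for ≥95% of copies within ±5 nt rather than all of them.

Transposase-ORF intactness uses global protein alignment (BLOSUM62, open −11 /
extend −1); "similarity" is the percentage of aligned columns with a positive
substitution score. The MITE rule's "no transposase homology in any frame"
uses a raw local-alignment score threshold (≥60) over six-frame peptides ≥30
aa, because percent-positives of a local alignment is high even for random
peptides.

Redundancy removal compares 100-nt flanks (both sides ≥95% identity ⇒ same
insertion seen from overlapping contigs); partial elements are flagged, never
removed. Names follow the Repbase binary convention (`Bari1_Dmel`,
`Bari_Dsec_MITE2`; MITE family numbers only when a species has more than one
family).

## Evolution statistics

* **p-distance / K2P**: pairwise deletion of gaps and ambiguities. Gamma rate
  variation (shape *a*, default 1) uses
  d = (a/2)[(1−2P−Q)^(−1/a) −1] + (a/4)[(1−2Q)^(−1/a) −1];
  a → ∞ recovers classic K2P. Saturated pairs are returned flagged, not NaN-ed
  silently.
* **Nei–Gojobori**: synonymous-site fractions per codon from the universal
  code (changes to stop codons remain in the denominator and count as
  nonsynonymous); multi-substitution codons average over all minimal pathways
  with equal weights, excluding pathways through stop codons unless all are
  blocked; dS = −¾ ln(1 − 4/3 pS) (no gamma correction, matching the classic
  method), flagged undefined at pS ≥ ¾. Trailing stop codons are dropped,
  internal ones are an error.
* **Horizontal-transfer test**: one-tailed Fisher exact test on
  [[round(Sd), round(S−Sd)] for TE; same for host gene], alternative "TE
  proportion lower", α = 0.005. The construction of the 2×2 table from rounded
  synonymous counts is an interpretation — published analyses print only the
  resulting p-values.
* **Dip test**: Hartigan & Hartigan's dip statistic, computed by the iterative
  greatest-convex-minorant / least-concave-majorant search over shrinking
  modal intervals. The implementation is validated in the test suite against
  an exact linear-programming oracle (minimise sup|F_n − G| over
  piecewise-linear unimodal G with an atom permitted at the mode). p-values
  are Monte-Carlo against uniform(0,1) nulls of the same n (seeded); published
  interpolation-table p-values are therefore not reproduced exactly. A null
  table can be shared across tests at the same n.
* **Group comparison**: Kruskal–Wallis, followed by pairwise two-sided
  Mann–Whitney U with Holm correction — a rank-based follow-up, since a
  parametric post-hoc test on rank data would be incoherent.

## Insertion-site and co-occurrence analysis

Flanks (default 2500 nt) are extracted in element orientation; logos need ≥4
sequences and report information content Rᵢ = 2 − Hᵢ bits with no small-sample
correction. Controls are seeded, non-overlapping, N-free random windows
(default 1000 × 2500 nt, the study-scale condition; desk-scale analyses in the
tests use 200 controls). For each superfamily and cumulative window
w ∈ {500, …, 2500}: λ = (control count in w / n_controls) × n_flanks,
p_enrich = P(X ≥ obs | λ), p_deplete = P(X ≤ obs | λ); both tails include the
point mass. Calls at α = 0.05. When λ = 0 with observed > 0 the call is
enriched with p reported at the 1/n_controls resolution bound, flagged.
"Relative probability" plots use −log10 of the smaller tail, signed positive
for enrichment.

## Synthetic data

The generator realises the study conditions: elements inserted at TA
dinucleotides inside AT-rich loci (AT 0.70 vs background 0.55 — the
qualitative target-preference pattern without inventing quantitative claims),
TSD written on both sides, 5% per-copy divergence as i.i.d. substitutions with
a 2:1 transition:transversion bias. SIR templates place the right-terminus DR
slots at offsets different from the left (the blocks are shared in sequence,
not placement); LIR templates make the right terminus the exact reverse
complement of the left. Autonomous copies have mutation-created stops/broken
starts repaired so the category means what it says; inactive copies get one
forced premature stop; truncations remove 15–55% from one end; partials
overlap contig extremities (one per end). MITEs derive from a template by
internal deletion between Lo–Lm and Rm–Ro, optionally with random filler.
Tandem clusters implant head-to-tail copies with canonical or CA-deleted
junctions and optional satellite blocks. Bursts: one wave mutates all copies
at r₁; a second wave re-copies half from one first-wave copy at r₂, producing
multimodal pairwise diversity.

What the generator does **not** emulate: indels and terminal rearrangements,
nested-insertion-riddled old copies (nesting exists as an option but is not in
the default mix), GC-content heterogeneity beyond the two-level AT model,
segmental duplications. Passing recovery benchmarks therefore demonstrates the
pipeline logic is correct under substitution-type divergence, not that recall
on heavily rearranged heterochromatic copies matches curated annotation.

## Benchmark problem sizes

The default recovery benchmark uses a 1-Mb single-contig genome with 50
implanted copies (12 autonomous / 12 inactive / 12 truncated / 12 MITE /
2 partial) at 5% divergence. Co-occurrence calibration uses 25 null replicates
× 4 superfamilies × 5 windows (500 cells) with 50 flanks and 200 controls and
per-family repeat density 1.2×10⁻⁴/bp (λ between 3 and 15 across windows, where
the discrete Poisson test has usable resolution); power uses a 3× density
multiplier for Tc1-mariner in flanks. Dip calibration: 200 uniform replicates
at n = 50 against a shared 2000-sample null; burst power: 20 replicates of 30
copies (435 pairwise distances) against a 500-sample null. These sizes were
chosen as the smallest at which the calibration quantities are statistically
meaningful.
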