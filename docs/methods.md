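# Methods

## Scope and model of the wet protocol

The package models the computational half of a multiplex gene-synthesis
and expression-correction workflow: sequence design (codon optimization,
synthon layout, oligo tiling), an idealized one-pot ligation assembly,
and the read-coverage quantification of pooled selection experiments.
Wet-lab physics — PCR amplification bias, emulsion compartmentalization,
cloning efficiency, growth-rate effects — is deliberately out of scope;
the suppression-PCR tail (`CATCAGGTTTCATCCTGCCGGCATGAGCGGCTAACGG`) and
its distal primer are carried only as sequence constants for ordering.

## Codon design

Reverse translation samples each codon independently with probability
proportional to an *E. coli* K-12 genome-wide usage table (packaged TSV,
per-1000 frequencies; user-overridable). Designs containing EcoRI/BamHI
sites on either strand are repaired by resampling only the codons
overlapping each hit, then fully rescanned; the procedure raises an
error rather than ever emitting a motif-containing sequence. Stop codons
are stripped by default because the ORFs are destined for N/C-terminal
fusion cloning; `strip_stop=False` retains them. No rare-codon floor is
applied by default (plain proportional weighting); an optional
`min_weight` filter exists for hosts where rare codons must be excluded.

## Synthon layout

Segment order is fixed as UF–SF–RE1–ORF–RE2–FILLER–SR–UR. The filler
sits after RE2, outside the RE1..RE2 cloning window, so the excised
insert is exactly the ORF and fuses in frame to the downstream reporter.
The 711 bp standard is defined as RE1+ORF+RE2+FILLER (primer regions
excluded); with 20 nt universal and specific primers the total is 791 bp,
under the 950 bp cap for any ORF ≤ 699 bp. The filler is random sequence
at GC 0.50 ± 0.05 (enforced for lengths ≥ 40 bp), free of forbidden
motifs and homopolymer runs > 6 nt (a synthesizability guard, not a
biological constraint; configurable), and screened against 16-mers of
the four primer regions in either orientation so primer landing sites
stay unique.

Specific primers are random 20-mers accepted when their nearest-neighbor
Tm is within ±3 °C of 57 °C (a realistic Tm for 20-mers at the model's
concentration defaults), they contain no forbidden motif or homopolymer
run > 4 nt, and they share no substring longer than 12 nt (either
orientation) with any previously accepted primer — enforced exactly via
a shared 13-mer index.

Because segment junctions can create restriction sites absent from every
individual part, the builder rescans the assembled synthon: a stray site
touching the filler triggers filler regeneration; one elsewhere makes
the library builder resample that gene's ORF and replace its specific
primers before retrying.

## Melting temperatures

Overlaps and primers are scored with the unified nearest-neighbor model:
Tm = 1000·ΔH°/(ΔS° + ΔS_salt + R·ln(C_T/x)) − 273.15, with the unified
stacking/initiation parameters stored in `data/nn_unified_dna.tsv`,
ΔS_salt = 0.368·(N−1)·ln[Na⁺], and defaults C_T = 0.25 µM, [Na⁺] = 50 mM,
x = 4 (x = 1 plus the entropic symmetry term for self-complementary
duplexes). The Wallace rule (2·AT + 4·GC) is available as a cross-check
model. A prefix-sum cache makes slice Tm queries O(1) so the tiler can
score thousands of candidate overlaps.

## Oligo tiling

Nicks strictly alternate strands (first nick on the bottom strand), so
the merged nick list partitions the synthon into segments, each segment
being the annealed overlap between exactly one top and one bottom oligo,
and each oligo spanning one or two segments. Constraints:

* segment length ≥ max(min_overlap, 16) and ≤ len_max/2; oligo lengths
  within [25, 175] nt;
* every segment's Tm ≥ tm_target − tm_tolerance (65 − 2.5 °C by
  default), including the two terminal segments, so every junction is
  stable at the ligation temperature;
* terminal uniqueness (below).

The search is greedy left-to-right, trying candidate nick positions in
order of decreasing overlap Tm (maximizing the Tm margin), with full
backtracking under a node budget (default 2·10⁵ expansions); failures
report the stuck coordinate window. Placement is deterministic for a
fixed sequence and constraint set.

### Terminal uniqueness

The pooled-assembly correctness constraint is that no two oligo termini
share an exact terminal match longer than k = 15 nt in any orientation.
All four anchored comparisons between two termini (5'–5' prefix, 3'–3'
suffix, and the two reverse-complement cross modes) reduce to the
longest common prefix of the termini's *inward words* — the oligo
sequence for a 5' terminus, its reverse complement for a 3' terminus.
A nick at coordinate y therefore contributes exactly two (k+1)-mers,
`revcomp(seq[y−16:y])` and `seq[y:y+16]`, and uniqueness is enforced
during the search by a library-wide word index.

Two classes of designed matches are excluded from the rule: (i) the two
strands' blunt ends of the same synthon, which are exact complements by
construction; and (ii) outer-end vs outer-end comparisons across genes —
every synthon begins with the shared universal forward primer region and
ends with the shared universal reverse one, so their outermost 16-mers
are identical by design, and no ligation junction exists at a blunt
outer end for a bridging oligo to exploit. Outer-end vs junction
comparisons are still enforced (a junction word equal to the UF prefix
could recruit a terminal oligo into the wrong junction). The audit
function `check_terminal_uniqueness` is a brute-force all-pairs scan and
reports every violating pair with its match length.

## Assembly simulation

Annealing/ligation at high temperature is idealized as: same-strand
oligos A→B join iff some opposite-strand oligo is perfectly
complementary across the junction for ≥ anneal_k (default 10) bases on
each side — i.e. the 2k-mer `A[-k:] + B[:k]` occurs in the bridging
oligo's complement. Join detection indexes oligo terminal k-mers so the
whole-library case stays fast; products are maximal simple paths of the
resulting graph (deduplicated by top-sense sequence across the two
strands), capped at a configurable count. A product is *full length*
when it spans one gene's synthon end to end, *chimeric* when its
constituents mix genes; termini with competing joins are flagged as
ambiguous. Mismatch-tolerant annealing, concentrations and kinetics are
not modeled, so clone-level statistics of real preps (gel excision,
cloning bias) are outside what this simulator can reproduce.

The error model applies independent per-position substitutions and
deletions (defaults 0.705/kb and 1.645/kb: 2.35 errors/kb total with the
deletion-dominated spectrum typical of microarray synthesis) and
optional per-gap insertions (default 0). The closed-form error-free
fraction exp(−rate·L/1000) is the Poisson limit of this process; the
Monte-Carlo estimator uses the same per-position binomial events and
agrees within sampling error at the default rates.

## Coverage quantification

Per-base coverage counts aligned (CIGAR match/mismatch) bases only;
deletions, skips and clips do not contribute, secondary/supplementary
records are excluded, and no duplicate marking is performed. The
per-gene score is the median over **all** reference positions — zeros
included, so genes represented mainly by partial fragments score low;
a `nonzero_only` flag exposes the alternative. Pool normalization
divides each median by the pool sum (fractions sum to 1 within 1e-9 and
are invariant to rescaling all counts); the detection cutoff is
fraction ≥ 0.05 % (inclusive). "Detected" means median > 0. Pool
summaries compute the median fraction over cutoff-passing genes only and
flag 1.5×IQR outliers among them. Enrichment between conditions is the
fraction ratio; zero denominators are reported as dropout records.
Fold killing is colonies without ampicillin divided by colonies under
selection; a zero selected count is reported as a censored "> control"
value rather than infinity.

## Synthetic data

The generator emulates the study conditions: ~100 genes (95 in the
quantifier recovery checks) of standardized ~791 bp synthons, selection
at ampicillin levels spanning a 5–100 µg/mL window, and 10⁵ single-end
reads of 150 nt per pool. Survival is a logistic function of a latent
solubility score, w = 1/(1+exp(−k·(s−θ(a)))), with per-level thresholds
θ non-decreasing in ampicillin and steepness k = 10 by default — the
simplest monotone model consistent with a selection window separating
positives from negatives; parameters are configuration, not constants,
and no claim is made that real enrichment magnitudes are reproduced.
Reads pick a gene by abundance, a uniform fragment start, and a uniform
strand; emitted SAM records carry truth coordinates and full-match
CIGARs. What the generator does **not** emulate — sequencing errors by
default, GC/library-prep bias, growth-rate differences between
surviving clones — bounds what passing tests show about real data:
they validate the estimators' arithmetic and the design constraints,
not robustness to alignment artifacts or biological confounders.

## Numerical and scale choices

Tests and the acceptance script run the pipeline at 10–100 genes and
10⁵ reads/replicates, sizes at which every stochastic check has
comfortable margin (multinomial/binomial standard errors ≲ 10⁻³ on
fractions) while the whole suite stays fast. Determinism: every source
of randomness is a seeded numpy Generator; per-gene streams derive from
a single SeedSequence so library designs are reproducible bit for bit.
Degenerate inputs (empty pools, all-zero coverage, zero-length fillers,
too-short synthons) raise typed errors rather than returning silently
wrong values.

## Known limitations

* The 711 bp core definition (restriction sites and filler inside,
  primer regions outside) is one consistent reading of a standard that
  could be drawn at other boundaries; it is a package constant.
* The ligation simulator's perfect-complementarity join rule cannot
  produce mismatch-mediated chimeras; its chimera sensitivity is to
  exact shared junction contexts only.
* The quantifier consumes alignments (SAM) or coverage tables; read
  trimming and alignment are upstream tools' responsibility.
* Secondary-structure screening of oligos (hairpins) and chip-specific
  synthesis constraints are not implemented.
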