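# Methods

This note documents the models and procedures implemented in `pheromat`,
the parameters that matter, what the synthetic data do and do not
emulate, and the numerical and design choices made where the underlying
biology or convention left the design open.

## Sequence handling

Internal coordinates are 0-based half-open on the forward strand
everywhere; GFF3 1-based inclusive coordinates are converted only at the
I/O boundary, which keeps off-by-one drift out of the core logic. Only
the standard genetic code is supported; codons containing ambiguity
characters translate to `X`; a trailing stop is stripped and internal
stops are retained as `*` and flagged. The GFF3 reader accepts both
`ID=`/`Parent=` chains (ab initio annotators) and `locus_tag=` (NCBI
dialect) as gene identifiers. It is a small dialect-tolerant line parser
rather than a database-backed loader so that structural problems — a CDS
without a resolvable gene, coordinates with end < start, features on
unknown contigs — surface as precise, line-numbered errors.

## Motif primitives

**CAAX/CPAX box.** The terminal test inspects exactly the last four
residues: C, then aliphatic (CAAX) or polar (CPAX), then aliphatic, then
anything, with CAAX taking precedence. The residue classes are
configurable because no published enumeration exists; the defaults —
aliphatic {A, V, L, I, M}, polar {S, T, C, N, Q, Y, H, K, R, D, E} —
cover every box observed among Leotiomycete a-factors (CTVM, CVVM, CIVM,
CTIL, CSIM, CSVM) while leaving G, P, W and F in neither class. Proline
is deliberately not polar here: no observed box requires it, and
including it would admit implausible C-P-X boxes.

**Processing sites.** KEX1/2 sites are the dipeptides KR, RR, KK
(overlaps reported). STE13 sites are X[AP] dipeptides; maximal chains
stepping by two from the run start (XAXA, XPXP, XAXP…) are reported as
single runs, with singletons included. Runs at different parities may
overlap and are both reported.

**Hydropathy.** Transmembrane and signal-like segments use sliding-window
mean Kyte–Doolittle hydropathy. Defaults follow standard hydropathy
practice: window 19, threshold 1.6, minimum merged run 15, merge gap 3
for TM helices; window 9, threshold 1.6, first 30 residues for signal
peptides. These replace external TM/signal predictors; on designed
hydrophobic-helix constructs they count helices exactly, but they are
not expected to reproduce any particular external tool's counts on real
receptors — receptor QC tests therefore use synthetic constructs only.

**Other evidence.** S/T richness is the S+T fraction of the first 20
residues, with ≥ 0.30 counting as "S/T-rich"; the GY motif is the last
GY whose start lies within 15 residues upstream of the box cysteine.
Both windows are configurable; neither has a published value.

## Homology search

The translated search stands in for BLASTn/tBLASTn: full Smith–Waterman
with BLOSUM62 and affine gaps (open 11, extend 1; a gap of length *k*
costs 11 + *k*), run against all six reading frames of each contig, with
frame translations split at stop codons so hits never cross a stop. No
seeding heuristics are used — correctness over speed, which is adequate
for desk-scale contigs (tens of kilobases). Significance uses the
Karlin–Altschul form E = *K·m·n·e^(−λS)* with the precomputed gapped
BLOSUM62 constants (λ = 0.267, K = 0.041) and the acceptance cutoff
E ≤ 0.05. Exact reproduction of BLAST bit scores is a non-goal; the
threshold's semantics are what is preserved. Note the statistical
consequence: at E ≤ 0.05 roughly one in twenty searches of a random
genome is *expected* to return a borderline hit. Downstream consumers
handle this two ways: the conservation-ranked a-factor screen is robust
because a decoy would need chance hits in several genomes at once, and
MAT-locus status assignment additionally requires ≥ 40% alignment
identity, standing in for the curator's rejection of low-identity
borderline alignments (the synthetic locus genes diverge 20% from their
references, i.e. align at ~80% identity, so the floor is far from the
signal).

## α-factor repeat grammar

A canonical pro-pheromone is signal peptide + *n* × (STE13 run, mature
repeat, KEX site). Annotation formalises the curation rule "repeats are
annotated between recognisable STE13 and KEX1/2 sites, starting at the
first residue after the XA/XP site":

1. Locate KEX sites and STE13 runs; note the signal region (advisory
   only — parsing proceeds without one).
2. Scan left to right between KEX sites. Within a region, anchor at
   successive STE13 runs and pick the longest candidate whose length
   falls inside the soft bounds [9, 14]; candidate ends are the next
   STE13 run start, the next KEX site, or the protein end. A repeat may
   start directly after a KEX site when no STE13 run intervenes.
3. If no anchor yields an in-bounds candidate, keep the natural span
   from the first site to the KEX and, once other units establish a
   consistent length (mode of in-bounds lengths, ties towards the
   shorter), trim the end to that length — this is the "extra residues
   before the KEX site" case.
4. Finally, since mature repeats are copies of one peptide, any unit
   disagreeing with the protein's majority repeat sequence while
   overlapping an exact occurrence of it is re-anchored onto that
   occurrence. Genuinely unique repeats are untouched.

Out-of-bounds repeats are flagged but retained (real pheromones stray
slightly outside 9–14). Spans shorter than 6 residues are treated as
linkers, not repeats. Classes: `typical` (≥ 2 repeats, each directly
followed by a KEX site), `atypical_single_repeat` (exactly one repeat,
no KEX anywhere), `ste13_dominant` (repeats present but KEX sites
missing after some of them), else `unparseable`. Intergenic scans
translate all ORFs ≥ 40 aa in a microsynteny window and by default
report only `typical` structures, because random open reading frames
routinely parse as degenerate site-rich patterns; the accepted class set
is configurable. A GQ-anchored fallback for proteins whose sites are not
proximal to the repeats is exposed as an option and off by default.

## a-factor screen

Filter: keep annotated proteins of ≤ 100 aa (inclusive) ending in a
CAAX/CPAX box. Rank: count, for each candidate, the relative genomes
with a passing translated-search hit, then sort by conservation
(descending), evidence score (S/T-rich indicator + GY indicator, equal
weights), length (ascending) and id — fully deterministic. An optional
ORF-rescue mode scans six-frame ORFs of 20–100 aa for genomes whose
annotation misses short genes.

## MAT locus and thallism

Each reference protein (the five classical MAT genes, *MAT1-1-13*, and
the APN2/SLA2 anchors) is searched genome-wide; hits within 1.5 kb are
clustered, and each cluster becomes a locus gene with a coverage-based
status: ≥ 90% of the reference covered by a single alignment → intact;
≥ 90% only as stop-separated pieces → pseudogenised; 50–90% → truncated
on the side with more missing sequence; < 50% → fragment. The anchor
pair defines the locus window; when no MAT gene is found the window is
scanned for unannotated ORFs, which are reported as novel-gene
candidates but never used in strategy calls.

Switching repeats are found as maximal *exact* pairs of substrings
≥ 100 bp, direct or inverted (approximate identity is not implemented:
the repeats that mediate switching are identical, and the generator
plants identical copies). Maximal extension can absorb a base or two of
chance flank identity, so a planted 250-bp repeat may be reported as
250–252 bp.

Classification order, with idiomorph *presence* meaning an intact or
truncated gene (fragments embedded in the opposite idiomorph do not
count — otherwise every heterothallic *Botrytis*-type idiomorph would
misclassify as homothallic):

1. intact *MAT1-1-3* as the only MAT1-1 gene, no trace of *MAT1-1-1*,
   no MAT1-2 gene → `lachnellula_HMG_only`;
2. one idiomorph present → `heterothallic_*` (unless switching-like
   repeats plus *MAT1-1-1* pieces make heterothallic-vs-switched
   undecidable → `undetermined`);
3. both idiomorphs on one locus: inverted repeat pair within ≥ 2
   *MAT1-1-1* pieces → `switching_inversion`; a direct pair →
   `switching_deletion`; both principal genes intact →
   `primary_homothallic`; otherwise `undetermined`;
4. both idiomorphs on disjoint contigs → `possible_mixed_culture`.

Fragmented multi-contig loci (the *S. borealis* pattern) deliberately
return `undetermined` — no attempt is made to guess. Every call carries
its evidence trail.

## Ancestral-state reconstruction

Thallism is a binary character (homothallic = 0, heterothallic = 1,
unknown = `?`) under a two-state continuous-time Markov chain with rates
q01, q10. The transition matrix has the closed form
P(t) = Π + (I − Π)·e^(−(q01+q10)t) with stationary frequencies
π0 = q10/(q01+q10), π1 = q01/(q01+q10) — no numerical matrix
exponential is needed. Likelihood is Felsenstein pruning; `?` tips
contribute (1, 1); marginal node posteriors come from the standard
up–down pass and are validated against exhaustive enumeration on small
trees. Rate uncertainty is integrated by Metropolis–Hastings on
(q01, q10) with log-normal proposals (Jacobian included), independent
exponential(mean 1) priors, 200 burn-in iterations and 1000 retained
samples by default, averaging node posteriors over every 5th sample.
The root prior defaults to the stationary distribution of the sampled
rates and can be set to uniform or fixed; both equal-rates and
all-rates-different parameterisations are supported, since the original
analysis tool's rate model is not documented. All chains are
seed-reproducible.

## Expression

RPKM = count × 10⁹ / (library size × gene length). Read mapping is out
of scope; counts arrive as a table. A gene is "expressed" at
RPKM ≥ 1.0 (configurable; motivated by treating RPKM < 1 as background),
and mating-type exclusivity requires expression in at least one pure
sample of one type and none of the other, with mixed-culture samples
excluded from the test but reported.

## Synthetic data: what it emulates, and what it does not

Background sequence is order-0 random DNA at 45% GC. Pro-pheromone
genes are built grammar-valid by construction: signal (M + 12–16
non-A/P hydrophobics), then per repeat a 2–5 aa spacer free of A/P and
K/R, a 4-residue STE13 run, the repeat, and a KEX site; introns
(canonical GT…AG, 50–80 bp) are inserted with probability 0.5 per gene.
Sampled mature repeats avoid internal KEX dipeptides (they would be
cleaved in vivo), A/P at the second position and K/R at the last (either
would shift the flanking sites of the very grammar that defines the
repeat). Real signal peptides do contain alanine and real repeats can be
grammar-ambiguous; passing round-trip tests therefore demonstrates
correctness of the grammar formalisation on unambiguous instances, not
annotation accuracy on every real pro-pheromone.

MAT architectures place diverged (20% of sites mutated) copies of
synthetic reference proteins — random sequences of realistic lengths,
generated once from a fixed seed — along contigs with 150–300 bp
spacers, reproducing ten named locus layouts: the two heterothallic
idiomorphs, a fused homothallic locus, inversion- and deletion-switching
structures with planted identical 250-bp repeat pairs, the two HMG-only
idiomorphs, a split two-contig locus, a truncated-principal locus and a
fragmented four-contig locus. Locus genes are generated intron-free so
homology coverage directly reflects gene integrity; intron handling is
exercised separately through the gene-model extraction path, including
the 330-bp two-exon construct (57-bp intron, 90-aa product) that mirrors
the short novel MAT1-1 gene. Receptor constructs are alternating
hydrophobic 21-aa helices and hydrophilic 15-aa linkers — idealised
membrane topology, not homologs of real receptors.

Cohorts draw a birth–death species tree (birth 1.0, death 0.2);
thallism states are either simulated under the Mk model, fixed, or laid
out as a target split with homothallic tips clustered clade-wise; each
genome receives the architecture its state implies, a cohort-wide
α-repeat (default WCGRPGQPC), one cohort-wide a-factor gene and 3–6
private decoy CAAX ORFs. Transposons, repeat landscapes and assembly
artifacts beyond the split-contig layouts are not modelled.

## Problem sizes and determinism

The test suite and the acceptance script size their simulations for a
single CPU: 300–500 grammar round-trips, 100–200 screen cohorts of five
small genomes each, the ten-architecture suite, 15–25 enumeration-oracle
trees (≤ 6 tips), 20 rate-recovery replicates on 64-tip trees, and one
124-tip cohort (96/15/13 state split) for the root-state reconstruction.
All randomness flows through seeded numpy generators (dendropy's tree
simulator receives a seeded `random.Random`), so every reported number
is reproducible from the seed.

## Known limitations

* E ≤ 0.05 admits borderline chance hits by construction; negative
  controls in the tests probe the same machinery at E ≤ 10⁻³.
* Approximate (< 100% identity) repeat pairs, profile-HMM domain
  checks, GQ-anchored repeat annotation by default, and nucleotide-space
  search are intentionally out of scope.
* The thallism caller trusts assembly layout; it cannot distinguish a
  genuinely unlinked second locus from an assembly artifact, and says so
  by returning `possible_mixed_culture` / `undetermined` rather than
  guessing.
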