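# Methods

This note documents the models and procedures implemented in `mytilomito`,
the parameters that matter, the synthetic-data generators the tests rely
on, and the numerical choices made where the design was genuinely open.

## Coordinate model and formats

All coordinates are 0-based half-open internally. GenBank and GFF3 (both
1-based inclusive) are converted at the boundary, once. Features crossing
the origin of a circular genome are stored with `wraps_origin=True` and
`start > end`; their length is computed modulo the genome length. Ambiguity
codes other than N are rejected; N is accepted but excluded from every
composition count and percentage denominator.

## Composition statistics

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C), signed, reported
to three decimals (percentages to two); a zero denominator yields an
explicit undefined marker, never a number. The coding summary reports each
protein-coding gene's first and last codon on its own strand. An incomplete
stop ("T" or "TA") is asserted only when the gene length mod 3 is 1 or 2
*and* the next annotated feature begins within 2 nt downstream: completion
of a truncated stop by polyadenylation presupposes an abutting gene, so a
dangling non-multiple length without a neighbour is reported as an anomaly
rather than silently "fixed".

## atp8 rediscovery

atp8 is short (tens of residues), extremely divergent in primary sequence,
and therefore routinely missing from automated mitogenome annotations. What
is conserved is its physical profile, and that is what the scanner scores:

1. **Intergenic regions**: maximal unannotated stretches of at least
   `min_intergenic` (default 60 bp), including the gap that wraps the
   origin on circular genomes.
2. **ORFs**: all six frames under the invertebrate mitochondrial code
   (NCBI table 5) with its full initiator set {TTG, ATT, ATC, ATA, ATG,
   GTG}; every in-frame initiator of a stop-bounded segment opens a
   candidate, candidates shorter than `min_aa` (default 25 aa) are
   dropped, and only complete-stop ORFs are reported. Start codons are
   translated literally by the table rather than forced to Met, so a
   GTG-started ORF reads Val-… and the N-terminal motif test accepts
   `[MV]PQL`.
3. **Diagnostics** per candidate protein:
   * Kyte–Doolittle hydropathy with window 19 and threshold 1.6 — the
     scale authors' own criterion for membrane-spanning segments; runs of
     above-threshold windows (bridging up to 2 sub-threshold positions)
     shorter than 18 residues are discarded. Exactly one transmembrane
     segment is the expected ATP8 topology. Spans are window-extended, so
     they are validated by overlap, not exact equality, against external
     TM predictions.
   * C-terminal R/H/K count after the TM segment (or in the last 10
     residues when no TM is called), capped at 3 for scoring.
   * PQ within the first six residues; MPQL/VPQL at residues 1–4 is
     recorded separately.
   * Protein length inside 30–150 aa, slightly wider than the band
     observed across Mytilidae (37–139 aa) to avoid clipping unseen taxa.
4. **Score** = 2·[exactly one TM] + min(RHK, 3)/3 + [PQ] + [length in
   band], ranked score-desc, then protein length desc, then genome start
   asc — deterministic always. When one stop-bounded segment offers
   several initiators, the most upstream one whose protein lies in the
   band represents the segment (the comparative start-codon correction
   used in manual annotation is not algorithmic; this is the deterministic
   stand-in).

The default reporting floor is 4.2. This is deliberately above
2 + 1 + 1 = 4.0, the best score available to a candidate lacking the PQ
signature: in AT-rich mitogenomes random ORFs are hydrophobic-biased
(F/I/L/M codons are AT-rich) and regularly present a TM-like block, an
in-band length and a charged tail, so those three features alone cannot
separate signal from noise. On 100 seeded synthetic genomes the planted
gene scores ≥ 4.33 and is recovered rank-1 at exact coordinates 100/100,
while the best impostor across 100 negative controls scores 4.0. The cost
is that a genuine PQ-less atp8 ranks first but is not auto-reported; the
ranked table is always emitted and the floor is a config field.

## Gene order

Arrangements are linearized by rotating the circular feature order to an
anchor (cox1: present everywhere and conventional), with labels normalized
to canonical names and duplicate tRNAs suffixed numerically. Comparison
reports identity, shared prefix, and the signed breakpoint distance: the
number of circular adjacencies of one order absent from the other, an
adjacency and its strand-flipped mirror counting as the same. Strand signs
participate in identity — the light-strand tRNA-Gly makes this observable.

## NG86 pairwise dN/dS

Site counts enumerate the nine single-nucleotide neighbours of each codon,
averaged over the two sequences; substitutions that would create a stop are
counted as nonsynonymous so that S + N = 3·(codon count) holds exactly.
Differences in multi-hit codons are averaged over minimal mutational
pathways, excluding pathways through stops whenever a stop-free one exists.
Proportions are Jukes–Cantor corrected, d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4
yields an undefined distance and ω = dN/dS is undefined when dS = 0.

## GY94 codon models

The generator over the 62 sense codons of the invertebrate mitochondrial
code has q_ij = 0 for multi-nucleotide changes and π_j, κπ_j, ωπ_j, ωκπ_j
for synonymous transversions/transitions and nonsynonymous
transversions/transitions. Codon frequencies default to F3x4 computed from
the alignment (F1x4 and uniform are options); a half-count pseudocount
keeps all sense frequencies positive. Equilibrium frequencies make the
chain reversible, so transition matrices come from an eigendecomposition in
the π-symmetrized basis — exact and stable, no Padé approximation.

**Scaling.** For branch models each ω-class generator is scaled to one
expected substitution per codon site; any per-class factor is absorbed into
that branch's free length, so only ratios matter. In the branch-site
mixture all site classes share a branch, so they must share a time scale:
all class matrices are scaled by the rate of the ω0 generator. The choice
of common factor is a reparameterization of branch lengths, but sharing one
is essential — with per-class scaling, positively selected sites would
lose their substitution-rate surplus and the test its power.

**Likelihood.** Felsenstein pruning over sense-codon states with pattern
compression. Partials are kept unscaled in double precision — ample for
the small trees this package targets (tens of taxa); a non-positive site
likelihood raises with the offending site index rather than returning
−inf. Gap- or N-containing columns are removed before fitting and the
count is recorded on the fit.

**Models.**
* one-ratio: single ω, free κ and branch lengths;
* branch model: one ω per branch class; classes are supplied as a
  taxon→class map (TSV or dict) lifted onto branches — an internal branch
  inherits a class when all its descendant leaves share it, otherwise it is
  background;
* branch-site model A: classes 0 (ω0 everywhere), 1 (neutral), 2a/2b
  (foreground ω2 over background ω0/1) with proportions parameterized as
  p0 = qr, p1 = q(1−r), p2a = (1−q)r, p2b = (1−q)(1−r), which enforces
  p2a/p2b = p0/p1 by construction; the null fixes ω2 = 1 (df = 1).

**Optimization.** Bounded L-BFGS-B over log-transformed branch lengths, κ
and ω (logit for q, r, ω0; 1 + exp for ω2), with analytic branch-length
gradients from an outside-partial (uppass) recursion, analytic mixture-
proportion gradients, and finite differences only for the two or three rate
parameters. Multi-start (default 3, seeded; the first start uses the input
tree's branch lengths) with a single seed controlling all randomness.
Convergence tolerance 1e-6 in lnL. Nested fits warm-start from the
one-ratio optimum. LRT statistics are clamped at zero for sub-0.1-lnL
optimizer noise; a larger deficit raises instead of producing a bogus
p-value.

**Site identification** uses naive empirical Bayes: posterior(site, class)
∝ class proportion × site likelihood at the ML point estimates, flagging
sites with P(2a ∪ 2b) > 0.95. Outputs are labelled NEB explicitly — these
are not Bayes-empirical-Bayes values and ignore parameter uncertainty, so
they are anticonservative near the boundary.

## Synthetic data

The genome generator emulates what the scan relies on: a circular molecule
carrying 13 protein-coding genes (atp8 deliberately unannotated), two
rRNAs and a few tRNAs (tRNA-Gly on the light strand), base composition
targeting AT ≈ 63% with negative AT-skew and positive GC-skew (the
mussel-typical regime), ordinary spacers of 30 bp (below the scan
minimum), and one 300 bp spacer optionally containing the planted
atp8-like ORF: a 39-aa protein with MPQL at the N-terminus, a 23-residue
L/I/V/F block starting at residue 6, three R/H/K residues in the last six,
encoded with random synonymous codons, guarded by an in-frame stop
immediately 5′ of the start codon so the planted start is provably the
most upstream in-band initiator of its segment. What it does *not*
emulate: real tRNA structure, duplications and rearrangements, homology
between genomes, and sequencing error — so passing recovery tests
demonstrates the detector's behaviour under the stated feature model, not
its performance on diverged real annotations.

The alignment simulator evolves root codons drawn from the frequency
vector along the tree using exact matrix-exponential transition matrices
from the same spectral machinery the likelihood uses — simulator/fitter
discrepancies therefore indicate bugs, not convention mismatches. Branch
mode assigns ω per branch class; branch-site mode plants a seeded fraction
of positively selected sites (ω2 on the foreground, background ω
elsewhere, shared time scale as above) and records the per-site truth.

## Problem sizes used in tests

Simulation-based checks run at sizes chosen to make the statistical claims
sharp while keeping the suite quick: ω recovery at 1,500 codons × 8 taxa
over 20 seeds (mean |ω̂ − 0.2| < 0.05); branch-LRT type-I calibration at
200 codons × 6 taxa over 200 null replicates (rejections at α = 0.05
inside the exact binomial 95% acceptance region); branch-site power at 300
codons × 6 taxa, ω2 = 5 on 10% of sites, over 20 replicates; calibration
and recovery fits use a single warm start (the multimodality that
motivates multi-starts shows up in the branch-site alternative, which is
always warm-started from the one-ratio fit).

## Known limitations

* Unscaled pruning partials limit tree size (hundreds of taxa would
  underflow); the intended scale is family-level analyses.
* NEB instead of BEB for site identification (see above).
* The published absolute lnL and ω̂ tables are not reproduced: they depend
  on the unstated CODEML frequency model and cleaning of the original
  44-taxon alignments, which are not redistributed. The shipped reference
  tables support LRT arithmetic and comparison, nothing more.
* The gene-order module compares arrangements; it does not attempt
  rearrangement phylogenetics.
* Branch classes are taxon-map based; tanglegram-style paraphyletic
  foregrounds must be supplied as explicit edge maps.
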