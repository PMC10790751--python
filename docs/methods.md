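# Methods

This note documents the models and procedures implemented in `anigap`,
the choices behind their defaults, and what the synthetic data do and do
not establish.

## The scientific question

Within a named bacterial species (genomes sharing >95% average
nucleotide identity, ANI), pairwise ANI values are not distributed
evenly: large genome collections show a pronounced scarcity of pairs in
the ~99.2–99.8% ANI range relative to either flank. This gap suggests
natural intra-species units and motivates threshold-based definitions:
*genomospecies* at 95% ANI, *genomovar* at 99.5% (the gap midpoint,
proposed as a whole-genome counterpart of MLST sequence types), and
*strain* at >99.99%. The package implements the full analysis needed to
detect such a gap and delineate the units, and a synthetic species
generator that plants known structure so that every stage can be scored
against ground truth.

## Synthetic species generator (`anigap.simulate`)

**Sequence model.** A species is a set of genomes evolved on a
two-level tree: genomovar ancestors branch off the species root and
genomes branch off their genomovar ancestor. Each branch carries an
integer number of substitution events; an event hits a uniformly random
site of a shared master coordinate frame and shifts the base by a
uniform non-zero amount mod 4. Because shifts compose additively, a
site hit k times differs from its ancestor with probability
3/4·(1−(−1/3)^k), and the expected identity of two genomes separated by
m events on their connecting path is

    planted(m) = 100 · (1 − 3/4·(1 − (1 − 4/(3L))^m)),

with L the master frame length. The *planted identity matrix* uses
this closed form, so realized Hamming identity concentrates on the
planted value with binomial noise (verified to 3σ in the tests). No
indels are simulated inside homologous segments; structural variation
enters only through gene gain/loss (below), which keeps the ANI
estimator analytically checkable against exact Hamming identity.

**Band placement.** Identity bands are enforced in event-count space by
inverting planted(m): per-genome depths are drawn so that within-unit
paths land in the intra-unit band (default 99.85–99.99%), and unit
depths so that every between-unit path, *including* the genome-level
branches, lands in the inter-unit band (default 96–99.2%). A gapped
scenario therefore has exactly zero planted pairs inside (99.2, 99.8)
by construction. Two genomovars are anchored at the minimal depth so
the inter-unit band is attained up to its top edge (otherwise the
planted gap would be wider than configured and its midpoint would drift
below 99.5); the remaining unit depths are stratified evenly across the
band with random jitter, which tiles the band without wide holes that
would read as spurious valleys. The default species has 8 genomovars ×
4 genomes (496 pairs) on a 100 kb master frame — large enough for
stable kernel density estimates, small enough that a full all-vs-all
ANI run takes seconds.

Scenarios: `gapped` as above; `gapless` is a star-like control in which
genome depths span the union of both bands, giving a broad gap-free
(roughly triangular) identity distribution over 96–100%; `clonal`
keeps every planted pair above 99.5% (bands 99.6–99.85 / 99.85–99.99).

**Gene content.** Genomes carry core genes (default 60 × 900 bp,
always present, category "annotated") and an accessory pool (default 40
genes) organised into *islands* of 4 adjacent genes that are gained and
lost as one block — mobile elements move as multi-gene units, and block
turnover also keeps indel junctions rare enough that fragment ANI stays
accurate. A configurable fraction of islands (default 0.5) is labelled
"hypothetical/mobile". Two turnover regimes create the category
contrast seen in real close-pair comparisons: mobile islands flip with
a fixed per-branch probability (default min(0.45, gain_loss_prob ×
terminal_mobile_boost) = 0.24) regardless of branch length — prophages
come and go on ecological timescales — while annotated islands flip
clock-like, with probability 0.5·(1−exp(−2·gain_loss_prob·d/0.01)) for
a branch of sequence divergence d. Recently diverged pairs therefore
differ almost only in mobile content, while divergent pairs accumulate
annotated differences too; this is the planted signal for the
enrichment test. `terminal_mobile_boost` is the single knob for the
contrast; the calibration of the z-test itself is checked on binomial
null draws, not on the generator.

**MLST loci.** Seven core genes, evenly spaced along the genome and
named after the classic *E. coli* scheme (adk, fumC, gyrB, icd, mdh,
purA, recA), are tagged as typing loci. By default locus sequences
evolve like any other sequence; with `mlst_locus_mutations="unit_only"`
genome-level (terminal) branches avoid the loci, making sequence types
coincide exactly with genomovars — the configuration used to
demonstrate the concordance machinery on a known answer.

**Truth tables.** The generator emits the lineage tree (Newick), the
planted identity matrix, genomovar labels, strain labels (connected
components of planted identity > 99.99%), the gene presence/absence
matrix and per-gene categories, plus (in memory) each genome's
master-frame sequence and presence mask — the exact-alignment oracle
used by the estimator tests.

## Fragment ANI (`anigap.ani`)

The estimator re-implements the fragment-mapping scheme of fast ANI
tools. The query is cut into consecutive non-overlapping fragments
(default 3,000 bp; per contig, terminal remainders discarded). Each
fragment is placed by exact 16-mer seeding: seed k-mers at a 59 bp
stride vote for candidate diagonals, the top three candidates are
scored by ungapped full-fragment identity, and the best placement is
kept if it reaches the minimum identity (default 80%).

Two screens make fragment identity mean what it should:

* **SNP evenness.** A placement whose mismatches pile up in a short run
  (any of ~20 sub-windows below 50% identity) is chimeric — the
  fragment straddles content private to the query, typically a gene
  presence difference — and is rejected rather than scored. Identity is
  only meaningful for evenly diverged homologs, and examining whether
  low identity is evenly distributed rather than concentrated in a
  couple of short regions is standard practice near these thresholds.
* **Reciprocal consistency.** A retained mapping is *bidirectional*
  when the reference fragment containing the mapped midpoint maps back
  to within half a fragment of the originating query fragment **and**
  the forward and reverse identities agree within 5 points. The second
  condition removes the remaining junction-straddling placements whose
  reverse mapping is clean; such content then counts as unshared
  instead of biasing ANI downward.

ANI is the mean identity over bidirectional mappings (undefined — not
zero — if there are none); the shared genome fraction is bidirectional
mappings over total query fragments. The pair table computes each
unordered pair once with the longer genome as reference (ties broken
toward the lexicographically smaller id as reference). On indel-free
pairs the estimator agrees with exact Hamming identity to within 0.05
points across 0.1–4% divergence; with default accessory turnover the
residual junction bias is below ~0.1 point on a 100 kb genome.

Gene-level sharing uses reciprocal best hits among annotated-strand
gene sequences with ungapped identity ≥95% (genes of unequal length
cannot match); the shared gene fraction divides ortholog count by the
mean gene count of the two genomes.

## Gap statistics (`anigap.gapstats`)

**Uniform null.** Expected counts under an even ANI distribution are
N·(r−l)/(b−a); the deficit ratio R = expected/observed quantifies the
gap (R is undefined, not infinite, when nothing is observed). Counting
is half-open [l, r) with a closed top edge at the range maximum.

**Dip statistic.** Hartigan's dip D is the sup-norm distance (halved)
between the empirical CDF and the closest unimodal CDF. It is computed
exactly by bisecting the band half-width t and testing whether a
nondecreasing convex-then-concave CDF fits inside the ECDF's
t-corridor. The feasibility test derives, for each candidate modal
position (between two sample points, outside the range, or an atom at a
sample point — ties make the atom case matter), the minimal achievable
end value of the convex prefix and the maximal start value of the
concave suffix from greatest-convex-minorant support lines, and checks
the monotone junction. Bisection runs to 1e-12; a brute-force oracle
(exhaustive minimisation over piecewise-linear unimodal CDFs via linear
programming, independent of this algorithm) agrees to better than 1e-9
on hundreds of random samples. D always lies in [1/(2n), 1/4]. The
O(K²)-per-step kernel is JIT-compiled with numba when available, with
an equivalent numpy fallback.

**Dip test.** p-values are Monte-Carlo: the fraction of U(0,1) samples
of the same size with dip ≥ D, with a +1/(n_boot+1) continuity
correction (default n_boot = 2000). The null table can be precomputed
and shared across same-size samples; type-I error at α = 0.05 is within
±0.02 of nominal over 500 uniform replicates.

**Valleys.** A Gaussian KDE is evaluated on a [95, 100] grid at 0.01%
steps with Silverman's rule-of-thumb bandwidth 0.9·min(sd,
IQR/1.34)·n^(−1/5). A local minimum flanked by local maxima is a
valley when its density is at most β (default 0.5) times the lower
flanking peak; the valley extent is the contiguous region around the
minimum below that bound, and the midpoint is the density argmin.

**Classification.** A species is `clonal` when every pair is above
99.5% ANI (checked first, regardless of other settings); `gap_99.2_99.8`
when a valley midpoint falls in [99.2, 99.8] and the dip test rejects at
α = 0.05; `shifted_gap` when significant valleys exist only outside
that window; otherwise `no_gap` (including fewer than 10 pairs, which
is too few to test). `gap_mode` histograms all valley midpoints in
0.1%-bins centred on multiples of 0.1 (left-closed; ties toward higher
ANI) and returns the modal bin centre — 99.5 across gapped simulations.

**Other operations.** Subsampling to k genomes restricts the pair
table to the sampled genomes (pairwise ANI depends only on the two
genomes, so restriction equals recomputation). The divergence-time
closed form t = d/(k·μ·g) uses μ = 4×10⁻¹⁰ substitutions/site/
generation and 100 generations/year by default; with d = 0.005 and two
lineages it gives 62,500 years. It treats every mutation as fixed and
ignores any fixation fraction, so it is a lower bound, not an estimate
to be matched against divergence dates that assume slower fixation.

## Units, typing, enrichment

`units` clusters by single linkage (connected components of the
at/above-threshold graph) because the unit definitions are stated as
pairwise threshold exceedance; nesting of strain ⊂ genomovar ⊂
genomospecies is then automatic from nested edge sets. Thresholds
95/99.5 are inclusive (≥); the strain threshold is strict (> 99.99),
matching the proposed definitions. Undefined ANI contributes no edge.

`sequence_typing` assigns alleles by exact, case-insensitive,
strand-normalised sequence identity, numbering alleles and STs in order
of first appearance. Concordance is defined over unordered genome
pairs with ST as predictor and the ANI unit as reference: TP = same ST
and ANI ≥ threshold; FP = same ST below; FN = different ST at/above.
Pairs with an untyped genome or undefined ANI are excluded and counted.
(Defining the metrics over pairs, rather than genomes, is a choice; it
makes precision/recall exactly the quantities of the worked examples.)

`enrich` pools non-shared-gene category counts over close pairs (ANI >
99.8) and divergent pairs (96 ≤ ANI ≤ 99.8) — disjoint strata, each
gene occurrence counted once per pair (a unique-gene mode exists) — and
applies a pooled two-proportion z-test, two-sided. The permutation
test in the suite is the independent check of the normal approximation.

## Problem sizes and runtime

The study conditions used by the test suite and the acceptance script
are: 20 gapped and 10 gapless species at the default configuration
(32 genomes, 496 pairs, 100 kb), a 2000-sample dip null table at
n = 200 with 500 calibration replicates, 200 random dip-oracle cases at
n ≤ 12, and a 7-point divergence sweep for estimator accuracy. These
sizes keep a full run in minutes on one core while leaving the
acceptance margins (≥90% recovery, ±0.02 calibration) statistically
meaningful.

## What passing tests do and do not show

The generator plants clean two-band structure with uniform substitution
placement and block-wise gene turnover. It does not emulate
recombination or HGT tracts, rate heterogeneity along the genome,
rearrangements, within-segment indels, sequencing/assembly error, or
real functional annotation — so passing tests demonstrate that the
statistics and estimators recover known structure under the stated
model, not that any particular real species is gapped. On real data the
gap can be eroded by isolation bias, assembly chimerism and
recombination; the classification thresholds (β, α, bandwidth) are
exposed precisely because those settings may need adjustment there.

Known limitations: the dip statistic is exact but O(K²) per bisection
step, so samples much above ~5,000 distinct values get slow; fragment
ANI is ungapped by design and treats genomes with pervasive small
indels poorly; the uniform-null deficit compares against an even
distribution, which is a deliberately weak null; and ST numbering
follows input order, so cross-run ST labels match only up to
renumbering.
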