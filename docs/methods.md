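# Methods

This note documents the models, rules and numerical choices behind the
package, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Coordinates, gene order and gaps

All genomic coordinates are 1-based inclusive (GFF convention); BED
input (0-based half-open) is converted at the I/O boundary and written
back unchanged, so BED → internal → BED is the identity. Gene order on
a contig is a 0-based *ordinal* assigned by ascending start, with ties
broken by ascending end and then lexicographic gene id — annotation
formats do not dictate an order for nested/overlapping ORFs, so a
deterministic tie rule is imposed. Every gap rule in the package counts
genes *strictly between* two genes (`ord_b − ord_a − 1`); "ten genes or
less" therefore means ≤ 10 intervening genes. This is one of two
defensible readings (the other being ordinal difference); it is applied
consistently and is configurable everywhere it appears.

## MAG quality gate

Thresholds: completeness ≥ 90%, contamination ≤ 5%, tRNA count ≥ 18,
rRNA classes, N50 ≥ 100 kb — all inclusive, so a MAG exactly at a
boundary passes. The rRNA criterion defaults to requiring all three of
5S/16S/23S (the high-quality-draft reading); a flag switches to
"any one class" for users who read the criterion disjunctively. N50 is
the length at which descending-sorted contigs first reach half the
assembly size; when absent from metadata it is recomputed from contig
lengths. Relaxing any threshold can only turn failures into passes
(monotonicity, property-tested).

## Defense-system assembly

A family rule holds the mandatory and accessory gene-name sets, MG
(minimum mandatory genes), SG (minimum total genes) and d_max (maximum
intervening-gene gap). Within one (contig, family), hits are chained
greedily left-to-right while the gap stays ≤ d_max; every chain is a
system, complete iff it reaches both MG and SG. Gene status is a
partition: members of complete chains are *complete*, members of
incomplete chains with ≥ 2 genes are *incomplete*, and single-gene
incomplete chains are *solitary* genes (not systems). Families without
a rule behave as single-gene systems (every isolated hit is a complete
singleton; adjacent same-family hits chain). This engine is a
deliberate simplification of full annotation-tool decision rules
(exchangeable components, per-system model variants are out of scope);
when the input already carries system assignments they are taken as
authoritative and assembly is skipped, so downstream statistics can run
on real annotation output unmodified.

## Defensome metrics

Densities are counts per kb (`count / (size_bp / 1000)`). Family
prevalence counts MAGs with ≥ 1 *complete* system of the family by
default (flag for any-defense-gene prevalence). Size correlations use
two-sided Spearman rank tests with average ranks on ties; constant
inputs are flagged rather than silently returning a value.
Phylogenetic depth is the mean root-to-tip distance of a rooted tree,
identical to the diagonal mean of the phylogenetic variance–covariance
matrix (both computed and cross-checked to 1e-9 in tests); a basal
polytomy is treated as the unrooted convention and rejected unless
midpoint rooting is requested. The regression of defensome abundance
on genome size and phylogenetic depth is bidirectional stepwise OLS by
AIC from the intercept-only model, on z-scored predictors, reporting
coefficients and partial R². Note that AIC retains a spurious
predictor with probability ≈ P(χ²₁ > 2) ≈ 0.16 per candidate under the
null — the intercept-only model is kept in only ~64% of pure-noise
replicates, which the tests assert as the statistically correct
behaviour. The response defaults to defense-gene counts (systems are a
flag), since gene counts are the better-powered abundance measure.
Habitat comparisons use two-sided Mann–Whitney U with boxplot
descriptives (median, quartiles, 1.5×IQR whiskers).

## Defense islands

An island is a maximal chain of defense units with ≤ 10 intervening
genes between consecutive units, ≥ 5 units and ≥ 3 distinct families.
Units are defense genes (default) or assembled systems (a system sits
at its first member's ordinal; in system mode the unit and family
minima count systems and system families). Hits with family "unknown"
count as units but not toward the family minimum. The island span runs
from the first to the last defense member *including* intervening
non-defensive genes — required for non-defensive content fractions to
be expressible. The greedy chain construction is provably maximal; an
O(n²) window enumerator serves as an independent oracle in the tests.
The skew ratio over island defense genes is (c − i)/(c + i) with
solitary genes counted in the incomplete class by default (the binary
complete/incomplete split leaves them open; a flag excludes them).
Per-family island enrichment is a 2×2 Fisher test (in-island vs
outside × family vs rest) with Haldane–Anscombe +0.5 on zero cells and
Benjamini–Hochberg adjustment across families (a conservative default;
raw p values are always reported alongside).

## Colocalization

A gene belongs to an MGE class when its span overlaps a
(conflict-filtered) interval by ≥ 1 bp, optionally extended by a flank
(default 0 bp — "close vicinity" is not quantified upstream, so the
strict reading is the default). Intervals overlapping an interval of a
different class are all removed (ambiguous multi-family hits), and
same-class overlaps are union-merged. Context densities divide by
summed interval lengths, with the chromosome context excluding all MGE
bp. The family × context expectation is the standard independence
margin E[f, m] = N_f · N_·m / N_·· over *all* defense genes, with the
chromosome as an explicit column — this preserves row margins, so the
expected-weighted mean O/E is identically 1. (A literal reading of the
per-family fraction wording for expected values would force O/E ≡ 1;
the independence margin is the meaningful interpretation and is used
throughout.) The global test is a chi-square over cells with expected
≥ 1 with (R−1)(C−1) degrees of freedom.

Family-pair colocalization enumerates unordered defense-gene pairs
with ≤ 5 intervening genes on one contig, drops pairs whose genes share
a system id (same-system members are trivially colocalized and would
inflate the counts), and classifies a pair as *inside* only when both
genes fall within one island's span — pairs straddling a boundary count
as outside (the discard alternative is a flag). Pairs in distinct
islands are not "inside". Pairs involving an unknown-family gene stay
in the totals but get no per-pair row.

## Variant enrichment

The analyzed region of a gene is its body plus the 200 bp immediately
upstream of the start codon, strand-aware (upstream of a minus-strand
gene lies at higher coordinates). The high-frequency gate keeps
variants with allele frequency ≥ 0.25 *and* ≥ 10 supporting reads,
boundaries inclusive. SNPs in the gene body are typed
synonymous/nonsynonymous by substituting the single allele into the
reference codon under the standard genetic code (no haplotype phasing;
start-codon special cases ignored for substitution typing); upstream
SNPs and SNPs without a CDS stay unclassified; indels are always typed
indel. Per-family enrichment compares the number of genes carrying
≥ 1 retained variant with N_f × (overall flagged fraction); families
with < 10 analyzed genes are excluded, and families with O/E ≥ 1.5 are
highlighted. The fraction of variants falling upstream is an output
statistic, never a filter.

## Pairwise dN/dS (NG86)

Synonymous sites per codon: for each position, the synonymous fraction
among the three single-nucleotide changes, excluding changes that
create stop codons from the denominator; s + n = 3 identically, and the
table is verified against an exhaustive enumeration oracle for all 61
sense codons. Codon differences are averaged with equal weight over all
minimal mutational pathways, excluding pathways through stops; if every
pathway is blocked the codon pair is skipped entirely (sites and
differences), keeping the two consistent. Gap-containing, ambiguous and
stop codons are skipped pairwise. Proportions use the Jukes–Cantor
correction d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 leaves d undefined and the
pair discarded with a reason, as are saturated pairs with dS > 1.
ω is undefined (flagged, not zero) when dS = 0. One consequence of
equal-weight pathway averaging worth knowing: two synonymous
substitutions on opposite lineages can still yield fractional Nd
(e.g. Arg codons AGA vs CGC average one all-synonymous and one
nonsynonymous-intermediate pathway), so a lineage history with zero
accepted nonsynonymous changes estimates ω near, not exactly, zero.
Within ortholog clusters all pairs are estimated, singletons are
dropped, and per-family distributions report median/quartiles plus the
discarded fraction. Maximum-likelihood codon models are out of scope;
cluster assignments and codon alignments are consumed, not computed.

## Synthetic data

The generator emulates the statistical structure the analyses assume,
at desk scale: 30 MAGs × 2 contigs × 250 genes by default, gene lengths
normal(900, 200) bp clipped at 300, exponential intergenic gaps
(mean 120 bp), a 20-family catalog with loosely log-uniform weights, a
3% background defense-gene rate, 2 planted islands per MAG (5–8 units,
internal gaps 0–3, ≥ 3 families), MGE intervals of 10–40 kb drawn per
class with defense-carriage multipliers (plasmid 3×, prophage 2.5×,
ICE/IME 4×, integron 2×, qualitatively matching the elevated carriage
the analyses are designed to detect), and ~10% of MAGs degraded on one
QC criterion. These sizes were chosen once so that island and pair
statistics have power on a desk machine; they are documented, not
fitted. In *strict spacing* mode background defense genes keep
> gap_max intervening genes from island members and from each other, so
planted islands are maximal and recoverable with exact boundaries and
no false islands can form — the basis of the recovery tests. A single
integer seed drives a hierarchical stream (one spawned substream per
MAG), so identical seeds give byte-identical files and growing the
cohort never reshuffles earlier MAGs.

Variants: each defense gene draws Poisson(1.5) variants; whether a
variant passes the high-frequency gate is decided first (base rate
0.25 times the family's enrichment multiplier), then frequency and read
support are drawn strictly on that side of the gate — truth flags are
exact by construction, which is what makes the filter-exactness test
sharp. Codon pairs: a uniform sense-codon ancestor evolves along two
lineages, each receiving Poisson(3L·t/2) uniformly proposed
single-nucleotide changes; stops are rejected, synonymous proposals
accepted, nonsynonymous accepted with probability ω. Uniform proposals
match the NG86 mutation model, so the estimator is near-unbiased here;
real sequences with transition bias or codon-usage bias would not enjoy
that luxury.

Two targeted designs support the statistical checks. The *null
contigs* fix island geometry (dense 6-unit structures with internal
gaps 6,6,2,6,6, and isolated close pairs) before family labels are
drawn i.i.d., so labels are independent of in/out-island status by
construction; islands are then called with the family minimum at 1 so
that geometry alone defines them, keeping the null exact. Structures
sit 12 filler genes apart and each contributes exactly one qualifying
close pair, so Fisher's independent-sampling assumption holds. The
pair-null uses a two-family label pool so the focal pair probability
(1/2) is large enough for Fisher's discrete test to run near its
nominal size; with rare focal pairs the exact test is markedly
conservative. The *association contig* plants a family-pair odds ratio
of (p_in/(1−p_in))/(p_out/(1−p_out)) = 4 across ~1000 disjoint
qualifying pairs, half inside islands.

## What passing tests do and do not show

The generator reproduces gene order, clustering, carriage and
frequency structure, not sequences: no GC/codon-usage realism, no
misannotation, no binning artifacts, no chimeric contigs, and MGE
intervals are conflict-free by construction (the conflict filter is
exercised by explicit fixtures instead). Recovery and calibration
results therefore validate the *statistical machinery* — that the
island caller matches its definition exactly, that the enrichment
tests hold their size and recover planted effects — not the biological
accuracy of upstream annotation tools on real data.

## Numerical conventions

Odds ratios apply Haldane–Anscombe +0.5 only when a cell is zero.
Chi-square statistics sum over cells with expected ≥ 1. All warnings
(duplicate hits, removed conflicting intervals, excluded small groups,
collinear predictors) use Python warnings so callers can promote them
to errors. Degenerate inputs error loudly: empty contig lists for N50,
non-positive genome sizes, chromosome length ≤ 0 after MGE
subtraction, unrooted trees without the midpoint flag.
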