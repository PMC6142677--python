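# Methods

This note documents the models, parameter choices and numerical conventions
behind `cosortpop`, and what the synthetic data do and do not emulate.

## Coordinate and format conventions

Internal coordinates are 0-based half-open everywhere; conversions to and
from 1-based conventions (SAM POS, GFF3, the SNP table on disk) happen only
at file boundaries. Reverse-strand alignments are assumed to be stored in
reference orientation (SAM convention). Ambiguous reference bases (N etc.)
are tolerated on input; pileup columns at such positions are excluded from
SNP calling and from every density denominator, so they can never create or
dilute a signal. Secondary (0x100), supplementary (0x800) and unmapped
(0x4) SAM records are dropped on read.

## Filter chain and allele counting

Thresholds follow a strict "discard if below" rule: reads with identity
< 0.95 (identity = 1 − NM / reference-consumed CIGAR length), mean Phred
quality < 30 (arithmetic mean of scores), or MAPQ < 20 are discarded; bases
with quality < 30 are not counted. The boundaries are therefore
inclusive-keep: a 150-nt read with NM = 7 (identity 0.9533) survives, NM = 8
does not; MAPQ 20 survives, 19 does not.

Per-site depth is equalised by sampling exactly 50 base observations
without replacement (multivariate hypergeometric, seeded); sites with fewer
than 50 reads leave all downstream denominators. Sampling without
replacement matches subsetting real reads and is unbiased for the
minor-allele fraction. Pooling k SAGs takes s = floor(50/k) observations
from each SAG and only at sites where every SAG has depth >= s, keeping the
per-SAG contribution exactly equal at the cost of a slightly smaller pooled
depth (k·s <= 50); sites where any SAG falls short are excluded rather than
rescaled.

SNPs are called at minor allele frequency >= 10% (inclusive: 5 of 50
qualifies, 4 of 50 does not). Multi-allelic sites emit one record with the
top minor allele. Density is SNPs per kb of downsample-surviving sites, not
per kb of assembly, which keeps densities comparable across unevenly
amplified SAGs.

## Consensus, cross-SAG SNPs and pN/pS

Within each SAG the consensus allele is the modal base; the site is masked
where strictly more than 10% of counted reads disagree or the mode is tied
(a 50/50 site is maximally ambiguous). Across SAGs, a site is eligible iff
at least 5 of the SAG consensuses are unmasked and covered; a SNP is
recorded iff the eligible alleles plus the reference contain two or more
distinct bases.

"Synonymous site" here means fourfold degenerate and "non-synonymous site"
means onefold degenerate, classified from the full reference codon under
translation table 11, strand-aware, with a premature stop counted as an
amino-acid change. Two- and threefold degenerate sites are excluded from
pN/pS entirely, so the statistic is not a Nei–Gojobori dN/dS and will
differ numerically from codon-model estimates; it is exactly the per-site
polymorphism ratio defined above. pN/pS with zero sSNPs is reported as
undefined (NaN with a flag), never as 0. Codon degeneracy is defined per
site from the reference codon regardless of neighbouring sites' coverage.

Per-gene densities use eligible (mapped) sites within the gene as the
denominator, and genes with fewer than 100 mapped sites are excluded — a
gene must offer a minimum of observable sequence before its density means
anything. Functional-category comparisons use a one-way ANOVA over per-gene
nSNP densities restricted to categories with at least 10 genes, Tukey HSD
post hoc (studentized range at the ANOVA's residual df, via statsmodels),
and a compact letter display built from maximal cliques of the
non-significant-pair graph at α = 0.05. A category ANOVA over identical
values reports F = 0, p = 1 (the 0/0 case is resolved to "no evidence of
difference"). The protein-region chi-square is a goodness-of-fit of
nSNP-bearing residues across internal/external/transmembrane regions with
expectations proportional to region sizes; N is the count of nSNP-bearing
residues.

## Rank-sum test

The clonality comparison uses a one-sided Wilcoxon rank-sum test with the
alternative "co-sorted density greater than baseline" (the biologically
motivated direction; two-sided is available). With n1 + n2 <= 12 and no
ties the p-value is exact by full enumeration of all C(n1+n2, n1) rank
assignments; otherwise the normal approximation with tie and continuity
corrections (scipy) is used.

## Clade delineation

Criteria are inclusive: >= 98% 16S identity over pairwise-comparable
(both-ungapped) columns; >= 95% ANI over >= 20 kb aligned; tree criterion =
mutual nearest leaves by patristic distance, or a minimal containing clade
with no non-members. ANI with under 20 kb aligned is insufficient evidence
(MISSING), never a numeric failure — treating it as 0% would turn missing
data into a conflict.

Seeding groups pairs with >= 2 PASS and 0 FAIL and merges them
transitively; any failed criterion between two members of a merged
component is raised as a conflict demanding manual resolution, while pairs
left with < 2 PASS through missing data are tolerated inside a component
(requiring 2 PASS on every within-component pair would reduce transitive
merging to cliques and contradict the extension rule's tolerance of missing
data). Extension then admits an unassigned genome iff its ANI criterion
passes against at least one member and no criterion fails against any
member; a genome qualifying for two clades is an error. All processing is
in lexicographic genome order, making the partition invariant to input
order.

ANI is fragment-based: the query is cut into 1020-bp fragments, each
aligned to the subject by a seeded banded aligner (exact 15-mer seeds,
best-diagonal vote, edit-distance alignment of the fragment against a
padded subject window in infix mode). Fragments with identity >= 30% and
coverage >= 70% are retained; fragments with no seed have zero coverage and
drop out, which is what leaves unrelated sequence pairs with negligible
aligned length. The result is symmetrised as the mean of both directions.
Self-ANI is exactly 100; a 5%-substituted copy measures 95.0 ± 0.5. The
seed length (15) trades sensitivity against chance seeding: random 50 kb
pairs share ~0.05 exact 15-mers per fragment, so almost all of their
fragments stay unaligned, while a 5%-diverged fragment contains hundreds of
intact 15-mers.

## Synthetic data: what it emulates

`make_genome` packs non-overlapping genes (100–400 codons, both strands,
ATG start, table-11 stop, no internal stops) to a target coding fraction
(default 0.85, the compact architecture of host-dependent ultra-small
archaea), assigns functional categories from a weight table, and gives
surface-protein genes per-residue topology labels with a 19-residue
transmembrane run near the N-terminus — the same signature
`classify_surface_protein` detects (single Kyte–Doolittle window >= 1.6
starting within the first 60 residues).

`simulate_population` places synonymous variants only at fourfold sites and
non-synonymous variants only at onefold sites (any substitution at such
sites preserves/changes the amino acid by construction, so the true pN/pS
is controlled exactly), with per-category non-synonymous rates if
requested. Variant frequencies default to uniform on {1/n, …, (n−1)/n};
each variant is carried by exactly round(freq·n) haplotypes.

`simulate_sag_reads` models MDA amplification bias as a log-normal
per-window depth multiplier (window 1 kb, sigma 1.0 by default — a free
modelling choice, since amplification bias is not quantified in a portable
way) and draws reads from the scenario's cell haplotypes in proportion to
mixture weights. Substitution errors (default 0.002/base) receive base
qualities uniform on [2, 34] so that a minority (~14%) survive the
quality-30 filter, while correct bases draw from [35, 40]; reads are
emitted at their true positions with NM set to the exact edit distance to
the reference. A read mapper is deliberately not implemented: mapping noise
enters only through the identity/MAPQ filters acting on the perturbed
records. Indels, chimeric MDA artifacts and alignment errors are not
modelled, which is why the simulated clonal baseline is ~0 SNPs/kb — real
co-sorted data carry an additional assembly/amplification error floor that
these simulations intentionally do not reproduce. Passing tests therefore
demonstrate correctness of the statistics under the modelled error
channels, not the absolute baseline of real SAGs.

`shred_contigs` emulates error-free synthetic read generation from an
assembly (paired 150-nt reads, inserts uniform in 180–400 nt, ~20x), and
`simulate_cosort` mixes a symbiont scenario with clonal host reads at a
binomial host read share over a two-target alignment table.

## Problem sizes

The end-to-end suite uses 500 kb genomes at 60x for the clonality contrast
(20 replicates), 7 SAGs at 15x for pN/pS recovery (52 replicates over true
ratios 0.1/0.16/0.5/1.0), and 50 kb sequences for ANI — sizes chosen so the
full test suite completes in a few minutes while keeping per-replicate
counting noise far below the tested tolerances. The analysis drivers use
200–300 kb genomes for the same reason. `scripts/acceptance.py` re-runs the
same computations at 500 kb with 3 replicates per quantity.

## Known limitations

- Substitutions only; no indel calling, no strand-bias filtering, no BAQ.
- pN/pS over strict one/fourfold site classes is conservative and excludes
  most first/third positions that are two- or threefold degenerate.
- The pooled-SAG experiment defaults to pooling in input order (subset
  identity in the original design is unrecoverable); `all_subsets=True`
  exposes the spread.
- The ANI aligner is tuned for intra-genus comparisons (>= ~80% identity);
  for distant pairs it under-reports aligned length by design, which the
  20 kb evidence threshold treats as missing data rather than failure.
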