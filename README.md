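# cosortpop

Population genomics of co-sorted symbiont single amplified genomes (SAGs).

Ultra-small archaea such as Nanoarchaeota live attached to the surface of a
host cell and are sequenced by sorting single cells — sometimes a symbiont
still attached to its host ("co-sort") — followed by whole-genome
amplification (MDA). Two questions drive the analyses implemented here:

1. **Clonality.** When several symbiont cells sit on one host, are they
   clones? A SAG amplified from clonal material shows only error-baseline
   SNP density after filtering; genetically distinct co-amplified cells
   produce minor-allele fractions near their mixture weights and a large
   excess of called SNPs.
2. **Selection.** Across a population of SAGs from one species-level clade,
   which genes diversify? Polymorphism at onefold degenerate sites (every
   substitution changes the amino acid) versus fourfold degenerate sites
   (none does) gives pN/pS, and per-gene non-synonymous SNP densities can
   be compared across functional categories.

The package is organised as a library (`src/cosortpop/`) driven by numbered
analysis scripts (`analysis/01..04`). A synthetic-data module generates
every input — annotated genomes, haplotype populations with exactly
controlled pN/pS, MDA-biased single-cell read sets, co-sorted host+symbiont
mixtures — with ground truth retained, so the whole pipeline is exercisable
and testable without any downloads.

## Core definitions

For one SAG mapped to a reference bin, reads are discarded below 95%
identity (1 − NM/aligned length), mean base quality 30, or mapping quality
20; bases below quality 30 are not counted. Per-site counts are downsampled
without replacement to 50 reads, and a SNP is called where the minor allele
frequency is at least 10%:

    MAF(site) = minor_count / depth        SNP iff MAF >= 0.10
    density   = SNPs per kb of sites surviving downsampling

Pooling k SAGs draws floor(50/k) reads per SAG at sites all k cover,
simulating k distinct attached cells. Across SAGs, a per-SAG consensus is
called (masked where > 10% of reads disagree), and sites covered by at
least 5 of 7 SAGs where any consensus differs from the others or the
reference are population SNPs. With S and N the SNP counts at fourfold and
onefold degenerate sites (translation table 11) and L4, L1 the eligible
site counts:

    pN/pS = (N / L1) / (S / L4)

a within-population analog of dN/dS (< 1 indicates purifying selection;
two/threefold sites are excluded entirely).

Genome bins group into species-level clades when at least 2 of 3 criteria
pass with none failing: >= 98% 16S rRNA identity, >= 95% ANI over >= 20 kb
aligned (fragment-based, 1020-bp fragments), mutual nearest neighbours or a
members-only branch in the ribosomal-protein tree. Unassigned bins join on
ANI alone if nothing conflicts.

## Worked example

```
python analysis/03_population_diversity.py --seed 1
```

simulates a 300 kb genome, a 20-haplotype population whose surface and
attachment genes carry elevated non-synonymous rates, and 7 single-cell
read sets, then runs the full consensus → SNP → degeneracy pipeline:

```
          quantity         value
    eligible_sites 299981.000000
        snps_total   2675.000000
snp_density_per_kb      8.917231
             nsnps   1316.000000
             ssnps   1353.000000
   intergenic_snps      5.000000
         true_pnps      0.263323
              pnps      0.266791

ANOVA on per-gene nSNP density: F(9, 333) = 64.55, p = 1.1e-67
```

The estimated pN/pS (0.267) recovers the generator's truth (0.263); the
category table that follows assigns Tukey-HSD letter groups, with
"Hypothetical external" and "Motility and attachment" significantly above
the information-processing categories — the diversification signature the
pipeline is built to detect. `01_clonality_survey.py` shows clonal and
co-sorted SAGs at zero excess density with one-sided rank-sum p = 1.0,
`02_pooling_simulation.py` shows density rising from 0 (k=1) to ~30 SNPs/kb
(k=6 pooled cells), and `04_clade_delineation.py` recovers two planted
clades plus an ANI-only extension from six synthetic genome bins.

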