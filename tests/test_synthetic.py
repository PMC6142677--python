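"""Synthetic genomes, populations and read sets against independent oracles."""

import numpy as np
import pytest

import cosortpop as cp
from cosortpop.io_formats import decode_seq, encode_seq
from cosortpop.population_diversity import FOURFOLD, ONEFOLD
from tests.conftest import random_dna


def biopython_translate(seq: str) -> str:
    """Independent oracle: Biopython translation under table 11."""
    from Bio.Seq import Seq

    return str(Seq(seq).translate(table=11))


class TestMakeGenome:
    def test_zero_gene_fraction_gives_pure_intergenic(self):
        g = cp.make_genome(seed=1, length=5000, gene_fraction=0.0)
        assert g.genes == []

    def test_same_seed_reproduces_genome(self):
        a = cp.make_genome(seed=7, length=12_000)
        b = cp.make_genome(seed=7, length=12_000)
        assert a.sequence == b.sequence
        assert [(g.start, g.end, g.strand) for g in a.genes] == [
            (g.start, g.end, g.strand) for g in b.genes]

    def test_every_gene_translates_cleanly(self, small_genome):
        """Brute-force oracle: every CDS starts M, ends *, no internal stops."""
        for gene in small_genome.genes:
            protein = biopython_translate(small_genome.gene_sequence(gene))
            assert protein[0] == "M"
            assert protein[-1] == "*"
            assert "*" not in protein[:-1]

    def test_genes_do_not_overlap(self, small_genome):
        ivals = sorted((g.start, g.end) for g in small_genome.genes)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            assert s2 >= e1

    def test_infeasible_length_is_error(self):
        with pytest.raises(ValueError, match="pack"):
            cp.make_genome(seed=1, length=500, gene_fraction=0.9)

    def test_region_labels_cover_labeled_categories(self, small_genome):
        labeled = [g for g in small_genome.genes if g.category == "Hypothetical external"]
        assert labeled, "fixture should contain labeled genes"
        for g in labeled:
            assert g.regions is not None
            assert len(g.regions) == g.length // 3
            assert "T" in g.regions


class TestSimulatePopulation:
    def test_zero_targets_give_identical_haplotypes(self, small_genome):
        pop = cp.simulate_population(small_genome, 4, 0.0, 0.0, seed=3)
        assert pop.n_variants == 0
        ref = small_genome.codes
        for i in range(4):
            assert np.array_equal(pop.haplotype_codes(i), ref)

    def test_ssnp_variants_are_synonymous_nsnp_nonsynonymous(self, small_genome, small_population):
        """Codon-translation oracle on every placed variant."""
        pop = small_population
        classes = {FOURFOLD: 0, ONEFOLD: 0}
        for _, v in pop.variants.iterrows():
            gene = next(
                g for g in small_genome.genes if g.start <= v["pos"] < g.end
            )
            ref_cds = small_genome.gene_sequence(gene)
            mutated = list(small_genome.sequence)
            mutated[v["pos"]] = v["alt"]
            mut_genome = "".join(mutated)
            sub = mut_genome[gene.start : gene.end]
            if gene.strand == "-":
                sub = decode_seq(
                    np.array([3 - c if c < 4 else 4 for c in encode_seq(sub)[::-1]],
                             dtype=np.uint8))
            changed = biopython_translate(ref_cds) != biopython_translate(sub)
            if v["klass"] == FOURFOLD:
                assert not changed, f"sSNP at {v['pos']} changed the protein"
            else:
                assert changed, f"nSNP at {v['pos']} left the protein unchanged"
            classes[v["klass"]] += 1
        assert classes[FOURFOLD] > 0 and classes[ONEFOLD] > 0

    def test_realized_density_matches_target(self):
        g = cp.make_genome(seed=21, length=100_000, gene_fraction=0.85)
        pop = cp.simulate_population(g, 10, 3.0, 2.0, seed=22)
        n_s = (pop.variants["klass"] == FOURFOLD).sum()
        n_n = (pop.variants["klass"] == ONEFOLD).sum()
        assert n_s == round(3.0 * len(g) / 1000)
        assert n_n == round(2.0 * len(g) / 1000)

    def test_excess_density_is_capacity_error(self, small_genome):
        with pytest.raises(ValueError, match="fourfold sites available"):
            cp.simulate_population(small_genome, 4, 1000.0, 0.0, seed=1)

    def test_ground_truth_matches_bruteforce_pairwise_comparison(self, small_population):
        """Inter-haplotype differing sites from truth == emitted sequences."""
        pop = small_population
        for i, j in [(0, 1), (2, 7)]:
            truth = pop.pairwise_differences(i, j)
            brute = int((pop.haplotype_codes(i) != pop.haplotype_codes(j)).sum())
            assert truth == brute

    def test_frequencies_carried_by_matching_haplotype_counts(self, small_population):
        carried = small_population.carriers.sum(axis=1)
        n = small_population.n_haplotypes
        expected = np.round(small_population.variants["freq"].to_numpy() * n)
        assert np.array_equal(carried, expected)


class TestSimulateSagReads:
    def test_error_free_clonal_reads_are_exact_substrings(self, small_population):
        sc = cp.SagScenario("ef", [3], coverage_mean=3, error_rate=0.0, seed=4)
        aln, truth = cp.simulate_sag_reads(sc, small_population)
        hap = decode_seq(small_population.haplotype_codes(3))
        for i in range(min(len(aln), 200)):
            s = truth.start[i]
            assert aln.seq[i] == hap[s : s + sc.read_length]

    def test_mixture_minor_fraction_matches_binomial_expectation(self, small_genome):
        pop = cp.simulate_population(small_genome, 2, 5.0, 5.0, seed=31)
        sc = cp.SagScenario("mix", [0, 1], coverage_mean=80, error_rate=0.0,
                            mda_bias=0.0, seed=32)
        aln, truth = cp.simulate_sag_reads(sc, pop)
        counts = cp.pileup(cp.filter_alignments(aln), small_genome, min_base_q=0)
        variant_pos = pop.variants["pos"].to_numpy()
        alt = pop.variants["alt_code"].to_numpy()
        depth = counts.depth[variant_pos]
        altc = counts.counts[variant_pos, alt]
        deep = depth >= 50
        assert deep.sum() > 20
        frac = altc[deep] / depth[deep]
        sd = np.sqrt(0.25 / depth[deep])
        assert (np.abs(frac - 0.5) <= 3 * sd + 1e-9).mean() > 0.95

    def test_same_seed_reproduces_reads_exactly(self, small_population):
        sc = cp.SagScenario("det", [1], coverage_mean=5, seed=77)
        a1, _ = cp.simulate_sag_reads(sc, small_population)
        a2, _ = cp.simulate_sag_reads(sc, small_population)
        assert np.array_equal(a1.pos, a2.pos)
        assert np.array_equal(a1.dense[0], a2.dense[0])
        assert np.array_equal(a1.dense[1], a2.dense[1])
        assert np.array_equal(a1.nm, a2.nm)

    def test_nm_is_exact_edit_distance_to_reference(self, small_population):
        sc = cp.SagScenario("nm", [0], coverage_mean=3, error_rate=0.01, seed=41)
        aln, truth = cp.simulate_sag_reads(sc, small_population)
        ref = small_population.reference.codes
        codes = aln.dense[0]
        for i in range(0, len(aln), 97):
            window = ref[aln.pos[i] : aln.pos[i] + sc.read_length]
            assert aln.nm[i] == int((codes[i] != window).sum())

    def test_invalid_coverage_is_error(self, small_population):
        sc = cp.SagScenario("bad", [0], coverage_mean=5, seed=1)
        sc.coverage_mean = 0
        with pytest.raises(ValueError, match="coverage"):
            cp.simulate_sag_reads(sc, small_population)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            cp.SagScenario("w", [0, 1], mixture_weights=[0.6, 0.6])


class TestShredContigs:
    def test_read_count_matches_coverage_formula(self):
        contigs = [("c1", random_dna(10_000, 1))]
        aln = cp.shred_contigs(contigs, coverage=20, read_length=150)
        assert len(aln) in (1333, 1334)

    def test_reads_are_exact_substrings(self):
        seq = random_dna(2_000, 2)
        aln = cp.shred_contigs([("c", seq)], coverage=5)
        for i in range(len(aln)):
            s = aln.pos[i]
            assert aln.seq[i] == seq[s : s + 150]
            assert aln.nm[i] == 0

    def test_insert_sizes_within_range(self):
        aln = cp.shred_contigs([("c", random_dna(3_000, 3))], coverage=10,
                               insert_range=(180, 400))
        pos = {}
        for rid, p in zip(aln.read_id, aln.pos):
            pair = rid.rsplit("/", 1)[0]
            pos.setdefault(pair, []).append(int(p))
        for pair, (p1, p2) in pos.items():
            insert = max(p1, p2) + 150 - min(p1, p2)
            assert 180 <= insert <= 400

    def test_short_contig_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            aln = cp.shred_contigs(
                [("tiny", "ACGT" * 10), ("ok", random_dna(1_000, 4))], coverage=2)
        assert set(aln.target_id.tolist()) == {"ok"}


class TestSimulateCosort:
    def test_host_fraction_binomial(self, small_genome, small_population):
        host = cp.make_genome(seed=51, length=len(small_genome), gene_fraction=0.5)
        sc = cp.SagScenario("co", [0], coverage_mean=10, seed=52)
        aln, truth = cp.simulate_cosort(sc, small_population, host, 0.5, seed=53)
        n_host = (truth["true_target"] == host.genome_id).sum()
        total = len(truth)
        # host count within 3 binomial SD of half the total
        assert abs(n_host - total / 2) <= 3 * 0.5 * np.sqrt(total)

    def test_truth_labels_partition_table(self, small_genome, small_population):
        host = cp.make_genome(seed=54, length=20_000, gene_fraction=0.5)
        sc = cp.SagScenario("co2", [2], coverage_mean=5, seed=55)
        aln, truth = cp.simulate_cosort(sc, small_population, host, 0.3, seed=56)
        assert len(truth) == len(aln)
        assert set(truth["true_target"]) == {small_genome.genome_id, host.genome_id}
        assert (truth["true_target"].to_numpy() == aln.target_id).all()

    def test_clonal_symbiont_partition_yields_no_snps(self, small_genome, small_population):
        host = cp.make_genome(seed=57, length=20_000, gene_fraction=0.5)
        sc = cp.SagScenario("co3", [1], coverage_mean=60, error_rate=0.0, seed=58)
        aln, _ = cp.simulate_cosort(sc, small_population, host, 0.3, seed=59)
        sym = aln.for_target(small_genome.genome_id)
        rec = cp.sag_density(sym, small_genome, seed=60, unit_id="sym")
        assert rec.snp_count == 0

    def test_invalid_host_fraction_is_error(self, small_genome, small_population):
        host = cp.make_genome(seed=61, length=20_000, gene_fraction=0.5)
        sc = cp.SagScenario("co4", [0], coverage_mean=5, seed=62)
        with pytest.raises(ValueError, match="host_read_fraction"):
            cp.simulate_cosort(sc, small_population, host, 1.0, seed=63)


class TestClassifySurfaceProtein:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            # one 19-Leu window starting at residue 5: KD mean 3.8 >= 1.6
            ("DDDDD" + "L" * 19 + "D" * 100, "external"),
            ("D" * 120, "not_external"),
            # two disjoint hydrophobic stretches -> not a single motif
            ("DDDDD" + "L" * 19 + "D" * 170 + "L" * 19 + "D" * 10, "not_external"),
            # single motif but deep in the protein (start > 60)
            ("D" * 80 + "L" * 19 + "D" * 50, "not_external"),
            ("LLL", "not_external"),  # shorter than the window
        ],
    )
    def test_motif_rules(self, seq, expected):
        assert cp.classify_surface_protein(seq) == expected

    def test_non_amino_acid_is_error(self):
        with pytest.raises(ValueError, match="residue"):
            cp.classify_surface_protein("LLLLLLLLLLLLLLLLLLLB")
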