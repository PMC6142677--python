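"""Consensus calling, cross-SAG SNPs, degeneracy classes, pN/pS, statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cosortpop as cp
from cosortpop.io_formats import AnnotatedGenome, GeneRecord
from cosortpop.population_diversity import (
    FOURFOLD,
    INTERGENIC,
    ONEFOLD,
    OTHER_CODING,
    CONS_MASKED,
    CONS_NOCOV,
    degeneracy_array,
    site_degeneracy,
)
from cosortpop.read_processing import SiteCounts


def counts_of(rows, ref_codes=None):
    arr = np.asarray(rows, dtype=np.int32)
    ref = np.zeros(len(arr), dtype=np.uint8) if ref_codes is None else ref_codes
    return SiteCounts("ref", arr, ref)


class TestConsensus:
    def test_exactly_ten_percent_disagreement_not_masked(self):
        cons = cp.consensus_alleles(counts_of([[9, 1, 0, 0]]))
        assert cons.codes[0] == 0  # consensus A

    def test_above_ten_percent_masked(self):
        cons = cp.consensus_alleles(counts_of([[8, 2, 0, 0]]))
        assert cons.codes[0] == CONS_MASKED

    def test_zero_depth_is_nocov(self):
        cons = cp.consensus_alleles(counts_of([[0, 0, 0, 0]]))
        assert cons.codes[0] == CONS_NOCOV

    def test_modal_tie_is_masked(self):
        cons = cp.consensus_alleles(counts_of([[5, 5, 0, 0]]))
        assert cons.codes[0] == CONS_MASKED

    def test_raising_mask_fraction_never_reduces_called_sites(self):
        rng = np.random.default_rng(5)
        rows = rng.integers(0, 20, size=(500, 4))
        counts = counts_of(rows)
        called = [
            (cp.consensus_alleles(counts, mask_fraction=f).codes < 4).sum()
            for f in (0.05, 0.10, 0.20, 0.50)
        ]
        assert all(b >= a for a, b in zip(called, called[1:]))


class TestCrossSagSnps:
    @pytest.fixture
    def ref(self):
        return AnnotatedGenome("ref", "AAAAAAAAAA")

    def cons(self, codes):
        from cosortpop.population_diversity import ConsensusSequence

        return ConsensusSequence("s", np.asarray(codes, dtype=np.uint8))

    def test_site_with_four_of_seven_ineligible(self, ref):
        # position 0: only 4 of 7 SAGs called
        rows = [[1] + [0] * 9 for _ in range(4)] + [[CONS_NOCOV] + [0] * 9 for _ in range(3)]
        res = cp.cross_sag_snps([self.cons(r) for r in rows], ref, min_sags=5)
        assert not res.eligible[0]
        assert (res.snps["pos"] != 0).all()

    def test_site_with_five_of_seven_eligible(self, ref):
        rows = [[1] + [0] * 9 for _ in range(5)] + [[CONS_NOCOV] + [0] * 9 for _ in range(2)]
        res = cp.cross_sag_snps([self.cons(r) for r in rows], ref, min_sags=5)
        assert res.eligible[0]
        assert 0 in res.snps["pos"].tolist()

    def test_all_agree_with_reference_no_snp(self, ref):
        rows = [[0] * 10 for _ in range(7)]
        res = cp.cross_sag_snps([self.cons(r) for r in rows], ref, min_sags=5)
        assert len(res.snps) == 0
        assert res.n_eligible == 10

    def test_unanimous_variant_relative_to_reference_is_snp(self, ref):
        rows = [[2] + [0] * 9 for _ in range(7)]
        res = cp.cross_sag_snps([self.cons(r) for r in rows], ref, min_sags=5)
        assert 0 in res.snps["pos"].tolist()
        row = res.snps.iloc[0]
        assert row["major_allele"] == "G" and row["minor_allele"] == "A"

    def test_masked_sites_do_not_count_toward_coverage(self, ref):
        rows = [[CONS_MASKED] + [0] * 9 for _ in range(3)] + [[0] * 10 for _ in range(4)]
        res = cp.cross_sag_snps([self.cons(r) for r in rows], ref, min_sags=5)
        assert not res.eligible[0]

    def test_min_sags_above_count_is_error(self, ref):
        with pytest.raises(ValueError, match="min_sags"):
            cp.cross_sag_snps([self.cons([0] * 10)], ref, min_sags=5)


class TestDegeneracy:
    def test_all_192_codon_position_cases_match_bruteforce(self):
        """Independent oracle: Biopython translation of every single-base
        substitution of every codon, table 11."""
        from Bio.Seq import Seq

        for codon_tuple in itertools.product("ACGT", repeat=3):
            codon = "".join(codon_tuple)
            genome = AnnotatedGenome(
                "t", codon + "TAA", [GeneRecord("g", 0, 6, "+", "c")])
            aa = str(Seq(codon).translate(table=11))
            for j in range(3):
                changes = 0
                for b in "ACGT":
                    if b == codon[j]:
                        continue
                    alt = codon[:j] + b + codon[j + 1:]
                    if str(Seq(alt).translate(table=11)) != aa:
                        changes += 1
                expected = {0: FOURFOLD, 3: ONEFOLD}.get(changes, OTHER_CODING)
                assert site_degeneracy(genome, j) == expected, (codon, j)

    def test_leucine_box_third_position_fourfold(self):
        g = AnnotatedGenome("t", "CTATAA", [GeneRecord("g", 0, 6, "+", "c")])
        assert site_degeneracy(g, 2) == FOURFOLD

    def test_tryptophan_third_position_onefold(self):
        g = AnnotatedGenome("t", "TGGTAA", [GeneRecord("g", 0, 6, "+", "c")])
        assert site_degeneracy(g, 2) == ONEFOLD

    def test_positions_outside_genes_intergenic(self):
        g = AnnotatedGenome("t", "CTATAAGGGG", [GeneRecord("g", 0, 6, "+", "c")])
        assert site_degeneracy(g, 8) == INTERGENIC

    def test_minus_strand_classification_mirrors_plus(self):
        # gene TTA-CTA-TGA read on the minus strand occupies the reverse
        # complement on the genome: TCA TAG TAA
        from cosortpop.io_formats import revcomp

        cds = "ATGCTATAA"
        g_plus = AnnotatedGenome("p", cds, [GeneRecord("g", 0, 9, "+", "c")])
        g_minus = AnnotatedGenome("m", revcomp(cds), [GeneRecord("g", 0, 9, "-", "c")])
        plus_classes = [site_degeneracy(g_plus, i) for i in range(9)]
        minus_classes = [site_degeneracy(g_minus, i) for i in range(9)]
        assert minus_classes == plus_classes[::-1]

    def test_non_codon_multiple_gene_classes_other_coding(self):
        with pytest.warns(UserWarning, match="multiple of 3"):
            g = AnnotatedGenome("t", "CTATAAG", [GeneRecord("g", 0, 7, "+", "c")])
            assert site_degeneracy(g, 2) == OTHER_CODING

    def test_simulated_ssnp_sites_all_classify_fourfold(self, small_genome, small_population):
        """Zero class confusion between generator and classifier."""
        v = small_population.variants
        classes, _ = degeneracy_array(small_genome)
        from cosortpop.population_diversity import _CLASS_CODES

        s_pos = v.loc[v["klass"] == FOURFOLD, "pos"].to_numpy()
        n_pos = v.loc[v["klass"] == ONEFOLD, "pos"].to_numpy()
        assert (classes[s_pos] == _CLASS_CODES[FOURFOLD]).all()
        assert (classes[n_pos] == _CLASS_CODES[ONEFOLD]).all()


class TestClassifyAndPnPs:
    def test_classification_fills_gene_and_class(self, small_genome):
        snps = cp.call_snps(counts_of([[45, 5, 0, 0]] * 3 + [[50, 0, 0, 0]] * 7),
                            maf_min=0.1)
        snps["target_id"] = small_genome.genome_id
        out = cp.classify_snps(snps, small_genome)
        assert set(out["degeneracy_class"]) <= {FOURFOLD, ONEFOLD, OTHER_CODING, INTERGENIC}

    def test_ratio_arithmetic(self):
        classified = pd.DataFrame({
            "degeneracy_class": [ONEFOLD] * 10 + [FOURFOLD] * 20,
        })
        res = cp.pn_ps(classified, {ONEFOLD: 10_000, FOURFOLD: 3178,
                                    OTHER_CODING: 0, INTERGENIC: 0})
        assert res.ratio == pytest.approx(0.1589, abs=2e-4)

    def test_zero_nsnps_gives_zero_ratio(self):
        classified = pd.DataFrame({"degeneracy_class": [FOURFOLD] * 5})
        res = cp.pn_ps(classified, {ONEFOLD: 100, FOURFOLD: 100,
                                    OTHER_CODING: 0, INTERGENIC: 0})
        assert res.ratio == 0.0

    def test_zero_ssnps_is_undefined_not_zero(self):
        classified = pd.DataFrame({"degeneracy_class": [ONEFOLD] * 5})
        res = cp.pn_ps(classified, {ONEFOLD: 100, FOURFOLD: 100,
                                    OTHER_CODING: 0, INTERGENIC: 0})
        assert res.undefined
        assert np.isnan(res.ratio)

    def test_zero_eligible_sites_is_error(self):
        classified = pd.DataFrame({"degeneracy_class": []})
        with pytest.raises(ValueError, match="eligible"):
            cp.pn_ps(classified, {ONEFOLD: 0, FOURFOLD: 100,
                                  OTHER_CODING: 0, INTERGENIC: 0})

    def test_neutral_uniform_substitutions_give_ratio_near_one(self, small_genome):
        """Neutral oracle: substitutions placed uniformly over eligible
        onefold+fourfold sites at equal per-site probability must recover
        pN/pS ~ 1 (95% CI over replicates covers 1)."""
        from cosortpop.population_diversity import _CLASS_CODES

        classes, _ = degeneracy_array(small_genome)
        one = np.flatnonzero(classes == _CLASS_CODES[ONEFOLD])
        four = np.flatnonzero(classes == _CLASS_CODES[FOURFOLD])
        sites = {ONEFOLD: len(one), FOURFOLD: len(four),
                 OTHER_CODING: 0, INTERGENIC: 0}
        rng = np.random.default_rng(13)
        ratios = []
        pool = np.concatenate([one, four])
        for _ in range(100):
            hit = pool[rng.random(len(pool)) < 0.02]
            classified = pd.DataFrame({
                "degeneracy_class": np.where(np.isin(hit, one), ONEFOLD, FOURFOLD)
            })
            ratios.append(cp.pn_ps(classified, sites).ratio)
        ratios = np.array(ratios)
        ci = (ratios.mean() - 1.96 * ratios.std() / 10,
              ratios.mean() + 1.96 * ratios.std() / 10)
        assert ci[0] <= 1.0 <= ci[1]


class TestGeneDensity:
    @pytest.fixture
    def genome_two_genes(self):
        # two genes of 300 bp each over a 1000 bp genome
        seq = ("ATG" + "CTA" * 98 + "TAA") * 2 + "A" * 400
        return AnnotatedGenome("t", seq, [
            GeneRecord("g1", 0, 300, "+", "catA"),
            GeneRecord("g2", 300, 600, "+", "catB"),
        ])

    def test_gene_below_mapped_site_threshold_excluded(self, genome_two_genes):
        eligible = np.zeros(1000, dtype=bool)
        eligible[:99] = True  # g1: 99 mapped sites
        eligible[300:600] = True  # g2: 300
        table = cp.gene_snp_density(pd.DataFrame(columns=["pos", "degeneracy_class"]),
                                    eligible, genome_two_genes)
        assert table["gene_id"].tolist() == ["g2"]

    def test_boundary_inclusive_at_100(self, genome_two_genes):
        eligible = np.zeros(1000, dtype=bool)
        eligible[:100] = True
        table = cp.gene_snp_density(pd.DataFrame(columns=["pos", "degeneracy_class"]),
                                    eligible, genome_two_genes)
        assert "g1" in table["gene_id"].tolist()

    def test_density_arithmetic(self, genome_two_genes):
        eligible = np.zeros(1000, dtype=bool)
        eligible[300:600] = True
        classified = pd.DataFrame({
            "pos": [310, 340, 400, 430, 500],
            "degeneracy_class": [ONEFOLD] * 5,
        })
        table = cp.gene_snp_density(classified, eligible, genome_two_genes)
        row = table[table["gene_id"] == "g2"].iloc[0]
        assert row["nsnp_density"] == pytest.approx(5 * 1000 / 300)

    def test_snp_free_gene_density_zero(self, genome_two_genes):
        eligible = np.ones(1000, dtype=bool)
        table = cp.gene_snp_density(pd.DataFrame(columns=["pos", "degeneracy_class"]),
                                    eligible, genome_two_genes)
        assert (table["nsnp_density"] == 0).all()


class TestCategoryAnova:
    def make_table(self, spec):
        rows = []
        for cat, values in spec.items():
            for i, v in enumerate(values):
                rows.append({"gene_id": f"{cat}{i}", "category": cat,
                             "nsnp_density": float(v)})
        return pd.DataFrame(rows)

    def test_identical_densities_give_zero_f(self):
        t = self.make_table({"a": [2.0] * 12, "b": [2.0] * 12})
        st = cp.category_anova(t)
        assert st.f_statistic == 0.0
        assert (st.tukey["p-adj"] > 0.05).all()

    def test_two_category_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        t = self.make_table({"a": rng.normal(1, 0.3, 15), "b": rng.normal(2, 0.3, 15)})
        st = cp.category_anova(t)
        tt = sps.ttest_ind(t[t.category == "a"].nsnp_density,
                           t[t.category == "b"].nsnp_density)
        assert st.f_statistic == pytest.approx(tt.statistic ** 2)

    def test_category_with_nine_genes_descriptive_only(self):
        t = self.make_table({"a": range(12), "b": range(12), "small": range(9)})
        st = cp.category_anova(t)
        assert "small" in st.descriptive["category"].tolist()
        assert "small" not in st.letters
        assert not st.tukey.apply(lambda r: "small" in r.values.tolist(), axis=1).any()

    def test_fewer_than_two_qualifying_categories_is_error(self):
        t = self.make_table({"a": range(12), "b": range(5)})
        with pytest.raises(ValueError, match="2 categories"):
            cp.category_anova(t)

    def test_distinct_letters_for_separated_groups(self):
        rng = np.random.default_rng(4)
        t = self.make_table({
            "low": rng.normal(0, 0.1, 12),
            "mid": rng.normal(5, 0.1, 12),
            "high": rng.normal(10, 0.1, 12),
        })
        st = cp.category_anova(t)
        assert len({st.letters[c] for c in ("low", "mid", "high")}) == 3


class TestRegionChisq:
    def test_proportional_distribution_gives_zero(self):
        gene = GeneRecord("g", 0, 300, "+", "c", "I" * 50 + "E" * 30 + "T" * 20)
        pos = np.concatenate([
            np.arange(10) * 3,          # 10 residues internal
            150 + np.arange(6) * 3,     # 6 external
            240 + np.arange(4) * 3,     # 4 transmembrane
        ])
        chi2, df, p, N = cp.region_chisq(pos, gene)
        assert chi2 == pytest.approx(0.0)
        assert (df, N) == (2, 20)
        assert p == pytest.approx(1.0)

    def test_fully_skewed_two_regions(self):
        gene = GeneRecord("g", 0, 300, "+", "c", "I" * 50 + "E" * 50)
        pos = np.arange(20) * 3
        chi2, df, p, N = cp.region_chisq(pos, gene)
        assert chi2 == pytest.approx(20.0)
        assert df == 1 and N == 20

    def test_minus_strand_residue_mapping(self):
        gene = GeneRecord("g", 0, 60, "-", "c", "I" * 10 + "E" * 10)
        # genomic positions 57-59 = first codon on minus strand = residue 0 (I)
        chi2, df, p, N = cp.region_chisq(np.array([58, 1]), gene)
        assert N == 2  # one residue in each region

    def test_single_region_class_is_error(self):
        gene = GeneRecord("g", 0, 30, "+", "c", "I" * 10)
        with pytest.raises(ValueError, match="one nonempty region"):
            cp.region_chisq(np.array([0]), gene)

    def test_gene_without_regions_is_error(self):
        gene = GeneRecord("g", 0, 30, "+", "c")
        with pytest.raises(ValueError, match="region labels"):
            cp.region_chisq(np.array([0]), gene)
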