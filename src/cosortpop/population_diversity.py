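"""Multi-SAG population analysis on a shared reference.

Per-SAG consensus calling with disagreement masking, cross-SAG SNP calls,
degenerate-site classification under translation table 11, pN/pS, per-gene
SNP densities, and the functional-category / protein-region diversification
statistics.

Site-class conventions: a "synonymous site" is a fourfold degenerate site
(every substitution preserves the amino acid) and a "non-synonymous site" is
a onefold degenerate site (every substitution changes it, a stop counting as
a change). Two- and threefold degenerate sites are tallied as
``other_coding`` and excluded from pN/pS entirely, so the ratio reported
here is a polymorphism statistic over unambiguous site classes, not a
Nei-Gojobori dN/dS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    BASES,
    N_CODE,
    REGION_EXTERNAL,
    REGION_INTERNAL,
    REGION_TRANSMEMBRANE,
    AnnotatedGenome,
    GeneRecord,
    empty_snp_table,
)
from .read_processing import SiteCounts

# Translation table 11 (bacterial/archaeal; identical residue assignments to
# the standard code — only initiation codons differ, which is irrelevant for
# degeneracy). Written out explicitly so the degeneracy classification has
# no library dependency and can be checked against an independent oracle.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = ("TAA", "TAG", "TGA")

# Degeneracy classes (integer codes used in the per-position arrays).
FOURFOLD = "fourfold"
ONEFOLD = "onefold"
OTHER_CODING = "other_coding"
INTERGENIC = "intergenic"

_CLASS_CODES = {INTERGENIC: 0, FOURFOLD: 1, ONEFOLD: 2, OTHER_CODING: 3}
_CLASS_NAMES = {v: k for k, v in _CLASS_CODES.items()}


def translate(seq: str) -> str:
    """Translate a CDS (coding orientation) under table 11."""
    return "".join(GENETIC_CODE[seq[i : i + 3]] for i in range(0, len(seq) - len(seq) % 3, 3))


def _codon_degeneracy_table() -> np.ndarray:
    """(64, 3) class codes: degeneracy of each codon position of each codon."""
    table = np.empty((64, 3), dtype=np.uint8)
    for idx in range(64):
        codon = BASES[idx >> 4] + BASES[(idx >> 2) & 3] + BASES[idx & 3]
        aa = GENETIC_CODE[codon]
        for j in range(3):
            changed = 0
            for b in BASES:
                if b == codon[j]:
                    continue
                alt = codon[:j] + b + codon[j + 1 :]
                if GENETIC_CODE[alt] != aa:
                    changed += 1
            if changed == 0:
                table[idx, j] = _CLASS_CODES[FOURFOLD]
            elif changed == 3:
                table[idx, j] = _CLASS_CODES[ONEFOLD]
            else:
                table[idx, j] = _CLASS_CODES[OTHER_CODING]
    return table

_DEGENERACY_BY_CODON = _codon_degeneracy_table()


def degeneracy_array(genome: AnnotatedGenome) -> tuple[np.ndarray, np.ndarray]:
    """Per-position degeneracy class codes and containing-gene index.

    Returns ``(classes, gene_idx)``: ``classes`` holds the integer class code
    per reference position (intergenic outside genes) and ``gene_idx`` the
    index into ``genome.genes`` of the first containing gene (-1 outside).
    Genes whose length is not a multiple of 3 classify as ``other_coding``
    with a warning; codons containing an ambiguous reference base classify
    as ``other_coding`` (the sites are excluded from denominators anyway
    because reference-N positions are never eligible).
    """
    cached = getattr(genome, "_degeneracy_cache", None)
    if cached is not None:
        return cached
    L = len(genome)
    classes = np.full(L, _CLASS_CODES[INTERGENIC], dtype=np.uint8)
    gene_idx = np.full(L, -1, dtype=np.int32)
    codes = genome.codes
    for gi, gene in enumerate(genome.genes):
        span = gene_idx[gene.start : gene.end]
        fresh = span == -1
        if not fresh.all():
            warnings.warn(
                f"gene {gene.gene_id} overlaps another gene; "
                "first containing gene wins for the overlapped positions"
            )
        span[fresh] = gi
        if not gene.is_codon_multiple:
            warnings.warn(
                f"gene {gene.gene_id}: length not a multiple of 3; classed other_coding"
            )
            cls = np.full(gene.length, _CLASS_CODES[OTHER_CODING], dtype=np.uint8)
        else:
            cds = codes[gene.start : gene.end]
            if gene.strand == "-":
                rc = cds[::-1]
                cds = np.where(rc < 4, 3 - rc, N_CODE).astype(np.uint8)
            tri = cds.reshape(-1, 3).astype(np.int32)
            ambiguous = (tri >= 4).any(axis=1)
            codon_idx = (tri[:, 0] << 4) + (tri[:, 1] << 2) + tri[:, 2]
            codon_idx[ambiguous] = 0
            cls = _DEGENERACY_BY_CODON[codon_idx]  # (n_codons, 3)
            cls[ambiguous] = _CLASS_CODES[OTHER_CODING]
            cls = cls.reshape(-1)
            if gene.strand == "-":
                cls = cls[::-1]
        target = classes[gene.start : gene.end]
        target[fresh] = cls[fresh]
    genome._degeneracy_cache = (classes, gene_idx)
    return classes, gene_idx


def site_degeneracy(genome: AnnotatedGenome, pos: int) -> str:
    """Degeneracy class of a reference position, strand-aware."""
    classes, _ = degeneracy_array(genome)
    return _CLASS_NAMES[int(classes[pos])]


# ---------------------------------------------------------------------------
# Consensus sequences

CONS_MASKED = 4
CONS_NOCOV = 5


@dataclass
class ConsensusSequence:
    """Per-SAG consensus: base codes 0-3, MASKED=4 where >10% of reads
    disagree (or the modal allele ties), NOCOV=5 where depth is zero."""

    sag_id: str
    codes: np.ndarray

    @property
    def n_masked(self) -> int:
        return int((self.codes == CONS_MASKED).sum())

    @property
    def n_nocov(self) -> int:
        return int((self.codes == CONS_NOCOV).sum())


def consensus_alleles(counts: SiteCounts, mask_fraction: float = 0.10) -> ConsensusSequence:
    """Modal allele per site; MASKED where the non-modal fraction is
    strictly greater than ``mask_fraction`` or the mode is tied."""
    c = counts.counts
    depth = counts.depth
    modal_count = c.max(axis=1)
    modal = c.argmax(axis=1).astype(np.uint8)
    ties = (c == modal_count[:, None]).sum(axis=1) > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        disagree = np.where(depth > 0, (depth - modal_count) / np.maximum(depth, 1), 0.0)
    out = modal.copy()
    out[(disagree > mask_fraction + 1e-12) | ties] = CONS_MASKED
    out[depth == 0] = CONS_NOCOV
    return ConsensusSequence(counts.sag_id or counts.target_id, out)


# ---------------------------------------------------------------------------
# Cross-SAG SNP calling


@dataclass
class CrossSagResult:
    snps: pd.DataFrame
    eligible: np.ndarray  # bool per reference position
    min_sags: int

    @property
    def n_eligible(self) -> int:
        return int(self.eligible.sum())


def cross_sag_snps(
    consensuses: list[ConsensusSequence],
    reference: AnnotatedGenome,
    min_sags: int = 5,
) -> CrossSagResult:
    """Call SNPs across SAG consensuses relative to each other or the reference.

    A site is eligible iff at least ``min_sags`` consensuses are unmasked and
    covered there (and the reference base is unambiguous). A SNP is emitted
    iff the eligible consensus alleles together with the reference allele
    contain at least two distinct bases.
    """
    if min_sags > len(consensuses):
        raise ValueError(
            f"min_sags={min_sags} exceeds the number of SAGs ({len(consensuses)})"
        )
    mat = np.vstack([c.codes for c in consensuses])  # (n_sags, L)
    ref = reference.codes
    if mat.shape[1] != len(ref):
        raise ValueError("consensus length differs from reference length")
    called = mat < 4  # unmasked, covered
    eligible = (called.sum(axis=0) >= min_sags) & (ref < 4)
    present = np.zeros((4, mat.shape[1]), dtype=bool)
    for b in range(4):
        present[b] = ((mat == b) & called).any(axis=0)
        present[b] |= ref == b
    n_distinct = present.sum(axis=0)
    is_snp = eligible & (n_distinct >= 2)
    pos = np.flatnonzero(is_snp)

    # Major allele = modal consensus allele among eligible SAGs; minor = the
    # most frequent other allele (falling back to the reference allele when
    # every SAG agrees but differs from the reference).
    snps = empty_snp_table()
    if len(pos):
        sub = mat[:, pos]
        sub_called = called[:, pos]
        tallies = np.zeros((4, len(pos)), dtype=np.int32)
        for b in range(4):
            tallies[b] = ((sub == b) & sub_called).sum(axis=0)
        ref_sub = ref[pos]
        order = np.argsort(-tallies, axis=0, kind="stable")
        major = order[0]
        minor = order[1].astype(np.int64)
        minor_count = np.take_along_axis(tallies, order[1][None, :], axis=0)[0]
        # all SAGs agree but differ from reference -> the reference is the minor allele
        agree_ref_minor = (minor_count == 0)
        minor[agree_ref_minor] = ref_sub[agree_ref_minor]
        depth = tallies.sum(axis=0)
        base_arr = np.array(list(BASES))
        snps = pd.DataFrame(
            {
                "target_id": reference.genome_id,
                "pos": pos.astype(np.int64),
                "ref_allele": base_arr[ref_sub],
                "major_allele": base_arr[major],
                "minor_allele": base_arr[minor],
                "minor_count": minor_count.astype(np.int64),
                "depth_used": depth.astype(np.int64),
                "maf": minor_count / np.maximum(depth, 1),
                "degeneracy_class": None,
                "gene_id": None,
            }
        )
    return CrossSagResult(snps=snps, eligible=eligible, min_sags=min_sags)


def classify_snps(snps: pd.DataFrame, genome: AnnotatedGenome) -> pd.DataFrame:
    """Fill degeneracy_class and gene_id from the reference annotation."""
    classes, gene_idx = degeneracy_array(genome)
    out = snps.copy()
    if len(out) == 0:
        return out
    pos = out["pos"].to_numpy()
    out["degeneracy_class"] = [_CLASS_NAMES[int(c)] for c in classes[pos]]
    ids = [None if gi < 0 else genome.genes[gi].gene_id for gi in gene_idx[pos]]
    out["gene_id"] = ids
    return out


def eligible_site_counts(eligible: np.ndarray, genome: AnnotatedGenome) -> dict[str, int]:
    """Eligible-site tallies by degeneracy class (same positions as the SNPs)."""
    classes, _ = degeneracy_array(genome)
    return {
        name: int((eligible & (classes == code)).sum())
        for name, code in _CLASS_CODES.items()
    }


# ---------------------------------------------------------------------------
# pN/pS


@dataclass
class PnPsResult:
    n_snps: int
    s_snps: int
    onefold_sites: int
    fourfold_sites: int
    undefined: bool = False

    @property
    def pn(self) -> float:
        return self.n_snps / self.onefold_sites

    @property
    def ps(self) -> float:
        return self.s_snps / self.fourfold_sites

    @property
    def ratio(self) -> float:
        if self.undefined:
            return float("nan")
        return self.pn / self.ps


def pn_ps(classified: pd.DataFrame, eligible_sites_by_class: dict[str, int]) -> PnPsResult:
    """pN/pS = (nSNPs per onefold site) / (sSNPs per fourfold site).

    With zero sSNPs the ratio is undefined (NaN + flag), never 0; zero
    eligible sites in either class is an error.
    """
    onefold_sites = eligible_sites_by_class[ONEFOLD]
    fourfold_sites = eligible_sites_by_class[FOURFOLD]
    if onefold_sites == 0 or fourfold_sites == 0:
        raise ValueError(
            f"no eligible sites in a class (onefold={onefold_sites}, fourfold={fourfold_sites})"
        )
    n_snps = int((classified["degeneracy_class"] == ONEFOLD).sum())
    s_snps = int((classified["degeneracy_class"] == FOURFOLD).sum())
    return PnPsResult(
        n_snps=n_snps,
        s_snps=s_snps,
        onefold_sites=onefold_sites,
        fourfold_sites=fourfold_sites,
        undefined=(s_snps == 0),
    )


# ---------------------------------------------------------------------------
# Per-gene densities and category statistics


def gene_snp_density(
    classified: pd.DataFrame,
    eligible: np.ndarray,
    genome: AnnotatedGenome,
    min_mapped_sites: int = 100,
) -> pd.DataFrame:
    """Per-gene nSNP/sSNP densities over mapped (eligible) sites.

    Genes with fewer than ``min_mapped_sites`` eligible positions are
    excluded. Densities are per kb of mapped sites, not gene length.
    """
    rows = []
    pos = classified["pos"].to_numpy() if len(classified) else np.empty(0, dtype=int)
    klass = classified["degeneracy_class"].to_numpy() if len(classified) else np.empty(0, dtype=object)
    for gene in genome.genes:
        mapped = int(eligible[gene.start : gene.end].sum())
        if mapped < min_mapped_sites:
            continue
        in_gene = (pos >= gene.start) & (pos < gene.end)
        n_count = int(((klass == ONEFOLD) & in_gene).sum())
        s_count = int(((klass == FOURFOLD) & in_gene).sum())
        rows.append(
            {
                "gene_id": gene.gene_id,
                "category": gene.category,
                "mapped_sites": mapped,
                "nsnp_count": n_count,
                "ssnp_count": s_count,
                "nsnp_density": n_count * 1000.0 / mapped,
                "ssnp_density": s_count * 1000.0 / mapped,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "category", "mapped_sites",
            "nsnp_count", "ssnp_count", "nsnp_density", "ssnp_density",
        ],
    )


@dataclass
class CategoryStats:
    descriptive: pd.DataFrame
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame
    letters: dict[str, str] = field(default_factory=dict)


def category_anova(
    gene_table: pd.DataFrame,
    min_genes: int = 10,
    value: str = "nsnp_density",
    alpha: float = 0.05,
) -> CategoryStats:
    """One-way ANOVA of per-gene SNP densities across functional categories.

    Categories with fewer than ``min_genes`` genes appear in the descriptive
    table but are excluded from the ANOVA and the Tukey HSD post hoc. The
    compact letter display is derived from the Tukey non-significance graph
    (categories sharing a letter are not significantly different).
    """
    from scipy import stats as sps

    desc = (
        gene_table.groupby("category")[value]
        .agg(n_genes="count", mean="mean", median="median")
        .reset_index()
        .sort_values("category")
        .reset_index(drop=True)
    )
    qualifying = desc.loc[desc["n_genes"] >= min_genes, "category"].tolist()
    if len(qualifying) < 2:
        raise ValueError(
            f"need >= 2 categories with >= {min_genes} genes, found {len(qualifying)}"
        )
    sub = gene_table[gene_table["category"].isin(qualifying)]
    groups = [sub.loc[sub["category"] == c, value].to_numpy() for c in qualifying]
    grand = np.concatenate(groups)
    df1 = len(qualifying) - 1
    df2 = len(grand) - len(qualifying)
    ss_between = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
    if ss_between <= 1e-300:  # identical group means (incl. all-identical data)
        F, p = 0.0, 1.0
    else:
        F, p = sps.f_oneway(*groups)
        F, p = float(F), float(p)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance edge case
        res = pairwise_tukeyhsd(sub[value].to_numpy(), sub["category"].to_numpy(), alpha=alpha)
    tukey = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    pvals = np.asarray(res.pvalues, dtype=float)
    # zero residual variance: identical data -> p=1, any difference -> p=0
    nan = np.isnan(pvals)
    if nan.any():
        diffs = np.asarray(res.meandiffs, dtype=float)
        pvals[nan] = np.where(np.abs(diffs[nan]) < 1e-12, 1.0, 0.0)
    tukey["p-adj"] = pvals
    letters = _compact_letter_display(qualifying, pvals, alpha)
    return CategoryStats(
        descriptive=desc,
        f_statistic=F,
        df_between=df1,
        df_within=df2,
        p_value=p,
        tukey=tukey,
        letters=letters,
    )


def _compact_letter_display(categories, pvalues, alpha) -> dict[str, str]:
    import itertools
    import string

    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(categories)
    pairs = list(itertools.combinations(sorted(categories), 2))
    for (a, b), p in zip(pairs, np.asarray(pvalues, dtype=float)):
        if p >= alpha:
            g.add_edge(a, b)
    cliques = sorted(
        (sorted(c) for c in nx.find_cliques(g)), key=lambda c: (len(c) == 1, c)
    )
    letters: dict[str, list[str]] = {c: [] for c in categories}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for c in clique:
            letters[c].append(letter)
    return {c: "".join(ls) for c, ls in letters.items()}


# ---------------------------------------------------------------------------
# Protein-region chi-square


def region_chisq(
    nsnp_positions: np.ndarray, gene: GeneRecord
) -> tuple[float, int, float, int]:
    """Goodness-of-fit of nSNP placement across protein regions.

    Observed counts are the residues carrying an nSNP per region class;
    expected counts are proportional to the per-class residue totals.
    Returns ``(chi2, df, p, N)`` with N the number of nSNP-bearing residues.
    """
    from scipy import stats as sps

    if gene.regions is None:
        raise ValueError(f"gene {gene.gene_id} has no region labels")
    nsnp_positions = np.asarray(nsnp_positions, dtype=np.int64)
    if np.any((nsnp_positions < gene.start) | (nsnp_positions >= gene.end)):
        raise ValueError("nSNP position outside the gene interval")
    if gene.strand == "+":
        residues = (nsnp_positions - gene.start) // 3
    else:
        residues = (gene.end - 1 - nsnp_positions) // 3
    residues = np.unique(residues)
    labels = np.array(list(gene.regions))
    region_classes = [c for c in (REGION_INTERNAL, REGION_EXTERNAL, REGION_TRANSMEMBRANE)
                      if (labels == c).any()]
    if len(region_classes) < 2:
        raise ValueError("only one nonempty region class (df would be 0)")
    sizes = np.array([(labels == c).sum() for c in region_classes], dtype=float)
    observed = np.array([(labels[residues] == c).sum() for c in region_classes], dtype=float)
    N = int(observed.sum())
    if N == 0:
        raise ValueError("no nSNP-bearing residues mapped to regions")
    expected = N * sizes / sizes.sum()
    chi2, p = sps.chisquare(observed, expected)
    return float(chi2), len(region_classes) - 1, float(p), N
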