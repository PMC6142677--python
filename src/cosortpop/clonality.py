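"""Within-SAG SNP density and the clonality test.

The logic: a SAG amplified from a single cell (or from several clonal
cells) should show only baseline, error-driven SNP density after the filter
chain; multiple genetically distinct cells co-amplified in one sorting
event produce minor-allele fractions near their mixture weights and hence a
large excess of MAF >= 10% SNPs. The pooled-SAG experiment calibrates the
expected signal by pooling reads from k distinct single cells with equal
per-SAG depth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BASES, AlignmentTable, AnnotatedGenome, empty_snp_table
from .read_processing import SiteCounts, filter_alignments, pileup, pool_counts, downsample_sites


@dataclass
class DensityRecord:
    unit_id: str
    snp_count: int
    covered_kb: float
    density: float


def call_snps(counts: SiteCounts, maf_min: float = 0.10) -> pd.DataFrame:
    """Call SNPs on downsampled counts at minor allele frequency >= maf_min.

    Per covered site the major allele is the most frequent base and the
    minor allele the second most frequent; a SNP is emitted iff
    minor_count / depth >= maf_min (inclusive). Multi-allelic sites emit a
    single record with the top minor allele. Non-uniform depth (input that
    was not downsampled/pooled) is an error.
    """
    depth = counts.depth
    covered = counts.covered
    if counts.downsampled_to is None:
        positive = np.unique(depth[covered])
        if len(positive) > 1:
            raise ValueError(
                "call_snps requires downsampled counts (uniform depth); "
                f"saw depths {positive[:5]}..."
            )
    c = counts.counts[covered]
    pos = np.flatnonzero(covered)
    if len(pos) == 0:
        return empty_snp_table()
    order = np.argsort(-c, axis=1, kind="stable")
    major = order[:, 0]
    minor = order[:, 1]
    minor_count = np.take_along_axis(c, minor[:, None], axis=1)[:, 0]
    d = depth[covered]
    # integer-exact inclusive threshold: minor_count >= ceil(maf_min * depth)
    is_snp = minor_count >= np.ceil(maf_min * d - 1e-9)
    is_snp &= minor_count > 0
    base_arr = np.array(list(BASES))
    sel = np.flatnonzero(is_snp)
    snps = pd.DataFrame(
        {
            "target_id": counts.target_id,
            "pos": pos[sel].astype(np.int64),
            "ref_allele": base_arr[counts.ref_codes[pos[sel]]],
            "major_allele": base_arr[major[sel]],
            "minor_allele": base_arr[minor[sel]],
            "minor_count": minor_count[sel].astype(np.int64),
            "depth_used": d[sel].astype(np.int64),
            "maf": minor_count[sel] / d[sel],
            "degeneracy_class": None,
            "gene_id": None,
        }
    )
    return snps


def snp_density(snps: pd.DataFrame, counts: SiteCounts, unit_id: str | None = None) -> DensityRecord:
    """SNPs per kb of covered (downsample-surviving) sites."""
    covered_sites = int(counts.covered.sum())
    if covered_sites == 0:
        raise ValueError("zero covered sites; density undefined")
    n = len(snps)
    return DensityRecord(
        unit_id=unit_id or counts.sag_id or counts.target_id,
        snp_count=n,
        covered_kb=covered_sites / 1000.0,
        density=n * 1000.0 / covered_sites,
    )


# ---------------------------------------------------------------------------
# One-sided Wilcoxon rank sum


@dataclass
class RankSumResult:
    statistic: float  # Mann-Whitney U for group a
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" | "normal_approximation"


def rank_sum_one_sided(
    a, b, alternative: str = "a_greater", exact_limit: int = 12
) -> RankSumResult:
    """One-sided Wilcoxon rank sum (Mann-Whitney) test.

    Exact p by full enumeration of all C(n1+n2, n1) rank assignments when
    n1 + n2 <= exact_limit and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    from scipy import stats as sps

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("a_greater", "a_less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[:n1].sum()
    u_a = r_a - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if n1 + n2 <= exact_limit and not has_ties:
        total = 0
        ge = le = 0
        for comb in itertools.combinations(range(n1 + n2), n1):
            s = sum(ranks[list(comb)])
            total += 1
            if s >= r_a - 1e-9:
                ge += 1
            if s <= r_a + 1e-9:
                le += 1
        if alternative == "a_greater":
            p = ge / total
        elif alternative == "a_less":
            p = le / total
        else:
            p = min(1.0, 2.0 * min(ge, le) / total)
        return RankSumResult(u_a, p, n1, n2, "exact")
    alt = {"a_greater": "greater", "a_less": "less", "two_sided": "two-sided"}[alternative]
    res = sps.mannwhitneyu(a, b, alternative=alt, method="asymptotic", use_continuity=True)
    return RankSumResult(float(res.statistic), float(res.pvalue), n1, n2, "normal_approximation")


# ---------------------------------------------------------------------------
# Pooled-SAG experiment


def pooling_experiment(
    sag_alignments: list[AlignmentTable],
    reference: AnnotatedGenome,
    k_values: list[int] | None = None,
    min_ref_coverage: float = 0.25,
    target_depth: int = 50,
    maf_min: float = 0.10,
    seed: int = 0,
    all_subsets: bool = False,
    sag_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate multiple attached cells by pooling reads from k single SAGs.

    SAGs must cover more than ``min_ref_coverage`` of the reference with at
    least one filtered read to qualify. For each k the first k qualifying
    SAGs (input order) are pooled with equal per-SAG depth, downsampled to
    ``target_depth`` and SNP-called at ``maf_min``; with ``all_subsets``
    every size-k subset contributes one row.
    """
    rng = np.random.default_rng(seed)
    ids = sag_ids or [f"sag{i}" for i in range(len(sag_alignments))]
    counts_list: list[SiteCounts] = []
    coverages: dict[str, float] = {}
    for sid, aln in zip(ids, sag_alignments):
        filtered = filter_alignments(aln)
        counts = pileup(filtered, reference, sag_id=sid)
        cov = float((counts.depth > 0).mean())
        coverages[sid] = cov
        if cov > min_ref_coverage:
            counts_list.append(counts)
    if k_values is None:
        k_values = list(range(1, len(counts_list) + 1))
    if not k_values or max(k_values) > len(counts_list):
        raise ValueError(
            f"insufficient qualifying SAGs for k={max(k_values) if k_values else 0}: "
            f"coverages {coverages}"
        )
    rows = []
    for k in sorted(k_values):
        subsets = (
            itertools.combinations(range(len(counts_list)), k)
            if all_subsets
            else [tuple(range(k))]
        )
        for subset in subsets:
            pooled = pool_counts(
                [counts_list[i] for i in subset],
                target_depth=target_depth,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            snps = call_snps(pooled, maf_min=maf_min)
            rec = snp_density(snps, pooled, unit_id=f"k{k}:" + ",".join(
                counts_list[i].sag_id or str(i) for i in subset))
            rows.append(
                {
                    "k": k,
                    "sags": ";".join(counts_list[i].sag_id or str(i) for i in subset),
                    "snp_count": rec.snp_count,
                    "covered_kb": rec.covered_kb,
                    "density": rec.density,
                }
            )
    return pd.DataFrame(rows)


def sag_density(
    aln: AlignmentTable,
    reference: AnnotatedGenome,
    target_depth: int = 50,
    maf_min: float = 0.10,
    seed: int = 0,
    unit_id: str | None = None,
) -> DensityRecord:
    """Filter -> pileup -> downsample -> SNP call -> density for one SAG."""
    filtered = filter_alignments(aln)
    counts = pileup(filtered, reference, sag_id=unit_id)
    down = downsample_sites(counts, target_depth=target_depth, seed=seed)
    snps = call_snps(down, maf_min=maf_min)
    return snp_density(snps, down, unit_id=unit_id)
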