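"""Filtered alignments -> per-site allele counts.

The filter chain mirrors standard single-cell read-mapping practice for SNP
calling from amplified material: reads below 95% identity to the assembly,
below mean base quality 30, or below mapping quality 20 are discarded;
individual bases below quality 30 are not counted. All thresholds are
"discard if strictly less than". Per-site depth is then equalised by
downsampling without replacement to a fixed number of reads (default 50) so
minor-allele fractions are comparable across unevenly amplified SAGs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import AlignmentTable, AnnotatedGenome, N_CODE, cigar_ops, encode_seq, reference_span

logger = logging.getLogger(__name__)


@dataclass
class SiteCounts:
    """Per-position A/C/G/T counts on one target.

    ``counts`` is (L, 4) int32; ``ref_codes`` the reference base codes.
    ``dropped_low_depth`` marks positions excluded by downsampling;
    ``reference_n`` marks ambiguous reference bases, which never enter SNP
    calls or density denominators. ``downsampled_to`` is the uniform depth
    after downsampling/pooling (None before).
    """

    target_id: str
    counts: np.ndarray
    ref_codes: np.ndarray
    dropped_low_depth: np.ndarray = field(default=None)  # type: ignore[assignment]
    downsampled_to: int | None = None
    sag_id: str | None = None

    def __post_init__(self) -> None:
        if self.dropped_low_depth is None:
            self.dropped_low_depth = np.zeros(len(self.counts), dtype=bool)
        self.counts = np.asarray(self.counts, dtype=np.int32)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def reference_n(self) -> np.ndarray:
        return self.ref_codes >= N_CODE

    @property
    def covered(self) -> np.ndarray:
        """Positions that count toward SNP calling and density denominators."""
        return (self.depth > 0) & ~self.dropped_low_depth & ~self.reference_n

    def __len__(self) -> int:
        return len(self.counts)


def filter_alignments(
    aln: AlignmentTable,
    min_identity: float = 0.95,
    min_mean_read_q: float = 30.0,
    min_mapq: int = 20,
) -> AlignmentTable:
    """Discard reads with identity < min_identity (1 - NM/aligned_length,
    aligned_length = reference-consuming CIGAR length), mean base quality
    < min_mean_read_q, or MAPQ < min_mapq. Idempotent."""
    n = len(aln)
    if n == 0:
        return aln
    dense = aln.dense
    if dense is not None:
        codes, quals = dense
        aligned_len = np.full(n, codes.shape[1], dtype=np.int64)
        mean_q = quals.mean(axis=1)
    else:
        aligned_len = np.array([reference_span(c) for c in aln.cigar], dtype=np.int64)
        mean_q = np.array([q.mean() for q in aln.qual])
    identity = 1.0 - aln.nm / aligned_len
    keep_identity = identity >= min_identity - 1e-12
    keep_q = mean_q >= min_mean_read_q - 1e-12
    keep_mapq = aln.mapq >= min_mapq
    keep = keep_identity & keep_q & keep_mapq
    logger.info(
        "filter_alignments: %d reads in; removed %d by identity, %d by mean "
        "base quality, %d by MAPQ; %d retained",
        n, int((~keep_identity).sum()), int((~keep_q).sum()),
        int((~keep_mapq).sum()), int(keep.sum()),
    )
    return aln.subset(keep)


def pileup(
    aln: AlignmentTable,
    reference: AnnotatedGenome,
    min_base_q: int = 30,
    sag_id: str | None = None,
) -> SiteCounts:
    """Count read bases with quality >= min_base_q at each reference position.

    CIGAR semantics: M/=/X consume read and reference; I consumes read only
    (inserted bases count toward no reference position); D consumes
    reference only; S is skipped. A read overhanging the target end is an
    error naming the read.
    """
    L = len(reference)
    sub = aln if set(aln.target_id.tolist()) <= {reference.genome_id} else aln.for_target(reference.genome_id)
    counts = np.zeros((L, 4), dtype=np.int32)
    n = len(sub)
    if n:
        dense = sub.dense
        if dense is not None:
            spans = np.full(n, dense[0].shape[1], dtype=np.int64)
        else:
            spans = np.array([reference_span(c) for c in sub.cigar], dtype=np.int64)
        overhang = sub.pos + spans > L
        if overhang.any():
            bad = sub.read_id[np.flatnonzero(overhang)[0]]
            raise ValueError(f"read {bad} overhangs the end of target {reference.genome_id}")
        if dense is not None:
            codes, quals = dense
            rl = codes.shape[1]
            positions = sub.pos[:, None] + np.arange(rl)[None, :]
            ok = (quals >= min_base_q) & (codes < 4)
            flat = positions[ok] * 4 + codes[ok].astype(np.int64)
            counts += np.bincount(flat, minlength=L * 4).reshape(L, 4).astype(np.int32)
        else:
            for i in range(n):
                _pileup_one(counts, sub.pos[i], encode_seq(sub.seq[i]), sub.qual[i],
                            sub.cigar[i], min_base_q)
    return SiteCounts(
        target_id=reference.genome_id,
        counts=counts,
        ref_codes=reference.codes,
        sag_id=sag_id,
    )


def _pileup_one(counts, pos, codes, quals, cigar, min_base_q) -> None:
    rpos, qpos = pos, 0
    for n_op, op in cigar_ops(cigar):
        if op in "M=X":
            seg = codes[qpos : qpos + n_op]
            qseg = quals[qpos : qpos + n_op]
            ok = (qseg >= min_base_q) & (seg < 4)
            idx = np.flatnonzero(ok)
            np.add.at(counts, (rpos + idx, seg[idx].astype(np.int64)), 1)
            rpos += n_op
            qpos += n_op
        elif op in "IS":
            qpos += n_op
        elif op == "D":
            rpos += n_op


def _hypergeom_split(rng: np.random.Generator, counts: np.ndarray, take: np.ndarray) -> np.ndarray:
    """Vectorised multivariate hypergeometric draw: per row of ``counts``
    (L, 4), sample ``take`` observations without replacement."""
    remaining = counts.sum(axis=1).astype(np.int64)
    take = take.astype(np.int64)
    out = np.zeros_like(counts)
    for b in range(4):
        good = counts[:, b].astype(np.int64)
        bad = remaining - good
        if len(good):
            drawn = rng.hypergeometric(good, bad, take)
        else:
            drawn = np.zeros(0, dtype=np.int64)
        out[:, b] = drawn
        take = take - drawn
        remaining = bad
    return out


def downsample_sites(counts: SiteCounts, target_depth: int = 50, seed: int | None = 0) -> SiteCounts:
    """Downsample each position to exactly ``target_depth`` base observations
    (without replacement); positions with lower depth are flagged
    dropped_low_depth and leave every downstream denominator."""
    if target_depth < 1:
        raise ValueError("target_depth must be >= 1")
    rng = np.random.default_rng(seed)
    depth = counts.depth
    enough = depth >= target_depth
    new = np.zeros_like(counts.counts)
    if enough.any():
        take = np.full(int(enough.sum()), target_depth, dtype=np.int64)
        new[enough] = _hypergeom_split(rng, counts.counts[enough], take)
    dropped = ~enough
    return SiteCounts(
        target_id=counts.target_id,
        counts=new,
        ref_codes=counts.ref_codes,
        dropped_low_depth=dropped,
        downsampled_to=target_depth,
        sag_id=counts.sag_id,
    )


def pool_counts(
    counts_list: list[SiteCounts],
    target_depth: int = 50,
    seed: int | None = 0,
) -> SiteCounts:
    """Pool pre-downsampling counts from k SAGs with equal per-SAG depth.

    Per position, s = floor(target_depth / k) observations are sampled
    without replacement from every SAG; the position is eligible only where
    all k SAGs have depth >= s, keeping the per-SAG contribution exactly
    equal (pooled depth k*s <= target_depth).
    """
    k = len(counts_list)
    if k < 1:
        raise ValueError("need at least one SAG")
    if k > target_depth:
        raise ValueError(f"k={k} exceeds target depth {target_depth}")
    tids = {c.target_id for c in counts_list}
    if len(tids) != 1:
        raise ValueError(f"pooling across different targets: {sorted(tids)}")
    s = target_depth // k
    rng = np.random.default_rng(seed)
    depths = np.vstack([c.depth for c in counts_list])
    eligible = (depths >= s).all(axis=0)
    pooled = np.zeros_like(counts_list[0].counts)
    for c in counts_list:
        sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        take = np.full(int(eligible.sum()), s, dtype=np.int64)
        pooled[eligible] += _hypergeom_split(sub_rng, c.counts[eligible], take)
    return SiteCounts(
        target_id=counts_list[0].target_id,
        counts=pooled,
        ref_codes=counts_list[0].ref_codes,
        dropped_low_depth=~eligible,
        downsampled_to=k * s,
        sag_id=f"pool_k{k}",
    )
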