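"""Synthetic genomes, haplotype populations and SAG read sets.

The generator emulates the study system end to end: a compact, gene-dense
archaeal-like genome; a population of haplotypes whose synonymous variants
sit only at fourfold degenerate sites and non-synonymous variants only at
onefold degenerate sites (so the true pN/pS is controlled exactly); and
single-cell read sets with MDA-style log-normal amplification bias across
windows, substitution sequencing error with low error-base qualities, and
clonal / mixed-cell / co-sorted compositions. Reads are emitted at their
true positions: the read-mapping step of a real pipeline is replaced by
exact truth, with mapping noise represented through the identity/MAPQ
filters acting on the perturbed records. Ground truth is retained for every
downstream test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    BASES,
    AlignmentTable,
    AnnotatedGenome,
    GeneRecord,
    REGION_EXTERNAL,
    REGION_INTERNAL,
    REGION_TRANSMEMBRANE,
    decode_seq,
    encode_seq,
)
from .population_diversity import (
    FOURFOLD,
    GENETIC_CODE,
    ONEFOLD,
    STOP_CODONS,
    _CLASS_CODES,
    degeneracy_array,
)

DEFAULT_CATEGORY_WEIGHTS = {
    "Translation and ribosome": 0.14,
    "DNA replication and repair": 0.10,
    "RNA modification and processing": 0.08,
    "Transcription": 0.08,
    "Protein modification": 0.08,
    "Energy production": 0.08,
    "Carbohydrate metabolism": 0.06,
    "Motility and attachment": 0.08,
    "Hypothetical": 0.20,
    "Hypothetical external": 0.10,
}

_SENSE_CODONS = sorted(set(GENETIC_CODE) - set(STOP_CODONS))


# ---------------------------------------------------------------------------
# Genome generation


def make_genome(
    seed: int,
    length: int = 500_000,
    gene_fraction: float = 0.85,
    category_weights: dict[str, float] | None = None,
    region_categories: tuple[str, ...] = ("Hypothetical external",),
) -> AnnotatedGenome:
    """Generate an annotated genome with non-overlapping genes on both strands.

    Every gene starts with ATG, ends with a stop codon and translates
    without internal stops under table 11. Genes in ``region_categories``
    get per-residue topology labels with a transmembrane run near the
    N-terminus (the surface-protein signature the classifier looks for).
    """
    if gene_fraction < 0 or gene_fraction > 1:
        raise ValueError("gene_fraction must lie in [0, 1]")
    min_gene = 303  # 100 codons + stop
    if gene_fraction > 0 and length < max(3000, min_gene):
        raise ValueError(
            f"cannot pack genes at fraction {gene_fraction} into {length} bp"
        )
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    weights = category_weights or DEFAULT_CATEGORY_WEIGHTS
    cats = list(weights)
    p = np.array([weights[c] for c in cats], dtype=float)
    p /= p.sum()

    genes: list[GeneRecord] = []
    if gene_fraction > 0:
        mean_gene = (150 + 400) / 2 * 3
        mean_gap = mean_gene * (1 - gene_fraction) / gene_fraction
        cursor = 0
        gi = 0
        while True:
            gap = int(rng.exponential(mean_gap)) if mean_gap > 0 else 0
            start = cursor + gap
            n_codons = int(rng.integers(100, 401))  # incl. stop codon
            end = start + 3 * n_codons
            if end > length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            category = cats[rng.choice(len(cats), p=p)]
            cds = _random_cds(rng, n_codons)
            sub = cds if strand == "+" else _revcomp_str(cds)
            codes[start:end] = encode_seq(sub)
            regions = None
            if category in region_categories:
                n_res = n_codons
                tm = REGION_TRANSMEMBRANE * 19
                head = REGION_INTERNAL * 3
                regions = (head + tm + REGION_EXTERNAL * max(0, n_res - len(head) - 19))[:n_res]
            gi += 1
            genes.append(
                GeneRecord(f"g{gi:04d}", start, end, strand, category, regions)
            )
            cursor = end
    return AnnotatedGenome(f"synth_{seed}", decode_seq(codes), genes)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    stop = STOP_CODONS[rng.choice(3)]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + stop


def _revcomp_str(seq: str) -> str:
    from .io_formats import revcomp

    return revcomp(seq)


# ---------------------------------------------------------------------------
# Haplotype populations


@dataclass
class HaplotypePopulation:
    """A set of haplotypes over a shared reference with per-variant truth.

    ``variants`` columns: pos, ref, alt (base letters), klass (fourfold /
    onefold), category, freq. ``carriers`` is (n_variants, n_haplotypes)
    bool. True per-site rates (for parameter-recovery tests) are exposed as
    ``true_pn``, ``true_ps`` and ``true_pnps``.
    """

    reference: AnnotatedGenome
    n_haplotypes: int
    variants: pd.DataFrame
    carriers: np.ndarray
    onefold_sites: int
    fourfold_sites: int

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def true_pn(self) -> float:
        return (self.variants["klass"] == ONEFOLD).sum() / self.onefold_sites

    @property
    def true_ps(self) -> float:
        return (self.variants["klass"] == FOURFOLD).sum() / self.fourfold_sites

    @property
    def true_pnps(self) -> float:
        return self.true_pn / self.true_ps

    def haplotype_codes(self, i: int) -> np.ndarray:
        codes = self.reference.codes.copy()
        mask = self.carriers[:, i]
        if mask.any():
            pos = self.variants.loc[mask, "pos"].to_numpy()
            alt = self.variants.loc[mask, "alt_code"].to_numpy()
            codes[pos] = alt
        return codes

    def pairwise_differences(self, i: int, j: int) -> int:
        return int((self.carriers[:, i] != self.carriers[:, j]).sum())


def simulate_population(
    genome: AnnotatedGenome,
    n_haplotypes: int,
    target_ssnp_per_kb: float,
    target_nsnp_per_kb: float | dict[str, float],
    freq_spectrum: np.ndarray | None = None,
    seed: int = 0,
) -> HaplotypePopulation:
    """Place synonymous variants at fourfold sites and non-synonymous
    variants at onefold sites, at the requested per-kb-of-genome densities.

    ``target_nsnp_per_kb`` may be a scalar (uniform across genes) or a dict
    of per-functional-category densities. Each variant's population
    frequency is drawn from ``freq_spectrum`` (default: uniform over
    {1/n, ..., (n-1)/n}) and the variant is carried by exactly
    ``round(freq * n)`` haplotypes.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    if target_ssnp_per_kb < 0:
        raise ValueError("densities must be >= 0")
    rng = np.random.default_rng(seed)
    classes, gene_idx = degeneracy_array(genome)
    L = len(genome)
    kb = L / 1000.0
    fourfold_pos = np.flatnonzero(classes == _CLASS_CODES[FOURFOLD])
    onefold_pos = np.flatnonzero(classes == _CLASS_CODES[ONEFOLD])

    chosen: list[np.ndarray] = []
    klasses: list[str] = []

    n_s = round(target_ssnp_per_kb * kb)
    if n_s > len(fourfold_pos):
        raise ValueError(
            f"requested {n_s} sSNPs but only {len(fourfold_pos)} fourfold sites available"
        )
    s_sites = rng.choice(fourfold_pos, size=n_s, replace=False)
    chosen.append(s_sites)
    klasses += [FOURFOLD] * n_s

    if isinstance(target_nsnp_per_kb, dict):
        gene_cat = np.array([g.category for g in genome.genes], dtype=object)
        for cat, rate in target_nsnp_per_kb.items():
            if rate < 0:
                raise ValueError("densities must be >= 0")
            in_cat = np.flatnonzero(gene_cat == cat)
            pool = onefold_pos[np.isin(gene_idx[onefold_pos], in_cat)]
            n_c = round(rate * kb)
            if n_c > len(pool):
                raise ValueError(
                    f"requested {n_c} nSNPs in category {cat!r} but only "
                    f"{len(pool)} onefold sites available"
                )
            sites = rng.choice(pool, size=n_c, replace=False)
            chosen.append(sites)
            klasses += [ONEFOLD] * n_c
    else:
        if target_nsnp_per_kb < 0:
            raise ValueError("densities must be >= 0")
        n_n = round(target_nsnp_per_kb * kb)
        if n_n > len(onefold_pos):
            raise ValueError(
                f"requested {n_n} nSNPs but only {len(onefold_pos)} onefold sites available"
            )
        sites = rng.choice(onefold_pos, size=n_n, replace=False)
        chosen.append(sites)
        klasses += [ONEFOLD] * n_n

    pos = np.concatenate(chosen).astype(np.int64)
    klass_arr = np.array(klasses, dtype=object)
    order = np.argsort(pos, kind="stable")
    pos, klass_arr = pos[order], klass_arr[order]

    ref_codes = genome.codes[pos]
    # Any substitution at a fourfold site is synonymous and any substitution
    # at a onefold site is non-synonymous, so a uniform draw over the three
    # alternatives preserves the class by construction.
    alt_codes = (ref_codes + rng.integers(1, 4, size=len(pos))) % 4

    if freq_spectrum is None:
        freq_spectrum = np.arange(1, n_haplotypes) / n_haplotypes
    freq_spectrum = np.asarray(freq_spectrum, dtype=float)
    freqs = rng.choice(freq_spectrum, size=len(pos))
    carriers = np.zeros((len(pos), n_haplotypes), dtype=bool)
    for v in range(len(pos)):
        k = int(round(freqs[v] * n_haplotypes))
        k = min(max(k, 1), n_haplotypes)
        carriers[v, rng.choice(n_haplotypes, size=k, replace=False)] = True

    base_arr = np.array(list(BASES))
    cat_col = [
        genome.genes[gi].category if gi >= 0 else ""
        for gi in gene_idx[pos]
    ]
    variants = pd.DataFrame(
        {
            "pos": pos,
            "ref": base_arr[ref_codes],
            "alt": base_arr[alt_codes],
            "ref_code": ref_codes,
            "alt_code": alt_codes,
            "klass": klass_arr,
            "category": cat_col,
            "freq": carriers.mean(axis=1),
        }
    )
    return HaplotypePopulation(
        reference=genome,
        n_haplotypes=n_haplotypes,
        variants=variants,
        carriers=carriers,
        onefold_sites=len(onefold_pos),
        fourfold_sites=len(fourfold_pos),
    )


def nsnp_rate_for_pnps(
    genome: AnnotatedGenome, target_pnps: float, ssnp_per_kb: float
) -> float:
    """nSNP density (per kb of genome) yielding ``target_pnps`` when paired
    with ``ssnp_per_kb`` synonymous density on this genome."""
    classes, _ = degeneracy_array(genome)
    n_four = int((classes == _CLASS_CODES[FOURFOLD]).sum())
    n_one = int((classes == _CLASS_CODES[ONEFOLD]).sum())
    return target_pnps * ssnp_per_kb * n_one / n_four


# ---------------------------------------------------------------------------
# SAG read simulation


@dataclass
class SagScenario:
    """One sorting event: which cells were amplified together and how reads
    come out. k = len(cell_haplotype_ids) = 1 with no host is a single-sort
    clonal scenario; k >= 2 models multiple distinct attached cells."""

    scenario_id: str
    cell_haplotype_ids: list[int]
    mixture_weights: list[float] | None = None
    coverage_mean: float = 60.0
    error_rate: float = 0.002
    mda_bias: float = 1.0  # log-normal sigma of per-window amplification
    window: int = 1000
    read_length: int = 150
    seed: int = 0
    correct_q: tuple[int, int] = (35, 40)
    error_q: tuple[int, int] = (2, 34)

    def __post_init__(self) -> None:
        if not self.cell_haplotype_ids:
            raise ValueError("need at least one cell haplotype")
        if self.mixture_weights is None:
            k = len(self.cell_haplotype_ids)
            self.mixture_weights = [1.0 / k] * k
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if len(self.mixture_weights) != len(self.cell_haplotype_ids):
            raise ValueError("one weight per cell haplotype required")


@dataclass
class ReadTruth:
    haplotype: np.ndarray  # per-read haplotype id
    start: np.ndarray  # per-read true 0-based start
    n_errors: np.ndarray  # injected sequencing errors per read


def simulate_sag_reads(
    scenario: SagScenario,
    population: HaplotypePopulation,
    n_reads: int | None = None,
) -> tuple[AlignmentTable, ReadTruth]:
    """Draw reads from the scenario's cell haplotypes with MDA-style bias.

    Window-level depth is scaled by a log-normal factor (sigma =
    ``mda_bias``, unit mean); reads are drawn from the k haplotypes in
    proportion to the mixture weights; substitution errors at ``error_rate``
    get low base qualities (uniform over ``error_q``) and correct bases high
    ones (uniform over ``correct_q``). Emitted positions are true positions;
    NM is the exact edit distance to the reference.
    """
    if scenario.coverage_mean <= 0:
        raise ValueError("coverage_mean must be > 0")
    for h in scenario.cell_haplotype_ids:
        if h < 0 or h >= population.n_haplotypes:
            raise ValueError(f"haplotype {h} not in population")
    rng = np.random.default_rng(scenario.seed)
    ref = population.reference
    L = len(ref)
    rl = scenario.read_length
    if L < rl:
        raise ValueError("reference shorter than read length")
    w = scenario.window
    n_windows = math.ceil(L / w)
    sigma = scenario.mda_bias
    mult = rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=n_windows) if sigma > 0 else np.ones(n_windows)

    starts_parts = []
    max_start = L - rl
    bounds = [(wi * w, min((wi + 1) * w, L)) for wi in range(n_windows)]
    lam = np.array(
        [scenario.coverage_mean * (hi - lo) / rl * mult[wi]
         for wi, (lo, hi) in enumerate(bounds)]
    )
    if n_reads is None:
        window_counts = rng.poisson(lam)
    else:
        # exact total: spread the fixed read budget over windows in
        # proportion to their amplification weight
        window_counts = rng.multinomial(n_reads, lam / lam.sum())
    for wi, (lo, hi) in enumerate(bounds):
        if window_counts[wi] == 0:
            continue
        lo_eff = min(lo, max_start)
        hi_eff = min(hi, max_start + 1)
        starts_parts.append(rng.integers(lo_eff, hi_eff, size=window_counts[wi]))
    starts = (
        np.concatenate(starts_parts).astype(np.int64)
        if starts_parts
        else np.empty(0, dtype=np.int64)
    )
    n = len(starts)

    k = len(scenario.cell_haplotype_ids)
    hap_choice = rng.choice(k, size=n, p=np.asarray(scenario.mixture_weights))
    hap_ids = np.asarray(scenario.cell_haplotype_ids)[hap_choice]
    hap_mat = np.vstack(
        [population.haplotype_codes(h) for h in scenario.cell_haplotype_ids]
    )

    offsets = np.arange(rl)[None, :]
    windows = starts[:, None] + offsets
    codes = hap_mat[hap_choice[:, None], windows]

    err = rng.random((n, rl)) < scenario.error_rate
    if err.any():
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        codes[err] = (codes[err] + shift) % 4
    lo_q, hi_q = scenario.correct_q
    quals = rng.integers(lo_q, hi_q + 1, size=(n, rl), dtype=np.uint8)
    if err.any():
        elo, ehi = scenario.error_q
        quals[err] = rng.integers(elo, ehi + 1, size=int(err.sum()), dtype=np.uint8)

    ref_codes = ref.codes
    nm = (codes != ref_codes[windows]).sum(axis=1).astype(np.int64)

    table = AlignmentTable.from_dense(
        read_id=np.array([f"{scenario.scenario_id}_r{i}" for i in range(n)], dtype=object),
        target_id=np.full(n, ref.genome_id, dtype=object),
        pos=starts,
        seq_codes=codes,
        qual_mat=quals,
        mapq=np.full(n, 60, dtype=np.int64),
        nm=nm,
    )
    truth = ReadTruth(haplotype=hap_ids, start=starts, n_errors=err.sum(axis=1))
    return table, truth


# ---------------------------------------------------------------------------
# Contig shredding (error-free paired reads)


def shred_contigs(
    contigs: list[tuple[str, str]],
    coverage: float = 20.0,
    insert_range: tuple[int, int] = (180, 400),
    read_length: int = 150,
    seed: int = 0,
) -> AlignmentTable:
    """Shred contigs into error-free read pairs at uniform positions.

    Pairs have insert sizes uniform in ``insert_range``; total read bases
    approximate coverage x contig length. Contigs shorter than the maximum
    insert are an error (precondition); contigs shorter than the read length
    are skipped with a warning.
    """
    import warnings

    rng = np.random.default_rng(seed)
    ids, tgts, poss, seq_rows, nm = [], [], [], [], []
    lo_ins, hi_ins = insert_range
    for cid, seq in contigs:
        clen = len(seq)
        if clen < read_length:
            warnings.warn(f"contig {cid} shorter than read length; skipped")
            continue
        if clen < hi_ins:
            raise ValueError(f"contig {cid} ({clen} bp) shorter than max insert {hi_ins}")
        codes = encode_seq(seq.upper())
        n_reads = math.ceil(coverage * clen / read_length)
        n_pairs = math.ceil(n_reads / 2)
        inserts = rng.integers(lo_ins, hi_ins + 1, size=n_pairs)
        starts = rng.integers(0, clen - inserts + 1)
        for pi in range(n_pairs):
            s, ins = int(starts[pi]), int(inserts[pi])
            for mate, rs in ((1, s), (2, s + ins - read_length)):
                ids.append(f"{cid}_p{pi}/{mate}")
                tgts.append(cid)
                poss.append(rs)
                seq_rows.append(codes[rs : rs + read_length])
                nm.append(0)
    n = len(ids)
    seq_codes = np.vstack(seq_rows) if n else np.empty((0, read_length), dtype=np.uint8)
    quals = np.full((n, read_length), 40, dtype=np.uint8)
    return AlignmentTable.from_dense(
        read_id=np.array(ids, dtype=object),
        target_id=np.array(tgts, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        seq_codes=seq_codes,
        qual_mat=quals,
        mapq=np.full(n, 60, dtype=np.int64),
        nm=np.asarray(nm, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Co-sorted host + symbiont mixtures


def single_genome_population(genome: AnnotatedGenome) -> HaplotypePopulation:
    """A degenerate single-haplotype 'population' (clonal; equals the
    reference). Used to represent a host cell."""
    variants = pd.DataFrame(
        {
            "pos": pd.Series(dtype=np.int64),
            "ref": pd.Series(dtype=object),
            "alt": pd.Series(dtype=object),
            "ref_code": pd.Series(dtype=np.uint8),
            "alt_code": pd.Series(dtype=np.uint8),
            "klass": pd.Series(dtype=object),
            "category": pd.Series(dtype=object),
            "freq": pd.Series(dtype=float),
        }
    )
    classes, _ = degeneracy_array(genome)
    return HaplotypePopulation(
        reference=genome,
        n_haplotypes=1,
        variants=variants,
        carriers=np.zeros((0, 1), dtype=bool),
        onefold_sites=int((classes == _CLASS_CODES[ONEFOLD]).sum()),
        fourfold_sites=max(int((classes == _CLASS_CODES[FOURFOLD]).sum()), 1),
    )


def simulate_cosort(
    symbiont_scenario: SagScenario,
    population: HaplotypePopulation,
    host_genome: AnnotatedGenome,
    host_read_fraction: float,
    seed: int = 0,
) -> tuple[AlignmentTable, pd.DataFrame]:
    """Mix symbiont reads with clonal host reads into a two-target table.

    The host contributes a binomial share ``host_read_fraction`` of the
    total read count; downstream modules see the table exactly as if a
    co-sorted SAG had been mapped against both genome bins. The returned
    truth frame labels every read with its true target.
    """
    if not (0 < host_read_fraction < 1):
        raise ValueError("host_read_fraction must lie strictly between 0 and 1")
    sym_aln, sym_truth = simulate_sag_reads(symbiont_scenario, population)
    rng = np.random.default_rng(seed)
    ns = len(sym_aln)
    total = round(ns / (1.0 - host_read_fraction))
    n_host = int(rng.binomial(total, host_read_fraction))
    host_cov = (
        n_host * symbiont_scenario.read_length / max(len(host_genome), 1)
    )
    host_pop = single_genome_population(host_genome)
    host_scenario = SagScenario(
        scenario_id=f"{symbiont_scenario.scenario_id}_host",
        cell_haplotype_ids=[0],
        coverage_mean=max(host_cov, 1e-6),
        error_rate=symbiont_scenario.error_rate,
        mda_bias=symbiont_scenario.mda_bias,
        window=symbiont_scenario.window,
        read_length=symbiont_scenario.read_length,
        seed=int(rng.integers(0, 2**31 - 1)),
        correct_q=symbiont_scenario.correct_q,
        error_q=symbiont_scenario.error_q,
    )
    host_aln, host_truth = simulate_sag_reads(host_scenario, host_pop, n_reads=n_host)
    combined = sym_aln.concat(host_aln)
    truth = pd.DataFrame(
        {
            "read_id": np.concatenate([sym_aln.read_id, host_aln.read_id]),
            "true_target": [population.reference.genome_id] * len(sym_aln)
            + [host_genome.genome_id] * len(host_aln),
            "haplotype": np.concatenate([sym_truth.haplotype, host_truth.haplotype]),
            "start": np.concatenate([sym_truth.start, host_truth.start]),
        }
    )
    return combined, truth


# ---------------------------------------------------------------------------
# Surface-protein heuristic

# Kyte-Doolittle hydropathy.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

TM_WINDOW = 19
TM_THRESHOLD = 1.6
NTERM_LIMIT = 60


def classify_surface_protein(protein_sequence: str) -> str:
    """'external' iff the protein has exactly one transmembrane-helix motif
    (mean Kyte-Doolittle >= 1.6 over a 19-residue window) and that motif
    starts within the first 60 residues; 'not_external' otherwise.

    Overlapping qualifying windows count as one motif. Sequences shorter
    than the window are 'not_external'.
    """
    seq = protein_sequence.upper().rstrip("*")
    if len(seq) < TM_WINDOW:
        return "not_external"
    try:
        scores = np.array([KYTE_DOOLITTLE[a] for a in seq], dtype=float)
    except KeyError as exc:
        raise ValueError(f"not an amino-acid sequence: unknown residue {exc}") from exc
    window_means = np.convolve(scores, np.ones(TM_WINDOW) / TM_WINDOW, mode="valid")
    hits = np.flatnonzero(window_means >= TM_THRESHOLD - 1e-12)
    if len(hits) == 0:
        return "not_external"
    # merge windows whose spans overlap into motifs
    motif_starts = [int(hits[0])]
    span_end = int(hits[0]) + TM_WINDOW
    for h in hits[1:]:
        if h < span_end:
            span_end = int(h) + TM_WINDOW
        else:
            motif_starts.append(int(h))
            span_end = int(h) + TM_WINDOW
    if len(motif_starts) != 1:
        return "not_external"
    return "external" if motif_starts[0] < NTERM_LIMIT else "not_external"
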