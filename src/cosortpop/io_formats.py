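"""Readers/writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; every 1-based
convention (SAM POS, GFF3, the SNP table on disk) is converted exactly once,
at the file boundary. Reverse-strand alignment records are assumed already
expressed in reference orientation (SAM convention) and are not
re-complemented.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Base encoding shared across the package: A=0 C=1 G=2 T=3, anything else
# (ambiguity codes) = 4. Positions whose reference code is 4 are excluded
# from SNP calling and from density denominators.
BASES = "ACGT"
N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode_seq(revcomp_codes(encode_seq(seq)))


# Per-residue region labels for membrane-protein topology.
REGION_INTERNAL = "I"
REGION_EXTERNAL = "E"
REGION_TRANSMEMBRANE = "T"


@dataclass
class GeneRecord:
    """A protein-coding gene on the reference, 0-based half-open.

    ``regions``, when present, is a string over {I, E, T} with one label per
    codon of the gene (internal / external / transmembrane topology of the
    encoded residue).
    """

    gene_id: str
    start: int
    end: int
    strand: str
    category: str = ""
    regions: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if self.regions is not None and len(self.regions) != (self.end - self.start) // 3:
            raise ValueError(
                f"gene {self.gene_id}: regions length {len(self.regions)} != "
                f"codon count {(self.end - self.start) // 3}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_codon_multiple(self) -> bool:
        return self.length % 3 == 0


@dataclass
class AnnotatedGenome:
    """Reference sequence plus gene annotations."""

    genome_id: str
    sequence: str
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        L = len(self.sequence)
        for g in self.genes:
            if g.start < 0 or g.end > L:
                raise ValueError(f"gene {g.gene_id} interval outside [0, {L})")
        ivals = sorted((g.start, g.end, g.gene_id) for g in self.genes)
        for (s1, e1, i1), (s2, e2, i2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                warnings.warn(f"genes {i1} and {i2} overlap; first containing gene wins")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        codes = getattr(self, "_codes", None)
        if codes is None:
            codes = self._codes = encode_seq(self.sequence)
        return codes

    def gene_sequence(self, gene: GeneRecord) -> str:
        """CDS in coding orientation."""
        sub = self.sequence[gene.start : gene.end]
        return sub if gene.strand == "+" else revcomp(sub)


class AlignmentTable:
    """Mapped-read records: the unit the alignment filters act on.

    Column-oriented: ``pos`` (0-based leftmost), ``mapq``, ``nm`` (edit
    distance, SAM NM), ``target_id``, ``cigar``, ``read_id`` are numpy
    arrays; sequences and qualities are kept as a dense (n, L) matrix when
    every read has the same length (the simulators' output), or as ragged
    lists otherwise. The dense path is what keeps genome-scale pileups fast.
    """

    def __init__(
        self,
        read_id: Sequence[str],
        target_id: Sequence[str],
        pos: np.ndarray,
        seq: Sequence[str] | None,
        qual: Sequence[np.ndarray] | None,
        mapq: np.ndarray,
        nm: np.ndarray,
        cigar: Sequence[str],
        seq_codes: np.ndarray | None = None,
        qual_mat: np.ndarray | None = None,
    ) -> None:
        n = len(pos)
        self.read_id = np.asarray(read_id, dtype=object)
        self.target_id = np.asarray(target_id, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.mapq = np.asarray(mapq, dtype=np.int64)
        self.nm = np.asarray(nm, dtype=np.int64)
        self.cigar = np.asarray(cigar, dtype=object)
        self._seq = list(seq) if seq is not None else None
        self._qual = list(qual) if qual is not None else None
        self._seq_codes = seq_codes  # (n, L) uint8 or None
        self._qual_mat = qual_mat  # (n, L) uint8 or None
        if self._seq is None and self._seq_codes is None:
            raise ValueError("need either ragged sequences or a dense matrix")
        for name, arr in (("read_id", self.read_id), ("target_id", self.target_id),
                          ("mapq", self.mapq), ("nm", self.nm), ("cigar", self.cigar)):
            if len(arr) != n:
                raise ValueError(f"column {name} has length {len(arr)} != {n}")
        if self._qual is not None:
            for s, q in zip(self.seq, self._qual):
                if len(q) != len(s):
                    raise ValueError("quality length differs from sequence length")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dense(
        cls,
        read_id: Sequence[str],
        target_id: Sequence[str],
        pos: np.ndarray,
        seq_codes: np.ndarray,
        qual_mat: np.ndarray,
        mapq: np.ndarray,
        nm: np.ndarray,
    ) -> "AlignmentTable":
        L = seq_codes.shape[1]
        cigar = np.full(len(pos), f"{L}M", dtype=object)
        return cls(read_id, target_id, pos, None, None, mapq, nm, cigar,
                   seq_codes=np.ascontiguousarray(seq_codes, dtype=np.uint8),
                   qual_mat=np.ascontiguousarray(qual_mat, dtype=np.uint8))

    # -- basic container protocol ------------------------------------------

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def seq(self) -> list[str]:
        if self._seq is None:
            self._seq = [decode_seq(row) for row in self._seq_codes]
        return self._seq

    @property
    def qual(self) -> list[np.ndarray]:
        if self._qual is None:
            self._qual = [row.copy() for row in self._qual_mat]
        return self._qual

    @property
    def dense(self) -> tuple[np.ndarray, np.ndarray] | None:
        """(seq_codes, qual_mat) if a uniform all-match dense form exists."""
        if self._seq_codes is not None:
            return self._seq_codes, self._qual_mat
        lengths = {len(s) for s in self._seq}
        if len(lengths) != 1:
            return None
        L = lengths.pop()
        if not all(c == f"{L}M" for c in self.cigar):
            return None
        codes = np.empty((len(self), L), dtype=np.uint8)
        quals = np.empty((len(self), L), dtype=np.uint8)
        for i, (s, q) in enumerate(zip(self._seq, self._qual)):
            codes[i] = encode_seq(s)
            quals[i] = q
        self._seq_codes, self._qual_mat = codes, quals
        return codes, quals

    def subset(self, index: np.ndarray) -> "AlignmentTable":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return AlignmentTable(
            self.read_id[index],
            self.target_id[index],
            self.pos[index],
            None if self._seq is None else [self._seq[i] for i in index],
            None if self._qual is None else [self._qual[i] for i in index],
            self.mapq[index],
            self.nm[index],
            self.cigar[index],
            seq_codes=None if self._seq_codes is None else self._seq_codes[index],
            qual_mat=None if self._qual_mat is None else self._qual_mat[index],
        )

    def for_target(self, target_id: str) -> "AlignmentTable":
        return self.subset(self.target_id == target_id)

    @property
    def targets(self) -> list[str]:
        return sorted(set(self.target_id.tolist()))

    def concat(self, other: "AlignmentTable") -> "AlignmentTable":
        a, b = self.dense, other.dense
        if a is not None and b is not None and a[0].shape[1] == b[0].shape[1]:
            return AlignmentTable.from_dense(
                np.concatenate([self.read_id, other.read_id]),
                np.concatenate([self.target_id, other.target_id]),
                np.concatenate([self.pos, other.pos]),
                np.vstack([a[0], b[0]]),
                np.vstack([a[1], b[1]]),
                np.concatenate([self.mapq, other.mapq]),
                np.concatenate([self.nm, other.nm]),
            )
        return AlignmentTable(
            np.concatenate([self.read_id, other.read_id]),
            np.concatenate([self.target_id, other.target_id]),
            np.concatenate([self.pos, other.pos]),
            self.seq + other.seq,
            self.qual + other.qual,
            np.concatenate([self.mapq, other.mapq]),
            np.concatenate([self.nm, other.nm]),
            np.concatenate([self.cigar, other.cigar]),
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse FASTA into (id, uppercased sequence) pairs.

    IDs are the first whitespace-delimited token of the header. A sequence
    line before any header is a parse error naming the line number.
    """
    records: list[tuple[str, str]] = []
    current_id: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current_id is not None:
                    records.append((current_id, "".join(chunks).upper()))
                current_id = line[1:].split()[0] if line[1:].split() else ""
                chunks = []
            else:
                if current_id is None:
                    raise ValueError(
                        f"{path}: sequence line before any FASTA header at line {lineno}"
                    )
                chunks.append(line)
    if current_id is not None:
        records.append((current_id, "".join(chunks).upper()))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM (documented subset: 11 mandatory columns + NM:i tag; header optional)

_SUPPORTED_CIGAR_OPS = set("MIDS=X")
_CIGAR_RE = re.compile(r"(\d+)([A-Z=])")

FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


def cigar_ops(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def reference_span(cigar: str) -> int:
    """Number of reference positions consumed by the alignment."""
    return sum(n for n, op in cigar_ops(cigar) if op in "MD=X")


def read_sam(path, target_ids: Sequence[str] | None = None) -> AlignmentTable:
    """Parse plain-text SAM into an AlignmentTable.

    Drops unmapped (0x4), secondary (0x100) and supplementary (0x800)
    records; converts POS to 0-based; rejects records lacking the NM tag and
    CIGAR operators outside {M, I, D, S, =, X}.
    """
    keep = set(target_ids) if target_ids is not None else None
    read_id, tgt, pos, seq, qual, mapq, nm, cigar = [], [], [], [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("@") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: SAM record with fewer than 11 columns")
            qname, flag_s, rname, pos_s, mapq_s, cig = fields[:6]
            flag = int(flag_s)
            if flag & (FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_SUPPLEMENTARY):
                continue
            if keep is not None and rname not in keep:
                continue
            ops = cigar_ops(cig)
            bad = {op for _, op in ops} - _SUPPORTED_CIGAR_OPS
            if bad:
                raise ValueError(
                    f"{path}:{lineno}: read {qname}: unsupported CIGAR op(s) {sorted(bad)}"
                )
            sam_seq, sam_qual = fields[9], fields[10]
            nm_value = None
            for tag in fields[11:]:
                if tag.startswith("NM:i:"):
                    nm_value = int(tag[5:])
                    break
            if nm_value is None:
                raise ValueError(f"{path}:{lineno}: read {qname} lacks the NM:i tag")
            read_id.append(qname)
            tgt.append(rname)
            pos.append(int(pos_s) - 1)  # 1-based -> 0-based
            mapq.append(int(mapq_s))
            nm.append(nm_value)
            cigar.append(cig)
            seq.append(sam_seq.upper())
            qual.append(
                np.frombuffer(sam_qual.encode("ascii"), dtype=np.uint8) - 33
            )
    return AlignmentTable(
        read_id, tgt, np.asarray(pos, dtype=np.int64), seq, qual,
        np.asarray(mapq, dtype=np.int64), np.asarray(nm, dtype=np.int64), cigar,
    )


def write_sam(aln: AlignmentTable, targets: dict[str, int], path) -> None:
    """Write an AlignmentTable as headered SAM (POS back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for tid, length in targets.items():
            fh.write(f"@SQ\tSN:{tid}\tLN:{length}\n")
        seqs = aln.seq
        quals = aln.qual
        for i in range(len(aln)):
            q = (quals[i] + 33).astype(np.uint8).tobytes().decode("ascii")
            fh.write(
                "\t".join(
                    [
                        str(aln.read_id[i]),
                        "0",
                        str(aln.target_id[i]),
                        str(aln.pos[i] + 1),
                        str(aln.mapq[i]),
                        str(aln.cigar[i]),
                        "*",
                        "0",
                        "0",
                        seqs[i],
                        q,
                        f"NM:i:{aln.nm[i]}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Gene tables (GFF3 1-based inclusive, or TSV 0-based half-open)


def _gene_from_fields(gene_id, start, end, strand, category, regions=None) -> GeneRecord:
    gene = GeneRecord(gene_id, start, end, strand, category, regions or None)
    return gene


def read_gene_table(path) -> list[GeneRecord]:
    """Read gene annotations from GFF3 or the documented TSV dialect.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open;
    the functional category is taken from a ``category=`` attribute. The TSV
    dialect (header line ``gene_id<TAB>start<TAB>...``) is already 0-based
    half-open. Coding genes whose length is not a multiple of 3 are retained
    with a warning; downstream degeneracy classing skips them.
    """
    genes: list[GeneRecord] = []
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if first.startswith("gene_id"):
            genes = _read_gene_tsv(fh, path)
        else:
            genes = _read_gene_gff3(fh, path)
    for g in genes:
        if not g.is_codon_multiple:
            warnings.warn(
                f"gene {g.gene_id}: length {g.length} not a multiple of 3; "
                "retained but excluded from degeneracy classing"
            )
    return genes


def _read_gene_tsv(fh, path) -> list[GeneRecord]:
    genes = []
    header = fh.readline().rstrip("\n").split("\t")
    idx = {name: i for i, name in enumerate(header)}
    for lineno, line in enumerate(fh, start=2):
        if not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        regions = f[idx["regions"]] if "regions" in idx and len(f) > idx["regions"] else None
        if regions == "":
            regions = None
        genes.append(
            _gene_from_fields(
                f[idx["gene_id"]],
                int(f[idx["start"]]),
                int(f[idx["end"]]),
                f[idx["strand"]],
                f[idx["category"]] if "category" in idx else "",
                regions,
            )
        )
    return genes


def _read_gene_gff3(fh, path) -> list[GeneRecord]:
    genes = []
    for lineno, line in enumerate(fh, start=1):
        if line.startswith("#") or not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 9:
            raise ValueError(f"{path}:{lineno}: GFF3 record with fewer than 9 columns")
        start_1, end_1, strand = int(f[3]), int(f[4]), f[6]
        attrs = dict(
            kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
        )
        gene_id = attrs.get("ID", attrs.get("Name", f"line{lineno}"))
        genes.append(
            _gene_from_fields(
                gene_id,
                start_1 - 1,  # 1-based inclusive -> 0-based half-open
                end_1,
                strand,
                attrs.get("category", ""),
                attrs.get("regions"),
            )
        )
    return genes


def write_gene_table(genes: Sequence[GeneRecord], path) -> None:
    """Write the documented TSV dialect (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tstart\tend\tstrand\tcategory\tregions\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}\t{g.category}\t"
                f"{g.regions or ''}\n"
            )


# ---------------------------------------------------------------------------
# SNP tables

SNP_COLUMNS = [
    "target_id",
    "pos",
    "ref_allele",
    "major_allele",
    "minor_allele",
    "minor_count",
    "depth_used",
    "maf",
    "degeneracy_class",
    "gene_id",
]


def empty_snp_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "target_id": pd.Series(dtype=object),
            "pos": pd.Series(dtype=np.int64),
            "ref_allele": pd.Series(dtype=object),
            "major_allele": pd.Series(dtype=object),
            "minor_allele": pd.Series(dtype=object),
            "minor_count": pd.Series(dtype=np.int64),
            "depth_used": pd.Series(dtype=np.int64),
            "maf": pd.Series(dtype=float),
            "degeneracy_class": pd.Series(dtype=object),
            "gene_id": pd.Series(dtype=object),
        }
    )


def write_snp_table(snps: pd.DataFrame, path) -> None:
    """Write a SNP table as TSV with 1-based positions."""
    out = snps.loc[:, SNP_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_snp_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: object for c in
                                            ("target_id", "ref_allele", "major_allele",
                                             "minor_allele", "degeneracy_class", "gene_id")})
    df["pos"] = df["pos"].astype(np.int64) - 1
    df["minor_count"] = df["minor_count"].astype(np.int64)
    df["depth_used"] = df["depth_used"].astype(np.int64)
    df["maf"] = df["maf"].astype(float)
    df["gene_id"] = df["gene_id"].where(df["gene_id"].notna(), None)
    return df.loc[:, SNP_COLUMNS]


# ---------------------------------------------------------------------------
# Newick trees


def read_newick(path):
    """Read a newick tree (dendropy). Duplicate leaf labels are an error.

    If any edge lacks a branch length the tree is flagged topology-only
    (``tree.topology_only = True``) and patristic distances are unavailable.
    """
    import dendropy

    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate leaf labels in tree: {exc}") from exc
    tree.is_rooted = True  # MRCA queries treat the seed node as root
    missing_lengths = any(
        e.length is None for e in tree.preorder_edge_iter() if e.head_node.parent_node is not None
    )
    tree.topology_only = missing_lengths
    return tree


def tree_leaf_labels(tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def patristic_distance(tree, label_a: str, label_b: str) -> float:
    if getattr(tree, "topology_only", False):
        raise ValueError("tree has missing branch lengths (topology-only mode)")
    pdm = getattr(tree, "_pdm", None)
    if pdm is None:
        pdm = tree._pdm = tree.phylogenetic_distance_matrix()
    ta = tree.taxon_namespace.get_taxon(label_a)
    tb = tree.taxon_namespace.get_taxon(label_b)
    if ta is None or tb is None:
        raise KeyError(f"taxon not in tree: {label_a if ta is None else label_b}")
    return pdm.patristic_distance(ta, tb)
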