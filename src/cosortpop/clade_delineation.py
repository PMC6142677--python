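"""Species-clade delineation from three lines of evidence.

Two genome bins are grouped when at least two of three criteria pass with
none failing: >= 98% 16S rRNA gene identity, >= 95% ANI over >= 20 kb of
aligned length, and the ribosomal-protein tree criterion (mutual nearest
neighbours, or a branch containing only clade members). After seeding,
unassigned bins are extended into clades on ANI alone provided no criterion
conflicts — missing data is tolerated, conflicting data is not. ANI
evidence with less than 20 kb aligned is insufficient (MISSING), never a
numeric failure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .io_formats import encode_seq, patristic_distance, tree_leaf_labels


class Criterion(str, Enum):
    PASS = "PASS"
    FAIL = "FAIL"
    MISSING = "MISSING"


MISSING = None  # sentinel for absent numeric evidence

NO_CLADE = "NO_CLADE"


@dataclass
class CladeEvidence:
    """Pairwise evidence for one unordered genome pair."""

    id_a: str
    id_b: str
    s16_identity: float | None = None  # percent, or None when missing
    ani_value: float | None = None  # percent, or None when missing
    ani_aligned_length: int = 0
    tree_relation: Criterion | None = None  # PASS/FAIL, or None when missing

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.id_a, self.id_b)))


@dataclass
class CladeAssignment:
    assignments: dict[str, str]  # genome_id -> clade label or NO_CLADE
    trail: dict[tuple[str, str], dict[str, str]] = field(default_factory=dict)

    def clade_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gid, label in sorted(self.assignments.items()):
            if label != NO_CLADE:
                out.setdefault(label, []).append(gid)
        return out


# ---------------------------------------------------------------------------
# 16S identity


def pairwise_16s_identity(aligned_a: str, aligned_b: str) -> float | None:
    """Percent identity over columns where both sequences are non-gap.

    Returns None (missing evidence) when no comparable columns exist.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    a = np.frombuffer(aligned_a.upper().encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(aligned_b.upper().encode("ascii"), dtype=np.uint8)
    gap_chars = np.frombuffer(b"-.", dtype=np.uint8)
    comparable = ~np.isin(a, gap_chars) & ~np.isin(b, gap_chars)
    n = int(comparable.sum())
    if n == 0:
        return None
    matches = int((a[comparable] == b[comparable]).sum())
    return 100.0 * matches / n


# ---------------------------------------------------------------------------
# ANIb-style average nucleotide identity (seeded banded aligner, no BLAST)


def _kmer_index(codes: np.ndarray, k: int) -> dict[int, list[int]]:
    if len(codes) < k:
        return {}
    # rolling integer k-mers over the 2-bit alphabet; windows containing
    # ambiguous bases are skipped
    valid = codes < 4
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), k)
    kmers = (windows * weights).sum(axis=1)
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    index: dict[int, list[int]] = {}
    for pos in np.flatnonzero(ok):
        index.setdefault(int(kmers[pos]), []).append(int(pos))
    return index


def _align_fragment(
    frag: np.ndarray,
    subject: np.ndarray,
    subject_index: dict[int, list[int]],
    k: int,
    pad: int = 60,
) -> tuple[float, int] | None:
    """Best banded alignment of a query fragment against the subject.

    Seeds exact shared k-mers, votes for the best diagonal, and computes the
    edit distance of the fragment against a subject window around that
    diagonal (edlib infix mode). Returns (identity, aligned_length) or None
    when no seed exists (the fragment has no detectable homolog).
    """
    import edlib

    if len(frag) < k:
        return None
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(frag.astype(np.int64), k)
    kmers = (windows * weights).sum(axis=1)
    valid = np.lib.stride_tricks.sliding_window_view(frag < 4, k).all(axis=1)
    votes: dict[int, int] = {}
    step = max(1, k // 3)
    for qpos in range(0, len(kmers), step):
        if not valid[qpos]:
            continue
        for spos in subject_index.get(int(kmers[qpos]), ()):
            diag = spos - qpos
            votes[diag] = votes.get(diag, 0) + 1
    if not votes:
        return None
    diag = max(sorted(votes), key=lambda d: votes[d])
    lo = max(0, diag - pad)
    hi = min(len(subject), diag + len(frag) + pad)
    window = subject[lo:hi]
    res = edlib.align(
        frag.tobytes(), window.tobytes(), mode="HW", task="distance"
    )
    dist = res["editDistance"]
    if dist < 0:
        return None
    identity = 1.0 - dist / len(frag)
    return identity, len(frag)


def anib(
    genome_a: str,
    genome_b: str,
    fragment: int = 1020,
    min_frag_identity: float = 0.30,
    min_frag_coverage: float = 0.70,
    seed_k: int = 15,
    min_fragment_len: int = 100,
) -> tuple[float | None, int]:
    """Fragment-based average nucleotide identity, symmetrised.

    The query is cut into consecutive ``fragment``-bp pieces, each aligned
    to the subject with the seeded banded aligner. Fragments are retained
    iff identity >= ``min_frag_identity`` and the alignment covers >=
    ``min_frag_coverage`` of the fragment (seeded alignments consume the
    whole fragment; unseeded fragments have zero coverage and drop out —
    this is what leaves unrelated genome pairs without sufficient aligned
    length). Returns (ANI percent or None, aligned length in bp), the mean
    of both directions.
    """
    a = encode_seq(genome_a.upper())
    b = encode_seq(genome_b.upper())
    if len(a) < min_fragment_len or len(b) < min_fragment_len:
        raise ValueError("genomes must be at least one fragment long")
    results = []
    for query, subject in ((a, b), (b, a)):
        index = _kmer_index(subject, seed_k)
        idents: list[float] = []
        aligned = 0
        for start in range(0, len(query), fragment):
            frag = query[start : start + fragment]
            if len(frag) < min_fragment_len:
                continue
            hit = _align_fragment(frag, subject, index, seed_k)
            if hit is None:
                continue
            identity, aln_len = hit
            if identity >= min_frag_identity and aln_len / len(frag) >= min_frag_coverage:
                idents.append(identity)
                aligned += aln_len
        results.append((idents, aligned))
    if not results[0][0] and not results[1][0]:
        return None, 0
    ani_dirs = [100.0 * float(np.mean(ids)) for ids, _ in results if ids]
    aligned_dirs = [al for _, al in results]
    return float(np.mean(ani_dirs)), int(round(float(np.mean(aligned_dirs))))


# ---------------------------------------------------------------------------
# Tree criterion


def tree_criterion(tree, member_ids: list[str]) -> Criterion:
    """PASS if the members are mutual nearest leaves (pairs) or form a
    branch containing only members; MISSING if any member is absent."""
    leaves = tree_leaf_labels(tree)
    members = sorted(set(member_ids))
    if any(m not in leaves for m in members):
        return Criterion.MISSING
    if len(members) < 2:
        return Criterion.PASS
    if len(members) == 2 and not getattr(tree, "topology_only", False):
        a, b = members
        if _mutual_nearest(tree, a, b, leaves):
            return Criterion.PASS
    # smallest clade (monophyletic group) containing all members
    taxa = [tree.taxon_namespace.get_taxon(m) for m in members]
    mrca = tree.mrca(taxa=taxa)
    clade_leaves = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    return Criterion.PASS if clade_leaves <= set(members) else Criterion.FAIL


def _mutual_nearest(tree, a: str, b: str, leaves: set[str]) -> bool:
    def nearest(x: str) -> float:
        return min(patristic_distance(tree, x, other) for other in leaves if other != x)

    dab = patristic_distance(tree, a, b)
    return dab <= nearest(a) + 1e-12 and dab <= nearest(b) + 1e-12


# ---------------------------------------------------------------------------
# Criterion evaluation and the 2-of-3 rule


def evaluate_pair(
    evidence: CladeEvidence,
    s16_min: float = 98.0,
    ani_min: float = 95.0,
    ani_min_aligned: int = 20_000,
) -> dict[str, Criterion]:
    """Map pairwise evidence to per-criterion PASS/FAIL/MISSING.

    Thresholds are inclusive (>=). ANI with less than ``ani_min_aligned``
    aligned bp is MISSING (insufficient alignment), never FAIL.
    """
    out: dict[str, Criterion] = {}
    if evidence.s16_identity is None:
        out["s16"] = Criterion.MISSING
    else:
        out["s16"] = Criterion.PASS if evidence.s16_identity >= s16_min - 1e-9 else Criterion.FAIL
    if evidence.ani_value is None or evidence.ani_aligned_length < ani_min_aligned:
        out["ani"] = Criterion.MISSING
    else:
        out["ani"] = Criterion.PASS if evidence.ani_value >= ani_min - 1e-9 else Criterion.FAIL
    out["tree"] = evidence.tree_relation if evidence.tree_relation is not None else Criterion.MISSING
    return out


def delineate_clades(
    all_evidence: list[CladeEvidence],
    genome_ids: list[str],
    s16_min: float = 98.0,
    ani_min: float = 95.0,
    ani_min_aligned: int = 20_000,
) -> CladeAssignment:
    """Group genomes by the 2-of-3 rule, then extend on ANI alone.

    Phase 1 (seeding): pairs with >= 2 PASS and 0 FAIL link genomes; linked
    components merge transitively, and any FAIL between two members of one
    component is a conflict that demands manual resolution (error). Phase 2
    (extension): an unassigned genome joins a clade iff its ANI criterion is
    PASS against at least one member and no criterion is FAIL against any
    member; a genome qualifying for two clades is an error. Processing order
    is lexicographic in genome ids, so the partition is order-invariant.
    """
    import networkx as nx

    ids = sorted(set(genome_ids))
    status: dict[tuple[str, str], dict[str, Criterion]] = {}
    for ev in all_evidence:
        key = ev.pair
        status[key] = evaluate_pair(ev, s16_min, ani_min, ani_min_aligned)
    all_missing = {
        "s16": Criterion.MISSING, "ani": Criterion.MISSING, "tree": Criterion.MISSING
    }
    for pair in itertools.combinations(ids, 2):
        status.setdefault(pair, dict(all_missing))

    def n_pass(st) -> int:
        return sum(1 for v in st.values() if v == Criterion.PASS)

    def n_fail(st) -> int:
        return sum(1 for v in st.values() if v == Criterion.FAIL)

    g = nx.Graph()
    g.add_nodes_from(ids)
    for (a, b), st in status.items():
        if n_pass(st) >= 2 and n_fail(st) == 0:
            g.add_edge(a, b)
    components = [sorted(c) for c in nx.connected_components(g) if len(c) > 1]
    components.sort()
    for comp in components:
        for a, b in itertools.combinations(comp, 2):
            if n_fail(status[(a, b)]) > 0:
                raise ValueError(
                    f"conflicting evidence inside candidate clade {comp}: pair "
                    f"({a}, {b}) has a failed criterion; manual resolution required"
                )

    assignments = {gid: NO_CLADE for gid in ids}
    members: dict[str, list[str]] = {}
    for i, comp in enumerate(components, start=1):
        label = f"clade{i}"
        members[label] = list(comp)
        for gid in comp:
            assignments[gid] = label

    # Phase 2: extension by ANI, conflicts blocking
    for gid in ids:
        if assignments[gid] != NO_CLADE:
            continue
        qualifying = []
        for label, mem in sorted(members.items()):
            ani_pass = False
            conflict = False
            for m in mem:
                st = status[tuple(sorted((gid, m)))]
                if st["ani"] == Criterion.PASS:
                    ani_pass = True
                if n_fail(st) > 0:
                    conflict = True
            if ani_pass and not conflict:
                qualifying.append(label)
        if len(qualifying) > 1:
            raise ValueError(
                f"genome {gid} qualifies for clades {qualifying}; manual resolution required"
            )
        if qualifying:
            label = qualifying[0]
            assignments[gid] = label
            members[label].append(gid)

    trail = {
        pair: {k: v.value for k, v in st.items()} for pair, st in sorted(status.items())
    }
    return CladeAssignment(assignments=assignments, trail=trail)
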