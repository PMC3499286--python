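"""EST processing: quality filtering, low-complexity masking, a greedy
clustering stand-in for a CAP3-style assembler, contig statistics, clone
selection, and the closed-form detection-miss probability.

The clusterer is deliberately simple (ungapped single-linkage on shared
seeds); it produces structurally faithful contigs — member lists with
consensus offsets — for the downstream selection logic, and makes no
claim to reproduce a production assembler's output on real data.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field

from .io_formats import QualityTrack, SeqRecord

__all__ = [
    "Contig",
    "CloneSelection",
    "quality_filter",
    "mask_low_complexity",
    "cluster_ests",
    "contig_size_distribution",
    "select_clones",
    "detection_miss_probability",
]

MIN_QUALITY_RUN = 100   # a kept read needs a run of MORE than this many bases
MIN_QUALITY = 10        # ... each with Phred quality >= this


@dataclass
class Contig:
    """An assembled cluster of >= 2 ESTs with per-member consensus offsets."""

    contig_id: str
    member_read_ids: list[str]           # ordered 5'-most first
    consensus_length: int
    member_offsets: dict[str, int]       # read id -> 0-based start in consensus
    consensus: str = ""

    def __post_init__(self) -> None:
        if len(self.member_read_ids) < 2:
            raise ValueError("a contig needs >=2 members (singletons are singlets)")
        for rid in self.member_read_ids:
            off = self.member_offsets[rid]
            if not (0 <= off < self.consensus_length):
                raise ValueError(f"offset of {rid} outside consensus")


@dataclass
class CloneSelection:
    selected_from_contigs: list[str] = field(default_factory=list)
    selected_from_singlets: list[str] = field(default_factory=list)
    reason: dict[str, str] = field(default_factory=dict)


def quality_filter(read: SeqRecord, qualities: QualityTrack) -> bool:
    """Keep a read iff it has a contiguous run of strictly more than
    ``MIN_QUALITY_RUN`` bases, each with quality >= ``MIN_QUALITY``.

    The boundary is strict: a run of exactly 100 such bases is discarded.
    """
    if len(read.sequence) != len(qualities.qualities):
        raise ValueError(
            f"read {read.id!r}: sequence length {len(read.sequence)} != "
            f"quality length {len(qualities.qualities)}"
        )
    run = 0
    for q in qualities.qualities:
        if q >= MIN_QUALITY:
            run += 1
            if run > MIN_QUALITY_RUN:
                return True
        else:
            run = 0
    return False


_HOMOPOLYMER = re.compile(r"([ACGTN])\1{11,}")  # runs >= 12


def mask_low_complexity(sequence: str, homopolymer_min: int = 12,
                        dinucleotide_min_units: int = 8) -> str:
    """Lowercase homopolymer runs >= 12 and dinucleotide repeats >= 8
    units (poly(A)-tract style screening); length is preserved."""
    chars = list(sequence)
    n = len(sequence)
    # homopolymers
    i = 0
    while i < n:
        j = i
        while j < n and sequence[j] == sequence[i]:
            j += 1
        if j - i >= homopolymer_min:
            for p in range(i, j):
                chars[p] = chars[p].lower()
        i = j
    # dinucleotide repeats (two distinct bases)
    i = 0
    while i < n - 1:
        a, b = sequence[i], sequence[i + 1]
        if a == b:
            i += 1
            continue
        j = i
        while j + 1 < n and sequence[j] == a and sequence[j + 1] == b:
            j += 2
        units = (j - i) // 2
        if units >= dinucleotide_min_units:
            for p in range(i, i + 2 * units):
                chars[p] = chars[p].lower()
            i = i + 2 * units
        else:
            i += 1
    return "".join(chars)


def _seed_positions(masked: str, k: int, stride: int) -> list[tuple[str, int]]:
    """Strided seeds drawn only from fully-uppercase (unmasked) windows."""
    out = []
    for p in range(0, len(masked) - k + 1, stride):
        w = masked[p:p + k]
        if w.isupper() and "N" not in w:
            out.append((w, p))
    return out


def _ungapped_identity(a: str, b: str, a_off: int, b_off: int) -> tuple[int, float]:
    """Overlap length and identity of two reads placed on one diagonal
    (read b starts ``b_off - a_off`` columns right of read a).

    Callers pass pre-uppercased sequences; masking case is ignored here.
    """
    d = b_off - a_off
    start = max(0, d)
    end = min(len(a), d + len(b))
    if end <= start:
        return 0, 0.0
    m = sum(x == y for x, y in zip(a[start:end], b[start - d:end - d]))
    return end - start, m / (end - start)


def cluster_ests(
    reads: list[SeqRecord],
    min_overlap: int = 40,
    min_identity: float = 0.95,
    seed_k: int = 16,
) -> tuple[list[Contig], list[str]]:
    """Greedy single-linkage clustering on ungapped overlaps.

    Two reads link when a shared unmasked seed places them on a diagonal
    whose implied overlap is >= ``min_overlap`` bases at >=
    ``min_identity``.  Seeding is strided (index every seed_k-th window,
    probe every seed_k//4-th), which still guarantees a hit for any
    exact shared stretch of at least 2*seed_k - 1 on any diagonal; once
    two reads are in the same component further pairs are skipped, so
    the link graph is a spanning forest and offsets propagate
    consistently.  Offsets come from pairwise diagonals; consensus is a
    per-column majority vote.  Deterministic under input order.
    """
    n = len(reads)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    index: dict[str, list[tuple[int, int]]] = defaultdict(list)
    # read index -> {other index: diagonal offset of other relative to self}
    links: dict[int, dict[int, int]] = defaultdict(dict)
    upper = [r.sequence.upper() for r in reads]
    for i, read in enumerate(reads):
        failed: set[tuple[int, int]] = set()
        for w, p in _seed_positions(read.sequence, seed_k, 1):
            for j, pj in index.get(w, ()):
                if find(i) == find(j):
                    continue
                d = pj - p  # read i starts d columns right of read j's start
                if (j, d) in failed:
                    continue
                ov, ident = _ungapped_identity(upper[j], upper[i], 0, d)
                if ov >= min_overlap and ident >= min_identity:
                    parent[max(find(i), find(j))] = min(find(i), find(j))
                    links[i][j] = -d
                    links[j][i] = d
                else:
                    failed.add((j, d))
        for w, p in _seed_positions(read.sequence, seed_k, seed_k):
            index[w].append((i, p))

    components: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        components[find(i)].append(i)

    contigs: list[Contig] = []
    singlets: list[str] = []
    contig_no = 0
    for root in sorted(components):
        members = components[root]
        if len(members) == 1:
            singlets.append(reads[members[0]].id)
            continue
        # propagate offsets by BFS over the link graph from the first member
    # (diagonals compose additively along any path in a consistent layout)
        offsets = {members[0]: 0}
        queue = [members[0]]
        while queue:
            u = queue.pop(0)
            for v, d in sorted(links[u].items()):
                if v not in offsets:
                    offsets[v] = offsets[u] + d
                    queue.append(v)
        shift = -min(offsets.values())
        offsets = {k: v + shift for k, v in offsets.items()}
        length = max(offsets[m] + len(reads[m].sequence) for m in members)
        votes: list[dict[str, int]] = [defaultdict(int) for _ in range(length)]
        for m in members:
            off = offsets[m]
            for p, c in enumerate(upper[m]):
                votes[off + p][c] += 1
        consensus = "".join(
            max(sorted(v), key=lambda c: v[c]) if v else "N" for v in votes
        )
        contig_no += 1
        ordered = sorted(members, key=lambda m: (offsets[m], -len(reads[m].sequence), reads[m].id))
        contigs.append(
            Contig(
                contig_id=f"contig{contig_no:05d}",
                member_read_ids=[reads[m].id for m in ordered],
                consensus_length=length,
                member_offsets={reads[m].id: offsets[m] for m in ordered},
                consensus=consensus,
            )
        )
    return contigs, singlets


def contig_size_distribution(contigs: list[Contig]) -> dict:
    """Integer histogram of contig sizes plus the summary bins used in
    project reports (contigs with <20 members and >=30 members)."""
    hist: dict[int, int] = {}
    for c in contigs:
        hist[len(c.member_read_ids)] = hist.get(len(c.member_read_ids), 0) + 1
    return {
        "histogram": dict(sorted(hist.items())),
        "n_lt_20": sum(v for k, v in hist.items() if k < 20),
        "n_ge_30": sum(v for k, v in hist.items() if k >= 30),
    }


def select_clones(
    contigs: list[Contig],
    singlets: list[str],
    gene_hits: dict[str, str] | None = None,
    read_lengths: dict[str, int] | None = None,
    previous: CloneSelection | None = None,
) -> CloneSelection:
    """Pick clones for full-insert sequencing.

    Per contig the 5'-most member (minimal consensus offset; ties go to
    the longer read, then lexicographic id) is the *forefront* pick.
    When re-run incrementally with a ``previous`` selection, a member now
    upstream of an existing pick is appended with reason
    ``upstream_update`` without dropping prior picks.  Singlets whose
    assigned gene is not already covered by a contig-derived pick are
    added with reason ``novel_gene_singlet``.
    """
    gene_hits = gene_hits or {}
    read_lengths = read_lengths or {}
    sel = CloneSelection()
    if previous is not None:
        sel.selected_from_contigs = list(previous.selected_from_contigs)
        sel.selected_from_singlets = list(previous.selected_from_singlets)
        sel.reason = dict(previous.reason)
    already = set(sel.selected_from_contigs) | set(sel.selected_from_singlets)

    for contig in contigs:
        best = min(
            contig.member_read_ids,
            key=lambda r: (
                contig.member_offsets[r],
                -read_lengths.get(r, 0),
                r,
            ),
        )
        if best in already:
            continue
        prior_offsets = [
            contig.member_offsets[r]
            for r in contig.member_read_ids
            if r in already
        ]
        if prior_offsets:
            if contig.member_offsets[best] < min(prior_offsets):
                sel.selected_from_contigs.append(best)
                sel.reason[best] = "upstream_update"
                already.add(best)
        else:
            sel.selected_from_contigs.append(best)
            sel.reason[best] = "forefront"
            already.add(best)

    covered_genes = {gene_hits[r] for r in sel.selected_from_contigs if r in gene_hits}
    for rid in singlets:
        gene = gene_hits.get(rid)
        if gene is None or gene in covered_genes or rid in already:
            continue
        sel.selected_from_singlets.append(rid)
        sel.reason[rid] = "novel_gene_singlet"
        covered_genes.add(gene)
        already.add(rid)
    return sel


def detection_miss_probability(freq: float, n_clones: int) -> float:
    """Probability that a transcript with expression frequency ``freq``
    is absent from a sample of ``n_clones`` cloned transcripts:
    ``(1 - freq) ** n_clones``."""
    if not (0.0 <= freq <= 1.0):
        raise ValueError(f"freq must be in [0,1], got {freq}")
    if n_clones < 0:
        raise ValueError(f"n_clones must be >=0, got {n_clones}")
    return (1.0 - freq) ** n_clones
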