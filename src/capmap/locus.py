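"""Transcript-to-genome locus assignment.

The algorithm anchors each query's best alignment (score > 100 and
identity > 90%, both strict), extends the locus region with other
alignments of the same query on the same subject and strand whenever the
genomic gap to the growing region is under 1 Mb (iterated to fixpoint,
so serial introns chain), and finally merges per-query loci that overlap
on the same strand.  Opposite-strand overlaps remain distinct loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import AlignmentRecord

__all__ = [
    "LocusCall",
    "MappingThresholds",
    "select_anchor",
    "extend_locus",
    "merge_loci",
    "call_loci",
    "tabulate_loci",
    "locus_density",
]


@dataclass
class MappingThresholds:
    """Anchoring and extension thresholds (score/identity strict)."""

    min_score: float = 100.0
    min_identity_pct: float = 90.0
    max_gap: int = 1_000_000

    def __post_init__(self) -> None:
        if self.min_score <= 0 or self.min_identity_pct <= 0 or self.max_gap <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class LocusCall:
    """A strand-oriented genomic interval owning its anchored queries."""

    locus_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    member_query_ids: set[str] = field(default_factory=set)
    is_unplaced_scaffold: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"locus {self.locus_id}: empty interval")
        if not self.member_query_ids:
            raise ValueError(f"locus {self.locus_id}: empty member set")


def select_anchor(
    alignments_of_query: list[AlignmentRecord],
    thresholds: MappingThresholds = MappingThresholds(),
) -> AlignmentRecord | None:
    """Best qualifying alignment of one query, or None if unmapped.

    Qualification is strict: score > min_score AND identity >
    min_identity_pct.  Ties on score break by identity, then alignment
    length, then smallest (subject_id, sstart).
    """
    qids = {a.query_id for a in alignments_of_query}
    if len(qids) > 1:
        raise ValueError(f"mixed query ids in anchor selection: {sorted(qids)}")
    qualifying = [
        a for a in alignments_of_query
        if a.score > thresholds.min_score
        and a.percent_identity > thresholds.min_identity_pct
    ]
    if not qualifying:
        return None
    return max(
        qualifying,
        key=lambda a: (a.score, a.percent_identity, a.aln_length,
                       _neg_str(a.subject_id), -a.sstart),
    )


class _neg_str(str):
    """Reverses string comparison so max() prefers the smallest subject id."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def _gap(lo1: int, hi1: int, lo2: int, hi2: int) -> int:
    """Genomic gap between two intervals; 0 when they overlap or abut."""
    if hi1 <= lo2:
        return lo2 - hi1
    if hi2 <= lo1:
        return lo1 - hi2
    return 0


def extend_locus(
    anchor: AlignmentRecord,
    alignments_of_query: list[AlignmentRecord],
    thresholds: MappingThresholds = MappingThresholds(),
    scaffold_prefix: str = "scaffold",
) -> LocusCall:
    """Grow the locus region from the anchor to fixpoint.

    Same-query alignments on the anchor's subject and strand are
    absorbed whenever their genomic distance to the current hull is
    strictly under ``max_gap``; absorption can bridge to further
    alignments (introns are serial).
    """
    start, end = anchor.sstart, anchor.send
    candidates = [
        a for a in alignments_of_query
        if a is not anchor
        and a.query_id == anchor.query_id
        and a.subject_id == anchor.subject_id
        and a.strand == anchor.strand
    ]
    changed = True
    while changed:
        changed = False
        remaining = []
        for a in candidates:
            if _gap(start, end, a.sstart, a.send) < thresholds.max_gap:
                start = min(start, a.sstart)
                end = max(end, a.send)
                changed = True
            else:
                remaining.append(a)
        candidates = remaining
    return LocusCall(
        locus_id=f"locus_{anchor.query_id}",
        chromosome=anchor.subject_id,
        start=start,
        end=end,
        strand=anchor.strand,
        member_query_ids={anchor.query_id},
        is_unplaced_scaffold=anchor.subject_id.startswith(scaffold_prefix),
    )


def merge_loci(locus_calls: list[LocusCall]) -> list[LocusCall]:
    """Transitive closure of the overlap-and-same-strand relation.

    Implemented as a sort-and-sweep per (chromosome, strand); merged
    intervals take the union hull and the union of member sets.  Output
    order is deterministic: (chromosome, start, strand).  Idempotent and
    permutation-invariant.
    """
    groups: dict[tuple[str, str], list[LocusCall]] = {}
    for lc in locus_calls:
        groups.setdefault((lc.chromosome, lc.strand), []).append(lc)

    merged: list[LocusCall] = []
    for (chrom, strand), group in groups.items():
        group = sorted(group, key=lambda l: (l.start, l.end))
        cur_start, cur_end = group[0].start, group[0].end
        cur_members = set(group[0].member_query_ids)
        cur_unplaced = group[0].is_unplaced_scaffold
        for lc in group[1:]:
            if lc.start < cur_end:  # strict overlap; abutting stays separate
                cur_end = max(cur_end, lc.end)
                cur_members |= lc.member_query_ids
            else:
                merged.append(LocusCall("", chrom, cur_start, cur_end, strand,
                                        cur_members, cur_unplaced))
                cur_start, cur_end = lc.start, lc.end
                cur_members = set(lc.member_query_ids)
        merged.append(LocusCall("", chrom, cur_start, cur_end, strand,
                                cur_members, cur_unplaced))

    merged.sort(key=lambda l: (l.chromosome, l.start, l.strand))
    for i, lc in enumerate(merged, start=1):
        lc.locus_id = f"L{i:06d}"
    return merged


def call_loci(
    alignments: list[AlignmentRecord],
    thresholds: MappingThresholds = MappingThresholds(),
    scaffold_prefix: str = "scaffold",
) -> tuple[list[LocusCall], list[str]]:
    """Full anchor/extend/merge chain over a mixed alignment list.

    Returns (merged loci, unmapped query ids).  Queries keep their input
    first-appearance order for the unmapped list.
    """
    by_query: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        by_query.setdefault(a.query_id, []).append(a)
    per_query: list[LocusCall] = []
    unmapped: list[str] = []
    for qid, alns in by_query.items():
        anchor = select_anchor(alns, thresholds)
        if anchor is None:
            unmapped.append(qid)
            continue
        per_query.append(extend_locus(anchor, alns, thresholds, scaffold_prefix))
    return merge_loci(per_query), unmapped


def tabulate_loci(loci: list[LocusCall], chromosomes: list[str] | None = None) -> pd.DataFrame:
    """Per-chromosome forward/reverse/total locus counts with a separate
    unplaced-scaffolds row and a totals row equal to the column sums."""
    rows: dict[str, dict[str, int]] = {}
    order: list[str] = list(chromosomes) if chromosomes else []
    for name in order:
        rows[name] = {"forward": 0, "reverse": 0}
    for lc in loci:
        key = "Unplaced scaffolds" if lc.is_unplaced_scaffold else lc.chromosome
        if key not in rows:
            rows[key] = {"forward": 0, "reverse": 0}
            if key != "Unplaced scaffolds":
                order.append(key)
        rows[key]["forward" if lc.strand == "+" else "reverse"] += 1
    if "Unplaced scaffolds" not in rows:
        rows["Unplaced scaffolds"] = {"forward": 0, "reverse": 0}
    order = [c for c in order if c != "Unplaced scaffolds"] + ["Unplaced scaffolds"]
    table = pd.DataFrame(
        [
            {
                "chromosome": name,
                "forward": rows[name]["forward"],
                "reverse": rows[name]["reverse"],
                "total": rows[name]["forward"] + rows[name]["reverse"],
            }
            for name in order
        ]
    )
    totals = {
        "chromosome": "Total",
        "forward": int(table["forward"].sum()),
        "reverse": int(table["reverse"].sum()),
        "total": int(table["total"].sum()),
    }
    return pd.concat([table, pd.DataFrame([totals])], ignore_index=True)


def locus_density(
    loci: list[LocusCall],
    chrom_lengths: dict[str, int],
    window: int = 5_000_000,
    step: int = 100_000,
) -> pd.DataFrame:
    """Sliding-window locus counts per strand.

    For each window [i*step, i*step + window), clipped at the chromosome
    end, count the loci whose interval intersects the window; forward
    and reverse tracks are reported separately.
    """
    by_chrom: dict[str, list[LocusCall]] = {}
    for lc in loci:
        by_chrom.setdefault(lc.chromosome, []).append(lc)
    rows = []
    for chrom, length in chrom_lengths.items():
        chrom_loci = by_chrom.get(chrom, [])
        n_windows = max(1, -(-length // step))  # ceil; last windows clip
        for i in range(n_windows):
            w_start = i * step
            if w_start >= length:
                break
            w_end = min(w_start + window, length)
            fwd = sum(1 for l in chrom_loci
                      if l.strand == "+" and l.start < w_end and w_start < l.end)
            rev = sum(1 for l in chrom_loci
                      if l.strand == "-" and l.start < w_end and w_start < l.end)
            rows.append({"chromosome": chrom, "window_start": w_start,
                         "window_end": w_end, "forward": fwd, "reverse": rev})
    return pd.DataFrame(rows, columns=["chromosome", "window_start", "window_end",
                                       "forward", "reverse"])
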