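"""RNA-editing and draft-genome accuracy estimation by cDNA/genome
comparison.

A-to-I editing is read by sequencers as guanosine, so genuine editing
shows up as an asymmetric excess of A(genome)->G(cDNA) discordances over
the G->A background, which polymorphism and sequencing error produce
symmetrically.  Counting is restricted to discordant columns flanked by
5 exact gap-free matches on each side, on the transcribed strand
(minus-strand loci are reverse-complemented before counting).  The
editing fraction reported is the excess-asymmetry estimator
(nAG - nGA) / (nAG + nGA); the raw counts are always echoed so any
alternative summary can be recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import AlignmentRecord
from .synthetic import revcomp

__all__ = [
    "EditingReport",
    "UtrComparison",
    "FLANK",
    "best_aligned_region",
    "count_flanked_changes",
    "editing_fraction",
    "utr_mismatch_rate",
    "pairing_from_alignment",
]

FLANK = 5  # exact gap-free matches required on each side of a counted change


@dataclass
class EditingReport:
    query_id: str
    n_AG: int
    n_GA: int
    region: tuple[str, int, int, str]  # chromosome, start, end, strand

    @property
    def only_AG(self) -> bool:
        return self.n_AG > 0 and self.n_GA == 0

    @property
    def only_GA(self) -> bool:
        return self.n_GA > 0 and self.n_AG == 0


@dataclass
class UtrComparison:
    query_id: str
    utr_length: int
    n_mismatches: int

    @property
    def perfect_match(self) -> bool:
        return self.n_mismatches == 0


def best_aligned_region(
    cdna_length: int,
    genome_alignments: list[AlignmentRecord],
) -> AlignmentRecord | None:
    """The single alignment covering the largest fraction of the cDNA
    (ties go to higher identity); None when the query is unalignable."""
    if not genome_alignments:
        return None
    return max(
        genome_alignments,
        key=lambda a: ((a.qend - a.qstart) / cdna_length, a.percent_identity),
    )


def pairing_from_alignment(
    cdna_seq: str,
    genome_seq: str,
    aln: AlignmentRecord,
) -> tuple[str, str]:
    """Base-level (genome_row, cdna_row) pairing on the transcribed strand.

    The tabular records are ungapped, so the paired segments have equal
    length; a minus-strand locus contributes the reverse complement of
    its genomic segment, placing both rows in cDNA (5'->3') orientation.
    """
    qseg = cdna_seq[aln.qstart:aln.qend]
    sseg = genome_seq[aln.sstart:aln.send]
    if aln.strand == "-":
        sseg = revcomp(sseg)
    if len(qseg) != len(sseg):
        raise ValueError(
            f"{aln.query_id}: gapped alignment segments not supported "
            f"({len(qseg)} vs {len(sseg)})"
        )
    return sseg, qseg


def count_flanked_changes(pairing: tuple[str, str], flank: int = FLANK) -> tuple[int, int]:
    """Flank-validated (n_AG, n_GA) over the gap-free columns of a pairing.

    A column counts toward n_AG iff genome=A, cDNA=G and the ``flank``
    columns on each side are all gap-free exact matches; n_GA is the
    symmetric G->A tally.  Gaps ('-') inside a flank window disqualify
    the column.
    """
    genome_row, cdna_row = pairing
    if len(genome_row) != len(cdna_row):
        raise ValueError("pairing rows differ in length")
    n = len(genome_row)
    is_match = [
        genome_row[i] == cdna_row[i] and genome_row[i] != "-" for i in range(n)
    ]
    n_ag = n_ga = 0
    for i in range(flank, n - flank):
        g, c = genome_row[i], cdna_row[i]
        if (g, c) not in (("A", "G"), ("G", "A")):
            continue
        if all(is_match[i - flank:i]) and all(is_match[i + 1:i + 1 + flank]):
            if g == "A":
                n_ag += 1
            else:
                n_ga += 1
    return n_ag, n_ga


def editing_fraction(n_AG_total: int, n_GA_total: int) -> float:
    """Excess-asymmetry estimate of the edited fraction of A/G
    discordances: (nAG - nGA) / (nAG + nGA).  Errors when both are 0."""
    if n_AG_total < 0 or n_GA_total < 0:
        raise ValueError("counts must be non-negative")
    total = n_AG_total + n_GA_total
    if total == 0:
        raise ValueError("no A/G discordances: editing fraction undefined")
    return (n_AG_total - n_GA_total) / total


def utr_mismatch_rate(
    utr_pairings: dict[str, tuple[str, str]],
) -> dict:
    """Per-query 3'-UTR mismatch counts plus the aggregate rate.

    ``utr_pairings`` maps query_id to a (genome_row, cdna_row) pairing
    restricted to the 3'-UTR.  The aggregate rate is total mismatches
    over total aligned columns; perfectly matching UTRs are tallied.
    """
    per_query: list[UtrComparison] = []
    total_cols = total_mm = 0
    for qid in sorted(utr_pairings):
        g_row, c_row = utr_pairings[qid]
        if len(g_row) != len(c_row):
            raise ValueError(f"{qid}: pairing rows differ in length")
        cols = sum(1 for a, b in zip(g_row, c_row) if a != "-" and b != "-")
        mm = sum(1 for a, b in zip(g_row, c_row) if a != "-" and b != "-" and a != b)
        per_query.append(UtrComparison(qid, cols, mm))
        total_cols += cols
        total_mm += mm
    return {
        "per_query": per_query,
        "aggregate_rate": (total_mm / total_cols) if total_cols else 0.0,
        "n_perfect": sum(1 for u in per_query if u.perfect_match),
        "n_total": len(per_query),
    }
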