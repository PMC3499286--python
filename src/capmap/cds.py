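"""CDS-coverage and ORF classification of cDNA clones.

A cDNA contains a full-length CDS when its best protein alignment trims
fewer than 10 amino acids off each end of the protein; the start-codon
call is the N-terminal half of that rule.  ORF finding scans the three
forward frames only (clones are unidirectionally cloned, so the sense
strand is known) and requires both an ATG and an in-frame stop; a clone
is non-coding when its longest ORF is not more than 30 amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import ProteinAlignment

__all__ = [
    "CdsStatus",
    "MAX_TRIM_AA",
    "MIN_ORF_AA",
    "classify_full_length",
    "classify_start_codon",
    "find_longest_orf",
    "classify_cdna",
    "pick_locus_representatives",
    "detect_duplications",
]

MAX_TRIM_AA = 10   # full-length requires each trim strictly below this
MIN_ORF_AA = 30    # coding requires an ORF strictly longer than this

_STOPS = frozenset(("TAA", "TAG", "TGA"))


@dataclass
class CdsStatus:
    query_id: str
    has_full_length_cds: bool
    has_start_codon: bool
    longest_orf_aa: int
    is_noncoding: bool
    n_term_trim: int
    c_term_trim: int

    def __post_init__(self) -> None:
        if self.has_full_length_cds and not self.has_start_codon:
            raise ValueError("full-length CDS implies start codon")
        if self.is_noncoding and self.has_full_length_cds:
            raise ValueError("non-coding excludes full-length CDS")


def classify_full_length(aln: ProteinAlignment, max_trim: int = MAX_TRIM_AA
                         ) -> tuple[bool, int, int]:
    """(full_length, n_term_trim, c_term_trim) for the best protein hit.

    Full-length iff both trims are strictly below ``max_trim`` (a trim
    of 9 qualifies; 10 does not).
    """
    n_trim = aln.n_term_trim
    c_trim = aln.c_term_trim
    return n_trim < max_trim and c_trim < max_trim, n_trim, c_trim


def classify_start_codon(aln: ProteinAlignment | None, max_trim: int = MAX_TRIM_AA) -> bool:
    """N-terminal analog of the full-length rule; False with no hit."""
    if aln is None:
        return False
    return aln.n_term_trim < max_trim


def find_longest_orf(sequence: str, min_aa: int = MIN_ORF_AA) -> tuple[int, bool]:
    """Longest ATG..stop peptide over the three forward frames.

    Returns (longest_orf_aa, is_noncoding); the peptide length excludes
    the stop codon, and ORFs running off the 3' end are not counted.
    Non-coding means no ORF strictly longer than ``min_aa``.
    """
    seq = sequence.upper()
    longest = 0
    for frame in range(3):
        start: int | None = None
        for p in range(frame, len(seq) - 2, 3):
            codon = seq[p:p + 3]
            if codon in _STOPS:
                if start is not None:
                    longest = max(longest, (p - start) // 3)
                    start = None
            elif codon == "ATG" and start is None:
                start = p
    return longest, longest <= min_aa


def classify_cdna(query_id: str, sequence: str,
                  best_protein_aln: ProteinAlignment | None,
                  max_trim: int = MAX_TRIM_AA, min_aa: int = MIN_ORF_AA) -> CdsStatus:
    """Combine the protein-alignment rules with the ORF scan."""
    longest, noncoding = find_longest_orf(sequence, min_aa)
    if best_protein_aln is None:
        return CdsStatus(query_id, False, False, longest, noncoding, 0, 0)
    full, n_trim, c_trim = classify_full_length(best_protein_aln, max_trim)
    if noncoding:
        full = False  # no qualifying ORF, so no full CDS either
    return CdsStatus(
        query_id=query_id,
        has_full_length_cds=full,
        has_start_codon=classify_start_codon(best_protein_aln, max_trim),
        longest_orf_aa=longest,
        is_noncoding=noncoding,
        n_term_trim=n_trim,
        c_term_trim=c_trim,
    )


def pick_locus_representatives(
    loci,
    cds_statuses: dict[str, CdsStatus],
    seq_lengths: dict[str, int] | None = None,
) -> dict[str, str]:
    """Per locus, the member with the longest ORF (ties: longer
    sequence, then id order).  A locus with no members is an error."""
    seq_lengths = seq_lengths or {}
    reps: dict[str, str] = {}
    for locus in loci:
        members = sorted(locus.member_query_ids)
        if not members:
            raise ValueError(f"locus {locus.locus_id} has no members")
        reps[locus.locus_id] = max(
            members,
            key=lambda q: (
                cds_statuses[q].longest_orf_aa if q in cds_statuses else -1,
                seq_lengths.get(q, 0),
                _rev(q),
            ),
        )
    return reps


class _rev(str):
    """Inverted ordering so max() prefers the smallest id on full ties."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def detect_duplications(
    representatives: dict[str, str],
    protein_hits: dict[str, ProteinAlignment | None],
    cds_statuses: dict[str, CdsStatus],
) -> pd.DataFrame:
    """Proteins matched by more than one locus, with shorter-ORF loci
    flagged as putative pseudogenes / duplication artefacts.

    Columns: protein_id, locus_id, representative, orf_aa, is_shorter.
    """
    by_protein: dict[str, list[tuple[str, str]]] = {}
    for locus_id, rep in representatives.items():
        aln = protein_hits.get(rep)
        if aln is not None:
            by_protein.setdefault(aln.protein_id, []).append((locus_id, rep))
    rows = []
    for protein_id in sorted(by_protein):
        group = by_protein[protein_id]
        if len(group) < 2:
            continue
        orfs = {rep: cds_statuses[rep].longest_orf_aa for _, rep in group}
        longest = max(orfs.values())
        for locus_id, rep in sorted(group):
            rows.append({
                "protein_id": protein_id,
                "locus_id": locus_id,
                "representative": rep,
                "orf_aa": orfs[rep],
                "is_shorter": orfs[rep] < longest,
            })
    return pd.DataFrame(rows, columns=["protein_id", "locus_id", "representative",
                                       "orf_aa", "is_shorter"])
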