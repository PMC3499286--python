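"""Naive seed-and-extend aligner for synthetic tests.

The pipeline consumes 12-column tabular alignments produced elsewhere;
this module exists only so the synthetic end-to-end tests can make such
records (and protein hits) without an external search tool.  It is a
k-mer seeded, ungapped, x-drop extended matcher — adequate for reads
that differ from their source by substitutions only, and not a
general-purpose aligner.
"""

from __future__ import annotations

from collections import defaultdict

from Bio.Seq import Seq

from .io_formats import AlignmentRecord, SeqRecord
from .synthetic import revcomp

__all__ = ["naive_align", "ProteinAlignment", "align_to_proteins"]

_MATCH = 2
_MISMATCH = -3
_XDROP = 24


def _extend(q: str, s: str, qpos: int, spos: int, k: int) -> tuple[int, int, int, int]:
    """Ungapped x-drop extension around an exact k-seed.

    Returns (qstart, qend, matches, mismatches), query coords half-open.
    """
    # right extension (seed included)
    score = best = k * _MATCH
    qi, si = qpos + k, spos + k
    best_q = qi
    while qi < len(q) and si < len(s):
        score += _MATCH if q[qi] == s[si] else _MISMATCH
        qi += 1
        si += 1
        if score > best:
            best, best_q = score, qi
        elif best - score > _XDROP:
            break
    right_end = best_q
    # left extension
    score = best = 0
    qi, si = qpos, spos
    best_q = qi
    while qi > 0 and si > 0:
        qi -= 1
        si -= 1
        score += _MATCH if q[qi] == s[si] else _MISMATCH
        if score > best:
            best, best_q = score, qi
        elif best - score > _XDROP:
            break
    left_start = best_q
    d = spos - qpos
    matches = sum(1 for i in range(left_start, right_end) if q[i] == s[i + d])
    return left_start, right_end, matches, right_end - left_start - matches


def naive_align(
    queries: list[SeqRecord],
    subjects: list[SeqRecord],
    k: int = 20,
    stride: int = 10,
    min_len: int = 25,
) -> list[AlignmentRecord]:
    """Align each query against all subjects on both strands.

    Emits one ungapped record per high-scoring segment (so a spliced
    read yields one record per exon).  Scores are ``2*matches -
    3*mismatches``; minus-strand hits carry ``strand='-'`` with subject
    coordinates normalised ``sstart < send``.
    """
    index: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for si, sub in enumerate(subjects):
        seq = sub.sequence
        for p in range(0, len(seq) - k + 1):
            index[seq[p:p + k]].append((si, p))

    records: list[AlignmentRecord] = []
    for q in queries:
        for strand in "+-":
            qseq = q.sequence if strand == "+" else revcomp(q.sequence)
            # (subject, diagonal) -> furthest query end already covered
            covered: dict[tuple[int, int], int] = {}
            for p in range(0, len(qseq) - k + 1, stride):
                for si, sp in index.get(qseq[p:p + k], ()):
                    diag = sp - p
                    if covered.get((si, diag), -1) >= p + k:
                        continue
                    qs, qe, m, mm = _extend(qseq, subjects[si].sequence, p, sp, k)
                    covered[(si, diag)] = qe
                    if qe - qs < min_len:
                        continue
                    score = _MATCH * m + _MISMATCH * mm
                    if score <= 0:
                        continue
                    ss, se = qs + diag, qe + diag
                    if strand == "+":
                        rqs, rqe = qs, qe
                    else:
                        rqs, rqe = len(qseq) - qe, len(qseq) - qs
                    records.append(
                        AlignmentRecord(
                            query_id=q.id,
                            subject_id=subjects[si].id,
                            percent_identity=100.0 * m / (qe - qs),
                            aln_length=qe - qs,
                            mismatches=mm,
                            gap_opens=0,
                            qstart=rqs,
                            qend=rqe,
                            sstart=ss,
                            send=se,
                            evalue=0.0,
                            score=float(score),
                            strand=strand,
                        )
                    )
    # drop exact duplicates from overlapping seeds
    seen: set[tuple] = set()
    out: list[AlignmentRecord] = []
    for r in records:
        key = (r.query_id, r.subject_id, r.strand, r.qstart, r.qend, r.sstart, r.send)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


class ProteinAlignment:
    """Ungapped alignment of a (translated) cDNA to a protein.

    ``pstart``/``pend`` are 0-based half-open on the protein;
    ``qstart``/``qend`` are nucleotide coordinates on the cDNA.
    """

    __slots__ = ("query_id", "protein_id", "protein_length",
                 "pstart", "pend", "qstart", "qend", "score")

    def __init__(self, query_id, protein_id, protein_length,
                 pstart, pend, qstart, qend, score):
        if not (0 <= pstart < pend <= protein_length):
            raise ValueError("protein interval outside protein")
        self.query_id = query_id
        self.protein_id = protein_id
        self.protein_length = protein_length
        self.pstart = pstart
        self.pend = pend
        self.qstart = qstart
        self.qend = qend
        self.score = score

    @property
    def n_term_trim(self) -> int:
        return self.pstart

    @property
    def c_term_trim(self) -> int:
        return self.protein_length - self.pend


def align_to_proteins(
    read: SeqRecord,
    proteins: dict[str, str],
    k: int = 6,
    index: dict | None = None,
) -> ProteinAlignment | None:
    """Best ungapped protein hit over the three forward reading frames.

    Reads come from unidirectionally cloned cDNA, so only the sense
    frames are scanned.  Returns the highest-scoring hit or None.
    """
    if index is None:
        index = build_protein_index(proteins, k)
    best: ProteinAlignment | None = None
    for frame in range(3):
        aa = str(Seq(read.sequence[frame:len(read.sequence) - (len(read.sequence) - frame) % 3]).translate())
        covered: dict[tuple[str, int], int] = {}
        for p in range(0, len(aa) - k + 1):
            for pid, sp in index.get(aa[p:p + k], ()):
                diag = sp - p
                if covered.get((pid, diag), -1) >= p + k:
                    continue
                qs, qe, m, mm = _extend(aa, proteins[pid], p, sp, k)
                covered[(pid, diag)] = qe
                score = _MATCH * m + _MISMATCH * mm
                if score <= 0:
                    continue
                cand = ProteinAlignment(
                    query_id=read.id,
                    protein_id=pid,
                    protein_length=len(proteins[pid]),
                    pstart=qs + diag,
                    pend=qe + diag,
                    qstart=frame + 3 * qs,
                    qend=frame + 3 * qe,
                    score=float(score),
                )
                if best is None or cand.score > best.score:
                    best = cand
    return best


def build_protein_index(proteins: dict[str, str], k: int = 6) -> dict:
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for pid, seq in proteins.items():
        for p in range(0, len(seq) - k + 1):
            index[seq[p:p + k]].append((pid, p))
    return index
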