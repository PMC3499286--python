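"""Readers and writers for the external formats the pipeline touches.

All coordinates are 0-based half-open internally; conversion to the
1-based inclusive conventions of GFF3 and tabular alignment records, and
to BED's 0-based half-open convention, happens only in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "QualityTrack",
    "AlignmentRecord",
    "read_fasta",
    "write_fasta",
    "read_qualities",
    "read_alignments",
    "write_alignments",
    "write_loci_bed",
    "write_truth_gff",
    "read_truth_gff",
    "write_tsv",
]

_VALID_BASES = set("ACGTN")


@dataclass
class SeqRecord:
    """A DNA sequence with identifier, uppercase over {A,C,G,T,N}."""

    id: str
    description: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class QualityTrack:
    """Per-base Phred quality values paired with a read."""

    read_id: str
    qualities: list[int]

    def __post_init__(self) -> None:
        bad = [q for q in self.qualities if not (0 <= q <= 93)]
        if bad:
            raise ValueError(
                f"quality values out of range 0-93 for {self.read_id!r}: {bad[:5]}"
            )


@dataclass
class AlignmentRecord:
    """One query-vs-subject local alignment.

    Coordinates are stored 0-based half-open on both query and subject;
    ``strand`` records the subject orientation inferred from the raw
    record (sstart>send in the tabular dialect means minus strand), and
    subject coordinates are normalised so ``sstart < send`` always holds.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    score: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.aln_length < 1:
            raise ValueError(f"alignment length must be >=1, got {self.aln_length}")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(f"percent identity out of range: {self.percent_identity}")
        if self.qstart >= self.qend:
            raise ValueError(
                f"query interval empty or reversed: [{self.qstart},{self.qend})"
            )
        if self.sstart >= self.send:
            raise ValueError(
                f"subject interval empty or reversed: [{self.sstart},{self.send})"
            )
        if self.score < 0:
            raise ValueError(f"score must be >=0, got {self.score}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def _normalise_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    if not seq:
        raise ValueError(f"empty sequence for record {record_id!r}")
    invalid = set(seq) - _VALID_BASES
    if invalid:
        raise ValueError(
            f"record {record_id!r} contains non-DNA characters: {sorted(invalid)}"
        )
    return seq


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file, preserving order, uppercasing and mapping U->T.

    Raises ``ValueError`` on duplicate ids or empty sequences.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SeqRecord(
                id=rec.id,
                description=rec.description,
                sequence=_normalise_sequence(str(rec.seq), rec.id),
            )
        )
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if rec.description in ("", rec.id) else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_qualities(path: str | Path) -> dict[str, QualityTrack]:
    """Read per-base qualities from FASTQ or a phred-style .qual file.

    The .qual dialect is FASTA-like: ``>read_id`` headers followed by
    whitespace-separated integers. The format is sniffed from the first
    non-blank character (``@`` means FASTQ).
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line.lstrip()[0]
                break
    fmt = "fastq" if first == "@" else "qual"
    tracks: dict[str, QualityTrack] = {}
    for rec in SeqIO.parse(str(path), fmt):
        if rec.id in tracks:
            raise ValueError(f"duplicate read id {rec.id!r} in {path}")
        tracks[rec.id] = QualityTrack(rec.id, list(rec.letter_annotations["phred_quality"]))
    return tracks


def write_qualities(tracks: Iterable[QualityTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tracks:
            fh.write(f">{t.read_id}\n")
            fh.write(" ".join(str(q) for q in t.qualities) + "\n")


_N_ALN_COLUMNS = 12


def read_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Parse 12-column tab-separated alignment records.

    Columns: query, subject, pident, length, mismatch, gapopen, qstart,
    qend, sstart, send, evalue, bitscore — all coordinates 1-based
    inclusive in the file. Minus-strand alignments are flagged by
    sstart > send; they are normalised on read and the strand recorded.
    Any deviation from exactly 12 columns, or a non-numeric field, is an
    error naming the offending line.
    """
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _N_ALN_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_N_ALN_COLUMNS} columns, got {len(cols)}"
                )
            try:
                pident = float(cols[2])
                length = int(cols[3])
                mismatch = int(cols[4])
                gapopen = int(cols[5])
                qstart, qend = int(cols[6]), int(cols[7])
                sstart, send = int(cols[8]), int(cols[9])
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if qstart > qend:
                raise ValueError(f"{path}:{lineno}: qstart > qend on the query")
            strand = "+" if sstart <= send else "-"
            lo, hi = (sstart, send) if strand == "+" else (send, sstart)
            records.append(
                AlignmentRecord(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=pident,
                    aln_length=length,
                    mismatches=mismatch,
                    gap_opens=gapopen,
                    qstart=qstart - 1,
                    qend=qend,
                    sstart=lo - 1,
                    send=hi,
                    evalue=evalue,
                    score=bitscore,
                    strand=strand,
                )
            )
    return records


def write_alignments(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    """Serialise records back to the 12-column dialect (minus strand as sstart>send)."""
    with open(path, "w") as fh:
        for r in records:
            if r.strand == "+":
                s1, s2 = r.sstart + 1, r.send
            else:
                s1, s2 = r.send, r.sstart + 1
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id,
                        r.subject_id,
                        f"{r.percent_identity:.2f}",
                        r.aln_length,
                        r.mismatches,
                        r.gap_opens,
                        r.qstart + 1,
                        r.qend,
                        s1,
                        s2,
                        f"{r.evalue:.2g}",
                        f"{r.score:.1f}",
                    )
                )
                + "\n"
            )


def write_loci_bed(loci: Sequence, path: str | Path) -> None:
    """Write loci as BED6 (0-based half-open), sorted by (chrom, start, end, strand)."""
    rows = sorted(
        (l.chromosome, l.start, l.end, l.locus_id, l.strand) for l in loci
    )
    with open(path, "w") as fh:
        for chrom, start, end, locus_id, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{locus_id}\t0\t{strand}\n")


def write_truth_gff(gene_models: Sequence, path: str | Path,
                    chrom_lengths: dict[str, int] | None = None) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon features, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in gene_models:
            gstart = min(s for s, _ in gm.exons)
            gend = max(e for _, e in gm.exons)
            if chrom_lengths is not None:
                limit = chrom_lengths.get(gm.chromosome)
                if limit is not None and (gstart < 0 or gend > limit):
                    raise ValueError(
                        f"gene {gm.gene_id} exons outside {gm.chromosome} bounds [0,{limit})"
                    )
            attrs = f"ID={gm.gene_id}"
            fh.write(
                f"{gm.chromosome}\tcapmap\tgene\t{gstart + 1}\t{gend}\t.\t{gm.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{gm.gene_id}.t1"
            fh.write(
                f"{gm.chromosome}\tcapmap\tmRNA\t{gstart + 1}\t{gend}\t.\t{gm.strand}\t."
                f"\tID={mrna_id};Parent={gm.gene_id}\n"
            )
            for i, (s, e) in enumerate(gm.exons, start=1):
                fh.write(
                    f"{gm.chromosome}\tcapmap\texon\t{s + 1}\t{e}\t.\t{gm.strand}\t."
                    f"\tID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )


def read_truth_gff(path: str | Path) -> list[dict]:
    """Read back a truth GFF3 into plain dicts (gene_id, chromosome, strand, exons).

    Only the gene/mRNA/exon feature types written by :func:`write_truth_gff`
    are recognised; exon intervals are returned 0-based half-open, sorted.
    """
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = cols
            kv = dict(p.split("=", 1) for p in attrs.split(";") if "=" in p)
            if ftype == "gene":
                genes[kv["ID"]] = {
                    "gene_id": kv["ID"],
                    "chromosome": chrom,
                    "strand": strand,
                    "exons": [],
                }
            elif ftype == "mRNA":
                mrna_to_gene[kv["ID"]] = kv["Parent"]
            elif ftype == "exon":
                gene_id = mrna_to_gene[kv["Parent"]]
                genes[gene_id]["exons"].append((int(start) - 1, int(end)))
    for g in genes.values():
        g["exons"].sort()
    return list(genes.values())


def write_tsv(df, path: str | Path) -> None:
    """Write a DataFrame as UTF-8 TSV with header row."""
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
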