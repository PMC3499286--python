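"""Synthetic genome / full-length-enriched cDNA library generator.

Emulates the structure of a 5'-EST project: a draft genome with
chromosomes and unplaced scaffolds, multi-exon genes on both strands
(some duplicated, some pseudogenised), transcripts biased toward
5'-completeness, geometric 5'-truncation of the remainder, a Zipf
expression law with an optional forced rare gene, cross-individual
polymorphism on the read haplotype, A-to-G editing at fixed transcript
sites, and per-base sequencing error.  Every stochastic choice flows
from a single seeded generator, so identical configs give bit-identical
output, and a ground-truth ledger accompanies everything for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .io_formats import QualityTrack, SeqRecord

__all__ = [
    "GeneModel",
    "SimConfig",
    "ReadTruth",
    "TruthSet",
    "simulate_genome",
    "simulate_reads",
    "sample_gene_indices",
    "expression_probabilities",
    "gene_transcript",
    "transcript_to_genomic",
    "revcomp",
]

_BASES = "ACGT"
_RC = str.maketrans("ACGTN", "TGCAN")
_STOPS = ("TAA", "TAG", "TGA")

# Truncated clones model incomplete first-strand synthesis: the start
# codon and at least the first 10 codons are lost (full-length
# enrichment means the retained fraction IS the start-codon fraction).
_MIN_CDS_LOSS_NT = 30
_POLYA_TAIL_LEN = 20
_UTR_DIVERGENCE = 0.03  # substitution rate distinguishing duplicated loci
_READ_QUALITY = 40


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class GeneModel:
    """A single-isoform gene: ordered genomic exons plus CDS bookkeeping."""

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted by genomic start
    cds_start_offset: int  # transcript coordinate of the start codon
    protein_id: str
    is_pseudogene: bool = False
    duplicate_of: str | None = None
    cds_length_nt: int = 0  # includes the stop codon
    editing_sites: list[int] = field(default_factory=list)  # transcript coords
    polymorphisms: list[tuple[int, str]] = field(default_factory=list)

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class SimConfig:
    """Study-condition knobs for the generator.

    ``full_length_prob`` defaults to the enrichment level of the
    emulated libraries (about three-fourths of clones retain the start
    codon); ``polymorphism_rate`` is set so that cDNA-vs-genome
    differences stay below the 0.4% the draft-genome comparison
    tolerates; ``expression_law`` is a Zipf rank-frequency exponent.
    """

    n_chromosomes: int = 2
    n_unplaced_scaffolds: int = 2
    chromosome_length: int = 200_000
    n_genes: int = 20
    frac_duplicated: float = 0.1
    frac_pseudogene: float = 0.05
    full_length_prob: float = 0.75
    truncation_geometric_p: float = 0.01
    expression_law: float = 1.0
    editing_rate: float = 5e-4
    polymorphism_rate: float = 0.002
    seq_error_rate: float = 0.001
    n_reads: int = 2000
    seed: int = 0
    read_length: int = 800
    rare_gene_freq: float | None = None
    scaffold_prefix: str = "scaffold"

    def __post_init__(self) -> None:
        for name in ("frac_duplicated", "frac_pseudogene", "full_length_prob",
                     "truncation_geometric_p", "editing_rate",
                     "polymorphism_rate", "seq_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if min(self.chromosome_length, self.read_length) <= 0:
            raise ValueError("lengths must be positive")
        if self.n_genes < 1 or self.n_reads < 0:
            raise ValueError("n_genes must be >=1 and n_reads >=0")


@dataclass
class ReadTruth:
    read_id: str
    gene_id: str
    is_full_length: bool
    truncation_offset: int


@dataclass
class TruthSet:
    """Ground-truth ledger tying every simulated artefact to its origin."""

    genes: list[GeneModel] = field(default_factory=list)
    proteins: dict[str, str] = field(default_factory=dict)
    reads: list[ReadTruth] = field(default_factory=list)
    # (gene_id, chromosome, genomic_pos, transcript_pos)
    editing_sites: list[tuple[str, str, int, int]] = field(default_factory=list)
    # (gene_id, chromosome, genomic_pos, transcript_pos, ref_transcript_base, alt)
    polymorphic_sites: list[tuple[str, str, int, int, str, str]] = field(default_factory=list)
    expression_freq: dict[str, float] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _random_utr(rng: np.random.Generator, length: int) -> str:
    """Random sequence with homopolymer A runs broken below 8 (so the
    polyA-tail detector never fires inside a UTR)."""
    chars = list(_random_seq(rng, length))
    run = 0
    for i, c in enumerate(chars):
        if c == "A":
            run += 1
            if run >= 7:
                chars[i] = _BASES[int(rng.integers(1, 4))]  # C/G/T
                run = 0
        else:
            run = 0
    return "".join(chars)


def _random_cds(rng: np.random.Generator, n_aa: int) -> str:
    codons = ["ATG"]
    while len(codons) < n_aa:
        c = _random_seq(rng, 3)
        if c not in _STOPS and c != "ATG":
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def transcript_to_genomic(gm: GeneModel, t: int) -> int:
    """Map a transcript coordinate to its genomic position (0-based)."""
    if not (0 <= t < gm.transcript_length):
        raise ValueError(f"transcript position {t} outside gene {gm.gene_id}")
    u = t if gm.strand == "+" else gm.transcript_length - 1 - t
    acc = 0
    for s, e in gm.exons:
        if u < acc + (e - s):
            return s + (u - acc)
        acc += e - s
    raise AssertionError("unreachable")


def gene_transcript(genome: dict[str, str], gm: GeneModel) -> str:
    """Reference (unedited, reference-allele) transcript, 5'->3'."""
    seq = "".join(genome[gm.chromosome][s:e] for s, e in gm.exons)
    return revcomp(seq) if gm.strand == "-" else seq


def _split_exons(rng: np.random.Generator, length: int, n_exons: int,
                 min_exon: int = 30) -> list[int]:
    """Partition ``length`` into ``n_exons`` segment lengths, each >= min_exon."""
    if n_exons * min_exon > length:
        n_exons = max(1, length // min_exon)
    if n_exons == 1:
        return [length]
    while True:
        cuts = np.sort(rng.choice(np.arange(min_exon, length - min_exon + 1),
                                  size=n_exons - 1, replace=False))
        bounds = [0, *cuts.tolist(), length]
        segs = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
        if min(segs) >= min_exon:
            return segs


def _pick_sites(rng: np.random.Generator, transcript: str, rate: float,
                min_spacing: int = 6, edge: int = 5) -> list[int]:
    """Editing sites: A positions chosen at ``rate``, spaced so flank
    validation cannot be spoiled by a neighbouring site."""
    sites: list[int] = []
    last = -(10**9)
    for p in range(edge, len(transcript) - edge):
        if transcript[p] == "A" and p - last >= min_spacing and rng.random() < rate:
            sites.append(p)
            last = p
    return sites


def _pick_polymorphisms(rng: np.random.Generator, transcript: str, rate: float,
                        editing_sites: list[int]) -> list[tuple[int, str]]:
    blocked = set()
    for s in editing_sites:
        blocked.update(range(s - 5, s + 6))
    out: list[tuple[int, str]] = []
    for p in range(len(transcript)):
        if p in blocked or rng.random() >= rate:
            continue
        ref = transcript[p]
        alt = _BASES[int(rng.integers(0, 3))]
        alt = alt if alt != ref else _BASES[3]
        out.append((p, alt))
    return out


def _synonym_table() -> dict[str, list[str]]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    return {
        codon: sorted(c for c in group if c != codon)
        for group in by_aa.values()
        for codon in group
    }


_SYNONYMS = _synonym_table()
_CDS_CODON_DIVERGENCE = 0.1


def _diverge_copy(rng: np.random.Generator, transcript: str, cds_start: int,
                  cds_len: int) -> str:
    """Make a duplicated locus near-identical but distinguishable.

    UTR bases substitute at a small rate; CDS codons substitute
    synonymously (start and stop untouched), so the encoded protein and
    ORF length are preserved while every CDS-spanning alignment strictly
    prefers its own locus.
    """
    chars = list(transcript)
    for p in range(len(chars)):
        if cds_start <= p < cds_start + cds_len:
            continue
        if rng.random() < _UTR_DIVERGENCE:
            alt = _BASES[int(rng.integers(0, 3))]
            chars[p] = alt if alt != chars[p] else _BASES[3]
    for ci in range(1, cds_len // 3 - 1):  # skip start and stop codons
        if rng.random() >= _CDS_CODON_DIVERGENCE:
            continue
        pos = cds_start + 3 * ci
        options = _SYNONYMS.get("".join(chars[pos:pos + 3]), [])
        if options:
            chars[pos:pos + 3] = options[int(rng.integers(0, len(options)))]
    return "".join(chars)


def simulate_genome(config: SimConfig) -> tuple[list[SeqRecord], list[GeneModel], TruthSet]:
    """Build the genome, place gene models, and start the truth ledger.

    Duplicated genes are near-identical second-locus copies of an
    original (UTR-diverged only, so ORFs stay equal); pseudogenes are
    copies carrying a premature stop, giving truncated ORFs relative to
    their template.  Raises if the requested genes exceed placeable
    capacity.
    """
    rng = np.random.default_rng(config.seed)
    n_dup = round(config.frac_duplicated * config.n_genes)
    n_pseu = round(config.frac_pseudogene * config.n_genes)
    n_orig = config.n_genes - n_dup - n_pseu
    if n_orig < 1:
        raise ValueError("frac_duplicated + frac_pseudogene leave no original genes")

    # -- transcript payloads -------------------------------------------------
    payloads: list[dict] = []
    for i in range(n_orig):
        utr5 = _random_utr(rng, int(rng.integers(30, 81)))
        n_aa = int(rng.integers(60, 201))
        cds = _random_cds(rng, n_aa)
        utr3 = _random_utr(rng, int(rng.integers(100, 201)))
        transcript = utr5 + cds + utr3
        payloads.append({
            "transcript": transcript,
            "cds_start": len(utr5),
            "cds_len": len(cds),
            "protein_idx": i,
            "is_pseudogene": False,
            "duplicate_of": None,
            "seg_lens": _split_exons(rng, len(transcript), int(rng.integers(1, 5))),
        })
    originals = list(payloads)
    for _ in range(n_dup):
        tmpl_idx = int(rng.integers(0, n_orig))
        t = originals[tmpl_idx]
        payloads.append({
            "transcript": _diverge_copy(rng, t["transcript"], t["cds_start"], t["cds_len"]),
            "cds_start": t["cds_start"],
            "cds_len": t["cds_len"],
            "protein_idx": t["protein_idx"],
            "is_pseudogene": False,
            "duplicate_of": tmpl_idx,
            "seg_lens": list(t["seg_lens"]),
        })
    for _ in range(n_pseu):
        tmpl_idx = int(rng.integers(0, n_orig))
        t = originals[tmpl_idx]
        seq = _diverge_copy(rng, t["transcript"], t["cds_start"], t["cds_len"])
        n_aa = t["cds_len"] // 3
        stop_codon = t["cds_start"] + 3 * max(2, n_aa // 3)
        seq = seq[:stop_codon] + "TAA" + seq[stop_codon + 3:]
        payloads.append({
            "transcript": seq,
            "cds_start": t["cds_start"],
            "cds_len": t["cds_len"],
            "protein_idx": t["protein_idx"],
            "is_pseudogene": True,
            "duplicate_of": tmpl_idx,
            "seg_lens": list(t["seg_lens"]),
        })

    # -- sequences and placement --------------------------------------------
    seq_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    seq_lengths = [config.chromosome_length] * config.n_chromosomes
    for i in range(config.n_unplaced_scaffolds):
        seq_names.append(f"{config.scaffold_prefix}_{i + 1}")
        seq_lengths.append(max(2000, config.chromosome_length // 5))
    arrays = {name: bytearray(_random_seq(rng, ln).encode())
              for name, ln in zip(seq_names, seq_lengths)}
    cursors = {name: 0 for name in seq_names}
    margin = 300

    models: list[GeneModel] = []
    truth = TruthSet()
    # place originals before their copies so a duplicate can be steered
    # to a different sequence than its template (a second locus under
    # the <1 Mb extension rule needs separation the toy genome lacks)
    order = list(rng.permutation(n_orig)) + [
        n_orig + i for i in rng.permutation(len(payloads) - n_orig)
    ]
    payload_chrom: dict[int, str] = {}
    for gi, pi in enumerate(order):
        p = payloads[pi]
        transcript = p["transcript"]
        seg_lens = p["seg_lens"]
        intron_lens = [int(rng.integers(200, 1001)) for _ in range(len(seg_lens) - 1)]
        span = sum(seg_lens) + sum(intron_lens)
        avoid = None
        if p["duplicate_of"] is not None:
            avoid = payload_chrom.get(p["duplicate_of"])
        candidates = [seq_names[(gi + j) % len(seq_names)] for j in range(len(seq_names))]
        if avoid is not None and len(candidates) > 1:
            candidates = [c for c in candidates if c != avoid] + [avoid]
        placed = None
        for name in candidates:
            gap = margin + int(rng.integers(0, 3 * margin))
            start = cursors[name] + gap
            if start + span + margin <= len(arrays[name]):
                placed = (name, start)
                cursors[name] = start + span
                break
        if placed is None:
            raise ValueError(
                f"cannot place gene {gi + 1}/{len(payloads)}: genome capacity exhausted"
            )
        chrom, gstart = placed
        payload_chrom[pi] = chrom
        strand = "+" if rng.random() < 0.5 else "-"
        # genomic exon intervals, left to right
        exons: list[tuple[int, int]] = []
        pos = gstart
        genomic_order = seg_lens if strand == "+" else seg_lens[::-1]
        for k, ln in enumerate(genomic_order):
            exons.append((pos, pos + ln))
            pos += ln
            if k < len(intron_lens):
                pos += intron_lens[k]
        # paste transcript segments
        segs5to3 = []
        off = 0
        for ln in seg_lens:
            segs5to3.append(transcript[off:off + ln])
            off += ln
        for k, (s, e) in enumerate(exons):
            piece = segs5to3[k] if strand == "+" else revcomp(segs5to3[len(exons) - 1 - k])
            arrays[chrom][s:e] = piece.encode()

        gene_id = f"gene{gi + 1:04d}"
        protein_id = f"prot{p['protein_idx'] + 1:04d}"
        gm = GeneModel(
            gene_id=gene_id,
            chromosome=chrom,
            strand=strand,
            exons=exons,
            cds_start_offset=p["cds_start"],
            protein_id=protein_id,
            is_pseudogene=p["is_pseudogene"],
            duplicate_of=None,
            cds_length_nt=p["cds_len"],
        )
        gm.editing_sites = _pick_sites(rng, transcript, config.editing_rate)
        gm.polymorphisms = _pick_polymorphisms(
            rng, transcript, config.polymorphism_rate, gm.editing_sites
        )
        models.append(gm)

    # resolve duplicate_of to gene ids (templates were payload indices)
    payload_to_gene = {pi: models[gi].gene_id for gi, pi in enumerate(order)}
    for gi, pi in enumerate(order):
        tmpl = payloads[pi]["duplicate_of"]
        if tmpl is not None:
            models[gi].duplicate_of = payload_to_gene[tmpl]

    records = [SeqRecord(id=name, description="", sequence=arrays[name].decode())
               for name in seq_names]
    genome = {r.id: r.sequence for r in records}

    truth.genes = models
    for gm in models:
        if gm.duplicate_of is None:
            tr = gene_transcript(genome, gm)
            cds = tr[gm.cds_start_offset:gm.cds_start_offset + gm.cds_length_nt]
            truth.proteins[gm.protein_id] = str(Seq(cds).translate()).rstrip("*")
        for t in gm.editing_sites:
            truth.editing_sites.append(
                (gm.gene_id, gm.chromosome, transcript_to_genomic(gm, t), t)
            )
        tr = gene_transcript(genome, gm)
        for t, alt in gm.polymorphisms:
            truth.polymorphic_sites.append(
                (gm.gene_id, gm.chromosome, transcript_to_genomic(gm, t), t, tr[t], alt)
            )
    return records, models, truth


def expression_probabilities(config: SimConfig) -> np.ndarray:
    """Zipf rank-frequency law over genes; optionally force the last
    gene to a fixed frequency (for rare-transcript experiments)."""
    ranks = np.arange(1, config.n_genes + 1, dtype=float)
    p = ranks ** (-config.expression_law)
    p /= p.sum()
    if config.rare_gene_freq is not None:
        f = config.rare_gene_freq
        if not (0.0 <= f < 1.0):
            raise ValueError("rare_gene_freq must be in [0,1)")
        p = p[:-1] / p[:-1].sum() * (1.0 - f)
        p = np.append(p, f)
    return p


def sample_gene_indices(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """The gene-sampling law used by :func:`simulate_reads`, exposed so
    detection-probability experiments can run at scale."""
    return rng.choice(config.n_genes, size=config.n_reads,
                      p=expression_probabilities(config))


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq
    chars = list(seq)
    for p in hits:
        alt = _BASES[int(rng.integers(0, 3))]
        chars[p] = alt if alt != chars[p] else _BASES[3]
    return "".join(chars)


def simulate_reads(
    genome: list[SeqRecord] | dict[str, str],
    models: list[GeneModel],
    config: SimConfig,
) -> tuple[list[SeqRecord], list[QualityTrack], TruthSet]:
    """Draw 5' single-pass reads from the gene models.

    Each read comes from a gene under the expression law; with
    probability ``full_length_prob`` it starts at the transcription
    start, otherwise 5'-truncation removes the start codon region plus a
    geometric overhang.  Editing sites are expressed as A->G on the
    transcript; polymorphisms ride the read haplotype; sequencing errors
    are applied last.  The returned truth ledger covers reads, sites,
    and realised expression frequencies.
    """
    if not isinstance(genome, dict):
        genome = {r.id: r.sequence for r in genome}
    rng = np.random.default_rng((config.seed, 1))
    truth = TruthSet(genes=models)
    for gm in models:
        tr = gene_transcript(genome, gm)
        if gm.duplicate_of is None:
            cds = tr[gm.cds_start_offset:gm.cds_start_offset + gm.cds_length_nt]
            truth.proteins[gm.protein_id] = str(Seq(cds).translate()).rstrip("*")
        for t in gm.editing_sites:
            truth.editing_sites.append(
                (gm.gene_id, gm.chromosome, transcript_to_genomic(gm, t), t)
            )
        for t, alt in gm.polymorphisms:
            truth.polymorphic_sites.append(
                (gm.gene_id, gm.chromosome, transcript_to_genomic(gm, t), t, tr[t], alt)
            )

    haplotypes: list[str] = []
    for gm in models:
        chars = list(gene_transcript(genome, gm))
        for t in gm.editing_sites:
            chars[t] = "G"
        for t, alt in gm.polymorphisms:
            chars[t] = alt
        haplotypes.append("".join(chars) + "A" * _POLYA_TAIL_LEN)

    gene_idx = sample_gene_indices(config, rng)
    reads: list[SeqRecord] = []
    quals: list[QualityTrack] = []
    counts = np.bincount(gene_idx, minlength=config.n_genes)
    for gm, c in zip(models, counts):
        truth.expression_freq[gm.gene_id] = c / max(1, config.n_reads)

    for i, g in enumerate(gene_idx):
        gm = models[g]
        hap = haplotypes[g]
        tlen = gm.transcript_length
        if rng.random() < config.full_length_prob:
            offset = 0
        else:
            base = gm.cds_start_offset + _MIN_CDS_LOSS_NT
            offset = base + int(rng.geometric(config.truncation_geometric_p))
            offset = min(offset, max(1, tlen - 50))
        seq = hap[offset:offset + config.read_length]
        seq = _apply_errors(rng, seq, config.seq_error_rate)
        read_id = f"read{i + 1:06d}"
        reads.append(SeqRecord(id=read_id, description=f"gene={gm.gene_id}", sequence=seq))
        quals.append(QualityTrack(read_id, [_READ_QUALITY] * len(seq)))
        truth.reads.append(ReadTruth(read_id, gm.gene_id, offset == 0, offset))

    return reads, quals, truth
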