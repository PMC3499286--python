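import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import capmap as cm
from capmap.editing import (
    best_aligned_region,
    count_flanked_changes,
    editing_fraction,
    pairing_from_alignment,
    utr_mismatch_rate,
)
from capmap.io_formats import AlignmentRecord
from capmap.synthetic import gene_transcript, revcomp


def _aln(q="q1", s="chr1", qstart=0, qend=100, sstart=0, send=100,
         ident=99.0, strand="+"):
    return AlignmentRecord(
        query_id=q, subject_id=s, percent_identity=ident, aln_length=qend - qstart,
        mismatches=0, gap_opens=0, qstart=qstart, qend=qend,
        sstart=sstart, send=send, evalue=0.0, score=100.0, strand=strand,
    )


class TestBestRegion:
    def test_largest_coverage_wins(self):
        big = _aln(qstart=0, qend=90)
        small = _aln(qstart=0, qend=40, sstart=500, send=540)
        assert best_aligned_region(100, [small, big]) is big

    def test_single_alignment(self):
        a = _aln()
        assert best_aligned_region(100, [a]) is a

    def test_coverage_tie_breaks_on_identity(self):
        a = _aln(ident=95.0)
        b = _aln(ident=99.0, sstart=500, send=600)
        assert best_aligned_region(100, [a, b]) is b

    def test_no_alignment_is_none(self):
        assert best_aligned_region(100, []) is None


def _bruteforce_flanked(genome_row, cdna_row, flank=5):
    """Independent oracle: direct column scan."""
    n_ag = n_ga = 0
    n = len(genome_row)
    for i in range(n):
        g, c = genome_row[i], cdna_row[i]
        if (g, c) not in (("A", "G"), ("G", "A")):
            continue
        if i < flank or i >= n - flank:
            continue
        ok = True
        for j in list(range(i - flank, i)) + list(range(i + 1, i + 1 + flank)):
            if genome_row[j] == "-" or genome_row[j] != cdna_row[j]:
                ok = False
                break
        if ok:
            if g == "A":
                n_ag += 1
            else:
                n_ga += 1
    return n_ag, n_ga


class TestFlankedCounting:
    def test_minimal_qualifying_window(self):
        genome = "CCCCC" + "A" + "GGGGG"
        cdna = "CCCCC" + "G" + "GGGGG"
        assert count_flanked_changes((genome, cdna)) == (1, 0)

    def test_flank_mismatch_disqualifies(self):
        genome = "CCCCC" + "A" + "GGGGG"
        cdna = "TCCCC" + "G" + "GGGGG"
        assert count_flanked_changes((genome, cdna)) == (0, 0)

    def test_mixed_changes_counted_separately(self):
        genome = "C" * 10 + "A" + "C" * 10 + "G" + "C" * 10 + "A" + "C" * 10
        cdna = "C" * 10 + "G" + "C" * 10 + "A" + "C" * 10 + "G" + "C" * 10
        assert count_flanked_changes((genome, cdna)) == (2, 1)

    def test_gap_in_flank_disqualifies(self):
        genome = "CC-CC C A GGGGG".replace(" ", "")
        cdna = "CC-CC C G GGGGG".replace(" ", "")
        # gap sits inside the left flank window of the A->G column
        assert count_flanked_changes((genome, cdna)) == (0, 0)

    @given(st.integers(0, 2**31 - 1), st.integers(20, 200))
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_bruteforce_scan(self, seed, length):
        rng = np.random.default_rng(seed)
        genome_row = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
        cdna = [
            ("ACGT"[int(rng.integers(0, 4))] if rng.random() < 0.15 else b)
            for b in genome_row
        ]
        pairing = (genome_row, "".join(cdna))
        assert count_flanked_changes(pairing) == _bruteforce_flanked(*pairing)

    def test_longer_flank_never_increases_counts(self):
        rng = np.random.default_rng(42)
        genome_row = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        cdna = "".join(
            ("G" if b == "A" and rng.random() < 0.2 else b) for b in genome_row
        )
        prev = count_flanked_changes((genome_row, cdna), flank=1)
        for flank in range(2, 9):
            cur = count_flanked_changes((genome_row, cdna), flank=flank)
            assert cur[0] <= prev[0] and cur[1] <= prev[1]
            prev = cur


class TestStrandHandling:
    def test_minus_strand_pairing_is_reverse_complemented_once(self):
        """A minus-strand locus must be counted in cDNA orientation: an
        edited A->G site on the transcript is a T->C change on the
        genome's plus strand."""
        transcript = "CCCCCTTTTTATTTTTCCCCC"
        edited = transcript.replace("A", "G")  # single central A edited
        genome_plus = revcomp(transcript)  # gene lies on the minus strand
        aln = _aln(qend=len(edited), send=len(genome_plus), strand="-")
        pairing = pairing_from_alignment(edited, genome_plus, aln)
        assert pairing[0] == transcript
        assert count_flanked_changes(pairing) == (1, 0)
        # normalising a second time turns the A->G column into T->C,
        # which is not counted at all: orientation must be applied once
        twice = (revcomp(pairing[0]), revcomp(pairing[1]))
        assert count_flanked_changes(twice) == (0, 0)


class TestEditingFraction:
    def test_published_style_counts(self):
        # 142 A->G vs 97 G->A discordances -> excess asymmetry 45/239
        assert editing_fraction(142, 97) == pytest.approx(45 / 239)

    def test_symmetry_gives_zero(self):
        assert editing_fraction(100, 100) == 0.0

    def test_pure_editing_limit(self):
        assert editing_fraction(50, 0) == 1.0

    def test_undefined_when_no_discordance(self):
        with pytest.raises(ValueError):
            editing_fraction(0, 0)

    def test_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b = int(rng.integers(0, 100)), int(rng.integers(0, 100))
            if a + b == 0:
                continue
            assert -1.0 <= editing_fraction(a, b) <= 1.0


class TestUtrComparison:
    def test_perfect_utr(self):
        out = utr_mismatch_rate({"q1": ("C" * 200, "C" * 200)})
        assert out["n_perfect"] == 1 and out["aggregate_rate"] == 0.0

    def test_aggregate_rate_arithmetic(self):
        perfect = ("C" * 100, "C" * 100)
        one_mm = ("C" * 100, "C" * 50 + "T" + "C" * 49)
        out = utr_mismatch_rate({"a": perfect, "b": one_mm})
        assert out["aggregate_rate"] == pytest.approx(0.005)
        assert out["n_perfect"] == 1 and out["n_total"] == 2

    def test_polymorphism_rate_recovered(self):
        """With polymorphism only (no editing, no sequencing error), the
        aggregate cDNA/genome mismatch rate estimates the configured
        polymorphism rate."""
        rate = 0.004
        cfg = cm.SimConfig(seed=41, n_genes=40, n_reads=10, n_chromosomes=3,
                           polymorphism_rate=rate, editing_rate=0.0,
                           seq_error_rate=0.0, frac_duplicated=0.0,
                           frac_pseudogene=0.0)
        genome, models, _ = cm.simulate_genome(cfg)
        gmap = {r.id: r.sequence for r in genome}
        pairings = {}
        for gm in models:
            ref = gene_transcript(gmap, gm)
            hap = list(ref)
            for t, alt in gm.polymorphisms:
                hap[t] = alt
            pairings[gm.gene_id] = (ref, "".join(hap))
        out = utr_mismatch_rate(pairings)
        total = sum(u.utr_length for u in out["per_query"])
        se = np.sqrt(rate * (1 - rate) / total)
        assert abs(out["aggregate_rate"] - rate) <= 3 * se


class TestPipelineEditingRecovery:
    def test_noiseless_editing_only_gives_fraction_one(self):
        cfg = cm.SimConfig(seed=4, n_reads=300, seq_error_rate=0.0,
                           polymorphism_rate=0.0, editing_rate=0.01,
                           frac_duplicated=0.0, frac_pseudogene=0.0, n_genes=8)
        genome, models, _ = cm.simulate_genome(cfg)
        reads, _, truth = cm.simulate_reads(genome, models, cfg)
        gmap = {r.id: r.sequence for r in genome}
        alns = cm.naive_align(reads, genome)
        by_q = {}
        for a in alns:
            by_q.setdefault(a.query_id, []).append(a)
        n_ag = n_ga = 0
        for r in reads:
            best = best_aligned_region(len(r.sequence), by_q.get(r.id, []))
            if best is None:
                continue
            ag, ga = count_flanked_changes(
                pairing_from_alignment(r.sequence, gmap[best.subject_id], best))
            n_ag += ag
            n_ga += ga
        assert truth.editing_sites
        assert n_ag > 0 and n_ga == 0
        assert editing_fraction(n_ag, n_ga) == 1.0
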