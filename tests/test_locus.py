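import numpy as np
import pytest

import capmap as cm
from capmap.io_formats import AlignmentRecord
from capmap.locus import (
    LocusCall,
    MappingThresholds,
    call_loci,
    extend_locus,
    locus_density,
    merge_loci,
    select_anchor,
    tabulate_loci,
)


def _aln(q="q1", s="chr1", sstart=0, send=1000, score=200.0, ident=99.0,
         strand="+", length=None):
    length = length or (send - sstart)
    return AlignmentRecord(
        query_id=q, subject_id=s, percent_identity=ident, aln_length=length,
        mismatches=0, gap_opens=0, qstart=0, qend=length,
        sstart=sstart, send=send, evalue=0.0, score=score, strand=strand,
    )


def brute_force_merge(intervals):
    """Independent oracle: exhaustive pairwise union-find closure of the
    overlap-and-same-strand relation."""
    n = len(intervals)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, a1, b1 = intervals[i]
            cj, sj, a2, b2 = intervals[j]
            if ci == cj and si == sj and a1 < b2 and a2 < b1:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = set()
    for members in groups.values():
        c, s = intervals[members[0]][0], intervals[members[0]][1]
        lo = min(intervals[m][2] for m in members)
        hi = max(intervals[m][3] for m in members)
        out.add((c, s, lo, hi, len(members)))
    return out


class TestAnchor:
    def test_highest_score_wins(self):
        a = _aln(score=250)
        b = _aln(score=180, sstart=5000, send=6000)
        assert select_anchor([a, b]) is a

    def test_score_boundary_strict(self):
        assert select_anchor([_aln(score=100.0, ident=95.0)]) is None
        assert select_anchor([_aln(score=100.5, ident=95.0)]) is not None

    def test_identity_boundary_strict(self):
        assert select_anchor([_aln(score=150.0, ident=90.0)]) is None
        assert select_anchor([_aln(score=150.0, ident=90.1)]) is not None

    def test_mixed_queries_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            select_anchor([_aln(q="q1"), _aln(q="q2")])

    def test_tie_break_is_deterministic(self):
        a = _aln(s="chr2", sstart=100, send=200, score=150, ident=95)
        b = _aln(s="chr1", sstart=100, send=200, score=150, ident=95)
        assert select_anchor([a, b]) is b  # smaller subject_id


class TestExtension:
    def test_intron_gap_under_1mb_absorbed(self):
        anchor = _aln(sstart=999_999, send=1_001_000)
        exon2 = _aln(sstart=1_499_999, send=1_500_500)
        locus = extend_locus(anchor, [anchor, exon2])
        assert (locus.start, locus.end) == (999_999, 1_500_500)

    def test_chaining_to_fixpoint(self):
        # third alignment is 2 Mb past the anchor but 0.9 Mb past the
        # second alignment: absorbed only because extension iterates
        anchor = _aln(sstart=0, send=1000)
        mid = _aln(sstart=900_000, send=901_000)
        far = _aln(sstart=1_800_000, send=1_801_000)
        locus = extend_locus(anchor, [anchor, mid, far])
        assert (locus.start, locus.end) == (0, 1_801_000)

    def test_gap_of_exactly_1mb_not_absorbed(self):
        anchor = _aln(sstart=0, send=1000)
        far = _aln(sstart=1_001_000, send=1_002_000)  # gap exactly 1 Mb
        locus = extend_locus(anchor, [anchor, far])
        assert locus.end == 1000

    def test_opposite_strand_not_absorbed(self):
        anchor = _aln(sstart=0, send=1000)
        near_rev = _aln(sstart=11_000, send=12_000, strand="-")
        locus = extend_locus(anchor, [anchor, near_rev])
        assert locus.end == 1000

    def test_other_subject_ignored(self):
        anchor = _aln(sstart=0, send=1000)
        other = _aln(s="chr2", sstart=1500, send=2500)
        locus = extend_locus(anchor, [anchor, other])
        assert (locus.chromosome, locus.end) == ("chr1", 1000)


def _locus(chrom, start, end, strand, members):
    return LocusCall("", chrom, start, end, strand, set(members))


class TestMerge:
    def test_overlapping_same_strand_merge(self):
        out = merge_loci([_locus("chr2", 100, 500, "+", {"a"}),
                          _locus("chr2", 400, 900, "+", {"b"})])
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (100, 900)
        assert out[0].member_query_ids == {"a", "b"}

    def test_opposite_strands_stay_apart(self):
        out = merge_loci([_locus("chr2", 100, 500, "+", {"a"}),
                          _locus("chr2", 100, 500, "-", {"b"})])
        assert len(out) == 2

    def test_transitive_chain_collapses(self):
        out = merge_loci([
            _locus("chr1", 0, 100, "+", {"a"}),
            _locus("chr1", 90, 200, "+", {"b"}),
            _locus("chr1", 190, 300, "+", {"c"}),
        ])
        assert len(out) == 1
        assert out[0].member_query_ids == {"a", "b", "c"}

    def test_abutting_intervals_not_merged(self):
        out = merge_loci([_locus("chr1", 0, 100, "+", {"a"}),
                          _locus("chr1", 100, 200, "+", {"b"})])
        assert len(out) == 2

    def test_idempotent_and_permutation_invariant(self):
        rng = np.random.default_rng(5)
        loci = [
            _locus("chr1", int(s), int(s) + int(l), "+-"[int(st)], {f"q{i}"})
            for i, (s, l, st) in enumerate(
                zip(rng.integers(0, 5000, 30), rng.integers(1, 800, 30),
                    rng.integers(0, 2, 30)))
        ]
        once = merge_loci(loci)
        twice = merge_loci(once)
        assert [(l.chromosome, l.start, l.end, l.strand, l.member_query_ids)
                for l in once] == [
            (l.chromosome, l.start, l.end, l.strand, l.member_query_ids)
            for l in twice]
        perm = [loci[i] for i in rng.permutation(len(loci))]
        assert [(l.start, l.end, l.strand) for l in merge_loci(perm)] == [
            (l.start, l.end, l.strand) for l in once]

    def test_matches_bruteforce_closure_on_random_intervals(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(1, 51))
            intervals = []
            for i in range(n):
                c = f"chr{int(rng.integers(1, 3))}"
                s = "+-"[int(rng.integers(0, 2))]
                a = int(rng.integers(0, 3000))
                b = a + int(rng.integers(1, 500))
                intervals.append((c, s, a, b))
            loci = [_locus(c, a, b, s, {f"q{i}"})
                    for i, (c, s, a, b) in enumerate(intervals)]
            got = {(l.chromosome, l.strand, l.start, l.end, len(l.member_query_ids))
                   for l in merge_loci(loci)}
            assert got == brute_force_merge(intervals)


class TestTables:
    def test_counts_by_chromosome_and_strand(self):
        loci = [_locus("chr1", 0, 10, "+", {"a"}),
                _locus("chr1", 20, 30, "+", {"b"}),
                _locus("chr1", 40, 50, "-", {"c"})]
        t = tabulate_loci(loci)
        row = t[t.chromosome == "chr1"].iloc[0]
        assert (row.forward, row.reverse, row.total) == (2, 1, 3)
        total = t[t.chromosome == "Total"].iloc[0]
        assert total.total == 3

    def test_scaffold_only_loci_fill_unplaced_row(self):
        loci = [LocusCall("L", "scaffold_1", 0, 10, "+", {"a"},
                          is_unplaced_scaffold=True)]
        t = tabulate_loci(loci, chromosomes=["chr1"])
        assert t[t.chromosome == "chr1"].iloc[0].total == 0
        assert t[t.chromosome == "Unplaced scaffolds"].iloc[0].forward == 1

    def test_density_window_enumeration(self):
        loci = [_locus("chr1", 2_400_000, 2_500_000, "+", {"a"})]
        d = locus_density(loci, {"chr1": 10_000_000})
        hits = d[d.forward > 0]
        # every window starting 0 .. 2.4 Mb intersects the locus
        assert hits.window_start.min() == 0
        assert hits.window_start.max() == 2_400_000
        assert (d[d.window_start > 2_400_000].forward == 0).all()

    def test_density_empty_chromosome_all_zero(self):
        d = locus_density([], {"chr1": 1_000_000})
        assert (d.forward == 0).all() and (d.reverse == 0).all()

    def test_density_strand_tracks_independent(self):
        loci = [_locus("chr1", 100, 200, "+", {"a"}),
                _locus("chr1", 100, 200, "-", {"b"})]
        d = locus_density(loci, {"chr1": 300_000})
        assert d.iloc[0].forward == 1 and d.iloc[0].reverse == 1


class TestRecovery:
    def test_noiseless_simulation_recovers_gene_count(self, noiseless_sim):
        alns = cm.naive_align(noiseless_sim["reads"], noiseless_sim["genome"])
        loci, unmapped = call_loci(alns)
        assert unmapped == []
        assert len(loci) == len(noiseless_sim["models"])
        # each locus coincides with exactly one gene (same chromosome and
        # strand, overlapping span; hull may overrun exon ends by a few
        # chance-match bases of ungapped extension)
        for l in loci:
            overlapping = [
                m for m in noiseless_sim["models"]
                if m.chromosome == l.chromosome and m.strand == l.strand
                and m.span[0] < l.end and l.start < m.span[1]
            ]
            assert len(overlapping) == 1

    def test_no_merged_locus_mixes_strands(self, small_sim):
        alns = cm.naive_align(small_sim["reads"], small_sim["genome"])
        by_query = {}
        for a in alns:
            by_query.setdefault(a.query_id, []).append(a)
        per_query = []
        thresholds = MappingThresholds()
        for q, group in by_query.items():
            anchor = select_anchor(group, thresholds)
            if anchor is not None:
                per_query.append(extend_locus(anchor, group, thresholds))
        merged = merge_loci(per_query)
        assert len(merged) <= len(per_query)
        for locus in merged:
            contributing = {p.strand for p in per_query
                            if p.member_query_ids & locus.member_query_ids}
            assert contributing == {locus.strand}
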