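"""Aligner: anchors vs exhaustive oracle, chaining, extension, one-to-one, diffs."""

import itertools

import numpy as np
import pytest

from pantrio.align import (AlignerConfig, AlignmentBlock, Anchor, align_genomes,
                           cluster_anchors, extend_cluster, filter_one_to_one,
                           find_anchors, summarize_diff)
from pantrio.seqio import SequenceSet, random_dna, revcomp


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def count_occurrences(hay: str, needle: str) -> int:
    n = 0
    start = 0
    while True:
        i = hay.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def brute_maximal_matches(ref: str, qry: str, min_len: int):
    """All maximal exact matches >= min_len on both strands, unique in ref.

    Exhaustive: for every (ref pos, qry pos, strand), extend and keep only
    matches that cannot be extended left; uniqueness = the matched substring
    occurs exactly once on the reference forward strand.
    """
    out = set()
    for strand in "+-":
        q = qry if strand == "+" else revcomp(qry)
        for i in range(len(ref)):
            for j in range(len(q)):
                if ref[i] != q[j] or ref[i] == "N":
                    continue
                if i > 0 and j > 0 and ref[i - 1] == q[j - 1] and ref[i - 1] != "N":
                    continue  # extendable left: not maximal
                length = 0
                while (i + length < len(ref) and j + length < len(q)
                       and ref[i + length] == q[j + length]
                       and ref[i + length] != "N"):
                    length += 1
                if length < min_len:
                    continue
                if count_occurrences(ref, ref[i:i + length]) != 1:
                    continue
                qf = j if strand == "+" else len(q) - (j + length)
                out.add((i, qf, length, strand))
    return out


def brute_best_subset(blocks, overlap_tol=10):
    """Exponential-search oracle for the max-weight consistent block subset."""
    def compatible(sub):
        for a, b in itertools.combinations(sub, 2):
            for name_a, s_a, e_a, name_b, s_b, e_b in (
                    (a.ref_name, a.ref_start, a.ref_end,
                     b.ref_name, b.ref_start, b.ref_end),
                    (a.qry_name, a.qry_start, a.qry_end,
                     b.qry_name, b.qry_start, b.qry_end)):
                if name_a == name_b:
                    ov = min(e_a, e_b) - max(s_a, s_b)
                    if ov > overlap_tol:
                        return False
        return True

    best_w, best = -1.0, ()
    for r in range(len(blocks) + 1):
        for sub in itertools.combinations(blocks, r):
            if compatible(sub):
                w = sum(b.weight for b in sub)
                if w > best_w:
                    best_w, best = w, sub
    return best_w, best


def mk_anchor(r, q, length, strand="+"):
    return Anchor("r", r, "q", q, length, strand, q)


def mk_block(i, rs, re_, qs, qe, identity=1.0, qname="q"):
    cols = re_ - rs
    return AlignmentBlock("r", rs, re_, qname, qs, qe, "+",
                          matches=int(cols * identity), columns=cols,
                          substitutions=i, small_indel_events=0)


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------

class TestAnchors:
    def test_identity_single_full_anchor(self):
        s = random_dna(np.random.default_rng(0), 500)
        an = find_anchors(SequenceSet({"r": s}), SequenceSet({"q": s}))
        assert [(a.ref_start, a.qry_start, a.length, a.strand)
                for a in an] == [(0, 0, 500, "+")]

    def test_reverse_complement_single_minus_anchor(self):
        s = random_dna(np.random.default_rng(1), 500)
        an = find_anchors(SequenceSet({"r": s}), SequenceSet({"q": revcomp(s)}))
        assert [(a.ref_start, a.qry_start, a.length, a.strand)
                for a in an] == [(0, 0, 500, "-")]

    def test_matches_exhaustive_oracle_many_seeds(self):
        """Random <=300 bp pairs sharing planted segments, 100 seeds."""
        config = AlignerConfig(min_match=12)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            core = random_dna(rng, int(rng.integers(20, 80)))
            ref = (random_dna(rng, int(rng.integers(0, 60))) + core
                   + random_dna(rng, int(rng.integers(0, 60))) + core[: 30])
            piece = core if rng.random() < 0.5 else revcomp(core)
            qry = (random_dna(rng, int(rng.integers(0, 60))) + piece
                   + random_dna(rng, int(rng.integers(0, 60))))
            got = {(a.ref_start, a.qry_start, a.length, a.strand)
                   for a in find_anchors(SequenceSet({"r": ref}),
                                         SequenceSet({"q": qry}), config)}
            assert got == brute_maximal_matches(ref, qry, 12), f"seed {seed}"

    def test_n_breaks_anchors(self):
        rng = np.random.default_rng(2)
        left, right = random_dna(rng, 80), random_dna(rng, 80)
        ref = left + "N" * 5 + right
        qry = left + right
        an = find_anchors(SequenceSet({"r": ref}), SequenceSet({"q": qry}))
        spans = sorted((a.ref_start, a.length) for a in an)
        assert spans == [(0, 80), (85, 80)]

    def test_repeat_copies_not_unique(self):
        rng = np.random.default_rng(3)
        unit = random_dna(rng, 60)
        ref = random_dna(rng, 50) + unit + random_dna(rng, 50) + unit + random_dna(rng, 50)
        qry = random_dna(rng, 40) + unit + random_dna(rng, 40)
        an = find_anchors(SequenceSet({"r": ref}), SequenceSet({"q": qry}))
        # the bare unit occurs twice in ref: no anchor may be unit-only
        assert all(not (a.length <= 60) for a in an) or an == []


class TestClustering:
    def test_same_diagonal_chain(self):
        c = cluster_anchors([mk_anchor(0, 0, 40), mk_anchor(90, 90, 40)])
        assert len(c) == 1 and len(c[0]) == 2

    def test_short_lone_anchor_discarded(self):
        assert cluster_anchors([mk_anchor(0, 0, 60)]) == []

    def test_long_lone_anchor_retained(self):
        assert len(cluster_anchors([mk_anchor(0, 0, 70)])) == 1

    def test_far_anchors_not_chained(self):
        c = cluster_anchors([mk_anchor(0, 0, 70), mk_anchor(500, 500, 70)])
        assert len(c) == 2

    def test_off_band_not_chained(self):
        # drift 41 over gap 1 exceeds band factor 5
        c = cluster_anchors([mk_anchor(0, 0, 70), mk_anchor(71, 30, 70)])
        assert len(c) == 2

    def test_mixed_groups_rejected(self):
        with pytest.raises(ValueError):
            cluster_anchors([mk_anchor(0, 0, 70),
                             Anchor("r2", 0, "q", 0, 70, "+", 0)])


class TestExtension:
    def test_identical_cluster_identity_one(self):
        s = random_dna(np.random.default_rng(4), 300)
        ref, qry = SequenceSet({"r": s}), SequenceSet({"q": s})
        blocks = extend_cluster([Anchor("r", 0, "q", 0, 300, "+", 0)], ref, qry)
        b, = blocks
        assert b.identity == 1.0
        assert b.substitutions == 0 and b.small_indel_events == 0

    def test_single_substitution(self):
        rng = np.random.default_rng(5)
        s = random_dna(rng, 200)
        pos = 100
        sub = "A" if s[pos] != "A" else "C"
        q = s[:pos] + sub + s[pos + 1:]
        res = align_genomes(SequenceSet({"r": s}), SequenceSet({"q": q}))
        b, = res.blocks
        assert b.substitutions == 1
        assert b.identity == pytest.approx((b.columns - 1) / b.columns)
        assert b.ref_span == 200

    def test_seven_bp_deletion_is_large_indel(self):
        rng = np.random.default_rng(6)
        s = random_dna(rng, 260)
        q = s[:120] + s[127:]        # 7 bp missing from the query
        res = align_genomes(SequenceSet({"r": s}), SequenceSet({"q": q}))
        b, = res.blocks
        assert b.large_indels == [(7, "ref")]
        assert b.small_indel_events == 0

    def test_three_bp_indel_is_small(self):
        rng = np.random.default_rng(7)
        s = random_dna(rng, 260)
        q = s[:120] + s[123:]
        res = align_genomes(SequenceSet({"r": s}), SequenceSet({"q": q}))
        b, = res.blocks
        assert b.small_indel_events == 1 and b.large_indels == []


class TestOneToOne:
    def test_keep_heavier_of_conflicting_pair(self):
        b1 = mk_block(0, 0, 900, 0, 900)
        b2 = mk_block(1, 1000, 1400, 0, 400)
        kept = filter_one_to_one([b1, b2])
        assert [b.substitutions for b in kept] == [0]

    def test_disjoint_all_kept(self):
        blocks = [mk_block(i, i * 1000, i * 1000 + 500, i * 1000, i * 1000 + 500)
                  for i in range(4)]
        assert len(filter_one_to_one(blocks)) == 4

    def test_matches_exponential_oracle(self):
        """Random instances of <= 12 blocks vs subset enumeration."""
        for seed in range(40):
            rng = np.random.default_rng(seed + 500)
            n = int(rng.integers(2, 13))
            blocks = []
            for i in range(n):
                rs = int(rng.integers(0, 2000))
                ln = int(rng.integers(50, 600))
                qs = int(rng.integers(0, 2000))
                ident = float(rng.uniform(0.8, 1.0))
                blocks.append(mk_block(i, rs, rs + ln, qs, qs + ln, ident))
            kept = filter_one_to_one(blocks)
            got_ids = {b.substitutions for b in kept}
            best_w, best = brute_best_subset(blocks)
            got_w = sum(blocks[i].weight for i in got_ids)
            assert got_w == pytest.approx(best_w), f"seed {seed}"

    def test_no_overlaps_after_filtering(self):
        rng = np.random.default_rng(99)
        blocks = [mk_block(i, int(rng.integers(0, 3000)),
                           0, int(rng.integers(0, 3000)), 0)
                  for i in range(20)]
        for i, b in enumerate(blocks):
            b.ref_end = b.ref_start + int(rng.integers(50, 400))
            b.qry_end = b.qry_start + (b.ref_end - b.ref_start)
            b.columns = b.ref_span
            b.matches = b.columns
        kept = filter_one_to_one(blocks)
        for a, b in itertools.combinations(kept, 2):
            assert min(a.ref_end, b.ref_end) <= max(a.ref_start, b.ref_start)
            assert min(a.qry_end, b.qry_end) <= max(a.qry_start, b.qry_start)


class TestDiffSummary:
    def test_identical_genomes(self):
        s = random_dna(np.random.default_rng(8), 2000)
        res = align_genomes(SequenceSet({"r": s}), SequenceSet({"q": s}))
        summ = res.summary
        assert summ.avg_identity == 1.0
        assert summ.unaligned_ref_fraction == 0.0
        assert summ.unaligned_qry_fraction == 0.0
        assert (summ.inversions, summ.relocations, summ.translocations) == (0, 0, 0)

    def test_inversion_detected(self):
        s = random_dna(np.random.default_rng(9), 3000)
        inv = s[:1000] + revcomp(s[1000:2000]) + s[2000:]
        summ = align_genomes(SequenceSet({"r": s}), SequenceSet({"q": inv})).summary
        assert summ.inversions >= 1
        assert summ.translocations == 0

    def test_translocation_detected(self):
        rng = np.random.default_rng(10)
        a1, a2 = random_dna(rng, 2000), random_dna(rng, 2000)
        ref = SequenceSet({"s1": a1, "s2": a2})
        qry = SequenceSet({"s1": a1[:1000] + a2[1000:],
                           "s2": a2[:1000] + a1[1000:]})
        summ = align_genomes(ref, qry).summary
        assert summ.translocations >= 1
        assert summ.inversions == 0

    def test_relocation_detected(self):
        rng = np.random.default_rng(11)
        a, b, c = random_dna(rng, 1500), random_dna(rng, 1500), random_dna(rng, 1500)
        ref = SequenceSet({"s": a + b + c})
        qry = SequenceSet({"s": b + a + c})   # a and b swapped: out of order
        summ = align_genomes(ref, qry).summary
        assert summ.relocations >= 1

    def test_empty_blocks(self):
        s = random_dna(np.random.default_rng(12), 300)
        summ = summarize_diff([], SequenceSet({"r": s}), SequenceSet({"q": s}))
        assert summ.unaligned_ref_fraction == 1.0
        assert summ.unaligned_qry_fraction == 1.0


class TestUnaligned:
    def test_full_alignment_empty(self):
        s = random_dna(np.random.default_rng(13), 1000)
        res = align_genomes(SequenceSet({"r": s}), SequenceSet({"q": s}))
        assert res.unaligned(SequenceSet({"r": s})).total_bp() == 0

    def test_planted_insertion_recovered(self):
        rng = np.random.default_rng(14)
        left, right = random_dna(rng, 3000), random_dna(rng, 3000)
        novel = random_dna(rng, 5000)
        ref = SequenceSet({"r": left + novel + right})
        qry = SequenceSet({"q": left + right})
        res = align_genomes(ref, qry)
        un = res.unaligned(ref)
        assert abs(un.total_bp() - 5000) <= 20      # extension slack only
        assert un.count() == 1

    def test_per_base_oracle_on_toy_pair(self):
        rng = np.random.default_rng(15)
        core = random_dna(rng, 120)
        ref = random_dna(rng, 60) + core + random_dna(rng, 60)
        qry = random_dna(rng, 30) + core + random_dna(rng, 30)
        config = AlignerConfig(min_match=20)
        res = align_genomes(SequenceSet({"r": ref}), SequenceSet({"q": qry}), config)
        un = res.unaligned(SequenceSet({"r": ref}))
        mask = np.ones(len(ref), dtype=bool)
        for b in res.blocks_all:
            mask[b.ref_start:b.ref_end] = False
        expected_bp = int(mask.sum())
        assert un.total_bp() == expected_bp


class TestInvariants:
    def test_monotonic_in_min_cluster(self):
        rng = np.random.default_rng(16)
        pieces = [random_dna(rng, int(rng.integers(40, 400))) for _ in range(12)]
        ref = "".join(pieces)
        order = list(range(12))
        rng.shuffle(order)
        qry = "".join(pieces[i] for i in order)
        totals = []
        refset = SequenceSet({"r": ref})
        for mc in (65, 150, 400, 800):
            config = AlignerConfig(min_cluster=mc)
            res = align_genomes(refset, SequenceSet({"q": qry}), config)
            totals.append(len(ref) - res.unaligned(refset).total_bp())
        assert totals == sorted(totals, reverse=True)

    def test_zero_divergence_symmetry(self, exact_trio):
        """Unaligned(A vs B) equals planted content absent from B, exactly."""
        truth = exact_trio.truth
        lab = exact_trio.labelings["A"]
        # unaligned to B = sectors not containing B: A, AC
        expect = truth.sector_set("A", ("A", "AC"))
        got = lab.specific.union(lab.shared_2 if lab.others[1] == "C"
                                 else lab.shared_1)
        assert got.total_bp() == expect.total_bp()
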