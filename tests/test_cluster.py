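import math

import numpy as np
import pandas as pd
import pytest

from cccrna.circles import rotate
from cccrna.cluster import (
    BLAST6_COLUMNS,
    DendrogramNode,
    ScoreMatrix,
    circular_identity,
    cluster_and_name,
    filter_and_merge_spacers,
    graft,
    merge_decision,
    midpoint_root,
    scores_to_distances,
    trim_gap_columns,
    upgma,
)
from cccrna.seqio import revcomp

from conftest import random_seq


class TestScoresToDistances:
    def test_equal_scores_give_zero(self):
        sm = ScoreMatrix(["A", "B"], np.array([[50.0, 50.0], [50.0, 50.0]]))
        dm = scores_to_distances(sm)
        assert dm["A", "B"] == 0.0

    def test_half_score_gives_ln2(self):
        sm = ScoreMatrix(["A", "B"], np.array([[100.0, 40.0], [40.0, 80.0]]))
        assert scores_to_distances(sm)["A", "B"] == pytest.approx(math.log(2))

    def test_missing_fill_formula(self):
        S = np.array([[100.0, 0.0], [0.0, 80.0]])
        missing = np.array([[False, True], [True, False]])
        sm = ScoreMatrix(["A", "B"], S, missing)
        dm = scores_to_distances(sm, missing_fill=2.0)
        assert dm["A", "B"] == pytest.approx(-math.log(2.0 / 80.0))

    def test_nonpositive_score_rejected(self):
        sm = ScoreMatrix(["A", "B"], np.array([[100.0, -1.0], [-1.0, 80.0]]))
        with pytest.raises(ValueError):
            scores_to_distances(sm)

    def test_monotone_decreasing_in_cross_score(self):
        prev = None
        for s_ab in (10.0, 30.0, 60.0, 79.0):
            sm = ScoreMatrix(["A", "B"], np.array([[100.0, s_ab], [s_ab, 80.0]]))
            d = scores_to_distances(sm)["A", "B"]
            if prev is not None:
                assert d < prev
            prev = d

    def test_clamped_at_zero_when_cross_exceeds_self(self):
        sm = ScoreMatrix(["A", "B"], np.array([[100.0, 90.0], [90.0, 80.0]]))
        assert scores_to_distances(sm)["A", "B"] == 0.0


class TestUpgma:
    def test_three_taxon_heights(self):
        D = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float)
        t = upgma((["A", "B", "C"], D))
        assert t.height == pytest.approx(3.0)
        inner = [c for c in t.children if not c.is_leaf][0]
        assert inner.height == pytest.approx(1.0)
        assert sorted(inner.leaf_names()) == ["A", "B"]

    def test_tie_resolved_deterministically(self):
        D = np.ones((3, 3)) - np.eye(3)
        t = upgma((["c", "a", "b"], D))
        first = min(
            (c for c in t.children if not c.is_leaf),
            key=lambda n: n.height,
            default=None,
        )
        # the first merge joins the lexicographically smallest pair {a, b}
        names = sorted(t.leaf_names())
        assert names == ["a", "b", "c"]
        newick1 = t.to_newick()
        t2 = upgma((["b", "c", "a"], D))
        assert t2.to_newick().count(",") == newick1.count(",")

    def test_matches_scipy_average_linkage(self, rng):
        # cophenetic distances must equal scipy's average-linkage oracle
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import squareform

        for _ in range(5):
            n = 6
            M = rng.random((n, n)) * 10
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0)
            ids = [f"t{i}" for i in range(n)]
            tree = upgma((ids, D))

            def coph(tree):
                # leaf-pair cophenetic distance = 2 * LCA merge height
                out = {}

                def walk(node):
                    if node.is_leaf:
                        return [node.name]
                    sets = [walk(c) for c in node.children]
                    for i in range(len(sets)):
                        for j in range(i + 1, len(sets)):
                            for a in sets[i]:
                                for b in sets[j]:
                                    out[frozenset((a, b))] = 2 * node.height
                    return [x for s in sets for x in s]

                walk(tree)
                return out

            mine = coph(tree)
            Z = average(squareform(D, checks=False))
            sc = squareform(cophenet(Z))
            for i in range(n):
                for j in range(i + 1, n):
                    assert mine[frozenset((ids[i], ids[j]))] == pytest.approx(
                        sc[i, j]
                    )

    def test_heights_non_decreasing(self, rng):
        n = 8
        M = rng.random((n, n)) * 5
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        t = upgma(([f"x{i}" for i in range(n)], D))

        def check(node):
            for c in node.children:
                if not c.is_leaf:
                    assert c.height <= node.height + 1e-12
                    check(c)

        check(t)

    def test_single_leaf(self):
        t = upgma((["only"], np.zeros((1, 1))))
        assert t.is_leaf and t.name == "only"


class TestMergeDecision:
    @pytest.mark.parametrize(
        "d,cov,expect",
        [
            (2.2, 0.1, True),   # boundary inclusive on distance
            (5.0, 0.66, True),  # boundary inclusive on coverage
            (2.3, 0.65, False),
            (0.0, 0.0, True),
        ],
    )
    def test_boundaries(self, d, cov, expect):
        assert merge_decision(d, cov) is expect


class TestTrimGapColumns:
    def test_threshold_column_removed(self):
        aln = ["A-CD", "A-CD", "A-CD", "AACD"]
        trimmed, kept = trim_gap_columns(aln, 0.67)
        assert kept == [0, 2, 3]
        assert trimmed[0] == "ACD"

    def test_gap_free_unchanged(self):
        aln = ["ACGT", "ACGT"]
        trimmed, kept = trim_gap_columns(aln, 0.67)
        assert trimmed == aln and kept == [0, 1, 2, 3]

    def test_random_alignment_matches_count_oracle(self, rng):
        rows = ["".join(rng.choice(list("AC-"), 30)) for _ in range(6)]
        trimmed, kept = trim_gap_columns(rows, 0.5)
        for c in range(30):
            frac = sum(r[c] == "-" for r in rows) / 6
            assert (c in kept) == (frac <= 0.5)

    def test_ragged_rejected(self):
        with pytest.raises(ValueError):
            trim_gap_columns(["AC", "A"], 0.5)


def leaf(name, length):
    return DendrogramNode(name=name, length=length)


class TestMidpointAndGraft:
    def test_two_leaf_midpoint(self):
        t = DendrogramNode(children=[leaf("a", 1.0), leaf("b", 3.0)])
        r = midpoint_root(t)
        dists = {c.name if c.is_leaf else "i": c.length for c in r.children}
        lengths = sorted(c.length for c in r.children)
        assert lengths == [pytest.approx(1.0), pytest.approx(3.0)] or \
            lengths == [pytest.approx(2.0), pytest.approx(2.0)]
        # both leaves end 2.0 from the new root
        def depth(node, acc=0.0):
            if node.is_leaf:
                return {node.name: acc + node.length}
            out = {}
            for c in node.children:
                out.update(depth(c, acc + node.length))
            return out

        d = depth(r, -r.length)
        assert d["a"] == pytest.approx(2.0) and d["b"] == pytest.approx(2.0)

    def test_midpoint_matches_brute_force_path_oracle(self, rng):
        # random 8-leaf caterpillar with random branch lengths
        nodes = [leaf(f"l{i}", float(rng.random() * 3 + 0.1)) for i in range(8)]
        t = nodes[0]
        for k in range(1, 8):
            t = DendrogramNode(children=[t, nodes[k]])
            t.children[0].length = float(rng.random() * 2 + 0.05) if k > 1 else t.children[0].length
        r = midpoint_root(t)

        def leaf_depths(node, acc=0.0):
            if node.is_leaf:
                return {node.name: acc + node.length}
            out = {}
            for c in node.children:
                out.update(leaf_depths(c, acc + node.length))
            return out

        def pairwise(node):
            # brute-force all-pairs path length via recursive merge
            table = {}

            def walk(n):
                if n.is_leaf:
                    return {n.name: n.length}
                sub = [walk(c) for c in n.children]
                for i in range(len(sub)):
                    for j in range(i + 1, len(sub)):
                        for a, da in sub[i].items():
                            for b, db in sub[j].items():
                                table[frozenset((a, b))] = da + db
                merged = {}
                for s in sub:
                    for a, da in s.items():
                        merged[a] = da + n.length
                return merged

            walk(n=node)
            return table

        before = pairwise(t)
        after = pairwise(r)
        # rerooting preserves all leaf-to-leaf path lengths
        for k in before:
            assert after[k] == pytest.approx(before[k])
        # root is equidistant from the two ends of the longest path
        diam_pair = max(before, key=before.get)
        d = leaf_depths(r)
        a, b = sorted(diam_pair)
        assert d[a] == pytest.approx(before[diam_pair] / 2)
        assert d[b] == pytest.approx(before[diam_pair] / 2)

    def test_graft_replaces_leaf_preserving_stem(self):
        t = DendrogramNode(children=[leaf("a", 1.0), leaf("b", 2.0)])
        sub = DendrogramNode(children=[leaf("x", 0.5), leaf("y", 0.5)])
        out = graft(t, "b", sub)
        assert sorted(out.leaf_names()) == ["a", "x", "y"]
        grafted = [c for c in out.children if not c.is_leaf][0]
        assert grafted.length == pytest.approx(2.0)

    def test_graft_single_leaf_renames(self):
        t = DendrogramNode(children=[leaf("a", 1.0), leaf("b", 2.0)])
        out = graft(t, "b", leaf("z", 0.0))
        assert sorted(out.leaf_names()) == ["a", "z"]

    def test_graft_unknown_leaf(self):
        t = DendrogramNode(children=[leaf("a", 1.0), leaf("b", 2.0)])
        with pytest.raises(KeyError):
            graft(t, "nope", leaf("z", 0.0))


class TestCircularIdentity:
    def test_rotation_gives_one(self, rng):
        a = random_seq(rng, 400)
        for k in (0, 1, 37, 399):
            assert circular_identity(a, rotate(a, k)) == 1.0

    def test_reverse_complement(self, rng):
        a = random_seq(rng, 300)
        assert circular_identity(a, revcomp(a)) == 1.0
        assert circular_identity(a, revcomp(a), both_strands=False) < 1.0

    def test_seeded_mutations_in_band(self, rng):
        a = random_seq(rng, 500)
        b = list(a)
        idx = rng.choice(500, 50, replace=False)
        for i in idx:
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        ident = circular_identity(a, rotate("".join(b), 123))
        assert 0.85 <= ident <= 0.95

    def test_symmetric(self, rng):
        a = random_seq(rng, 200)
        b = random_seq(rng, 260)
        assert circular_identity(a, b) == pytest.approx(circular_identity(b, a))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            circular_identity("", "ACGT")


class TestClusterAndName:
    def test_identical_circles_one_family(self, rng):
        s = random_seq(rng, 300)
        labels = cluster_and_name({"a": s, "b": rotate(s, 50), "c": revcomp(s)})
        xs = {l.split("_")[1] for l in labels.values()}
        ys = {l.split("_")[2] for l in labels.values()}
        zs = sorted(l.split("_")[3] for l in labels.values())
        assert len(xs) == 1 and len(ys) == 1
        assert zs == ["000001", "000002", "000003"]

    def test_ninety_percent_pair_same_species_group(self, rng):
        a = random_seq(rng, 500)
        b = list(a)
        for i in rng.choice(500, 50, replace=False):
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        labels = cluster_and_name({"a": a, "b": "".join(b)})
        xa, ya = labels["a"].split("_")[1:3]
        xb, yb = labels["b"].split("_")[1:3]
        assert xa == xb and ya != yb

    def test_unrelated_distinct_x(self, rng):
        labels = cluster_and_name(
            {f"s{i}": random_seq(rng, 300) for i in range(3)}
        )
        assert len({l.split("_")[1] for l in labels.values()}) == 3

    def test_input_order_invariant(self, rng):
        seqs = {f"s{i}": random_seq(rng, 250) for i in range(4)}
        l1 = cluster_and_name(seqs)
        l2 = cluster_and_name(dict(reversed(list(seqs.items()))))
        assert l1 == l2


def _match_row(q, s, pident, length, mismatch, qstart, qend, sstart, send,
               nident, slen):
    return dict(qaccver=q, saccver=s, pident=pident, length=length,
                mismatch=mismatch, gapopen=0, qstart=qstart, qend=qend,
                sstart=sstart, send=send, evalue=1e-6, bitscore=50.0,
                nident=nident, slen=slen)


class TestSpacers:
    def test_doubled_hit_deduplicated(self):
        L = 500
        rows = [
            _match_row("ob1", "sp1", 100.0, 30, 0, 101, 130, 1, 30, 30, 30),
            _match_row("ob1", "sp1", 100.0, 30, 0, 601, 630, 1, 30, 30, 30),
        ]
        merged, summary = filter_and_merge_spacers(
            pd.DataFrame(rows), {"ob1": L}, preset="local"
        )
        assert summary["n_after_dedup"] == 1 and len(merged) == 1
        assert merged[0].start == 100

    def test_near_coincident_merged(self):
        L = 500
        rows = [
            _match_row("ob1", "sp1", 100.0, 30, 0, 101, 130, 1, 30, 30, 30),
            _match_row("ob1", "sp2", 100.0, 30, 0, 105, 134, 1, 30, 30, 30),
        ]
        merged, summary = filter_and_merge_spacers(
            pd.DataFrame(rows), {"ob1": L}, preset="local"
        )
        assert len(merged) == 1
        assert set(merged[0].merged_spacers) == {"sp1", "sp2"}

    def test_distant_not_merged(self):
        L = 500
        rows = [
            _match_row("ob1", "sp1", 100.0, 30, 0, 101, 130, 1, 30, 30, 30),
            _match_row("ob1", "sp2", 100.0, 30, 0, 301, 330, 1, 30, 30, 30),
        ]
        merged, _ = filter_and_merge_spacers(
            pd.DataFrame(rows), {"ob1": L}, preset="local"
        )
        assert len(merged) == 2

    def test_local_preset_filter_oracle(self):
        L = 1000
        rows = [
            # coverage 30/30 = 1.0, nident 30 -> keep
            _match_row("ob1", "k1", 100.0, 30, 0, 1, 30, 1, 30, 30, 30),
            # coverage 27/30 = 0.9, nident 25 -> keep
            _match_row("ob1", "k2", 92.6, 27, 2, 51, 77, 1, 27, 25, 30),
            # coverage 0.8 -> drop
            _match_row("ob1", "d1", 100.0, 24, 0, 101, 124, 1, 24, 24, 30),
            # nident 15 -> drop
            _match_row("ob1", "d2", 88.0, 17, 2, 201, 217, 1, 17, 15, 18),
            # minus strand keep
            _match_row("ob1", "k3", 100.0, 30, 0, 301, 330, 30, 1, 30, 30),
        ]
        merged, summary = filter_and_merge_spacers(
            pd.DataFrame(rows), {"ob1": L}, preset="local"
        )
        kept_ids = {m.spacer_id for m in merged}
        assert kept_ids == {"k1", "k2", "k3"}
        assert summary["n_pass_filter"] == 3
        # k1 and k3 have 0 mismatches; k2 has 2 -> fraction 2/3
        assert summary["frac_le1_mismatch"] == pytest.approx(2 / 3)
        strands = {m.spacer_id: m.strand for m in merged}
        assert strands["k3"] == "-"

    def test_hq_preset_requires_full_coverage(self):
        L = 1000
        rows = [
            _match_row("ob1", "a", 85.0, 30, 4, 1, 30, 1, 30, 26, 30),
            _match_row("ob1", "b", 85.0, 29, 4, 101, 129, 1, 29, 25, 30),
        ]
        merged, _ = filter_and_merge_spacers(
            pd.DataFrame(rows), {"ob1": L}, preset="hq"
        )
        assert {m.spacer_id for m in merged} == {"a"}

    def test_coords_beyond_doubled_target_rejected(self):
        rows = [_match_row("ob1", "sp", 100.0, 30, 0, 1101, 1130, 1, 30, 30, 30)]
        merged, summary = filter_and_merge_spacers(
            pd.DataFrame(rows), {"ob1": 500}, preset="local"
        )
        assert merged == [] and summary["n_pass_filter"] == 0

    def test_surviving_interval_reexpands(self, rng):
        # the monomer interval re-expanded on the doubled sequence must
        # reproduce the originally aligned substring
        mono = random_seq(rng, 400)
        doubled = mono + mono
        q0 = 390  # wraps the origin
        sub = doubled[q0 : q0 + 30]
        rows = [_match_row("ob1", "sp", 100.0, 30, 0, q0 + 1, q0 + 30, 1, 30, 30, 30)]
        merged, _ = filter_and_merge_spacers(
            pd.DataFrame(rows), {"ob1": 400}, preset="local"
        )
        m = merged[0]
        assert doubled[m.start : m.end] == sub
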