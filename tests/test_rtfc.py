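"""The range tree with fractional cascading: FC indices, build shape, queries."""

from bisect import bisect_left

import numpy as np
import pytest

from allenrange.allen_core import AllenRelation, Bound, GenomicInterval
from allenrange.fixtures import add_duplicates, adversarial_suite, generate_uniform
from allenrange.oracle import brute_interval_query
from allenrange.rtfc import (
    build_rtfc,
    find_split_node,
    make_fc_index,
    query_rtfc,
    visit_count,
)
from conftest import all_valid_intervals

R = AllenRelation


class TestFCIndex:
    def test_strict_subset(self):
        assert make_fc_index([1, 3, 5, 7], [3, 7]).entries == (0, 0, 1, 1)

    def test_identity_when_equal(self):
        assert make_fc_index([2, 4, 6], [2, 4, 6]).entries == (0, 1, 2)

    def test_no_successor_sentinel(self):
        assert make_fc_index([1, 9], [1]).entries == (0, -1)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            make_fc_index([3, 1], [1])
        with pytest.raises(ValueError, match="sorted"):
            make_fc_index([1, 3], [3, 1])

    def test_sentinel_region_is_suffix_and_entries_monotone(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            a1 = sorted(rng.integers(0, 40, size=rng.integers(1, 25)).tolist())
            keep = rng.random(len(a1)) < 0.5
            a2 = [v for v, k in zip(a1, keep) if k]
            entries = make_fc_index(a1, a2).entries
            live = [e for e in entries if e != -1]
            assert live == sorted(live)
            first_sentinel = next((i for i, e in enumerate(entries) if e == -1),
                                  len(entries))
            assert all(e == -1 for e in entries[first_sentinel:])


def _leaves(root):
    out, stack = [], [root]
    while stack:
        v = stack.pop()
        if v.is_leaf:
            out.append(v.interval)
        else:
            stack.append(v.rchild)
            stack.append(v.lchild)
    return out


def _internal_nodes(root):
    out, stack = [], [root]
    while stack:
        v = stack.pop()
        if not v.is_leaf:
            out.append(v)
            stack.append(v.rchild)
            stack.append(v.lchild)
    return out


def _height(root):
    if root.is_leaf:
        return 0
    return 1 + max(_height(root.lchild), _height(root.rchild))


class TestBuild:
    def test_singleton_is_leaf(self, iv):
        root = build_rtfc([iv(3, 9, 0)])
        assert root.is_leaf and root.interval.index == 0
        assert root.ys == [9] and root.idx == [0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_rtfc([])

    def test_multi_chromosome_rejected(self, iv):
        with pytest.raises(ValueError, match="chromosome"):
            build_rtfc([iv(1, 2, 0, chrom="chr1"), iv(1, 2, 1, chrom="chr2")])

    def test_eight_interval_shape(self):
        """Depth-3 tree with split keys at x-order ranks {4; 2,6; 1,3,5,7}."""
        S = adversarial_suite()["cascade_demo8"]
        xs = sorted(a.start for a in S)
        root = build_rtfc(S)
        assert _height(root) == 3
        assert root.x_key == xs[3]
        assert root.lchild.x_key == xs[1] and root.rchild.x_key == xs[5]
        grand = [root.lchild.lchild, root.lchild.rchild,
                 root.rchild.lchild, root.rchild.rchild]
        assert [g.x_key for g in grand] == [xs[0], xs[2], xs[4], xs[6]]
        assert len(root.ys) == 8

    def test_leaves_are_sorted_by_start_then_index(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            S = add_duplicates(
                generate_uniform(int(rng.integers(2, 120)), 40,
                                 int(rng.integers(0, 2**31))),
                5, int(rng.integers(0, 2**31)),
            )
            root = build_rtfc(S)
            got = [(a.start, a.index) for a in _leaves(root)]
            assert got == sorted((a.start, a.index) for a in S)

    def test_internal_data_is_merge_of_children(self):
        S = add_duplicates(generate_uniform(200, 50, 21), 40, 22)
        for v in _internal_nodes(build_rtfc(S)):
            child_pairs = sorted(
                list(zip(v.lchild.ys, v.lchild.idx))
                + list(zip(v.rchild.ys, v.rchild.idx))
            )
            assert list(zip(v.ys, v.idx)) == child_pairs

    def test_x_key_separates_subtrees(self):
        S = generate_uniform(150, 60, 4)
        for v in _internal_nodes(build_rtfc(S)):
            assert max(a.start for a in _leaves(v.lchild)) == v.x_key
            assert all(a.start >= v.x_key for a in _leaves(v.rchild))


class TestSplitNode:
    def test_demo8_split_is_root(self):
        S = adversarial_suite()["cascade_demo8"]
        root = build_rtfc(S)
        # the d query against [2, 10]: open bounds stand in for 2.5 / 9.5
        v = find_split_node(root, Bound.open_at(2), Bound.open_at(10))
        assert v is root

    def test_degenerate_range_splits_at_key_or_leaf(self):
        S = generate_uniform(32, 1000, 14)
        root = build_rtfc(S)
        target = sorted(a.start for a in S)[10]
        b = Bound.closed_at(target)
        v = find_split_node(root, b, b)
        # paths diverge exactly at the node keyed on the target (duplicates of
        # the key may live in its right subtree), or reach a common leaf
        if v.is_leaf:
            assert v.interval.start == target
        else:
            assert v.x_key == target

    def test_degenerate_range_on_absent_value_ends_at_leaf(self):
        S = generate_uniform(32, 1000, 14)
        root = build_rtfc(S)
        absent = max(a.start for a in S) + 5
        b = Bound.closed_at(absent)
        v = find_split_node(root, b, b)
        assert v.is_leaf  # both descents run off the same side of the tree

    def test_matches_independent_path_walk(self):
        rng = np.random.default_rng(31)
        S = generate_uniform(100, 200, 32)
        root = build_rtfc(S)
        for _ in range(200):
            lo, hi = sorted(rng.integers(-5, 205, size=2).tolist())
            x1 = Bound(int(lo), closed=bool(rng.integers(2)))
            x2 = Bound(int(hi), closed=bool(rng.integers(2)))
            # walk the two descent paths independently; last common node wins
            path1, v = [], root
            while True:
                path1.append(v)
                if v.is_leaf:
                    break
                v = v.lchild if x1.admits_above(v.x_key) else v.rchild
            path2, v = [], root
            while True:
                path2.append(v)
                if v.is_leaf:
                    break
                v = v.rchild if x2.admits_below(v.x_key) else v.lchild
            common = root
            for u, w in zip(path1, path2):
                if u is not w:
                    break
                common = u
            assert find_split_node(root, x1, x2) is common


class TestQuery:
    def test_single_leaf_non_matching_relation_empty(self, iv):
        root = build_rtfc([iv(5, 9, 0)])
        assert query_rtfc(root, iv(5, 9), R.OVERLAPS) == set()
        assert visit_count(root) == 1
        assert query_rtfc(root, iv(5, 9), R.EQUALS) == {0}

    def test_demo8_during_query_has_four_results(self, iv):
        S = adversarial_suite()["cascade_demo8"]
        root = build_rtfc(S)
        q = iv(2, 10)
        got = query_rtfc(root, q, R.DURING)
        assert len(got) == 4
        assert got == brute_interval_query(S, q, R.DURING)

    def test_exhaustive_small_universe(self):
        """Every (S, q, r) with endpoints in {0..5}: tree equals oracle."""
        S = all_valid_intervals(5)
        root = build_rtfc(S)
        for q in S:
            for r in R:
                assert query_rtfc(root, q, r) == brute_interval_query(S, q, r), (q, r)

    @pytest.mark.parametrize("name", sorted(adversarial_suite()))
    def test_adversarial_fixtures_match_oracle(self, name, iv):
        S = adversarial_suite()[name]
        root = build_rtfc(S)
        queries = [iv(2, 10), iv(5, 6), iv(10, 20), iv(0, 300), iv(45, 155)]
        for q in queries:
            for r in R:
                assert query_rtfc(root, q, r) == brute_interval_query(S, q, r), (q, r)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(2024)
        rels = list(R)
        for _ in range(40):
            n = int(rng.integers(2, 400))
            S = add_duplicates(
                generate_uniform(n, int(rng.choice([30, 200, 5000])),
                                 int(rng.integers(0, 2**31))),
                max(1, n // 8), int(rng.integers(0, 2**31)),
            )
            root = build_rtfc(S)
            q = generate_uniform(1, 5000, int(rng.integers(0, 2**31)))[0]
            for r in rels:
                assert query_rtfc(root, q, r) == brute_interval_query(S, q, r)

    def test_identical_intervals_all_reported_once_each(self, iv):
        S = adversarial_suite()["identical"]
        root = build_rtfc(S)
        got = query_rtfc(root, iv(10, 20), R.EQUALS)
        assert got == set(range(16))

    def test_empty_result_visit_count_bounded_by_paths(self, iv):
        S = generate_uniform(512, 10**6, 8)
        root = build_rtfc(S)
        h = _height(root)
        q = iv(10**6 + 5, 10**6 + 9)  # beyond all data
        for r in (R.EQUALS, R.DURING, R.OVERLAPS):
            assert query_rtfc(root, q, r) == set()
            assert visit_count(root) <= 2 * h + 1


class TestCascadeCorrectness:
    def test_cascaded_positions_equal_child_binary_search(self):
        S = generate_uniform(512, 2000, 77)
        root = build_rtfc(S)
        rng = np.random.default_rng(78)
        probes = rng.integers(0, 2100, size=40).tolist()
        for v in _internal_nodes(root):
            for p in probes:
                i = bisect_left(v.ys, p)
                if i == len(v.ys):
                    continue
                for fc, child in ((v.lfc, v.lchild), (v.rfc, v.rchild)):
                    expect = bisect_left(child.ys, p)
                    got = fc[i] if fc[i] != -1 else len(child.ys)
                    assert got == expect
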