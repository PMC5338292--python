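import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from ohgt.genome_io import Feature, HomologyHit, TaxonomyLineage
from ohgt.mtpt_caller import (
    GenomeMtptStats,
    exclude_ancient,
    exclude_annotated_ptmts,
    filter_hits,
    genome_stats,
    merge_mtpts,
    spearman,
)


def _hit(q0, q1, ident=95.0, qid="mt1", sid="pt1", bit=500.0, ev=1e-50):
    span = q1 - q0 + 1
    return HomologyHit(qid, sid, ident, span, 0, 0, q0, q1, 1, span, ev, bit)


class TestFilterHits:
    def test_span_boundary_strict(self):
        kept = filter_hits([_hit(1, 200), _hit(1, 201)])
        assert [(h.q_start, h.q_end) for h in kept] == [(1, 201)]

    def test_identity_boundary_strict(self):
        kept = filter_hits([_hit(1, 300, ident=70.0), _hit(1, 300, ident=70.1)])
        assert [h.pct_identity for h in kept] == [70.1]

    def test_empty(self):
        assert filter_hits([]) == []


class TestExcludeAncient:
    FEATS = [Feature(name="rrn18", start=1000, end=2000)]

    def test_one_bp_overlap_dropped(self):
        assert exclude_ancient([_hit(2000, 2500)], self.FEATS) == []

    def test_adjacent_kept(self):
        kept = exclude_ancient([_hit(2001, 2500)], self.FEATS)
        assert len(kept) == 1

    def test_extended_blacklist(self):
        feats = [Feature(name="rrn16", start=100, end=300)]
        hits = [_hit(250, 600)]
        assert exclude_ancient(hits, feats) == hits  # rrn16 not default
        assert exclude_ancient(hits, feats, {"atp1", "rrn18", "rrn26", "rrn16"}) == []

    def test_absent_blacklist_gene_noop(self):
        hits = [_hit(1, 300)]
        assert exclude_ancient(hits, [], {"atp1"}) == hits

    def test_non_gene_features_ignored(self):
        feats = [Feature(name="rrn18", start=100, end=300, kind="mtpt_annotation")]
        hits = [_hit(200, 600)]
        assert exclude_ancient(hits, feats) == hits


class TestExcludePtmtAnnotated:
    def test_subject_overlap_dropped(self):
        feats = {"pt1": [Feature(name="p", start=1, end=150, kind="ptmt_annotation")]}
        assert exclude_annotated_ptmts([_hit(1, 300)], feats) == []

    def test_other_subject_kept(self):
        feats = {"ptX": [Feature(name="p", start=1, end=150, kind="ptmt_annotation")]}
        hits = [_hit(1, 300)]
        assert exclude_annotated_ptmts(hits, feats) == hits


def _oracle_merge(intervals, max_gap=99):
    """Independent transitive-closure oracle: connect intervals whose gap
    is <= max_gap, return the envelope of every connected component."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            gap = max(a[0], b[0]) - min(a[1], b[1]) - 1
            if gap <= max_gap:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(intervals[i])
    return sorted(
        (min(x[0] for x in c), max(x[1] for x in c)) for c in comps.values()
    )


class TestMergeMtpts:
    def test_gap_89_merges(self):
        calls = merge_mtpts([_hit(1000, 1300), _hit(1390, 1700)])
        assert [(c.start, c.end) for c in calls] == [(1000, 1700)]

    def test_gap_boundary(self):
        merged = merge_mtpts([_hit(1000, 1300), _hit(1400, 1700)])
        assert [(c.start, c.end) for c in merged] == [(1000, 1700)]  # gap 99
        split = merge_mtpts([_hit(1000, 1300), _hit(1401, 1700)])
        assert [(c.start, c.end) for c in split] == [(1000, 1300), (1401, 1700)]

    def test_order_invariant(self, rng):
        hits = [_hit(int(a), int(a) + int(b)) for a, b in
                zip(rng.integers(1, 5000, 20), rng.integers(200, 400, 20))]
        base = [(c.start, c.end) for c in merge_mtpts(hits)]
        for _ in range(10):
            perm = list(hits)
            rng.shuffle(perm)
            assert [(c.start, c.end) for c in merge_mtpts(perm)] == base

    def test_idempotent_and_min_gap_invariant(self, rng):
        hits = [_hit(int(a), int(a) + int(b)) for a, b in
                zip(rng.integers(1, 8000, 30), rng.integers(201, 500, 30))]
        calls = merge_mtpts(hits)
        for a, b in zip(calls, calls[1:]):
            assert b.start - a.end - 1 >= 100
        again = merge_mtpts(
            [_hit(c.start, c.end) for c in calls]
        )
        assert [(c.start, c.end) for c in again] == [(c.start, c.end) for c in calls]

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 12))
            intervals = []
            for _k in range(n):
                a = int(rng.integers(1, 3000))
                intervals.append((a, a + int(rng.integers(1, 600))))
            hits = [_hit(a, b) for a, b in intervals]
            got = [(c.start, c.end) for c in sorted(merge_mtpts(hits), key=lambda c: c.start)]
            assert got == _oracle_merge(intervals)

    def test_multiple_mt_ids_rejected(self):
        with pytest.raises(ValueError):
            merge_mtpts([_hit(1, 300, qid="a"), _hit(400, 700, qid="b")])

    def test_gene_content_and_lineage(self):
        hits = [
            HomologyHit("mt1", "ptA", 95.0, 300, 0, 0, 1000, 1299, 50, 349, 1e-50, 400.0),
            HomologyHit("mt1", "ptB", 92.0, 300, 0, 0, 1350, 1649, 50, 349, 1e-40, 300.0),
        ]
        lineages = {
            "ptA": TaxonomyLineage.from_string("rosids; Rosales"),
            "ptB": TaxonomyLineage.from_string("asterids; Lamiales"),
        }
        feats = {"ptA": [Feature(name="psbA", start=100, end=500)], "ptB": []}
        (call,) = merge_mtpts(hits, subject_lineages=lineages, subject_features=feats)
        assert call.gene_content == ["psbA"]
        assert call.best_subject_lineage.ranks == ("rosids", "Rosales")


class TestGenomeStats:
    def test_empty(self):
        st = genome_stats([], 10000)
        assert st.n_mtpts == 0 and st.pct_mtdna == 0.0

    def test_percent(self):
        (call,) = merge_mtpts([_hit(1, 1038)])
        st = genome_stats([call], 10000)
        assert st.pct_mtdna == pytest.approx(10.38)

    def test_overlapping_calls_assert(self):
        c1 = merge_mtpts([_hit(100, 500)])[0]
        c2 = merge_mtpts([_hit(400, 900)])[0]
        with pytest.raises(AssertionError):
            genome_stats([c1, c2], 10000)


class TestSpearman:
    def test_monotone_rho_one(self):
        res = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert res.rho == pytest.approx(1.0)
        assert res.p_value < 0.02

    def test_matches_scipy_oracle_with_ties(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(4, 30))
            x = rng.integers(0, 6, n).astype(float)  # heavy ties
            y = rng.integers(0, 6, n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            got = spearman(x, y)
            want_rho, want_p = sps.spearmanr(x, y)
            assert got.rho == pytest.approx(want_rho, abs=1e-12)
            assert got.p_value == pytest.approx(want_p, abs=1e-9)

    def test_exact_permutation_matches_bruteforce(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        res = spearman(x, y, exact=True)
        # independent brute force over all 120 rank permutations
        rx = np.argsort(np.argsort(x)) + 1.0
        ry = np.argsort(np.argsort(y)) + 1.0
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        for perm in itertools.permutations(ry):
            if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / math.factorial(5))
        assert res.rho == pytest.approx(np.corrcoef(rx, ry)[0, 1])

    def test_all_ties_flagged_undefined(self):
        res = spearman([1, 2, 3, 4], [7, 7, 7, 7])
        assert not res.defined

    def test_length_mismatch_and_small_n(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])
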