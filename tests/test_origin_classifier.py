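import numpy as np
import pytest

from ohgt.genome_io import TaxonomyLineage, read_newick
from ohgt.origin_classifier import (
    HomologPanel,
    PanelMember,
    build_alignment,
    classify_placement,
    gtr_distance_matrix,
    infer_tree,
    neighbor_joining,
    screen_best_hit,
    seq_to_codes,
)
from ohgt.mtpt_caller import merge_mtpts
from ohgt.synthetic_data import mutate_codes
from tests.test_mtpt_caller import _hit


def _panel(seqs: dict[str, str], focal="focal") -> HomologPanel:
    return HomologPanel(
        focal_id=focal,
        members=[PanelMember(id=k, sequence=v) for k, v in seqs.items()],
    )


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestBuildAlignment:
    def test_identical_sequences_gap_free(self, rng):
        s = _rand(rng, 300)
        panel = build_alignment(_panel({"focal": s, "b": s, "c": s}))
        assert all(row == s for row in panel.alignment.values())

    def test_single_deletion_one_gap_run(self, rng):
        s = _rand(rng, 400)
        deleted = s[:200] + s[210:]
        panel = build_alignment(_panel({"focal": s, "b": deleted}))
        row = panel.alignment["b"]
        runs = [r for r in row.split("-") if r == ""]  # crude: count gap chars
        assert row.count("-") == 10
        # exactly one contiguous gap run
        import re

        assert len(re.findall(r"-+", row)) == 1
        assert panel.alignment["focal"] == s  # no gaps in the longer row

    def test_column_count_at_least_longest(self, rng):
        seqs = {"focal": _rand(rng, 300), "b": _rand(rng, 250), "c": _rand(rng, 280)}
        panel = build_alignment(_panel(seqs))
        L = len(next(iter(panel.alignment.values())))
        assert L >= 300
        assert len({len(v) for v in panel.alignment.values()}) == 1

    def test_too_few_sequences_error(self):
        with pytest.raises(ValueError):
            build_alignment(_panel({"focal": "ACGTACGT"}))

    def test_deterministic(self, rng):
        base = _rand(rng, 300)
        rng2 = np.random.default_rng(5)
        seqs = {"focal": base}
        for i in range(4):
            codes = mutate_codes(seq_to_codes(base), 0.05, 2.0, rng2)
            seqs[f"m{i}"] = "".join("ACGT"[c] for c in codes)
        a1 = build_alignment(_panel(dict(seqs))).alignment
        a2 = build_alignment(_panel(dict(seqs))).alignment
        assert a1 == a2


class TestNeighborJoining:
    def test_additive_quartet_recovers_true_split(self):
        # additive distances on ((A,B),(C,D)) with internal edge 3
        #   A,B at 1 from their node; C,D at 2
        D = np.array(
            [
                [0, 2, 6, 6],
                [2, 0, 6, 6],
                [6, 6, 0, 4],
                [6, 6, 4, 0],
            ],
            dtype=float,
        )
        edges, n_nodes = neighbor_joining(D)
        # oracle: enumerate the three quartet splits, pick the one with
        # minimal sum of pairwise path lengths consistency (four-point)
        sums = {
            "AB|CD": D[0, 1] + D[2, 3],
            "AC|BD": D[0, 2] + D[1, 3],
            "AD|BC": D[0, 3] + D[1, 2],
        }
        assert min(sums, key=sums.get) == "AB|CD"
        adj = {}
        for u, v, _l in edges:
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
        # A and B must attach to the same internal node
        (na,) = adj[0]
        (nb,) = adj[1]
        assert na == nb

    def test_branch_lengths_recover_additive_tree(self):
        D = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]], dtype=float
        )
        edges, _ = neighbor_joining(D)
        total = sum(l for _u, _v, l in edges)
        # additive tree total length: 1+1+3+2+2 = 9
        assert total == pytest.approx(9.0)


class TestInferTree:
    def _sim_alignment(self, internal=0.3, terminal=0.02, L=200, seed=9):
        rng = np.random.default_rng(seed)
        root = rng.integers(0, 4, L).astype(np.int8)
        left = mutate_codes(root, internal, 2.0, rng)
        right = mutate_codes(root, internal, 2.0, rng)
        tips = {
            "A": mutate_codes(left, terminal, 2.0, rng),
            "B": mutate_codes(left, terminal, 2.0, rng),
            "C": mutate_codes(right, terminal, 2.0, rng),
            "D": mutate_codes(right, terminal, 2.0, rng),
        }
        return {k: "".join("ACGT"[c] for c in v) for k, v in tips.items()}

    def test_clean_quartet_high_support(self):
        aln = self._sim_alignment()
        tree = infer_tree(aln, n_bootstrap=200, seed=3)
        sups = [n.support for n in tree.internal_nodes() if getattr(n, "support", None) is not None]
        assert sups and max(sups) >= 95
        # AB must form a clade in the unrooted tree: check bipartition
        tree.encode_bipartitions()
        splits = set()
        for edge in tree.preorder_edge_iter():
            if edge.head_node and not edge.head_node.is_leaf():
                tips = frozenset(
                    l.taxon.label for l in edge.head_node.leaf_iter()
                )
                splits.add(tips)
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_zero_variance_supports_100(self, rng):
        # columns all identical replicas of one informative pattern
        pattern = {"A": "A", "B": "A", "C": "T", "D": "T", "E": "G"}
        aln = {k: v * 120 for k, v in pattern.items()}
        tree = infer_tree(aln, n_bootstrap=50, seed=0)
        sups = [n.support for n in tree.internal_nodes() if getattr(n, "support", None) is not None]
        assert sups and all(s == 100 for s in sups)

    def test_tip_order_invariance(self):
        aln = self._sim_alignment(seed=21)
        t1 = infer_tree(aln, n_bootstrap=100, seed=5)
        shuffled = dict(reversed(list(aln.items())))
        t2 = infer_tree(shuffled, n_bootstrap=100, seed=5)
        def support_set(t):
            out = {}
            for n in t.internal_nodes():
                if getattr(n, "support", None) is not None:
                    out[frozenset(l.taxon.label for l in n.leaf_iter())] = n.support
            return out
        assert support_set(t1) == support_set(t2)

    def test_all_gap_column_dropped(self, caplog):
        import logging

        aln = {"A": "ACGT-", "B": "ACGT-", "C": "AGGT-", "D": "ATGT-"}
        with caplog.at_level(logging.WARNING, logger="ohgt"):
            infer_tree(aln, n_bootstrap=10, seed=0)
        assert any("all-gap" in m for m in caplog.messages)

    def test_requires_four(self):
        with pytest.raises(ValueError):
            infer_tree({"A": "ACGT", "B": "ACGT", "C": "ACGT"}, n_bootstrap=5)


class TestGtrDistances:
    def test_zero_distance_for_identical(self):
        codes = np.vstack([seq_to_codes("ACGT" * 100)] * 2)
        D = gtr_distance_matrix(codes)
        assert D[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_increases_with_divergence(self):
        rng = np.random.default_rng(0)
        root = rng.integers(0, 4, 2000).astype(np.int8)
        prev = 0.0
        for t in (0.05, 0.15, 0.4):
            tip = mutate_codes(root, t, 2.0, rng)
            D = gtr_distance_matrix(np.vstack([root, tip]))
            assert D[0, 1] > prev
            assert D[0, 1] == pytest.approx(t, rel=0.35)
            prev = D[0, 1]


LIN = {
    "hn_pt": "asterids; lamiids; Solanales; Hyoscyamus",
    "sol2_pt": "asterids; lamiids; Solanales; Solanum",
    "cs_mtpt": "rosids; Rosales; Cannabaceae; Cannabis",
    "cs_pt": "rosids; Rosales; Cannabaceae; Cannabis",
    "hum_pt": "rosids; Rosales; Cannabaceae; Humulus",
    "fab_pt": "rosids; fabids; Fabales; Glycine",
}


def _taxonomy():
    return {k: TaxonomyLineage.from_string(v) for k, v in LIN.items()}


class TestClassifyPlacement:
    RECIPIENT = TaxonomyLineage.from_string("asterids; lamiids; Solanales; Hyoscyamus")

    def test_foreign_sister_to_donor_mtpt(self):
        tree = read_newick(
            "(((focal:0.01,cs_mtpt:0.01)100:0.05,(cs_pt:0.01,hum_pt:0.01)99:0.02)98:0.1,"
            "(hn_pt:0.01,sol2_pt:0.01)100:0.1,fab_pt:0.2);"
        )
        res = classify_placement(
            tree, "focal", self.RECIPIENT, _taxonomy(),
            compartments={"cs_mtpt": "mtpt", "cs_pt": "pt", "hum_pt": "pt",
                          "hn_pt": "pt", "sol2_pt": "pt", "fab_pt": "pt"},
        )
        assert res.verdict == "foreign"
        assert res.support > 70
        assert res.donor_lineage.ranks[:3] == ("rosids", "Rosales", "Cannabaceae")
        assert res.donor_sister_flag
        assert res.sister_group == ["cs_mtpt"]

    def test_native_nested_in_own_clade(self):
        tree = read_newick(
            "((focal:0.01,(hn_pt:0.01,sol2_pt:0.02)90:0.01)100:0.1,"
            "(cs_pt:0.01,hum_pt:0.01)100:0.1,fab_pt:0.2);"
        )
        res = classify_placement(tree, "focal", self.RECIPIENT, _taxonomy())
        assert res.verdict == "native"

    def test_low_support_never_foreign(self):
        tree = read_newick(
            "((focal:0.01,cs_pt:0.01)65:0.05,(hn_pt:0.01,sol2_pt:0.01)60:0.02,fab_pt:0.2);"
        )
        res = classify_placement(tree, "focal", self.RECIPIENT, _taxonomy())
        assert res.verdict == "unresolved"
        assert res.donor_lineage is None

    def test_missing_focal_raises(self):
        tree = read_newick("((a:1,b:1)90:1,c:1,d:1);")
        taxonomy = {x: TaxonomyLineage.from_string("k; p; o") for x in "abcd"}
        with pytest.raises(ValueError):
            classify_placement(tree, "focal", self.RECIPIENT, taxonomy)


class TestScreenBestHit:
    def test_unrelated_order_is_putatively_foreign(self):
        lineages = {"pt1": TaxonomyLineage.from_string("rosids; Rosales; Cannabaceae")}
        (call,) = merge_mtpts([_hit(1000, 1300)], subject_lineages=lineages)
        recipient = TaxonomyLineage.from_string("asterids; lamiids; Solanales")
        assert screen_best_hit(call, recipient) is True

    def test_same_order_screens_native(self):
        lineages = {"pt1": TaxonomyLineage.from_string("asterids; lamiids; Solanales; Solanaceae")}
        (call,) = merge_mtpts([_hit(1000, 1300)], subject_lineages=lineages)
        recipient = TaxonomyLineage.from_string("asterids; lamiids; Solanales")
        assert screen_best_hit(call, recipient) is False

    def test_missing_lineage_ambiguous(self, caplog):
        import logging

        (call,) = merge_mtpts([_hit(1000, 1300)])
        recipient = TaxonomyLineage.from_string("asterids; lamiids; Solanales")
        with caplog.at_level(logging.WARNING, logger="ohgt"):
            assert screen_best_hit(call, recipient) is None
        assert call.status == "ambiguous"


class TestGuardrailFuzz:
    def test_never_foreign_at_low_support(self):
        """Hard invariant: no foreign verdict when every support <= 70."""
        rng = np.random.default_rng(77)
        ranks = ["rosids; Rosales; Cannabaceae", "asterids; lamiids; Solanales",
                 "rosids; fabids; Fabales", "monocots; Poales; Poaceae"]
        recipient = TaxonomyLineage.from_string(ranks[1])
        for _ in range(100):
            n = int(rng.integers(4, 9))
            tips = [f"t{i}" for i in range(n)] + ["focal"]
            rng.shuffle(tips)
            def grow(names):
                if len(names) == 1:
                    return f"{names[0]}:{rng.uniform(0.01, 0.3):.4f}"
                k = int(rng.integers(1, len(names)))
                sup = int(rng.integers(0, 71))  # all supports <= 70
                return (
                    f"({grow(names[:k])},{grow(names[k:])}){sup}:"
                    f"{rng.uniform(0.01, 0.3):.4f}"
                )
            k = int(rng.integers(1, len(tips)))
            newick = f"({grow(tips[:k])},{grow(tips[k:])});"
            tree = read_newick(newick)
            taxonomy = {
                t: TaxonomyLineage.from_string(ranks[int(rng.integers(0, len(ranks)))])
                for t in tips
                if t != "focal"
            }
            res = classify_placement(tree, "focal", recipient, taxonomy)
            assert res.verdict != "foreign"
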