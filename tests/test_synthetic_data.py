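import numpy as np
import pytest

from ohgt.genome_io import revcomp
from ohgt.homology_search import SearchParams, find_hits
from ohgt.synthetic_data import (
    HgtEvent,
    HgtEventLog,
    SimConfig,
    _k80_matrix,
    mutate_codes,
    score_recovery,
    simulate_corpus,
    simulate_species_tree,
)

SMALL = dict(
    n_species=6,
    mt_length=26000,
    pt_length=12000,
    n_native_mtpt=2,
    n_mt2mt_events=2,
    n_pt2mt_events=2,
    mtpt_length_range=(300, 600),
)


class TestSimConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n_species=2)
        with pytest.raises(ValueError):
            SimConfig(n_mt2mt_events=-1)
        with pytest.raises(ValueError):
            SimConfig(mt_length=0)


class TestSpeciesTree:
    def test_deterministic_newick(self):
        cfg = SimConfig(seed=5, n_species=4)
        t1 = simulate_species_tree(cfg)
        t2 = simulate_species_tree(cfg)
        assert t1.newick() == t2.newick()

    def test_branch_lengths_positive(self):
        tree = simulate_species_tree(SimConfig(seed=8, n_species=10))

        def walk(node):
            for c in node.children:
                assert c.end - c.time > 0
                walk(c)

        walk(tree.root)

    def test_ultrametric_root_to_tip(self):
        tree = simulate_species_tree(SimConfig(seed=8, n_species=10))
        depths = []

        def walk(node, d):
            if node.is_leaf:
                depths.append(d + node.end - node.time)
                return
            for c in node.children:
                walk(c, d + node.end - node.time if False else d + (node.end - node.time))

        for c in tree.root.children:
            walk(c, 0.0)
        assert max(depths) - min(depths) < 1e-9
        assert depths[0] == pytest.approx(tree.height)

    def test_lineages_have_four_ranks(self):
        tree = simulate_species_tree(SimConfig(seed=8, n_species=12))
        lineages = tree.lineages()
        assert len(lineages) == 12
        for name, lin in lineages.items():
            assert len(lin.ranks) == 4
            assert lin.ranks[3] == name
            assert lin.ranks[0] in ("cladeA", "cladeB")


class TestSubstitutionModel:
    def test_k80_rows_sum_to_one(self):
        P = _k80_matrix(0.3, 2.0)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_branch_substitution_count_matches_expectation(self):
        """Observed differences after t=0.1 on 10 kb match the analytic
        K80 expectation L*(1 - P_same(t)) within 4 sigma."""
        rng = np.random.default_rng(3)
        L, t, kappa = 10000, 0.1, 2.0
        codes = rng.integers(0, 4, L).astype(np.int8)
        mutated = mutate_codes(codes, t, kappa, rng)
        p_diff = 1.0 - _k80_matrix(t, kappa)[0, 0]
        expected = L * p_diff
        sigma = np.sqrt(L * p_diff * (1 - p_diff))
        observed = int((codes != mutated).sum())
        assert abs(observed - expected) < 4 * sigma

    def test_zero_branch_identity(self, rng):
        codes = rng.integers(0, 4, 500).astype(np.int8)
        assert (mutate_codes(codes, 0.0, 2.0, rng) == codes).all()

    def test_rate_multipliers_respected(self, rng):
        codes = rng.integers(0, 4, 20000).astype(np.int8)
        rates = np.ones(20000)
        rates[:10000] = 0.05
        out = mutate_codes(codes, 0.5, 2.0, rng, rates)
        slow = (out[:10000] != codes[:10000]).mean()
        fast = (out[10000:] != codes[10000:]).mean()
        assert slow < 0.1 < fast


class TestCorpus:
    def test_bit_identical_for_same_config(self):
        cfg = SimConfig(seed=17, **SMALL)
        c1, c2 = simulate_corpus(cfg), simulate_corpus(cfg)
        for rid in c1.records:
            assert c1.records[rid].sequence == c2.records[rid].sequence
        assert [vars(e) for e in c1.truth.events] == [vars(e) for e in c2.truth.events]

    def test_zero_events_leave_genomes_unannotated(self):
        cfg = SimConfig(
            seed=17, n_species=6, mt_length=26000, pt_length=12000,
            n_native_mtpt=0, n_mt2mt_events=0, n_pt2mt_events=0,
        )
        corpus = simulate_corpus(cfg)
        assert corpus.truth.events == []
        for rec in corpus.records.values():
            assert all(f.kind == "gene" for f in rec.features)

    def test_mt2mt_tract_covers_flanks(self):
        corpus = simulate_corpus(SimConfig(seed=17, **SMALL))
        for e in corpus.truth.of_type("mt2mt_hgt"):
            lo, hi = e.co_transferred_tract_interval
            mlo, mhi = e.mt_insert_interval
            assert lo <= mlo - 1000 and hi >= mhi + 1000

    def test_pt2mt_has_no_tract(self):
        corpus = simulate_corpus(SimConfig(seed=17, **SMALL))
        events = corpus.truth.of_type("pt2mt_hgt")
        assert events and all(e.co_transferred_tract_interval is None for e in events)

    def test_donors_from_opposite_root_side(self):
        corpus = simulate_corpus(SimConfig(seed=17, **SMALL))
        lin = corpus.tree.lineages()
        for e in corpus.truth.events:
            if e.type in ("mt2mt_hgt", "pt2mt_hgt"):
                assert lin[e.donor_species].ranks[0] != lin[e.recipient_species].ranks[0]

    def test_implanted_bases_trace_to_source(self):
        """Every implanted pt2mt interval aligns to its recorded donor
        source at >= (1 - divergence - 3 sigma) identity."""
        cfg = SimConfig(seed=17, **SMALL)
        corpus = simulate_corpus(cfg)
        for e in corpus.truth.of_type("pt2mt_hgt"):
            rec = corpus.records[f"{e.recipient_species}_mt"]
            donor = corpus.records[f"{e.donor_species}_pt"]
            got = rec.sequence[e.mt_insert_interval[0] - 1 : e.mt_insert_interval[1]]
            src = donor.sequence[
                e.plastid_source_interval[0] - 1 : e.plastid_source_interval[1]
            ]
            assert len(got) == len(src)
            ident = sum(a == b for a, b in zip(got, src)) / len(got)
            p = 1.0 - _k80_matrix(cfg.divergence_at_transfer, cfg.kappa)[0, 0]
            sigma = np.sqrt(p * (1 - p) / len(got))
            assert ident >= 1.0 - p - 3 * sigma

    def test_ancient_locus_found_by_cross_compartment_search(self):
        corpus = simulate_corpus(SimConfig(seed=17, **SMALL))
        mt = corpus.records["sp01_mt"]
        pt = corpus.records["sp04_pt"]  # a different species
        hits = find_hits(mt, pt, SearchParams.mt2pt())
        atp1 = next(f for f in mt.features if f.name == "atp1")
        assert any(
            h.q_start <= atp1.end and h.q_end >= atp1.start for h in hits
        )


def _call(mt_id, start, end):
    class C:
        pass

    c = C()
    c.mt_id, c.start, c.end = mt_id, start, end
    return c


class TestScoreRecovery:
    def _truth(self):
        return HgtEventLog(
            [
                HgtEvent("pt2mt_hgt", "d", "r", mt_insert_interval=[100, 400]),
                HgtEvent("mt2mt_hgt", "d", "r", mt_insert_interval=[1000, 1500]),
            ]
        )

    def test_perfect(self):
        calls = [_call("r_mt", 100, 400), _call("r_mt", 1000, 1500)]
        sc = score_recovery(self._truth(), calls)
        assert sc.recall == 1.0 and sc.precision == 1.0

    def test_empty_calls(self):
        sc = score_recovery(self._truth(), [])
        assert sc.recall == 0.0 and sc.precision is None

    def test_shifted_below_half_overlap(self):
        calls = [_call("r_mt", 350, 650)]  # 51/301 overlap with [100,400]
        sc = score_recovery(self._truth(), calls)
        assert sc.recall == 0.0 and sc.precision == 0.0

    def test_flag_rates_by_class(self):
        calls = [_call("r_mt", 100, 400), _call("r_mt", 1000, 1500)]
        flags = {(100, 400): False, (1000, 1500): True}
        sc = score_recovery(
            self._truth(),
            calls,
            mt2mt_flag_of_call=lambda c: flags[(c.start, c.end)],
        )
        assert sc.mt2mt_flag_rates == {"mt2mt_hgt": 1.0, "pt2mt_hgt": 0.0}


class TestEventLogIO:
    def test_json_roundtrip(self, tmp_path):
        log = HgtEventLog(
            [HgtEvent("native_igt", "a", "a", mt_insert_interval=[5, 10])]
        )
        p = tmp_path / "log.json"
        log.to_json(p)
        back = HgtEventLog.from_json(p)
        assert vars(back.events[0]) == vars(log.events[0])

    def test_tsv_written(self, tmp_path):
        log = HgtEventLog(
            [HgtEvent("native_igt", "a", "a", mt_insert_interval=[5, 10])]
        )
        p = tmp_path / "log.tsv"
        log.to_tsv(p)
        lines = p.read_text().splitlines()
        assert len(lines) == 2 and "5-10" in lines[1]
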