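import logging

import numpy as np
import pytest

from ohgt.pipeline import AnalysisSettings, CorpusAnalyzer
from ohgt.synthetic_data import SimConfig, simulate_corpus

logging.getLogger("ohgt").setLevel(logging.WARNING)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture()
def make_seq(rng):
    return lambda n: random_seq(rng, n)


@pytest.fixture(scope="session")
def small_corpus():
    """Cheap 8-species corpus shared by unit-level pipeline tests."""
    cfg = SimConfig(
        seed=11,
        n_species=8,
        mt_length=30000,
        pt_length=13000,
        n_native_mtpt=4,
        n_mt2mt_events=4,
        n_pt2mt_events=4,
        mtpt_length_range=(300, 800),
    )
    return simulate_corpus(cfg)


@pytest.fixture(scope="session")
def default_corpus_analysis():
    """The acceptance-scale corpus (20 species, 30 mt2mt + 30 pt2mt
    events, seed 1) analysed once per session; several acceptance
    criteria read off this shared run."""
    corpus = simulate_corpus(SimConfig(seed=1))
    analyzer = CorpusAnalyzer(
        corpus, AnalysisSettings(seed=1, n_bootstrap=100, run_ptmt=False)
    )
    analyzer.run_search()
    analyzer.run_call_mtpt()
    analyzer.run_classify_origin()
    analyzer.run_classify_flanks()
    return corpus, analyzer, analyzer.score()
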