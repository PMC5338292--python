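"""End-to-end orchestration: simulate -> search -> call-mtpt ->
classify-origin -> classify-flanks -> call-ptmt -> summarize.

Stage outputs are pure functions of (inputs, config, seed): one global
seed is fanned out by fixed offsets, nothing reads the clock, and the run
manifest records a digest of every artefact so a rerun can be checked for
bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .genome_io import (
    Feature,
    GenomeRecord,
    TaxonomyLineage,
    write_fasta,
    write_gff3,
    write_hit_table,
    write_taxonomy,
)
from .homology_search import SearchParams, SubjectIndex, find_hits
from .mtpt_caller import (
    DEFAULT_BLACKLIST,
    GenomeMtptStats,
    MtptCall,
    exclude_ancient,
    exclude_annotated_ptmts,
    filter_hits,
    genome_stats,
    merge_mtpts,
    spearman,
)
from .origin_classifier import (
    HomologPanel,
    PanelMember,
    PhyloPlacement,
    place_mtpt,
    screen_best_hit,
)
from .flank_classifier import (
    FlankEvidence,
    ForeignMtptRecord,
    categorize_flank,
    extract_flanks,
    summarize_corpus,
)
from .ptmt_caller import call_ptmts
from .synthetic_data import Corpus, SimConfig, score_recovery, simulate_corpus

logger = logging.getLogger("ohgt")


@dataclass(frozen=True)
class AnalysisSettings:
    seed: int = 1
    n_bootstrap: int = 100
    bs_threshold: int = 70
    rank_depth: int = 2
    flank_width: int = 1000
    flank_word_size: int = 11
    min_len: int = 201
    min_identity: float = 70.0
    max_gap: int = 99
    blacklist: tuple[str, ...] = tuple(sorted(DEFAULT_BLACKLIST))
    max_pt_panel_members: int = 12
    max_mt_panel_members: int = 4
    max_flank_panel_members: int = 10
    run_ptmt: bool = True


@dataclass
class CallAnnotation:
    call: MtptCall
    placement: PhyloPlacement | None = None
    donor_lineage: TaxonomyLineage | None = None
    donor_sister_flag: bool = False


@dataclass
class AnalysisResult:
    settings: AnalysisSettings
    hits_by_mt: dict = field(default_factory=dict)
    calls_by_mt: dict = field(default_factory=dict)
    stats_by_mt: dict = field(default_factory=dict)
    annotations: list = field(default_factory=list)  # CallAnnotation
    foreign_records: list = field(default_factory=list)  # ForeignMtptRecord
    ptmt_calls: list = field(default_factory=list)
    spearman_results: dict = field(default_factory=dict)
    summary: object = None

    def all_calls(self) -> list[MtptCall]:
        return [c for calls in self.calls_by_mt.values() for c in calls]


def _species_of(record_id: str) -> str:
    return record_id.rsplit("_", 1)[0]


def _call_seed(base: int, mt_id: str, start: int) -> int:
    h = hashlib.sha256(f"{base}:{mt_id}:{start}".encode()).digest()
    return int.from_bytes(h[:4], "big")


def _subject_envelope(hits, subject_id, max_span: int = 6000, join_gap: int = 1000):
    """Subject-side interval for a panel member: anchored on the best hit
    and grown only by nearby hit intervals, so one stray hit elsewhere in
    the genome cannot blow the envelope up to genome scale."""
    ranked = sorted(
        (h for h in hits if h.subject_id == subject_id),
        key=lambda h: -h.bitscore,
    )
    if not ranked:
        return None
    lo, hi = ranked[0].s_interval
    for h in ranked[1:]:
        a, b = h.s_interval
        new_lo, new_hi = min(lo, a), max(hi, b)
        if new_hi - new_lo + 1 > max_span:
            continue
        if a > hi + join_gap or b < lo - join_gap:
            continue
        lo, hi = new_lo, new_hi
    return lo, hi


class CorpusAnalyzer:
    """Runs the full MTPT/PTMT analysis over an in-memory corpus."""

    def __init__(self, corpus: Corpus, settings: AnalysisSettings | None = None):
        self.corpus = corpus
        self.settings = settings or AnalysisSettings()
        self.index_cache: dict[tuple[str, int], SubjectIndex] = {}
        self.result = AnalysisResult(settings=self.settings)

    # -- stage: homology search -------------------------------------------
    def run_search(self) -> None:
        params = SearchParams.mt2pt()
        pt_records = self.corpus.pt_records()
        for mt in sorted(self.corpus.mt_records(), key=lambda r: r.id):
            hits = []
            for pt in sorted(pt_records, key=lambda r: r.id):
                idx = self.index_cache.setdefault(
                    (pt.id, params.word_size), SubjectIndex(pt, params.word_size)
                )
                hits.extend(find_hits(mt, pt, params, subject_index=idx))
            self.result.hits_by_mt[mt.id] = hits
            logger.info("search: %s -> %d raw hits", mt.id, len(hits))

    # -- stage: MTPT calling ----------------------------------------------
    def run_call_mtpt(self) -> None:
        s = self.settings
        pt_features = {r.id: r.features for r in self.corpus.pt_records()}
        for mt in sorted(self.corpus.mt_records(), key=lambda r: r.id):
            hits = self.result.hits_by_mt.get(mt.id, [])
            kept = filter_hits(hits, min_len=s.min_len, min_identity=s.min_identity)
            kept = exclude_ancient(kept, mt.features, s.blacklist)
            kept = exclude_annotated_ptmts(kept, pt_features)
            calls = merge_mtpts(
                kept,
                max_gap=s.max_gap,
                subject_lineages=self.corpus.taxonomy,
                subject_features=pt_features,
            )
            self.result.calls_by_mt[mt.id] = calls
            self.result.stats_by_mt[mt.id] = genome_stats(calls, len(mt.sequence))
            logger.info(
                "call-mtpt: %s %d hits -> %d kept -> %d calls",
                mt.id,
                len(hits),
                len(kept),
                len(calls),
            )
        stats = [self.result.stats_by_mt[m] for m in sorted(self.result.stats_by_mt)]
        if len(stats) >= 4:
            x = [st.mtdna_length for st in stats]
            self.result.spearman_results = {
                "size_vs_total_mtpt_len": spearman(x, [st.total_mtpt_length for st in stats]),
                "size_vs_n_mtpts": spearman(x, [float(st.n_mtpts) for st in stats]),
                "size_vs_pct": spearman(x, [st.pct_mtdna for st in stats]),
            }

    # -- stage: origin classification -------------------------------------
    def _build_panel(self, mt: GenomeRecord, call: MtptCall) -> HomologPanel | None:
        s = self.settings
        focal_seq = mt.sequence[call.start - 1 : call.end]
        # partial homologs shorter than this mostly contribute gap columns
        # and garbage placements, so they are excluded from panels
        min_member_len = max(120, int(0.6 * len(focal_seq)))
        members = [PanelMember(id="focal", sequence=focal_seq, lineage=None, compartment="pt")]
        # plastid homologs straight from the call's supporting hits
        ranked: list[tuple[float, PanelMember]] = []
        for pt in self.corpus.pt_records():
            env = _subject_envelope(call.supporting_hits, pt.id)
            if env is None or env[1] - env[0] + 1 < min_member_len:
                continue
            best = max(
                h.bitscore for h in call.supporting_hits if h.subject_id == pt.id
            )
            ranked.append(
                (
                    best,
                    PanelMember(
                        id=pt.id,
                        sequence=pt.sequence[env[0] - 1 : env[1]],
                        lineage=pt.lineage,
                        compartment="pt",
                    ),
                )
            )
        ranked.sort(key=lambda t: (-t[0], t[1].id))
        members.extend(m for _b, m in ranked[: s.max_pt_panel_members])
        # MTPT homologs: the focal region searched against the other mtDNAs
        focal_rec = GenomeRecord(
            id="focal", compartment="mt", sequence=focal_seq, circular=False
        )
        params = SearchParams(word_size=s.flank_word_size)
        mt_ranked: list[tuple[float, PanelMember]] = []
        for other in sorted(self.corpus.mt_records(), key=lambda r: r.id):
            if other.id == mt.id:
                continue
            idx = self.index_cache.setdefault(
                (other.id, params.word_size), SubjectIndex(other, params.word_size)
            )
            hits = find_hits(focal_rec, other, params, subject_index=idx)
            env = _subject_envelope(hits, other.id)
            if env is None or env[1] - env[0] + 1 < min_member_len:
                continue
            best = max(h.bitscore for h in hits)
            mt_ranked.append(
                (
                    best,
                    PanelMember(
                        id=f"{other.id}_mtpt",
                        sequence=other.sequence[env[0] - 1 : env[1]],
                        lineage=other.lineage,
                        compartment="mtpt",
                    ),
                )
            )
        mt_ranked.sort(key=lambda t: (-t[0], t[1].id))
        members.extend(m for _b, m in mt_ranked[: s.max_mt_panel_members])
        if len(members) < 4:
            return None
        return HomologPanel(focal_id="focal", members=members)

    def run_classify_origin(self) -> None:
        s = self.settings
        for mt_id in sorted(self.result.calls_by_mt):
            mt = self.corpus.records[mt_id]
            recipient = mt.lineage
            for call in self.result.calls_by_mt[mt_id]:
                ann = CallAnnotation(call=call)
                self.result.annotations.append(ann)
                screened = screen_best_hit(call, recipient, s.rank_depth)
                if screened is None:
                    call.status = "ambiguous"
                    continue
                if not screened:
                    call.status = "native"
                    continue
                panel = self._build_panel(mt, call)
                if panel is None:
                    call.status = "putatively_foreign"
                    continue
                placement = place_mtpt(
                    panel,
                    recipient,
                    n_bootstrap=s.n_bootstrap,
                    seed=_call_seed(s.seed, mt_id, call.start),
                    bs_threshold=s.bs_threshold,
                    unrelated_rank_depth=s.rank_depth,
                )
                ann.placement = placement
                if placement.verdict == "foreign":
                    call.status = "foreign"
                    ann.donor_lineage = placement.donor_lineage
                    ann.donor_sister_flag = placement.donor_sister_flag
                elif placement.verdict == "native":
                    call.status = "native"
                else:
                    call.status = "putatively_foreign"

    # -- stage: flank classification ---------------------------------------
    def _flank_phylo(
        self,
        flank_seq: str,
        flank_hits,
        donor_lineage: TaxonomyLineage,
        recipient: TaxonomyLineage,
        seed: int,
    ) -> bool:
        s = self.settings
        members = [PanelMember(id="focal", sequence=flank_seq, lineage=None)]
        min_member_len = max(120, int(0.5 * len(flank_seq)))
        ranked = []
        for other in sorted({h.subject_id for h in flank_hits}):
            env = _subject_envelope(flank_hits, other, max_span=3000)
            if env[1] - env[0] + 1 < min_member_len:
                continue
            rec = self.corpus.records[other]
            best = max(h.bitscore for h in flank_hits if h.subject_id == other)
            ranked.append(
                (
                    best,
                    PanelMember(
                        id=other,
                        sequence=rec.sequence[env[0] - 1 : env[1]],
                        lineage=rec.lineage,
                        compartment="mtpt",
                    ),
                )
            )
        ranked.sort(key=lambda t: (-t[0], t[1].id))
        members.extend(m for _b, m in ranked[: s.max_flank_panel_members])
        if len(members) < 4:
            return False
        try:
            placement = place_mtpt(
                HomologPanel(focal_id="focal", members=members),
                recipient,
                n_bootstrap=s.n_bootstrap,
                seed=seed,
                bs_threshold=s.bs_threshold,
                unrelated_rank_depth=s.rank_depth,
            )
        except ValueError:
            return False
        return (
            placement.verdict == "foreign"
            and placement.donor_lineage is not None
            and placement.donor_lineage.related_at(donor_lineage, s.rank_depth)
        )

    def run_classify_flanks(self) -> None:
        s = self.settings
        params = SearchParams(word_size=s.flank_word_size)
        mt_records = sorted(self.corpus.mt_records(), key=lambda r: r.id)
        for ann in self.result.annotations:
            if ann.call.status != "foreign" or ann.donor_lineage is None:
                continue
            call = ann.call
            mt = self.corpus.records[call.mt_id]
            recipient = mt.lineage
            flank5, flank3 = extract_flanks(call, mt, width=s.flank_width)
            evidences: dict[str, FlankEvidence] = {}
            for side, flank in (("five_prime", flank5), ("three_prime", flank3)):
                if flank is None:
                    evidences[side] = FlankEvidence(side=side, window=None, category=None)
                    continue
                window, seq = flank
                flank_rec = GenomeRecord(
                    id="flank", compartment="mt", sequence=seq, circular=False
                )
                hits = []
                for other in mt_records:
                    if other.id == mt.id:
                        continue
                    idx = self.index_cache.setdefault(
                        (other.id, params.word_size),
                        SubjectIndex(other, params.word_size),
                    )
                    hits.extend(find_hits(flank_rec, other, params, subject_index=idx))
                seed = _call_seed(s.seed + 7, call.mt_id, call.start + (0 if side == "five_prime" else 1))
                evidences[side] = categorize_flank(
                    hits,
                    ann.donor_lineage,
                    recipient,
                    self.corpus.taxonomy,
                    side=side,
                    window=window,
                    rank_depth=s.rank_depth,
                    phylo=lambda seq=seq, hits=hits, seed=seed: self._flank_phylo(
                        seq, hits, ann.donor_lineage, recipient, seed
                    ),
                )
            self.result.foreign_records.append(
                ForeignMtptRecord(
                    mt_id=call.mt_id,
                    recipient_species=_species_of(call.mt_id),
                    recipient_lineage=recipient,
                    start=call.start,
                    end=call.end,
                    length=call.length,
                    genes=list(call.gene_content),
                    bs=ann.placement.support if ann.placement else None,
                    donor_lineage=ann.donor_lineage,
                    donor_sister_flag=ann.donor_sister_flag,
                    flank5=evidences["five_prime"],
                    flank3=evidences["three_prime"],
                )
            )
        self.result.summary = summarize_corpus(self.result.foreign_records)

    # -- stage: PTMT calling ----------------------------------------------
    def run_call_ptmt(self) -> None:
        # annotate our own MTPT calls on copies of the mt records so the
        # reverse scan can exclude plastid-derived tracts
        annotated: list[GenomeRecord] = []
        for mt in sorted(self.corpus.mt_records(), key=lambda r: r.id):
            feats = list(mt.features)
            for call in self.result.calls_by_mt.get(mt.id, []):
                feats.append(
                    Feature(
                        name="called_mtpt",
                        start=call.start,
                        end=call.end,
                        kind="mtpt_annotation",
                    )
                )
            annotated.append(
                GenomeRecord(
                    id=mt.id,
                    compartment="mt",
                    sequence=mt.sequence,
                    features=feats,
                    lineage=mt.lineage,
                )
            )
        pt_records = sorted(self.corpus.pt_records(), key=lambda r: r.id)
        for pt in pt_records:
            self.result.ptmt_calls.extend(
                call_ptmts(
                    pt,
                    annotated,
                    pt_records,
                    locus_blacklist=self.settings.blacklist,
                    index_cache=self.index_cache,
                )
            )

    # -- recovery scoring ---------------------------------------------------
    def score(self):
        truth = self.corpus.truth
        lineages = {s: self.corpus.taxonomy[f"{s}_mt"] for s in
                    {e.donor_species for e in truth.events} |
                    {e.recipient_species for e in truth.events}}
        mtpt_truth = type(truth)(
            [e for e in truth.events if e.type in ("native_igt", "mt2mt_hgt", "pt2mt_hgt")]
        )
        detection = score_recovery(mtpt_truth, self.all_mtpt_calls())
        foreign_truth = type(truth)(
            [e for e in truth.events if e.type in ("mt2mt_hgt", "pt2mt_hgt")]
        )
        classification = score_recovery(
            foreign_truth,
            self.result.foreign_records,
            donor_of_call=lambda r: r.donor_lineage,
            mt2mt_flag_of_call=lambda r: r.mt2mt_supported,
            lineages=lineages,
        )
        return {"detection": detection, "classification": classification}

    def all_mtpt_calls(self) -> list[MtptCall]:
        return self.result.all_calls()

    def run_all(self) -> AnalysisResult:
        self.run_search()
        self.run_call_mtpt()
        self.run_classify_origin()
        self.run_classify_flanks()
        if self.settings.run_ptmt:
            self.run_call_ptmt()
        return self.result


# ---------------------------------------------------------------------------
# File-emitting front end with manifest
# ---------------------------------------------------------------------------


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _calls_tsv(result: AnalysisResult, path: Path) -> None:
    cols = [
        "mt_id", "start", "end", "length", "status", "genes",
        "best_subject", "donor_lineage", "donor_sister", "bs",
        "flank5", "flank3", "mt2mt_supported",
    ]
    fr_by_key = {(r.mt_id, r.start): r for r in result.foreign_records}
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for ann in result.annotations:
            c = ann.call
            fr = fr_by_key.get((c.mt_id, c.start))

            def code(ev: FlankEvidence | None) -> str:
                if ev is None or ev.category is None:
                    return "NA"
                return ("yes" if ev.supports_mt2mt else "no") + str(ev.category)

            fh.write(
                "\t".join(
                    [
                        c.mt_id,
                        str(c.start),
                        str(c.end),
                        str(c.length),
                        c.status,
                        ";".join(c.gene_content),
                        c.best_hit.subject_id if c.supporting_hits else "-",
                        str(ann.donor_lineage) if ann.donor_lineage else "-",
                        "1" if ann.donor_sister_flag else "0",
                        str(ann.placement.support) if ann.placement else "-",
                        code(fr.flank5) if fr else "-",
                        code(fr.flank3) if fr else "-",
                        ("1" if fr.mt2mt_supported else "0") if fr else "-",
                    ]
                )
                + "\n"
            )


def run_all(
    sim_config: SimConfig,
    settings: AnalysisSettings,
    out_dir: str | Path,
) -> dict:
    """Simulate a corpus, run every stage, write reports + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    corpus = simulate_corpus(sim_config)

    write_fasta(corpus.mt_records(), out / "mt_genomes.fasta")
    write_fasta(corpus.pt_records(), out / "pt_genomes.fasta")
    write_gff3({r.id: r.features for r in corpus.records.values()}, out / "annotations.gff3")
    write_taxonomy(corpus.taxonomy, out / "taxonomy.tsv")
    (out / "species_tree.nwk").write_text(corpus.tree.newick() + "\n")
    corpus.truth.to_json(out / "truth.json")
    corpus.truth.to_tsv(out / "truth.tsv")

    analyzer = CorpusAnalyzer(corpus, settings)
    result = analyzer.run_all()

    all_hits = [h for mt_id in sorted(result.hits_by_mt) for h in result.hits_by_mt[mt_id]]
    write_hit_table(all_hits, out / "hits.tsv")
    _calls_tsv(result, out / "mtpt_calls.tsv")
    with open(out / "genome_stats.tsv", "w") as fh:
        fh.write("mt_id\tmtdna_length\tn_mtpts\ttotal_mtpt_length\tpct_mtdna\n")
        for mt_id in sorted(result.stats_by_mt):
            st: GenomeMtptStats = result.stats_by_mt[mt_id]
            fh.write(
                f"{mt_id}\t{st.mtdna_length}\t{st.n_mtpts}\t"
                f"{st.total_mtpt_length}\t{st.pct_mtdna:.4f}\n"
            )
    with open(out / "ptmt_calls.tsv", "w") as fh:
        fh.write("pt_id\tstart\tend\tlength\tbest_mt_bitscore\tbest_pt_bitscore\n")
        for c in result.ptmt_calls:
            fh.write(
                f"{c.pt_id}\t{c.start}\t{c.end}\t{c.length}\t"
                f"{c.best_mt_bitscore:.1f}\t{c.best_pt_bitscore:.1f}\n"
            )

    scores = analyzer.score()
    summary = {
        "corpus": {
            "n_species": sim_config.n_species,
            "seed": sim_config.seed,
        },
        "funnel": {
            "raw_hits": len(all_hits),
            "calls": len(result.all_calls()),
            "foreign": len(result.foreign_records),
            "mt2mt_supported": sum(
                1 for r in result.foreign_records if r.mt2mt_supported
            ),
        },
        "flank_summary": result.summary.to_dict() if result.summary else None,
        "spearman": {
            k: {"rho": v.rho, "p": v.p_value, "n": v.n, "defined": v.defined}
            for k, v in result.spearman_results.items()
        },
        "recovery": {
            name: {
                "recall": sc.recall,
                "precision": sc.precision,
                "donor_accuracy": sc.donor_accuracy,
                "mt2mt_flag_rates": sc.mt2mt_flag_rates,
                "n_truth": sc.n_truth,
                "n_calls": sc.n_calls,
            }
            for name, sc in scores.items()
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")

    manifest = {
        "tool_version": __version__,
        "seed": settings.seed,
        "sim_config": asdict(sim_config),
        "settings": asdict(settings),
        "files": {
            p.name: _digest(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return summary
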