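"""Reverse-direction detector: mitochondrion-derived regions in plastid
genomes (PTMTs).

A plastid region is reported only when (i) its mitochondrial hits survive
the annotation/ancient-homology exclusions and (ii) its best
mitochondrial bit score strictly exceeds its best plastid bit score
against any other plastome (the nr corroboration step of the original
procedure is replaced by this plastid-panel cross-check).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .genome_io import GenomeRecord, HomologyHit
from .homology_search import SearchParams, SubjectIndex, find_hits
from .mtpt_caller import DEFAULT_BLACKLIST

logger = logging.getLogger("ohgt")


@dataclass
class PtmtCall:
    pt_id: str
    start: int
    end: int
    best_mt_bitscore: float
    best_pt_bitscore: float
    supporting_hits: list[HomologyHit] = field(default_factory=list)
    excluded_reason: str | None = None  # None | mtpt-annotated | ancient-homology

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _subject_excluded(hit: HomologyHit, mt: GenomeRecord, blacklist: set[str]) -> str | None:
    lo, hi = hit.s_interval
    for f in mt.features:
        if not f.overlaps(lo, hi):
            continue
        if f.kind == "mtpt_annotation":
            return "mtpt-annotated"
        if f.kind == "gene" and f.name in blacklist:
            return "ancient-homology"
    return None


def call_ptmts(
    pt: GenomeRecord,
    mt_panel: list[GenomeRecord],
    pt_panel: list[GenomeRecord],
    params: SearchParams | None = None,
    locus_blacklist=DEFAULT_BLACKLIST,
    min_len: int = 30,
    max_gap: int = 99,
    index_cache: dict[tuple[str, int], SubjectIndex] | None = None,
) -> list[PtmtCall]:
    """Scan one plastid genome against a mitochondrial panel.

    Hits whose mitochondrial subject interval overlaps an annotated
    plastid-derived tract or a blacklisted ancient-homology locus are
    dropped; surviving plastid regions (merged at <100 bp gaps) are
    reported iff their best mitochondrial bit score strictly exceeds the
    best bit score against any other plastome.
    """
    params = params or SearchParams.pt2mt()
    blacklist = set(locus_blacklist)
    if not mt_panel:
        return []

    kept: list[HomologyHit] = []
    excluded: list[tuple[HomologyHit, str]] = []
    for mt in mt_panel:
        if mt.id == pt.id:
            continue
        idx = None
        if index_cache is not None:
            key = (mt.id, params.word_size)
            idx = index_cache.setdefault(key, SubjectIndex(mt, params.word_size))
        for hit in find_hits(pt, mt, params, subject_index=idx):
            reason = _subject_excluded(hit, mt, blacklist)
            if reason is None:
                kept.append(hit)
            else:
                excluded.append((hit, reason))
    if not kept:
        return []

    # merge query intervals of surviving hits into candidate regions
    kept.sort(key=lambda h: (h.q_start, h.q_end))
    regions: list[list[HomologyHit]] = [[kept[0]]]
    env_end = kept[0].q_end
    for h in kept[1:]:
        if h.q_start - env_end - 1 <= max_gap:
            regions[-1].append(h)
            env_end = max(env_end, h.q_end)
        else:
            regions.append([h])
            env_end = h.q_end

    calls: list[PtmtCall] = []
    others = [p for p in pt_panel if p.id != pt.id]
    for group in regions:
        start = min(h.q_start for h in group)
        end = max(h.q_end for h in group)
        if end - start + 1 < min_len:
            continue
        best_mt = max(h.bitscore for h in group)
        region_rec = GenomeRecord(
            id=f"{pt.id}:{start}-{end}",
            compartment="pt",
            sequence=pt.sequence[start - 1 : end],
            circular=False,
        )
        best_pt = 0.0
        for other in others:
            idx = None
            if index_cache is not None:
                key = (other.id, params.word_size)
                idx = index_cache.setdefault(key, SubjectIndex(other, params.word_size))
            for h in find_hits(region_rec, other, params, subject_index=idx):
                best_pt = max(best_pt, h.bitscore)
        if best_mt > best_pt:
            calls.append(
                PtmtCall(
                    pt_id=pt.id,
                    start=start,
                    end=end,
                    best_mt_bitscore=best_mt,
                    best_pt_bitscore=best_pt,
                    supporting_hits=group,
                )
            )
        else:
            logger.debug(
                "%s %d..%d: plastid bitscore %.1f >= mitochondrial %.1f; not reported",
                pt.id,
                start,
                end,
                best_pt,
                best_mt,
            )
    return calls
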