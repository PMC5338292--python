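"""Flanking-region evidence for the mitochondrion-to-mitochondrion
transfer hypothesis.

Each foreign MTPT contributes two flank windows (up to 1 kb each side).
Homology hits of a window are partitioned by lineage affinity into the
six-way evidence code:

1. no hit
2. all hits related to the recipient lineage
3. hits only to lineages unrelated to donor and recipient
4. all hits related to the donor lineage
5. hits to diverse lineages -> settled by a flank phylogeny
6. external (literature) evidence, carried through as an annotation

A flank supports the mt-to-mt hypothesis iff its category is 4, 5 with a
supporting phylogeny, or 6.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .genome_io import GenomeRecord, HomologyHit, TaxonomyLineage
from .mtpt_caller import MtptCall


@dataclass
class FlankEvidence:
    side: str  # five_prime | three_prime
    window: tuple[int, int] | None
    category: int | None  # 1..6 or None (NA)
    phylo_support: bool | None = None  # only meaningful for category 5

    def __post_init__(self) -> None:
        if self.side not in ("five_prime", "three_prime"):
            raise ValueError(f"bad side {self.side!r}")
        if self.category is not None and self.category not in range(1, 7):
            raise ValueError(f"bad category {self.category!r}")

    @property
    def supports_mt2mt(self) -> bool:
        if self.category == 4 or self.category == 6:
            return True
        if self.category == 5:
            return bool(self.phylo_support)
        return False

    @classmethod
    def from_code(cls, code: str, side: str) -> "FlankEvidence":
        """Parse a printed evidence code like ``yes4``, ``no3`` or ``NA``;
        the yes/no flag must agree with the category truth table."""
        code = code.strip()
        if code.upper() == "NA":
            return cls(side=side, window=None, category=None)
        flag = code.lower().startswith("yes")
        digits = "".join(ch for ch in code if ch.isdigit())
        if not digits:
            raise ValueError(f"unparseable flank code {code!r}")
        category = int(digits)
        phylo = flag if category == 5 else None
        ev = cls(side=side, window=None, category=category, phylo_support=phylo)
        if ev.supports_mt2mt != flag:
            raise ValueError(
                f"flank code {code!r} contradicts the category truth table"
            )
        return ev


@dataclass
class ForeignMtptRecord:
    """One foreign MTPT with its flank evidence and provenance flags."""

    mt_id: str
    recipient_species: str
    recipient_lineage: TaxonomyLineage | None
    start: int | None
    end: int | None
    length: int | None
    genes: list[str] = field(default_factory=list)
    bs: int | None = None
    donor_lineage: TaxonomyLineage | None = None
    donor_sister_flag: bool = False
    flank5: FlankEvidence | None = None
    flank3: FlankEvidence | None = None
    host_parasite: bool = False
    source_ref: str = ""

    @property
    def mt2mt_supported(self) -> bool:
        return bool(
            (self.flank5 and self.flank5.supports_mt2mt)
            or (self.flank3 and self.flank3.supports_mt2mt)
        )


# ---------------------------------------------------------------------------
# Flank extraction and categorisation
# ---------------------------------------------------------------------------


def extract_flanks(
    call: MtptCall,
    genome: GenomeRecord,
    width: int = 1000,
    circular: bool | None = None,
) -> tuple[tuple[tuple[int, int], str] | None, tuple[tuple[int, int], str] | None]:
    """The <=1 kb windows [start-width, start-1] and [end+1, end+width].

    Circular genomes wrap around the origin; linear genomes truncate at
    the ends, and a flank that truncates to <1 bp is returned as None
    (NA).  Returns ((coords, sequence) | None) per side.
    """
    if circular is None:
        circular = genome.circular
    n = len(genome.sequence)
    out = []
    for lo, hi in ((call.start - width, call.start - 1), (call.end + 1, call.end + width)):
        if circular:
            out.append(((lo, hi), genome.slice(lo, hi)))
            continue
        lo_c, hi_c = max(lo, 1), min(hi, n)
        if hi_c < lo_c:
            out.append(None)
        else:
            out.append(((lo_c, hi_c), genome.sequence[lo_c - 1 : hi_c]))
    return out[0], out[1]


def categorize_flank(
    flank_hits: Sequence[HomologyHit],
    donor_lineage: TaxonomyLineage,
    recipient_lineage: TaxonomyLineage,
    subject_lineages: dict[str, TaxonomyLineage],
    side: str = "five_prime",
    window: tuple[int, int] | None = None,
    rank_depth: int = 2,
    phylo: Callable[[], bool] | None = None,
) -> FlankEvidence:
    """Partition flank hit subjects into recipient-related, donor-related
    and other at ``rank_depth``; category 5 (mixture) defers to the
    ``phylo`` callback for its verdict."""
    if not flank_hits:
        return FlankEvidence(side=side, window=window, category=1)
    rec = don = other = 0
    for h in sorted(flank_hits, key=lambda h: (h.subject_id, h.q_start)):
        lin = subject_lineages.get(h.subject_id)
        if lin is None:
            other += 1
        elif lin.related_at(donor_lineage, rank_depth):
            don += 1
        elif lin.related_at(recipient_lineage, rank_depth):
            rec += 1
        else:
            other += 1
    if don and not rec and not other:
        return FlankEvidence(side=side, window=window, category=4)
    if rec and not don and not other:
        return FlankEvidence(side=side, window=window, category=2)
    if other and not don and not rec:
        return FlankEvidence(side=side, window=window, category=3)
    support = phylo() if phylo is not None else None
    return FlankEvidence(side=side, window=window, category=5, phylo_support=support)


# ---------------------------------------------------------------------------
# Corpus summary
# ---------------------------------------------------------------------------


@dataclass
class CorpusSummary:
    n_total: int
    n_mt2mt: int
    n_host_parasite: int
    per_species: dict[str, int]

    @property
    def pct_mt2mt(self) -> float:
        return 100.0 * self.n_mt2mt / self.n_total if self.n_total else 0.0

    @property
    def pct_host_parasite(self) -> float:
        return 100.0 * self.n_host_parasite / self.n_total if self.n_total else 0.0

    @property
    def pct_mt2mt_display(self) -> int:
        return int(round(self.pct_mt2mt))

    @property
    def pct_host_parasite_display(self) -> int:
        return int(round(self.pct_host_parasite))

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_mt2mt": self.n_mt2mt,
            "pct_mt2mt": self.pct_mt2mt,
            "pct_mt2mt_display": self.pct_mt2mt_display,
            "n_host_parasite": self.n_host_parasite,
            "pct_host_parasite": self.pct_host_parasite,
            "pct_host_parasite_display": self.pct_host_parasite_display,
            "per_species": self.per_species,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


def summarize_corpus(records: Iterable[ForeignMtptRecord]) -> CorpusSummary:
    records = list(records)
    per_species: dict[str, int] = {}
    n_mt2mt = n_hp = 0
    for r in records:
        per_species[r.recipient_species] = per_species.get(r.recipient_species, 0) + 1
        if r.mt2mt_supported:
            n_mt2mt += 1
        if r.host_parasite:
            n_hp += 1
    return CorpusSummary(
        n_total=len(records),
        n_mt2mt=n_mt2mt,
        n_host_parasite=n_hp,
        per_species=per_species,
    )


# ---------------------------------------------------------------------------
# Packaged catalogue fixture
# ---------------------------------------------------------------------------


def table1_path() -> Path:
    return Path(str(resources.files("ohgt.data") / "table1_foreign_mtpts.tsv"))


def load_table1(path: str | Path | None = None) -> list[ForeignMtptRecord]:
    """Load the packaged transcription of the published foreign-MTPT
    catalogue (46 records) into ForeignMtptRecord objects."""
    path = Path(path) if path is not None else table1_path()
    records: list[ForeignMtptRecord] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            def opt_int(key: str) -> int | None:
                v = row[key].strip()
                return int(v) if v not in ("-", "") else None

            start, end, length = opt_int("start"), opt_int("end"), opt_int("length")
            if start is not None and end is not None and length is not None:
                if end - start + 1 != length:
                    raise ValueError(
                        f"row {row['row_id']}: end-start+1={end - start + 1} "
                        f"!= printed length {length}"
                    )
            records.append(
                ForeignMtptRecord(
                    mt_id=row["accession"],
                    recipient_species=row["recipient_species"],
                    recipient_lineage=TaxonomyLineage.from_string(
                        row["recipient_lineage"]
                    ),
                    start=start,
                    end=end,
                    length=length,
                    genes=[g.strip() for g in row["genes"].split(";")],
                    bs=opt_int("bs"),
                    donor_lineage=TaxonomyLineage.from_string(row["donor_lineage"]),
                    donor_sister_flag=row["donor_sister_flag"] == "1",
                    flank5=FlankEvidence.from_code(row["flank5_code"], "five_prime"),
                    flank3=FlankEvidence.from_code(row["flank3_code"], "three_prime"),
                    host_parasite=row["host_parasite_flag"] == "1",
                    source_ref=row["source_ref"],
                )
            )
    if not records:
        raise ValueError(f"{path}: empty catalogue")
    return records
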