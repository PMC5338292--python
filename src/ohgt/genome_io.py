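"""Readers/writers for the external formats the pipeline touches.

Coordinate convention: every coordinate in an external file or report is
1-based inclusive.  Minus-strand subject hits are encoded by coordinate
inversion (``s_start > s_end``), following the BLAST tabular convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO

logger = logging.getLogger("ohgt")

VALID_BASES = frozenset("ACGTN")

HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonomyLineage:
    """Ordered list of rank names from broad to narrow.

    Lineages are compared positionally: two lineages share the prefix of
    ranks on which they agree, and "relatedness at depth ``d``" means the
    shared prefix extends past rank index ``d``.
    """

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ranks:
            raise ValueError("lineage must contain at least one rank")
        if any(not r for r in self.ranks):
            raise ValueError(f"empty rank in lineage {self.ranks!r}")

    @classmethod
    def from_string(cls, text: str) -> "TaxonomyLineage":
        ranks = tuple(r.strip() for r in text.split(";") if r.strip())
        return cls(ranks)

    def shared_prefix(self, other: "TaxonomyLineage") -> tuple[str, ...]:
        out = []
        for a, b in zip(self.ranks, other.ranks):
            if a != b:
                break
            out.append(a)
        return tuple(out)

    def shared_depth(self, other: "TaxonomyLineage") -> int:
        """Number of leading ranks on which the two lineages agree."""
        return len(self.shared_prefix(other))

    def related_at(self, other: "TaxonomyLineage", depth: int = 2) -> bool:
        """True iff both lineages agree on ranks 0..depth inclusive.

        ``depth=2`` is the order-level default: lineages such as
        "rosids; fabids; Fabales; ..." must match through index 2 to count
        as related.  Lineages too short to reach ``depth`` are compared on
        the ranks they do have; they are related only if one is a prefix
        of the other.
        """
        limit = min(depth + 1, len(self.ranks), len(other.ranks))
        return self.ranks[:limit] == other.ranks[:limit]

    def __str__(self) -> str:
        return "; ".join(self.ranks)


@dataclass(frozen=True)
class Feature:
    """A named annotation interval on a genome (1-based inclusive)."""

    name: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "gene"  # gene | mtpt_annotation | other

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad feature interval {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """One organellar genome: sequence, compartment, annotations, lineage."""

    id: str
    compartment: str  # "mt" | "pt"
    sequence: str
    features: list[Feature] = field(default_factory=list)
    lineage: TaxonomyLineage | None = None
    circular: bool = True

    def __post_init__(self) -> None:
        if self.compartment not in ("mt", "pt"):
            raise ValueError(f"bad compartment {self.compartment!r}")
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.id}")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"{self.id}: invalid characters {sorted(bad)}")
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"{self.id}: feature {f.name} at {f.start}..{f.end} "
                    f"exceeds genome length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive subsequence; wraps the origin when circular."""
        n = len(self.sequence)
        if start >= 1 and end <= n:
            return self.sequence[start - 1 : end]
        if not self.circular:
            raise ValueError(f"{self.id}: slice {start}..{end} outside linear genome")
        idx = [((p - 1) % n) for p in range(start, end + 1)]
        return "".join(self.sequence[i] for i in idx)


@dataclass(frozen=True)
class HomologyHit:
    """One local alignment, BLAST outfmt-6 shaped."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError("q_start must be <= q_end")
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity {self.pct_identity} out of [0,100]")
        if self.evalue < 0:
            raise ValueError("negative evalue")

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start + 1

    @property
    def s_minus(self) -> bool:
        return self.s_start > self.s_end

    @property
    def s_interval(self) -> tuple[int, int]:
        """Subject interval in ascending order regardless of strand."""
        return (min(self.s_start, self.s_end), max(self.s_start, self.s_end))

    def to_row(self) -> str:
        return "\t".join(
            [
                self.query_id,
                self.subject_id,
                f"{self.pct_identity:.2f}",
                str(self.aln_len),
                str(self.mismatches),
                str(self.gap_opens),
                str(self.q_start),
                str(self.q_end),
                str(self.s_start),
                str(self.s_end),
                f"{self.evalue:.2e}",
                f"{self.bitscore:.1f}",
            ]
        )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Uppercase, U->T, any other non-ACGTN character -> N (logged)."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - VALID_BASES
    if bad:
        logger.warning(
            "%s: %d non-ACGTN character type(s) %s mapped to N",
            record_id,
            len(bad),
            "".join(sorted(bad)),
        )
        seq = re.sub(f"[^{''.join(sorted(VALID_BASES))}]", "N", seq)
    return seq


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, compartment: str = "mt") -> list[GenomeRecord]:
    """Read a (multi-)FASTA into GenomeRecords.

    Lineages and features are attached separately; ``compartment`` tags
    every record in the file.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq), rec.id)
        records.append(GenomeRecord(id=rec.id, compartment=compartment, sequence=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST outfmt-6 tables
# ---------------------------------------------------------------------------


def read_hit_table(path: str | Path) -> list[HomologyHit]:
    """Parse a 12-column BLAST tabular file (outfmt 6)."""
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                hits.append(
                    HomologyHit(
                        query_id=parts[0],
                        subject_id=parts[1],
                        pct_identity=float(parts[2]),
                        aln_len=int(parts[3]),
                        mismatches=int(parts[4]),
                        gap_opens=int(parts[5]),
                        q_start=int(parts[6]),
                        q_end=int(parts[7]),
                        s_start=int(parts[8]),
                        s_end=int(parts[9]),
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_hit_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for hit in hits:
            fh.write(hit.to_row() + "\n")


# ---------------------------------------------------------------------------
# Taxonomy TSV
# ---------------------------------------------------------------------------


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyLineage]:
    """TSV: column 1 = record id, column 2 = semicolon-separated ranks."""
    out: dict[str, TaxonomyLineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[1].strip():
                raise ValueError(f"{path}: line {lineno}: id with empty lineage")
            out[parts[0].strip()] = TaxonomyLineage.from_string(parts[1])
    return out


def write_taxonomy(taxonomy: dict[str, TaxonomyLineage], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, lin in taxonomy.items():
            fh.write(f"{rid}\t{lin}\n")


# ---------------------------------------------------------------------------
# GFF3 (seqid / type / start / end / strand / Name only)
# ---------------------------------------------------------------------------

_KIND_MAP = {
    "gene": "gene",
    "mtpt_annotation": "mtpt_annotation",
    "ptmt_annotation": "ptmt_annotation",
}


def read_gff3(path: str | Path) -> dict[str, list[Feature]]:
    """Minimal GFF3 reader; only seqid, type, start, end, strand and the
    Name attribute are consumed."""
    out: dict[str, list[Feature]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            name = ""
            for item in attrs.split(";"):
                if item.startswith("Name="):
                    name = item[5:]
            kind = _KIND_MAP.get(ftype, "other")
            out.setdefault(seqid, []).append(
                Feature(
                    name=name or ftype,
                    start=int(start),
                    end=int(end),
                    strand=strand if strand in "+-" else "+",
                    kind=kind,
                )
            )
    return out


def write_gff3(features: dict[str, list[Feature]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, feats in features.items():
            for f in feats:
                ftype = f.kind if f.kind in _KIND_MAP else "region"
                fh.write(
                    f"{seqid}\tohgt\t{ftype}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t"
                    f"Name={f.name}\n"
                )


def attach_annotations(
    records: Sequence[GenomeRecord],
    features: dict[str, list[Feature]] | None = None,
    taxonomy: dict[str, TaxonomyLineage] | None = None,
) -> None:
    for rec in records:
        if features and rec.id in features:
            rec.features = list(features[rec.id])
        if taxonomy and rec.id in taxonomy:
            rec.lineage = taxonomy[rec.id]


# ---------------------------------------------------------------------------
# Newick with integer support labels
# ---------------------------------------------------------------------------


def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Read a newick tree; internal-node labels are treated as integer
    bootstrap supports where they parse as numbers."""
    text = str(path_or_string)
    if "(" not in text and len(text) < 4096:
        p = Path(text)
        if p.exists():
            text = p.read_text()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed newick: {exc}") from exc
    for node in tree.internal_nodes():
        if node.label is not None:
            try:
                node.support = int(round(float(node.label)))
            except ValueError:
                node.support = None
        else:
            node.support = None
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    for node in tree.internal_nodes():
        sup = getattr(node, "support", None)
        if sup is not None:
            node.label = str(int(sup))
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    ).strip()
    return text


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree) + "\n")
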