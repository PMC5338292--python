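"""Synthetic organellar corpora with known IGT/HGT histories.

Each simulated species carries a mitochondrial and a plastid genome
evolved from shared root sequences along a Yule species tree (K80
substitutions plus indels outside gene features).  Plastid sequences
evolve slowly relative to mitochondrial intergenic DNA, and the three
ancient-homology loci are planted as conserved mt/pt homolog pairs so the
exclusion rules have something to exclude.

Implanted events:

* ``native_igt``     - own-plastid segment copied into the own mtDNA;
* ``mt2mt_hgt``      - IGT in a distant donor first, then the donor MTPT
                       plus flanking donor mitochondrial sequence copied
                       into the recipient mtDNA (tract co-transfer);
* ``pt2mt_hgt``      - distant donor plastid segment copied directly into
                       the recipient mtDNA, no mitochondrial padding;
* ``ptmt_igt``       - own-mitochondrial segment copied into the own
                       ptDNA (reverse-direction control).

Every implanted interval is recorded in the truth log for recovery
scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np

from .genome_io import Feature, GenomeRecord, TaxonomyLineage

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 1
    n_species: int = 20
    species_tree_height: float = 0.8  # expected subs/site, root to tip, mt rate
    mt_length: int = 48000
    pt_length: int = 15000
    n_native_mtpt: int = 20  # corpus totals, spread over random recipients
    n_mt2mt_events: int = 30
    n_pt2mt_events: int = 30
    n_ptmt_events: int = 0
    mtpt_length_range: tuple[int, int] = (300, 1200)
    mt_tract_padding: int = 1500
    divergence_at_transfer: float = 0.05
    igt_age_divergence: float = 0.02
    indel_rate: float = 0.02  # relative to the substitution rate
    kappa: float = 2.0
    pt_rate_scale: float = 0.15  # plastid rate relative to mt intergenic
    gene_rate_scale: float = 0.4  # ordinary genes, relative to compartment rate
    ancient_rate_scale: float = 0.05  # absolute rate of the ancient trio
    ultrametric: bool = True
    insert_margin: int = 1100  # clearance of insertion sites from features/implants

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("need n_species >= 4")
        if min(self.mt_length, self.pt_length) <= 0:
            raise ValueError("genome lengths must be positive")
        for count in (
            self.n_native_mtpt,
            self.n_mt2mt_events,
            self.n_pt2mt_events,
            self.n_ptmt_events,
        ):
            if count < 0:
                raise ValueError("event counts must be >= 0")


@dataclass
class HgtEvent:
    type: str  # native_igt | mt2mt_hgt | pt2mt_hgt | ptmt_igt
    donor_species: str
    recipient_species: str
    mt_insert_interval: list[int] | None = None  # recipient mt coords (MTPT)
    plastid_source_interval: list[int] | None = None  # donor pt coords
    co_transferred_tract_interval: list[int] | None = None  # recipient mt coords
    pt_insert_interval: list[int] | None = None  # recipient pt coords (ptmt)
    mt_source_interval: list[int] | None = None  # donor mt coords (ptmt/mt2mt)


@dataclass
class HgtEventLog:
    events: list[HgtEvent] = field(default_factory=list)

    def of_type(self, kind: str) -> list[HgtEvent]:
        return [e for e in self.events if e.type == kind]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps([asdict(e) for e in self.events], indent=1) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "HgtEventLog":
        raw = json.loads(Path(path).read_text())
        return cls([HgtEvent(**e) for e in raw])

    def to_tsv(self, path: str | Path) -> None:
        cols = [
            "type",
            "donor_species",
            "recipient_species",
            "mt_insert_interval",
            "plastid_source_interval",
            "co_transferred_tract_interval",
            "pt_insert_interval",
            "mt_source_interval",
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for e in self.events:
                row = []
                for c in cols:
                    v = getattr(e, c)
                    if isinstance(v, list):
                        v = f"{v[0]}-{v[1]}"
                    row.append(str(v) if v is not None else "-")
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------


@dataclass
class SimNode:
    time: float  # birth time of the node (root = 0)
    name: str | None = None
    children: list["SimNode"] = field(default_factory=list)
    parent: "SimNode | None" = None
    end: float = 0.0  # time at which the branch below this node ends

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["SimNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class SpeciesTree:
    root: SimNode
    height: float

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def newick(self) -> str:
        def render(node: SimNode) -> str:
            length = node.end - node.time
            if node.is_leaf:
                return f"{node.name}:{length:.6f}"
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}):{length:.6f}"

        inner = ",".join(render(c) for c in self.root.children)
        return f"({inner});"

    def lineages(self, cuts: tuple[float, float] = (0.35, 0.7)) -> dict[str, TaxonomyLineage]:
        """Derive ordered lineages from tree structure.

        Rank 0 = side of the root split, ranks 1-2 = monophyletic groups
        obtained by cutting the tree at ``cuts`` (fractions of tree
        height), rank 3 = species name.  Rank index 2 plays the role of
        the taxonomic order.
        """
        sides: dict[str, int] = {}
        for s, child in enumerate(self.root.children):
            for leaf in child.leaves():
                sides[leaf.name] = s

        def groups_at(frac: float) -> dict[str, int]:
            cut = frac * self.height
            gid = 0
            assign: dict[str, int] = {}

            def walk(node: SimNode) -> None:
                nonlocal gid
                # branch (node.time, node.end] crosses the cut -> one group
                if node.time <= cut < node.end or (node.is_leaf and node.time > cut):
                    for leaf in node.leaves():
                        assign[leaf.name] = gid
                    gid += 1
                    return
                if node.is_leaf:
                    assign[node.name] = gid
                    gid += 1
                    return
                for c in node.children:
                    walk(c)

            for c in self.root.children:
                walk(c)
            return assign

        g1 = groups_at(cuts[0])
        g2 = groups_at(cuts[1])
        out = {}
        for name in self.leaf_names():
            out[name] = TaxonomyLineage(
                (
                    f"clade{'AB'[sides[name]]}",
                    f"superord{g1[name]:02d}",
                    f"ord{g2[name]:02d}",
                    name,
                )
            )
        return out


def simulate_species_tree(config: SimConfig, rng: np.random.Generator | None = None) -> SpeciesTree:
    """Yule topology with exponential waiting times, scaled to the
    configured height; optionally non-ultrametric via lognormal branch
    rate multipliers."""
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_species
    root = SimNode(time=0.0)
    a, b = SimNode(time=0.0, parent=root), SimNode(time=0.0, parent=root)
    root.children = [a, b]
    open_branches = [a, b]
    t = 0.0
    while len(open_branches) < n:
        k = len(open_branches)
        t += rng.exponential(1.0 / k)
        idx = int(rng.integers(0, k))
        node = open_branches.pop(idx)
        node.end = t
        c1, c2 = SimNode(time=t, parent=node), SimNode(time=t, parent=node)
        node.children = [c1, c2]
        open_branches.extend([c1, c2])
    t += rng.exponential(1.0 / n)
    for i, leaf in enumerate(open_branches):
        leaf.end = t
        leaf.name = f"sp{i + 1:02d}"
    root.end = 0.0

    scale = config.species_tree_height / t

    def rescale(node: SimNode) -> None:
        node.time *= scale
        node.end *= scale
        for c in node.children:
            rescale(c)

    rescale(root)
    tree = SpeciesTree(root=root, height=config.species_tree_height)
    if not config.ultrametric:
        node_end_map = {id(root): 0.0}

        def jitter(node: SimNode) -> None:
            for c in node.children:
                rate = float(rng.lognormal(0.0, 0.3))
                length = (c.end - c.time) * rate
                c.time = node_end_map[id(node)]
                c.end = c.time + length
                node_end_map[id(c)] = c.end
                jitter(c)

        jitter(root)
    return tree


# ---------------------------------------------------------------------------
# Sequence evolution (K80 + indels)
# ---------------------------------------------------------------------------


def _k80_matrix(t: float, kappa: float) -> np.ndarray:
    """Transition probability matrix for branch length t expected
    substitutions/site under K80 (equal base frequencies)."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    # order A C G T; transitions A<->G and C<->T
    P = np.full((4, 4), p_tv)
    np.fill_diagonal(P, p_same)
    P[0, 2] = P[2, 0] = P[1, 3] = P[3, 1] = p_ts
    return P


def mutate_codes(
    codes: np.ndarray, t: float, kappa: float, rng: np.random.Generator,
    rates: np.ndarray | None = None,
) -> np.ndarray:
    """Substitute along a branch; per-site rate multipliers supported."""
    out = codes.copy()
    if t <= 0:
        return out
    if rates is None:
        groups = {1.0: np.arange(len(codes))}
    else:
        groups = {}
        for r in np.unique(rates):
            groups[float(r)] = np.flatnonzero(rates == r)
    for r, idx in groups.items():
        if r <= 0 or len(idx) == 0:
            continue
        P = _k80_matrix(t * r, kappa)
        cum = np.cumsum(P, axis=1)
        u = rng.random(len(idx))
        sub = codes[idx]
        new = np.empty(len(idx), dtype=np.int8)
        for b in range(4):
            mask = sub == b
            if mask.any():
                new[mask] = np.searchsorted(cum[b], u[mask]).astype(np.int8)
        out[idx] = new
    return out


class _GenomeState:
    """Mutable genome during simulation: codes, per-site rates, features,
    and a registry of intervals to shift on indels/insertions."""

    def __init__(self, codes: np.ndarray, rates: np.ndarray, features: list[list]):
        self.codes = codes
        self.rates = rates
        self.features = features  # [name, start, end, strand, kind] (1-based)
        self.registry: list[list[int]] = []  # [start, end] pairs, 1-based

    def clone(self) -> "_GenomeState":
        return _GenomeState(
            self.codes.copy(), self.rates.copy(), [list(f) for f in self.features]
        )

    def __len__(self) -> int:
        return len(self.codes)

    def _shift(self, pos: int, delta: int) -> None:
        """Shift features/registered intervals at 1-based positions >= pos."""
        for f in self.features:
            if f[1] >= pos:
                f[1] += delta
                f[2] += delta
        for iv in self.registry:
            if iv[0] >= pos:
                iv[0] += delta
                iv[1] += delta

    def insert(self, pos: int, codes: np.ndarray, rate: float) -> tuple[int, int]:
        """Insert before 1-based position pos; returns the inserted
        interval (1-based inclusive)."""
        i = pos - 1
        self.codes = np.concatenate([self.codes[:i], codes, self.codes[i:]])
        self.rates = np.concatenate(
            [self.rates[:i], np.full(len(codes), rate), self.rates[i:]]
        )
        self._shift(pos, len(codes))
        return (pos, pos + len(codes) - 1)

    def delete(self, pos: int, length: int) -> None:
        i = pos - 1
        self.codes = np.concatenate([self.codes[:i], self.codes[i + length :]])
        self.rates = np.concatenate([self.rates[:i], self.rates[i + length :]])
        for f in self.features:
            if f[1] >= pos + length:
                f[1] -= length
                f[2] -= length
        for iv in self.registry:
            if iv[0] >= pos + length:
                iv[0] -= length
                iv[1] -= length

    def feature_free(self, pos: int, margin: int) -> bool:
        for f in self.features:
            if f[1] - margin <= pos <= f[2] + margin:
                return False
        return True

    def blocked(self, pos: int, margin: int) -> bool:
        if not self.feature_free(pos, margin):
            return True
        for iv in self.registry:
            if iv[0] - margin <= pos <= iv[1] + margin:
                return True
        return False

    def sequence(self) -> str:
        return _DECODE[self.codes].tobytes().decode()


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.int8)


def _apply_indels(
    state: _GenomeState, t: float, config: SimConfig, rng: np.random.Generator,
    rate_scale: float,
) -> None:
    L = len(state)
    lam = config.indel_rate * t * rate_scale * L
    n_indels = int(rng.poisson(lam)) if lam > 0 else 0
    for _ in range(n_indels):
        length = min(int(rng.geometric(1.0 / 3.0)), 50)
        pos = int(rng.integers(2, len(state) - 50))
        if not state.feature_free(pos, 1):
            continue
        if rng.random() < 0.5:
            state.insert(pos, _random_codes(rng, length), rate_scale)
        else:
            # clip deletions so they never touch a feature
            end = pos + length - 1
            ok = all(not (f[1] <= end and pos <= f[2]) for f in state.features)
            if ok and len(state) - length > 100:
                state.delete(pos, length)


def _build_root(
    config: SimConfig, rng: np.random.Generator
) -> tuple[_GenomeState, _GenomeState]:
    """Root mt/pt genomes with shared ancient-homology loci."""
    p = config.pt_rate_scale
    shared = {
        "atp1": _random_codes(rng, 1100),
        "rrn18": _random_codes(rng, 1200),
        "rrn26": _random_codes(rng, 1500),
    }
    ancient = set(shared)

    def assemble(
        layout: list[tuple[str, int]], total: int, base_rate: float, gene_rate: float
    ) -> _GenomeState:
        pieces: list[np.ndarray] = []
        rates: list[np.ndarray] = []
        feats: list[list] = []
        pos = 1
        for name, length in layout:
            if name == "spacer":
                seq = _random_codes(rng, length)
                rates.append(np.full(length, base_rate))
            else:
                seq = shared.get(name)
                if seq is None:
                    seq = _random_codes(rng, length)
                seq = seq.copy()
                # the ancient trio stays detectable across the whole tree;
                # ordinary genes are only mildly conserved
                r = config.ancient_rate_scale if name in ancient else gene_rate
                rates.append(np.full(len(seq), r))
                feats.append([name, pos, pos + len(seq) - 1, "+", "gene"])
                length = len(seq)
            pieces.append(seq)
            pos += length
        used = pos - 1
        if used < total:
            pieces.append(_random_codes(rng, total - used))
            rates.append(np.full(total - used, base_rate))
        return _GenomeState(
            np.concatenate(pieces), np.concatenate(rates), feats
        )

    # spacer widths scale with the configured genome lengths so small
    # test corpora stay small while the default leaves room for implants
    mt_genes = [("atp1", 0), ("cox1", 1500), ("rrn18", 0), ("nad1", 1000), ("rrn26", 0)]
    mt_gene_total = 1100 + 1500 + 1200 + 1000 + 1500
    mt_spacer = max(2200, (config.mt_length - mt_gene_total - 2000) // 6)
    mt_layout: list[tuple[str, int]] = []
    for name, length in mt_genes:
        mt_layout.append(("spacer", mt_spacer))
        mt_layout.append((name, length))

    pt_genes = [("atp1", 0), ("psbA", 1000), ("rrn18", 0), ("rbcL", 1400), ("rrn26", 0), ("matK", 1500)]
    pt_gene_total = 1100 + 1000 + 1200 + 1400 + 1500 + 1500
    pt_spacer = max(500, (config.pt_length - pt_gene_total - 500) // 7)
    pt_layout = []
    for name, length in pt_genes:
        pt_layout.append(("spacer", pt_spacer))
        pt_layout.append((name, length))
    mt = assemble(mt_layout, config.mt_length, 1.0, config.gene_rate_scale)
    pt = assemble(pt_layout, config.pt_length, p, p * config.gene_rate_scale)
    return mt, pt


def evolve_genomes(
    tree: SpeciesTree, config: SimConfig, rng: np.random.Generator | None = None
) -> dict[str, tuple[_GenomeState, _GenomeState]]:
    """Evolve root mt/pt genomes down the species tree; returns
    species -> (mt state, pt state)."""
    rng = rng or np.random.default_rng(config.seed + 1)
    root_mt, root_pt = _build_root(config, rng)
    out: dict[str, tuple[_GenomeState, _GenomeState]] = {}

    def walk(node: SimNode, mt: _GenomeState, pt: _GenomeState) -> None:
        t = max(node.end - node.time, 0.0)
        if t > 0:
            mt = mt.clone()
            pt = pt.clone()
            mt.codes = mutate_codes(mt.codes, t, config.kappa, rng, mt.rates)
            pt.codes = mutate_codes(pt.codes, t, config.kappa, rng, pt.rates)
            _apply_indels(mt, t, config, rng, 1.0)
            _apply_indels(pt, t, config, rng, config.pt_rate_scale)
        if node.is_leaf:
            out[node.name] = (mt, pt)
            return
        for c in node.children:
            walk(c, mt, pt)

    for child in tree.root.children:
        walk(child, root_mt.clone(), root_pt.clone())
    return out


# ---------------------------------------------------------------------------
# Event implantation
# ---------------------------------------------------------------------------


def _pick_position(
    state: _GenomeState,
    rng: np.random.Generator,
    feature_margin: int,
    registry_margin: int,
    tries: int = 800,
) -> int:
    for _ in range(tries):
        pos = int(rng.integers(2000, len(state) - 2000))
        if not state.feature_free(pos, feature_margin):
            continue
        if any(
            iv[0] - registry_margin <= pos <= iv[1] + registry_margin
            for iv in state.registry
        ):
            continue
        return pos
    raise RuntimeError("could not find a free insertion position")


def _pick_source(state: _GenomeState, rng: np.random.Generator, length: int) -> int:
    if length >= len(state) - 200:
        raise ValueError("requested insert longer than source genome")
    return int(rng.integers(1, len(state) - length))


def _diverge(
    codes: np.ndarray, divergence: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    if divergence <= 0:
        return codes.copy()
    return mutate_codes(codes, divergence, kappa, rng)


def implant_events(
    genomes: dict[str, tuple[_GenomeState, _GenomeState]],
    tree: SpeciesTree,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> HgtEventLog:
    """Implant native IGT, mt-to-mt HGT, pt-to-mt HGT and reverse ptmt
    events into the evolved genomes (mutated in place); returns the truth
    log.  Donors are drawn from the opposite side of the root split, the
    taxonomically most distant group available."""
    rng = rng or np.random.default_rng(config.seed + 2)
    species = sorted(genomes)
    lineages = tree.lineages()
    sides = {s: lineages[s].ranks[0] for s in species}
    log = HgtEventLog()

    def register(state: _GenomeState, interval: tuple[int, int]) -> list[int]:
        iv = [interval[0], interval[1]]
        state.registry.append(iv)
        return iv

    def distant_donor(recipient: str) -> str:
        pool = [s for s in species if sides[s] != sides[recipient]]
        if not pool:  # degenerate root split; fall back to any other species
            pool = [s for s in species if s != recipient]
        return pool[int(rng.integers(0, len(pool)))]

    def rand_len() -> int:
        lo, hi = config.mtpt_length_range
        return int(rng.integers(lo, hi + 1))

    def recipient_cycle(n_events: int) -> list[str]:
        """Spread events over species round-robin (shuffled) so no single
        genome has to absorb an unbounded number of inserts."""
        order = list(species)
        rng.shuffle(order)
        reps = (n_events + len(order) - 1) // len(order)
        return (order * reps)[:n_events]

    pad = config.mt_tract_padding

    # ---- phase 1: donor-side IGT for mt2mt events -------------------------
    mt2mt_prep = []
    for recipient in recipient_cycle(config.n_mt2mt_events):
        donor = distant_donor(recipient)
        d_mt, d_pt = genomes[donor]
        length = rand_len()
        src = _pick_source(d_pt, rng, length)
        segment = d_pt.codes[src - 1 : src - 1 + length]
        igt_copy = _diverge(segment, config.igt_age_divergence, config.kappa, rng)
        # tract [mtpt - pad, mtpt + pad] must stay clear of genes and of
        # other implants, so clearance includes the padding
        pos = _pick_position(d_mt, rng, pad + 150, pad + config.insert_margin)
        mtpt_iv = d_mt.insert(pos, igt_copy, 1.0)
        d_mt.features.append([f"mtpt_{donor}", mtpt_iv[0], mtpt_iv[1], "+", "mtpt_annotation"])
        donor_mtpt_iv = register(d_mt, mtpt_iv)
        register(d_mt, (mtpt_iv[0] - pad, mtpt_iv[1] + pad))  # block the tract
        src_iv = register(d_pt, (src, src + length - 1))
        # the donor-side copy is itself a genuine native MTPT
        log.events.append(
            HgtEvent(
                type="native_igt",
                donor_species=donor,
                recipient_species=donor,
                mt_insert_interval=donor_mtpt_iv,
                plastid_source_interval=src_iv,
            )
        )
        mt2mt_prep.append((recipient, donor, donor_mtpt_iv, src_iv))

    # ---- phase 2: native IGT ---------------------------------------------
    for recipient in recipient_cycle(config.n_native_mtpt):
        r_mt, r_pt = genomes[recipient]
        length = rand_len()
        src = _pick_source(r_pt, rng, length)
        segment = r_pt.codes[src - 1 : src - 1 + length]
        copy = _diverge(segment, config.igt_age_divergence, config.kappa, rng)
        pos = _pick_position(r_mt, rng, config.insert_margin, config.insert_margin)
        iv = r_mt.insert(pos, copy, 1.0)
        r_mt.features.append([f"mtpt_{recipient}", iv[0], iv[1], "+", "mtpt_annotation"])
        log.events.append(
            HgtEvent(
                type="native_igt",
                donor_species=recipient,
                recipient_species=recipient,
                mt_insert_interval=register(r_mt, iv),
                plastid_source_interval=register(r_pt, (src, src + length - 1)),
            )
        )

    # ---- phase 3: mt2mt transfers ----------------------------------------
    for recipient, donor, donor_mtpt_iv, src_iv in mt2mt_prep:
        d_mt, _d_pt = genomes[donor]
        tract_lo = donor_mtpt_iv[0] - pad
        tract_hi = donor_mtpt_iv[1] + pad
        tract = d_mt.codes[tract_lo - 1 : tract_hi]
        moved = _diverge(tract, config.divergence_at_transfer, config.kappa, rng)
        r_mt, _r_pt = genomes[recipient]
        # flank windows live inside the co-transferred tract, so only a
        # small clearance from recipient features is needed
        pos = _pick_position(r_mt, rng, 200, 500)
        iv = r_mt.insert(pos, moved, 1.0)
        mtpt_lo = iv[0] + pad
        mtpt_hi = iv[1] - pad
        r_mt.features.append([f"mtpt_{donor}", mtpt_lo, mtpt_hi, "+", "mtpt_annotation"])
        log.events.append(
            HgtEvent(
                type="mt2mt_hgt",
                donor_species=donor,
                recipient_species=recipient,
                mt_insert_interval=register(r_mt, (mtpt_lo, mtpt_hi)),
                plastid_source_interval=src_iv,
                co_transferred_tract_interval=register(r_mt, iv),
                mt_source_interval=donor_mtpt_iv,
            )
        )

    # ---- phase 4: direct pt2mt transfers ---------------------------------
    for recipient in recipient_cycle(config.n_pt2mt_events):
        donor = distant_donor(recipient)
        _d_mt, d_pt = genomes[donor]
        length = rand_len()
        src = _pick_source(d_pt, rng, length)
        segment = d_pt.codes[src - 1 : src - 1 + length]
        moved = _diverge(segment, config.divergence_at_transfer, config.kappa, rng)
        r_mt, _r_pt = genomes[recipient]
        # flank windows extend into native recipient sequence: keep them
        # clear of genes and of other implants
        pos = _pick_position(r_mt, rng, config.insert_margin, config.insert_margin)
        iv = r_mt.insert(pos, moved, 1.0)
        r_mt.features.append([f"mtpt_{donor}", iv[0], iv[1], "+", "mtpt_annotation"])
        log.events.append(
            HgtEvent(
                type="pt2mt_hgt",
                donor_species=donor,
                recipient_species=recipient,
                mt_insert_interval=register(r_mt, iv),
                plastid_source_interval=register(d_pt, (src, src + length - 1)),
            )
        )

    # ---- phase 5: reverse-direction mt -> pt (ptmt) ----------------------
    for recipient in recipient_cycle(config.n_ptmt_events):
        r_mt, r_pt = genomes[recipient]
        length = max(200, rand_len() // 2)
        for _try in range(300):
            src = _pick_source(r_mt, rng, length)
            if all(
                not (f[1] <= src + length - 1 and src <= f[2]) for f in r_mt.features
            ):
                break
        segment = r_mt.codes[src - 1 : src - 1 + length]
        copy = _diverge(segment, config.igt_age_divergence, config.kappa, rng)
        pos = _pick_position(r_pt, rng, 200, 500)
        iv = r_pt.insert(pos, copy, config.pt_rate_scale)
        r_pt.features.append([f"ptmt_{recipient}", iv[0], iv[1], "+", "ptmt_annotation"])
        log.events.append(
            HgtEvent(
                type="ptmt_igt",
                donor_species=recipient,
                recipient_species=recipient,
                pt_insert_interval=register(r_pt, iv),
                mt_source_interval=register(r_mt, (src, src + length - 1)),
            )
        )
    return log


# ---------------------------------------------------------------------------
# Corpus assembly
# ---------------------------------------------------------------------------


@dataclass
class Corpus:
    config: SimConfig
    tree: SpeciesTree
    records: dict[str, GenomeRecord]  # id -> record ("spNN_mt"/"spNN_pt")
    taxonomy: dict[str, TaxonomyLineage]
    truth: HgtEventLog

    def mt_records(self) -> list[GenomeRecord]:
        return [r for r in self.records.values() if r.compartment == "mt"]

    def pt_records(self) -> list[GenomeRecord]:
        return [r for r in self.records.values() if r.compartment == "pt"]

    def mt_id(self, species: str) -> str:
        return f"{species}_mt"

    def pt_id(self, species: str) -> str:
        return f"{species}_pt"


def simulate_corpus(config: SimConfig) -> Corpus:
    """One-call simulation: tree, genomes, events, taxonomy. Fully
    determined by the config (including its seed)."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_species_tree(config, rng)
    genomes = evolve_genomes(tree, config, np.random.default_rng(config.seed + 1))
    truth = implant_events(
        genomes, tree, config, np.random.default_rng(config.seed + 2)
    )
    lineages = tree.lineages()
    records: dict[str, GenomeRecord] = {}
    taxonomy: dict[str, TaxonomyLineage] = {}
    for species, (mt, pt) in sorted(genomes.items()):
        for comp, state in (("mt", mt), ("pt", pt)):
            rid = f"{species}_{comp}"
            feats = [
                Feature(name=f[0], start=f[1], end=f[2], strand=f[3], kind=f[4])
                for f in state.features
            ]
            records[rid] = GenomeRecord(
                id=rid,
                compartment=comp,
                sequence=state.sequence(),
                features=feats,
                lineage=lineages[species],
            )
            taxonomy[rid] = lineages[species]
    return Corpus(config=config, tree=tree, records=records, taxonomy=taxonomy, truth=truth)


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0] + 1), ov / (b[1] - b[0] + 1))


@dataclass
class RecoveryScore:
    recall: float
    precision: float | None
    donor_accuracy: float | None
    mt2mt_flag_rates: dict[str, float | None]
    n_truth: int
    n_calls: int
    matched: int


def score_recovery(
    truth: HgtEventLog,
    calls: Iterable,
    min_overlap: float = 0.5,
    call_genome=lambda c: c.mt_id,
    call_interval=lambda c: (c.start, c.end),
    truth_genome=lambda e, _=None: f"{e.recipient_species}_mt",
    truth_interval=lambda e: tuple(e.mt_insert_interval),
    donor_of_call=None,
    mt2mt_flag_of_call=None,
    lineages: dict[str, TaxonomyLineage] | None = None,
) -> RecoveryScore:
    """Match calls to truth events by >=50% reciprocal overlap on the
    recipient genome; report recall/precision, donor accuracy at the
    shallowest simulated rank, and the mt-to-mt flag rate per truth
    class."""
    calls = list(calls)
    events = [e for e in truth.events if truth_interval(e) is not None]
    matches: dict[int, object] = {}
    used = set()
    for ei, e in enumerate(events):
        best = None
        for ci, c in enumerate(calls):
            if ci in used or call_genome(c) != truth_genome(e):
                continue
            ov = _reciprocal_overlap(call_interval(c), truth_interval(e))
            if ov >= min_overlap and (best is None or ov > best[0]):
                best = (ov, ci)
        if best is not None:
            used.add(best[1])
            matches[ei] = calls[best[1]]
    recall = len(matches) / len(events) if events else 0.0
    precision = (len(used) / len(calls)) if calls else None

    donor_acc = None
    if donor_of_call is not None and lineages is not None:
        ok = tot = 0
        for ei, call in matches.items():
            e = events[ei]
            if e.type not in ("mt2mt_hgt", "pt2mt_hgt"):
                continue
            assigned = donor_of_call(call)
            if assigned is None:
                tot += 1
                continue
            true_lin = lineages[e.donor_species]
            tot += 1
            if assigned.ranks[0] == true_lin.ranks[0]:
                ok += 1
        donor_acc = ok / tot if tot else None

    flag_rates: dict[str, float | None] = {}
    if mt2mt_flag_of_call is not None:
        for kind in ("mt2mt_hgt", "pt2mt_hgt"):
            flagged = tot = 0
            for ei, call in matches.items():
                if events[ei].type != kind:
                    continue
                tot += 1
                if mt2mt_flag_of_call(call):
                    flagged += 1
            flag_rates[kind] = flagged / tot if tot else None
    return RecoveryScore(
        recall=recall,
        precision=precision,
        donor_accuracy=donor_acc,
        mt2mt_flag_rates=flag_rates,
        n_truth=len(events),
        n_calls=len(calls),
        matched=len(matches),
    )
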