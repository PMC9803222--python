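"""Synthetic genome evolution with known event histories.

Simulates a gene repertoire along a species tree under whole-genome
duplications (WGD), tandem duplications, gene losses, translocations and
chromosome fusions, then evolves protein sequences along the same tree under
a 20-state Jukes-Cantor-type substitution channel with planted domain
cassettes. The complete event history and per-node ancestral repertoires are
recorded, so every downstream inference (homology, domain architecture,
trees, synteny, repertoires) can be scored against ground truth.

Event semantics
---------------
* WGD duplicates every chromosome of the lineage genome; copies get the
  parent chromosome id suffixed ``a``/``b`` and genes the suffix ``.a``/``.b``.
  Within-chromosome gene order is preserved on both copies.
* Tandem duplication inserts the copy immediately downstream on the same
  chromosome and strand, separated by a configurable gap (default 20 kb,
  mirroring observed local duplicates).
* Losses delete a gene; translocations move a gene to another chromosome
  (uniformly chosen when not scripted); fusions concatenate two chromosomes.
* Scripted events in scenario files may also ``rename`` genes, which is how
  post-WGD survivors acquire their subfamily identities (e.g. CNGA1-4).

Sequences evolve by substitution only (no indels); functionally constrained
motifs inside cassettes (e.g. the trimming anchors VVID/EYPD, NLMY/GTPK) can
be declared invariant, emulating strong purifying selection.
"""

from __future__ import annotations

import copy as _copy
import json
import math
from collections import Counter
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .io_formats import (
    GeneLocus,
    load_yaml,
    read_fasta,
    read_gff3_with_attrs,
    write_fasta,
    write_gff3,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_IDX = {a: i for i, a in enumerate(AA)}


# ---------------------------------------------------------------------------
# Substitution channel: 20-state Jukes-Cantor-type model
# ---------------------------------------------------------------------------


def p_same(d: float) -> float:
    """Probability a site is in the same state after distance d (subs/site)."""
    return 1 / 20 + (19 / 20) * math.exp(-20 * d / 19)


def expected_p_diff(d1: float, d2: float) -> float:
    """Expected proportion of differing sites between two leaves at distances
    d1 and d2 from their common ancestor (closed form from the channel)."""
    a1, a2 = p_same(d1), p_same(d2)
    b1, b2 = (1 - a1) / 19, (1 - a2) / 19
    return 1 - (a1 * a2 + 19 * b1 * b2)


def evolve_sequence(seq: str, d: float, rng: np.random.Generator, mask=None,
                    rates=None) -> str:
    """Evolve a protein sequence for ``d`` substitutions/site.

    ``mask`` marks invariant positions (True = never substituted);
    ``rates`` optionally scales the per-site rate (e.g. < 1 inside conserved
    domain cassettes, 1 in linkers), emulating among-site rate variation.
    """
    if d <= 0:
        return seq
    arr = np.array([_AA_IDX.get(c, -1) for c in seq], dtype=np.int64)
    if rates is None:
        ps = np.full(arr.size, p_same(d))
    else:
        ps = 1 / 20 + (19 / 20) * np.exp(-20 * d * np.asarray(rates) / 19)
    change = rng.random(arr.size) >= ps
    if mask is not None:
        change &= ~np.asarray(mask, dtype=bool)
    change &= arr >= 0  # leave non-standard letters alone
    idx = np.flatnonzero(change)
    if idx.size:
        # uniform over the 19 other residues
        shift = rng.integers(1, 20, size=idx.size)
        arr[idx] = (arr[idx] + shift) % 20
    out = list(seq)
    for i in idx:
        out[i] = AA[arr[i]]
    return "".join(out)


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, size=length))


# ---------------------------------------------------------------------------
# Domain cassettes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Cassette:
    """A domain cassette: consensus sequence, planting noise, invariant
    motifs, and the relative substitution rate of its sites (domains evolve
    slower than the linkers around them)."""

    name: str
    consensus: str
    noise: float = 0.05
    invariant: tuple = ()  # ((motif, offset), ...) positions within cassette
    rate: float = 0.6

    def mask(self) -> np.ndarray:
        m = np.zeros(len(self.consensus), dtype=bool)
        for motif, off in self.invariant:
            m[off : off + len(motif)] = True
        return m


def _fixed_consensus(length: int, stream: int) -> str:
    rng = np.random.default_rng([0xC5EED, stream])
    return random_protein(length, rng)


def default_cassettes() -> dict[str, Cassette]:
    """The packaged cassette definitions (channel-like architecture).

    Ion_trans-like opens with the VVID anchor; cNMP_binding-like starts with
    NLMY and ends with ...EYPDGTPK so that both the A-type (VVID..EYPD) and
    B-type (NLMY..GTPK) trimming anchors fall on invariant sites.
    """
    ion = "VVID" + _fixed_consensus(96, 1)
    cnmp_core = _fixed_consensus(168, 2)
    cnmp = "NLMY" + cnmp_core + "EYPDGTPK"
    clz = _fixed_consensus(64, 3)
    return {
        "ion_trans": Cassette(
            "ion_trans", ion, invariant=(("VVID", 0),)
        ),
        "cnmp": Cassette(
            "cnmp",
            cnmp,
            invariant=(("NLMY", 0), ("EYPD", len(cnmp) - 8), ("GTPK", len(cnmp) - 4)),
        ),
        "clz": Cassette("clz", clz),
    }


#: segment order of the full scaffold; each cassette owns the linker after it
CASSETTE_ORDER = ("ion_trans", "cnmp", "clz")
LINKER_LENGTHS = {"linker0": 30, "ion_trans": 25, "cnmp": 25, "clz": 20}


# ---------------------------------------------------------------------------
# Config / events / genomes
# ---------------------------------------------------------------------------


@dataclass
class RootGene:
    gene_id: str
    family: str
    chromosome: str
    start: int
    subfamily: str | None = None
    architecture: tuple = ()  # cassette names, in CASSETTE_ORDER
    length: int = 150  # only for genes without an architecture
    conserve_motifs: bool = True  # purifying selection on cassette motifs

    def __post_init__(self):
        if self.subfamily is None:
            self.subfamily = self.family


@dataclass
class SimConfig:
    """Scenario configuration; see the packaged ``scenarios/*.yaml`` files."""

    species_tree: str
    root_genes: list = field(default_factory=list)
    root_family_tree: str | None = None
    scripted_events: dict = field(default_factory=dict)  # branch -> [event dict]
    wgd_events: list = field(default_factory=list)  # (branch, round) pairs
    tandem_rate: float = 0.0
    loss_rate: float = 0.0
    transloc_rate: float = 0.0
    neighbor_loss_rate: float = 0.0
    n_chromosomes: int = 3
    neighbor_family_count: int = 0
    neighbors: dict = field(default_factory=dict)  # chrom -> spec dict
    domain_cassettes: dict = field(default_factory=default_cassettes)
    seed: int = 0
    tandem_gap: int = 20_000
    gene_length_bp: int = 10_000
    gene_spacing_bp: int = 400_000
    neighbor_length_aa: int = 150
    name: str = "scenario"
    pipeline: dict = field(default_factory=dict)  # analysis-stage settings

    def __post_init__(self):
        for r, v in [
            ("tandem_rate", self.tandem_rate),
            ("loss_rate", self.loss_rate),
            ("transloc_rate", self.transloc_rate),
            ("neighbor_loss_rate", self.neighbor_loss_rate),
        ]:
            if v < 0:
                raise ValueError(f"{r} must be >= 0, got {v}")
        tree = self.tree()
        names = {n.name for n in tree.traverse(include_self=True)}
        if sum(1 for _ in tree.tips()) < 2:
            raise ValueError("species tree needs at least 2 leaves")
        if None in names or len(names) != sum(1 for _ in tree.traverse(include_self=True)):
            raise ValueError("every species-tree node must carry a unique name")
        for br, rnd in self.all_wgd_events():
            if br not in names:
                raise ValueError(f"WGD round {rnd} on unknown branch {br!r}")
        for br in self.scripted_events:
            if br not in names:
                raise ValueError(f"scripted events on unknown branch {br!r}")

    def tree(self) -> TreeNode:
        return TreeNode.read(StringIO(self.species_tree))

    def all_wgd_events(self):
        out = [tuple(x) for x in self.wgd_events]
        for br, evs in self.scripted_events.items():
            for ev in evs:
                if ev.get("type") == "wgd":
                    out.append((br, ev.get("round", "WGD")))
        return out

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = load_yaml(path)
        raw.pop("kind", None)
        genes = [RootGene(**g) for g in raw.pop("root_genes", [])]
        for g in genes:
            g.architecture = tuple(g.architecture)
        cass = raw.pop("domain_cassettes", None)
        cfg = cls(root_genes=genes, **raw)
        if cass is not None and cass != "default":
            cfg.domain_cassettes = {
                n: Cassette(n, c["consensus"], c.get("noise", 0.05),
                            tuple((m, o) for m, o in c.get("invariant", [])))
                for n, c in cass.items()
            }
        return cfg


@dataclass
class SimGene:
    """A gene tracked through the simulation (mutable working record)."""

    gene_id: str
    family: str
    subfamily: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    origin: str = "root"

    def locus(self, species: str) -> GeneLocus:
        return GeneLocus(self.gene_id, species, self.chromosome, self.start, self.end, self.strand)


@dataclass
class Event:
    event_type: str  # wgd | tandem_dup | loss | transloc | fusion | rename
    branch: str
    time: float  # fraction along the branch
    genes: tuple
    details: dict

    def to_json(self) -> dict:
        return {
            "event_type": self.event_type,
            "branch": self.branch,
            "time": self.time,
            "genes": list(self.genes),
            "details": self.details,
        }


@dataclass
class Genome:
    """A species' gene complement: coordinates plus protein sequences."""

    species: str
    loci: list
    sequences: dict
    families: dict = field(default_factory=dict)
    subfamilies: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [l.gene_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.species}: duplicate gene ids")
        missing = [g for g in ids if g not in self.sequences]
        if missing:
            raise ValueError(f"{self.species}: loci without sequences: {missing[:5]}")

    def loci_by_chromosome(self) -> dict:
        out: dict[str, list] = {}
        for l in sorted(self.loci, key=lambda x: (x.chromosome, x.start)):
            out.setdefault(l.chromosome, []).append(l)
        return out


@dataclass
class EventHistory:
    """Ground truth: replayable event list plus per-node repertoires."""

    species_tree: str
    events: list
    ancestral_counts: dict  # (node, subfamily) -> int
    subfamily_family: dict  # subfamily -> family
    root_state: list  # list[SimGene] snapshot at the root node
    node_states: dict  # node name -> list[SimGene]

    def counts_by_family(self, node: str) -> Counter:
        c: Counter = Counter()
        for (n, sub), k in self.ancestral_counts.items():
            if n == node:
                c[self.subfamily_family.get(sub, sub)] += k
        return c

    def count(self, node: str, subfamily: str) -> int:
        return self.ancestral_counts.get((node, subfamily), 0)

    def branch_events(self, branch: str) -> list:
        return [e for e in self.events if e.branch == branch]

    def state_after(self, branch: str, upto_event_index: int | None = None):
        """Genome state on ``branch`` after applying its first k events.

        With ``upto_event_index=None`` all events apply (= the child node
        state). Used to interrogate mid-branch repertoires, e.g. the
        pre-WGD vertebrate ancestor.
        """
        tree = TreeNode.read(StringIO(self.species_tree))
        node = tree.find(branch)
        parent = node.parent
        state = _copy.deepcopy(
            self.root_state if parent is None else self.node_states[parent.name]
        )
        evs = self.branch_events(branch)
        if upto_event_index is not None:
            evs = evs[:upto_event_index]
        genes = {g.gene_id: g for g in state}
        for ev in evs:
            _apply_event(genes, ev)
        return sorted(genes.values(), key=lambda g: g.gene_id)

    def replay(self) -> dict:
        """Re-apply all events from the root snapshot; returns node states."""
        tree = TreeNode.read(StringIO(self.species_tree))
        states = {tree.name: _copy.deepcopy(self.root_state)}
        for node in tree.preorder(include_self=False):
            genes = {g.gene_id: _copy.deepcopy(g) for g in states[node.parent.name]}
            for ev in self.branch_events(node.name):
                _apply_event(genes, ev)
            states[node.name] = sorted(genes.values(), key=lambda g: g.gene_id)
        return states


# ---------------------------------------------------------------------------
# Event application (shared by simulation and replay)
# ---------------------------------------------------------------------------


def _apply_event(genes: dict, ev: Event) -> None:
    d = ev.details
    if ev.event_type == "wgd":
        new = {}
        for gid in sorted(genes):
            g = genes[gid]
            ca, cb = d["chrom_map"][g.chromosome]
            ia, ib = d["gene_map"][gid]
            ga = _copy.deepcopy(g)
            ga.gene_id, ga.chromosome, ga.origin = ia, ca, f"wgd:{d['round']}"
            gb = _copy.deepcopy(g)
            gb.gene_id, gb.chromosome, gb.origin = ib, cb, f"wgd:{d['round']}"
            new[ia] = ga
            new[ib] = gb
        genes.clear()
        genes.update(new)
    elif ev.event_type == "tandem_dup":
        src = genes[d["source"]]
        cp = _copy.deepcopy(src)
        cp.gene_id = d["copy"]
        cp.start, cp.end = d["start"], d["end"]
        cp.origin = "tandem"
        genes[cp.gene_id] = cp
    elif ev.event_type == "loss":
        del genes[d["gene"]]
    elif ev.event_type == "transloc":
        g = genes[d["gene"]]
        g.chromosome = d["to"]
        g.start, g.end = d["new_start"], d["new_end"]
        g.origin = "transloc"
    elif ev.event_type == "fusion":
        c1, c2 = d["chroms"]
        for g in genes.values():
            if g.chromosome == c2:
                g.start += d["offset"]
                g.end += d["offset"]
                g.chromosome = d["new"]
            elif g.chromosome == c1:
                g.chromosome = d["new"]
    elif ev.event_type == "rename":
        for old in sorted(d["map"]):
            new_id, new_sub = d["map"][old]
            g = genes.pop(old)
            g.gene_id = new_id
            if new_sub:
                g.subfamily = new_sub
            genes[new_id] = g
    else:  # pragma: no cover
        raise ValueError(f"unknown event type {ev.event_type}")


# ---------------------------------------------------------------------------
# simulate_history
# ---------------------------------------------------------------------------


def _build_root_state(config: SimConfig) -> list:
    genes = []
    for rg in config.root_genes:
        genes.append(
            SimGene(
                rg.gene_id,
                rg.family,
                rg.subfamily,
                rg.chromosome,
                rg.start,
                rg.start + config.gene_length_bp,
            )
        )
    by_id = {g.gene_id: g for g in genes}
    for chrom in sorted(config.neighbors):
        spec = config.neighbors[chrom]
        anchor = by_id[spec["anchor"]]
        prefix = spec.get("prefix", f"N{chrom}")
        for i in range(spec["count"]):
            k = i // 2 + 1
            sign = 1 if i % 2 == 0 else -1
            start = anchor.start + sign * k * config.gene_spacing_bp
            if start < 0:
                start = anchor.start + (spec["count"] + k) * config.gene_spacing_bp
            fam = f"{prefix}{i + 1}"
            genes.append(
                SimGene(fam, fam, fam, chrom, start, start + config.gene_length_bp)
            )
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate root gene ids")
    return sorted(genes, key=lambda g: g.gene_id)


def _max_end(genes: dict, chrom: str) -> int:
    ends = [g.end for g in genes.values() if g.chromosome == chrom]
    return max(ends) if ends else 0


def simulate_history(config: SimConfig) -> EventHistory:
    """Run the event layer of the simulation; sequences are evolved separately."""
    rng = np.random.default_rng(config.seed)
    tree = config.tree()
    root_state = _build_root_state(config)
    states = {tree.name: root_state}
    all_events: list[Event] = []

    for node in tree.preorder(include_self=False):
        branch = node.name
        genes = {g.gene_id: _copy.deepcopy(g) for g in states[node.parent.name]}
        start_ids = sorted(genes)

        pending: list[tuple[float, int, dict]] = []
        scripted = config.scripted_events.get(branch, [])
        n_s = len(scripted)
        for i, ev in enumerate(scripted):
            t = ev.get("time", (i + 1) / (n_s + 1))
            pending.append((t, i, dict(ev)))
        for br, rnd in config.wgd_events:
            if br == branch:
                pending.append((0.5, len(pending), {"type": "wgd", "round": rnd}))
        # stochastic events sampled against the branch-start gene set
        order = len(pending)
        for gid in start_ids:
            is_neighbor = genes[gid].family not in {rg.family for rg in config.root_genes}
            lrate = config.neighbor_loss_rate if is_neighbor else config.loss_rate
            for _ in range(rng.poisson(config.tandem_rate)):
                pending.append(
                    (float(rng.random()), order, {"type": "tandem_dup", "gene": gid, "sampled": True})
                )
                order += 1
            if lrate > 0 and rng.random() < lrate:
                pending.append(
                    (float(rng.random()), order, {"type": "loss", "gene": gid, "sampled": True})
                )
                order += 1
            for _ in range(rng.poisson(config.transloc_rate)):
                pending.append(
                    (float(rng.random()), order, {"type": "transloc", "gene": gid, "sampled": True})
                )
                order += 1
        pending.sort(key=lambda x: (x[0], x[1]))

        td_counter = 0
        for t, _, spec in pending:
            etype = spec["type"]
            if etype == "wgd":
                chroms = sorted({g.chromosome for g in genes.values()})
                chrom_map = {c: (c + "a", c + "b") for c in chroms}
                gene_map = {gid: (gid + ".a", gid + ".b") for gid in sorted(genes)}
                ev = Event("wgd", branch, t, tuple(sorted(genes)),
                           {"round": spec.get("round", "WGD"),
                            "chrom_map": chrom_map, "gene_map": gene_map})
            elif etype == "tandem_dup":
                gid = spec["gene"]
                if gid not in genes:
                    if not spec.get("sampled"):
                        raise ValueError(f"tandem_dup of unknown gene {gid!r} on {branch}")
                    continue
                src = genes[gid]
                td_counter += 1
                cp_id = spec.get("new_id", f"{gid}-td{td_counter}")
                gap = spec.get("gap", config.tandem_gap)
                start = src.end + gap
                ev = Event("tandem_dup", branch, t, (gid,),
                           {"source": gid, "copy": cp_id, "chromosome": src.chromosome,
                            "start": start, "end": start + (src.end - src.start),
                            "strand": src.strand})
            elif etype == "loss":
                gid = spec["gene"]
                if gid not in genes:
                    if not spec.get("sampled"):
                        raise ValueError(f"loss of unknown gene {gid!r} on {branch}")
                    continue
                ev = Event("loss", branch, t, (gid,), {"gene": gid})
            elif etype == "transloc":
                gid = spec["gene"]
                if gid not in genes:
                    if not spec.get("sampled"):
                        raise ValueError(f"transloc of unknown gene {gid!r} on {branch}")
                    continue
                src = genes[gid]
                if "to" in spec:
                    target = spec["to"]
                else:
                    others = sorted({g.chromosome for g in genes.values()} - {src.chromosome})
                    if not others:
                        continue
                    target = others[int(rng.integers(0, len(others)))]
                ns = _max_end(genes, target) + config.gene_spacing_bp
                ev = Event("transloc", branch, t, (gid,),
                           {"gene": gid, "from": src.chromosome, "to": target,
                            "new_start": ns, "new_end": ns + (src.end - src.start)})
            elif etype == "fusion":
                c1, c2 = spec["chroms"]
                ev = Event("fusion", branch, t, (),
                           {"chroms": [c1, c2], "new": spec.get("new", c1),
                            "offset": _max_end(genes, c1) + config.gene_spacing_bp})
            elif etype == "rename":
                m = {}
                for old, val in spec["map"].items():
                    if isinstance(val, str):
                        m[old] = (val, None)
                    else:
                        m[old] = (val["id"], val.get("subfamily"))
                missing = [o for o in m if o not in genes]
                if missing:
                    raise ValueError(f"rename of unknown genes {missing} on {branch}")
                ev = Event("rename", branch, t, tuple(sorted(m)), {"map": m})
            else:
                raise ValueError(f"unknown scripted event type {etype!r} on {branch}")
            _apply_event(genes, ev)
            all_events.append(ev)

        states[branch] = sorted(genes.values(), key=lambda g: g.gene_id)

    counts: dict = {}
    sub_fam: dict = {}
    for name, state in states.items():
        c = Counter(g.subfamily for g in state)
        for sub, k in c.items():
            counts[(name, sub)] = k
        for g in state:
            sub_fam[g.subfamily] = g.family
    return EventHistory(config.species_tree, all_events, counts, sub_fam,
                        root_state, states)


# ---------------------------------------------------------------------------
# evolve_sequences
# ---------------------------------------------------------------------------


def _scaffold_layout(cassettes: dict) -> list:
    """Full scaffold segments: (name, length); linkers follow their cassette."""
    layout = [("linker0", LINKER_LENGTHS["linker0"])]
    for cname in CASSETTE_ORDER:
        if cname in cassettes:
            layout.append((cname, len(cassettes[cname].consensus)))
            layout.append((f"linker_{cname}", LINKER_LENGTHS[cname]))
    return layout


def _master_scaffold(cassettes: dict, rng: np.random.Generator):
    """Build the master full-architecture sequence, its invariant mask and
    the segment coordinate table."""
    layout = _scaffold_layout(cassettes)
    parts, mask_parts, rate_parts, spans = [], [], [], {}
    pos = 0
    for name, length in layout:
        if name in cassettes:
            cas = cassettes[name]
            seq = list(cas.consensus)
            m = cas.mask()
            noise = (rng.random(length) < cas.noise) & ~m
            for i in np.flatnonzero(noise):
                seq[i] = AA[(int(_AA_IDX[seq[i]]) + int(rng.integers(1, 20))) % 20]
            parts.append("".join(seq))
            mask_parts.append(m)
            rate_parts.append(np.full(length, cas.rate))
        else:
            parts.append(random_protein(length, rng))
            mask_parts.append(np.zeros(length, dtype=bool))
            rate_parts.append(np.ones(length))
        spans[name] = (pos, pos + length)
        pos += length
    return ("".join(parts), np.concatenate(mask_parts),
            np.concatenate(rate_parts), spans)


def _excise(seq: str, mask: np.ndarray, rates: np.ndarray, spans: dict,
            architecture: tuple):
    """Project the master scaffold onto a family's architecture."""
    keep = [spans["linker0"]]
    for cname in CASSETTE_ORDER:
        if cname in architecture and cname in spans:
            keep.append(spans[cname])
            keep.append(spans[f"linker_{cname}"])
    out_seq = "".join(seq[a:b] for a, b in keep)
    out_mask = np.concatenate([mask[a:b] for a, b in keep])
    out_rates = np.concatenate([rates[a:b] for a, b in keep])
    return out_seq, out_mask, out_rates


def evolve_sequences(history: EventHistory, config: SimConfig) -> dict:
    """Evolve protein sequences along the species tree; returns per-species
    :class:`Genome` objects keyed by leaf name."""
    rng = np.random.default_rng([config.seed, 0xE5])
    tree = config.tree()
    cassettes = config.domain_cassettes

    # --- root sequences -----------------------------------------------------
    master, master_mask, master_rates, spans = _master_scaffold(cassettes, rng)
    root_seq: dict[str, str] = {}
    root_mask: dict[str, np.ndarray] = {}
    root_rates: dict[str, np.ndarray] = {}
    arch_by_gene = {rg.gene_id: rg.architecture for rg in config.root_genes}
    conserve = {rg.gene_id: rg.conserve_motifs for rg in config.root_genes}
    no_mask = np.zeros_like(master_mask)

    if config.root_family_tree:
        ftree = TreeNode.read(StringIO(config.root_family_tree))
        node_seq = {id(ftree): master}
        for n in ftree.preorder(include_self=False):
            parent_seq = node_seq[id(n.parent)]
            # motif conservation is family-specific purifying selection: a
            # terminal branch to a non-conserving family evolves unmasked
            mask = master_mask
            if n.is_tip() and not conserve.get(n.name, True):
                mask = no_mask
            node_seq[id(n)] = evolve_sequence(
                parent_seq, n.length or 0.0, rng, mask, master_rates
            )
        for tip in ftree.tips():
            gid = tip.name
            if gid not in arch_by_gene:
                raise ValueError(f"family-tree leaf {gid!r} is not a root gene")
            src_mask = master_mask if conserve.get(gid, True) else no_mask
            root_seq[gid], root_mask[gid], root_rates[gid] = _excise(
                node_seq[id(tip)], src_mask, master_rates, spans, arch_by_gene[gid]
            )
    for g in sorted(history.root_state, key=lambda x: x.gene_id):
        if g.gene_id in root_seq:
            continue
        arch = arch_by_gene.get(g.gene_id, ())
        if arch:
            src_mask = master_mask if conserve.get(g.gene_id, True) else no_mask
            seq, mask, rates = _excise(
                evolve_sequence(master, 0.1, rng, master_mask, master_rates),
                src_mask, master_rates, spans, arch,
            )
            root_seq[g.gene_id] = seq
            root_mask[g.gene_id] = mask
            root_rates[g.gene_id] = rates
        else:
            length = next(
                (rg.length for rg in config.root_genes if rg.gene_id == g.gene_id),
                config.neighbor_length_aa,
            )
            root_seq[g.gene_id] = random_protein(length, rng)
            root_mask[g.gene_id] = np.zeros(length, dtype=bool)
            root_rates[g.gene_id] = np.ones(length)

    # --- walk the tree, evolving in segments between events -----------------
    node_seqs = {tree.name: dict(root_seq)}
    node_masks = {tree.name: dict(root_mask)}
    node_rates = {tree.name: dict(root_rates)}
    genomes: dict[str, Genome] = {}

    for node in tree.preorder(include_self=False):
        branch = node.name
        blen = node.length or 0.0
        seqs = dict(node_seqs[node.parent.name])
        masks = dict(node_masks[node.parent.name])
        rates = dict(node_rates[node.parent.name])
        t_prev = 0.0
        for ev in history.branch_events(branch):
            dt = max(0.0, (ev.time - t_prev)) * blen
            if dt > 0:
                for gid in sorted(seqs):
                    seqs[gid] = evolve_sequence(seqs[gid], dt, rng, masks[gid], rates[gid])
            t_prev = ev.time
            d = ev.details
            if ev.event_type == "wgd":
                new_s, new_m, new_r = {}, {}, {}
                for gid in sorted(seqs):
                    ia, ib = d["gene_map"][gid]
                    new_s[ia] = new_s[ib] = seqs[gid]
                    new_m[ia] = new_m[ib] = masks[gid]
                    new_r[ia] = new_r[ib] = rates[gid]
                seqs, masks, rates = new_s, new_m, new_r
            elif ev.event_type == "tandem_dup":
                seqs[d["copy"]] = seqs[d["source"]]
                masks[d["copy"]] = masks[d["source"]]
                rates[d["copy"]] = rates[d["source"]]
            elif ev.event_type == "loss":
                del seqs[d["gene"]]
                del masks[d["gene"]]
                del rates[d["gene"]]
            elif ev.event_type == "rename":
                for old in sorted(d["map"]):
                    new_id, _ = d["map"][old]
                    seqs[new_id] = seqs.pop(old)
                    masks[new_id] = masks.pop(old)
                    rates[new_id] = rates.pop(old)
            # transloc/fusion do not touch sequences
        dt = (1.0 - t_prev) * blen
        if dt > 0:
            for gid in sorted(seqs):
                seqs[gid] = evolve_sequence(seqs[gid], dt, rng, masks[gid], rates[gid])
        node_seqs[branch] = seqs
        node_masks[branch] = masks
        node_rates[branch] = rates
        if node.is_tip():
            state = history.node_states[branch]
            loci = [g.locus(branch) for g in state]
            genomes[branch] = Genome(
                branch,
                loci,
                {g.gene_id: seqs[g.gene_id] for g in state},
                families={g.gene_id: g.family for g in state},
                subfamilies={g.gene_id: g.subfamily for g in state},
            )
    return genomes


# ---------------------------------------------------------------------------
# emit / read back
# ---------------------------------------------------------------------------


def emit(genomes: dict, history: EventHistory, outdir) -> None:
    """Write per-species FASTA + GFF3 and the truth tables (TSV + JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp in sorted(genomes):
        g = genomes[sp]
        loci = sorted(g.loci, key=lambda l: (l.chromosome, l.start, l.gene_id))
        write_fasta({l.gene_id: g.sequences[l.gene_id] for l in loci}, outdir / f"{sp}.faa")
        attrs = {
            l.gene_id: {
                "gene_family": g.families.get(l.gene_id, ""),
                "subfamily": g.subfamilies.get(l.gene_id, ""),
            }
            for l in loci
        }
        write_gff3(loci, outdir / f"{sp}.gff3", attrs)
    with open(outdir / "truth_genes.tsv", "w") as fh:
        fh.write("species\tgene_id\tfamily\tsubfamily\tchromosome\tstart\tend\tstrand\torigin\n")
        for sp in sorted(genomes):
            for g in sorted(history.node_states[sp], key=lambda x: x.gene_id):
                fh.write(
                    f"{sp}\t{g.gene_id}\t{g.family}\t{g.subfamily}\t{g.chromosome}\t"
                    f"{g.start}\t{g.end}\t{g.strand}\t{g.origin}\n"
                )
    with open(outdir / "truth_events.tsv", "w") as fh:
        fh.write("index\tevent_type\tbranch\ttime\tgenes\tdetails\n")
        for i, ev in enumerate(history.events):
            fh.write(
                f"{i}\t{ev.event_type}\t{ev.branch}\t{ev.time:.6f}\t"
                f"{','.join(ev.genes)}\t{json.dumps(ev.details, sort_keys=True)}\n"
            )
    with open(outdir / "ancestral_counts.tsv", "w") as fh:
        fh.write("node\tsubfamily\tfamily\tcount\n")
        for (node, sub), k in sorted(history.ancestral_counts.items()):
            fh.write(f"{node}\t{sub}\t{history.subfamily_family.get(sub, sub)}\t{k}\n")
    with open(outdir / "history.json", "w") as fh:
        json.dump(
            {
                "species_tree": history.species_tree,
                "events": [e.to_json() for e in history.events],
                "ancestral_counts": {
                    f"{n}|{s}": k for (n, s), k in sorted(history.ancestral_counts.items())
                },
            },
            fh,
            indent=1,
            sort_keys=True,
        )


def read_genomes(outdir) -> dict:
    """Parse an :func:`emit` directory back into Genome objects (round trip)."""
    outdir = Path(outdir)
    genomes = {}
    for faa in sorted(outdir.glob("*.faa")):
        sp = faa.stem
        seqs = read_fasta(faa)
        loci, attrs = read_gff3_with_attrs(outdir / f"{sp}.gff3", species=sp)
        genomes[sp] = Genome(
            sp,
            loci,
            seqs,
            families={g: a.get("gene_family", "") for g, a in attrs.items()},
            subfamilies={g: a.get("subfamily", "") for g, a in attrs.items()},
        )
    return genomes


# ---------------------------------------------------------------------------
# Planted layout fixtures (chromosome maps, not tree-evolved)
# ---------------------------------------------------------------------------


@dataclass
class LayoutTruth:
    reference: str
    anchors: dict  # anchor set name -> list of reference gene ids
    families: dict  # species -> gene_id -> family
    ancestral_chromosome: dict  # species -> gene_id -> reference chromosome
    half_widths: dict


def layout_genomes(layout: dict, seed: int = 0):
    """Instantiate a planted chromosome-layout fixture.

    ``layout`` maps each species to chromosomes holding ordered gene entries
    ``[family, ancestral_reference_chromosome]`` (a bare family string means
    "its own chromosome", used for the reference genome). Sequences are drawn
    hierarchically - family consensus, then a sub-consensus per ancestral
    reference chromosome (paralogue divergence), then the species copy - so
    reciprocal-best-hit mapping recovers the planted orthology.
    """
    rng = np.random.default_rng([seed, 0xF16])
    spacing = layout.get("gene_spacing_bp", 400_000)
    glen = layout.get("gene_length_bp", 10_000)
    length_aa = layout.get("family_length_aa", 150)
    d_para = layout.get("paralog_divergence", 0.35)
    d_sp = layout.get("species_divergence", 0.08)

    species_maps = layout["species"]
    fam_names = sorted(
        {
            (e if isinstance(e, str) else e[0])
            for chroms in species_maps.values()
            for entries in chroms.values()
            for e in entries
        }
    )
    fam_consensus = {f: random_protein(length_aa, rng) for f in fam_names}
    sub_consensus: dict = {}

    def sub_seq(family: str, anc_chrom: str) -> str:
        key = (family, anc_chrom)
        if key not in sub_consensus:
            sub_consensus[key] = evolve_sequence(fam_consensus[family], d_para, rng)
        return sub_consensus[key]

    # materialize sub-consensus in deterministic order
    for sp in sorted(species_maps):
        for chrom in sorted(species_maps[sp]):
            for e in species_maps[sp][chrom]:
                fam, anc = (e, chrom) if isinstance(e, str) else (e[0], e[1])
                sub_seq(fam, anc)

    genomes, families, ancestral = {}, {}, {}
    for sp in sorted(species_maps):
        loci, seqs, fam_map, anc_map = [], {}, {}, {}
        counters: Counter = Counter()
        for chrom in sorted(species_maps[sp]):
            for slot, e in enumerate(species_maps[sp][chrom]):
                fam, anc = (e, chrom) if isinstance(e, str) else (e[0], e[1])
                counters[fam] += 1
                gid = fam if counters[fam] == 1 else f"{fam}.{counters[fam]}"
                start = (slot + 1) * spacing
                loci.append(GeneLocus(gid, sp, chrom, start, start + glen))
                seqs[gid] = evolve_sequence(sub_seq(fam, anc), d_sp, rng)
                fam_map[gid] = fam
                anc_map[gid] = anc
        genomes[sp] = Genome(sp, loci, seqs, families=fam_map, subfamilies=dict(fam_map))
        families[sp] = fam_map
        ancestral[sp] = anc_map
    truth = LayoutTruth(
        reference=layout["reference"],
        anchors={k: list(v) for k, v in layout.get("anchors", {}).items()},
        families=families,
        ancestral_chromosome=ancestral,
        half_widths=layout.get("half_widths", {}),
    )
    return genomes, truth


def load_scenario(path):
    """Load a scenario YAML; returns ("sim", SimConfig) or ("layout", dict)."""
    raw = load_yaml(path)
    if raw.get("kind") == "layout":
        return "layout", raw
    return "sim", SimConfig.from_yaml(path)
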