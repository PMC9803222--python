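"""Conserved-synteny engine: windows around anchor genes, neighbor-family
selection, cross-species ortholog mapping, paralogon assembly and
rearrangement reporting.

A paralogon is a set of related chromosome segments within one genome
descending from a single pre-WGD region (classically a quartet after two
rounds). The detection logic mirrors the comparative protocol: take windows
around the anchor genes in a reference genome (5 Mb half-width for the
A-side analysis, 10 Mb for the B-side), keep gene families with members in
windows on every anchor-bearing chromosome, then map those members into
other genomes by reciprocal best hits and group them into blocks per target
chromosome, assigning each block to a reference chromosome by majority of
its orthologs' origins (ties flagged, never resolved silently).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from .homology import reciprocal_best_hits
from .io_formats import GeneLocus
from .synthgenome import Genome


@dataclass
class SyntenyWindow:
    anchor_id: str
    chromosome: str
    start: int  # bp, 0-based half-open
    end: int
    members: list  # loci overlapping the interval, sorted by start

    def __post_init__(self):
        self.members = sorted(self.members, key=lambda l: (l.start, l.gene_id))
        if not any(l.gene_id == a for l in self.members for a in self.anchor_id.split("+")):
            raise ValueError(f"window does not contain its anchor {self.anchor_id}")


@dataclass
class NeighborFamily:
    family_id: str
    members_by_chromosome: dict  # chromosome -> list of loci
    qualifies: bool


@dataclass
class Paralogon:
    genome: str
    chromosomes: list
    genes_by_chromosome: dict  # chromosome -> list of qualifying-family loci
    wgd_rounds: tuple = ()
    quartet_families: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.chromosomes) < 2:
            raise ValueError("a paralogon needs at least 2 chromosomes")


def extract_window(loci, anchor_id: str, half_width: int) -> SyntenyWindow:
    """Window [anchor.start - W, anchor.end + W) clipped at 0; loci overlap
    by interval intersection (half-open), gene not midpoint."""
    anchor = next((l for l in loci if l.gene_id == anchor_id), None)
    if anchor is None:
        raise ValueError(f"unknown anchor {anchor_id!r}")
    start = max(0, anchor.start - half_width)
    end = anchor.end + half_width
    members = [
        l for l in loci if l.chromosome == anchor.chromosome and l.overlaps(start, end)
    ]
    return SyntenyWindow(anchor_id, anchor.chromosome, start, end, members)


def merge_windows(windows) -> SyntenyWindow:
    """Union of overlapping/adjacent windows on one chromosome (the case of
    two anchors so close that their windows overlap)."""
    if not windows:
        raise ValueError("no windows to merge")
    chroms = {w.chromosome for w in windows}
    if len(chroms) > 1:
        raise ValueError(f"windows on different chromosomes: {sorted(chroms)}")
    ws = sorted(windows, key=lambda w: w.start)
    for prev, nxt in zip(ws, ws[1:]):
        if nxt.start > prev.end:
            raise ValueError(
                f"windows disjoint with a gap ({prev.end} < {nxt.start}); not merging"
            )
    seen = {}
    for w in ws:
        for l in w.members:
            seen[l.gene_id] = l
    return SyntenyWindow(
        "+".join(w.anchor_id for w in ws),
        ws[0].chromosome,
        ws[0].start,
        max(w.end for w in ws),
        list(seen.values()),
    )


def anchor_windows(loci, anchor_ids, half_width: int) -> dict:
    """One (possibly merged) window per anchor-bearing chromosome."""
    by_chrom: dict[str, list] = {}
    for a in sorted(anchor_ids):
        w = extract_window(loci, a, half_width)
        by_chrom.setdefault(w.chromosome, []).append(w)
    return {c: merge_windows(ws) if len(ws) > 1 else ws[0] for c, ws in by_chrom.items()}


def select_neighbor_families(loci, anchor_ids, families: dict,
                             half_width: int):
    """Families with >= 1 member inside a window on EVERY anchor-bearing
    chromosome of the focal genome (the selection criterion of the emulated
    protocol). Only qualifying families are returned."""
    windows = anchor_windows(loci, anchor_ids, half_width)
    chroms = sorted(windows)
    if len(chroms) < 2:
        warnings.warn(
            "anchors on a single chromosome: the all-chromosomes criterion degenerates",
            stacklevel=2,
        )
    members: dict[str, dict] = {}
    anchor_set = set(anchor_ids)
    for c, w in windows.items():
        for l in w.members:
            if l.gene_id in anchor_set:
                continue
            fam = families.get(l.gene_id)
            if fam is None:
                continue
            members.setdefault(fam, {}).setdefault(c, []).append(l)
    out = []
    for fam in sorted(members):
        by_chrom = members[fam]
        if set(by_chrom) == set(chroms):
            out.append(NeighborFamily(fam, by_chrom, True))
    return out


@dataclass
class OrthologMap:
    pairs: dict  # gene id in A -> gene id in B
    unpaired_a: list
    unpaired_b: list
    ties: dict


def map_orthologs(genome_a: Genome, genome_b: Genome) -> OrthologMap:
    """Reciprocal-best-hit ortholog pairs between two genomes; unpaired
    genes are reported, mirroring the follow-up searches for missing genes."""
    mapping, ties = reciprocal_best_hits(genome_a.sequences, genome_b.sequences)
    pairs = {a: b for a, b in mapping.items() if b is not None}
    paired_b = set(pairs.values())
    return OrthologMap(
        pairs,
        sorted(a for a, b in mapping.items() if b is None),
        sorted(b for b in genome_b.sequences if b not in paired_b),
        ties,
    )


@dataclass
class SyntenyBlock:
    chromosome: str  # target-genome chromosome
    assigned_reference: str | None
    tie: bool
    votes: dict  # reference chromosome -> count
    genes: list  # (target gene id, reference gene id) pairs


def assemble_paralogon(reference: Genome, anchor_ids, families: dict,
                       half_width: int, others: dict | None = None,
                       ortholog_maps: dict | None = None,
                       wgd_rounds=()):
    """Build the reference paralogon and per-genome block tables.

    The reference paralogon consists of the anchor-bearing chromosomes plus
    all qualifying-family members in their windows. Each other genome's
    orthologs of those members are grouped by chromosome into blocks; a
    block is assigned to the reference chromosome contributing the majority
    (> 50%) of its orthologs, ties are flagged. A family whose members cover
    four reference-assigned blocks (or reference chromosomes) is reported as
    a quartet.
    """
    qualifying = select_neighbor_families(
        reference.loci, anchor_ids, families, half_width
    )
    fam_ids = {f.family_id for f in qualifying}
    # paralogon members: the anchors plus ALL reference copies of qualifying
    # families - the extra paralogs outside the anchor windows are what
    # reveal segments that lost their anchor gene (the quartet's 4th member)
    sel = [
        l for l in reference.loci
        if l.gene_id in set(anchor_ids) or families.get(l.gene_id) in fam_ids
    ]
    genes_by_chrom: dict[str, list] = {}
    ref_chrom_of: dict[str, str] = {}
    for l in sorted(sel, key=lambda x: (x.chromosome, x.start)):
        genes_by_chrom.setdefault(l.chromosome, []).append(l)
        ref_chrom_of[l.gene_id] = l.chromosome

    block_tables: dict[str, list] = {}
    fam_coverage: dict[str, dict] = {}  # family -> genome -> set of assigned refs
    for fam in fam_ids:
        fam_coverage[fam] = {
            reference.species: {
                c for c, ls in genes_by_chrom.items()
                if any(families.get(l.gene_id) == fam for l in ls)
            }
        }
    for name in sorted(others or {}):
        other = others[name]
        omap = ortholog_maps[name]
        target_loci = {l.gene_id: l for l in other.loci}
        by_target_chrom: dict[str, list] = {}
        for ref_gene, tgt_gene in sorted(omap.pairs.items()):
            if ref_gene not in ref_chrom_of or tgt_gene not in target_loci:
                continue
            by_target_chrom.setdefault(target_loci[tgt_gene].chromosome, []).append(
                (tgt_gene, ref_gene)
            )
        blocks = []
        for chrom in sorted(by_target_chrom):
            genes = by_target_chrom[chrom]
            votes = Counter(ref_chrom_of[rg] for _, rg in genes)
            top = votes.most_common()
            total = sum(votes.values())
            best, best_n = top[0]
            tie = len(top) > 1 and top[1][1] == best_n
            assigned = None if tie else (best if best_n * 2 > total else None)
            if assigned is None and not tie and best_n * 2 == total:
                tie = True
            blocks.append(SyntenyBlock(chrom, assigned, tie, dict(votes), genes))
        block_tables[name] = blocks
        for fam in fam_ids:
            cov = set()
            for b in blocks:
                if b.assigned_reference is None:
                    continue
                for tgt_gene, ref_gene in b.genes:
                    if families.get(ref_gene) == fam:
                        cov.add(b.assigned_reference)
            fam_coverage[fam][name] = cov
    quartets = sorted(
        fam for fam, per_genome in fam_coverage.items()
        if any(len(cov) >= 4 for cov in per_genome.values())
    )
    par = Paralogon(
        reference.species,
        sorted(genes_by_chrom),
        genes_by_chrom,
        tuple(wgd_rounds),
        quartets,
    )
    return par, block_tables, fam_coverage


def dispersal_count(reference: Genome, ref_chromosome: str, member_ids,
                    target: Genome, omap: OrthologMap):
    """How many target chromosomes carry orthologs of one reference
    chromosome's paralogon members (1 = fully syntenic)."""
    target_loci = {l.gene_id: l for l in target.loci}
    table = {}
    for g in sorted(member_ids):
        t = omap.pairs.get(g)
        if t is not None and t in target_loci:
            table[g] = target_loci[t].chromosome
    if not table:
        raise ValueError(
            f"no orthologs mapped for members of {ref_chromosome} in {target.species}"
        )
    return len(set(table.values())), table
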