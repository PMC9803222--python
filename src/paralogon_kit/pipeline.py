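"""End-to-end orchestration of the analysis stages on scenario data.

Each stage is a plain function from in-memory state to in-memory state; the
command-line interface wraps them with file I/O so any stage can be swapped
for an external tool's output. All randomness flows from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from . import domains as dm
from . import homology as hm
from . import msa_trim as mt
from . import phylo as ph
from . import repertoire as rp
from . import synteny as sy
from . import synthgenome as sg
from .io_formats import SupportedTree, stage_timer, write_fasta, write_newick


def scenario_path(name: str) -> Path:
    """Path of a packaged scenario file (e.g. ``fig8_metazoa``)."""
    return Path(resources.files("paralogon_kit") / "scenarios" / f"{name}.yaml")


@dataclass
class PipelineState:
    config: sg.SimConfig
    history: sg.EventHistory | None = None
    genomes: dict = field(default_factory=dict)
    labels_all: dict = field(default_factory=dict)  # sp -> gene -> family
    labels_cng: dict = field(default_factory=dict)  # sp -> gene -> family|rejected
    cluster_reps: dict = field(default_factory=dict)
    architectures: dict = field(default_factory=dict)  # sp -> gene -> Architecture
    cooccurrence: tuple | None = None
    alignments: dict = field(default_factory=dict)  # family -> Alignment
    trees: dict = field(default_factory=dict)  # family -> SupportedTree
    rooted_trees: dict = field(default_factory=dict)
    clade_calls: list = field(default_factory=list)
    assignment: dict = field(default_factory=dict)  # leaf -> subfamily
    recons: dict = field(default_factory=dict)
    verdicts: dict = field(default_factory=dict)
    synteny: dict = field(default_factory=dict)
    paralogons: dict = field(default_factory=dict)
    counts: rp.CountTable | None = None
    duplication_calls: list = field(default_factory=list)

    @property
    def p(self) -> dict:
        return self.config.pipeline


def simulate_stage(cfg: sg.SimConfig, seed: int | None = None,
                   outdir=None) -> PipelineState:
    if seed is not None:
        cfg.seed = seed
    with stage_timer("simulate"):
        history = sg.simulate_history(cfg)
        genomes = sg.evolve_sequences(history, cfg)
        if outdir:
            sg.emit(genomes, history, outdir)
    return PipelineState(cfg, history, genomes)


def classify_stage(state: PipelineState,
                   thresholds: hm.Thresholds | None = None) -> PipelineState:
    """Family assignment by best hit against the labelled reference
    proteome, with the top-k screen for the target families, plus identity
    clustering where the protocol applies it."""
    th = thresholds or hm.Thresholds()
    p = state.p
    ref_sp = p["classification_reference"]
    ref = state.genomes[ref_sp]
    targets = set(p["target_families"])
    with stage_timer("classify"):
        for sp in sorted(state.genomes):
            g = state.genomes[sp]
            if sp == ref_sp:
                state.labels_all[sp] = dict(g.families)
                state.labels_cng[sp] = {
                    gid: fam for gid, fam in g.families.items() if fam in targets
                }
                continue
            scores = hm.score_matrix(g.sequences, ref.sequences)
            state.labels_all[sp] = hm.classify_by_reference(
                g.sequences, ref.sequences, ref.families,
                target_families=set(ref.families.values()),
                thresholds=th, screen=False, scores=scores,
            )
            screen_on = p.get("screen", True)
            screen_species = p.get("screen_species")
            if screen_species is not None:
                screen_on = screen_on and sp in screen_species
            state.labels_cng[sp] = hm.classify_by_reference(
                g.sequences, ref.sequences, ref.families,
                target_families=targets, thresholds=th, screen=screen_on,
                scores=scores,
            )
        # duplicate/isoform collapse where the emulated protocol ran it
        for sp in p.get("cluster_species", []):
            cands = {
                gid: state.genomes[sp].sequences[gid]
                for gid, lab in state.labels_cng[sp].items() if lab != hm.REJECTED
            }
            if cands:
                clusters = hm.cluster_identity(cands, th)
                state.cluster_reps[sp] = sorted(c["representative"] for c in clusters)
    return state


def domains_stage(state: PipelineState,
                  thresholds: hm.Thresholds | None = None) -> PipelineState:
    th = thresholds or hm.Thresholds()
    with stage_timer("domains"):
        models = dm.default_models(quantile=th.domain_quantile)
        arch_by_taxon = {}
        for sp in sorted(state.genomes):
            g = state.genomes[sp]
            archs = {}
            for gid in sorted(g.sequences):
                if state.labels_cng.get(sp, {}).get(gid, hm.REJECTED) == hm.REJECTED:
                    continue
                archs[gid] = dm.scan(g.sequences[gid], models)
            state.architectures[sp] = archs
            arch_by_taxon[sp] = list(archs.values())
        state.cooccurrence = dm.cooccurrence_check(arch_by_taxon)
    return state


def _cng_leaf_sequences(state: PipelineState) -> dict:
    """Leaves entering the tree: accepted target-family genes (cluster
    representatives where clustering ran) plus the outgroup family."""
    p = state.p
    out = {}
    for sp in sorted(state.genomes):
        g = state.genomes[sp]
        reps = state.cluster_reps.get(sp)
        for gid in sorted(g.sequences):
            lab_cng = state.labels_cng.get(sp, {}).get(gid, hm.REJECTED)
            lab_all = state.labels_all.get(sp, {}).get(gid)
            is_cng = lab_cng != hm.REJECTED
            if is_cng and reps is not None and gid not in reps:
                continue
            if is_cng or lab_all == p["outgroup_family"]:
                out[f"{sp}|{gid}"] = g.sequences[gid]
    return out


def _outgroup_leaves(state: PipelineState, rows) -> list:
    fam = state.p["outgroup_family"]
    return [
        leaf for leaf in rows
        if state.labels_all[leaf.split("|", 1)[0]].get(leaf.split("|", 1)[1]) == fam
    ]


def _ingroup_subtree(rooted: SupportedTree, outgroup):
    out_set = set(outgroup)
    return next(
        c for c in rooted.tree.children
        if not ({t.name for t in c.tips()} if not c.is_tip() else {c.name}) & out_set
    ).copy()


def _root_mode(state: PipelineState, fam: str) -> str:
    return state.p.get("family_root", {}).get(fam, "outgroup")


def family_sequences(state: PipelineState, fam: str) -> dict:
    """Members of one target family, plus the outgroup-family leaves when
    the family is rooted with the outgroup (families rooted by minimal
    reconciliation cost need no outgroup in the alignment)."""
    all_seqs = _cng_leaf_sequences(state)
    seqs = {
        leaf: s for leaf, s in all_seqs.items()
        if state.labels_cng[leaf.split("|", 1)[0]].get(leaf.split("|", 1)[1]) == fam
    }
    if len(seqs) < 3:
        return {}
    if _root_mode(state, fam) == "outgroup":
        for og in sorted(_outgroup_leaves(state, all_seqs)):
            sp, gid = og.split("|", 1)
            seqs[og] = state.genomes[sp].sequences[gid]
    return seqs


def build_family_alignment(state: PipelineState, fam: str,
                           th: hm.Thresholds) -> mt.Alignment | None:
    """Align one family (plus outgroup), trim to its motif anchors and
    apply the one-third-of-mean length filter."""
    seqs = family_sequences(state, fam)
    if not seqs:
        return None
    aln = mt.progressive_align(seqs)
    trim = state.p.get("family_trim", {}).get(fam) or state.p.get("trim")
    if trim:
        aln = mt.trim_to_anchors(aln, trim["reference"], trim["start"], trim["end"])
    retained, _removed = hm.length_filter(aln.rows, th.length_fraction)
    return mt.Alignment(retained, anchors=aln.anchors)


def build_family_tree(state: PipelineState, fam: str, aln: mt.Alignment,
                      th: hm.Thresholds, seed: int, n_boot: int | None):
    tree = ph.dual_support(aln, n_boot=n_boot, seed=seed, thresholds=th)
    if _root_mode(state, fam) == "min_cost":
        rooted = ph.root_by_reconciliation(tree, state.config.tree())
    else:
        rooted = ph.root_with_outgroup(tree, _outgroup_leaves(state, aln.rows))
    return tree, rooted


def _subfamily_refs(state: PipelineState, subfamilies, rows) -> dict:
    refs = {}
    for sub in subfamilies:
        ids = [
            f"{sp}|{gid}"
            for sp in state.p["reference_species"]
            for gid, s in state.genomes[sp].subfamilies.items()
            if s == sub and f"{sp}|{gid}" in rows
        ]
        if ids:
            refs[sub] = ids
    return refs


def tree_stage(state: PipelineState, thresholds: hm.Thresholds | None = None,
               seed: int = 0, n_boot: int | None = None) -> PipelineState:
    """Build the combined family tree plus one tree per target family
    (each family alignment trimmed with its own motif anchors, as in the
    emulated protocol), root with the outgroup, call subfamily clades and
    reconcile everything against the species tree."""
    th = thresholds or hm.Thresholds()
    p = state.p
    sp_tree = state.config.tree()
    marks = p.get("wgd_marks", {})

    fam_subs = p.get("family_subfamilies", {})
    all_subs = list(p.get("anchor_subfamilies_a", [])) + list(
        p.get("anchor_subfamilies_b", [])
    )
    state.clade_calls, state.assignment = [], {}
    for fam in p["target_families"]:
        with stage_timer(f"align+tree({fam})"):
            faln = build_family_alignment(state, fam, th)
            if faln is None:
                continue
            ftree, frooted = build_family_tree(state, fam, faln, th, seed, n_boot)
            state.alignments[fam] = faln
            state.trees[fam] = ftree
            state.rooted_trees[fam] = frooted
            outgroup = set(_outgroup_leaves(state, faln.rows))
            fingroup = (
                _ingroup_subtree(frooted, outgroup) if outgroup else frooted.tree
            )
            state.recons[fam] = ph.reconcile(fingroup, sp_tree)
            subs = fam_subs.get(fam, [s for s in all_subs if s.startswith(fam)])
            refs = _subfamily_refs(state, subs, faln.rows)
            if refs:
                calls, assignment = ph.assign_subfamilies(frooted, refs, th)
                state.clade_calls.extend(calls)
                for leaf, sub in assignment.items():
                    if sub != "unresolved" or leaf not in state.assignment:
                        state.assignment[leaf] = sub

    state.verdicts = {
        label: ph.wgd_timing_test(recon, marks)
        for label, recon in state.recons.items()
    }
    return state


def synteny_stage(state: PipelineState,
                  thresholds: hm.Thresholds | None = None) -> PipelineState:
    th = thresholds or hm.Thresholds()
    p = state.p
    ref_sp = p["synteny_reference"]
    ref = state.genomes[ref_sp]
    families = state.labels_all[ref_sp]
    with stage_timer("synteny"):
        # anchors are the reference genome's identified family members (the
        # protocol starts from the reference species' known CNG genes)
        def anchors_for(family):
            return sorted(
                gid for gid, lab in state.labels_cng.get(ref_sp, {}).items()
                if lab == family
            )

        anchors_a = anchors_for(p.get("anchor_family_a", p["target_families"][0]))
        anchors_b = (
            anchors_for(p.get("anchor_family_b", p["target_families"][1]))
            if len(p["target_families"]) > 1 or "anchor_family_b" in p
            else []
        )
        res: dict = {"anchors_a": anchors_a, "anchors_b": anchors_b}
        omaps = {}
        others = {}
        for other in p.get("synteny_others", []):
            if other == ref_sp:
                continue
            others[other] = state.genomes[other]
            omaps[other] = sy.map_orthologs(ref, state.genomes[other])
        rounds = tuple(r for rs in p.get("wgd_marks", {}).values() for r in rs)
        merged_chroms: dict[str, set] = {}
        merged_genes: dict[str, dict] = {}
        for side, anchors, width in (("a", anchors_a, th.window_a),
                                     ("b", anchors_b, th.window_b)):
            if not anchors:
                continue
            qual = sy.select_neighbor_families(ref.loci, anchors, families, width)
            par, blocks, coverage = sy.assemble_paralogon(
                ref, anchors, families, width, others, omaps, wgd_rounds=rounds,
            )
            res.update({
                f"qualifying_{side}": [f.family_id for f in qual],
                f"paralogon_{side}": par,
                f"blocks_{side}": blocks,
                f"coverage_{side}": coverage,
            })
            merged_chroms.setdefault(ref_sp, set()).update(par.chromosomes)
            merged_genes.setdefault(ref_sp, {}).update(
                {c: [l.gene_id for l in ls] for c, ls in par.genes_by_chromosome.items()}
            )
            for other, blocks_ in blocks.items():
                chroms = {b.chromosome for b in blocks_}
                merged_chroms.setdefault(other, set()).update(chroms)
                for b in blocks_:
                    merged_genes.setdefault(other, {}).setdefault(
                        b.chromosome, []
                    ).extend(t for t, _ in b.genes)
        for sp, chroms in merged_chroms.items():
            if len(chroms) >= 2:
                state.paralogons[sp] = sy.Paralogon(
                    sp, sorted(chroms), merged_genes.get(sp, {}), rounds
                )
        disp = p.get("dispersal")
        if disp and "paralogon_a" in res:
            chrom = disp["reference_chromosome"]
            members = [
                l.gene_id for l in res["paralogon_a"].genes_by_chromosome.get(chrom, [])
            ]
            n, table = sy.dispersal_count(
                ref, chrom, members, state.genomes[disp["target_species"]],
                omaps[disp["target_species"]],
            )
            res["dispersal_count"] = n
            res["dispersal_table"] = table
        res["ortholog_maps"] = omaps
        state.synteny = res
    return state


def repertoire_stage(state: PipelineState) -> PipelineState:
    with stage_timer("repertoire"):
        sp_tree = state.config.tree()
        state.counts = rp.ancestral_counts(state.recons, sp_tree)
        loci_by_species = {
            sp: {l.gene_id: l for l in g.loci} for sp, g in state.genomes.items()
        }
        state.duplication_calls = []
        for fam in sorted(state.recons):
            state.duplication_calls.extend(
                rp.classify_duplications(
                    state.recons[fam], loci_by_species, state.paralogons,
                    state.verdicts.get(fam, {}),
                )
            )
    return state


def run_all(scenario, seed: int = 0, outdir=None, n_boot: int | None = None,
            thresholds: hm.Thresholds | None = None) -> PipelineState:
    """Run the whole chain on a simulation scenario (path or SimConfig)."""
    cfg = scenario if isinstance(scenario, sg.SimConfig) else sg.SimConfig.from_yaml(scenario)
    state = simulate_stage(cfg, seed=seed,
                           outdir=Path(outdir) / "genomes" if outdir else None)
    classify_stage(state, thresholds)
    domains_stage(state, thresholds)
    tree_stage(state, thresholds, seed=seed, n_boot=n_boot)
    synteny_stage(state, thresholds)
    repertoire_stage(state)
    if outdir:
        write_artifacts(state, outdir)
    return state


def summary(state: PipelineState) -> dict:
    """The headline numbers a scenario run recovers."""
    p = state.p
    out: dict = {}
    nodes = p.get("nodes", {})
    fams = [f for f in p["target_families"] if state.counts is not None
            and f in state.counts.table.columns]
    if state.counts is not None:
        for label, node in sorted(nodes.items()):
            out[f"cng_count_{label}"] = sum(state.counts.count(node, f) for f in fams)
            for fam in fams:
                out[f"{fam.lower()}_count_{label}"] = state.counts.count(node, fam)
        for sp in state.counts.leaf_names:
            out[f"cng_count_{sp.lower()}"] = sum(state.counts.count(sp, f) for f in fams)
    marks = p.get("wgd_marks", {})
    stem = p.get("stem_branch") or (sorted(marks)[0] if marks else None)
    if stem and state.recons:
        out["pre_wgd_lineages_entering_" + stem.lower()] = sum(
            state.recons[f].lineages_entering(stem) for f in sorted(state.recons)
        )
    if state.synteny:
        if "qualifying_a" in state.synteny:
            out["qualifying_neighbor_families_a"] = len(state.synteny["qualifying_a"])
        if "qualifying_b" in state.synteny:
            out["qualifying_neighbor_families_b"] = len(state.synteny["qualifying_b"])
        if "paralogon_a" in state.synteny:
            out["paralogon_chromosomes"] = len(state.synteny["paralogon_a"].chromosomes)
        if "dispersal_count" in state.synteny:
            out["dispersal_count"] = state.synteny["dispersal_count"]
    if state.cooccurrence is not None:
        report, ok = state.cooccurrence
        out["clz_cooccurrence_violations"] = sum(
            1 for r in report.values() if r["violation"]
        )
    modes = [c.mode for c in state.duplication_calls]
    out["n_local_duplications"] = sum(1 for m in modes if m == "local")
    out["n_wgd_duplications"] = sum(1 for m in modes if m.startswith("wgd:"))
    return out


def write_artifacts(state: PipelineState, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "classify").mkdir(exist_ok=True)
    with open(outdir / "classify" / "labels.tsv", "w") as fh:
        fh.write("species\tgene_id\tfamily\tcng_label\n")
        for sp in sorted(state.labels_all):
            for gid in sorted(state.labels_all[sp]):
                fh.write(
                    f"{sp}\t{gid}\t{state.labels_all[sp][gid]}\t"
                    f"{state.labels_cng[sp].get(gid, hm.REJECTED)}\n"
                )
    if state.alignments:
        (outdir / "align").mkdir(exist_ok=True)
        for fam, aln in sorted(state.alignments.items()):
            write_fasta(aln.rows, outdir / "align" / f"{fam}_trimmed.fasta")
    if state.rooted_trees:
        (outdir / "tree").mkdir(exist_ok=True)
        for fam, st in sorted(state.rooted_trees.items()):
            write_newick(st, outdir / "tree" / f"{fam}_rooted.nwk")
        with open(outdir / "tree" / "subfamilies.tsv", "w") as fh:
            fh.write("leaf\tsubfamily\n")
            for leaf, sub in sorted(state.assignment.items()):
                fh.write(f"{leaf}\t{sub}\n")
    if state.counts is not None:
        (outdir / "repertoire").mkdir(exist_ok=True)
        state.counts.table.to_csv(outdir / "repertoire" / "counts.tsv", sep="\t")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary(state), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# planted layout analysis (chromosome-map fixtures)
# ---------------------------------------------------------------------------


def run_layout(scenario, seed: int = 0,
               thresholds: hm.Thresholds | None = None) -> dict:
    """Analyse a planted chromosome-layout fixture: neighbor-family
    selection on the reference, ortholog mapping, paralogon assembly,
    dispersal and quartet detection."""
    th = thresholds or hm.Thresholds()
    kind, raw = sg.load_scenario(scenario) if not isinstance(scenario, dict) else ("layout", scenario)
    if kind != "layout":
        raise ValueError("run_layout expects a layout scenario")
    genomes, truth = sg.layout_genomes(raw, seed=seed)
    ref = genomes[truth.reference]
    families = truth.families[truth.reference]
    res: dict = {"genomes": genomes, "truth": truth}
    omaps = {
        sp: sy.map_orthologs(ref, genomes[sp]) for sp in sorted(genomes)
        if sp != truth.reference
    }
    others = {sp: genomes[sp] for sp in omaps}
    for side, anchor_ids in sorted(truth.anchors.items()):
        width = truth.half_widths.get(side, th.window_a)
        qual = sy.select_neighbor_families(ref.loci, anchor_ids, families, width)
        res[f"qualifying_{side}"] = [f.family_id for f in qual]
        par, blocks, coverage = sy.assemble_paralogon(
            ref, anchor_ids, families, width, others, omaps
        )
        res[f"paralogon_{side}"] = par
        res[f"blocks_{side}"] = blocks
        res[f"coverage_{side}"] = coverage
    res["ortholog_maps"] = omaps
    return res
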