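import warnings

import pytest
from hypothesis import given, settings, strategies as st

from paralogon_kit import synteny as sy
from paralogon_kit.io_formats import GeneLocus
from paralogon_kit.synthgenome import Genome, random_protein


def mk_loci(spec):
    """spec: list of (gene_id, chrom, start, end)."""
    return [GeneLocus(g, "sp", c, s, e) for g, c, s, e in spec]


def test_zero_width_window_contains_only_overlapping_genes():
    loci = mk_loci(
        [("a", "c1", 100, 200), ("b", "c1", 150, 180), ("c", "c1", 300, 400)]
    )
    w = sy.extract_window(loci, "a", 0)
    assert [l.gene_id for l in w.members] == ["a", "b"]


def test_window_boundaries_are_half_open():
    # window is [900, 1200): a gene ending exactly at 900 or starting
    # exactly at 1200 is excluded, one starting at 1199 is included
    loci = mk_loci([("a", "c1", 1000, 1100), ("left", "c1", 800, 900),
                    ("touch", "c1", 1200, 1300), ("edge", "c1", 1199, 1250)])
    w = sy.extract_window(loci, "a", 100)
    assert [l.gene_id for l in w.members] == ["a", "edge"]


def test_planted_window_membership_counts():
    inside = [(f"i{k}", "c1", 5_000_000 + k * 300_000, 5_010_000 + k * 300_000)
              for k in range(11)]
    outside = [(f"o{k}", "c1", 15_000_000 + k * 1_000_000, 15_010_000 + k * 1_000_000)
               for k in range(3)]
    loci = mk_loci([("anchor", "c1", 5_000_000, 5_010_000)] + inside[1:] + outside)
    w = sy.extract_window(loci, "anchor", 5_000_000)
    assert len(w.members) == 11  # anchor + 10 planted neighbors
    assert not any(l.gene_id.startswith("o") for l in w.members)


def test_unknown_anchor_errors():
    with pytest.raises(ValueError, match="unknown anchor"):
        sy.extract_window(mk_loci([("a", "c1", 0, 10)]), "zz", 100)


@settings(derandomize=True, max_examples=25)
@given(
    w1=st.integers(0, 2_000_000),
    w2=st.integers(0, 2_000_000),
    starts=st.lists(st.integers(0, 8_000_000), min_size=1, max_size=15),
)
def test_window_membership_monotone_in_width(w1, w2, starts):
    if w1 > w2:
        w1, w2 = w2, w1
    loci = [GeneLocus("anchor", "sp", "c1", 4_000_000, 4_010_000)] + [
        GeneLocus(f"g{i}", "sp", "c1", s, s + 10_000) for i, s in enumerate(starts)
    ]
    small = {l.gene_id for l in sy.extract_window(loci, "anchor", w1).members}
    big = {l.gene_id for l in sy.extract_window(loci, "anchor", w2).members}
    assert small <= big


def test_merge_overlapping_windows_spans_both_anchors():
    loci = mk_loci(
        [("a1", "c1", 4_000_000, 4_010_000), ("a2", "c1", 6_000_000, 6_010_000),
         ("x", "c1", 1_000_000, 1_010_000), ("y", "c1", 9_000_000, 9_010_000)]
    )
    w1 = sy.extract_window(loci, "a1", 5_000_000)
    w2 = sy.extract_window(loci, "a2", 5_000_000)
    merged = sy.merge_windows([w1, w2])
    assert merged.start == 0 and merged.end == 11_010_000
    ids = [l.gene_id for l in merged.members]
    assert ids == sorted(set(ids), key=lambda g: [l.start for l in loci if l.gene_id == g][0])
    assert len(ids) == len(set(ids))
    assert sy.merge_windows([w1, w1]).members == w1.members


def test_merge_rejects_disjoint_windows_and_mixed_chromosomes():
    loci = mk_loci([("a", "c1", 0, 10), ("b", "c1", 10_000, 10_010),
                    ("c", "c2", 0, 10)])
    wa = sy.extract_window(loci, "a", 100)
    wb = sy.extract_window(loci, "b", 100)
    wc = sy.extract_window(loci, "c", 100)
    with pytest.raises(ValueError, match="disjoint"):
        sy.merge_windows([wa, wb])
    with pytest.raises(ValueError, match="chromosomes"):
        sy.merge_windows([wa, wc])


def _three_chrom_setup():
    loci = []
    fams = {}
    for chrom in ("c1", "c2", "c3"):
        loci.append(GeneLocus(f"A_{chrom}", "sp", chrom, 4_000_000, 4_010_000))
        fams[f"A_{chrom}"] = "CNGA"
    for chrom in ("c1", "c2", "c3"):  # qualifies: all three chromosomes
        loci.append(GeneLocus(f"q_{chrom}", "sp", chrom, 4_500_000, 4_510_000))
        fams[f"q_{chrom}"] = "QF"
    for chrom in ("c1", "c2"):  # only two of three
        loci.append(GeneLocus(f"p_{chrom}", "sp", chrom, 3_500_000, 3_510_000))
        fams[f"p_{chrom}"] = "PF"
    anchors = ["A_c1", "A_c2", "A_c3"]
    return loci, fams, anchors


def test_select_neighbor_families_requires_every_anchor_chromosome():
    loci, fams, anchors = _three_chrom_setup()
    out = sy.select_neighbor_families(loci, anchors, fams, 5_000_000)
    assert [f.family_id for f in out] == ["QF"]
    assert out[0].qualifies


def test_select_neighbor_families_order_invariant():
    loci, fams, anchors = _three_chrom_setup()
    out1 = sy.select_neighbor_families(loci, anchors, fams, 5_000_000)
    out2 = sy.select_neighbor_families(list(reversed(loci)), anchors, fams, 5_000_000)
    assert [f.family_id for f in out1] == [f.family_id for f in out2]


def test_single_anchor_chromosome_warns():
    loci = mk_loci([("a", "c1", 0, 10), ("n", "c1", 20, 30)])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sy.select_neighbor_families(loci, ["a"], {"n": "F"}, 1000)
    assert any("single chromosome" in str(w.message) for w in caught)


def _toy_genome(name, rng, n=6):
    loci, seqs = [], {}
    for i in range(n):
        gid = f"g{i}"
        loci.append(GeneLocus(gid, name, "c1", i * 100_000, i * 100_000 + 10_000))
        seqs[gid] = random_protein(80, rng)
    return Genome(name, loci, seqs)


def test_map_orthologs_identical_genomes_is_perfect(rng):
    a = _toy_genome("A", rng)
    b = Genome("B", [GeneLocus(l.gene_id, "B", l.chromosome, l.start, l.end)
                     for l in a.loci], dict(a.sequences))
    omap = sy.map_orthologs(a, b)
    assert omap.pairs == {g: g for g in a.sequences}
    assert omap.unpaired_a == [] and omap.unpaired_b == []


def test_map_orthologs_reports_missing_genes(rng):
    a = _toy_genome("A", rng)
    b_loci = [l for l in a.loci if l.gene_id != "g3"]
    b = Genome("B", [GeneLocus(l.gene_id, "B", l.chromosome, l.start, l.end)
                     for l in b_loci],
               {l.gene_id: a.sequences[l.gene_id] for l in b_loci})
    omap = sy.map_orthologs(a, b)
    assert "g3" in omap.unpaired_a


def test_fig6_qualifying_family_counts(fig6_results):
    """Seven families qualify around the CNGA anchors, ten around CNGB."""
    assert sorted(fig6_results["qualifying_A"]) == [
        "BMX", "F1", "F2", "F3", "F4", "F5", "F6"
    ]
    assert len(fig6_results["qualifying_B"]) == 10


def test_fig6_paralogon_is_a_chromosome_quartet(fig6_results):
    par = fig6_results["paralogon_A"]
    assert sorted(par.chromosomes) == ["LG17", "LG2", "LG4", "LG7"]


def test_fig6_human_disperses_one_chromosome_over_four(fig6_results):
    from paralogon_kit import synteny as sy_

    par = fig6_results["paralogon_A"]
    ref = fig6_results["genomes"]["spotted_gar"]
    members = [l.gene_id for l in par.genes_by_chromosome["LG17"]]
    n, table = sy_.dispersal_count(
        ref, "LG17", members, fig6_results["genomes"]["human"],
        fig6_results["ortholog_maps"]["human"],
    )
    assert n == 4
    assert set(table.values()) == {"chr2", "chr11", "chr13", "chr15"}


def test_fig6_quartet_family_found_in_human_and_zebrafish_only(fig6_results):
    assert fig6_results["paralogon_A"].quartet_families == ["BMX"]
    cov = fig6_results["coverage_A"]["BMX"]
    assert len(cov["human"]) == 4 and len(cov["zebrafish"]) == 4
    assert len(cov["chicken"]) == 3


def test_fig6_chicken_fusion_block_assigned_by_majority(fig6_results):
    blocks = {b.chromosome: b for b in fig6_results["blocks_A"]["chicken"]}
    assert blocks["chr4"].assigned_reference == "LG7"
    assert blocks["chr4"].tie is False


def test_reference_against_itself_reproduces_its_chromosomes(fig6_results, rng):
    ref = fig6_results["genomes"]["spotted_gar"]
    truth = fig6_results["truth"]
    clone = Genome("clone", [GeneLocus(l.gene_id, "clone", l.chromosome, l.start, l.end)
                             for l in ref.loci], dict(ref.sequences))
    omap = sy.map_orthologs(ref, clone)
    par, blocks, _ = sy.assemble_paralogon(
        ref, truth.anchors["A"], truth.families["spotted_gar"], 5_000_000,
        {"clone": clone}, {"clone": omap},
    )
    for b in blocks["clone"]:
        assert b.assigned_reference == b.chromosome
        assert not b.tie


def test_dispersal_count_set_semantics(fig6_results):
    ref = fig6_results["genomes"]["spotted_gar"]
    omap = fig6_results["ortholog_maps"]["human"]
    par = fig6_results["paralogon_A"]
    members = [l.gene_id for l in par.genes_by_chromosome["LG2"]]
    n, table = sy.dispersal_count(ref, "LG2", members,
                                  fig6_results["genomes"]["human"], omap)
    assert n == 1  # fully syntenic block
    # adding another member mapping to an already-counted chromosome
    n2, _ = sy.dispersal_count(ref, "LG2", members + members[:1],
                               fig6_results["genomes"]["human"], omap)
    assert n2 == n


def test_dispersal_with_no_mapped_orthologs_errors(fig6_results):
    ref = fig6_results["genomes"]["spotted_gar"]
    with pytest.raises(ValueError, match="no orthologs"):
        sy.dispersal_count(ref, "LGX", ["not_a_gene"],
                           fig6_results["genomes"]["human"],
                           fig6_results["ortholog_maps"]["human"])
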