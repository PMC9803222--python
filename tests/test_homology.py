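import numpy as np
import pytest

from paralogon_kit import homology as hm
from paralogon_kit.synthgenome import random_protein

# documented toy scoring for the brute-force oracle: BLOSUM62, affine gaps,
# open -11 (first gap residue), extend -1 — the same parameters align_pair uses
GAP_OPEN, GAP_EXT = 11.0, 1.0


def _blosum():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def smith_waterman_score(a: str, b: str) -> float:
    """Exhaustive affine-gap local DP, independent of Biopython."""
    B = _blosum()
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i, j] = max(M[i - 1, j] - GAP_OPEN, Ix[i - 1, j] - GAP_EXT)
            Iy[i, j] = max(M[i, j - 1] - GAP_OPEN, Iy[i, j - 1] - GAP_EXT)
            sub = B[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0, sub + max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]))
            best = max(best, M[i, j])
    return best


def test_self_alignment_is_fully_identical():
    hit = hm.align_pair("MKTAYIAKQR", "MKTAYIAKQR")
    assert hit.identity == 100.0
    assert hit.aln_len == 10
    assert hit.score == sum(_blosum()[c, c] for c in "MKTAYIAKQR")


def test_local_score_matches_bruteforce_dp_oracle(rng):
    pairs = [("HEAGAWGHEE", "PAWHEAE")]
    for _ in range(10):
        pairs.append((random_protein(25, rng), random_protein(18, rng)))
    for a, b in pairs:
        hit = hm.align_pair(a, b, mode="local")
        assert hit.score == pytest.approx(smith_waterman_score(a, b)), (a, b)


def test_global_alignment_length_at_least_longest_input():
    hit = hm.align_pair("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", "MKT", mode="global")
    assert hit.aln_len >= 33


def test_illegal_character_error_names_position():
    with pytest.raises(ValueError, match="position 3"):
        hm.align_pair("MKT1AY", "MKTAY")


def test_rbh_maps_identical_sequences():
    mapping, ties = hm.reciprocal_best_hits(
        {"q": "MKTAYIAKQRQISFVK"}, {"r": "MKTAYIAKQRQISFVK"}
    )
    assert mapping == {"q": "r"}
    assert ties == {"q": False}


def test_rbh_tie_breaks_lexicographically_and_flags():
    seq = "MKTAYIAKQRQISFVK"
    mapping, ties = hm.reciprocal_best_hits({"q": seq}, {"rB": seq, "rA": seq})
    assert mapping["q"] == "rA"
    assert ties["q"] is True


def test_rbh_is_injective_partial_matching(rng):
    queries = {f"q{i}": random_protein(60, rng) for i in range(12)}
    refs = {f"r{i}": random_protein(60, rng) for i in range(8)}
    mapping, _ = hm.reciprocal_best_hits(queries, refs)
    matched = [r for r in mapping.values() if r is not None]
    assert len(matched) == len(set(matched))


def test_rbh_recovers_planted_orthologs(fig8_state):
    """Reciprocal best hits against the reference genome pair >= 95% of
    orthologs correctly (gene identities are preserved by the simulator)."""
    omap = fig8_state.synteny["ortholog_maps"]["Tetrapod"]
    shared = set(fig8_state.genomes["Gar"].sequences) & set(
        fig8_state.genomes["Tetrapod"].sequences
    )
    correct = sum(1 for g in shared if omap.pairs.get(g) == g)
    assert correct / len(shared) >= 0.95


def test_classify_assigns_identical_candidate_its_reference_label():
    ref = {"r1": "MKTAYIAKQRQISFVKSHFSRQ", "r2": "GGGGGGGGGGGGGGGGGGGGGG"}
    labels = {"r1": "CNGA", "r2": "OTHER"}
    out = hm.classify_by_reference({"c": ref["r1"]}, ref, labels,
                                   target_families={"CNGA"}, screen=False)
    assert out == {"c": "CNGA"}


def test_classify_rejects_when_top_hits_are_non_target(rng):
    # five non-target references closer than the lone target family member
    cand = random_protein(60, rng)
    ref = {f"n{i}": cand[:50] + random_protein(10, rng) for i in range(5)}
    ref["t"] = random_protein(60, rng)
    labels = {**{f"n{i}": "OTHER" for i in range(5)}, "t": "CNGA"}
    out = hm.classify_by_reference({"c": cand}, ref, labels, target_families={"CNGA"})
    assert out == {"c": hm.REJECTED}


def test_classify_screen_modes_differ_on_mixed_top_hits(rng):
    target = random_protein(80, rng)
    near_nontarget = target[:70] + random_protein(10, rng)
    ref = {"t": target, "n": near_nontarget}
    labels = {"t": "CNGA", "n": "OTHER"}
    cand = {"c": target}
    strict = hm.classify_by_reference(cand, ref, labels, {"CNGA"},
                                      screen_mode="any_non_target_rejects")
    permissive = hm.classify_by_reference(cand, ref, labels, {"CNGA"},
                                          screen_mode="none_in_top_k")
    assert strict == {"c": hm.REJECTED}
    assert permissive == {"c": "CNGA"}


def test_classification_matches_truth_per_species(fig8_state):
    """Retained family member counts equal the simulated truth."""
    for sp, genome in fig8_state.genomes.items():
        if sp == "Tetrapod":
            continue
        for gid, fam in genome.families.items():
            lab = fig8_state.labels_cng[sp].get(gid)
            if fam == "CNGB":
                assert lab == "CNGB", (sp, gid)
            elif fam.startswith("CNG"):
                assert lab == "CNGA", (sp, gid)  # A-side families hit CNGA
            elif fam == "HCN":
                assert lab == hm.REJECTED, (sp, gid)


# ---------------------------------------------------------------------------
# clustering / isoforms / length filter
# ---------------------------------------------------------------------------


def test_identical_sequences_form_one_cluster():
    clusters = hm.cluster_identity({"a": "MKTAYIAKQRQISFVKSHFSRQ",
                                    "b": "MKTAYIAKQRQISFVKSHFSRQ"})
    assert len(clusters) == 1
    assert clusters[0]["representative"] == "a"


def test_sequences_below_identity_threshold_stay_apart(rng):
    base = random_protein(100, rng)
    # ~90% identity: 10 substitutions
    other = list(base)
    for i in range(0, 100, 10):
        other[i] = "A" if base[i] != "A" else "C"
    clusters = hm.cluster_identity({"a": base, "b": "".join(other)})
    assert len(clusters) == 2


def test_greedy_clustering_matches_all_pairs_oracle(rng):
    """Cluster membership equals a brute-force replay of the same greedy
    order over a precomputed all-pairs identity matrix."""
    seqs = {}
    for fam in range(8):
        base = random_protein(int(rng.integers(60, 120)), rng)
        for k in range(int(rng.integers(2, 6))):
            s = list(base)
            for i in rng.choice(len(s), size=int(0.03 * len(s)), replace=False):
                s[i] = "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(0, 20))]
            seqs[f"f{fam}_{k}"] = "".join(s)[: len(base) - k]  # vary lengths
    th = hm.Thresholds()
    clusters = hm.cluster_identity(seqs, th)

    # oracle: same greedy order, identities from an independent full matrix
    order = sorted(seqs, key=lambda s: (-len(seqs[s]), s))
    ident = {
        (x, y): hm.pair_identity_over_shorter(seqs[x], seqs[y])
        for x in order for y in order if x != y
    }
    oracle = []
    for sid in order:
        for cl in oracle:
            if ident[(sid, cl[0])] >= th.cluster_identity:
                cl.append(sid)
                break
        else:
            oracle.append([sid])
    assert [set(c["members"]) for c in clusters] == [set(c) for c in oracle]
    # partition + representative containment
    members = [m for c in clusters for m in c["members"]]
    assert sorted(members) == sorted(seqs)
    for c in clusters:
        assert c["representative"] in c["members"]


def test_select_isoform_keeps_longest_then_lexicographic():
    recs = [
        hm.ProteinRecord("c", "M" * 100, gene_id="g1"),
        hm.ProteinRecord("a", "M" * 250, gene_id="g1"),
        hm.ProteinRecord("b", "M" * 250, gene_id="g1"),
        hm.ProteinRecord("x", "M" * 10, gene_id="g2"),
    ]
    chosen = hm.select_isoform(recs)
    assert chosen["g1"].record_id == "a"
    assert chosen["g2"].record_id == "x"
    assert len(chosen) == 2


@pytest.mark.parametrize(
    "lengths,removed",
    [
        ((300, 300, 300), []),
        ((300, 300, 90), []),  # mean 230, cutoff 76.7: 90 is retained
        ((300, 300, 60), ["s2"]),  # cutoff 73.3 removes the 60-mer
    ],
)
def test_length_filter_is_mean_based_single_pass(lengths, removed):
    members = {f"s{i}": "A" * n for i, n in enumerate(lengths)}
    retained, dropped = hm.length_filter(members, fraction=1 / 3)
    assert dropped == removed
    assert set(retained) == set(members) - set(removed)


def test_length_filter_ignores_gaps():
    members = {"a": "AAA---AAA", "b": "AAAAAA"}
    retained, dropped = hm.length_filter(members)
    assert dropped == [] and set(retained) == {"a", "b"}
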