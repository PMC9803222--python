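# paralogon-kit

Tools for reconstructing the evolutionary history of a gene family across
genomes, with the early-vertebrate whole-genome duplications (WGDs) in
focus. The package grew out of the analysis pattern used for the cyclic
nucleotide-gated (CNG) channel family — CNGA and CNGB subunits of the
photoreceptor channels — but every stage is generic:

1. **Identification** — candidate proteins are classified against a
   labelled reference proteome by best alignment hit (BLOSUM62, affine
   gaps), with reciprocal-best-hit (RBH) orthology, a top-*k* hit screen,
   ≥ 95 % identity clustering of duplicate records/isoforms and a
   one-third-of-mean length filter.
2. **Domain architecture** — PSSM scans for the ion-transport,
   cNMP-binding and CLZ (C-terminal leucine zipper) cassettes with
   shuffled-decoy calibrated cutoffs; proteins are classified
   A-like-with-CLZ / A-like-no-CLZ / B-like, and the co-occurrence rule
   (taxa with B-type genes also have CLZ-bearing A-type genes) is checked.
3. **Phylogeny** — self-contained progressive alignment, motif-anchored
   trimming of the variable termini (VVID…EYPD for the A family,
   NLMY…GTPK for B), neighbor-joining on 20-state-corrected protein
   distances, two resampling supports per internal edge (classical
   bootstrap + half-sample), outgroup or minimum-reconciliation-cost
   rooting, support-thresholded subfamily clade calls (≥ 80 / ≥ 95, or
   ≥ 90 in consensus mode), and LCA gene-tree/species-tree reconciliation.
4. **Synteny** — windows around anchor genes (5 Mb / 10 Mb half-widths),
   selection of neighbor families present on *every* anchor-bearing
   chromosome, RBH ortholog maps into other genomes, paralogon assembly
   (majority block assignment, quartet detection) and dispersal counts.
5. **Repertoire** — every duplication node is classified WGD-derived
   (ohnolog), local, or ambiguous from chromosome co-location, paralogon
   co-membership and WGD-timing; ancestral gene counts are read off the
   reconciliations for every species-tree node.

Because public gene-family datasets carry no ground truth, the package
ships a first-class **synthetic genome simulator**: a species tree with
nested WGDs (1R/2R on the vertebrate stem, 3R in the teleost stem), tandem
duplications, losses, translocations and fusions; protein sequences evolve
under a 20-state substitution channel with planted domain cassettes,
invariant functional motifs and among-site rate variation. The full event
history and per-node ancestral repertoires are recorded, so every inference
can be scored against truth. Two scenario files are packaged:
`fig8_metazoa.yaml` (the metazoan CNG history: six ancestral subfamilies,
stepwise losses to a two-gene vertebrate ancestor, re-expansion to four
CNGA + two CNGB genes in the gnathostome ancestor, teleost 3R) and
`fig6_gnathostome.yaml` (a planted chromosome-layout fixture of the
gnathostome CNGA/CNGB paralogon, including the four-way dispersal of one
chromosome's orthologs in a human-like genome).

## Worked example

Run the demonstration scenario (one WGD on a three-species tree) end to
end:

```bash
paralogon-kit all \
    --config src/paralogon_kit/scenarios/mini_vertebrate.yaml \
    --seed 3 --outdir demo --n-boot 50
```

prints (and writes to `demo/summary.json`):

```json
{
 "clz_cooccurrence_violations": 0,
 "cng_count_ingroup_ancestor": 4,
 "cng_count_outgroup": 2,
 "cng_count_spa": 4,
 "cng_count_spb": 4,
 "cnga_count_ingroup_ancestor": 2,
 "cngb_count_ingroup_ancestor": 2,
 "n_local_duplications": 0,
 "n_wgd_duplications": 2,
 "paralogon_chromosomes": 2,
 "pre_wgd_lineages_entering_ingroup": 2,
 "qualifying_neighbor_families_a": 3,
 "qualifying_neighbor_families_b": 2
}
```

Reading: the simulated WGD doubled the two-gene ancestral repertoire
(`pre_wgd_lineages_entering_ingroup: 2` → `cng_count_ingroup_ancestor: 4`);
both duplications were recognised as WGD-derived from paralogon
co-membership plus reconciliation timing (`n_wgd_duplications: 2`); all
three CNGA-side neighbor families qualified on both post-WGD chromosomes,
giving a two-chromosome paralogon; and no taxon violates the CLZ
co-occurrence rule. Intermediate artifacts (FASTA/GFF3 genomes, label
tables, trimmed alignments, rooted Newick trees with dual supports,
synteny and repertoire reports) land under `demo/`, and each stage can be
re-run individually (`simulate`, `classify`, `domains`, `align`, `tree`,
`synteny`, `repertoire`).

The same machinery is available as a library:

```python
from paralogon_kit import pipeline as pl
state = pl.run_all(pl.scenario_path("fig8_metazoa"), seed=1)
print(pl.summary(state)["cnga_count_gnathostome_ancestor"])  # 4
```

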