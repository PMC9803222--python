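# Small demonstration scenario: one WGD on the ingroup stem, three species.
# Fast enough for command-line smoke runs and examples.
name: mini_vertebrate
species_tree: >
  (Outgroup:0.30,(SpA:0.15,SpB:0.18)Ingroup:0.25)Root;
root_family_tree: >
  ((CNGA:0.20,CNGB:0.35)cng:0.25,HCN:0.60)panchannel;
n_chromosomes: 2
seed: 0
root_genes:
  - {gene_id: CNGA, family: CNGA, chromosome: chr1, start: 4000000,
     architecture: [ion_trans, cnmp, clz]}
  - {gene_id: CNGB, family: CNGB, chromosome: chr2, start: 4000000,
     architecture: [cnmp]}
  - {gene_id: HCN, family: HCN, chromosome: chr2, start: 8000000,
     architecture: [ion_trans, cnmp], conserve_motifs: false}
neighbors:
  chr1: {count: 3, anchor: CNGA, prefix: F}
  chr2: {count: 2, anchor: CNGB, prefix: G}
scripted_events:
  Ingroup:
    - {type: wgd, round: 1R, time: 0.5}
    - {type: loss, gene: HCN.b, time: 0.7}
    - {type: rename, time: 0.8, map:
        {CNGA.a: {id: CNGA1, subfamily: CNGA1},
         CNGA.b: {id: CNGA2, subfamily: CNGA2},
         HCN.a: {id: HCN}}}
pipeline:
  reference_species: [SpA, SpB]
  classification_reference: SpA
  screen: false  # the tiny reference proteome has fewer than 5 CNG genes
  synteny_reference: SpB
  synteny_others: [SpA]
  outgroup_family: HCN
  target_families: [CNGA, CNGB]
  anchor_subfamilies_a: [CNGA1, CNGA2]
  anchor_subfamilies_b: [CNGB]
  wgd_marks: {Ingroup: [1R]}
  stem_branch: Ingroup
  nodes:
    ingroup_ancestor: Ingroup
# note: no trim anchors here - the demo keeps full-length sequences
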