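# Metazoan CNG gene-family scenario: six ancestral subfamilies (CNGA-CNGF),
# stepwise losses down to the two-gene vertebrate ancestor, a local (tandem)
# duplication of CNGA on the vertebrate stem, expansion in the 1R+2R WGDs
# (placed before the cyclostome/gnathostome split; the event format can
# express the after-split variant equally), an extra lamprey CNGA4
# duplicate, and the teleost 3R WGD plus a local CNGB3 duplicate.
# Expected repertoires: vertebrate ancestor pre-WGD 2 genes; cyclostome and
# gnathostome ancestors 6 genes (4 CNGA + 2 CNGB); teleost 11.
name: fig8_metazoa
species_tree: >
  (Cnidaria:0.30,(Protostome:0.26,(Amphioxus:0.22,(Tunicate:0.20,
  (Lamprey:0.16,((Gar:0.10,Teleost:0.12)Actinopterygii:0.10,Tetrapod:0.12)
  Gnathostome:0.12)Vertebrata:0.30)Olfactores:0.10)Chordata:0.09)
  Bilateria:0.12)Metazoa;
root_family_tree: >
  (((CNGA:0.15,(CNGC:0.22,(CNGD:0.22,(CNGE:0.25,CNGF:0.25)EFanc:0.05)
  DEFanc:0.04)CDEFanc:0.08)Aanc:0.12,CNGB:0.32)CNGanc:0.25,HCN:1.1)panchannel;
n_chromosomes: 3
seed: 0
root_genes:
  - {gene_id: CNGA, family: CNGA, chromosome: chr1, start: 4000000,
     architecture: [ion_trans, cnmp, clz]}
  - {gene_id: CNGB, family: CNGB, chromosome: chr2, start: 4000000,
     architecture: [cnmp]}
  - {gene_id: CNGC, family: CNGC, chromosome: chr3, start: 1000000,
     architecture: [ion_trans, cnmp]}
  - {gene_id: CNGD, family: CNGD, chromosome: chr3, start: 2000000,
     architecture: [ion_trans, cnmp]}
  - {gene_id: CNGE, family: CNGE, chromosome: chr3, start: 3000000,
     architecture: [ion_trans, cnmp]}
  - {gene_id: CNGF, family: CNGF, chromosome: chr3, start: 4000000,
     architecture: [ion_trans, cnmp]}
  - {gene_id: HCN, family: HCN, chromosome: chr3, start: 5000000,
     architecture: [ion_trans, cnmp], conserve_motifs: false}
  # decoy neighbor families retained on too few anchor chromosomes
  - {gene_id: NX1, family: NX1, chromosome: chr1, start: 1200000, length: 150}
  - {gene_id: NX2, family: NX2, chromosome: chr1, start: 6800000, length: 150}
neighbors:
  chr1: {count: 7, anchor: CNGA, prefix: F}
  chr2: {count: 10, anchor: CNGB, prefix: G}
scripted_events:
  Bilateria:
    - {type: loss, gene: CNGE, time: 0.5}
  Olfactores:
    - {type: loss, gene: CNGC, time: 0.3}
    - {type: loss, gene: CNGF, time: 0.6}
  Vertebrata:
    - {type: loss, gene: CNGD, time: 0.05}
    - {type: tandem_dup, gene: CNGA, new_id: CNGA4anc, time: 0.15}
    - {type: wgd, round: 1R, time: 0.45}
    - {type: wgd, round: 2R, time: 0.65}
    - {type: rename, time: 0.90, map:
        {CNGA.a.a: {id: CNGA1, subfamily: CNGA1},
         CNGA.a.b: {id: CNGA2, subfamily: CNGA2},
         CNGA.b.a: {id: CNGA3, subfamily: CNGA3},
         CNGA4anc.b.a: {id: CNGA4, subfamily: CNGA4},
         CNGB.a.a: {id: CNGB1, subfamily: CNGB1},
         CNGB.b.a: {id: CNGB3, subfamily: CNGB3},
         HCN.a.a: {id: HCN}}}
    - {type: loss, gene: CNGA.b.b, time: 0.91}
    - {type: loss, gene: CNGA4anc.a.a, time: 0.92}
    - {type: loss, gene: CNGA4anc.a.b, time: 0.93}
    - {type: loss, gene: CNGA4anc.b.b, time: 0.94}
    - {type: loss, gene: CNGB.a.b, time: 0.95}
    - {type: loss, gene: CNGB.b.b, time: 0.96}
    - {type: loss, gene: HCN.a.b, time: 0.965}
    - {type: loss, gene: HCN.b.a, time: 0.97}
    - {type: loss, gene: HCN.b.b, time: 0.975}
    - {type: loss, gene: NX1.a.a, time: 0.98}
    - {type: loss, gene: NX1.b.a, time: 0.985}
    - {type: loss, gene: NX2.a.b, time: 0.99}
    - {type: loss, gene: NX2.b.b, time: 0.995}
  Lamprey:
    - {type: tandem_dup, gene: CNGA4, new_id: CNGA4b, time: 0.5}
  Tetrapod:
    # rearrangement of the CNGA3/CNGA4-bearing paralogon chromosome,
    # dispersing its genes to four chromosomes
    - {type: transloc, gene: CNGA3, to: chr2H, time: 0.55}
    - {type: transloc, gene: F1.b.a, to: chr2H, time: 0.56}
    - {type: transloc, gene: F7.b.a, to: chr2H, time: 0.57}
    - {type: transloc, gene: CNGA4, to: chr11H, time: 0.58}
    - {type: transloc, gene: F2.b.a, to: chr11H, time: 0.59}
    - {type: transloc, gene: F3.b.a, to: chr13H, time: 0.60}
    - {type: transloc, gene: F4.b.a, to: chr13H, time: 0.61}
    - {type: transloc, gene: F5.b.a, to: chr15H, time: 0.62}
    - {type: transloc, gene: F6.b.a, to: chr15H, time: 0.63}
  Teleost:
    - {type: wgd, round: 3R, time: 0.30}
    - {type: loss, gene: CNGA4.b, time: 0.55}
    - {type: loss, gene: CNGB3.b, time: 0.60}
    - {type: loss, gene: HCN.b, time: 0.65}
    - {type: tandem_dup, gene: CNGB3.a, new_id: CNGB3L, time: 0.75}
pipeline:
  reference_species: [Tetrapod, Gar, Lamprey]
  classification_reference: Tetrapod
  synteny_reference: Gar
  synteny_others: [Tetrapod, Teleost]
  outgroup_family: HCN
  target_families: [CNGA, CNGB]
  cluster_species: [Cnidaria, Protostome, Amphioxus, Tunicate]
  # the emulated protocol applies the top-five screen in the non-vertebrate
  # identification step
  screen_species: [Cnidaria, Protostome, Amphioxus, Tunicate]
  trim: {reference: Tetrapod|CNGA1, start: VVID, end: EYPD}
  family_trim:
    CNGA: {reference: Tetrapod|CNGA1, start: VVID, end: EYPD}
    CNGB: {reference: Tetrapod|CNGB1, start: NLMY, end: GTPK}
  family_subfamilies:
    CNGA: [CNGA1, CNGA2, CNGA3, CNGA4]
    CNGB: [CNGB1, CNGB3]
  # the B tree is rooted by minimal reconciliation cost (the protocol roots
  # B trees by a subtype clade; the HCN outgroup is too distant)
  family_root: {CNGB: min_cost}
  anchor_subfamilies_a: [CNGA1, CNGA2, CNGA3, CNGA4]
  anchor_subfamilies_b: [CNGB1, CNGB3]
  wgd_marks: {Vertebrata: [1R, 2R], Teleost: [3R]}
  stem_branch: Vertebrata
  dispersal:
    reference_chromosome: chr1ba
    target_species: Tetrapod
  nodes:
    metazoan_ancestor: Metazoa
    olfactores_ancestor: Olfactores
    vertebrate_node: Vertebrata
    gnathostome_ancestor: Gnathostome
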