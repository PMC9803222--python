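# Planted gnathostome CNGA/CNGB paralogon layout fixture.
# Chromosome maps (not tree-evolved): the spotted gar reference carries the
# CNGA anchors on three linkage groups (CNGA3 and CNGA4 close together on
# LG17) plus a fourth paralogon chromosome (LG4) that lost its anchor; six
# neighbor families F1-F6 and the quartet family BMX qualify on the A side
# (7 families), G1-G10 on the two CNGB linkage groups (10 families).
# Human disperses the LG17 orthologs over chromosomes 2, 11, 13 and 15;
# chicken fuses the LG7 and LG4 blocks onto its chromosome 4; zebrafish
# carries 3R duplicates. BMX is the single quartet family in human and
# zebrafish. Entries are [family, ancestral reference chromosome]; a bare
# family name means "its own chromosome" (reference rows).
kind: layout
name: fig6_gnathostome
reference: spotted_gar
anchors:
  A: [CNGA1, CNGA2, CNGA3, CNGA4]
  B: [CNGB1, CNGB3]
half_widths: {A: 5000000, B: 10000000}
family_length_aa: 150
paralog_divergence: 0.35
species_divergence: 0.08
species:
  spotted_gar:
    LG2: [CNGA1, F1, F2, F3, F4, F5, F6, BMX, D1]
    LG7: [CNGA2, F1, F2, F3, F4, F5, F6, BMX, D1]
    LG17: [CNGA3, CNGA4, F1, F2, F3, F4, F5, F6, BMX, D2]
    LG4: [BMX, H1, H2]
    LG5: [CNGB1, G1, G2, G3, G4, G5, G6, G7, G8, G9, G10]
    LG9: [CNGB3, G1, G2, G3, G4, G5, G6, G7, G8, G9, G10]
  human:
    chr5: [[CNGA1, LG2], [F1, LG2], [F2, LG2], [F3, LG2], [F4, LG2],
           [F5, LG2], [F6, LG2], [BMX, LG2], [D1, LG2]]
    chr17: [[CNGA2, LG7], [F1, LG7], [F2, LG7], [F3, LG7], [F4, LG7],
            [F5, LG7], [F6, LG7], [BMX, LG7], [D1, LG7]]
    chr2: [[CNGA3, LG17], [F1, LG17], [F6, LG17]]
    chr11: [[CNGA4, LG17], [F2, LG17]]
    chr13: [[F3, LG17], [F4, LG17]]
    chr15: [[F5, LG17], [BMX, LG17]]
    chrX: [[BMX, LG4], [H1, LG4], [H2, LG4]]
    chr1: [[CNGB1, LG5], [G1, LG5], [G2, LG5], [G3, LG5], [G4, LG5],
           [G5, LG5], [G6, LG5], [G7, LG5], [G8, LG5], [G9, LG5], [G10, LG5]]
    chr8: [[CNGB3, LG9], [G1, LG9], [G2, LG9], [G3, LG9], [G4, LG9],
           [G5, LG9], [G6, LG9], [G7, LG9], [G8, LG9], [G9, LG9], [G10, LG9]]
  chicken:
    chr1: [[CNGA1, LG2], [F1, LG2], [F2, LG2], [F3, LG2], [F4, LG2],
           [F5, LG2], [F6, LG2], [BMX, LG2]]
    chr4: [[CNGA2, LG7], [F1, LG7], [F2, LG7], [F3, LG7], [F4, LG7],
           [F5, LG7], [F6, LG7], [BMX, LG7], [BMX, LG4], [H1, LG4], [H2, LG4]]
    chr3: [[CNGA3, LG17], [CNGA4, LG17], [F1, LG17], [F2, LG17], [F3, LG17],
           [F4, LG17], [F5, LG17], [F6, LG17], [BMX, LG17]]
  zebrafish:
    dre5: [[CNGA1, LG2], [F1, LG2], [F2, LG2], [F3, LG2], [BMX, LG2]]
    dre10: [[CNGA1, LG2], [F4, LG2], [F5, LG2], [F6, LG2]]
    dre6: [[CNGA2, LG7], [F1, LG7], [F4, LG7], [BMX, LG7]]
    dre22: [[F2, LG7], [F5, LG7], [F6, LG7]]
    dre9: [[CNGA3, LG17], [CNGA4, LG17], [F1, LG17], [F2, LG17], [BMX, LG17]]
    dre13: [[F3, LG17], [F5, LG17]]
    dre14: [[BMX, LG4], [H1, LG4]]
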