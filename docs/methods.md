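# Methods

This note documents the models and procedures implemented in
`paralogon_kit`, the defaults they run with, and what the synthetic
validation does and does not demonstrate.

## The inference problem

Given protein sequences and gene coordinates for a set of genomes, a
labelled reference proteome, and a species tree, the pipeline reconstructs
a gene family's history: which genes belong to the family and its
subfamilies, which duplications derive from whole-genome duplications
(WGDs) versus local events, which chromosome segments form paralogons
(related segments descending from one pre-WGD region), and how many family
members each ancestral genome carried.

## Sequence identification

Candidates are scored against the reference proteome with affine-gap local
alignments (BLOSUM62, gap open −11 / extend −1, Biopython's pairwise
aligner). Alignment scores replace E-values for ranking: the emulated
search protocol ranks by best hit under standard settings, so score order
is the operative contract. A candidate inherits the family label of its
best hit; in the non-vertebrate identification step a candidate is
additionally rejected when any of its top five hits belongs to a
non-target family (the stricter of the two possible readings of the
protocol; the permissive one is available as `screen_mode="none_in_top_k"`).
Duplicate records and alternative transcripts are collapsed by greedy
incremental clustering at ≥ 95 % identity (identity computed over the
shorter sequence, the convention of the clustering tool being emulated;
representatives are the longest members). Isoform selection keeps the
longest sequence per gene, ties broken by record id. Records flagged as
low quality are carried through and reported, never excluded — removing
putative pseudogenes would hide duplications. After alignment and
trimming, sequences shorter than one third of the mean ungapped length are
removed in a single pass (the mean is computed once, before any removal).

## Domain architectures

Profile-HMM search against a curated database is replaced by
position-specific scoring matrices built from seed alignments of the three
cassettes (ion-transport-like, cNMP-binding-like, CLZ-like): per-column
log-odds versus a uniform background with +1 pseudocount. The score cutoff
is calibrated on shuffled composition-matched decoys as the quantile at
which 1 % of decoy best-window scores would be accepted — the operative
surrogate for an E-value threshold of 0.01 — and a hit must additionally
score above the background (positive log-odds), so windows of unknown
residues never count. Overlaps are resolved greedily by score, then
leftmost start, which makes the scan deterministic. Class labels follow
channel-subunit logic: A-like requires ion-transport + cNMP-binding (with
or without CLZ), B-like is cNMP-binding alone. The co-occurrence check
flags any taxon with a B-like gene but no CLZ-bearing A-like gene.

## Alignment and trimming

The progressive aligner is self-contained: a guide tree from 3-mer
distances (average linkage), then profile–profile merges under affine gap
penalties with sum-of-pairs BLOSUM62 column scores, processed in
lexicographic id order so the result is independent of input order. An
adapter accepts alignments computed by external tools. Trimming is
anchored on short motifs of a designated reference row — columns from the
start motif's first residue through the end motif's last residue are kept,
inclusive; a motif that is absent or occurs more than once in the
reference is an error, never silently repaired.

## Trees, supports, rooting, reconciliation

Distances are p-distances over mutually ungapped standard-residue columns
with the 20-state Poisson-type correction d = −(19/20) ln(1 − 20p/19)
(saturated pairs are capped at d = 12). Trees are built by canonical
neighbor joining, which is exact on additive matrices; maximum-likelihood
search is deliberately out of scope because the downstream logic consumes
only topology plus support thresholds. Every internal edge of the
full-data tree carries two resampling supports: a classical column
bootstrap and a half-sample support (columns drawn without replacement,
size ⌈L/2⌉), 100 replicates by default (a desk-scale stand-in for the
usual 10⁴). A clade is "well supported" when the half-sample support is
≥ 80 and the bootstrap ≥ 95 (jointly), or ≥ 90 in single-threshold
consensus mode. Subfamily labels propagate from the smallest
well-supported clade containing all of a subfamily's curated reference
members; leaves in no such clade stay "unresolved" — an expected outcome,
not an error (real families do contain subfamilies that fail to form a
single well-supported clade, and synteny evidence then carries the
orthology argument).

Family trees are rooted with a designated outgroup family when one is
close enough; otherwise (`family_root: min_cost`) on the edge minimizing
the duplication + loss reconciliation cost against the species tree, a
formalization of "rooting by one of the subtype clades". Reconciliation is
standard LCA mapping: a gene-tree node is a duplication iff it maps to the
same species node as one of its children; losses are counted by path
skipping and attributed to the species branch on which the lineage
disappeared. Ancestral counts are lineage counts at each species node
under a post-event convention (a duplication mapped to a node has already
happened there). The repertoire entering a branch (e.g. the pre-WGD
vertebrate ancestor on a WGD-carrying stem) is the number of gene edges
crossing its top.

### WGD timing

WGD rounds are marks on species-tree branches. A duplication mapped to a
marked branch is compatible with the rounds not already required below it:
with m rounds on the branch and a chain of more than m duplications, the
surplus top duplications must predate the first round (pre-WGD). This
counting rule is what recovers "a local duplication before the two rounds
generated the ancestral gene pair" when three duplications chain on a
two-round stem. Off-branch duplications are pre-WGD if a marked branch
lies below them and post-WGD if one lies above; duplications in lineages
unrelated to any marked branch are reported as `unrelated-lineage` rather
than forced into pre/post.

### Duplication modes

One call per duplication node, over a witness pair of descendant paralogs
drawn from the lexicographically smallest species retaining both sides; a
same-chromosome witness pair is preferred when one exists, because
retained synteny of the duplicates is the strongest local-mode evidence.
Same chromosome ⇒ local (the distance is reported, never thresholded —
retained local pairs range from tens of kb to tens of Mb). Distinct
chromosomes inside a paralogon with a compatible timing verdict ⇒
WGD-derived. Everything else ⇒ ambiguous, a first-class outcome with an
annotation; the tool never silently resolves it.

## Synteny and paralogons

Windows are [anchor.start − W, anchor.end + W), clipped at zero, with
interval-intersection membership (gene, not midpoint). Two half-widths are
first-class configuration — 5 Mb for the A-side analysis and 10 Mb for the
B-side, both inherited from the emulated protocol, which used both without
explanation. Overlapping windows of nearby anchors merge into one span.
A neighbor family qualifies iff it has a member inside a window on every
anchor-bearing chromosome. The reference paralogon consists of the anchors
plus all reference copies of qualifying families — the copies outside the
anchor windows are what reveal segments that lost their anchor gene (the
quartet's fourth chromosome). Orthologs of those members are grouped per
target chromosome into blocks; a block is assigned to the reference
chromosome contributing a strict majority of its orthologs, ties are
flagged and never resolved silently (the human analyst resolves such cases
by eye; the tool must not guess). A family covering four assigned blocks
is reported as a quartet.

## The simulator

`synthgenome` evolves a genome along a species tree. Events per branch are
scripted (scenario files encode event lists, since the emulated study
states no loss/translocation rates) and/or sampled (Poisson tandem
duplications and translocations, Bernoulli losses, against the
branch-start gene set). WGDs duplicate every chromosome (ids suffixed
`a`/`b`, gene ids `.a`/`.b`, within-chromosome order preserved on both
copies); tandem copies insert immediately downstream at a 20 kb default
gap, mirroring observed local duplicates; translocations move a gene to a
uniformly chosen (or scripted) other chromosome; scripted renames give
post-WGD survivors their subfamily identities. The event history is
replayable — re-applying the recorded events to the root snapshot
reproduces every node state exactly — and per-node ancestral counts are
recorded as ground truth.

Sequences evolve by substitution only under a 20-state Jukes–Cantor-type
channel: P(same) = 1/20 + (19/20)·e^(−20d/19) at branch length d
(substitutions/site), sampled exactly per site, so closed-form expectations
exist for test oracles. Three realism features matter downstream:

* **Planted cassettes.** Root sequences are built from a master scaffold
  (linkers + ion-transport 100 aa + cNMP-binding 180 aa + CLZ 64 aa)
  evolved along a pre-root family tree, then projected onto each family's
  architecture (A: all three cassettes; B: cNMP only; the outgroup family:
  ion + cNMP). Domain lengths are in the range of their real counterparts.
* **Invariant motifs.** The trimming anchors (VVID at the ion-transport
  start; NLMY/EYPD/GTPK in the cNMP cassette) are invariant sites —
  purifying selection on functional motifs — so motif-anchored trimming is
  exercised end to end. The outgroup family's motifs evolve freely
  (`conserve_motifs: false`): trimming motifs are family-specific in real
  proteins, and letting a distant outgroup keep them would give it an
  artificial similarity floor.
* **Among-site rate variation.** Cassette sites evolve at 0.6× the linker
  rate. Without it, cross-family comparisons at the scenario's depths drop
  into the twilight zone (~12 % identity) and best-hit ranks become
  noise-dominated; with it, domains stay alignable while linkers saturate,
  as in real proteins.

The packaged metazoan scenario (`fig8_metazoa.yaml`) encodes: six
ancestral subfamilies (CNGA, CNGB plus the A-side sisters CNGC–CNGF) and
an outgroup channel family; loss of CNGE on the bilaterian stem, of
CNGC/CNGF on the Olfactores stem, of CNGD on the vertebrate stem
(following the more specific of the two accounts in the source analysis);
a tandem duplication of CNGA before 1R; 1R + 2R on the vertebrate stem
(before the cyclostome/gnathostome split — the split-timing ambiguity is
real, and the event format can express the after-split variant, but the
packaged default takes the before-split form); losses shaping the
six-gene cyclostome/gnathostome repertoire (CNGA1–4, CNGB1, CNGB3); an
extra lamprey CNGA4 duplicate; tetrapod translocations dispersing one
paralogon chromosome over four; and the teleost 3R with retained CNGA1–3
and CNGB1 duplicates plus a local CNGB3 duplicate (11 genes). Neighbor
families (7 on the CNGA chromosome, 10 on the CNGB chromosome, plus two
decoys that survive on too few chromosomes) evolve without loss so the
paralogon signal survives anchor-gene loss, as the windowing method
requires. Branch lengths (root-to-leaf ≈ 0.4–0.8 substitutions/site) were
chosen once so that the planted structure is recoverable by the pipeline's
own statistics — orthologs within ~0.3–0.5 subs/site of the reference,
subfamily-defining internal branches of ≥ ~10 expected substitutions —
and then frozen; they are the study conditions, not tuning knobs.

`fig6_gnathostome.yaml` is a planted chromosome-layout fixture (not
tree-evolved): the reference genome carries the CNGA anchors on three
linkage groups plus a fourth paralogon chromosome that lost its anchor;
sequences are drawn hierarchically (family consensus → per-ancestral-
chromosome sub-consensus at 0.35 subs/site → species copy at 0.08) so RBH
recovers the planted orthology, including which paralogous copy is which.

## What the validation shows — and does not

The acceptance run demonstrates that, under the scenario conditions, the
pipeline recovers the planted history from sequences and coordinates
alone: the ancestral repertoires at every named node, the modern
repertoires, the qualifying neighbor-family counts, the four-chromosome
paralogon, the dispersal count, and the pre-WGD timing of the
anchor-generating local duplication. Because the simulation has no indels,
no assembly errors, no annotation noise and no gene conversion, passing
these tests shows the *logic* of the pipeline is sound, not that real
genomes at comparable divergences would be recovered as cleanly; in real
data the manual-curation steps the protocol includes (inspecting
alignments, extending truncated sequences) absorb exactly the noise the
simulator omits. Tree inference on single-copy deep lineages remains the
fragile step: in a ten-seed sweep one seed misplaced one deep invertebrate
branch, shifting one ancestral count by one. The acceptance script
therefore reports the median over three replicate simulations, a plain
robustness device, not a correction.

## Numerical and degenerate-input choices

* Parsers reject rather than repair; every error names the offending line
  or motif. Coordinates are 0-based half-open internally, 1-based
  inclusive in GFF3; BED is accepted on input only.
* Dual supports serialize as slash-separated internal Newick labels
  (`95/99`); a tree without supports round-trips with supports absent,
  not zero.
* NJ ties in the Q-matrix and all greedy tie-breaks resolve
  lexicographically; identical sequences are retained, never collapsed, in
  tree building.
* Saturated distances cap at 12 substitutions/site; zero comparable
  columns between two rows is an error.
* All randomness flows from a single seed per run; same seed, same
  configuration ⇒ byte-identical outputs.
* Problem sizes: the packaged scenario has 8 species, ~25–160 genes per
  genome, proteins of 125–440 aa, and 100 bootstrap replicates per family
  tree; a full end-to-end run takes ~25 s on one CPU.
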