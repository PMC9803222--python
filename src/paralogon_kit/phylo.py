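"""Distance trees with dual resampling supports, rooting, subfamily clade
calls, gene/species-tree reconciliation and WGD-timing verdicts.

Maximum-likelihood tree search is deliberately replaced by neighbor joining
on corrected protein distances: the downstream inference consumes only
topology plus support thresholds, and NJ is exact on additive matrices.
Two resampling supports are attached to every internal edge of the
full-data tree: a classical column bootstrap (``support_b``) and a
half-sample support (columns drawn without replacement, size ceil(L/2);
``support_a``), thresholded jointly (defaults 80/95) to call a clade well
supported, or singly (>= 90) in consensus mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

from .homology import Thresholds
from .io_formats import SupportedTree
from .msa_trim import Alignment
from .synthgenome import _AA_IDX

#: distance assigned to saturated pairs (observed difference beyond the
#: correctable range of the 20-state Poisson-type correction)
MAX_DISTANCE = 12.0


def correct_distance(p: float) -> float:
    """20-state Jukes-Cantor-type saturation correction of a p-distance."""
    arg = 1 - 20 * p / 19
    if arg <= 0:
        return MAX_DISTANCE
    return min(MAX_DISTANCE, -(19 / 20) * np.log(arg))


def _encode_alignment(aln: Alignment):
    ids = sorted(aln.rows)
    mat = np.array(
        [[_AA_IDX.get(c, -1) for c in aln.rows[i]] for i in ids], dtype=np.int16
    )
    return ids, mat


def _pairwise_p(mat: np.ndarray):
    """p-distances over mutually ungapped standard-residue columns."""
    n = mat.shape[0]
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = (mat[i] >= 0) & (mat[j] >= 0)
            ncomp = int(comp.sum())
            if ncomp == 0:
                raise ValueError(
                    f"zero comparable columns between rows {i} and {j}"
                )
            p[i, j] = p[j, i] = (mat[i, comp] != mat[j, comp]).mean()
    return p


def protein_distance(aln: Alignment) -> DistanceMatrix:
    """Corrected pairwise protein distances (substitutions/site)."""
    if len(aln.rows) < 2:
        raise ValueError("need at least 2 rows")
    ids, mat = _encode_alignment(aln)
    p = _pairwise_p(mat)
    d = np.vectorize(correct_distance)(p)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids)


def nj_tree(dm: DistanceMatrix) -> SupportedTree:
    """Canonical neighbor joining (unrooted); exact on additive matrices.

    Ids are processed in lexicographic order so equal-Q ties resolve
    deterministically.
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    order = sorted(dm.ids)
    tree = _skbio_nj(dm.filter(order))
    for n in tree.non_tips(include_self=True):
        if n.length is not None and n.length < 0:
            n.length = 0.0
        n.support_a = None
        n.support_b = None
    return SupportedTree(tree)


def _splits(tree: TreeNode) -> set:
    """Unrooted bipartitions as frozensets of the side not containing the
    lexicographically smallest tip."""
    all_tips = frozenset(t.name for t in tree.tips())
    ref = min(all_tips)
    out = set()
    for n in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in n.tips())
        if ref in side:
            side = all_tips - side
        if 1 < len(side) < len(all_tips) - 1:
            out.add(side)
    return out


def _tree_from_columns(ids, mat, cols):
    sub = mat[:, cols]
    p = _pairwise_p(sub)
    d = np.vectorize(correct_distance)(p)
    np.fill_diagonal(d, 0.0)
    return nj_tree(DistanceMatrix(d, ids))


def dual_support(aln: Alignment, n_boot: int | None = None, seed: int = 0,
                 thresholds: Thresholds | None = None) -> SupportedTree:
    """Full-data NJ tree with bootstrap and half-sample supports attached.

    ``support_b`` is the classical column-bootstrap percentage over
    ``n_boot`` replicates; ``support_a`` the percentage over ``n_boot``
    half-sample replicates (columns without replacement, size ceil(L/2)).
    ``n_boot = 0`` leaves supports absent.
    """
    th = thresholds or Thresholds()
    if n_boot is None:
        n_boot = th.n_boot
    ids, mat = _encode_alignment(aln)
    L = mat.shape[1]
    full = _tree_from_columns(ids, mat, np.arange(L))
    if n_boot == 0:
        return full
    rng = np.random.default_rng(seed)
    boot_counts: dict = {}
    half_counts: dict = {}
    half = int(np.ceil(L / 2))
    for _ in range(n_boot):
        cols = rng.integers(0, L, size=L)
        for s in _splits(_tree_from_columns(ids, mat, cols).tree):
            boot_counts[s] = boot_counts.get(s, 0) + 1
    for _ in range(n_boot):
        cols = rng.choice(L, size=half, replace=False)
        for s in _splits(_tree_from_columns(ids, mat, cols).tree):
            half_counts[s] = half_counts.get(s, 0) + 1
    all_tips = frozenset(ids)
    ref = min(all_tips)
    for n in full.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in n.tips())
        if ref in side:
            side = all_tips - side
        if not (1 < len(side) < len(all_tips) - 1):
            continue
        n.support_a = 100.0 * half_counts.get(side, 0) / n_boot
        n.support_b = 100.0 * boot_counts.get(side, 0) / n_boot
    return full


def root_with_outgroup(st: SupportedTree, outgroup_ids) -> SupportedTree:
    """Root on the edge separating a monophyletic outgroup from the ingroup."""
    outgroup = set(outgroup_ids)
    tree = st.tree
    tips = {t.name for t in tree.tips()}
    missing = outgroup - tips
    if missing:
        raise ValueError(f"outgroup ids not in tree: {sorted(missing)}")
    if outgroup == tips:
        raise ValueError("outgroup cannot contain all leaves")
    target = None
    for n in tree.traverse(include_self=False):
        side = {t.name for t in n.tips()} if not n.is_tip() else {n.name}
        if side == outgroup or (tips - side) == outgroup:
            target = n
            break
    if target is None:
        # not monophyletic in the unrooted sense: report the intruders
        lca = tree.lca(sorted(outgroup))
        clade = {t.name for t in lca.tips()} if not lca.is_tip() else {lca.name}
        intruders = sorted(clade - outgroup) or sorted(outgroup)
        raise ValueError(f"outgroup not monophyletic; intruding leaves: {intruders}")
    rooted = tree.root_at(target, above=True,
                          branch_attrs=["support_a", "support_b"])
    for n in rooted.non_tips(include_self=True):
        for attr in ("support_a", "support_b"):
            if not hasattr(n, attr):
                setattr(n, attr, None)
    return SupportedTree(rooted)


def root_by_reconciliation(st: SupportedTree,
                           species_tree: SupportedTree | TreeNode,
                           species_of=None) -> SupportedTree:
    """Root an unrooted gene tree on the edge minimizing the duplication +
    loss reconciliation cost against the species tree (deterministic: first
    minimal edge in traversal order).

    This formalizes rooting "by one of the subtype clades" when no close
    outgroup is available: a distant outgroup attaches too noisily to root a
    family tree reliably, whereas the most parsimonious rooting is defined
    by the species history itself.
    """
    species_of = species_of or default_species_of
    tree = st.tree
    best = None
    for node in list(tree.traverse(include_self=False)):
        cand = tree.root_at(node, above=True,
                            branch_attrs=["support_a", "support_b"])
        for n in cand.non_tips(include_self=True):
            for attr in ("support_a", "support_b"):
                if not hasattr(n, attr):
                    setattr(n, attr, None)
        rec = reconcile(cand, species_tree, species_of)
        cost = rec.n_duplications + rec.n_losses
        if best is None or cost < best[0]:
            best = (cost, cand)
    if best is None:
        raise ValueError("tree has no internal edge to root on")
    return SupportedTree(best[1])


@dataclass
class CladeCall:
    label: str
    member_ids: list
    support_a: float | None
    support_b: float | None
    status: str  # supported | unsupported

    @property
    def supported(self) -> bool:
        return self.status == "supported"


def _clade_supported(node: TreeNode, th: Thresholds, mode: str) -> bool:
    if node.is_tip():
        return True  # a single leaf is trivially a clade
    a = getattr(node, "support_a", None)
    b = getattr(node, "support_b", None)
    if mode == "dual":
        return a is not None and b is not None and a >= th.support_a_min and b >= th.support_b_min
    if mode == "consensus":
        return a is not None and a >= th.consensus_support_min
    raise ValueError(f"unknown support mode {mode!r}")


def assign_subfamilies(st: SupportedTree, reference_members: dict,
                       thresholds: Thresholds | None = None,
                       mode: str = "dual"):
    """Label query leaves by the smallest well-supported clade that contains
    all of a subfamily's reference members.

    Leaves inside no supported subfamily clade are labelled ``unresolved``
    (the situation of a subfamily whose sequences do not form a single
    well-supported clade). Returns (clade calls, leaf -> label dict).
    """
    th = thresholds or Thresholds()
    tree = st.tree
    tips = {t.name for t in tree.tips()}
    calls = []
    clade_members: dict[str, set] = {}
    for label in sorted(reference_members):
        members = list(reference_members[label])
        missing = [m for m in members if m not in tips]
        if missing:
            raise ValueError(f"subfamily {label}: reference members missing: {missing}")
        node = tree.lca(members) if len(members) > 1 else tree.find(members[0])
        leaf_set = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        ok = _clade_supported(node, th, mode)
        calls.append(
            CladeCall(label, sorted(leaf_set),
                      getattr(node, "support_a", None),
                      getattr(node, "support_b", None),
                      "supported" if ok else "unsupported")
        )
        if ok:
            clade_members[label] = leaf_set
    assignment = {}
    for leaf in sorted(tips):
        containing = [(len(m), lab) for lab, m in clade_members.items() if leaf in m]
        assignment[leaf] = min(containing)[1] if containing else "unresolved"
    return calls, assignment


# ---------------------------------------------------------------------------
# reconciliation
# ---------------------------------------------------------------------------


@dataclass
class Reconciliation:
    """LCA reconciliation of a rooted gene tree into a rooted species tree."""

    gene_tree: TreeNode
    species_tree: TreeNode
    mapping: dict  # gene TreeNode -> species node name
    events: dict  # gene TreeNode -> "speciation" | "duplication" | "leaf"
    losses: dict  # species branch (child node name) -> inferred loss count
    _sp_nodes: dict = field(default_factory=dict, repr=False)
    _ancestors: dict = field(default_factory=dict, repr=False)

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events.values() if e == "duplication")

    @property
    def n_losses(self) -> int:
        return sum(self.losses.values())

    def duplications(self) -> list:
        return [n for n in self.gene_tree.postorder() if self.events.get(n) == "duplication"]

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff species node a is an ancestor of (or equal to) b."""
        return a in self._ancestors[b]

    def lineages_at(self, species_node: str) -> int:
        """Number of gene lineages present at a species-tree node.

        Node counts follow the post-event convention: a duplication mapped
        to node s has already happened at s (its products count, the parent
        lineage does not). A lineage lost below s still counts at s when the
        reconciliation implies it existed there.
        """
        s = species_node
        count = 0
        for v in self.gene_tree.postorder(include_self=True):
            u = v.parent
            mv = self.mapping[v]
            v_is_dup = self.events.get(v) == "duplication"
            if u is None:
                # virtual edge above the gene root: the ancestral lineage is
                # assumed present from the species root down to M(root)
                if not self.is_ancestor(s, mv):
                    continue
            else:
                mu = self.mapping[u]
                u_is_dup = self.events.get(u) == "duplication"
                if not (self.is_ancestor(mu, s) and self.is_ancestor(s, mv)):
                    continue  # s not on the edge's species path
                if s == mu and not u_is_dup:
                    continue  # a speciation splits exactly at its node
            if s == mv and v_is_dup:
                continue  # the duplication has already replaced this lineage
            count += 1
        return count

    def lineages_entering(self, branch: str) -> int:
        """Gene lineages crossing the top of a species branch: edges whose
        parent maps at or above the branch's parent node and whose child
        maps inside the branch's subtree. This is the repertoire of the
        ancestor just before the branch's own events (e.g. the pre-WGD
        vertebrate ancestor on a WGD-carrying stem)."""
        node = self._sp_nodes[branch]
        if node.parent is None:
            raise ValueError("the species root has no entering branch")
        parent = node.parent.name
        count = 0
        for v in self.gene_tree.postorder(include_self=True):
            mv = self.mapping[v]
            if not self.is_ancestor(branch, mv):
                continue
            u = v.parent
            if u is None or self.is_ancestor(self.mapping[u], parent):
                count += 1
        return count


def _species_index(sp_tree: TreeNode):
    nodes = {}
    ancestors = {}
    for n in sp_tree.traverse(include_self=True):
        nodes[n.name] = n
    for n in sp_tree.traverse(include_self=True):
        anc = set()
        cur = n
        while cur is not None:
            anc.add(cur.name)
            cur = cur.parent
        ancestors[n.name] = anc
    return nodes, ancestors


def default_species_of(leaf_name: str) -> str:
    """Leaf naming convention: ``Species|gene_id``."""
    return leaf_name.split("|", 1)[0]


def reconcile(gene_tree: SupportedTree | TreeNode,
              species_tree: SupportedTree | TreeNode,
              species_of=default_species_of) -> Reconciliation:
    """Standard LCA (most-parsimonious) reconciliation.

    Each gene-tree node maps to the LCA of its leaves' species; a node is a
    duplication iff it maps to the same species node as one of its children.
    Losses are counted by path skipping and attributed to the species branch
    (identified by its child node) on which the lineage disappeared.
    """
    gt = gene_tree.tree if isinstance(gene_tree, SupportedTree) else gene_tree
    sp = species_tree.tree if isinstance(species_tree, SupportedTree) else species_tree
    sp_nodes, ancestors = _species_index(sp)
    depth = {}
    for name, node in sp_nodes.items():
        d, cur = 0, node
        while cur.parent is not None:
            d += 1
            cur = cur.parent
        depth[name] = d

    def lca_name(a: str, b: str) -> str:
        na, nb = sp_nodes[a], sp_nodes[b]
        while depth[na.name] > depth[nb.name]:
            na = na.parent
        while depth[nb.name] > depth[na.name]:
            nb = nb.parent
        while na is not nb:
            na, nb = na.parent, nb.parent
        return na.name

    mapping: dict = {}
    events: dict = {}
    for v in gt.postorder(include_self=True):
        if v.is_tip():
            spname = species_of(v.name)
            if spname not in sp_nodes:
                raise ValueError(f"gene-tree leaf {v.name!r} maps to unknown species {spname!r}")
            mapping[v] = spname
            events[v] = "leaf"
        else:
            ms = [mapping[c] for c in v.children]
            m = ms[0]
            for other in ms[1:]:
                m = lca_name(m, other)
            mapping[v] = m
            events[v] = "duplication" if any(mc == m for mc in ms) else "speciation"

    losses: dict = {}
    for v in gt.postorder(include_self=True):
        if v.is_tip():
            continue
        for c in v.children:
            mv, mc = mapping[v], mapping[c]
            # walk the species path from mc up to mv
            path = []
            cur = sp_nodes[mc]
            while cur.name != mv:
                path.append(cur)
                cur = cur.parent
            path.append(sp_nodes[mv])
            path.reverse()  # mv ... mc, top down
            skipped = path[:-1] if events[v] == "duplication" else path[1:-1]
            for s_node in skipped:
                on_path_child = path[path.index(s_node) + 1]
                for ch in s_node.children:
                    if ch is not on_path_child:
                        losses[ch.name] = losses.get(ch.name, 0) + 1
    return Reconciliation(gt, sp, mapping, events, losses, sp_nodes, ancestors)


# ---------------------------------------------------------------------------
# WGD timing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimingVerdict:
    status: str  # compatible | pre-WGD | post-WGD | unrelated-lineage
    rounds: tuple = ()

    def __str__(self):
        if self.status == "compatible":
            return "compatible-with-" + "/".join(self.rounds)
        return self.status


def wgd_timing_test(recon: Reconciliation, wgd_marks: dict) -> dict:
    """Classify each duplication relative to marked WGD branches.

    ``wgd_marks`` maps species branch names (child-node ids) to the ordered
    list of WGD rounds carried by that branch (oldest first). A duplication
    mapped to a marked branch is compatible with the rounds not already
    required by duplications below it on the same branch; when more
    duplications are chained on one branch than it has rounds, the surplus
    top ones must predate the first round (pre-WGD). Off-branch duplications
    are pre-WGD if a marked branch lies below them, post-WGD if one lies
    above, otherwise in an unrelated lineage.
    """
    for br in wgd_marks:
        if br not in recon._sp_nodes:
            raise ValueError(f"WGD mark on unknown species branch {br!r}")

    def chain_same_branch(node, b) -> int:
        """Longest duplication chain mapped to branch b in node's subtree,
        counting node itself."""
        if recon.mapping[node] != b or node.is_tip():
            return 0
        own = 1 if recon.events.get(node) == "duplication" else 0
        sub = max((chain_same_branch(c, b) for c in node.children), default=0)
        return own + sub

    verdicts: dict = {}
    for v in recon.duplications():
        b = recon.mapping[v]
        marks = list(wgd_marks.get(b, []))
        if marks:
            n_below = max((chain_same_branch(c, b) for c in v.children), default=0)
            if n_below >= len(marks):
                verdicts[v] = TimingVerdict("pre-WGD")
            else:
                verdicts[v] = TimingVerdict("compatible", tuple(marks[: len(marks) - n_below]))
        else:
            below = any(recon.is_ancestor(b, mb) and b != mb for mb in wgd_marks)
            above = any(recon.is_ancestor(mb, b) and b != mb for mb in wgd_marks)
            if below:
                verdicts[v] = TimingVerdict("pre-WGD")
            elif above:
                verdicts[v] = TimingVerdict("post-WGD")
            else:
                verdicts[v] = TimingVerdict("unrelated-lineage")
    return verdicts
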