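"""Sequence-identification stage: pairwise similarity, reciprocal best hits,
reference-based family classification, identity clustering, isoform
selection and length filtering.

Alignment scores (BLOSUM62, affine gaps) replace E-values for ranking: the
search strategy being emulated ranks candidates by best hit under standard
settings, so score order is the operative contract. Records flagged as low
quality are carried through and reported, never excluded - pseudogenes can
hide duplications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    subject: str
    score: float
    identity: float  # percent over aligned (non-gap) columns
    aln_len: int

    def __post_init__(self):
        if not (0 <= self.identity <= 100):
            raise ValueError(f"identity out of range: {self.identity}")
        if not np.isfinite(self.score):
            raise ValueError("non-finite score")


@dataclass
class Thresholds:
    """Every numeric operating point of the pipeline, with its default."""

    cluster_identity: float = 95.0  # percent; duplicate/isoform collapse
    length_fraction: float = 1 / 3  # of mean ungapped length in an alignment
    top_k_screen: int = 5  # best-hit screen depth
    domain_quantile: float = 0.01  # decoy quantile standing in for E < 0.01
    window_a: int = 5_000_000  # bp half-width, A-side synteny windows
    window_b: int = 10_000_000  # bp half-width, B-side synteny windows
    support_a_min: float = 80.0  # percent (half-sample support)
    support_b_min: float = 95.0  # percent (bootstrap support)
    consensus_support_min: float = 90.0  # single-threshold consensus mode
    n_boot: int = 100

    def __post_init__(self):
        for name in ("cluster_identity", "support_a_min", "support_b_min",
                     "consensus_support_min"):
            v = getattr(self, name)
            if not (0 < v <= 100):
                raise ValueError(f"{name} must be in (0, 100], got {v}")
        for name in ("length_fraction", "top_k_screen", "domain_quantile",
                     "window_a", "window_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_boot < 0:
            raise ValueError("n_boot must be >= 0")


@dataclass(frozen=True)
class ProteinRecord:
    record_id: str
    sequence: str
    gene_id: str | None = None
    low_quality: bool = False  # reported, never used to exclude


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    for i, c in enumerate(seq):
        if c not in VALID_AA:
            raise ValueError(f"{name}: illegal character {c!r} at position {i}")


def _aligner(mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    a.mode = mode
    return a


def align_pair(a: str, b: str, mode: str = "global") -> SimilarityHit:
    """Affine-gap dynamic-programming alignment of two proteins (BLOSUM62,
    gap open -11 / extend -1). Identity is computed over aligned non-gap
    columns; the score is symmetric in (a, b)."""
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be global or local, got {mode!r}")
    _check_sequence(a, "a")
    _check_sequence(b, "b")
    aligner = _aligner(mode)
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    aligned_cols = counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / aligned_cols if aligned_cols else 0.0
    return SimilarityHit("a", "b", float(aln.score), identity, int(aln.length))


def score_matrix(queries: dict, subjects: dict, mode: str = "local") -> np.ndarray:
    """Pairwise score matrix (rows: sorted query ids, cols: sorted subject ids)."""
    aligner = _aligner(mode)
    qids, sids = sorted(queries), sorted(subjects)
    mat = np.empty((len(qids), len(sids)))
    cache: dict = {}
    for i, q in enumerate(qids):
        for j, s in enumerate(sids):
            key = (queries[q], subjects[s]) if queries[q] <= subjects[s] else (
                subjects[s], queries[q])
            if key not in cache:
                cache[key] = aligner.score(*key)
            mat[i, j] = cache[key]
    return mat


def _best_hits(ids_q, ids_s, mat):
    """Per-query best subject with lexicographic tie-break; returns
    (best dict, tie-flag dict)."""
    best, ties = {}, {}
    for i, q in enumerate(ids_q):
        row = mat[i]
        m = row.max()
        winners = [ids_s[j] for j in np.flatnonzero(row == m)]
        best[q] = min(winners)
        ties[q] = len(winners) > 1
    return best, ties


def reciprocal_best_hits(query_set: dict, reference_set: dict,
                         mode: str = "local", scores: np.ndarray | None = None):
    """Reciprocal-best-hit orthology between two sequence sets.

    q maps to r iff r is q's top-scoring reference and q is r's top-scoring
    query. Ties break to the lexicographically smaller id and are flagged.
    ``scores`` may supply a precomputed matrix over sorted ids.
    Returns (mapping q -> r or None, tie_flags q -> bool).
    """
    if not query_set or not reference_set:
        raise ValueError("both sequence sets must be non-empty")
    qids, rids = sorted(query_set), sorted(reference_set)
    mat = score_matrix(query_set, reference_set, mode) if scores is None else scores
    fwd, tie_f = _best_hits(qids, rids, mat)
    rev, tie_r = _best_hits(rids, qids, mat.T)
    mapping, ties = {}, {}
    for q in qids:
        r = fwd[q]
        if rev[r] == q:
            mapping[q] = r
            ties[q] = tie_f[q] or tie_r[r]
        else:
            mapping[q] = None
            ties[q] = tie_f[q]
    return mapping, ties


def top_k_hits(query_seq: str, reference_set: dict, k: int,
               mode: str = "local") -> list[str]:
    """The k best-scoring reference ids (score desc, then id asc)."""
    aligner = _aligner(mode)
    scored = sorted(
        ((-aligner.score(query_seq, reference_set[r]), r) for r in sorted(reference_set)),
    )
    return [r for _, r in scored[:k]]


REJECTED = "rejected"


def classify_by_reference(candidates: dict, reference: dict, labels: dict,
                          target_families: set | None = None,
                          thresholds: Thresholds | None = None,
                          screen: bool = True,
                          screen_mode: str = "any_non_target_rejects",
                          scores: np.ndarray | None = None) -> dict:
    """Assign each candidate the family label of its best reference hit.

    A candidate is rejected when its best hit's family is not a target
    family, or (with the screen on, the default) when the top-k hit list
    contains a non-target family - the emulated protocol excluded sequences
    with anything else among the top five hits. ``screen_mode
    "none_in_top_k"`` instead rejects only when no top-k hit is a target.
    """
    th = thresholds or Thresholds()
    if target_families is None:
        target_families = set(labels.values())
    rids = sorted(reference)
    if scores is None:
        scores = score_matrix(candidates, reference)
    out = {}
    for i, cid in enumerate(sorted(candidates)):
        row = scores[i]
        hits = [r for _, r in sorted(zip(-row, rids))][: th.top_k_screen]
        best_fam = labels[hits[0]]
        label = best_fam if best_fam in target_families else REJECTED
        if label != REJECTED and screen:
            fams = [labels[h] for h in hits]
            if screen_mode == "any_non_target_rejects":
                if any(f not in target_families for f in fams):
                    label = REJECTED
            elif screen_mode == "none_in_top_k":
                if not any(f in target_families for f in fams):
                    label = REJECTED
            else:
                raise ValueError(f"unknown screen_mode {screen_mode!r}")
        out[cid] = label
    return out


def pair_identity_over_shorter(a: str, b: str) -> float:
    """Percent identity with the shorter sequence as denominator (the
    convention of the clustering tool being emulated)."""
    aligner = _aligner("local")
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / min(len(a), len(b))


def cluster_identity(sequences: dict, thresholds: Thresholds | None = None):
    """Greedy incremental identity clustering.

    Sequences sorted by decreasing length (ties: id) each join the first
    existing cluster whose representative they match at >= the identity
    threshold (identity over the shorter sequence), else found a new
    cluster. Representatives are the longest member (the founder).
    Returns a list of clusters, each a dict with "representative", "members".
    """
    th = thresholds or Thresholds()
    order = sorted(sequences, key=lambda s: (-len(sequences[s]), s))
    clusters: list[dict] = []
    for sid in order:
        placed = False
        for cl in clusters:
            ident = pair_identity_over_shorter(sequences[sid], sequences[cl["representative"]])
            if ident >= th.cluster_identity:
                cl["members"].append(sid)
                placed = True
                break
        if not placed:
            clusters.append({"representative": sid, "members": [sid]})
    return clusters


def select_isoform(records: list) -> dict:
    """One record per gene: longest sequence, ties by lexicographic id."""
    by_gene: dict[str, list] = {}
    for rec in records:
        if rec.gene_id is None:
            raise ValueError(f"record {rec.record_id} has no gene id")
        by_gene.setdefault(rec.gene_id, []).append(rec)
    return {
        gid: min(rs, key=lambda r: (-len(r.sequence), r.record_id))
        for gid, rs in by_gene.items()
    }


def length_filter(members: dict, fraction: float = 1 / 3):
    """Drop sequences shorter than ``fraction`` x the mean ungapped length.

    The mean is computed once, before any removal (single pass). Accepts
    gapped rows; gaps do not count toward length. Returns (retained dict,
    removed ids).
    """
    if not members:
        raise ValueError("length_filter needs at least one member")
    lengths = {k: len(v.replace("-", "")) for k, v in members.items()}
    cutoff = fraction * (sum(lengths.values()) / len(lengths))
    retained = {k: v for k, v in members.items() if lengths[k] >= cutoff}
    removed = sorted(k for k in members if k not in retained)
    return retained, removed
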