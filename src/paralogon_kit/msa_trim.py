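"""Progressive multiple alignment and motif-anchored trimming.

The aligner is self-contained: a guide tree from k-mer distances, then
profile-profile merges with affine gap penalties (BLOSUM62, open 11 /
extend 1, sum-of-pairs column scores). It is deterministic and independent
of the input order (sequences are processed in lexicographic id order). An
adapter (:func:`alignment_from_fasta`) accepts pre-computed alignments from
external tools.

Trimming removes the variable N- and C-terminal regions by anchoring on
short motifs of a designated reference row (e.g. VVID..EYPD for A-type
channel subunits, NLMY..GTPK for B-type): columns from the first residue of
the start motif through the last residue of the end motif are kept,
inclusive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .synthgenome import _AA_IDX

GAP_OPEN = 11.0
GAP_EXT = 1.0
NEG = -1e30


def _blosum62() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((21, 21))
    for i, a in enumerate("ACDEFGHIKLMNPQRSTVWY"):
        for j, b in enumerate("ACDEFGHIKLMNPQRSTVWY"):
            out[i, j] = m[a, b]
    return out  # row/col 20 (X and friends) score 0


_B62 = _blosum62()


@dataclass
class Alignment:
    """Gapped rows of equal length keyed by sequence id."""

    rows: dict
    anchors: tuple | None = None  # (start motif, end motif) once trimmed

    def __post_init__(self):
        lens = {len(v) for v in self.rows.values()}
        if len(lens) > 1:
            raise ValueError(f"rows differ in length: {sorted(lens)}")

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def degapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace("-", "")

    def project_pair(self, id_a: str, id_b: str):
        """The induced pairwise alignment of two rows (all-gap columns dropped)."""
        a, b = self.rows[id_a], self.rows[id_b]
        keep = [i for i in range(len(a)) if a[i] != "-" or b[i] != "-"]
        return "".join(a[i] for i in keep), "".join(b[i] for i in keep)


def alignment_from_fasta(seqs: dict) -> Alignment:
    """Adapter for alignments computed by an external tool."""
    return Alignment(dict(seqs))


# ---------------------------------------------------------------------------
# guide tree + profile-profile merging
# ---------------------------------------------------------------------------


def _kmer_distance_matrix(ids, seqs, k: int = 3) -> np.ndarray:
    counters = []
    for i in ids:
        s = seqs[i]
        counters.append(Counter(s[j : j + k] for j in range(max(0, len(s) - k + 1))))
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = counters[i], counters[j]
            shared = sum((ci & cj).values())
            denom = min(sum(ci.values()), sum(cj.values())) or 1
            d[i, j] = d[j, i] = 1.0 - shared / denom
    return d


def _profile_counts(rows: list) -> np.ndarray:
    """Column residue counts (n_cols x 21); gaps are simply absent."""
    ncols = len(rows[0])
    counts = np.zeros((ncols, 21))
    for r in rows:
        for i, c in enumerate(r):
            if c != "-":
                counts[i, _AA_IDX.get(c, 20)] += 1
    return counts


def _align_profiles(rows_a: list, rows_b: list):
    """Affine-gap DP between two profiles; returns merged gapped rows."""
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    na = ca.sum(axis=1, keepdims=True).clip(min=1)
    nb = cb.sum(axis=1, keepdims=True).clip(min=1)
    fa, fb = ca[:, :20] / na, cb[:, :20] / nb
    sc = fa @ _B62[:20, :20] @ fb.T  # expected substitution score per column pair
    n, m = sc.shape

    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # consume a column of A (gap in B)
    Iy = np.full((n + 1, m + 1), NEG)  # consume a column of B (gap in A)
    M[0, 0] = 0.0
    if n:
        Ix[1:, 0] = -GAP_OPEN - GAP_EXT * np.arange(n)
    if m:
        Iy[0, 1:] = -GAP_OPEN - GAP_EXT * np.arange(m)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = sc[i - 1] + prev_best[:-1]
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] - GAP_OPEN, Ix[i - 1, 1:] - GAP_EXT)
        # Iy within the row via a running-max identity
        j = np.arange(m + 1)
        v = np.maximum(M[i], Ix[i]) + GAP_EXT * j
        run = np.maximum.accumulate(v[:-1])
        Iy[i, 1:] = run - GAP_OPEN - GAP_EXT * (j[1:] - 1)

    # traceback
    ops = []  # (consume_a, consume_b)
    i, j = n, m
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    eps = 1e-9
    while i > 0 or j > 0:
        if state == 0:
            ops.append((True, True))
            prev = np.array([M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]])
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:
            ops.append((True, False))
            stay = Ix[i - 1, j] - GAP_EXT
            state = 1 if i > 1 and abs(Ix[i, j] - stay) < eps else 0
            i -= 1
        else:
            ops.append((False, True))
            stay = Iy[i, j - 1] - GAP_EXT
            state = 2 if j > 1 and abs(Iy[i, j] - stay) < eps else 0
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    ops.reverse()

    merged_a = ["" for _ in rows_a]
    merged_b = ["" for _ in rows_b]
    ia = ib = 0
    for ca_used, cb_used in ops:
        for r_idx, r in enumerate(rows_a):
            merged_a[r_idx] += r[ia] if ca_used else "-"
        for r_idx, r in enumerate(rows_b):
            merged_b[r_idx] += r[ib] if cb_used else "-"
        ia += ca_used
        ib += cb_used
    return merged_a, merged_b


def progressive_align(seqs: dict) -> Alignment:
    """Progressively align sequences following a k-mer-distance guide tree."""
    if len(seqs) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    ids = sorted(seqs)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sequence ids")
    dmat = _kmer_distance_matrix(ids, seqs)
    Z = linkage(squareform(dmat, checks=False), method="average")
    clusters: dict[int, tuple] = {
        i: ([ids[i]], [seqs[ids[i]]]) for i in range(len(ids))
    }
    nxt = len(ids)
    for a, b, _, _ in Z:
        ids_a, rows_a = clusters.pop(int(a))
        ids_b, rows_b = clusters.pop(int(b))
        merged_a, merged_b = _align_profiles(rows_a, rows_b)
        clusters[nxt] = (ids_a + ids_b, merged_a + merged_b)
        nxt += 1
    (final_ids, final_rows), = clusters.values()
    rows = dict(sorted(zip(final_ids, final_rows)))
    out = Alignment(rows)
    for sid in ids:  # degapping must return the input
        assert out.degapped(sid) == seqs[sid]
    return out


# ---------------------------------------------------------------------------
# motif-anchored trimming
# ---------------------------------------------------------------------------


def _motif_positions(degapped: str, motif: str) -> list:
    return [i for i in range(len(degapped) - len(motif) + 1)
            if degapped.startswith(motif, i)]


def trim_to_anchors(aln: Alignment, reference_id: str, start_motif: str,
                    end_motif: str) -> Alignment:
    """Keep columns from the start motif's first residue through the end
    motif's last residue of the reference row, inclusive."""
    if reference_id not in aln.rows:
        raise ValueError(f"reference row {reference_id!r} not in alignment")
    ref = aln.rows[reference_id]
    degapped = ref.replace("-", "")
    pos_s = _motif_positions(degapped, start_motif)
    pos_e = _motif_positions(degapped, end_motif)
    for motif, pos in ((start_motif, pos_s), (end_motif, pos_e)):
        if len(pos) == 0:
            raise ValueError(f"motif {motif!r} absent from reference {reference_id!r}")
        if len(pos) > 1:
            raise ValueError(f"motif {motif!r} occurs {len(pos)} times in reference")
    start_res = pos_s[0]
    end_res = pos_e[0] + len(end_motif) - 1
    if start_res >= end_res:
        raise ValueError(
            f"start motif {start_motif!r} does not precede end motif {end_motif!r}"
        )
    res_to_col = [i for i, c in enumerate(ref) if c != "-"]
    c0, c1 = res_to_col[start_res], res_to_col[end_res]
    rows = {sid: row[c0 : c1 + 1] for sid, row in aln.rows.items()}
    return Alignment(rows, anchors=(start_motif, end_motif))
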