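"""Domain-cassette detection and architecture classification.

Profile-HMM search against a curated domain database is replaced by
position-specific scoring matrices (PSSMs) built from seed alignments, with
score cutoffs calibrated on shuffled decoys: the cutoff is the score
quantile at which a configurable fraction (default 1%) of decoy best-window
scores would be accepted - the operative surrogate for an E-value threshold
of 0.01. Class labels implement the channel-subunit architecture logic:
A-type subunits carry an ion-transport domain plus a cyclic-nucleotide
binding domain (with or without a C-terminal leucine zipper, CLZ), B-type
subunits carry the cNMP-binding domain alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthgenome import AA, _AA_IDX, default_cassettes, evolve_sequence

ALPHABET = AA  # 20 residues; X scores 0 everywhere


@dataclass
class DomainModel:
    name: str
    pssm: np.ndarray  # length x 21 log-odds (bits); column 20 is X/unknown
    length: int
    score_cutoff: float

    def __post_init__(self):
        if self.length < 5:
            raise ValueError("domain model shorter than 5 columns")
        if not np.isfinite(self.score_cutoff):
            raise ValueError("non-finite cutoff")


@dataclass(frozen=True)
class DomainHit:
    name: str
    start: int
    end: int
    score: float


@dataclass
class Architecture:
    """Ordered non-overlapping domain hits plus the class label."""

    hits: list
    label: str  # A-like-with-CLZ | A-like-no-CLZ | B-like | other

    def has(self, name: str) -> bool:
        return any(h.name == name for h in self.hits)


def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_IDX.get(c, 20) for c in seq], dtype=np.int64)


def _window_scores(model_pssm: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Score of every alignment window of the model along the sequence."""
    L = model_pssm.shape[0]
    n = idx.size - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for i in range(L):
        scores += model_pssm[i, idx[i : i + n]]
    return scores


def build_pssm(seed_alignment: dict, name: str, quantile: float = 0.01,
               n_decoys: int = 1000, rng=None) -> DomainModel:
    """Per-column log-odds versus a uniform background with +1 pseudocount.

    The cutoff is calibrated as the (1 - quantile) quantile of best-window
    scores on shuffled composition-matched decoys, so about ``quantile`` of
    random sequences score at or above it.
    """
    if not seed_alignment:
        raise ValueError("empty seed alignment")
    rng = np.random.default_rng(0) if rng is None else rng
    rows = list(seed_alignment.values())
    ncol_all = len(rows[0])
    if any(len(r) != ncol_all for r in rows):
        raise ValueError("seed alignment rows differ in length")
    cols = [j for j in range(ncol_all) if all(r[j] != "-" for r in rows)]
    if len(cols) < 5:
        raise ValueError("fewer than 5 ungapped columns in seed alignment")
    n = len(rows)
    counts = np.ones((len(cols), 20))  # +1 pseudocount
    for r in rows:
        for i, j in enumerate(cols):
            a = _AA_IDX.get(r[j])
            if a is not None:
                counts[i, a] += 1
    freqs = counts / (n + 20)
    pssm = np.zeros((len(cols), 21))
    pssm[:, :20] = np.log2(freqs / (1 / 20))

    # decoys: shuffled residues drawn from the seed residue pool, 3x length
    pool = np.array(
        [_AA_IDX[c] for r in rows for c in r if c in _AA_IDX], dtype=np.int64
    )
    best = np.empty(n_decoys)
    for k in range(n_decoys):
        decoy = pool[rng.integers(0, pool.size, size=3 * len(cols))]
        best[k] = _window_scores(pssm, decoy).max()
    cutoff = float(np.quantile(best, 1 - quantile, method="higher"))
    return DomainModel(name, pssm, len(cols), cutoff)


def _classify(hit_names: set) -> str:
    has_ion = "Ion_trans-like" in hit_names
    has_cnmp = "cNMP_binding-like" in hit_names
    has_clz = "CLZ-like" in hit_names
    if has_ion and has_cnmp:
        return "A-like-with-CLZ" if has_clz else "A-like-no-CLZ"
    if has_cnmp:
        return "B-like"
    return "other"


def scan(sequence: str, models: list) -> Architecture:
    """Best non-overlapping hit set, greedy by score then leftmost start.

    All windows at or above each model's cutoff are candidates; the greedy
    order (score desc, start asc, model name asc) makes the scan
    deterministic.
    """
    idx = _encode(sequence)
    candidates = []
    for m in sorted(models, key=lambda m: m.name):
        scores = _window_scores(m.pssm, idx)
        # a hit must clear the decoy-calibrated cutoff AND the background:
        # non-positive log-odds (e.g. all-unknown windows) never count
        for s in np.flatnonzero((scores >= m.score_cutoff) & (scores > 0)):
            candidates.append(DomainHit(m.name, int(s), int(s) + m.length, float(scores[s])))
    candidates.sort(key=lambda h: (-h.score, h.start, h.name))
    chosen: list[DomainHit] = []
    for h in candidates:
        if all(h.end <= c.start or h.start >= c.end for c in chosen):
            chosen.append(h)
    chosen.sort(key=lambda h: h.start)
    return Architecture(chosen, _classify({h.name for h in chosen}))


def cooccurrence_check(architectures_by_taxon: dict):
    """Check the CLZ co-occurrence rule across taxa.

    A taxon violates the rule iff it has a B-like gene while lacking any
    A-like gene with a CLZ domain (groups with B-type channel genes are
    expected to also have CLZ-bearing A-type genes). Returns (per-taxon
    report, global boolean = no violations).
    """
    report = {}
    for taxon in sorted(architectures_by_taxon):
        archs = architectures_by_taxon[taxon]
        labels = [a.label for a in archs]
        has_b = "B-like" in labels
        has_a_clz = "A-like-with-CLZ" in labels
        report[taxon] = {
            "has_b_like": has_b,
            "has_a_like_with_clz": has_a_clz,
            "violation": has_b and not has_a_clz,
        }
    return report, not any(r["violation"] for r in report.values())


_MODEL_NAMES = {"ion_trans": "Ion_trans-like", "cnmp": "cNMP_binding-like",
                "clz": "CLZ-like"}


def seed_alignments(n_seqs: int = 8, divergence: float = 0.1, seed: int = 7) -> dict:
    """Seed alignments for the packaged cassette models, derived from the
    simulator's cassette consensus definitions (ungapped: the cassettes are
    fixed-length blocks)."""
    rng = np.random.default_rng([seed, 0xD0])
    out = {}
    for cname, cas in default_cassettes().items():
        mask = cas.mask()
        rows = {
            f"{cname}_{i}": evolve_sequence(cas.consensus, divergence, rng, mask)
            for i in range(n_seqs)
        }
        out[_MODEL_NAMES[cname]] = rows
    return out


def default_models(quantile: float = 0.01, n_decoys: int = 1000) -> list:
    """The three packaged domain models (deterministic)."""
    rng = np.random.default_rng(0xD031)
    return [
        build_pssm(rows, name, quantile=quantile, n_decoys=n_decoys, rng=rng)
        for name, rows in seed_alignments().items()
    ]
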