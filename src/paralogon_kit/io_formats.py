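"""Readers and writers for the flat formats the pipeline exchanges.

Gene annotations travel as GFF3 gene lines (1-based inclusive on disk,
0-based half-open in memory), BED is accepted on input only, trees as Newick
with dual node supports encoded as ``a/b`` internal labels, sequences as
FASTA. Parsers reject malformed input rather than silently repairing it.
"""

from __future__ import annotations

import logging
import re
import sys
import time
from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from io import StringIO
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

logger = logging.getLogger("paralogon_kit")
if not logger.handlers:  # stderr logging with per-stage timers
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(asctime)s] %(message)s", "%H:%M:%S"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@contextmanager
def stage_timer(stage: str):
    """Log wall time of a pipeline stage to stderr."""
    t0 = time.perf_counter()
    logger.info("stage %s: start", stage)
    yield
    logger.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)


class ParserError(ValueError):
    """Malformed input file; message carries the offending line number."""


STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GeneLocus:
    """A gene's position: 0-based half-open internally."""

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and self.end > start

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# GFF3 (gene lines only) and BED
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r"([^=;]+)=([^;]*)")


def _parse_attrs(s: str) -> dict:
    return {m.group(1).strip(): m.group(2) for m in _ATTR_RE.finditer(s)}


def read_gff3(path, species: str | None = None) -> list[GeneLocus]:
    """Read gene-type features from a GFF3 file.

    File coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention. Malformed lines raise :class:`ParserError`
    with the line number.
    """
    loci, _ = read_gff3_with_attrs(path, species)
    return loci


def read_gff3_with_attrs(path, species: str | None = None):
    """Like :func:`read_gff3` but also return per-gene attribute dicts."""
    path = Path(path)
    loci: list[GeneLocus] = []
    attrs_by_gene: dict[str, dict] = {}
    sp = species if species is not None else path.stem
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParserError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParserError(f"{path}:{lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise ParserError(f"{path}:{lineno}: end < start")
            attrs = _parse_attrs(attr_s)
            if "ID" not in attrs:
                raise ParserError(f"{path}:{lineno}: gene feature without ID attribute")
            if strand not in STRANDS:
                raise ParserError(f"{path}:{lineno}: bad strand {strand!r}")
            gid = attrs["ID"]
            loci.append(GeneLocus(gid, sp, seqid, start1 - 1, end1, strand))
            attrs_by_gene[gid] = attrs
    ids = [l.gene_id for l in loci]
    if len(set(ids)) != len(ids):
        dup = sorted({g for g in ids if ids.count(g) > 1})
        raise ParserError(f"{path}: duplicate gene IDs {dup}")
    return loci, attrs_by_gene


def write_gff3(loci, path, attrs: dict[str, dict] | None = None) -> None:
    """Write gene lines; internal 0-based half-open -> 1-based inclusive."""
    attrs = attrs or {}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for l in loci:
            extra = "".join(
                f";{k}={v}" for k, v in sorted(attrs.get(l.gene_id, {}).items()) if k != "ID"
            )
            fh.write(
                f"{l.chromosome}\tparalogon_kit\tgene\t{l.start + 1}\t{l.end}\t.\t"
                f"{l.strand}\t.\tID={l.gene_id}{extra}\n"
            )


def read_bed(path, species: str | None = None) -> list[GeneLocus]:
    """Read a BED file (already 0-based half-open; input only)."""
    path = Path(path)
    sp = species if species is not None else path.stem
    loci = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ParserError(f"{path}:{lineno}: BED needs >= 4 columns for gene ids")
            chrom, start_s, end_s, name = cols[:4]
            strand = cols[5] if len(cols) >= 6 else "+"
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParserError(f"{path}:{lineno}: non-integer coordinates") from None
            if end <= start:
                raise ParserError(f"{path}:{lineno}: end <= start")
            loci.append(GeneLocus(name, sp, chrom, start, end, strand))
    return loci


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read a protein FASTA into an id -> sequence mapping (order preserved)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParserError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Newick trees with dual supports
# ---------------------------------------------------------------------------

_SUPPORT_RE = re.compile(r"^(\d+(?:\.\d+)?)(?:/(\d+(?:\.\d+)?))?$")


@dataclass
class SupportedTree:
    """A tree whose internal nodes may carry a pair of support percentages.

    ``support_a`` is the half-sample support (the aLRT stand-in) and
    ``support_b`` the classical bootstrap support; both live in [0, 100].
    Serialized as slash-separated internal labels (``(A,B)95/99``), the
    convention of standard tree viewers.
    """

    tree: TreeNode

    def __post_init__(self):
        for n in self.tree.non_tips(include_self=False):
            for attr in ("support_a", "support_b"):
                if not hasattr(n, attr):
                    setattr(n, attr, None)
                v = getattr(n, attr)
                if v is not None and not (0 <= v <= 100):
                    raise ValueError(f"support out of [0,100]: {v}")
        tips = [t.name for t in self.tree.tips()]
        if len(set(tips)) != len(tips):
            raise ValueError("leaf labels not unique")

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def copy(self) -> "SupportedTree":
        return SupportedTree(
            self.tree.copy()
            if not hasattr(self.tree, "deepcopy")
            else self.tree.copy()
        )

    def support_pair(self, node: TreeNode):
        return (getattr(node, "support_a", None), getattr(node, "support_b", None))


def _label_to_supports(tree: TreeNode) -> None:
    for n in tree.non_tips(include_self=False):
        n.support_a = None
        n.support_b = None
        if n.name:
            m = _SUPPORT_RE.match(n.name)
            if m:
                a = float(m.group(1))
                b = float(m.group(2)) if m.group(2) is not None else a
                n.support_a, n.support_b = a, b
                n.name = None


def _supports_to_label(tree: TreeNode) -> None:
    def fmt(v):
        return f"{v:g}"

    for n in tree.non_tips(include_self=False):
        a = getattr(n, "support_a", None)
        b = getattr(n, "support_b", None)
        if a is not None and b is not None and not n.name:
            n.name = f"{fmt(a)}/{fmt(b)}"


def parse_newick(text: str) -> SupportedTree:
    try:
        tree = TreeNode.read(StringIO(text))
    except Exception as exc:  # skbio raises several parse error types
        raise ParserError(f"Newick parse error: {exc}") from exc
    _label_to_supports(tree)
    return SupportedTree(tree)


def read_newick(path) -> SupportedTree:
    return parse_newick(Path(path).read_text())


def to_newick(st: SupportedTree) -> str:
    tree = st.tree.copy()
    _supports_to_label(tree)
    buf = StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def write_newick(st: SupportedTree, path) -> None:
    Path(path).write_text(to_newick(st) + "\n")


# ---------------------------------------------------------------------------
# YAML config
# ---------------------------------------------------------------------------


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParserError(f"{path}: expected a mapping at top level")
    return data
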