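"""Gene annotation parsing and exhaustive genomic category maps.

Every base of the genome is assigned to exactly one of seven gene-relative
categories -- exon, intron, 5' near, 3' near, 5' far, 3' far, distant --
by flattening a gene annotation under a fixed precedence order.  "Near" and
"far" flanks are measured from the 5' end (transcription start) and 3' end
(transcription end) of each gene, in the gene's own orientation, with
user-settable limits (defaults 5 kb and 25 kb).

All coordinates are 0-based half-open throughout; GTF/GFF3 input (1-based
inclusive) is converted on read.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import gffutils
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

DEFAULT_NEAR_LIMIT = 5_000
DEFAULT_FAR_LIMIT = 25_000


class Category(str, Enum):
    """The seven mutually exclusive genomic categories.

    Declaration order is precedence order (highest first): a base inside an
    exon and also within the 5' flank of a neighbouring gene is an exon.
    """

    EXON = "exon"
    INTRON = "intron"
    FIVE_NEAR = "five_near"
    THREE_NEAR = "three_near"
    FIVE_FAR = "five_far"
    THREE_FAR = "three_far"
    DISTANT = "distant"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Categories from highest to lowest precedence.
CATEGORY_ORDER: tuple[Category, ...] = tuple(Category)


def merge_intervals(intervals):
    """Union of 0-based half-open intervals, returned sorted and disjoint."""
    out = []
    for s, e in sorted(intervals):
        if s >= e:
            continue
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


@dataclass
class GeneModel:
    """A single gene: strand, span, and exon-union structure.

    All transcripts of a gene are merged into one model whose exons are the
    union of the transcripts' exons and whose span covers them.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list = field(default_factory=list)
    biotype: str | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = merge_intervals(self.exons)
        if self.exons[0][0] < self.start or self.exons[-1][1] > self.end:
            raise ValueError(f"gene {self.gene_id}: exons outside gene span")

    @property
    def tss(self) -> int:
        """Coordinate of the 5' end (transcription start)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Coordinate of the 3' end (transcription end)."""
        return self.end if self.strand == "+" else self.start

    @property
    def span_length(self) -> int:
        return self.end - self.start


@dataclass
class ElementTrack:
    """A named set of genomic intervals (CpG islands, ESTs, ...)."""

    name: str
    intervals: dict = field(default_factory=dict)  # chrom -> sorted [(s, e)]
    _trees: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.intervals = {
            c: merge_intervals(iv) for c, iv in self.intervals.items()
        }
        self._trees = {
            c: IntervalTree.from_tuples(iv)
            for c, iv in self.intervals.items()
            if iv
        }

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) shares >= 1 base with any track interval."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))


@dataclass
class CategoryMap:
    """Exhaustive single-category-per-base partition of a genome.

    ``runs[chrom]`` is a sorted list of ``(start, end, Category)`` tiles that
    covers ``[0, chrom_length)`` exactly, with no gaps or overlaps.
    """

    chrom_lengths: dict
    runs: dict
    near_limit: int
    far_limit: int
    _starts: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._starts = {c: [r[0] for r in rs] for c, rs in self.runs.items()}

    @property
    def chromosomes(self):
        return list(self.runs)

    def category_at(self, chrom: str, pos: int) -> Category:
        """Category of a single base position."""
        if chrom not in self.runs:
            raise KeyError(chrom)
        if not 0 <= pos < self.chrom_lengths[chrom]:
            raise ValueError(
                f"position {pos} outside {chrom} [0, {self.chrom_lengths[chrom]})"
            )
        i = bisect.bisect_right(self._starts[chrom], pos) - 1
        return self.runs[chrom][i][2]

    def category_bp(self) -> dict:
        """Total genomic bp per category."""
        totals = {c: 0 for c in Category}
        for rs in self.runs.values():
            for s, e, cat in rs:
                totals[cat] += e - s
        return totals


def _flank_intervals(gene: GeneModel, near: int, far: int):
    """Candidate flank intervals for one gene, keyed by category.

    Flanks are oriented: 5' flanks extend upstream of the TSS (lower
    coordinates on '+', higher on '-'), 3' flanks downstream of the TES.
    """
    if gene.strand == "+":
        return {
            Category.FIVE_NEAR: (gene.tss - near, gene.tss),
            Category.FIVE_FAR: (gene.tss - far, gene.tss - near),
            Category.THREE_NEAR: (gene.tes, gene.tes + near),
            Category.THREE_FAR: (gene.tes + near, gene.tes + far),
        }
    return {
        Category.FIVE_NEAR: (gene.tss, gene.tss + near),
        Category.FIVE_FAR: (gene.tss + near, gene.tss + far),
        Category.THREE_NEAR: (gene.tes - near, gene.tes),
        Category.THREE_FAR: (gene.tes - far, gene.tes - near),
    }


def flatten_categories(
    genes,
    near_limit: int = DEFAULT_NEAR_LIMIT,
    far_limit: int = DEFAULT_FAR_LIMIT,
    chrom_lengths: dict | None = None,
) -> CategoryMap:
    """Flatten gene models into an exhaustive per-base category partition.

    Overlapping annotations are resolved purely by category precedence
    (exon > intron > 5' near > 3' near > 5' far > 3' far > distant);
    within one tier, membership from any gene suffices.  Flanks are clipped
    at chromosome boundaries.

    When ``chrom_lengths`` is not given, each chromosome's length defaults
    to its maximum annotated coordinate plus ``far_limit`` so the partition
    stays well-defined.
    """
    if near_limit <= 0:
        raise ValueError("near_limit must be positive")
    if near_limit > far_limit:
        raise ValueError("near_limit must not exceed far_limit")

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    if chrom_lengths is None:
        chrom_lengths = {
            c: max(g.end for g in gs) + far_limit for c, gs in by_chrom.items()
        }
    else:
        chrom_lengths = dict(chrom_lengths)
        for c, gs in by_chrom.items():
            hi = max(g.end for g in gs)
            if c not in chrom_lengths:
                chrom_lengths[c] = hi + far_limit
            elif hi > chrom_lengths[c]:
                raise ValueError(f"gene beyond stated length of {c}")

    runs: dict[str, list] = {}
    for chrom, length in chrom_lengths.items():
        cand: dict[Category, list] = {c: [] for c in CATEGORY_ORDER[:-1]}
        for g in by_chrom.get(chrom, []):
            cand[Category.EXON].extend(g.exons)
            cand[Category.INTRON].append((g.start, g.end))
            for cat, (s, e) in _flank_intervals(g, near_limit, far_limit).items():
                cand[cat].append((max(0, s), min(length, e)))
        merged = {c: merge_intervals(iv) for c, iv in cand.items()}
        starts = {c: [s for s, _ in iv] for c, iv in merged.items()}

        breaks = {0, length}
        for iv in merged.values():
            for s, e in iv:
                breaks.add(s)
                breaks.add(e)
        edges = sorted(b for b in breaks if 0 <= b <= length)

        chrom_runs = []
        for s, e in zip(edges, edges[1:]):
            label = Category.DISTANT
            for cat in CATEGORY_ORDER[:-1]:
                idx = bisect.bisect_right(starts[cat], s) - 1
                if idx >= 0 and s < merged[cat][idx][1]:
                    label = cat
                    break
            if chrom_runs and chrom_runs[-1][2] is label:
                chrom_runs[-1] = (chrom_runs[-1][0], e, label)
            else:
                chrom_runs.append((s, e, label))
        runs[chrom] = chrom_runs

    return CategoryMap(
        chrom_lengths=chrom_lengths,
        runs=runs,
        near_limit=near_limit,
        far_limit=far_limit,
    )


# ---------------------------------------------------------------------------
# parsing


def _parse_bed12(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                log.warning("%s:%d: not BED12, skipped", path, ln)
                continue
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                nblocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                if len(sizes) != nblocks or len(offsets) != nblocks:
                    raise ValueError("blockCount mismatch")
                exons = [
                    (start + o, start + o + s) for o, s in zip(offsets, sizes)
                ]
                genes.append(
                    GeneModel(
                        gene_id=name, chrom=chrom, start=start, end=end,
                        strand=strand, exons=exons,
                    )
                )
            except (ValueError, IndexError) as exc:
                log.warning("%s:%d: rejected (%s)", path, ln, exc)
    return genes


def _gene_id_of_exon(db, feat):
    """Gene identifier for an exon feature (GTF attribute or GFF3 parent walk)."""
    if "gene_id" in feat.attributes:
        return feat.attributes["gene_id"][0]
    node = feat
    while True:
        parents = list(db.parents(node, level=1))
        if not parents:
            return node.id
        gene_parents = [p for p in parents if p.featuretype == "gene"]
        node = gene_parents[0] if gene_parents else parents[0]
        if node.featuretype == "gene":
            return node.id


def _parse_gff_like(path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=False,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_gene: dict[str, dict] = {}
    for ex in db.features_of_type("exon"):
        gid = _gene_id_of_exon(db, ex)
        rec = per_gene.setdefault(
            gid, {"chroms": set(), "strands": set(), "exons": [], "biotype": None}
        )
        rec["chroms"].add(ex.seqid)
        rec["strands"].add(ex.strand)
        rec["exons"].append((ex.start - 1, ex.end))  # to 0-based half-open
        for key in ("gene_biotype", "biotype", "gene_type"):
            if key in ex.attributes:
                rec["biotype"] = ex.attributes[key][0]
                break

    genes = []
    for gid, rec in per_gene.items():
        if len(rec["chroms"]) > 1 or len(rec["strands"]) > 1:
            log.warning(
                "gene %s spans multiple chromosomes/strands; record rejected", gid
            )
            continue
        strand = next(iter(rec["strands"]))
        if strand not in ("+", "-"):
            log.warning("gene %s has no usable strand; record rejected", gid)
            continue
        exons = merge_intervals(rec["exons"])
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=next(iter(rec["chroms"])),
                start=exons[0][0],
                end=exons[-1][1],
                strand=strand,
                exons=exons,
                biotype=rec["biotype"],
            )
        )
    return genes


def parse_gene_models(path, fmt: str | None = None) -> list[GeneModel]:
    """Parse gene models from GTF, GFF3 or BED12.

    Transcripts sharing a gene are merged: the model's exons are the union
    of all transcript exons and its span is the union span.  A gene whose
    exons fall on multiple chromosomes or strands is rejected with a logged
    warning.  ``fmt`` may be ``gtf``, ``gff3`` or ``bed12``; when omitted it
    is inferred from the file extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        ext = path.suffix.lower()
        fmt = {".gtf": "gtf", ".gff3": "gff3", ".gff": "gff3", ".bed": "bed12"}.get(ext)
        if fmt is None:
            raise ValueError(f"cannot infer annotation format from {path.name!r}")
    fmt = fmt.lower()
    if fmt == "bed12":
        return _parse_bed12(path)
    if fmt in ("gtf", "gff3"):
        return _parse_gff_like(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def load_element_track(path, name: str) -> ElementTrack:
    """Load an element track (CpG islands, ESTs, ...) from a BED file."""
    intervals: dict[str, list] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) == 1:
                f = line.split()
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                if start >= end:
                    raise ValueError("start >= end")
            except (ValueError, IndexError) as exc:
                log.warning("%s:%d: rejected (%s)", path, ln, exc)
                continue
            intervals.setdefault(chrom, []).append((start, end))
    return ElementTrack(name=name, intervals=intervals)


def read_chrom_sizes(path) -> dict:
    """Read a two-column (name, length) chromosome-sizes file."""
    sizes = {}
    with open(path) as fh:
        for line in fh:
            f = line.split()
            if len(f) >= 2:
                sizes[f[0]] = int(f[1])
    return sizes
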