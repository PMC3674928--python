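"""Per-locus genomic context: category, nearest gene, signed distances.

A locus is categorised at its midpoint, ``floor((start + end) / 2)``, which
keeps the seven categories mutually exclusive even for wide peaks.  Signed
distances to the nearest gene's 5' and 3' ends are measured along the gene's
orientation: positive means the midpoint lies 3'-ward (downstream, in the
direction of transcription) of that end, negative means upstream of it.
Inside a gene the 5' distance is therefore >= 0 and the 3' distance <= 0,
and their difference always equals the gene's span length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from pyfaidx import Fasta

from .annotation import Category, CategoryMap, ElementTrack, GeneModel

log = logging.getLogger(__name__)

DEFAULT_HIST_RANGE = (-100_000, 100_000)
DEFAULT_HIST_BIN = 5_000


@dataclass
class Locus:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"locus {self.chrom}:{self.start}-{self.end}: start must be < end")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class LocusContext:
    """A locus with its genomic-context annotation."""

    locus: Locus
    midpoint: int
    category: Category
    nearest_gene_id: str | None = None
    dist_to_5prime: int | None = None
    dist_to_3prime: int | None = None
    nearest_gene_strand: str | None = None
    element_flags: dict = field(default_factory=dict)


@dataclass
class CategoryDistribution:
    """Counts of loci over the seven categories."""

    counts: dict
    total: int
    label: str = ""

    def __post_init__(self):
        self.counts = {c: int(self.counts.get(c, 0)) for c in Category}
        if self.total != sum(self.counts.values()):
            raise ValueError("total does not match category counts")

    @classmethod
    def from_counts(cls, counts, label: str = "") -> "CategoryDistribution":
        counts = {c: int(counts.get(c, 0)) for c in Category}
        return cls(counts=counts, total=sum(counts.values()), label=label)

    def freq(self, cat: Category) -> float:
        return self.counts[cat] / self.total if self.total else 0.0


@dataclass
class DistanceHistogram:
    end: str  # "5prime" or "3prime"
    bin_edges: list
    counts: list
    n_out_of_range: int


def categorize(locus: Locus, cmap: CategoryMap) -> Category:
    """Category of the locus midpoint.

    A locus on a chromosome absent from the map is reported distant, with a
    logged warning, rather than dropped.
    """
    if locus.chrom not in cmap.runs:
        log.warning(
            "locus %s:%d-%d on chromosome absent from annotation; counted as distant",
            locus.chrom, locus.start, locus.end,
        )
        return Category.DISTANT
    if locus.midpoint >= cmap.chrom_lengths[locus.chrom]:
        # beyond the mapped extent: farther than far_limit from every gene
        return Category.DISTANT
    return cmap.category_at(locus.chrom, locus.midpoint)


def _span_distance(m: int, gene: GeneModel) -> int:
    """Unsigned bp distance from a midpoint to a gene span (0 inside)."""
    if m < gene.start:
        return gene.start - m
    if m >= gene.end:
        return m - gene.end
    return 0


def signed_end_distances(m: int, gene: GeneModel) -> tuple[int, int]:
    """Signed distances from midpoint ``m`` to the gene's 5' and 3' ends.

    Positive = 3'-ward of the end in gene orientation; negative = upstream.
    """
    if gene.strand == "+":
        return m - gene.tss, m - gene.tes
    return gene.tss - m, gene.tes - m


class GeneIndex:
    """Per-chromosome index of gene models for nearest-gene queries.

    The nearest gene minimises the unsigned distance from the query midpoint
    to the gene *span* (0 when the midpoint lies inside the gene).  Ties are
    broken deterministically: smallest gene start, then lexicographic
    gene_id.
    """

    def __init__(self, genes):
        self.genes = list(genes)
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for c, gs in self._by_chrom.items():
            gs.sort(key=lambda g: (g.start, g.gene_id))

    def nearest(self, chrom: str, m: int) -> GeneModel | None:
        gs = self._by_chrom.get(chrom)
        if not gs:
            return None
        best = min(
            gs, key=lambda g: (_span_distance(m, g), g.start, g.gene_id)
        )
        return best

    def tss_count(self, chrom: str, lo: int, hi: int) -> int:
        """Number of gene 5' ends with coordinate in [lo, hi] (inclusive)."""
        gs = self._by_chrom.get(chrom, [])
        return sum(1 for g in gs if lo <= g.tss <= hi)


def nearest_gene_context(
    locus: Locus,
    genes,
    cmap: CategoryMap,
    tracks: list[ElementTrack] | None = None,
    index: GeneIndex | None = None,
) -> LocusContext:
    """Full genomic context of one locus.

    ``genes`` may be a list of :class:`GeneModel` or a prebuilt
    :class:`GeneIndex` (pass via ``index`` to reuse across loci).  When the
    locus chromosome carries no genes the gene-related fields are ``None``.
    """
    idx = index if index is not None else GeneIndex(genes)
    m = locus.midpoint
    cat = categorize(locus, cmap)
    gene = idx.nearest(locus.chrom, m)
    flags = {
        t.name: t.overlaps(locus.chrom, locus.start, locus.end)
        for t in (tracks or [])
    }
    if gene is None:
        if idx.genes:
            log.warning(
                "no genes on chromosome %s; nearest-gene fields left empty",
                locus.chrom,
            )
        return LocusContext(
            locus=locus, midpoint=m, category=cat, element_flags=flags
        )
    d5, d3 = signed_end_distances(m, gene)
    return LocusContext(
        locus=locus,
        midpoint=m,
        category=cat,
        nearest_gene_id=gene.gene_id,
        dist_to_5prime=d5,
        dist_to_3prime=d3,
        nearest_gene_strand=gene.strand,
        element_flags=flags,
    )


def annotate_loci(loci, genes, cmap, tracks=None) -> list[LocusContext]:
    """Contexts for a list of loci, sharing one gene index."""
    idx = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return [
        nearest_gene_context(l, idx.genes, cmap, tracks=tracks, index=idx)
        for l in loci
    ]


def summarize(contexts, label: str = "") -> CategoryDistribution:
    """Category counts of a locus set."""
    counts = {c: 0 for c in Category}
    for ctx in contexts:
        counts[ctx.category] += 1
    return CategoryDistribution(counts=counts, total=len(contexts), label=label)


def distance_histogram(
    contexts,
    end: str = "5prime",
    bin_width: int = DEFAULT_HIST_BIN,
    hist_range: tuple[int, int] = DEFAULT_HIST_RANGE,
) -> DistanceHistogram:
    """Histogram of signed distances to gene 5' or 3' ends.

    Bins are half-open ``[edge, edge + bin_width)``; distances at or beyond
    the upper range bound, below the lower bound, or undefined (no nearest
    gene) are tallied out of range.
    """
    if end not in ("5prime", "3prime"):
        raise ValueError("end must be '5prime' or '3prime'")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = hist_range
    if lo >= hi:
        raise ValueError("invalid histogram range")
    edges = [lo]
    while edges[-1] < hi:
        edges.append(min(edges[-1] + bin_width, hi))
    attr = "dist_to_5prime" if end == "5prime" else "dist_to_3prime"
    dists = [
        getattr(c, attr) for c in contexts if getattr(c, attr) is not None
    ]
    in_range = [d for d in dists if lo <= d < hi]
    counts, _ = np.histogram(in_range, bins=edges)
    return DistanceHistogram(
        end=end,
        bin_edges=edges,
        counts=counts.tolist(),
        n_out_of_range=len(dists) - len(in_range),
    )


def tss_in_window(locus: Locus, genes, window: int, index: GeneIndex | None = None) -> int:
    """Number of gene 5' ends within +/- window bp of the locus midpoint."""
    if window < 0:
        raise ValueError("window must be non-negative")
    idx = index if index is not None else GeneIndex(genes)
    m = locus.midpoint
    return idx.tss_count(locus.chrom, m - window, m + window)


def overlap_elements(locus: Locus, tracks) -> dict:
    """Per-track boolean overlap flags for one locus."""
    return {t.name: t.overlaps(locus.chrom, locus.start, locus.end) for t in tracks}


def extract_sequences(loci, fasta_path) -> list[tuple[Locus, str]]:
    """Reference sequence of each locus; reverse-complemented on '-' strand."""
    ref = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=False)
    out = []
    for locus in loci:
        if locus.chrom not in ref:
            raise KeyError(f"chromosome {locus.chrom!r} not in reference")
        chrom_len = len(ref[locus.chrom])
        if locus.end > chrom_len:
            raise ValueError(
                f"locus {locus.chrom}:{locus.start}-{locus.end} beyond "
                f"sequence end ({chrom_len})"
            )
        seq = ref[locus.chrom][locus.start:locus.end]
        if locus.strand == "-":
            seq = _revcomp(seq)
        out.append((locus, str(seq)))
    return out


_COMP = str.maketrans("ACGTacgtNnRYKMrykm", "TGCAtgcaNnYRMKyrmk")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
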