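"""Seeded synthetic annotations and locus sets with known category structure.

The generator emulates a small genome with strand-annotated multi-exon
genes, written as Ensembl-dialect GTF, and locus sets drawn category-first:
a category is sampled from a target probability vector, then a base is
sampled uniformly within that category's territory, so each generated locus
categorises exactly as drawn.  All randomness flows from a single explicit
seed and outputs are byte-identical across runs with the same spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import CATEGORY_ORDER, Category, CategoryMap, GeneModel
from .context import Locus

#: Default target category mix, loosely shaped like a TF ChIP peak set:
#: gene-body heavy with a promoter-proximal component and an intergenic tail.
DEFAULT_CATEGORY_PROBS = {
    Category.EXON: 0.10,
    Category.INTRON: 0.35,
    Category.FIVE_NEAR: 0.12,
    Category.THREE_NEAR: 0.08,
    Category.FIVE_FAR: 0.10,
    Category.THREE_FAR: 0.07,
    Category.DISTANT: 0.18,
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic genome, annotation and locus sets."""

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (2, 6)
    gene_length: tuple[int, int] = (2_000, 20_000)
    target_category_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS)
    )
    n_loci: int = 2_000
    locus_halfwidth: int = 25
    seed: int = 0

    def probs_vector(self) -> np.ndarray:
        p = np.array(
            [float(self.target_category_probs.get(c, 0.0)) for c in CATEGORY_ORDER]
        )
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
            raise ValueError("category probabilities must be non-negative and sum to 1")
        return p / p.sum()

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_lengths(self) -> dict:
        return {c: self.chrom_length for c in self.chrom_names()}


def _place_gene(rng, occupied, length, chrom_length, max_tries=200):
    """Uniform non-overlapping placement of one gene span; None if it won't fit."""
    for _ in range(max_tries):
        start = int(rng.integers(0, chrom_length - length + 1))
        end = start + length
        if all(end <= s or start >= e for s, e in occupied):
            return start, end
    return None


def _make_exons(rng, start, end, n_exons):
    """Exon intervals partitioning [start, end): first starts at ``start``,
    last ends at ``end``, alternating exon/intron segments each >= 1 bp."""
    length = end - start
    n_cuts = 2 * (n_exons - 1)
    if n_cuts == 0:
        return [(start, end)]
    if length <= n_cuts + 1:
        return [(start, end)]
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_cuts, replace=False))
    bounds = [0, *cuts.tolist(), length]
    return [
        (start + bounds[i], start + bounds[i + 1])
        for i in range(0, len(bounds) - 1, 2)
    ]


def synth_genes(spec: SyntheticSpec) -> list[GeneModel]:
    """Generate non-overlapping multi-exon gene models per the spec."""
    lo_len, hi_len = spec.gene_length
    if hi_len > spec.chrom_length:
        raise ValueError("gene_length exceeds chrom_length; infeasible spec")
    rng = np.random.default_rng(spec.seed)
    chroms = spec.chrom_names()
    occupied = {c: [] for c in chroms}
    genes = []
    for i in range(spec.n_genes):
        chrom = chroms[i % len(chroms)]
        length = int(rng.integers(lo_len, hi_len + 1))
        placed = _place_gene(rng, occupied[chrom], length, spec.chrom_length)
        if placed is None:
            raise ValueError(
                f"could not place gene {i + 1}/{spec.n_genes}; infeasible spec"
            )
        start, end = placed
        occupied[chrom].append((start, end))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        n_exons = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        exons = _make_exons(rng, start, end, n_exons)
        genes.append(
            GeneModel(
                gene_id=f"SYNG{i + 1:04d}",
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                exons=exons,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gtf(genes, path) -> None:
    """Write gene models as Ensembl-dialect GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("#!genomecontext synthetic annotation\n")
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\tsynth\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tgene_id \"{g.gene_id}\";\n"
            )
            fh.write(
                f"{g.chrom}\tsynth\ttranscript\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tsynth\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def synth_annotation(spec: SyntheticSpec, out_dir) -> tuple[Path, Path]:
    """Generate and write a synthetic annotation: (GTF path, chrom-sizes path)."""
    from .io import write_chrom_sizes

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes = synth_genes(spec)
    gtf = out_dir / "annotation.gtf"
    sizes = out_dir / "chrom.sizes"
    write_gtf(genes, gtf)
    write_chrom_sizes(spec.chrom_lengths(), sizes)
    return gtf, sizes


def synth_loci(
    spec: SyntheticSpec,
    cmap: CategoryMap,
    rng: np.random.Generator | None = None,
    probs: dict | None = None,
) -> list[Locus]:
    """Sample loci category-first from a category map.

    For each locus a category is drawn from the target probabilities and a
    base sampled uniformly within that category's runs; the locus is written
    as the base +/- ``locus_halfwidth`` (shrunk symmetrically at chromosome
    edges so the midpoint is exactly the sampled base).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    if probs is not None:
        spec_probs = SyntheticSpec(
            target_category_probs=probs
        ).probs_vector()
    else:
        spec_probs = spec.probs_vector()

    runs_by_cat = {c: [] for c in CATEGORY_ORDER}
    for chrom, runs in cmap.runs.items():
        for s, e, cat in runs:
            runs_by_cat[cat].append((chrom, s, e))
    totals = {
        c: sum(e - s for _, s, e in rs) for c, rs in runs_by_cat.items()
    }
    for c, p in zip(CATEGORY_ORDER, spec_probs):
        if p > 0 and totals[c] == 0:
            raise ValueError(
                f"category {c.value} requested with probability {p} but absent "
                "from the category map"
            )

    cum = {}
    for c, rs in runs_by_cat.items():
        lengths = np.array([e - s for _, s, e in rs], dtype=np.int64)
        cum[c] = np.cumsum(lengths)

    loci = []
    # category counts are one multinomial draw; then positions uniform within
    # each category's territory
    n_per_cat = rng.multinomial(spec.n_loci, spec_probs)
    cats = [
        c for c, n in zip(CATEGORY_ORDER, n_per_cat) for _ in range(int(n))
    ]
    for i, cat in enumerate(cats):
        offset = int(rng.integers(0, totals[cat]))
        j = int(np.searchsorted(cum[cat], offset, side="right"))
        chrom, s, e = runs_by_cat[cat][j]
        prev = int(cum[cat][j - 1]) if j > 0 else 0
        base = s + (offset - prev)
        L = cmap.chrom_lengths[chrom]
        w = min(spec.locus_halfwidth, base, L - base)
        if w == 0:
            start, end = base, base + 1
        else:
            start, end = base - w, base + w
        loci.append(Locus(chrom=chrom, start=start, end=end, name=f"L{i:05d}"))
    return loci


def synth_locus_file(spec: SyntheticSpec, cmap: CategoryMap, path,
                     rng=None, probs=None) -> Path:
    """Generate loci and write them as BED."""
    from .io import write_bed

    loci = synth_loci(spec, cmap, rng=rng, probs=probs)
    write_bed(loci, path)
    return Path(path)
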