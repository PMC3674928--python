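import numpy as np
import pytest

from genomecontext import (
    CATEGORY_ORDER,
    Category,
    GeneModel,
    flatten_categories,
)
from genomecontext.synthetic import SyntheticSpec, synth_genes


@pytest.fixture
def toy_genes():
    """Two-gene toy annotation on a 10 kb chromosome.

    G1 forward, span [1000, 2000) with exons [1000, 1200) and [1800, 2000);
    G2 reverse, span [4000, 5000), single exon.
    """
    return [
        GeneModel("G1", "chr1", 1000, 2000, "+", [(1000, 1200), (1800, 2000)]),
        GeneModel("G2", "chr1", 4000, 5000, "-"),
    ]


@pytest.fixture
def toy_map(toy_genes):
    """Toy category map with near = 100 bp, far = 500 bp."""
    return flatten_categories(
        toy_genes, near_limit=100, far_limit=500, chrom_lengths={"chr1": 10_000}
    )


@pytest.fixture(scope="session")
def synth_setup():
    """A seeded synthetic annotation with its category map (near 1 kb, far 3 kb)."""
    spec = SyntheticSpec(seed=11)
    genes = synth_genes(spec)
    cmap = flatten_categories(
        genes, near_limit=1_000, far_limit=3_000, chrom_lengths=spec.chrom_lengths()
    )
    return spec, genes, cmap


def random_genes(rng, n_chroms=2, chrom_length=200_000, n_genes=12):
    """Small random annotation used by oracle-comparison property tests."""
    genes = []
    for i in range(n_genes):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        length = int(rng.integers(500, 20_000))
        start = int(rng.integers(0, chrom_length - length))
        end = start + length
        n_ex = int(rng.integers(1, 5))
        if n_ex == 1 or length < 4 * n_ex:
            exons = [(start, end)]
        else:
            cuts = np.sort(
                rng.choice(np.arange(1, length), size=2 * (n_ex - 1), replace=False)
            )
            bounds = [0, *cuts.tolist(), length]
            exons = [
                (start + bounds[j], start + bounds[j + 1])
                for j in range(0, len(bounds) - 1, 2)
            ]
        genes.append(
            GeneModel(
                f"R{i}", chrom, start, end,
                "+" if rng.integers(0, 2) == 0 else "-", exons,
            )
        )
    return genes


def brute_force_category(genes, chrom, pos, near, far):
    """Independent per-gene precedence scan: category of one base position."""
    best = Category.DISTANT
    order = {c: i for i, c in enumerate(CATEGORY_ORDER)}

    def consider(label):
        nonlocal best
        if order[label] < order[best]:
            best = label

    for g in genes:
        if g.chrom != chrom:
            continue
        if any(s <= pos < e for s, e in g.exons):
            consider(Category.EXON)
        if g.start <= pos < g.end:
            consider(Category.INTRON)
        if g.strand == "+":
            up = g.start - pos      # bp upstream of the 5' end
            down = pos - g.end + 1  # bp downstream of the 3' end
        else:
            up = pos - g.end + 1
            down = g.start - pos
        if 0 < up <= near:
            consider(Category.FIVE_NEAR)
        elif near < up <= far:
            consider(Category.FIVE_FAR)
        if 0 < down <= near:
            consider(Category.THREE_NEAR)
        elif near < down <= far:
            consider(Category.THREE_FAR)
    return best
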