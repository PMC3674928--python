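"""Reading locus files and writing tab-separated result tables.

BED input is read leniently: ``track``/``browser``/comment lines are
skipped and malformed data lines are rejected with a logged warning rather
than aborting the run.  All output tables are tab-separated with a single
header line starting with ``#``.
"""

from __future__ import annotations

import logging

from .annotation import CATEGORY_ORDER
from .compare import ComparisonReport, format_pvalue
from .context import CategoryDistribution, Locus

log = logging.getLogger(__name__)


def read_bed(path) -> list[Locus]:
    """Read loci from a 3-6 column BED file (0-based half-open kept as-is)."""
    loci = []
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
                name = f[3] if len(f) > 3 and f[3] != "." else None
                score = float(f[4]) if len(f) > 4 and f[4] != "." else None
                strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else None
            except (ValueError, IndexError) as exc:
                log.warning("%s:%d: rejected BED line (%s)", path, ln, exc)
                continue
            loci.append(
                Locus(chrom=chrom, start=start, end=end, name=name,
                      score=score, strand=strand)
            )
    if not loci:
        raise ValueError(f"no valid BED records in {path}")
    return loci


def write_bed(loci, path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            fields = [l.chrom, str(l.start), str(l.end)]
            if l.name is not None or l.score is not None or l.strand is not None:
                fields.append(l.name if l.name is not None else ".")
            if l.score is not None or l.strand is not None:
                fields.append(f"{l.score:g}" if l.score is not None else "0")
            if l.strand is not None:
                fields.append(l.strand)
            fh.write("\t".join(fields) + "\n")


def write_context_table(contexts, path, track_names=()) -> None:
    """Per-locus context table: coordinates, category, nearest gene, distances."""
    cols = [
        "chrom", "start", "end", "name", "category", "nearest_gene",
        "gene_strand", "dist_5prime", "dist_3prime", *track_names,
    ]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for c in contexts:
            row = [
                c.locus.chrom,
                str(c.locus.start),
                str(c.locus.end),
                c.locus.name or ".",
                c.category.value,
                c.nearest_gene_id or ".",
                c.nearest_gene_strand or ".",
                "." if c.dist_to_5prime is None else str(c.dist_to_5prime),
                "." if c.dist_to_3prime is None else str(c.dist_to_3prime),
            ]
            row += ["1" if c.element_flags.get(t) else "0" for t in track_names]
            fh.write("\t".join(row) + "\n")


def read_context_table(path):
    """Read back a context table written by :func:`write_context_table`."""
    from .annotation import Category
    from .context import LocusContext

    contexts = []
    with open(path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        track_names = header[9:]
        for line in fh:
            f = line.rstrip("\n").split("\t")
            locus = Locus(
                chrom=f[0], start=int(f[1]), end=int(f[2]),
                name=None if f[3] == "." else f[3],
            )
            contexts.append(
                LocusContext(
                    locus=locus,
                    midpoint=locus.midpoint,
                    category=Category(f[4]),
                    nearest_gene_id=None if f[5] == "." else f[5],
                    nearest_gene_strand=None if f[6] == "." else f[6],
                    dist_to_5prime=None if f[7] == "." else int(f[7]),
                    dist_to_3prime=None if f[8] == "." else int(f[8]),
                    element_flags={
                        t: v == "1" for t, v in zip(track_names, f[9:])
                    },
                )
            )
    return contexts


def write_distribution(dist: CategoryDistribution, path) -> None:
    with open(path, "w") as fh:
        fh.write("#category\tcount\tfrequency\n")
        for cat in CATEGORY_ORDER:
            fh.write(f"{cat.value}\t{dist.counts[cat]}\t{dist.freq(cat):.6g}\n")


def read_distribution(path, label: str = "") -> CategoryDistribution:
    from .annotation import Category

    counts = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.split("\t")
            counts[Category(f[0])] = int(f[1])
    return CategoryDistribution.from_counts(counts, label=label)


def write_comparison_table(report: ComparisonReport, path) -> None:
    """Statistics table plus a one-line homogeneity summary and warnings."""
    h = report.homogeneity
    with open(path, "w") as fh:
        fh.write(
            "#category\tfg_count\tbg_count\tfg_freq\tbg_freq\tratio\tG\tp\t"
            "p_adjusted\tstars\n"
        )
        for r in report.per_category:
            ratio = "NA" if r.ratio is None else f"{r.ratio:.4g}"
            fh.write(
                f"{r.category.value}\t{r.fg_count}\t{r.bg_count}\t"
                f"{r.fg_freq:.6g}\t{r.bg_freq:.6g}\t{ratio}\t"
                f"{r.g_statistic:.4g}\t{format_pvalue(r.p_value)}\t"
                f"{format_pvalue(r.p_adjusted)}\t{r.stars}\n"
            )
        fh.write(
            f"# homogeneity: chi2 = {h.chi2:.4g}, df = {h.df}, "
            f"p = {format_pvalue(h.p_value)} (n_fg = {h.n1}, n_bg = {h.n2})\n"
        )
        for w in report.warnings:
            fh.write(f"# warning: {w}\n")


def write_term_table(results, path) -> None:
    with open(path, "w") as fh:
        fh.write("#term_id\tname\tstudy\tpopulation\tp\tp_adjusted\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.study_hits}/{r.study_size}\t"
                f"{r.pop_hits}/{r.pop_size}\t{format_pvalue(r.p_value)}\t"
                f"{format_pvalue(r.p_adjusted)}\n"
            )


def write_fasta(records, path, width: int = 60) -> None:
    """Write (locus, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for locus, seq in records:
            name = locus.name or f"{locus.chrom}:{locus.start}-{locus.end}"
            strand = f"({locus.strand})" if locus.strand else ""
            fh.write(f">{name} {locus.chrom}:{locus.start}-{locus.end}{strand}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_chrom_sizes(sizes: dict, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")
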