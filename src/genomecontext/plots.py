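"""SVG report plots: pie, side-by-side frequency bars, ratio bars, histograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .annotation import CATEGORY_ORDER
from .compare import ComparisonReport
from .context import CategoryDistribution, DistanceHistogram

CATEGORY_LABELS = {
    "exon": "exon",
    "intron": "intron",
    "five_near": "5' near",
    "three_near": "3' near",
    "five_far": "5' far",
    "three_far": "3' far",
    "distant": "distant",
}
_LABELS = [CATEGORY_LABELS[c.value] for c in CATEGORY_ORDER]


def plot_pie(dist: CategoryDistribution, path) -> Path:
    """Pie chart of a locus set's category shares."""
    if dist.total == 0:
        raise ValueError("cannot plot an empty distribution")
    fig, ax = plt.subplots(figsize=(5, 5))
    values = [dist.counts[c] for c in CATEGORY_ORDER]
    keep = [(v, l) for v, l in zip(values, _LABELS) if v > 0]
    ax.pie(
        [v for v, _ in keep],
        labels=[f"{l} ({v})" for v, l in keep],
        startangle=90,
        counterclock=False,
    )
    ax.set_title(dist.label or "genomic distribution")
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def plot_frequency_bars(
    fg: CategoryDistribution, bg: CategoryDistribution, path
) -> Path:
    """Side-by-side barplot of foreground vs background category frequencies."""
    fig, ax = plt.subplots(figsize=(7, 4))
    x = range(len(CATEGORY_ORDER))
    w = 0.38
    ax.bar(
        [i - w / 2 for i in x],
        [fg.freq(c) for c in CATEGORY_ORDER],
        width=w,
        label=fg.label or "foreground",
    )
    ax.bar(
        [i + w / 2 for i in x],
        [bg.freq(c) for c in CATEGORY_ORDER],
        width=w,
        label=bg.label or "background",
    )
    ax.set_xticks(list(x), _LABELS, rotation=30, ha="right")
    ax.set_ylabel("relative frequency")
    ax.legend()
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def plot_ratio_bars(report: ComparisonReport, path) -> Path:
    """Barplot of per-category fg/bg frequency ratios annotated with stars."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ratios = [
        r.ratio if r.ratio is not None else 0.0 for r in report.per_category
    ]
    bars = ax.bar(range(len(ratios)), ratios, color="#d4579b")
    for bar, r in zip(bars, report.per_category):
        txt = r.stars if r.ratio is not None else "n/a"
        if txt:
            ax.annotate(
                txt,
                (bar.get_x() + bar.get_width() / 2, bar.get_height()),
                ha="center",
                va="bottom",
            )
    ax.axhline(1.0, color="grey", linewidth=0.8, linestyle="--")
    ax.set_xticks(range(len(_LABELS)), _LABELS, rotation=30, ha="right")
    ax.set_ylabel("foreground / background frequency ratio")
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def plot_distance_histogram(hist: DistanceHistogram, path) -> Path:
    """Histogram of signed distances to gene 5' or 3' ends."""
    fig, ax = plt.subplots(figsize=(7, 4))
    lefts = hist.bin_edges[:-1]
    widths = [b - a for a, b in zip(hist.bin_edges, hist.bin_edges[1:])]
    ax.bar(lefts, hist.counts, width=widths, align="edge", edgecolor="white")
    end_label = "5'" if hist.end == "5prime" else "3'"
    ax.set_xlabel(
        f"signed distance to nearest gene {end_label} end (bp); "
        f"{hist.n_out_of_range} out of range"
    )
    ax.set_ylabel("loci")
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def render_report(
    fg: CategoryDistribution,
    bg: CategoryDistribution | None = None,
    report: ComparisonReport | None = None,
    histograms=(),
    out_dir=".",
    prefix: str = "",
) -> list[Path]:
    """Write the SVG plot family for a run; returns the paths written.

    Foreground alone yields a pie chart (plus any distance histograms);
    adding a background and a comparison report adds the side-by-side
    frequency barplot and the star-annotated ratio barplot.
    """
    if fg.total == 0:
        raise ValueError("foreground distribution is empty; nothing to plot")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = [plot_pie(fg, out_dir / f"{prefix}pie.svg")]
    if bg is not None:
        paths.append(
            plot_frequency_bars(fg, bg, out_dir / f"{prefix}frequencies.svg")
        )
    if report is not None:
        paths.append(plot_ratio_bars(report, out_dir / f"{prefix}ratios.svg"))
    for hist in histograms:
        paths.append(
            plot_distance_histogram(
                hist, out_dir / f"{prefix}dist_{hist.end}.svg"
            )
        )
    return paths
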