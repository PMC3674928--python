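"""Term-for-term GO over-representation of nearest-gene sets.

The genes nearest to a foreground locus set (the study set) are tested for
over-representation of each GO term against the genes nearest to a
background locus set (the population).  Each term is tested independently
("term for term") with a one-sided hypergeometric test: with ``pop_size``
genes of which ``pop_hits`` carry the term, the p-value is the probability
of drawing at least ``study_hits`` carriers in ``study_size`` draws without
replacement.  p-values are Benjamini-Hochberg adjusted across tested terms.

Gene annotations are propagated to ancestor terms along ``is_a`` relations
(a gene annotated to a term is implicitly annotated to all its ancestors);
``part_of`` and other relations are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import obonet
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class GeneSet:
    label: str
    gene_ids: set

    def __post_init__(self):
        self.gene_ids = set(self.gene_ids)


@dataclass
class TermResult:
    term_id: str
    term_name: str
    study_hits: int
    study_size: int
    pop_hits: int
    pop_size: int
    p_value: float
    p_adjusted: float = 1.0


class Gene2TermMap:
    """Gene-to-GO-term annotation with is_a ancestor closure.

    Parameters
    ----------
    direct
        Mapping gene_id -> set of directly annotated term ids.
    parents
        Mapping term id -> set of direct ``is_a`` parents.  Terms absent
        from the mapping are treated as roots.
    term_names
        Optional term id -> human-readable name.
    """

    def __init__(self, direct, parents=None, term_names=None):
        self.direct = {g: set(ts) for g, ts in direct.items()}
        self.parents = {t: set(ps) for t, ps in (parents or {}).items()}
        self.term_names = dict(term_names or {})
        self._ancestors_cache: dict[str, frozenset] = {}
        self._closed_cache: dict[str, frozenset] = {}

    @classmethod
    def from_files(cls, gene2term_path, obo_path=None) -> "Gene2TermMap":
        """Load from a two-column gene<TAB>term file and an optional OBO ontology."""
        direct: dict[str, set] = {}
        with open(gene2term_path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) == 1:
                    f = line.split()
                if len(f) < 2:
                    log.warning("%s:%d: not two columns, skipped", gene2term_path, ln)
                    continue
                direct.setdefault(f[0], set()).add(f[1])
        parents: dict[str, set] = {}
        names: dict[str, str] = {}
        if obo_path is not None:
            graph = obonet.read_obo(obo_path)
            for node, data in graph.nodes(data=True):
                if "name" in data:
                    names[node] = data["name"]
            # obonet edges run child -> parent, keyed by relation type
            for child, parent, rel in graph.edges(keys=True):
                if rel == "is_a":
                    parents.setdefault(child, set()).add(parent)
        return cls(direct, parents=parents, term_names=names)

    def ancestors(self, term: str) -> frozenset:
        """All is_a ancestors of a term (excluding the term itself)."""
        if term not in self._ancestors_cache:
            seen: set[str] = set()
            stack = list(self.parents.get(term, ()))
            while stack:
                t = stack.pop()
                if t in seen:
                    continue
                seen.add(t)
                stack.extend(self.parents.get(t, ()))
            self._ancestors_cache[term] = frozenset(seen)
        return self._ancestors_cache[term]

    def closed_terms(self, gene_id: str) -> frozenset:
        """Direct terms of a gene plus all their is_a ancestors."""
        if gene_id not in self._closed_cache:
            terms: set[str] = set()
            for t in self.direct.get(gene_id, ()):
                terms.add(t)
                terms |= self.ancestors(t)
            self._closed_cache[gene_id] = frozenset(terms)
        return self._closed_cache[gene_id]

    @property
    def mapped_genes(self) -> set:
        return set(self.direct)

    def name(self, term: str) -> str:
        return self.term_names.get(term, "")


def nearest_gene_set(contexts, label: str = "") -> GeneSet:
    """Deduplicated set of nearest-gene ids from locus contexts."""
    return GeneSet(
        label=label,
        gene_ids={
            c.nearest_gene_id for c in contexts if c.nearest_gene_id is not None
        },
    )


def hypergeom_upper_tail(
    study_hits: int, study_size: int, pop_hits: int, pop_size: int
) -> float:
    """P(X >= study_hits) for X hypergeometric(pop_size, pop_hits, study_size)."""
    return float(stats.hypergeom.sf(study_hits - 1, pop_size, pop_hits, study_size))


def adjust_pvalues(p_list, method: str = "bh") -> list[float]:
    """Multiple-testing adjustment, preserving input order.

    ``method`` is ``"bh"`` (Benjamini-Hochberg step-up) or ``"bonferroni"``;
    adjusted values are clipped to [0, 1].
    """
    ps = list(p_list)
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    if not ps:
        return []
    sm_method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return list(multipletests(ps, method=sm_method)[1])


def term_for_term(
    study: GeneSet, population: GeneSet, mapping: Gene2TermMap
) -> list[TermResult]:
    """Term-for-term hypergeometric over-representation test.

    Both gene sets are intersected with the mapped genes; study genes absent
    from the population are dropped with a warning.  Every term annotating
    at least one population gene (after ancestor closure) is tested; results
    are sorted by raw p-value, then term id.
    """
    pop = population.gene_ids & mapping.mapped_genes
    stu = study.gene_ids & mapping.mapped_genes
    dropped = stu - pop
    if dropped:
        log.warning(
            "%d study gene(s) absent from the population were dropped", len(dropped)
        )
        stu = stu & pop
    if not pop:
        raise ValueError("population has no genes with term annotations")
    if not stu:
        raise ValueError("study set has no genes with term annotations")

    pop_terms: dict[str, int] = {}
    stu_terms: dict[str, int] = {}
    for g in pop:
        for t in mapping.closed_terms(g):
            pop_terms[t] = pop_terms.get(t, 0) + 1
    for g in stu:
        for t in mapping.closed_terms(g):
            stu_terms[t] = stu_terms.get(t, 0) + 1

    pop_size, study_size = len(pop), len(stu)
    results = [
        TermResult(
            term_id=t,
            term_name=mapping.name(t),
            study_hits=stu_terms.get(t, 0),
            study_size=study_size,
            pop_hits=k,
            pop_size=pop_size,
            p_value=hypergeom_upper_tail(
                stu_terms.get(t, 0), study_size, k, pop_size
            ),
        )
        for t, k in pop_terms.items()
    ]
    adjusted = adjust_pvalues([r.p_value for r in results], method="bh")
    for r, pa in zip(results, adjusted):
        r.p_adjusted = float(min(1.0, pa))
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results
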