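"""Over-representation analysis of a candidate gene list.

A self-contained stand-in for web annotation servers: term -> gene-set
annotations come from a flat GMT file, the background universe is caller
supplied, and each term with at least one query hit is tested with the
one-sided Fisher exact test on the 2x2 table

                    in term      not in term
    query              a        list_total - a
    rest of bg       K - a      (N - K) - (list_total - a)

where K = pop hits and N = pop total. The optional EASE variant removes one
query gene from the overlap (a - 1 in the query/in-term cell) before testing,
a deliberately conservative jackknife used by the DAVID server. Multiple
testing families are per category (one family per GO namespace, one for
KEGG, ...), with Bonferroni and Benjamini-Hochberg columns; totals use the
genes mapped to at least one term of that category, mirroring the usual
annotation-tool semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str
    category: str
    genes: frozenset[str]


@dataclass(frozen=True)
class AnnotationCatalog:
    """Term annotations restricted to a background gene universe."""

    terms: Mapping[str, Term]
    background: frozenset[str]

    def __post_init__(self) -> None:
        if not self.background:
            raise ConfigurationError("annotation background is empty")
        for t in self.terms.values():
            if not t.genes:
                raise ConfigurationError(f"term {t.term_id} has no genes")
            if not t.genes <= self.background:
                raise ConfigurationError(
                    f"term {t.term_id} annotates genes outside the background"
                )

    @classmethod
    def from_gmt(
        cls,
        stream: IO[str] | Iterable[str],
        background: Iterable[str] | None = None,
        categories: Mapping[str, str] | None = None,
    ) -> "AnnotationCatalog":
        """Build a catalog from GMT rows ``term<TAB>description<TAB>genes...``.

        When no explicit background is given, the union of all annotated
        genes is used. Genes of a term outside an explicit background are
        clipped. ``categories`` maps term id -> category label; unmapped
        terms fall in the ``"GMT"`` category.
        """
        raw: dict[str, tuple[str, set[str]]] = {}
        for line in stream:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                continue
            term_id, desc = fields[0], fields[1]
            genes = {g for g in fields[2:] if g}
            if genes:
                raw[term_id] = (desc, genes)
        if background is None:
            bg: set[str] = set()
            for _, genes in raw.values():
                bg |= genes
        else:
            bg = set(background)
        terms: dict[str, Term] = {}
        for term_id, (desc, genes) in raw.items():
            clipped = frozenset(genes & bg)
            if not clipped:
                continue
            cat = categories.get(term_id, "GMT") if categories else "GMT"
            terms[term_id] = Term(term_id, desc, cat, clipped)
        return cls(terms=terms, background=frozenset(bg))


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    category: str
    name: str
    count: int
    percentage: float
    p_value: float
    genes: tuple[str, ...]
    list_total: int
    pop_hits: int
    pop_total: int
    fold_enrichment: float
    bonferroni: float
    benjamini: float
    fdr: float


def fisher_pvalue(
    count: int, list_total: int, pop_hits: int, pop_total: int
) -> float:
    """One-sided (enrichment) Fisher exact p for the 2x2 overlap table."""
    a = count
    b = list_total - count
    c = pop_hits - count
    d = pop_total - pop_hits - b
    if min(a, b, c, d) < 0:
        raise ValueError(
            f"inconsistent table: count={count} list_total={list_total} "
            f"pop_hits={pop_hits} pop_total={pop_total}"
        )
    return float(fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def ease_pvalue(
    count: int, list_total: int, pop_hits: int, pop_total: int
) -> float:
    """EASE score: Fisher p after removing one gene from the overlap cell."""
    if count < 1:
        raise ValueError("EASE score requires count >= 1")
    a = count - 1
    b = list_total - count
    c = pop_hits - count
    d = pop_total - pop_hits - b
    return float(fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def enrich(
    query: Sequence[str],
    catalog: AnnotationCatalog,
    ease: bool = False,
) -> list[EnrichmentRow]:
    """Test every term with at least one query hit; rank by ascending p.

    Query genes outside the background are dropped (logged implicitly via the
    returned totals); an empty effective query is a configuration error.
    Bonferroni/Benjamini-Hochberg corrections are applied within each
    category; the FDR column repeats the Benjamini-Hochberg value. Rows sort
    ascending by p-value, ties by term id.
    """
    if not query:
        raise ConfigurationError("query gene list is empty")
    query_set = {g for g in query if g in catalog.background}
    if not query_set:
        raise ConfigurationError(
            "no query gene maps into the annotation background"
        )
    by_cat: dict[str, list[Term]] = {}
    for t in catalog.terms.values():
        by_cat.setdefault(t.category, []).append(t)

    rows: list[EnrichmentRow] = []
    for cat in sorted(by_cat):
        terms = by_cat[cat]
        annotated = frozenset().union(*(t.genes for t in terms))
        pop_total = len(annotated & catalog.background)
        list_total = len(query_set & annotated)
        if list_total == 0:
            continue
        cat_rows: list[EnrichmentRow] = []
        for t in sorted(terms, key=lambda t: t.term_id):
            hit = query_set & t.genes
            count = len(hit)
            if count == 0:
                continue
            pop_hits = len(t.genes)
            p = (
                ease_pvalue(count, list_total, pop_hits, pop_total)
                if ease
                else fisher_pvalue(count, list_total, pop_hits, pop_total)
            )
            fold = (count / list_total) / (pop_hits / pop_total)
            cat_rows.append(
                EnrichmentRow(
                    term_id=t.term_id,
                    category=cat,
                    name=t.name,
                    count=count,
                    percentage=count / len(query_set),
                    p_value=p,
                    genes=tuple(sorted(hit)),
                    list_total=list_total,
                    pop_hits=pop_hits,
                    pop_total=pop_total,
                    fold_enrichment=fold,
                    bonferroni=p,  # corrected below once m is known
                    benjamini=p,
                    fdr=p,
                )
            )
        if not cat_rows:
            continue
        m = len(cat_rows)
        pvals = [r.p_value for r in cat_rows]
        bh = multipletests(pvals, method="fdr_bh")[1]
        for i, r in enumerate(cat_rows):
            rows.append(
                EnrichmentRow(
                    **{
                        **r.__dict__,
                        "bonferroni": min(1.0, r.p_value * m),
                        "benjamini": float(bh[i]),
                        "fdr": float(bh[i]),
                    }
                )
            )
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows


_TSV_COLUMNS = (
    "Category", "Term", "Count", "Percentage", "PValue", "Genes",
    "List Total", "Pop Hits", "Pop Total", "Fold Enrichment",
    "Bonferroni", "Benjamini", "FDR",
)


def write_enrichment_tsv(rows: Iterable[EnrichmentRow], stream: IO[str]) -> None:
    """Write the standard 13-column annotation-tool layout (percent as %)."""
    stream.write("\t".join(_TSV_COLUMNS) + "\n")
    for r in rows:
        term = f"{r.term_id}~{r.name}" if r.name else r.term_id
        stream.write(
            "\t".join(
                [
                    r.category,
                    term,
                    str(r.count),
                    f"{100 * r.percentage:.6g}",
                    f"{r.p_value:.6g}",
                    ", ".join(r.genes),
                    str(r.list_total),
                    str(r.pop_hits),
                    str(r.pop_total),
                    f"{r.fold_enrichment:.6g}",
                    f"{r.bonferroni:.6g}",
                    f"{r.benjamini:.6g}",
                    f"{r.fdr:.6g}",
                ]
            )
            + "\n"
        )
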