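"""Term-wise two-group comparison: Pearson chi-square with an
expected-count filter and Bonferroni correction.

For every candidate term the two groups yield a 2x2 table

    ==============  ==========  =============
    .               with term   without term
    group 1         a           b
    group 2         c           d
    ==============  ==========  =============

tested with the Pearson statistic (1 df, no continuity correction)

    X^2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)),   n = a+b+c+d.

Terms whose expected value (row total x column total / n) falls below 5
in any cell are omitted; the Bonferroni factor m is the number of terms
actually tested, and a term is significant when m * p <= alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .errors import ComparisonError
from .ontology import Ontology
from .propagate import GroupTermCounts

EXPECTED_COUNT_FLOOR = 5.0  # strict: a cell expecting exactly 5.0 is tested


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: (a, b) = group 1 with/without, (c, d) = group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ComparisonError("negative cell count")
        if self.n == 0:
            raise ComparisonError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def min_expected(self) -> float:
        return min(expected_counts(self))


def expected_counts(table: ContingencyTable) -> tuple[float, float, float, float]:
    """Expected cell values (row total x column total / n), in a,b,c,d order."""
    n = table.n
    r1 = table.a + table.b
    r2 = table.c + table.d
    c1 = table.a + table.c
    c2 = table.b + table.d
    return (r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n)


def pearson_chi2(table: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square statistic (1 df) and its two-sided p-value.

    No continuity correction is applied.  A zero marginal total makes the
    statistic undefined (degenerate table).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    marginals = (a + b, c + d, a + c, b + d)
    if 0 in marginals:
        raise ComparisonError(f"degenerate table (zero marginal): {table}")
    stat = n * (a * d - b * c) ** 2 / math.prod(marginals)
    p = float(_chi2_dist.sf(stat, df=1))
    return stat, p


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, m * p_raw)."""
    if not 0.0 <= p_raw <= 1.0:
        raise ComparisonError(f"p-value out of range: {p_raw}")
    if m < 1:
        raise ComparisonError(f"number of tests must be >= 1, got {m}")
    return min(1.0, p_raw * m)


@dataclass(frozen=True)
class TermComparison:
    """One term's 2x2 comparison between the two groups."""

    term: str
    label: str
    table: ContingencyTable
    pct1: float
    pct2: float
    chi2: float | None
    p_raw: float | None
    p_corrected: float | None
    tested: bool
    significant: bool


@dataclass(frozen=True)
class ComparisonRun:
    """All term comparisons for one pair of groups.

    ``m`` is the number of terms that passed the expected-count filter;
    ``bonferroni_m`` is the factor actually applied (equal to ``m``
    unless explicitly overridden).
    """

    group_labels: tuple[str, str]
    group_sizes: tuple[int, int]
    alpha: float
    m: int
    bonferroni_m: int
    results: tuple

    @property
    def significant(self) -> tuple:
        return tuple(r for r in self.results if r.significant)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "term_id": r.term,
                    "term_label": r.label,
                    "count1": r.table.a,
                    "total1": r.table.a + r.table.b,
                    "pct1": r.pct1,
                    "count2": r.table.c,
                    "total2": r.table.c + r.table.d,
                    "pct2": r.pct2,
                    "chi2": r.chi2,
                    "p_raw": r.p_raw,
                    "p_corrected": r.p_corrected,
                    "tested": r.tested,
                    "significant": r.significant,
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, sink: IO[str]) -> None:
        """Deterministic TSV report (corrected p with 5 decimal places)."""
        cols = (
            "term_id\tterm_label\tcount1\ttotal1\tpct1\tcount2\ttotal2"
            "\tpct2\tchi2\tp_raw\tp_corrected\ttested\tsignificant\n"
        )
        sink.write(cols)
        for r in self.results:
            chi = f"{r.chi2:.4f}" if r.chi2 is not None else ""
            praw = f"{r.p_raw:.6g}" if r.p_raw is not None else ""
            pcor = f"{r.p_corrected:.5f}" if r.p_corrected is not None else ""
            sink.write(
                f"{r.term}\t{r.label}\t{r.table.a}\t{r.table.a + r.table.b}"
                f"\t{r.pct1:.2f}\t{r.table.c}\t{r.table.c + r.table.d}"
                f"\t{r.pct2:.2f}\t{chi}\t{praw}\t{pcor}"
                f"\t{int(r.tested)}\t{int(r.significant)}\n"
            )


def compare_groups(
    counts1: GroupTermCounts,
    counts2: GroupTermCounts,
    ontology: Ontology,
    alpha: float = 0.05,
    m_override: int | None = None,
) -> ComparisonRun:
    """Compare per-term frequencies between two groups.

    Candidate terms are the union of terms counted in either group (a
    term absent from one group's map has count 0 there).  Terms failing
    the expected-count filter are reported untested; the remaining ``m``
    terms get raw and Bonferroni-corrected p-values and a significance
    flag at ``p_corrected <= alpha``.  ``m_override`` substitutes an
    externally fixed Bonferroni factor, e.g. when reproducing a published
    correction whose test count is known.

    Results are ordered: tested before untested, then ascending corrected
    p, then term id.
    """
    for counts in (counts1, counts2):
        if counts.ontology is not None and counts.ontology is not ontology:
            raise ComparisonError(
                "group counts were built over a different ontology"
            )
    if not 0.0 < alpha < 1.0:
        raise ComparisonError(f"alpha out of range: {alpha}")

    n1, n2 = counts1.group_size, counts2.group_size
    candidates = sorted(set(counts1.counts) | set(counts2.counts))

    tables: dict[str, ContingencyTable] = {}
    tested: dict[str, bool] = {}
    for term in candidates:
        a = counts1.get(term)
        c = counts2.get(term)
        table = ContingencyTable(a, n1 - a, c, n2 - c)
        tables[term] = table
        tested[term] = table.min_expected >= EXPECTED_COUNT_FLOOR

    m = sum(tested.values())
    factor = m_override if m_override is not None else m

    results = []
    for term in candidates:
        table = tables[term]
        pct1 = 100.0 * table.a / n1
        pct2 = 100.0 * table.c / n2
        if tested[term] and factor >= 1:
            stat, p_raw = pearson_chi2(table)
            p_cor = bonferroni(p_raw, factor)
            significant = p_cor <= alpha
        else:
            stat = p_raw = p_cor = None
            significant = False
        results.append(
            TermComparison(
                term=term,
                label=ontology.label(term) if term in ontology else "",
                table=table,
                pct1=pct1,
                pct2=pct2,
                chi2=stat,
                p_raw=p_raw,
                p_corrected=p_cor,
                tested=tested[term],
                significant=significant,
            )
        )

    results.sort(
        key=lambda r: (
            not r.tested,
            r.p_corrected if r.p_corrected is not None else math.inf,
            r.term,
        )
    )
    return ComparisonRun(
        group_labels=(counts1.label, counts2.label),
        group_sizes=(n1, n2),
        alpha=alpha,
        m=m,
        bonferroni_m=factor,
        results=tuple(results),
    )


def overlap_phenotypes(
    annotations: Mapping[str, Iterable[str]],
    panel: Iterable[str],
    combination_sizes: Sequence[int] = (1,),
    ontology: Ontology | None = None,
    closure: bool = False,
) -> dict[frozenset, frozenset]:
    """Panel terms covered by each gene (or gene combination).

    For every combination of genes of the requested sizes, returns the
    subset of *panel* terms present in the union of those genes'
    annotation sets (a Venn-style overlap).  With ``closure=True`` (needs
    an ontology) a gene annotated to a descendant of a panel term also
    covers it; the default matches term ids exactly.
    """
    panel_set = frozenset(panel)
    if not panel_set:
        raise ComparisonError("empty phenotype panel")
    if closure and ontology is None:
        raise ComparisonError("closure matching requires an ontology")

    covered_by_gene: dict[str, frozenset] = {}
    for gene, terms in annotations.items():
        terms = set(terms)
        if closure:
            closed: set[str] = set()
            for t in terms:
                closed |= ontology.ancestors(t, include_self=True)
            covered_by_gene[gene] = frozenset(panel_set & closed)
        else:
            covered_by_gene[gene] = frozenset(panel_set & terms)

    out: dict[frozenset, frozenset] = {}
    genes = sorted(annotations)
    for k in combination_sizes:
        for combo in combinations(genes, k):
            covered: frozenset = frozenset()
            for g in combo:
                covered |= covered_by_gene[g]
            out[frozenset(combo)] = covered
    return out
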