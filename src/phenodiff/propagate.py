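"""Annotation propagation (the true-path rule) and per-term group counts.

A patient observed at a term is implicitly annotated to every ancestor of
that term: someone with *Flexion contracture of the 2nd finger* also
counts toward *Flexion contracture of finger*, *Abnormal 2nd finger
morphology*, and so on up to the root.  :func:`induce` closes one
patient's observation set; :func:`count_terms` tallies, for every term,
how many patients in a group carry it directly or by closure.  Each
patient contributes at most once per term no matter how many observed
descendants it subsumes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .cohort import CaseReport
from .errors import CohortError
from .ontology import Ontology


@dataclass(frozen=True)
class InducedAnnotations:
    """A patient's ancestor-closed annotation set."""

    patient_id: str
    closed_terms: frozenset


@dataclass(frozen=True, eq=False)
class GroupTermCounts:
    """Sparse per-term patient counts for one group.

    ``counts[t]`` is the number of patients annotated to ``t`` directly or
    through a descendant; zero-count terms are omitted.  When the ontology
    defines a phenotypic root, counting is restricted to that subtree.
    """

    label: str
    group_size: int
    counts: Mapping[str, int]
    ontology: Ontology | None = None

    def __post_init__(self) -> None:
        for term, n in self.counts.items():
            if not 0 <= n <= self.group_size:
                raise CohortError(
                    f"count {n} for {term} outside [0, {self.group_size}]"
                )

    def get(self, term: str) -> int:
        """Count at *term*; absent means zero."""
        return self.counts.get(term, 0)


def induce(case: CaseReport, ontology: Ontology) -> InducedAnnotations:
    """Close one patient's observed terms under the ancestor relation."""
    closed: set[str] = set()
    for term in case.observed_terms:
        try:
            closed |= ontology.ancestors(term, include_self=True)
        except Exception as exc:
            raise CohortError(f"patient {case.patient_id}: {exc}") from exc
    return InducedAnnotations(case.patient_id, frozenset(closed))


def check_monotonic(counts: Mapping[str, int], ontology: Ontology) -> None:
    """Assert counts never increase from parent to child along any edge."""
    for child, parent in ontology.edges():
        c = counts.get(child, 0)
        p = counts.get(parent, 0)
        if parent in counts or child in counts:
            if p < c and ontology.in_reporting_subtree(parent):
                raise CohortError(
                    f"count monotonicity violated on edge "
                    f"{child} ({c}) -> {parent} ({p})"
                )


def count_terms(
    group: Iterable[CaseReport],
    ontology: Ontology,
    label: str = "group",
) -> GroupTermCounts:
    """Per-term patient counts for one group of case reports.

    Counts are restricted to the phenotypic subtree when the ontology
    declares one (modifier branches and the global root are closed over
    but not reported).  Edge-wise monotonicity is asserted on every call.
    """
    cases = list(group)
    if not cases:
        raise CohortError("cannot count an empty group")
    tally: Counter = Counter()
    for case in cases:
        closed = induce(case, ontology).closed_terms
        for term in closed:
            if ontology.in_reporting_subtree(term):
                tally[term] += 1
    check_monotonic(tally, ontology)
    return GroupTermCounts(
        label=label,
        group_size=len(cases),
        counts=dict(tally),
        ontology=ontology,
    )
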