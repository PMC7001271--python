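"""Curated case reports and gene-defined group assignment.

A :class:`CaseReport` is the minimal record a literature curator produces
for one patient: publication, disease gene, and the set of observed HPO
terms.  A :class:`StagePartition` maps each pathway gene to one of exactly
two group labels (e.g. the GPI-anchor *synthesis* genes versus the
*transamidase + remodeling* genes); :func:`assign_groups` splits a cohort
accordingly.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

from .errors import CohortError
from .ontology import Ontology, TermId

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("patient_id", "publication_id", "gene", "terms")
#: negated/excluded phenotype assertions are not modeled; reject rather
#: than silently drop such a column
_UNSUPPORTED_COLUMNS = frozenset(
    {"negated_terms", "excluded_terms", "absent_terms", "not_terms"}
)


@dataclass(frozen=True)
class CaseReport:
    """One patient: id, source publication, disease gene, observed terms."""

    patient_id: str
    publication_id: str
    gene: str
    observed_terms: frozenset
    variant_labels: tuple = ()

    def __post_init__(self) -> None:
        if not self.observed_terms:
            raise CohortError(
                f"patient {self.patient_id} has an empty term list"
            )
        for t in self.observed_terms:
            TermId(t)


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of case reports with unique patient ids."""

    cases: tuple

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for case in self.cases:
            if case.patient_id in seen:
                raise CohortError(f"duplicate patient_id: {case.patient_id}")
            seen.add(case.patient_id)

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)

    def resolve_terms(self, ontology: Ontology) -> "Cohort":
        """Return a copy with every term remapped to its primary id."""
        cases = []
        for case in self.cases:
            try:
                terms = frozenset(
                    ontology.primary_id(t) for t in case.observed_terms
                )
            except Exception as exc:
                raise CohortError(
                    f"patient {case.patient_id}: {exc}"
                ) from exc
            cases.append(
                CaseReport(
                    case.patient_id,
                    case.publication_id,
                    case.gene,
                    terms,
                    case.variant_labels,
                )
            )
        return Cohort(tuple(cases))


@dataclass(frozen=True)
class StagePartition:
    """A named two-way split of pathway genes.

    ``synonym_map`` remaps alternate symbols to the canonical one used in
    ``gene_to_group`` (the printed tables use *MPPE1* for the gene now
    called *PGAP5*).
    """

    name: str
    gene_to_group: Mapping[str, str]
    synonym_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = set(self.gene_to_group.values())
        if len(labels) != 2:
            raise CohortError(
                f"partition {self.name!r} must define exactly 2 groups, "
                f"got {sorted(labels)}"
            )
        for alt, canonical in self.synonym_map.items():
            if canonical not in self.gene_to_group:
                raise CohortError(
                    f"synonym {alt} -> {canonical}: unknown canonical gene"
                )

    @property
    def labels(self) -> tuple[str, str]:
        """The two group labels, in first-appearance order."""
        seen: list[str] = []
        for g in self.gene_to_group.values():
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def group_of(self, gene: str) -> str | None:
        return self.gene_to_group.get(self.synonym_map.get(gene, gene))


def _parse_terms(raw: str | Iterable[str], where: str) -> frozenset:
    if isinstance(raw, str):
        parts = [p.strip() for p in raw.split(";")]
    else:
        parts = [str(p).strip() for p in raw]
    terms = frozenset(p for p in parts if p)
    if not terms:
        raise CohortError(f"{where}: empty term list")
    return terms


def read_cases(source: str | Path | IO[str], format: str = "tsv") -> Cohort:
    """Read case reports from TSV or JSON.

    TSV: header row with columns ``patient_id``, ``publication_id``,
    ``gene``, ``terms`` (``;``-joined term ids) and optionally
    ``variants``.  JSON: an array of objects with the same keys.  Term
    validation against an ontology is deferred until one is supplied
    (see :meth:`Cohort.resolve_terms`).
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()

    if format == "tsv":
        rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
        if rows:
            header = set(rows[0].keys())
            bad = header & _UNSUPPORTED_COLUMNS
            if bad:
                raise CohortError(
                    f"unsupported column(s) {sorted(bad)}: negated or "
                    "excluded phenotype assertions are not modeled"
                )
            missing = set(_REQUIRED_COLUMNS) - header
            if missing:
                raise CohortError(f"missing column(s): {sorted(missing)}")
    elif format == "json":
        rows = json.loads(text)
        if not isinstance(rows, list):
            raise CohortError("JSON cohort must be an array of objects")
    else:
        raise CohortError(f"unknown cohort format: {format!r}")

    cases = []
    for i, row in enumerate(rows):
        bad = set(row) & _UNSUPPORTED_COLUMNS
        if bad:
            raise CohortError(
                f"row {i}: unsupported column(s) {sorted(bad)}"
            )
        for key in _REQUIRED_COLUMNS:
            if key == "terms":
                continue
            if key not in row or row[key] in (None, ""):
                raise CohortError(f"row {i}: missing {key!r}")
        if "terms" not in row:
            raise CohortError(f"row {i}: missing 'terms'")
        variants = row.get("variants") or ()
        if isinstance(variants, str):
            variants = tuple(v for v in variants.split(";") if v)
        cases.append(
            CaseReport(
                patient_id=str(row["patient_id"]),
                publication_id=str(row["publication_id"]),
                gene=str(row["gene"]),
                observed_terms=_parse_terms(
                    row["terms"] or "", f"patient {row['patient_id']}"
                ),
                variant_labels=tuple(variants),
            )
        )
    return Cohort(tuple(cases))


def write_cases(cohort: Cohort, sink: str | Path | IO[str], format: str = "tsv") -> None:
    """Write a cohort in the interchange format read by :func:`read_cases`."""
    if format == "tsv":
        lines = ["patient_id\tpublication_id\tgene\tterms\tvariants"]
        for case in cohort:
            terms = ";".join(sorted(case.observed_terms))
            variants = ";".join(case.variant_labels)
            lines.append(
                f"{case.patient_id}\t{case.publication_id}\t"
                f"{case.gene}\t{terms}\t{variants}"
            )
        text = "\n".join(lines) + "\n"
    elif format == "json":
        text = json.dumps(
            [
                {
                    "patient_id": c.patient_id,
                    "publication_id": c.publication_id,
                    "gene": c.gene,
                    "terms": sorted(c.observed_terms),
                    "variants": list(c.variant_labels),
                }
                for c in cohort
            ],
            indent=1,
        )
    else:
        raise CohortError(f"unknown cohort format: {format!r}")
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text, encoding="utf-8")
    else:
        sink.write(text)


def read_partition(source: str | Path | IO[str]) -> StagePartition:
    """Read a gene partition TSV.

    Format: an optional leading ``# partition: NAME`` comment, a header
    ``gene<TAB>group<TAB>synonym_of``, then one row per symbol.  Rows with
    a non-empty ``synonym_of`` declare alternate symbols and leave
    ``group`` empty.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    name = "partition"
    lines = text.splitlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            if "partition:" in line:
                name = line.split("partition:", 1)[1].strip()
        elif line.strip():
            body.append(line)
    gene_to_group: dict[str, str] = {}
    synonym_map: dict[str, str] = {}
    for row in csv.DictReader(body, delimiter="\t"):
        gene = row["gene"].strip()
        synonym_of = (row.get("synonym_of") or "").strip()
        if synonym_of:
            synonym_map[gene] = synonym_of
        else:
            group = (row.get("group") or "").strip()
            if not group:
                raise CohortError(f"gene {gene}: empty group label")
            if gene in gene_to_group:
                raise CohortError(f"gene {gene} mapped twice")
            gene_to_group[gene] = group
    return StagePartition(name, gene_to_group, synonym_map)


def assign_groups(
    cohort: Cohort, partition: StagePartition
) -> tuple[dict[str, list], list]:
    """Split a cohort into the partition's two groups by disease gene.

    Returns ``(groups, unassigned)`` where ``groups`` maps each group
    label to the cases placed in it (cohort order preserved) and
    ``unassigned`` lists cases whose gene the partition does not cover;
    these are excluded from analysis with a logged warning.
    """
    groups: dict[str, list] = {label: [] for label in partition.labels}
    unassigned: list = []
    for case in cohort:
        label = partition.group_of(case.gene)
        if label is None:
            unassigned.append(case)
        else:
            groups[label].append(case)
    if unassigned:
        logger.warning(
            "%d case(s) with genes outside partition %r excluded: %s",
            len(unassigned),
            partition.name,
            sorted({c.gene for c in unassigned}),
        )
    return groups, unassigned
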