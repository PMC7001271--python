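"""Seeded synthetic cohorts with the statistical structure the pipeline
assumes.

Three generators cover the testing needs end to end:

* :func:`generate_ontology` builds a random rooted DAG in its own term
  namespace, so ontology-independent behavior can be exercised at any
  scale.
* :func:`generate_cohort` draws two gene-defined patient groups.  Each
  leaf term is included independently per patient with a group-specific
  probability, and with probability ``specificity_noise`` an included
  leaf is reported as a uniformly chosen proper ancestor instead —
  emulating curators who record a less specific term than the patient
  actually shows.
* :func:`realize_counts` constructs a cohort whose propagated per-term
  counts reproduce a given count table exactly, which lets published
  count tables drive full end-to-end runs even though the underlying
  per-patient records were never deposited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import CaseReport, Cohort
from .errors import InfeasibleCountsError, PhenodiffError
from .ontology import Ontology, OntologyTerm
from .propagate import GroupTermCounts

DEFAULT_GROUP_SIZES = (93, 59)  # the curated cohort's two group sizes
DEFAULT_SPECIFICITY_NOISE = 0.1


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Recipe for a two-group synthetic cohort.

    ``leaf_freqs`` maps each sampled leaf term to its per-group inclusion
    probabilities ``(p_group1, p_group2)``.  ``specificity_noise`` is the
    probability that an included leaf is reported as a random proper
    ancestor (curation-depth noise).
    """

    ontology: Ontology
    leaf_freqs: Mapping[str, tuple[float, float]]
    group_sizes: tuple[int, int] = DEFAULT_GROUP_SIZES
    specificity_noise: float = DEFAULT_SPECIFICITY_NOISE
    genes_per_group: tuple[Sequence[str], Sequence[str]] = (("GENE1",), ("GENE2",))
    group_labels: tuple[str, str] = ("group1", "group2")
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.group_sizes) < 1:
            raise PhenodiffError("group sizes must be >= 1")
        if not 0.0 <= self.specificity_noise <= 1.0:
            raise PhenodiffError(
                f"specificity_noise out of [0, 1]: {self.specificity_noise}"
            )
        leaves = self.ontology.leaves()
        for term, (p1, p2) in self.leaf_freqs.items():
            if term not in leaves:
                raise PhenodiffError(f"{term} is not an ontology leaf")
            if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
                raise PhenodiffError(f"probability out of [0, 1] for {term}")
        if not (self.genes_per_group[0] and self.genes_per_group[1]):
            raise PhenodiffError("each group needs at least one gene symbol")

    @classmethod
    def default(cls, seed: int = 0) -> "SyntheticCohortSpec":
        """The packaged default: toy ontology, group sizes 93 and 59,
        leaf frequencies mirroring the curated GPI-deficiency cohort."""
        from . import datasets

        return cls(
            ontology=datasets.toy_ontology(),
            leaf_freqs=datasets.default_leaf_freqs(),
            genes_per_group=datasets.pathway_genes(),
            group_labels=("synthesis", "transamidase_remodeling"),
            seed=seed,
        )


def generate_ontology(
    n_terms: int,
    max_parents: int = 2,
    seed: int = 0,
    prefix: str = "ST",
    with_phenotypic_root: bool = True,
) -> Ontology:
    """Random rooted DAG of ``n_terms`` terms, deterministic per seed.

    Term ``i`` (created in id order) receives 1..``max_parents`` distinct
    parents among earlier terms, so the graph is acyclic by construction.
    With ``with_phenotypic_root`` (default) term 1 is the sole child of
    the root and every later term descends from it, mirroring the HPO's
    phenotypic-abnormality subtree.
    """
    if n_terms < 2:
        raise PhenodiffError("need at least a root and one child")
    if max_parents < 1:
        raise PhenodiffError("max_parents must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"{prefix}:{i:07d}" for i in range(n_terms)]
    terms = [OntologyTerm(id=ids[0], label="synthetic root")]
    first_free = 1
    phenotypic_root = None
    if with_phenotypic_root:
        terms.append(
            OntologyTerm(
                id=ids[1],
                label="synthetic phenotypic root",
                parents=frozenset({ids[0]}),
            )
        )
        phenotypic_root = ids[1]
        first_free = 2
    for i in range(first_free, n_terms):
        lo = 1 if with_phenotypic_root else 0
        pool = ids[lo:i]
        k = int(rng.integers(1, max_parents + 1))
        k = min(k, len(pool))
        parents = rng.choice(len(pool), size=k, replace=False)
        terms.append(
            OntologyTerm(
                id=ids[i],
                label=f"synthetic term {i}",
                parents=frozenset(pool[j] for j in sorted(parents)),
            )
        )
    return Ontology(terms, root=ids[0], phenotypic_root=phenotypic_root)


def generate_cohort(spec: SyntheticCohortSpec) -> Cohort:
    """Draw a two-group cohort from a :class:`SyntheticCohortSpec`.

    Fully deterministic for a fixed spec (one seeded generator drives
    every draw).  Patients whose term draw comes up empty are annotated
    to the phenotypic root (or the root when none is set) so every case
    report carries at least one term.
    """
    ont = spec.ontology
    rng = np.random.default_rng(spec.seed)
    leaves = sorted(spec.leaf_freqs)
    # proper ancestors per leaf, sorted for reproducible uniform choice
    ancestry = {t: sorted(ont.ancestors(t, include_self=False)) for t in leaves}
    fallback = ont.phenotypic_root or ont.root
    q = spec.specificity_noise

    cases = []
    for gi, label in enumerate(spec.group_labels):
        genes = list(spec.genes_per_group[gi])
        for j in range(spec.group_sizes[gi]):
            observed: set[str] = set()
            for leaf in leaves:
                if rng.random() >= spec.leaf_freqs[leaf][gi]:
                    continue
                term = leaf
                if q > 0.0 and rng.random() < q:
                    anc = ancestry[leaf]
                    term = anc[int(rng.integers(len(anc)))]
                observed.add(term)
            if not observed:
                observed.add(fallback)
            gene = genes[int(rng.integers(len(genes)))]
            cases.append(
                CaseReport(
                    patient_id=f"{label}-{j + 1:04d}",
                    publication_id=f"SIM:{spec.seed}",
                    gene=gene,
                    observed_terms=frozenset(observed),
                )
            )
    return Cohort(tuple(cases))


def _check_feasible(
    counts: Mapping[str, int], group_size: int, ontology: Ontology, label: str
) -> None:
    for term, n in counts.items():
        if not 0 <= n <= group_size:
            raise InfeasibleCountsError(
                f"group {label}: count {n} at {term} outside "
                f"[0, {group_size}]"
            )
    for term, n in counts.items():
        for anc in ontology.ancestors(term, include_self=False):
            if anc in counts and counts[anc] < n:
                raise InfeasibleCountsError(
                    f"group {label}: monotonicity violated on edge "
                    f"{term} ({n}) -> {anc} ({counts[anc]})"
                )


def realize_counts(
    counts1: GroupTermCounts,
    counts2: GroupTermCounts,
    ontology: Ontology,
    gene_counts: Mapping[str, Sequence[tuple[str, int]]] | None = None,
) -> Cohort:
    """Construct a cohort whose propagated counts reproduce a count table.

    Within each group, patients are indexed 0..size-1 and patient *j* is
    made a carrier of every fixture term with count > *j* (nested prefix
    sets); because counts never increase from descendant to ancestor,
    each patient's carrier set is automatically closed over the fixture
    terms, and the realized count at every fixture term is exact.  The
    patient's observed annotations are the deepest carried terms.
    Patients carrying nothing are annotated to the phenotypic root
    (every curated patient has at least one phenotypic term even when a
    published table omits the root row) — unless the fixture itself
    prescribes a count for the phenotypic root, in which case they fall
    back to the global root so that the prescribed count stays exact.

    ``gene_counts`` optionally maps each group label to ``(gene, n)``
    pairs whose counts must sum to the group size; genes are then
    assigned to patients in order, so a per-gene patient census can be
    reproduced alongside the term counts.
    """
    cases = []
    for counts in (counts1, counts2):
        _check_feasible(counts.counts, counts.group_size, ontology, counts.label)
        genes: list[str] = []
        if gene_counts is not None and counts.label in gene_counts:
            for gene, n in gene_counts[counts.label]:
                genes.extend([gene] * n)
            if len(genes) != counts.group_size:
                raise InfeasibleCountsError(
                    f"group {counts.label}: gene counts sum to "
                    f"{len(genes)}, expected {counts.group_size}"
                )
        fixture = counts.counts
        phen_root = ontology.phenotypic_root
        if phen_root is not None and phen_root not in fixture:
            fallback = phen_root
        else:
            fallback = ontology.root
        for j in range(counts.group_size):
            carried = {t for t, n in fixture.items() if n > j}
            # keep only the deepest terms; closure restores the rest
            observed = {
                t
                for t in carried
                if not any(
                    t in ontology.ancestors(s) for s in carried if s != t
                )
            }
            if not observed:
                observed = {fallback}
            cases.append(
                CaseReport(
                    patient_id=f"{counts.label}-{j + 1:03d}",
                    publication_id="fixture",
                    gene=genes[j] if genes else f"GENE_{counts.label}",
                    observed_terms=frozenset(observed),
                )
            )
    return Cohort(tuple(cases))
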