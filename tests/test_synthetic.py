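"""Synthetic ontologies and cohorts; realizing published count tables."""

import networkx as nx
import pytest

from phenodiff import (
    GroupTermCounts,
    InfeasibleCountsError,
    Ontology,
    OntologyTerm,
    PhenodiffError,
    compare_groups,
    count_terms,
    datasets,
)
from phenodiff.synthetic import (
    SyntheticCohortSpec,
    generate_cohort,
    generate_ontology,
    realize_counts,
)


# -- generate_ontology -------------------------------------------------


def test_two_term_ontology_is_root_plus_child():
    ont = generate_ontology(2, max_parents=1, seed=3, with_phenotypic_root=False)
    assert len(ont) == 2
    child = next(t for t in ont.terms if t != ont.root)
    assert ont.terms[child].parents == {ont.root}


def test_same_seed_gives_identical_edges():
    a = generate_ontology(80, max_parents=3, seed=11)
    b = generate_ontology(80, max_parents=3, seed=11)
    assert set(a.edges()) == set(b.edges())
    c = generate_ontology(80, max_parents=3, seed=12)
    assert set(a.edges()) != set(c.edges())


def test_large_random_dag_satisfies_ontology_invariants():
    ont = generate_ontology(500, max_parents=3, seed=7)
    assert len(ont) == 500
    assert nx.is_directed_acyclic_graph(ont.graph)
    # every term reaches the root through parent edges
    assert ont.descendants(ont.root, include_self=True) == set(ont.terms)
    for tid, term in ont.terms.items():
        if tid != ont.root:
            assert term.parents


# -- generate_cohort ---------------------------------------------------


def test_cohort_generation_is_seed_deterministic(toy_ontology):
    spec = SyntheticCohortSpec.default(seed=5)
    a = generate_cohort(spec)
    b = generate_cohort(spec)
    assert [(c.patient_id, c.gene, c.observed_terms) for c in a] == [
        (c.patient_id, c.gene, c.observed_terms) for c in b
    ]
    other = generate_cohort(SyntheticCohortSpec.default(seed=6))
    assert [c.observed_terms for c in a] != [c.observed_terms for c in other]


def test_default_spec_draws_93_and_59_patients():
    cohort = generate_cohort(SyntheticCohortSpec.default(seed=1))
    labels = [c.patient_id.rsplit("-", 1)[0] for c in cohort]
    assert labels.count("synthesis") == 93
    assert labels.count("transamidase_remodeling") == 59


def test_deterministic_leaf_separates_groups_perfectly(toy_ontology):
    leaf = "HP:0011927"
    spec = SyntheticCohortSpec(
        ontology=toy_ontology,
        leaf_freqs={leaf: (1.0, 0.0)},
        group_sizes=(10, 10),
        specificity_noise=0.0,
        seed=0,
    )
    cohort = generate_cohort(spec)
    for case in cohort:
        if case.patient_id.startswith("group1"):
            assert case.observed_terms == {leaf}
        else:  # empty draw falls back to the phenotypic root
            assert case.observed_terms == {"HP:0000118"}


def test_spec_rejects_invalid_probability(toy_ontology):
    with pytest.raises(PhenodiffError, match="probability"):
        SyntheticCohortSpec(
            ontology=toy_ontology,
            leaf_freqs={"HP:0011927": (1.5, 0.0)},
        )


def test_spec_rejects_non_leaf_term(toy_ontology):
    with pytest.raises(PhenodiffError, match="leaf"):
        SyntheticCohortSpec(
            ontology=toy_ontology,
            leaf_freqs={"HP:0011297": (0.5, 0.5)},  # has children
        )


def test_specificity_noise_promotes_to_proper_ancestors(toy_ontology):
    leaf = "HP:0009537"
    spec = SyntheticCohortSpec(
        ontology=toy_ontology,
        leaf_freqs={leaf: (1.0, 1.0)},
        group_sizes=(200, 1),
        specificity_noise=1.0,
        seed=2,
    )
    ancestors = toy_ontology.ancestors(leaf)
    observed = set()
    for case in generate_cohort(spec):
        observed |= case.observed_terms
    assert leaf not in observed
    assert observed <= ancestors


# -- realize_counts ----------------------------------------------------


def _chain_ontology():
    return Ontology(
        [
            OntologyTerm(id="CC:0000001", label="root"),
            OntologyTerm(id="CC:0000002", label="parent",
                         parents=frozenset({"CC:0000001"})),
            OntologyTerm(id="CC:0000003", label="child",
                         parents=frozenset({"CC:0000002"})),
        ]
    )


def test_realize_nests_child_within_parent():
    ont = _chain_ontology()
    cohort = realize_counts(
        GroupTermCounts("g1", 2, {"CC:0000002": 2, "CC:0000003": 1}, ont),
        GroupTermCounts("g2", 1, {"CC:0000002": 1}, ont),
        ont,
    )
    g1 = [c for c in cohort if c.patient_id.startswith("g1")]
    assert g1[0].observed_terms == {"CC:0000003"}
    assert g1[1].observed_terms == {"CC:0000002"}


def test_realize_rejects_infeasible_fixture_naming_edge():
    ont = _chain_ontology()
    with pytest.raises(InfeasibleCountsError, match="CC:0000003.*CC:0000002"):
        realize_counts(
            GroupTermCounts("g1", 5, {"CC:0000002": 1, "CC:0000003": 3}, ont),
            GroupTermCounts("g2", 1, {}, ont),
            ont,
        )


def test_realize_rejects_mismatched_gene_census():
    ont = _chain_ontology()
    with pytest.raises(InfeasibleCountsError, match="gene counts"):
        realize_counts(
            GroupTermCounts("g1", 3, {"CC:0000002": 1}, ont),
            GroupTermCounts("g2", 1, {}, ont),
            ont,
            gene_counts={"g1": [("PIGA", 1)]},
        )


def test_realized_cohort_reproduces_published_counts(toy_ontology):
    cohort, ont = datasets.reference_cohort()
    from phenodiff import assign_groups

    grouped, _ = assign_groups(cohort, datasets.stage_partition())
    counts_syn = count_terms(grouped["synthesis"], ont, label="synthesis")
    counts_tr = count_terms(
        grouped["transamidase_remodeling"], ont, label="transamidase_remodeling"
    )
    for row in datasets.enriched_terms().itertuples():
        assert counts_syn.get(row.term_id) == row.count_synthesis
        assert counts_tr.get(row.term_id) == row.count_tr


@pytest.mark.parametrize("seed", range(100))
def test_realize_then_count_roundtrip(seed):
    """For any feasible (ancestor-complete) count fixture, realizing a
    cohort and re-counting reproduces the fixture exactly."""
    ont = generate_ontology(25, max_parents=2, seed=5)
    leaves = sorted(ont.leaves())[:6]
    spec = SyntheticCohortSpec(
        ontology=ont,
        leaf_freqs={t: (0.6, 0.25) for t in leaves},
        group_sizes=(12, 9),
        specificity_noise=0.2,
        seed=seed,
    )
    cohort = generate_cohort(spec)
    g1 = [c for c in cohort if c.gene == "GENE1"]
    g2 = [c for c in cohort if c.gene == "GENE2"]
    fixture1 = count_terms(g1, ont, label="g1")
    fixture2 = count_terms(g2, ont, label="g2")
    realized = realize_counts(fixture1, fixture2, ont)
    r1 = [c for c in realized if c.patient_id.startswith("g1")]
    r2 = [c for c in realized if c.patient_id.startswith("g2")]
    assert dict(count_terms(r1, ont).counts) == dict(fixture1.counts)
    assert dict(count_terms(r2, ont).counts) == dict(fixture2.counts)


# -- power regression --------------------------------------------------


def _flat_ontology(n_fillers):
    terms = [
        OntologyTerm(id="SY:0000000", label="root"),
        OntologyTerm(id="SY:0000001", label="phenotypic root",
                     parents=frozenset({"SY:0000000"})),
        OntologyTerm(id="SY:0000002", label="focal",
                     parents=frozenset({"SY:0000001"})),
    ]
    for i in range(n_fillers):
        terms.append(
            OntologyTerm(
                id=f"SY:{i + 3:07d}",
                label=f"filler {i}",
                parents=frozenset({"SY:0000001"}),
            )
        )
    return Ontology(terms, phenotypic_root="SY:0000001")


def test_power_to_detect_digit_like_effect():
    """A leaf at frequencies 0.33 vs 0.07 (the published digit-row
    effect) at group sizes 93/59, Bonferroni-corrected over ~200 filler
    tests, is detected in roughly half the replicates.  The replicate
    count is a frozen regression value for the packaged seeds."""
    ont = _flat_ontology(199)
    focal = "SY:0000002"
    freqs = {focal: (0.33, 0.07)}
    freqs.update(
        {t: (0.15, 0.15) for t in sorted(ont.leaves()) if t != focal}
    )
    hits = 0
    n_reps = 200
    for rep in range(n_reps):
        spec = SyntheticCohortSpec(
            ontology=ont,
            leaf_freqs=freqs,
            group_sizes=(93, 59),
            specificity_noise=0.0,
            seed=10_000 + rep,
        )
        cohort = generate_cohort(spec)
        g1 = [c for c in cohort if c.gene == "GENE1"]
        g2 = [c for c in cohort if c.gene == "GENE2"]
        run = compare_groups(
            count_terms(g1, ont, label="g1"),
            count_terms(g2, ont, label="g2"),
            ont,
        )
        by_term = {r.term: r for r in run.results}
        if by_term[focal].significant:
            hits += 1
    # detection rate far exceeds the family-wise false-positive budget
    assert hits > 50
    assert hits == 95  # frozen regression value for these seeds
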