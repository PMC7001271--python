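"""Packaged reference data.

Ships a toy phenotype ontology plus the published summary tables of the
curated GPI-anchor-deficiency cohort: the per-gene patient census for the
two pathway stages, the two gene partitions, and the per-term counts and
corrected p-values of the significantly enriched phenotypes.  The
per-patient records behind those tables were never deposited, so
:func:`reference_cohort` reconstructs an equivalent cohort from the
counts with :func:`~phenodiff.synthetic.realize_counts`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort import StagePartition, read_partition
from .ontology import Ontology, parse_obo
from .propagate import GroupTermCounts
from .synthetic import realize_counts

#: the Bonferroni factor consistent with every published corrected
#: p-value (back-derived; the publication does not print it)
REFERENCE_BONFERRONI_M = 211

GROUP_SYNTHESIS = "synthesis"
GROUP_TR = "transamidase_remodeling"

_PARTITION_FILES = {
    "synthesis_vs_transamidase_remodeling": "partition_synthesis_vs_tr.tsv",
    "synthesis_transamidase_vs_remodeling": "partition_synta_vs_remodeling.tsv",
}


def _data(name: str):
    return resources.files("phenodiff").joinpath("data", name)


def toy_ontology() -> Ontology:
    """The packaged ~40-term miniature phenotype ontology."""
    with resources.as_file(_data("toy_hpo.obo")) as path:
        return parse_obo(path)


def gene_counts() -> pd.DataFrame:
    """Per-gene curated patient counts with pathway stage labels."""
    with _data("gene_groups.tsv").open() as handle:
        return pd.read_csv(handle, sep="\t")


def pathway_genes() -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Gene symbols of the synthesis and transamidase+remodeling stages."""
    df = gene_counts()
    return (
        tuple(df.loc[df.stage == GROUP_SYNTHESIS, "gene"]),
        tuple(df.loc[df.stage == GROUP_TR, "gene"]),
    )


def stage_partition(name: str = "synthesis_vs_transamidase_remodeling") -> StagePartition:
    """One of the two packaged gene partitions."""
    try:
        fname = _PARTITION_FILES[name]
    except KeyError:
        raise KeyError(
            f"unknown partition {name!r}; available: "
            f"{sorted(_PARTITION_FILES)}"
        ) from None
    with _data(fname).open() as handle:
        return read_partition(handle)


def enriched_terms() -> pd.DataFrame:
    """Published per-term counts and corrected p-values of the 21
    significantly enriched phenotypes (5 synthesis-enriched, 16
    transamidase+remodeling-enriched)."""
    with _data("significant_terms.tsv").open() as handle:
        return pd.read_csv(handle, sep="\t")


def enriched_term_counts(ontology: Ontology | None = None) -> tuple[GroupTermCounts, GroupTermCounts]:
    """The published per-term counts as a pair of sparse count maps."""
    df = enriched_terms()
    sizes = group_sizes()
    syn = {r.term_id: int(r.count_synthesis) for r in df.itertuples() if r.count_synthesis > 0}
    tr = {r.term_id: int(r.count_tr) for r in df.itertuples() if r.count_tr > 0}
    return (
        GroupTermCounts(GROUP_SYNTHESIS, sizes[0], syn, ontology),
        GroupTermCounts(GROUP_TR, sizes[1], tr, ontology),
    )


def group_sizes() -> tuple[int, int]:
    """Group sizes implied by the per-gene patient census."""
    df = gene_counts()
    return (
        int(df.loc[df.stage == GROUP_SYNTHESIS, "n_patients"].sum()),
        int(df.loc[df.stage == GROUP_TR, "n_patients"].sum()),
    )


def reference_cohort(ontology: Ontology | None = None):
    """A cohort realizing the published per-term counts and per-gene
    census on the toy ontology.

    Returns ``(cohort, ontology)``; propagated counting of the cohort's
    two gene-defined groups reproduces all 42 published counts.
    """
    if ontology is None:
        ontology = toy_ontology()
    counts_syn, counts_tr = enriched_term_counts(ontology)
    df = gene_counts()
    per_gene = {
        GROUP_SYNTHESIS: [
            (r.gene, int(r.n_patients))
            for r in df[df.stage == GROUP_SYNTHESIS].itertuples()
            if r.n_patients > 0
        ],
        GROUP_TR: [
            (r.gene, int(r.n_patients))
            for r in df[df.stage == GROUP_TR].itertuples()
            if r.n_patients > 0
        ],
    }
    cohort = realize_counts(counts_syn, counts_tr, ontology, gene_counts=per_gene)
    return cohort, ontology


def default_leaf_freqs() -> dict[str, tuple[float, float]]:
    """Per-leaf annotation frequencies for the default synthetic cohort.

    Frequencies mirror the curated cohort where a published percentage
    attaches to a toy-ontology leaf (e.g. *Short digit*, *Osteopenia*,
    *Intellectual disability*); the remaining leaves carry rates in the
    range the case-report narrative suggests.
    """
    return {
        "HP:0011927": (0.237, 0.017),  # Short digit
        "HP:0001500": (0.05, 0.017),   # Broad finger
        "HP:0001217": (0.03, 0.0),     # Clubbing
        "HP:0009537": (0.19, 0.0),     # Flexion contracture of the 2nd finger
        "HP:0003560": (0.04, 0.0),     # Muscular dystrophy
        "HP:0001382": (0.05, 0.017),   # Joint hypermobility
        "HP:0001771": (0.011, 0.0),    # Abnormality of the Achilles tendon
        "HP:0002753": (0.011, 0.0),    # Thin bony cortex
        "HP:0000938": (0.0215, 0.2203),  # Osteopenia
        "HP:0000939": (0.0, 0.017),    # Osteoporosis
        "HP:0002265": (0.0108, 0.2373),  # Large fleshy ears
        "HP:0002360": (0.0, 0.2203),   # Sleep disturbance
        "HP:0012758": (0.6129, 0.9153),  # Neurodevelopmental delay
        "HP:0001249": (0.1613, 0.661),   # Intellectual disability
        "HP:0000708": (0.1505, 0.4237),  # Behavioral abnormality
        "HP:0000455": (0.14, 0.25),    # Broad nasal tip
        "HP:0000431": (0.14, 0.30),    # Wide nasal bridge
        "HP:0000448": (0.0, 0.15),     # Prominent nose
        "HP:0000426": (0.011, 0.0),    # Prominent nasal bridge
        "HP:0000204": (0.02, 0.05),    # Cleft upper lip
        "HP:0100336": (0.0, 0.034),    # Median cleft lip and palate
    }
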