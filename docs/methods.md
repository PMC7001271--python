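# Methods

## Model and procedure

The pipeline compares the phenotypic spectra of two gene-defined
patient groups over an HPO-style ontology.

1. **Ontology.** An OBO flat file is parsed into a rooted DAG; only
   `is_a` relations become edges (the HPO phenotype subtree uses `is_a`
   exclusively), every other relationship tag is ignored. Obsolete
   terms are retained but excluded from the graph; ids naming an
   obsolete term are remapped through `replaced_by`, secondary
   (`alt_id`) identifiers to their primary id — both with a warning and
   an entry in the ontology's remap log, because curated literature
   data frequently carries merged ids. The root is inferred as the
   unique parentless term (override available for synthetic
   namespaces); duplicate ids, dangling `is_a` targets and cycles are
   hard errors.

2. **Propagation (true-path rule).** A patient's induced annotation set
   is the union of ancestor closures of the observed terms, so each
   patient contributes at most once to any term's count regardless of
   how many observed descendants it subsumes. Reported counts are
   restricted to the phenotypic subtree when the ontology declares a
   phenotypic root (`HP:0000118` for the real HPO): every published
   comparison row is a phenotypic abnormality, and modifier branches
   would only dilute the multiple-testing budget. Edge-wise count
   monotonicity (`count(parent) ≥ count(child)`) is asserted on every
   counting call.

3. **Comparison.** Candidate terms are the union of terms counted in
   either group (absent ⇒ 0). Each gets a 2×2 table tested by Pearson
   χ² with 1 df and **no continuity correction**: with Yates'
   correction the published *Abnormality of digit* row (31/93 vs 4/59)
   is inconsistent with its printed corrected p under any plausible
   test count, while without it every published row is consistent with
   a single factor. The expected-count filter is strict (`< 5` is
   omitted, exactly 5.0 is tested), with expected values computed from
   the marginals. The Bonferroni factor *m* is the number of terms
   actually tested after filtering — back-calculation from the
   published corrected p-values gives a per-row ratio of 210.9–211.2
   (rows printed to ≥3 significant figures), so the published analysis
   is pinned by `m_override=211` when reproducing it; significance is
   inclusive, `p_corr ≤ α`. Reports order rows by (tested, corrected p,
   term id) so output is byte-stable.

## Reference data

The curated cohort's per-patient records are not public; the package
ships the published summaries instead: the per-gene patient census
(93 synthesis-stage + 59 transamidase/remodeling-stage patients = 152),
two gene partitions (the stage split, and the alternative isolating the
remodeling genes PGAP1/2/3/5; *MPPE1* is treated as a synonym of
*PGAP5*), and the per-term counts and corrected p-values of the 21
enriched phenotypes. A ~40-term toy ontology embeds those 21 terms with
their real hierarchical relations (bone-density chain, ear, oral-cleft
and neurodevelopmental neighborhoods, including the multi-parent
*Cleft palate*) such that every ancestor of a published term below the
phenotypic root is itself a published term; propagated counting of a
realized cohort therefore reproduces exactly the published rows and
nothing else.

`realize_counts` rebuilds a concrete cohort from any feasible count
table by nested prefix sets: patient *j* of a group carries every
fixture term with count > *j*. Monotonicity of the fixture along
ancestor paths makes each carrier set ancestor-closed and every
realized count exact; infeasible fixtures are rejected naming the
offending edge. Patients with an empty carrier pattern observe the
phenotypic root (every curated patient has at least one phenotypic
finding even though published tables omit the root row) unless the
fixture itself constrains that root, in which case they fall back to
the global root so prescribed counts stay exact. The root row then has
a zero "without" margin and is automatically removed by the
expected-count filter.

## Synthetic cohorts

The generator emulates the study's structure: two gene-defined groups
of 93 and 59 patients by default, per-leaf annotation probabilities
(the packaged defaults mirror the published per-term frequencies where
a percentage attaches to a toy leaf, e.g. *Short digit* 0.237 vs 0.017,
*Osteopenia* 0.0215 vs 0.2203), genes drawn uniformly from each
group's pathway gene list, and a **specificity-noise** parameter *q*
(default 0.1): with probability *q* an included leaf is reported as a
uniformly chosen proper ancestor, emulating curation-depth variability
across case reports. Patients with an empty draw receive the
phenotypic root. Leaf inclusions are independent across terms — no
phenotype-correlation model — so passing tests demonstrate correctness
of propagation, filtering and correction, not realism of comorbidity
structure; real cohorts also carry publication-level correlation
(several patients per report) that the generator does not model.
Random ontologies assign each new term 1–`max_parents` parents among
earlier terms, acyclic by construction. All randomness flows from one
seeded NumPy generator per cohort; the seed is echoed in output
metadata.

## Numerical and design notes

* χ² p-values use the exact upper-tail `χ²₁` survival function
  (equivalently `erfc(√(X²/2))`); tests require agreement with an
  independent contingency-table implementation to 1e-12.
* A zero observed cell is legal when its expected count is ≥ 5 (the
  published *Abnormal tendon morphology* row is 19/93 vs 0/59); a zero
  marginal is degenerate and — since it forces an expected value of
  0 — can never pass the filter.
* A printed corrected p of `0.00000` is read as "< 0.000005", not as
  exactly zero; reports print corrected p with 5 decimals.
* Negated/excluded phenotype assertions are not modeled; a column for
  them is rejected explicitly rather than silently dropped.
  Inheritance mode is carried as metadata only.
* Simulation sizes: the type-I check runs 200 replicates of the full
  93 + 59 cohort under equal group frequencies (family-wise hit rate
  must stay ≤ α; Bonferroni makes the expected rate well below it),
  and leaf-frequency recovery uses 5000 patients per group (±3 SE).
  The power regression for a digit-row-like effect (0.33 vs 0.07,
  Bonferroni over ~200 filler tests) detects the focal term in 95/200
  replicates under the packaged seeds — the raw p of the true effect
  sits essentially at the corrected threshold 0.05/200, so ~50% power
  is the expected operating point, and the count is frozen as a
  regression value.

## Known limitations

* Only `is_a` edges are traversed; OWL and non-hierarchical relations
  are out of scope.
* The candidate-term universe is the union of observed (propagated)
  terms; with the expected-count filter this coincides with testing
  all ontology terms, but the two conventions differ if the filter is
  relaxed.
* Fisher's exact test, FDR control and covariate adjustment are
  deliberately not provided; the comparison is a faithful
  implementation of the χ²/Bonferroni design it reproduces.
* `realize_counts` guarantees exact reproduction on the fixture's own
  terms (and on all terms for ancestor-complete fixtures); it is a
  reconstruction device, not a model of patient heterogeneity.
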