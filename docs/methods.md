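# Methods

## Data model

The knowledge base is a multi-species, ontology-linked store: species (one
flagged as the reference, human), gene catalogs per species, pathways held
directly as human gene sets, human↔model ortholog pairs, per-species
gene–phenotype annotations (ontology term identifiers such as
`WBPhenotype:…` or `ZP:…` CURIEs, treated as opaque case-sensitive tokens),
compounds with optional fixed-length binary fingerprints,
compound–phenotype observations, and compound in-vitro target hits on human
genes. Pathways are stored at the gene level — a protein/reaction layer
would add nothing to the statistics, which all operate on gene sets.

Two deliberate simplifications:

* **No ontology traversal.** A query phenotype matches annotations by exact
  term identity; is-a parents/children are not expanded. With propagation,
  annotation sets grow monotonically, so rankings would shift but the
  machinery would be unchanged; exact matching keeps the null model and
  the universe definition crisp.
* **Observed-but-never-annotated phenotypes are warnings, not errors.** A
  chemical can elicit phenotypes that no genetic variant has produced; such
  terms simply contribute no gene evidence.

Loading is strict (any referential-integrity failure aborts) or lenient
(offending rows dropped and reported). Relation labels in `orthologs.tsv`
are cross-checked against the degree-derived classification and relabelled
with a warning on disagreement, so one definition governs real dumps and
synthetic data alike.

## Forward enrichment (phenotypes → pathways)

Per species *s*:

* **Universe** *U_s* = genes of *s* with ≥ 1 phenotype annotation. Genes
  never annotated are unobservable in this assay class; including them
  would only dilute the null and reward large pathways.
* **Gene score** *x_g* = number of *distinct* query phenotypes annotated to
  *g* (not binary membership): when several observed phenotypes converge on
  one gene, that convergence is informative and should lift the gene in the
  ranking.
* **Set statistic** — Mann–Whitney AUC of the pathway's projected gene set
  against its complement within *U_s*, ties credited ½. Computed from
  average ranks: AUC = (Σ ranks_in − k(k+1)/2) / (k(n−k)). This is invariant
  under any strictly monotone transform of the scores and satisfies
  AUC(S) = 1 − AUC(U\S).
* **Null model** — uniform random gene sets of the same size drawn without
  replacement from *U_s* (gene sampling, not phenotype-label permutation:
  the simplest exchangeability assumption, and the one the synthetic
  calibration tests). p = (1 + #{AUC\* ≥ AUC}) / (n_samples + 1), the
  add-one estimator, so p ∈ [1/(n+1), 1] and never 0.
* **Degenerate sets** — a pathway whose projection is empty in *U_s* or
  spans all of *U_s* has no defined AUC and is skipped in that species.

Across species, per-pathway p-values are combined with the **unweighted
harmonic mean** k / Σ 1/p_i. It is used purely as a ranking score: no
harmonic-mean-p significance correction (Landau/Wilson style) is applied,
and no species weighting — absent a principled weighting of, say, worm
versus fish evidence, equal weights are the defensible default. Species
contributing no evidence are excluded, never imputed at p = 1.

In-vitro target hits enter as evidence *flags* plus the supporting gene
list (targets ∩ pathway genes). They are deliberately kept out of the
combined p-value: there is no obvious exchangeable null that would put a
binary target hit and a phenotype-derived AUC on one scale. Results can be
filtered by evidence type (non-mammalian phenotypes, mammalian phenotypes,
in-vitro targets, all, any). Final ordering is ascending combined p with
lexicographic pathway-id tie-break; ranks are 1-based and contiguous.

## Reverse prediction (pathway → phenotypes)

Same universe convention. The projected set is the pathway's ortholog image
∩ *U_s* (empty projection is an error: the pathway is not conserved there).
Each phenotype with K ≥ 1 annotated universe genes is tested with the
upper-tail hypergeometric probability P(X ≥ k | N, K, n) — the standard
“≥ k” enrichment convention — and BH-adjusted across all phenotypes of the
one (pathway, species) query. Per-query adjustment matches how a user
inspects one pathway at a time; a global FDR across pathways would answer a
different question. The q ≤ 0.05 flag is reported, never used to drop rows.

## Similarity

Tanimoto coefficient |a∧b|/|a∨b| on precomputed fixed-length bitstring
fingerprints; undefined (error) when both vectors are all-zero. Generation
of fingerprints from SMILES is out of scope — the coefficient is a single
function, swappable if another is preferred. Lookup is exact: ids, CAS, EC
and SMILES case-sensitively, names case-insensitively; ambiguous queries
list their candidates rather than guessing.

## Orthology classification

Within one model species, a human gene is `one2one` (single, mutually
exclusive partner), `one2many` (several partners, all exclusive to it) or
`many2many` (some partner also maps to another human gene), computed from
bipartite degrees of the pair set. An equivalent characterisation — the
connected component of the gene contains >1 human gene ⇔ many2many — is
used as the independent test oracle. Conservation profiles count each human
pathway gene once under its class; the counts sum to `n_conserved` and the
fraction is monotone under pair addition.

## Synthetic generator

The generator emulates the *shape* of the real stores — catalog sizes,
pathway size spread, ortholog retention and relation mix, annotation
sparsity — not their content. Defaults (the “strong” preset) describe a
clearly-affected compound screened in three non-mammalian species:

| knob | default | rationale |
|---|---|---|
| n_model_species | 3 | worm, zebrafish, fly — the common NAM trio |
| n_human_genes | 300 | enough pathway-size spread at desk scale |
| genes_per_model_species | 450 | headroom for one2many images |
| n_pathways | 20 | 19 competitors for rank-1 recovery |
| pathway_size_range | (10, 30) | typical curated-pathway sizes |
| ortholog_retention | 0.8 | deep conservation of core pathways |
| one2many / many2many rate | 0.15 / 0.10 | duplication-heavy lineages |
| n_phenotypes_per_species | 100 | vocabulary per species |
| annotation_rate | 0.01 | ≈ 1 link per gene: sparse, like curated data |
| signal_strength | 0.9 | most observed phenotypes trace to the pathway |
| n_observed_phenotypes | 15 | a rich phenotype profile per species |
| fingerprint_length | 128 | short but collision-free at this scale |

The signal is planted at the *observation* level: the planted compound's
phenotypes are drawn from the pool annotated to the target pathway's
projected genes with probability `signal_strength`, else uniformly from the
species vocabulary. Annotations are never edited, so the null structure of
the knowledge base is untouched — a null fixture is simply
`signal_strength = 0`. One seed drives generation; planting uses a second
stream derived from the same seed, so fixtures are byte-reproducible.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: ontology hierarchy and annotation
propagation; correlated pathway membership (real pathways overlap and nest);
non-uniform annotation depth (well-studied genes carry many more links);
realistic chemistry (fingerprints are random bits, so similarity results
exercise the machinery, not chemical meaning); and mammalian text-mined
phenotype channels.

## Numerical choices

* Null-vs-observed AUC comparisons use a 1e-12 slack so exact ties (same
  rank arithmetic on both sides) always count toward the tail; this is what
  makes the Monte Carlo estimator agree with the exact enumeration oracle
  to binomial noise.
* The exact permutation oracle enumerates all C(n, k) subsets and refuses
  above a 200,000-subset cap.
* `hypergeometric_pvalue` short-circuits k = 0 → 1 and delegates to the
  scipy survival function otherwise; BH delegates to statsmodels
  (`fdr_bh`), with an independent step-up implementation kept in the test
  suite as the oracle.
* Monte Carlo subsets are drawn by arg-partitioning one uniform random
  matrix (vectorised, without replacement); all streams are
  `numpy.random.Generator` seeded explicitly, and `run_ppea` consumes a
  single stream in sorted (species, pathway) order, making the whole pass
  bit-reproducible.
* Harmonic-mean combination returns the input unchanged for a single
  species, avoiding a gratuitous double-reciprocal rounding.

## Problem sizes in the test and acceptance suites

Oracle equivalences run on exhaustively enumerable instances (AUC ≤ 20
genes × 200 instances; Monte Carlo vs exact on universes ≤ 15 with 20,000
samples × 50 instances; hypergeometric on all consistent tuples with
N ≤ 12; BH on 100 random vectors). Calibration uses 100 signal-free
replicates of the strong preset (the planted pathway's Monte Carlo p at 999
samples must be ≤ 0.05 in at most 8); recovery uses 50 strong-preset
replicates (rank 1 required in ≥ 45). These sizes give stable counts at
desk scale while keeping the full suite under a minute of compute.

## Known limitations

* Exact-term phenotype matching understates evidence when observations are
  recorded at a different ontology granularity than annotations.
* The gene-sampling null ignores annotation correlation between genes of a
  pathway (co-annotation would widen the null); the calibration results
  apply to the generator's independence structure.
* The harmonic mean is a ranking heuristic here; combined values should not
  be read as calibrated tail probabilities without a multiple-combination
  correction.
* Evidence flags summarise provenance only; they carry no weight in the
  ranking statistic.
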