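# toxpaths

Cross-species phenotype–pathway enrichment for predictive toxicology.

Regulatory hazard assessment increasingly relies on new approach methods
(NAMs): assays in small model organisms — *C. elegans*, zebrafish,
*Drosophila*, *Dictyostelium* — and in vitro systems, instead of rodent
studies. The hard part is integrating those heterogeneous readouts into a
single mechanistic prediction for humans. `toxpaths` does this through
evolutionarily conserved molecular pathways: phenotypes observed in each
species are mapped to genes via phenotype-ontology annotations, human
pathways are projected into each species through orthology, and the species
are combined into one ranked list of candidate pathways for a compound.

It is a library plus a small CLI, aimed at computational toxicologists and
systems biologists who have per-species gene–phenotype tables (WormBase-,
ZFIN-, FlyBase-style), human pathway membership and ortholog pairs, and
want auditable, reproducible pathway rankings.

## The statistics at the core

**Forward direction — phenotypes → pathways.** For a species *s* with
annotated-gene universe *U_s*, each gene *g* gets score
*x_g* = #{query phenotypes annotated to *g*}. A pathway *P* projected into
*s* (union of ortholog images of its human members, restricted to *U_s*)
is scored by the Mann–Whitney AUC

  AUC = P(x_in > x_out) + ½·P(x_in = x_out),

for random in-set/out-set gene pairs. Significance comes from a Monte Carlo
null of uniform random same-size gene sets with the add-one estimator
*p* = (1 + #{AUC\* ≥ AUC}) / (n + 1), and species are combined per pathway
by the unweighted harmonic mean *p̃* = k / Σ 1/p_i, which drives the final
ranking. In-vitro target hits inside a pathway are reported as corroborating
evidence flags, never folded into *p̃*.

**Reverse direction — pathway → expected phenotypes.** For a human pathway
projected into a model species, each phenotype with *K* annotated universe
genes is tested for over-representation among the *n* projected genes with
the upper-tail hypergeometric probability P(X ≥ k | N, K, n), then
Benjamini–Hochberg adjusted within the query. This predicts which phenotypic
endpoints a pathway-perturbing chemical should produce in that species —
i.e. which follow-up assay would validate the mechanism.

Also included: ortholog relation classification (one2one / one2many /
many2many from bipartite degrees), pathway conservation profiles, Tanimoto
fingerprint similarity for read-across, and a synthetic knowledge-base
generator with plantable ground-truth signals.

## Worked example

Simulate a knowledge base with a signal planted on pathway `PWY_001`
(compound `CPD_PLANTED`), then run the substance-first flow:

```sh
toxpaths simulate --out demo/kb --seed 7
toxpaths substance CPD_PLANTED --kb demo/kb --out demo/results --seed 11 --similar
cut -f1-7 demo/results/pathways_ranked.tsv | head -4
```

```text
pathway_id  pathway_name           combined_p             rank  nonmammalian_phenotypes  mammalian_phenotypes  in_vitro_targets
PWY_001     Synthetic pathway 001  0.000999000999000999   1     1                        0                     1
PWY_020     Synthetic pathway 020  0.0029900266447564464  2     1                        0                     0
PWY_017     Synthetic pathway 017  0.12930466915088554    3     1                        0                     0
```

The planted pathway ranks first with the smallest attainable combined
p-value (1/1001 in every species at the default 1000 null samples — the
add-one floor), supported by non-mammalian phenotype evidence and by
in-vitro target hits inside the pathway. The per-species AUC, p and gene
counts follow in the remaining columns of the table.

The pathway-first flow reports conservation and predicted phenotypes:

```sh
toxpaths pathway PWY_001 --kb demo/kb --out demo/pathway --predict-species celegans
head -4 demo/pathway/conservation.tsv
```

```text
species_id  n_human_genes  n_conserved  conservation_fraction  n_one2one  n_one2many  n_many2many
celegans    16             12           0.75                   11         0           1
drosophila  16             10           0.625                  8          0           2
zebrafish   16             15           0.9375                 11         3           1
```

Twelve of the sixteen human pathway genes have a worm ortholog (75 %
conserved, mostly one-to-one), so the worm is a sensible validation species;
`predicted_phenotypes.tsv` then lists each worm phenotype with its overlap
counts, hypergeometric p and BH q. Every command writes a `manifest.json`
(parameters, seed, input digests, version) sufficient to reproduce the run,
and `toxpaths validate --kb DIR` checks a knowledge base strictly.

The same operations are available as library functions
(`toxpaths.run_ppea`, `toxpaths.predict_phenotypes`,
`toxpaths.conservation_profile`, `toxpaths.top_k_similar`, …) on a
`KnowledgeBase` loaded from eight TSV tables.

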