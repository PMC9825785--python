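"""Phenotype prediction by hypergeometric enrichment of projected pathways.

The reverse direction of the platform: given a human pathway and a model
species, which phenotypes should a chemical hitting that pathway produce in
that species?  The pathway is projected through orthology into the species,
restricted to the annotated-gene universe (the same universe convention the
enrichment direction uses), and each phenotype with at least one annotated
universe gene is tested for over-representation among the projected genes
with an upper-tail hypergeometric test; p-values are Benjamini-Hochberg
adjusted within the (pathway, species) query.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .knowledge_base import KnowledgeBase, pathway_gene_set

__all__ = [
    "PhenotypePrediction",
    "hypergeometric_pvalue",
    "bh_adjust",
    "predict_phenotypes",
]


@dataclass(frozen=True)
class PhenotypePrediction:
    """One phenotype's enrichment among a pathway's projected genes."""

    pathway_id: str
    species_id: str
    phenotype_id: str
    k_overlap: int       # projected pathway genes annotated with the phenotype
    n_pathway: int       # projected pathway genes in the universe
    K_annotated: int     # universe genes annotated with the phenotype
    N_universe: int
    p_value: float
    q_value: float
    significant: bool = False


def hypergeometric_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` successes among ``n`` drawn genes, when ``K`` of the ``N`` universe
    genes are annotated.  ``k = 0`` gives 1 exactly.
    """
    if N < 0 or not 0 <= K <= N or not 0 <= n <= N:
        raise ValueError(f"inconsistent counts: n={n}, K={K}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"inconsistent counts: k={k} not in [0, min({n}, {K})]")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order-aligned with the
    input, monotone after sorting and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def predict_phenotypes(
    kb: KnowledgeBase,
    pathway_id: str,
    species_id: str,
    q_threshold: float = 0.05,
) -> list[PhenotypePrediction]:
    """Test every annotated phenotype of a model species for enrichment in
    the projected gene set of a human pathway.

    The universe is the species' annotated genes; the projected set is the
    pathway's ortholog image intersected with the universe.  One test is run
    per phenotype with ``K_annotated >= 1``; BH adjustment is applied across
    all tested phenotypes of this query.  Results are sorted by
    (q, p, phenotype_id) and flagged against ``q_threshold`` (always
    reported, never silently filtered).

    Raises :class:`ValueError` when the species is the reference species or
    the pathway has no conserved annotated gene in the species.
    """
    kb._require_species(species_id)
    if species_id == kb.reference_species_id:
        raise ValueError("phenotype prediction targets a model species, not the reference")
    universe = set(kb.annotated_genes(species_id))
    projected = pathway_gene_set(kb, pathway_id, species_id) & universe
    if not projected:
        raise ValueError(
            f"pathway {pathway_id!r} not conserved in species {species_id!r} "
            "(empty projected set over the annotated universe)"
        )
    N = len(universe)
    n = len(projected)

    phen_to_genes = kb.phenotype_to_genes(species_id)
    tested: list[tuple[str, int, int]] = []  # (phenotype, k, K)
    for pid in sorted(phen_to_genes):
        annotated = phen_to_genes[pid] & universe
        K = len(annotated)
        if K == 0:
            continue
        k = len(annotated & projected)
        tested.append((pid, k, K))
    p_values = [hypergeometric_pvalue(k, n, K, N) for _, k, K in tested]
    q_values = bh_adjust(p_values)

    predictions = [
        PhenotypePrediction(
            pathway_id=pathway_id,
            species_id=species_id,
            phenotype_id=pid,
            k_overlap=k,
            n_pathway=n,
            K_annotated=K,
            N_universe=N,
            p_value=p,
            q_value=q,
            significant=q <= q_threshold,
        )
        for (pid, k, K), p, q in zip(tested, p_values, q_values)
    ]
    predictions.sort(key=lambda r: (r.q_value, r.p_value, r.phenotype_id))
    return predictions


def predictions_to_rows(predictions: Sequence[PhenotypePrediction]) -> list[dict[str, object]]:
    return [
        {
            "phenotype_id": r.phenotype_id,
            "k_overlap": r.k_overlap,
            "n_pathway": r.n_pathway,
            "K_annotated": r.K_annotated,
            "N_universe": r.N_universe,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "significant": int(r.significant),
        }
        for r in predictions
    ]
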