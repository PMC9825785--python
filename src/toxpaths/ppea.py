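"""Phenotype Pathway Enrichment Analysis (PPEA).

Given phenotypes observed in model organisms after exposure to a chemical,
rank human pathways by how strongly their (ortholog-projected) gene sets are
enriched among the genes linked to those phenotypes:

1. per species, score every annotated gene by the number of distinct query
   phenotypes annotated to it (genes never annotated in that species are
   outside the universe — they are unobservable in this assay class and
   would dilute the null);
2. score each pathway's projected gene set with the Mann-Whitney AUC — the
   probability that a random in-set gene outscores a random out-set gene,
   ties credited 0.5;
3. turn the AUC into a p-value by Monte Carlo sampling of random same-size
   gene sets from the universe, with the add-one estimator
   ``(1 + #{null >= observed}) / (n + 1)`` so p is never zero;
4. combine per-species p-values for each pathway with the unweighted
   harmonic mean and rank ascending.

In-vitro target hits enter as corroborating evidence flags (plus the
supporting gene list), never into the combined p-value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .knowledge_base import (
    KnowledgeBase,
    ObservedPhenotypeSet,
    genes_for_phenotypes,
    pathway_gene_set,
)

if TYPE_CHECKING:  # pragma: no cover
    pass

__all__ = [
    "GeneScoreVector",
    "SpeciesEnrichment",
    "EvidenceFlags",
    "EnrichmentResult",
    "EvidenceFilter",
    "DegenerateSetError",
    "NoEvidenceError",
    "auc_score",
    "monte_carlo_pvalue",
    "exact_permutation_pvalue",
    "harmonic_mean_combine",
    "build_gene_score_vector",
    "in_vitro_pathway_hits",
    "run_ppea",
    "filter_results",
    "EVIDENCE_FILTER_MODES",
]

#: float slack when comparing null AUCs against the observed AUC, so that
#: exact ties (same rank arithmetic on both sides) always count as >=
_AUC_TIE_TOL = 1e-12

#: subsets enumerated by exact_permutation_pvalue before it refuses
DEFAULT_EXACT_CAP = 200_000

EVIDENCE_FILTER_MODES = (
    "nonmammalian_phenotypes",
    "mammalian_phenotypes",
    "in_vitro_targets",
    "all_evidence",
    "any_evidence",
)


class DegenerateSetError(ValueError):
    """Gene set empty (after restriction to the universe) or equal to it."""


class NoEvidenceError(ValueError):
    """No species yields any scoreable pathway for the given observations."""


# ---------------------------------------------------------------------------
# Score vectors
# ---------------------------------------------------------------------------


@dataclass
class GeneScoreVector:
    """Per-species gene scores over an ordered universe.

    ``scores[i]`` is the number of distinct query phenotypes annotated to
    ``universe[i]``; genes matched by no query phenotype score 0.
    """

    species_id: str
    universe: tuple[str, ...]
    scores: np.ndarray  # int array aligned with `universe`

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if len(self.scores) != len(self.universe):
            raise ValueError("scores and universe lengths differ")
        if np.any(self.scores < 0):
            raise ValueError("scores must be non-negative")
        self._index = {g: i for i, g in enumerate(self.universe)}

    @classmethod
    def from_counts(
        cls, species_id: str, counts: Mapping[str, int], universe: Iterable[str]
    ) -> "GeneScoreVector":
        universe = tuple(universe)
        scores = np.array([counts.get(g, 0) for g in universe], dtype=np.int64)
        return cls(species_id=species_id, universe=universe, scores=scores)

    @property
    def ranks(self) -> np.ndarray:
        """Average ranks of the scores (ties share their mean rank)."""
        cached = getattr(self, "_ranks", None)
        if cached is None:
            cached = rankdata(self.scores, method="average")
            self._ranks = cached
        return cached

    def indices_of(self, gene_set: Iterable[str]) -> np.ndarray:
        """Universe indices of the genes in ``gene_set`` that lie in the
        universe (silently restricting to it)."""
        idx = sorted(self._index[g] for g in gene_set if g in self._index)
        return np.asarray(idx, dtype=np.intp)


def build_gene_score_vector(
    kb: KnowledgeBase, species_id: str, phenotype_ids: Iterable[str]
) -> GeneScoreVector:
    """Score the annotated-gene universe of a species against query
    phenotypes (count of distinct matched phenotypes per gene)."""
    universe = kb.annotated_genes(species_id)
    counts = genes_for_phenotypes(kb, species_id, phenotype_ids)
    return GeneScoreVector.from_counts(species_id, counts, universe)


# ---------------------------------------------------------------------------
# AUC and its null distribution
# ---------------------------------------------------------------------------


def _auc_from_rank_sum(rank_sum: float, k: int, n: int) -> float:
    """Mann-Whitney AUC from the sum of average ranks of the in-set genes.

    U = rank_sum - k(k+1)/2 counts out-set genes beaten by in-set genes with
    half-credit for ties; AUC = U / (k * (n - k)).
    """
    return (rank_sum - k * (k + 1) / 2.0) / (k * (n - k))


def auc_score(scores: GeneScoreVector, gene_set: Iterable[str]) -> float:
    """Probability a random in-set gene outscores a random out-set gene
    (ties 0.5), restricted to the universe.

    Raises :class:`DegenerateSetError` when the restricted set or its
    complement is empty — the AUC is undefined there.
    """
    idx = scores.indices_of(gene_set)
    n = len(scores.universe)
    k = len(idx)
    if k == 0 or k == n:
        raise DegenerateSetError(
            f"degenerate set: {k} of {n} universe genes in the set"
        )
    return _auc_from_rank_sum(float(scores.ranks[idx].sum()), k, n)


def _null_aucs(
    scores: GeneScoreVector, set_size: int, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """AUCs of ``n_samples`` uniform random gene sets of ``set_size`` drawn
    without replacement from the universe (vectorised via argpartition of a
    random matrix; each row is a uniform random subset)."""
    n = len(scores.universe)
    k = set_size
    noise = rng.random((n_samples, n))
    idx = np.argpartition(noise, k - 1, axis=1)[:, :k]
    rank_sums = scores.ranks[idx].sum(axis=1)
    return (rank_sums - k * (k + 1) / 2.0) / (k * (n - k))


def monte_carlo_pvalue(
    scores: GeneScoreVector,
    set_size: int,
    observed_auc: float,
    n_samples: int,
    seed: int | np.random.Generator,
) -> float:
    """Add-one Monte Carlo p-value for an observed AUC.

    Draws ``n_samples`` uniform random gene sets of ``set_size`` from the
    universe and returns ``(1 + #{null AUC >= observed}) / (n_samples + 1)``;
    deterministic for a fixed integer seed.  The estimate is bounded below by
    ``1 / (n_samples + 1)`` so downstream harmonic-mean combination never
    sees a zero.
    """
    n = len(scores.universe)
    if not 0 < set_size < n:
        raise ValueError(f"set_size must be in (0, {n}), got {set_size}")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    aucs = _null_aucs(scores, set_size, n_samples, rng)
    n_ge = int(np.count_nonzero(aucs >= observed_auc - _AUC_TIE_TOL))
    return (1 + n_ge) / (n_samples + 1)


def exact_permutation_pvalue(
    scores: GeneScoreVector,
    set_size: int,
    observed_auc: float,
    cap: int = DEFAULT_EXACT_CAP,
) -> float:
    """Exhaustive version of the Monte Carlo null: the proportion of *all*
    size-k subsets of the universe whose AUC >= observed (no add-one term).

    Intended as a small-universe oracle; refuses when the number of subsets
    exceeds ``cap``.
    """
    n = len(scores.universe)
    if not 0 < set_size < n:
        raise ValueError(f"set_size must be in (0, {n}), got {set_size}")
    total = math.comb(n, set_size)
    if total > cap:
        raise ValueError(f"{total} subsets exceed the cap of {cap}")
    ranks = scores.ranks
    k = set_size
    n_ge = 0
    threshold = observed_auc - _AUC_TIE_TOL
    for combo in itertools.combinations(range(n), k):
        auc = _auc_from_rank_sum(float(ranks[list(combo)].sum()), k, n)
        if auc >= threshold:
            n_ge += 1
    return n_ge / total


def harmonic_mean_combine(p_values: Sequence[float]) -> float:
    """Unweighted harmonic mean k / sum(1/p_i) of per-species p-values.

    Species without evidence must be excluded by the caller, never imputed.
    Values must lie in (0, 1]; the result lies between min(p) and max(p).
    """
    if len(p_values) == 0:
        raise ValueError("cannot combine an empty list of p-values")
    for p in p_values:
        if not 0 < p <= 1:
            raise ValueError(f"p-values must be in (0, 1], got {p}")
    if len(p_values) == 1:
        return float(p_values[0])  # exact identity on singletons
    return len(p_values) / sum(1.0 / p for p in p_values)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesEnrichment:
    pathway_id: str
    species_id: str
    set_size_in_species: int
    auc: float
    p_value: float
    n_null_samples: int
    seed: int


@dataclass(frozen=True)
class EvidenceFlags:
    nonmammalian_phenotypes: bool = False
    mammalian_phenotypes: bool = False
    in_vitro_targets: bool = False

    def as_dict(self) -> dict[str, bool]:
        return {
            "nonmammalian_phenotypes": self.nonmammalian_phenotypes,
            "mammalian_phenotypes": self.mammalian_phenotypes,
            "in_vitro_targets": self.in_vitro_targets,
        }


@dataclass
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    per_species: list[SpeciesEnrichment]
    combined_p: float
    evidence: EvidenceFlags
    #: human in-vitro target genes of the queried compound inside this pathway
    in_vitro_support: frozenset[str] = frozenset()
    rank: int = 0


@dataclass(frozen=True)
class EvidenceFilter:
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in EVIDENCE_FILTER_MODES:
            raise ValueError(
                f"unknown filter mode {self.mode!r}; expected one of "
                f"{EVIDENCE_FILTER_MODES}"
            )

    def keeps(self, evidence: EvidenceFlags) -> bool:
        flags = (
            evidence.nonmammalian_phenotypes,
            evidence.mammalian_phenotypes,
            evidence.in_vitro_targets,
        )
        if self.mode == "all_evidence":
            return all(flags)
        if self.mode == "any_evidence":
            return any(flags)
        return getattr(evidence, self.mode)


def in_vitro_pathway_hits(kb: KnowledgeBase, compound_id: str) -> dict[str, set[str]]:
    """Pathway -> the compound's in-vitro target genes inside that pathway
    (human gene set intersection); pathways without support are omitted."""
    if compound_id not in kb.compounds:
        raise ValueError(f"unknown compound {compound_id!r}")
    targets = {h.target_gene_id for h in kb.in_vitro_hits if h.compound_id == compound_id}
    out: dict[str, set[str]] = {}
    for pid, pathway in kb.pathways.items():
        overlap = targets & pathway.human_gene_ids
        if overlap:
            out[pid] = overlap
    return out


def run_ppea(
    kb: KnowledgeBase,
    observations: Sequence[ObservedPhenotypeSet],
    n_samples: int = 1000,
    seed: int = 0,
    compound_id: str | None = None,
) -> list[EnrichmentResult]:
    """Full enrichment pass: per-species AUC + Monte Carlo p for every
    scoreable pathway, harmonic-mean combination across species, evidence
    flags, ascending rank by combined p (ties by pathway_id).

    A pathway is skipped in a species when its projected gene set (restricted
    to the annotated-gene universe) is empty or spans the whole universe.
    ``compound_id``, when given, adds in-vitro evidence flags from that
    compound's target hits.

    Bit-reproducible for fixed ``(kb, observations, n_samples, seed)``: one
    random stream drives all Monte Carlo draws, consumed in sorted
    (species, pathway) order.
    """
    if not observations:
        raise ValueError("at least one observed phenotype set is required")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")

    # pool phenotypes per species across observation sets
    phen_by_species: dict[str, set[str]] = {}
    for obs in observations:
        phen_by_species.setdefault(obs.species_id, set()).update(obs.phenotype_ids)

    rng = np.random.default_rng(seed)
    per_pathway: dict[str, list[SpeciesEnrichment]] = {}
    species_with_signal: list[str] = []

    for sp in sorted(phen_by_species):
        scores = build_gene_score_vector(kb, sp, phen_by_species[sp])
        if len(scores.universe) == 0 or int(scores.scores.max(initial=0)) == 0:
            continue  # no query phenotype matched any annotated gene
        species_with_signal.append(sp)
        n = len(scores.universe)
        for pid in sorted(kb.pathways):
            idx = scores.indices_of(pathway_gene_set(kb, pid, sp))
            k = len(idx)
            if k == 0 or k == n:
                continue
            auc = _auc_from_rank_sum(float(scores.ranks[idx].sum()), k, n)
            p = monte_carlo_pvalue(scores, k, auc, n_samples, rng)
            per_pathway.setdefault(pid, []).append(
                SpeciesEnrichment(
                    pathway_id=pid,
                    species_id=sp,
                    set_size_in_species=k,
                    auc=auc,
                    p_value=p,
                    n_null_samples=n_samples,
                    seed=seed,
                )
            )

    if not per_pathway:
        raise NoEvidenceError(
            "no evidence: the observed phenotypes match no annotated gene in "
            "any species, or no pathway is scoreable"
        )

    vitro = in_vitro_pathway_hits(kb, compound_id) if compound_id is not None else {}
    mammal = {sp: kb.species[sp].is_mammal for sp in species_with_signal}

    results: list[EnrichmentResult] = []
    for pid, entries in per_pathway.items():
        combined = harmonic_mean_combine([e.p_value for e in entries])
        sp_here = {e.species_id for e in entries}
        evidence = EvidenceFlags(
            nonmammalian_phenotypes=any(not mammal[sp] for sp in sp_here),
            mammalian_phenotypes=any(mammal[sp] for sp in sp_here),
            in_vitro_targets=pid in vitro,
        )
        results.append(
            EnrichmentResult(
                pathway_id=pid,
                pathway_name=kb.pathways[pid].name,
                per_species=entries,
                combined_p=combined,
                evidence=evidence,
                in_vitro_support=frozenset(vitro.get(pid, ())),
            )
        )

    results.sort(key=lambda r: (r.combined_p, r.pathway_id))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results


def filter_results(
    results: Sequence[EnrichmentResult], evidence_filter: EvidenceFilter
) -> list[EnrichmentResult]:
    """Keep results matching the evidence filter; relative order preserved."""
    return [r for r in results if evidence_filter.keeps(r.evidence)]


# ---------------------------------------------------------------------------
# Tabular / JSON views (used by the CLI writers)
# ---------------------------------------------------------------------------


def results_to_rows(
    results: Sequence[EnrichmentResult], species_ids: Sequence[str]
) -> list[dict[str, object]]:
    rows = []
    for r in results:
        row: dict[str, object] = {
            "pathway_id": r.pathway_id,
            "pathway_name": r.pathway_name,
            "combined_p": r.combined_p,
            "rank": r.rank,
            "nonmammalian_phenotypes": int(r.evidence.nonmammalian_phenotypes),
            "mammalian_phenotypes": int(r.evidence.mammalian_phenotypes),
            "in_vitro_targets": int(r.evidence.in_vitro_targets),
        }
        by_sp = {e.species_id: e for e in r.per_species}
        for sp in species_ids:
            e = by_sp.get(sp)
            row[f"auc_{sp}"] = e.auc if e else ""
            row[f"p_{sp}"] = e.p_value if e else ""
            row[f"n_genes_{sp}"] = e.set_size_in_species if e else ""
        rows.append(row)
    return rows


def results_to_json(results: Sequence[EnrichmentResult]) -> list[dict[str, object]]:
    return [
        {
            "pathway_id": r.pathway_id,
            "pathway_name": r.pathway_name,
            "combined_p": r.combined_p,
            "rank": r.rank,
            "evidence": r.evidence.as_dict(),
            "in_vitro_support": sorted(r.in_vitro_support),
            "per_species": [
                {
                    "species_id": e.species_id,
                    "set_size_in_species": e.set_size_in_species,
                    "auc": e.auc,
                    "p_value": e.p_value,
                    "n_null_samples": e.n_null_samples,
                    "seed": e.seed,
                }
                for e in r.per_species
            ],
        }
        for r in results
    ]
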