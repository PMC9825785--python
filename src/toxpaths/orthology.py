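"""Orthology relation classification and pathway conservation profiles.

A human gene's relation class within one model species is derived from the
bipartite degrees of the human<->model ortholog pair set:

* ``one2one``  — the gene maps to exactly one model gene, and that model gene
  maps back only to this human gene;
* ``one2many`` — the gene maps to several model genes, each of which maps
  back only to it;
* ``many2many`` — at least one of its model genes also maps to another human
  gene.

Classes are always determined within a single model species at a time, the
convention used by comparative-genomics resources.  The class is *derived*
from the pair set rather than trusted from input; loaded labels that disagree
are flagged by knowledge-base validation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .knowledge_base import KnowledgeBase, OrthologPair

__all__ = [
    "OrthologyProfile",
    "classify_orthology_relation",
    "conservation_profile",
]


@dataclass(frozen=True)
class OrthologyProfile:
    """Cross-species conservation summary of one pathway in one species."""

    pathway_id: str
    species_id: str
    n_human_genes: int
    n_conserved: int
    conservation_fraction: float
    #: human pathway genes per relation class (each gene counted once)
    relation_counts: Mapping[str, int]


def classify_orthology_relation(
    pairs: Sequence["OrthologPair"],
    gene_species: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Classify each human gene appearing in ``pairs`` as one2one /
    one2many / many2many from the bipartite degree structure.

    ``pairs`` must all belong to one model species.  When ``gene_species``
    (gene_id -> species_id) is supplied, this precondition is checked and a
    :class:`ValueError` is raised on mixed-species input.
    """
    if gene_species is not None:
        model_species = {gene_species[p.model_gene_id] for p in pairs}
        if len(model_species) > 1:
            raise ValueError(
                f"ortholog pairs span multiple model species: {sorted(model_species)}"
            )
    human_to_model: dict[str, set[str]] = defaultdict(set)
    model_to_human: dict[str, set[str]] = defaultdict(set)
    for p in pairs:
        human_to_model[p.human_gene_id].add(p.model_gene_id)
        model_to_human[p.model_gene_id].add(p.human_gene_id)

    out: dict[str, str] = {}
    for hg, models in human_to_model.items():
        if any(len(model_to_human[mg]) > 1 for mg in models):
            out[hg] = "many2many"
        elif len(models) > 1:
            out[hg] = "one2many"
        else:
            out[hg] = "one2one"
    return out


def conservation_profile(kb: "KnowledgeBase", pathway_id: str) -> list["OrthologyProfile"]:
    """Per model species: how much of a human pathway is conserved and under
    which relation classes.

    Species with zero conserved genes still appear, with fraction 0.  The
    relation counts sum to ``n_conserved`` (each conserved human gene counted
    once under its class within that species).
    """
    from .knowledge_base import RELATION_CLASSES

    pathway = kb.pathways.get(pathway_id)
    if pathway is None:
        raise ValueError(f"unknown pathway {pathway_id!r}")
    n_human = len(pathway.human_gene_ids)

    profiles: list[OrthologyProfile] = []
    for sp in kb.model_species_ids:
        pairs = kb.ortholog_pairs_for_species(sp)
        classes = classify_orthology_relation(pairs)
        conserved = [hg for hg in pathway.human_gene_ids if hg in classes]
        counts = {cls: 0 for cls in RELATION_CLASSES}
        for hg in conserved:
            counts[classes[hg]] += 1
        profiles.append(
            OrthologyProfile(
                pathway_id=pathway_id,
                species_id=sp,
                n_human_genes=n_human,
                n_conserved=len(conserved),
                conservation_fraction=len(conserved) / n_human if n_human else 0.0,
                relation_counts=counts,
            )
        )
    return profiles


def profiles_to_rows(profiles: Iterable[OrthologyProfile]) -> list[dict[str, object]]:
    """Flatten profiles for tabular output."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "species_id": p.species_id,
                "n_human_genes": p.n_human_genes,
                "n_conserved": p.n_conserved,
                "conservation_fraction": p.conservation_fraction,
                "n_one2one": p.relation_counts.get("one2one", 0),
                "n_one2many": p.relation_counts.get("one2many", 0),
                "n_many2many": p.relation_counts.get("many2many", 0),
            }
        )
    return rows
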