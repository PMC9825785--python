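"""Synthetic knowledge-base generator with plantable compound signals.

Builds complete, schema-valid multi-species knowledge bases so every
statistic in the package can be exercised and calibrated without any
external download: a human gene catalog, model-species catalogs, random
human-gene pathways, ortholog pairs honouring a configurable
one2one/one2many/many2many mix, per-species phenotype vocabularies with
background gene-phenotype annotations, and compounds with random binary
fingerprints.

A compound -> pathway signal is planted at the *observation* level: the
planted compound's observed phenotypes are drawn, with probability
``signal_strength``, from the phenotypes annotated to the target pathway's
projected genes (else uniformly from the species vocabulary) — mirroring how
a real chemical produces phenotypes that converge on the genes of the
pathway it perturbs.  Annotations themselves are never edited.

All randomness flows from the single ``seed`` in :class:`SyntheticConfig`;
generation is fully deterministic (byte-identical TSV output for a fixed
seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .knowledge_base import (
    Compound,
    Gene,
    InVitroHit,
    KnowledgeBase,
    ObservedPhenotypeSet,
    OrthologPair,
    Pathway,
    PhenotypeAnnotation,
    Species,
    ValidationReport,
    pathway_gene_set,
    write_knowledge_base,
)

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "generate_knowledge_base",
    "plant_compound_signal",
    "write_fixture_set",
]

#: model-species roster, drawn from in order; (id, display name, is_mammal)
_SPECIES_ROSTER = (
    ("celegans", "Caenorhabditis elegans", False),
    ("zebrafish", "Danio rerio", False),
    ("drosophila", "Drosophila melanogaster", False),
    ("mouse", "Mus musculus", True),
    ("dicty", "Dictyostelium discoideum", False),
)

_GENE_PREFIX = {
    "human": "HSA",
    "celegans": "CEL",
    "zebrafish": "DRE",
    "drosophila": "DME",
    "mouse": "MMU",
    "dicty": "DDI",
}


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator knobs.  The defaults are the package's "strong" preset:
    a clearly-affected compound observed in three non-mammalian model
    species, sized so the full enrichment pass runs in seconds.

    Rates are probabilities in [0, 1]; ``signal_strength`` is the fraction
    of the planted compound's observed phenotypes drawn from the target
    pathway's phenotype pool rather than uniformly from the vocabulary.
    """

    seed: int = 0
    n_model_species: int = 3
    n_human_genes: int = 300
    genes_per_model_species: int = 450
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (10, 30)
    ortholog_retention: float = 0.8
    one2many_rate: float = 0.15
    many2many_rate: float = 0.10
    n_phenotypes_per_species: int = 100
    annotation_rate: float = 0.01
    signal_strength: float = 0.9
    n_observed_phenotypes: int = 15
    fingerprint_length: int = 128
    n_background_compounds: int = 3

    def validate(self) -> None:
        lo, hi = self.pathway_size_range
        if not (2 <= lo <= hi <= self.n_human_genes):
            raise ValueError(
                f"pathway_size_range {self.pathway_size_range} must lie within "
                f"[2, n_human_genes={self.n_human_genes}]"
            )
        for name in ("ortholog_retention", "one2many_rate", "many2many_rate",
                     "annotation_rate", "signal_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.one2many_rate + self.many2many_rate > 1.0:
            raise ValueError("one2many_rate + many2many_rate must not exceed 1")
        if not 1 <= self.n_model_species <= len(_SPECIES_ROSTER):
            raise ValueError(
                f"n_model_species must be in [1, {len(_SPECIES_ROSTER)}]"
            )
        for name in ("n_human_genes", "genes_per_model_species", "n_pathways",
                     "n_phenotypes_per_species", "n_observed_phenotypes",
                     "fingerprint_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_background_compounds < 0:
            raise ValueError("n_background_compounds must be >= 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        if "pathway_size_range" in data:
            data["pathway_size_range"] = tuple(data["pathway_size_range"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_json(self) -> str:
        data = dataclasses.asdict(self)
        data["pathway_size_range"] = list(self.pathway_size_range)
        return json.dumps(data, indent=2, sort_keys=True)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a planted compound -> pathway signal."""

    compound_id: str
    target_pathway_id: str
    #: species -> phenotype ids drawn from the pathway's phenotype pool
    signal_phenotypes: dict[str, list[str]] = field(default_factory=dict)
    #: species -> phenotype ids drawn uniformly from the vocabulary
    background_phenotypes: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "compound_id": self.compound_id,
                "target_pathway_id": self.target_pathway_id,
                "signal_phenotypes": self.signal_phenotypes,
                "background_phenotypes": self.background_phenotypes,
            },
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _species_rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # distinct reproducible streams for generation (0) and planting (1)
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                        spawn_key=(stream,)))


def generate_knowledge_base(config: SyntheticConfig) -> KnowledgeBase:
    """Generate a knowledge base that passes strict validation, fully
    deterministic for a fixed ``config.seed``."""
    config.validate()
    rng = _species_rng(config, 0)

    species = {"human": Species("human", "Homo sapiens", True, True)}
    for sid, name, mammal in _SPECIES_ROSTER[: config.n_model_species]:
        species[sid] = Species(sid, name, mammal, False)

    genes: dict[str, Gene] = {}
    human_genes = [f"HSA_{i:04d}" for i in range(1, config.n_human_genes + 1)]
    for gid in human_genes:
        genes[gid] = Gene(gid, "human", symbol=gid.replace("_", ""))
    model_catalog: dict[str, list[str]] = {}
    for sid in species:
        if sid == "human":
            continue
        prefix = _GENE_PREFIX[sid]
        catalog = [f"{prefix}_{i:04d}" for i in range(1, config.genes_per_model_species + 1)]
        for gid in catalog:
            genes[gid] = Gene(gid, sid, symbol=gid.replace("_", ""))
        model_catalog[sid] = catalog

    # pathways: random human-gene subsets
    lo, hi = config.pathway_size_range
    pathways: dict[str, Pathway] = {}
    for i in range(1, config.n_pathways + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(human_genes, size=size, replace=False)
        pid = f"PWY_{i:03d}"
        pathways[pid] = Pathway(pid, f"Synthetic pathway {i:03d}", frozenset(members))

    # orthologs: per species, assign each retained human gene a relation
    # class, then realise it with exclusive model partners (one2one /
    # one2many) or shared partners (many2many pairs of human genes)
    ortholog_pairs: list[OrthologPair] = []
    p_o2m, p_m2m = config.one2many_rate, config.many2many_rate
    p_o2o = 1.0 - p_o2m - p_m2m
    for sid in sorted(model_catalog):
        pool = iter(rng.permutation(model_catalog[sid]))
        retained = [g for g in human_genes if rng.random() < config.ortholog_retention]
        classes = rng.choice(
            ["one2one", "one2many", "many2many"],
            size=len(retained),
            p=[p_o2o, p_o2m, p_m2m],
        )
        m2m_queue: list[str] = []
        try:
            for hg, cls in zip(retained, classes):
                if cls == "one2one":
                    ortholog_pairs.append(OrthologPair(hg, next(pool), "one2one"))
                elif cls == "one2many":
                    for _ in range(int(rng.integers(2, 4))):
                        ortholog_pairs.append(OrthologPair(hg, next(pool), "one2many"))
                else:
                    m2m_queue.append(hg)
                    if len(m2m_queue) == 2:
                        shared = [next(pool), next(pool)]
                        for h in m2m_queue:
                            for m in shared:
                                ortholog_pairs.append(OrthologPair(h, m, "many2many"))
                        m2m_queue.clear()
            # a dangling many2many gene has no partner to share with: one2one
            for hg in m2m_queue:
                ortholog_pairs.append(OrthologPair(hg, next(pool), "one2one"))
        except StopIteration:
            raise ValueError(
                f"infeasible config: model gene catalog of {sid!r} "
                f"({config.genes_per_model_species}) exhausted while assigning "
                "orthologs; increase genes_per_model_species"
            ) from None

    # phenotype vocabularies + background annotations (all species)
    annotations: list[PhenotypeAnnotation] = []
    for sid in sorted(species):
        vocab = [f"PH_{sid}_{i:04d}" for i in range(1, config.n_phenotypes_per_species + 1)]
        catalog = human_genes if sid == "human" else model_catalog[sid]
        links = rng.random((len(catalog), len(vocab))) < config.annotation_rate
        for gi, pi in zip(*np.nonzero(links)):
            annotations.append(PhenotypeAnnotation(vocab[pi], sid, catalog[gi]))

    # background compounds with random fingerprints and in-vitro hits
    compounds: dict[str, Compound] = {}
    hits: list[InVitroHit] = []
    for i in range(1, config.n_background_compounds + 1):
        cid = f"CPD_BG{i}"
        fp = "".join(map(str, rng.integers(0, 2, size=config.fingerprint_length)))
        compounds[cid] = Compound(
            compound_id=cid,
            names=(f"background compound {i}",),
            cas=f"{10000 + i}-{50 + i}-{i}",
            fingerprint=fp,
        )
        for gid in rng.choice(human_genes, size=int(rng.integers(1, 4)), replace=False):
            hits.append(InVitroHit(cid, gid))

    return KnowledgeBase(
        species=species,
        genes=genes,
        pathways=pathways,
        ortholog_pairs=ortholog_pairs,
        phenotype_annotations=annotations,
        compounds=compounds,
        observed_phenotype_sets=[],
        in_vitro_hits=hits,
        validation_report=ValidationReport(),
    )


def plant_compound_signal(
    kb: KnowledgeBase,
    config: SyntheticConfig,
    pathway_id: str,
) -> tuple[list[ObservedPhenotypeSet], PlantedTruth]:
    """Create a compound whose observed phenotypes converge on one pathway.

    Per model species with a non-empty projected gene set,
    ``n_observed_phenotypes`` phenotypes are drawn: with probability
    ``signal_strength`` uniformly from the phenotypes annotated to the
    pathway's projected genes, otherwise uniformly from the species
    vocabulary.  The compound, its observations and two in-vitro hits inside
    the target pathway are added to ``kb``; the draws and ground truth are
    returned.  Deterministic for a fixed ``config.seed``.
    """
    if pathway_id not in kb.pathways:
        raise ValueError(f"unknown pathway {pathway_id!r}")
    rng = _species_rng(config, 1)

    signal: dict[str, list[str]] = {}
    background: dict[str, list[str]] = {}
    observations: list[ObservedPhenotypeSet] = []
    any_conserved = False
    for sid in kb.model_species_ids:
        projected = pathway_gene_set(kb, pathway_id, sid)
        if not projected:
            continue
        any_conserved = True
        phen_to_genes = kb.phenotype_to_genes(sid)
        pool = sorted(
            pid for pid, gset in phen_to_genes.items() if gset & projected
        )
        vocab = [f"PH_{sid}_{i:04d}" for i in range(1, config.n_phenotypes_per_species + 1)]
        drawn_signal: list[str] = []
        drawn_background: list[str] = []
        for _ in range(config.n_observed_phenotypes):
            if pool and rng.random() < config.signal_strength:
                drawn_signal.append(pool[int(rng.integers(len(pool)))])
            else:
                drawn_background.append(vocab[int(rng.integers(len(vocab)))])
        signal[sid] = drawn_signal
        background[sid] = drawn_background
        observations.append(
            ObservedPhenotypeSet(
                compound_id="CPD_PLANTED",
                species_id=sid,
                phenotype_ids=frozenset(drawn_signal + drawn_background),
            )
        )
    if not any_conserved:
        raise ValueError(
            f"pathway {pathway_id!r} has no ortholog in any model species"
        )

    fp = "".join(map(str, rng.integers(0, 2, size=config.fingerprint_length)))
    kb.compounds["CPD_PLANTED"] = Compound(
        compound_id="CPD_PLANTED",
        names=("planted test compound",),
        cas="99999-99-9",
        fingerprint=fp,
    )
    pathway_genes = sorted(kb.pathways[pathway_id].human_gene_ids)
    n_hits = min(2, len(pathway_genes))
    for gid in rng.choice(pathway_genes, size=n_hits, replace=False):
        kb.in_vitro_hits.append(InVitroHit("CPD_PLANTED", gid))
    kb.observed_phenotype_sets.extend(observations)

    truth = PlantedTruth(
        compound_id="CPD_PLANTED",
        target_pathway_id=pathway_id,
        signal_phenotypes=signal,
        background_phenotypes=background,
    )
    return observations, truth


def write_fixture_set(
    kb: KnowledgeBase,
    observations: list[ObservedPhenotypeSet],
    truth: PlantedTruth | None,
    directory: str | Path,
) -> dict[str, int]:
    """Write the eight knowledge-base TSV tables plus ``planted_truth.json``;
    returns {filename: row count}.  ``load_knowledge_base`` round-trips the
    output."""
    directory = Path(directory)
    manifest = write_knowledge_base(kb, directory)
    if truth is not None:
        (directory / "planted_truth.json").write_text(
            truth.to_json() + "\n", encoding="utf-8"
        )
        manifest["planted_truth.json"] = 1
    return manifest
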