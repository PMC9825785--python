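"""Multi-species knowledge base: typed records, TSV I/O and validation.

The knowledge base is the hub every analysis reads from: gene catalogs per
species, human pathway membership (pathways are stored directly as human gene
sets; the protein layer is collapsed because all downstream statistics operate
on genes), human<->model ortholog pairs with their relation class,
per-species gene-phenotype annotations, compounds with optional binary
fingerprints, compound-phenotype observations and in-vitro target hits.

On-disk format is eight UTF-8 TSV tables with a header row (see
``TABLE_COLUMNS``).  Loading validates referential integrity: in strict mode
any integrity error aborts; in lenient mode offending rows are dropped and
recorded in the :class:`ValidationReport` attached to the returned
:class:`KnowledgeBase`.

Identifiers are opaque, case-sensitive tokens; only surrounding whitespace is
trimmed.  Phenotype term identifiers are matched exactly — no ontology
(is-a) propagation is performed.
"""

from __future__ import annotations

import io
from collections import defaultdict
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Species",
    "Gene",
    "OrthologPair",
    "Pathway",
    "PhenotypeAnnotation",
    "Compound",
    "ObservedPhenotypeSet",
    "InVitroHit",
    "KnowledgeBase",
    "ValidationIssue",
    "ValidationReport",
    "KnowledgeBaseError",
    "MissingTableError",
    "SchemaError",
    "IntegrityError",
    "RELATION_CLASSES",
    "TABLE_COLUMNS",
    "load_knowledge_base",
    "write_knowledge_base",
    "genes_for_phenotypes",
    "pathway_gene_set",
]

RELATION_CLASSES = ("one2one", "one2many", "many2many")

#: table stem -> ordered column names of <stem>.tsv
TABLE_COLUMNS: dict[str, tuple[str, ...]] = {
    "species": ("species_id", "display_name", "is_mammal", "is_reference"),
    "genes": ("gene_id", "species_id", "symbol"),
    "pathways": ("pathway_id", "name", "gene_id"),
    "orthologs": ("human_gene_id", "model_gene_id", "relation"),
    "phenotype_annotations": ("phenotype_id", "species_id", "gene_id"),
    "compounds": ("compound_id", "name", "cas", "ec", "smiles", "fingerprint"),
    "observed_phenotypes": ("compound_id", "species_id", "phenotype_id"),
    "in_vitro_hits": ("compound_id", "target_gene_id"),
}


class KnowledgeBaseError(Exception):
    """Base class for knowledge-base loading/validation failures."""


class MissingTableError(KnowledgeBaseError):
    """A required TSV table is absent from the input directory."""


class SchemaError(KnowledgeBaseError):
    """A table is present but lacks a required column."""


class IntegrityError(KnowledgeBaseError):
    """Referential-integrity violation (strict mode, or unrecoverable)."""


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Species:
    species_id: str
    display_name: str
    is_mammal: bool
    is_reference: bool = False


@dataclass(frozen=True)
class Gene:
    gene_id: str
    species_id: str
    symbol: str = ""


@dataclass(frozen=True)
class OrthologPair:
    """A human gene paired with one of its model-species orthologs.

    ``relation`` is the one2one / one2many / many2many class of the *human*
    gene within the model species, derived from the bipartite degrees of the
    full pair set (see :mod:`toxpaths.orthology`).
    """

    human_gene_id: str
    model_gene_id: str
    relation: str


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    human_gene_ids: frozenset[str]


@dataclass(frozen=True)
class PhenotypeAnnotation:
    phenotype_id: str
    species_id: str
    gene_id: str


@dataclass(frozen=True)
class Compound:
    compound_id: str
    names: tuple[str, ...] = ()
    cas: str = ""
    ec: str = ""
    smiles: str = ""
    #: bitstring of '0'/'1'; empty string means no fingerprint
    fingerprint: str = ""


@dataclass(frozen=True)
class ObservedPhenotypeSet:
    """Phenotypes observed in one species after exposure to a compound."""

    compound_id: str
    species_id: str
    phenotype_ids: frozenset[str]


@dataclass(frozen=True)
class InVitroHit:
    compound_id: str
    target_gene_id: str


@dataclass(frozen=True)
class ValidationIssue:
    level: str  # "error" | "warning"
    category: str  # "missing table" | "schema" | "integrity" | ...
    table: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    def add(self, level: str, category: str, table: str, message: str) -> None:
        self.issues.append(ValidationIssue(level, category, table, message))

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.level == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.level == "warning"]

    def summary(self) -> str:
        lines = [f"{i.level}[{i.category}] {i.table}: {i.message}" for i in self.issues]
        return "\n".join(lines) if lines else "no issues"


# ---------------------------------------------------------------------------
# The knowledge base container
# ---------------------------------------------------------------------------


@dataclass
class KnowledgeBase:
    species: dict[str, Species]
    genes: dict[str, Gene]
    pathways: dict[str, Pathway]
    ortholog_pairs: list[OrthologPair]
    phenotype_annotations: list[PhenotypeAnnotation]
    compounds: dict[str, Compound]
    observed_phenotype_sets: list[ObservedPhenotypeSet]
    in_vitro_hits: list[InVitroHit]
    validation_report: ValidationReport = field(default_factory=ValidationReport)

    # -- species helpers ----------------------------------------------------

    @cached_property
    def reference_species_id(self) -> str:
        refs = [s.species_id for s in self.species.values() if s.is_reference]
        if len(refs) != 1:
            raise IntegrityError(
                f"knowledge base must have exactly one reference species, found {refs}"
            )
        return refs[0]

    @property
    def model_species_ids(self) -> list[str]:
        ref = self.reference_species_id
        return sorted(s for s in self.species if s != ref)

    # -- derived indexes (built lazily, assume loaded data is immutable) ----

    @cached_property
    def _annotations_by_species(self) -> dict[str, dict[str, set[str]]]:
        """species -> phenotype_id -> set of gene_ids."""
        out: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
        for ann in self.phenotype_annotations:
            out[ann.species_id][ann.phenotype_id].add(ann.gene_id)
        return {sp: dict(d) for sp, d in out.items()}

    @cached_property
    def _gene_phenotypes(self) -> dict[str, set[str]]:
        """gene_id -> set of phenotype_ids annotated to it."""
        out: dict[str, set[str]] = defaultdict(set)
        for ann in self.phenotype_annotations:
            out[ann.gene_id].add(ann.phenotype_id)
        return dict(out)

    @cached_property
    def _orthologs_by_species(self) -> dict[str, list[OrthologPair]]:
        """model species -> ortholog pairs whose model gene lives there."""
        out: dict[str, list[OrthologPair]] = defaultdict(list)
        for pair in self.ortholog_pairs:
            gene = self.genes.get(pair.model_gene_id)
            if gene is not None:
                out[gene.species_id].append(pair)
        return dict(out)

    @cached_property
    def _human_to_model(self) -> dict[str, dict[str, set[str]]]:
        """model species -> human gene -> set of model genes."""
        out: dict[str, dict[str, set[str]]] = {}
        for sp, pairs in self._orthologs_by_species.items():
            mapping: dict[str, set[str]] = defaultdict(set)
            for p in pairs:
                mapping[p.human_gene_id].add(p.model_gene_id)
            out[sp] = dict(mapping)
        return out

    def annotated_genes(self, species_id: str) -> tuple[str, ...]:
        """Genes of a species carrying at least one phenotype annotation.

        This is the score/test universe shared by the enrichment and the
        phenotype-prediction directions of the platform.
        """
        self._require_species(species_id)
        genes = {
            ann.gene_id
            for ann in self.phenotype_annotations
            if ann.species_id == species_id
        }
        return tuple(sorted(genes))

    def phenotype_vocabulary(self, species_id: str) -> tuple[str, ...]:
        self._require_species(species_id)
        return tuple(sorted(self._annotations_by_species.get(species_id, {})))

    def phenotype_to_genes(self, species_id: str) -> Mapping[str, set[str]]:
        self._require_species(species_id)
        return self._annotations_by_species.get(species_id, {})

    def ortholog_pairs_for_species(self, species_id: str) -> list[OrthologPair]:
        self._require_species(species_id)
        return list(self._orthologs_by_species.get(species_id, []))

    def observations_for_compound(self, compound_id: str) -> list[ObservedPhenotypeSet]:
        if compound_id not in self.compounds:
            raise ValueError(f"unknown compound {compound_id!r}")
        return [o for o in self.observed_phenotype_sets if o.compound_id == compound_id]

    def _require_species(self, species_id: str) -> None:
        if species_id not in self.species:
            raise ValueError(f"unknown species {species_id!r}")


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def _read_table(directory: Path, stem: str) -> pd.DataFrame:
    path = directory / f"{stem}.tsv"
    if not path.is_file():
        raise MissingTableError(f"missing table: {path.name} (in {directory})")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in TABLE_COLUMNS[stem]:
        if col not in df.columns:
            raise SchemaError(f"schema error: table {stem!r} lacks column {col!r}")
    for col in df.columns:
        df[col] = df[col].str.strip()
    return df


def _parse_flag(value: str) -> bool:
    return value.strip() in ("1", "true", "True")


def load_knowledge_base(directory: str | Path, strict: bool = True) -> KnowledgeBase:
    """Load and validate the eight TSV tables of a knowledge base.

    Parameters
    ----------
    directory
        Directory holding ``species.tsv``, ``genes.tsv``, ``pathways.tsv``,
        ``orthologs.tsv``, ``phenotype_annotations.tsv``, ``compounds.tsv``,
        ``observed_phenotypes.tsv`` and ``in_vitro_hits.tsv``.
    strict
        If True, any referential-integrity error raises
        :class:`IntegrityError`.  If False, offending rows are dropped and
        the problems recorded in ``kb.validation_report``.

    Missing files raise :class:`MissingTableError` and missing columns raise
    :class:`SchemaError` in both modes.
    """
    directory = Path(directory)
    report = ValidationReport()
    tables = {stem: _read_table(directory, stem) for stem in TABLE_COLUMNS}

    # species ---------------------------------------------------------------
    species: dict[str, Species] = {}
    for row in tables["species"].itertuples(index=False):
        sid = row.species_id
        if not sid:
            report.add("error", "integrity", "species", "empty species_id")
            continue
        if sid in species:
            report.add("error", "integrity", "species", f"duplicate species_id {sid!r}")
            continue
        species[sid] = Species(
            species_id=sid,
            display_name=row.display_name,
            is_mammal=_parse_flag(row.is_mammal),
            is_reference=_parse_flag(row.is_reference),
        )
    refs = [s for s in species.values() if s.is_reference]
    if len(refs) != 1:
        raise IntegrityError(
            f"exactly one reference species required, found {len(refs)}"
        )
    ref_id = refs[0].species_id

    # genes -----------------------------------------------------------------
    genes: dict[str, Gene] = {}
    for row in tables["genes"].itertuples(index=False):
        gid = row.gene_id
        if not gid:
            report.add("error", "integrity", "genes", "empty gene_id")
            continue
        if gid in genes:
            report.add("error", "integrity", "genes", f"duplicate gene_id {gid!r}")
            continue
        if row.species_id not in species:
            report.add(
                "error", "integrity", "genes",
                f"gene {gid!r} references unknown species {row.species_id!r}",
            )
            continue
        genes[gid] = Gene(gene_id=gid, species_id=row.species_id, symbol=row.symbol)

    # pathways (one row per membership) -------------------------------------
    pathway_rows: dict[str, tuple[str, set[str]]] = {}
    for row in tables["pathways"].itertuples(index=False):
        pid, gid = row.pathway_id, row.gene_id
        gene = genes.get(gid)
        if gene is None:
            report.add(
                "error", "integrity", "pathways",
                f"pathway {pid!r} member {gid!r} is not a known gene",
            )
            continue
        if gene.species_id != ref_id:
            report.add(
                "error", "integrity", "pathways",
                f"pathway {pid!r} member {gid!r} is not a reference-species gene",
            )
            continue
        name, members = pathway_rows.setdefault(pid, (row.name, set()))
        members.add(gid)
    pathways: dict[str, Pathway] = {}
    for pid, (name, members) in pathway_rows.items():
        if not members:
            report.add("error", "integrity", "pathways", f"pathway {pid!r} has no genes")
            continue
        pathways[pid] = Pathway(pathway_id=pid, name=name, human_gene_ids=frozenset(members))

    # orthologs --------------------------------------------------------------
    ortholog_pairs: list[OrthologPair] = []
    seen_pairs: set[tuple[str, str]] = set()
    for row in tables["orthologs"].itertuples(index=False):
        hg, mg, rel = row.human_gene_id, row.model_gene_id, row.relation
        human = genes.get(hg)
        model = genes.get(mg)
        if human is None or model is None:
            report.add(
                "error", "integrity", "orthologs",
                f"ortholog pair ({hg!r}, {mg!r}) references unknown gene",
            )
            continue
        if human.species_id != ref_id:
            report.add(
                "error", "integrity", "orthologs",
                f"ortholog pair ({hg!r}, {mg!r}): {hg!r} is not a reference-species gene",
            )
            continue
        if model.species_id == ref_id:
            report.add(
                "error", "integrity", "orthologs",
                f"ortholog pair ({hg!r}, {mg!r}): {mg!r} is a reference-species gene",
            )
            continue
        if rel not in RELATION_CLASSES:
            report.add(
                "error", "integrity", "orthologs",
                f"ortholog pair ({hg!r}, {mg!r}) has invalid relation {rel!r}",
            )
            continue
        if (hg, mg) in seen_pairs:
            report.add(
                "error", "integrity", "orthologs",
                f"duplicate ortholog pair ({hg!r}, {mg!r})",
            )
            continue
        seen_pairs.add((hg, mg))
        ortholog_pairs.append(OrthologPair(hg, mg, rel))

    # relation labels must match the bipartite-degree classification;
    # mismatches are warnings and the label is replaced by the derived class
    ortholog_pairs = _relabel_relations(ortholog_pairs, genes, report)

    # phenotype annotations ---------------------------------------------------
    annotations: list[PhenotypeAnnotation] = []
    seen_ann: set[tuple[str, str, str]] = set()
    for row in tables["phenotype_annotations"].itertuples(index=False):
        pid, sp, gid = row.phenotype_id, row.species_id, row.gene_id
        gene = genes.get(gid)
        if sp not in species:
            report.add(
                "error", "integrity", "phenotype_annotations",
                f"annotation ({pid!r}, {sp!r}, {gid!r}) references unknown species",
            )
            continue
        if gene is None:
            report.add(
                "error", "integrity", "phenotype_annotations",
                f"annotation ({pid!r}, {sp!r}, {gid!r}) references unknown gene",
            )
            continue
        if gene.species_id != sp:
            report.add(
                "error", "integrity", "phenotype_annotations",
                f"annotation ({pid!r}, {sp!r}, {gid!r}): gene belongs to "
                f"{gene.species_id!r}",
            )
            continue
        key = (pid, sp, gid)
        if key in seen_ann:
            report.add(
                "error", "integrity", "phenotype_annotations",
                f"duplicate annotation {key!r}",
            )
            continue
        seen_ann.add(key)
        annotations.append(PhenotypeAnnotation(pid, sp, gid))

    # compounds ---------------------------------------------------------------
    compounds: dict[str, Compound] = {}
    fp_length: int | None = None
    for row in tables["compounds"].itertuples(index=False):
        cid = row.compound_id
        if not cid:
            report.add("error", "integrity", "compounds", "empty compound_id")
            continue
        if cid in compounds:
            report.add("error", "integrity", "compounds", f"duplicate compound_id {cid!r}")
            continue
        fp = row.fingerprint
        if fp:
            if set(fp) - {"0", "1"}:
                report.add(
                    "error", "integrity", "compounds",
                    f"compound {cid!r} fingerprint is not a 0/1 bitstring",
                )
                continue
            if fp_length is None:
                fp_length = len(fp)
            elif len(fp) != fp_length:
                report.add(
                    "error", "integrity", "compounds",
                    f"compound {cid!r} fingerprint length {len(fp)} != {fp_length}",
                )
                continue
        names = tuple(n.strip() for n in row.name.split("|") if n.strip())
        compounds[cid] = Compound(
            compound_id=cid, names=names, cas=row.cas, ec=row.ec,
            smiles=row.smiles, fingerprint=fp,
        )

    # observed phenotypes (grouped per compound x species) --------------------
    grouped: dict[tuple[str, str], set[str]] = defaultdict(set)
    for row in tables["observed_phenotypes"].itertuples(index=False):
        cid, sp, pid = row.compound_id, row.species_id, row.phenotype_id
        if cid not in compounds:
            report.add(
                "error", "integrity", "observed_phenotypes",
                f"observation references unknown compound {cid!r}",
            )
            continue
        if sp not in species:
            report.add(
                "error", "integrity", "observed_phenotypes",
                f"observation references unknown species {sp!r}",
            )
            continue
        grouped[(cid, sp)].add(pid)
    annotated_terms = {(a.species_id, a.phenotype_id) for a in annotations}
    observed: list[ObservedPhenotypeSet] = []
    for (cid, sp), pids in sorted(grouped.items()):
        for pid in sorted(pids):
            if (sp, pid) not in annotated_terms:
                # a compound can elicit phenotypes never seen in genetic
                # variants — a warning, never an error
                report.add(
                    "warning", "annotation", "observed_phenotypes",
                    f"observed phenotype {pid!r} ({cid!r}, {sp!r}) has no "
                    f"genetic annotation in {sp!r}",
                )
        observed.append(ObservedPhenotypeSet(cid, sp, frozenset(pids)))

    # in-vitro hits -----------------------------------------------------------
    hits: list[InVitroHit] = []
    seen_hits: set[tuple[str, str]] = set()
    for row in tables["in_vitro_hits"].itertuples(index=False):
        cid, gid = row.compound_id, row.target_gene_id
        gene = genes.get(gid)
        if cid not in compounds:
            report.add(
                "error", "integrity", "in_vitro_hits",
                f"hit references unknown compound {cid!r}",
            )
            continue
        if gene is None or gene.species_id != ref_id:
            report.add(
                "error", "integrity", "in_vitro_hits",
                f"hit target {gid!r} is not a reference-species gene",
            )
            continue
        if (cid, gid) in seen_hits:
            continue
        seen_hits.add((cid, gid))
        hits.append(InVitroHit(cid, gid))

    if strict and report.errors:
        raise IntegrityError(
            f"{len(report.errors)} integrity error(s):\n" + report.summary()
        )

    return KnowledgeBase(
        species=species,
        genes=genes,
        pathways=pathways,
        ortholog_pairs=ortholog_pairs,
        phenotype_annotations=annotations,
        compounds=compounds,
        observed_phenotype_sets=observed,
        in_vitro_hits=hits,
        validation_report=report,
    )


def _relabel_relations(
    pairs: list[OrthologPair],
    genes: Mapping[str, Gene],
    report: ValidationReport,
) -> list[OrthologPair]:
    """Replace loaded relation labels by the degree-derived class, warning on
    disagreement.  Classification is done within one model species at a time."""
    from .orthology import classify_orthology_relation

    by_species: dict[str, list[OrthologPair]] = defaultdict(list)
    for p in pairs:
        by_species[genes[p.model_gene_id].species_id].append(p)
    out: list[OrthologPair] = []
    for sp in sorted(by_species):
        sp_pairs = by_species[sp]
        derived = classify_orthology_relation(sp_pairs)
        for p in sp_pairs:
            want = derived[p.human_gene_id]
            if p.relation != want:
                report.add(
                    "warning", "relation", "orthologs",
                    f"pair ({p.human_gene_id!r}, {p.model_gene_id!r}) labelled "
                    f"{p.relation!r} but degree structure implies {want!r}",
                )
                p = OrthologPair(p.human_gene_id, p.model_gene_id, want)
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_knowledge_base(kb: KnowledgeBase, directory: str | Path) -> dict[str, int]:
    """Write the eight TSV tables; returns {filename: data row count}.

    Rows are emitted in sorted order so output is deterministic for a given
    knowledge base (round-trips with :func:`load_knowledge_base`).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}

    def emit(stem: str, rows: Iterable[tuple[str, ...]]) -> None:
        rows = sorted(rows)
        buf = io.StringIO()
        buf.write("\t".join(TABLE_COLUMNS[stem]) + "\n")
        for row in rows:
            buf.write("\t".join(row) + "\n")
        (directory / f"{stem}.tsv").write_text(buf.getvalue(), encoding="utf-8")
        manifest[f"{stem}.tsv"] = len(rows)

    emit("species", (
        (s.species_id, s.display_name, "1" if s.is_mammal else "0",
         "1" if s.is_reference else "0")
        for s in kb.species.values()
    ))
    emit("genes", ((g.gene_id, g.species_id, g.symbol) for g in kb.genes.values()))
    emit("pathways", (
        (p.pathway_id, p.name, gid)
        for p in kb.pathways.values()
        for gid in p.human_gene_ids
    ))
    emit("orthologs", (
        (p.human_gene_id, p.model_gene_id, p.relation) for p in kb.ortholog_pairs
    ))
    emit("phenotype_annotations", (
        (a.phenotype_id, a.species_id, a.gene_id) for a in kb.phenotype_annotations
    ))
    emit("compounds", (
        (c.compound_id, "|".join(c.names), c.cas, c.ec, c.smiles, c.fingerprint)
        for c in kb.compounds.values()
    ))
    emit("observed_phenotypes", (
        (o.compound_id, o.species_id, pid)
        for o in kb.observed_phenotype_sets
        for pid in o.phenotype_ids
    ))
    emit("in_vitro_hits", ((h.compound_id, h.target_gene_id) for h in kb.in_vitro_hits))
    return manifest


# ---------------------------------------------------------------------------
# Query operations
# ---------------------------------------------------------------------------


def genes_for_phenotypes(
    kb: KnowledgeBase, species_id: str, phenotype_ids: Iterable[str]
) -> dict[str, int]:
    """Genes of a species annotated with at least one query phenotype.

    Returns ``{gene_id: number of distinct query phenotypes annotated to it}``.
    Query terms absent from the annotation table contribute nothing.
    """
    kb._require_species(species_id)
    query = set(phenotype_ids)
    if not query:
        raise ValueError("no input phenotypes")
    phen_to_genes = kb.phenotype_to_genes(species_id)
    counts: dict[str, int] = defaultdict(int)
    for pid in query:
        for gid in phen_to_genes.get(pid, ()):
            counts[gid] += 1
    return dict(counts)


def pathway_gene_set(kb: KnowledgeBase, pathway_id: str, species_id: str) -> set[str]:
    """Project a human pathway into a species.

    For the reference species this is the pathway's own gene set; for a model
    species it is the union of all model genes orthologous to any member.  May
    be empty when the pathway is not conserved in that species.
    """
    kb._require_species(species_id)
    pathway = kb.pathways.get(pathway_id)
    if pathway is None:
        raise ValueError(f"unknown pathway {pathway_id!r}")
    if species_id == kb.reference_species_id:
        return set(pathway.human_gene_ids)
    mapping = kb._human_to_model.get(species_id, {})
    out: set[str] = set()
    for hg in pathway.human_gene_ids:
        out |= mapping.get(hg, set())
    return out
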