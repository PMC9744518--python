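"""Core ranking: HPO terms → CUIs (three-path union) → GDAs → genes by score.

The query pipeline mirrors how a clinician would interrogate a gene-disease
knowledge graph: the patient's HPO terms (optionally widened by ontology
traversal) are mapped to disease/disorder/finding concepts along three
independent paths — Metathesaurus cross-references, HPO-ORDO mappings
composed through the ORDO disease's UMLS cross-reference, and
phenotype-disease annotations. The union of matched CUIs selects the
gene-disease associations; grouping them by NCBI gene id and taking the
highest association score per gene yields the ranking, ties broken by
ascending gene id so repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import RuntimeFailure, UsageError
from .knowledge_store import GeneDiseaseAssociation, KnowledgeStore, format_score
from .ontology import Ontology, expand_terms

logger = logging.getLogger("phenoprio.prioritizer")

OUTPUT_HEADER = (
    "gene (NCBI)",
    "highest GDA score",
    "diseases (UMLS) with sources per disease",
)


@dataclass(frozen=True)
class EvidenceEntry:
    """One matched disease concept supporting a gene, with score and PubMed ids."""

    cui: str
    score: float
    pmids: frozenset[int] = field(default_factory=frozenset)


@dataclass(frozen=True)
class PrioritizedGene:
    """A gene with its highest association score and per-CUI evidence.

    ``evidence`` is ordered by descending score, then ascending CUI;
    ``highest_score`` always equals the top entry's score.
    """

    gene: int
    highest_score: float
    evidence: tuple[EvidenceEntry, ...]


@dataclass(frozen=True)
class QueryInfo:
    """Provenance of one prioritization run."""

    input_terms: tuple[str, ...]
    expanded_terms: tuple[str, ...]
    matched_cuis: tuple[str, ...]
    mode: str | None = None
    max_distance: int | None = None


@dataclass(frozen=True)
class PrioritizationResult:
    """Ranked genes plus the query provenance.

    ``genes`` is sorted by descending ``highest_score`` with ties broken by
    ascending gene id; no gene appears twice.
    """

    genes: tuple[PrioritizedGene, ...]
    query: QueryInfo

    def gene_ids(self) -> list[int]:
        return [g.gene for g in self.genes]


def map_hpo_to_cuis(store: KnowledgeStore, terms: Iterable[str]) -> set[str]:
    """Union of CUIs matched to ``terms`` along the three mapping paths.

    A term absent from all three tables contributes the empty set; every
    returned CUI exists in the store's concept table.
    """
    terms = set(terms)
    if not terms:
        raise UsageError("map_hpo_to_cuis requires at least one HPO term")
    cuis: set[str] = set()
    for h in terms:
        matched = (
            store.metathesaurus.get(h, set())
            | store.hoom_cuis(h)
            | store.pda.get(h, set())
        )
        if not matched:
            logger.debug("HPO term %s matched no CUI in any mapping path", h)
        cuis |= matched
    return cuis


def retrieve_gdas(
    store: KnowledgeStore, cuis: Iterable[str]
) -> list[GeneDiseaseAssociation]:
    """All associations whose CUI is in ``cuis``, without duplicates."""
    out: list[GeneDiseaseAssociation] = []
    for cui in sorted(set(cuis)):
        out.extend(store.gdas_for_cui(cui))
    return out


def prioritize(
    store: KnowledgeStore,
    terms: Iterable[str],
    expansion: tuple[Ontology, str, int] | None = None,
) -> PrioritizationResult:
    """Rank genes for a set of patient HPO terms.

    Parameters
    ----------
    store : KnowledgeStore
        The indexed gene-disease knowledge store.
    terms : iterable of str
        Patient HPO codes (``HP:NNNNNNN``).
    expansion : (Ontology, mode, max_distance), optional
        When given, the terms are first widened by ontology traversal
        (see :func:`phenoprio.ontology.expand_terms`).

    Returns
    -------
    PrioritizationResult
        Genes in descending order of highest association score (ties by
        ascending gene id). Zero matched CUIs or zero associations yield an
        empty result, not an error — downstream pipelines expect a file.
    """
    input_terms = tuple(sorted(set(terms)))
    if not input_terms:
        raise UsageError("at least one HPO term is required")
    mode = max_distance = None
    if expansion is not None:
        ontology, mode, max_distance = expansion
        query_terms = expand_terms(ontology, input_terms, mode, max_distance)
    else:
        query_terms = set(input_terms)

    cuis = map_hpo_to_cuis(store, query_terms)
    associations = retrieve_gdas(store, cuis)
    if not associations:
        logger.info("query matched %d CUIs but no gene-disease associations",
                    len(cuis))

    per_gene: dict[int, dict[str, EvidenceEntry]] = {}
    for a in associations:
        bucket = per_gene.setdefault(a.gene, {})
        prior = bucket.get(a.cui)
        if prior is None or a.score > prior.score:
            pmids = a.pmids | (prior.pmids if prior else frozenset())
            bucket[a.cui] = EvidenceEntry(cui=a.cui, score=a.score, pmids=pmids)

    ranked = []
    for gene, bucket in per_gene.items():
        evidence = tuple(
            sorted(bucket.values(), key=lambda e: (-e.score, e.cui))
        )
        ranked.append(
            PrioritizedGene(
                gene=gene,
                highest_score=evidence[0].score,
                evidence=evidence,
            )
        )
    ranked.sort(key=lambda g: (-g.highest_score, g.gene))

    return PrioritizationResult(
        genes=tuple(ranked),
        query=QueryInfo(
            input_terms=input_terms,
            expanded_terms=tuple(sorted(query_terms)),
            matched_cuis=tuple(sorted(cuis)),
            mode=mode,
            max_distance=max_distance,
        ),
    )


def _render_evidence(entries: Sequence[EvidenceEntry]) -> str:
    parts = []
    for e in entries:
        text = f"{e.cui} ({format_score(e.score)})"
        if e.pmids:
            text += ": " + ",".join(str(p) for p in sorted(e.pmids))
        parts.append(text)
    return "|".join(parts)


def write_output(result: PrioritizationResult, path, genes_only: bool = False) -> Path:
    """Write a result as the three-column TSV or the genes-only line.

    The TSV has a header row and one row per gene, evidence entries joined by
    ``|`` and rendered ``CUI (score)`` or ``CUI (score): pmid,pmid,...`` with
    PubMed ids ascending. Genes-only output is a single newline-terminated
    line of comma-separated gene ids; an empty result yields an empty file.
    """
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            if genes_only:
                if result.genes:
                    fh.write(",".join(str(g) for g in result.gene_ids()) + "\n")
            else:
                fh.write("\t".join(OUTPUT_HEADER) + "\n")
                for g in result.genes:
                    fh.write(
                        f"{g.gene}\t{format_score(g.highest_score)}\t"
                        f"{_render_evidence(g.evidence)}\n"
                    )
    except OSError as exc:
        raise RuntimeFailure(f"cannot write output file {path}: {exc}")
    if not result.genes:
        logger.info("empty prioritization result written to %s", path)
    return path
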