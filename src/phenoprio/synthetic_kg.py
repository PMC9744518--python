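"""Deterministic synthetic knowledge graphs, patient cases and gene pools.

Real gene-disease knowledge graphs (scored gene-disease associations with
PubMed evidence, phenotype-disease annotations, Metathesaurus and HPO-ORDO
mappings, the HPO ``is_a`` hierarchy) are large third-party releases. This
module generates structurally faithful miniatures with a full ground-truth
manifest, so every query, minimization and benchmark path is testable
offline and byte-reproducibly from ``(config, seed)``.

Synthetic identifiers live in reserved blocks (``HP:9xxxxxx``,
``C9xxxxxx``) so they cannot collide with real HPO terms or UMLS concepts.
All randomness flows through explicitly seeded ``numpy`` generators; no
global RNG state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import UsageError
from .knowledge_store import (
    Concept,
    GeneDiseaseAssociation,
    KnowledgeStore,
    export_store,
    format_score,
)
from .ontology import HpoTerm, Ontology

SEMANTIC_TYPES = ("disease", "disorder", "finding")

CASE_FILE_HEADER = ("case_id", "hpo_ids", "causal_genes")


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape and densities of a synthetic knowledge graph.

    Parameters
    ----------
    seed : int
        Master RNG seed; all outputs are byte-identical for the same config.
    n_genes, n_concepts, n_hpo_terms : int
        Entity counts (each >= 1).
    gda_density : float in (0, 1]
        Bernoulli probability that a (gene, concept) pair carries an
        association.
    mapping_density : mapping path -> float in (0, 1]
        Per-term probability that an HPO term has rows in each mapping path
        (``metathesaurus``, ``hoom``, ``pda``); a mapped term links to 1-3
        concepts on that path.
    score_distribution : "uniform" or ("beta", a, b)
        Distribution of association scores, rounded to 2 decimals as scored
        gene-disease releases conventionally print them.
    pmid_rate : float
        Expected PubMed ids per association (Poisson).
    n_orphan_concepts : int
        Extra concepts injected with no association and no mapping; they are
        unreachable by construction and should vanish under minimization.
    """

    seed: int = 0
    n_genes: int = 100
    n_concepts: int = 80
    n_hpo_terms: int = 50
    gda_density: float = 0.05
    mapping_density: Mapping[str, float] = field(
        default_factory=lambda: {"metathesaurus": 0.35, "hoom": 0.2, "pda": 0.4}
    )
    score_distribution: object = "uniform"
    pmid_rate: float = 2.0
    n_orphan_concepts: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_concepts", "n_hpo_terms"):
            if getattr(self, name) < 1:
                raise UsageError(f"{name} must be >= 1")
        if not 0 < self.gda_density <= 1:
            raise UsageError("gda_density must be in (0, 1]")
        for path in ("metathesaurus", "hoom", "pda"):
            d = self.mapping_density.get(path)
            if d is None or not 0 < d <= 1:
                raise UsageError(f"mapping_density[{path!r}] must be in (0, 1]")
        if self.n_orphan_concepts < 0:
            raise UsageError("n_orphan_concepts must be >= 0")
        dist = self.score_distribution
        if dist != "uniform" and not (
            isinstance(dist, (tuple, list)) and len(dist) == 3 and dist[0] == "beta"
        ):
            raise UsageError(
                "score_distribution must be 'uniform' or ('beta', a, b)"
            )


@dataclass
class Manifest:
    """Ground truth of one generated knowledge graph."""

    counts: dict
    hpo_to_cuis: dict  # hpo -> {"metathesaurus": [...], "hoom": [...], "pda": [...]}
    reachable_cuis: list
    reachable_gda_count: int
    probe_rankings: dict  # hpo -> [[gene, score], ...] best first

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Manifest":
        return cls(**json.loads(text))


@dataclass
class GeneratedKG:
    """In-memory handles plus file paths of one generated knowledge graph."""

    config: GeneratorConfig
    ontology: Ontology
    store: KnowledgeStore
    manifest: Manifest
    paths: dict = field(default_factory=dict)


def _draw_scores(rng: np.random.Generator, n: int, dist) -> np.ndarray:
    if dist == "uniform":
        raw = rng.uniform(0.0, 1.0, size=n)
    else:
        _, a, b = dist
        raw = rng.beta(a, b, size=n)
    return np.round(raw, 2)


def _generate_ontology(rng: np.random.Generator, n_terms: int):
    ids = [f"HP:{9000000 + i + 1:07d}" for i in range(n_terms)]
    terms = [HpoTerm(id=ids[0], name="synthetic phenotype root")]
    for i in range(1, n_terms):
        n_parents = 2 if (i >= 2 and rng.random() < 0.2) else 1
        parent_idx = rng.choice(i, size=min(n_parents, i), replace=False)
        terms.append(
            HpoTerm(
                id=ids[i],
                name=f"synthetic phenotype {i}",
                parents=frozenset(ids[int(j)] for j in parent_idx),
            )
        )
    return ids, Ontology(terms)


def _write_obo(ontology: Ontology, path: Path) -> None:
    lines = ["format-version: 1.4", "ontology: synthetic-hp", ""]
    for tid in sorted(ontology.terms):
        t = ontology.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {t.id}")
        lines.append(f"name: {t.name}")
        for p in sorted(t.parents):
            lines.append(f"is_a: {p}")
        if t.obsolete:
            lines.append("is_obsolete: true")
            if t.replaced_by:
                lines.append(f"replaced_by: {t.replaced_by}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


def generate_kg(config: GeneratorConfig, outdir=None) -> GeneratedKG:
    """Generate a knowledge graph; optionally write all artifacts to ``outdir``.

    Writes (when ``outdir`` is given): ``ontology.obo``, the tabular store
    under ``tabular/``, the Turtle store as ``store.ttl`` and
    ``manifest.json``. Identical ``config`` (including seed) yields
    byte-identical files.
    """
    rng = np.random.default_rng(config.seed)

    hpo_ids, ontology = _generate_ontology(rng, config.n_hpo_terms)

    n_total_concepts = config.n_concepts + config.n_orphan_concepts
    cuis = [f"C{9000000 + i + 1:07d}" for i in range(n_total_concepts)]
    regular_cuis = cuis[: config.n_concepts]
    concepts = [
        Concept(
            cui=cuis[i],
            name=f"synthetic concept {i}",
            semantic_type=SEMANTIC_TYPES[int(rng.integers(3))],
        )
        for i in range(n_total_concepts)
    ]

    genes = sorted(int(g) for g in rng.choice(
        np.arange(1, 100000), size=config.n_genes, replace=False
    ))

    # associations over the (gene, regular-concept) grid
    mask = rng.random((config.n_genes, config.n_concepts)) < config.gda_density
    pairs = [(genes[i], regular_cuis[j]) for i, j in np.argwhere(mask)]
    scores = _draw_scores(rng, len(pairs), config.score_distribution)
    pmid_counts = rng.poisson(config.pmid_rate, size=len(pairs))
    gdas = []
    for (gene, cui), score, k in zip(pairs, scores, pmid_counts):
        pmids = frozenset(
            int(p) for p in rng.integers(1_000_000, 40_000_000, size=int(k))
        )
        gdas.append(
            GeneDiseaseAssociation(gene=gene, cui=cui, score=float(score),
                                   pmids=pmids)
        )

    # three mapping paths
    meta, hoom, pda = [], [], []
    hpo_truth = {h: {"metathesaurus": [], "hoom": [], "pda": []} for h in hpo_ids}
    for h in hpo_ids:
        for path_name, rows in (("metathesaurus", meta), ("hoom", hoom),
                                ("pda", pda)):
            if rng.random() >= config.mapping_density[path_name]:
                continue
            k = int(rng.integers(1, 4))
            targets = rng.choice(config.n_concepts, size=min(k, config.n_concepts),
                                 replace=False)
            for j in sorted(int(t) for t in targets):
                cui = regular_cuis[j]
                if path_name == "hoom":
                    ordo = f"Orphanet:{int(rng.integers(100000, 999999))}"
                    rows.append((h, ordo, cui))
                else:
                    rows.append((h, cui))
                hpo_truth[h][path_name].append(cui)

    store = KnowledgeStore(
        concepts=concepts, gdas=gdas, metathesaurus=meta, hoom=hoom, pda=pda
    )

    reachable = store.mapped_cuis()
    manifest = Manifest(
        counts={
            "n_hpo_terms": len(ontology),
            "n_is_a_edges": len(ontology.edges),
            "n_concepts": n_total_concepts,
            "n_genes": len(genes),
            "n_gdas": store.n_gdas(),
            "n_metathesaurus_rows": len(meta),
            "n_hoom_rows": len(hoom),
            "n_pda_rows": len(pda),
        },
        hpo_to_cuis={h: {k: sorted(v) for k, v in d.items()}
                     for h, d in hpo_truth.items()},
        reachable_cuis=sorted(reachable),
        reachable_gda_count=sum(1 for a in store.gdas if a.cui in reachable),
        probe_rankings=_probe_rankings(hpo_ids[:5], hpo_truth, gdas),
    )

    kg = GeneratedKG(config=config, ontology=ontology, store=store,
                     manifest=manifest)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        obo = outdir / "ontology.obo"
        _write_obo(ontology, obo)
        tab_files = export_store(store, outdir / "tabular", dialect="tabular")
        ttl_files = export_store(store, outdir / "store.ttl", dialect="turtle")
        (outdir / "manifest.json").write_text(manifest.to_json() + "\n",
                                              encoding="utf-8")
        kg.paths = {
            "ontology": obo,
            "tabular": outdir / "tabular",
            "turtle": ttl_files[0],
            "manifest": outdir / "manifest.json",
            "tabular_files": tab_files,
        }
    return kg


def _probe_rankings(probe_terms, hpo_truth, gdas):
    """Expected rankings for single-term probes, by direct table scan."""
    by_cui: dict[str, list] = {}
    for a in gdas:
        by_cui.setdefault(a.cui, []).append(a)
    out = {}
    for h in probe_terms:
        matched = set()
        for path_cuis in hpo_truth[h].values():
            matched.update(path_cuis)
        best: dict[int, float] = {}
        for cui in matched:
            for a in by_cui.get(cui, []):
                if a.gene not in best or a.score > best[a.gene]:
                    best[a.gene] = a.score
        ranking = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
        out[h] = [[gene, format_score(score)] for gene, score in ranking]
    return out


# ---------------------------------------------------------------------------
# patient cases and gene pool


@dataclass(frozen=True)
class Case:
    """One synthetic patient: HPO terms plus the planted causal gene(s)."""

    case_id: str
    hpo_ids: tuple[str, ...]
    causal_genes: tuple[int, ...]


def generate_cases(
    kg: GeneratedKG,
    n_cases: int,
    dual_fraction: float = 0.0,
    path=None,
) -> list[Case]:
    """Generate patient cases whose causal genes are reachable from their terms.

    Each case carries 1-15 HPO terms, at least one of which maps (on some
    path) to a CUI that the causal gene is associated with, so the planted
    gene always appears in the prioritizer's output for its case. A
    ``dual_fraction`` share of cases (rounded) receives two causal genes,
    emulating dual molecular diagnoses. Case/gene assignments are drawn
    without replacement from the plantable (gene, CUI) association pairs;
    requesting more than exist is fatal.
    """
    if not 0 <= dual_fraction < 1:
        raise UsageError("dual_fraction must be in [0, 1)")
    if n_cases < 1:
        raise UsageError("n_cases must be >= 1")
    rng = np.random.default_rng([kg.config.seed, 101])

    store = kg.store
    cui_to_hpos: dict[str, list[str]] = {}
    for h, cs in store.metathesaurus.items():
        for c in cs:
            cui_to_hpos.setdefault(c, []).append(h)
    for h, _o, c in store.hoom:
        cui_to_hpos.setdefault(c, []).append(h)
    for h, cs in store.pda.items():
        for c in cs:
            cui_to_hpos.setdefault(c, []).append(h)
    cui_to_hpos = {c: sorted(set(hs)) for c, hs in cui_to_hpos.items()}

    plantable = [a for a in store.gdas if a.cui in cui_to_hpos]
    n_dual = int(round(dual_fraction * n_cases))
    needed = n_cases + n_dual
    if needed > len(plantable):
        raise UsageError(
            f"requested {n_cases} cases ({n_dual} dual) but only "
            f"{len(plantable)} plantable gene-disease pairs exist"
        )

    picks = rng.choice(len(plantable), size=needed, replace=False)
    primary, extra = list(picks[:n_cases]), list(picks[n_cases:])
    all_hpos = sorted(kg.ontology.terms)

    cases = []
    for i in range(n_cases):
        chosen = [plantable[int(primary[i])]]
        if i < n_dual:
            # dual diagnosis: ensure the second causal gene differs
            j = int(extra[i])
            while plantable[j].gene == chosen[0].gene:
                j = (j + 1) % len(plantable)
            chosen.append(plantable[j])
        hpo_set = set()
        for a in chosen:
            mappers = cui_to_hpos[a.cui]
            hpo_set.add(mappers[int(rng.integers(len(mappers)))])
        n_terms = min(int(rng.integers(1, 16)), len(all_hpos))
        while len(hpo_set) < n_terms:
            extra_term = all_hpos[int(rng.integers(len(all_hpos)))]
            if len(hpo_set) >= 15:
                break
            hpo_set.add(extra_term)
            if len(hpo_set) >= n_terms:
                break
        cases.append(
            Case(
                case_id=f"case{i + 1:04d}",
                hpo_ids=tuple(sorted(hpo_set)),
                causal_genes=tuple(sorted({a.gene for a in chosen})),
            )
        )

    if path is not None:
        write_case_file(cases, path)
    return cases


def write_case_file(cases: Sequence[Case], path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(CASE_FILE_HEADER) + "\n")
        for c in cases:
            fh.write(
                f"{c.case_id}\t{','.join(c.hpo_ids)}\t"
                f"{','.join(str(g) for g in c.causal_genes)}\n"
            )
    return path


def read_case_file(path) -> list[Case]:
    cases = []
    with open(path, encoding="utf-8") as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = tuple(line.split("\t"))
                if header != CASE_FILE_HEADER:
                    raise UsageError(
                        f"{path}: expected header {list(CASE_FILE_HEADER)}"
                    )
                continue
            cid, hpos, genes = line.split("\t")
            cases.append(
                Case(
                    case_id=cid,
                    hpo_ids=tuple(hpos.split(",")) if hpos else (),
                    causal_genes=tuple(int(g) for g in genes.split(",")),
                )
            )
    return cases


def write_gene_pool(kg: GeneratedKG, path) -> Path:
    """Write the clinical-gene pool: every gene with an association, one per line."""
    path = Path(path)
    genes = sorted({a.gene for a in kg.store.gdas})
    path.write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")
    return path


def read_gene_pool(path) -> list[int]:
    with open(path, encoding="utf-8") as fh:
        return [int(line) for line in fh if line.strip() and not
                line.startswith("#")]
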