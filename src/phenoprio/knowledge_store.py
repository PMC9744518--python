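"""The gene-disease knowledge store: loading, validation, minimization, export.

The store holds four record kinds behind fast indexes:

* UMLS-style concepts (CUIs) restricted to the three semantic classes the
  ranking algorithm retrieves: *disease*, *disorder* and *finding*;
* scored gene-disease associations (GDAs), one per (gene, CUI) pair, each
  carrying a score in [0, 1] and optional PubMed evidence;
* three HPO-to-CUI mapping paths: (a) direct Metathesaurus mappings,
  (b) HPO-ORDO mappings whose ORDO disease cross-references a CUI, and
  (c) phenotype-disease annotations (PDAs).

Two on-disk dialects are supported and round-trip losslessly:

**Tabular** — a directory of UTF-8 TSV files with a header row; ``#`` lines
are comments::

    concepts.tsv                 cui, name, semantic_type
    gda.tsv                      gene, cui, score, pmids (comma-joined, may be empty)
    hpo2cui_metathesaurus.tsv    hpo, cui
    hpo2ordo2cui_hoom.tsv        hpo, ordo, cui
    hpo2cui_pda.tsv              hpo, cui

**Turtle** — ``.ttl`` files encoding associations SIO-style as typed
association nodes (one node per GDA, one ``pp:pmid`` triple per PubMed id),
mirroring the structure of gene-disease RDF releases without claiming IRI
fidelity. The predicate/class IRIs are documented constants of this package
(see ``SCHEMA``); HP terms use their canonical OBO PURLs.

Duplicate (gene, CUI) association rows collapse to the maximum score with the
union of PubMed ids, consistent with highest-score-wins ranking. Malformed or
unresolvable rows are dropped with a logged count; per-source provenance
satisfies ``loaded == retained + dropped``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

from .errors import RuntimeFailure, UsageError
from .ontology import HP_IRI_PREFIX

logger = logging.getLogger("phenoprio.store")

CUI_RE = re.compile(r"^C\d{7}$")
ORDO_RE = re.compile(r"^Orphanet:\d+$")
HPO_RE = re.compile(r"^HP:\d{7}$")

SEMANTIC_TYPES = ("disease", "disorder", "finding")

#: Documented IRI constants of the Turtle dialect.
SCHEMA = {
    "base": "http://rdf.phenoprio.local/",
    "prefix": "http://rdf.phenoprio.local/schema#",
    "gene_iri": "http://rdf.phenoprio.local/gene/{gene}",
    "cui_iri": "http://rdf.phenoprio.local/umls/{cui}",
    "ordo_iri": "http://rdf.phenoprio.local/ordo/{ordo}",
    "gda_iri": "http://rdf.phenoprio.local/gda/{gene}-{cui}",
    "hoom_iri": "http://rdf.phenoprio.local/hoom/{hpo}-{ordo}-{cui}",
}

TABULAR_FILES = {
    "concepts.tsv": ("cui", "name", "semantic_type"),
    "gda.tsv": ("gene", "cui", "score", "pmids"),
    "hpo2cui_metathesaurus.tsv": ("hpo", "cui"),
    "hpo2ordo2cui_hoom.tsv": ("hpo", "ordo", "cui"),
    "hpo2cui_pda.tsv": ("hpo", "cui"),
}


def format_score(score: float) -> str:
    """Shortest decimal rendering that round-trips the stored value."""
    text = repr(float(score))
    return text


@dataclass(frozen=True)
class Concept:
    """A UMLS-style concept: ``C`` plus seven digits, with a semantic class."""

    cui: str
    name: str = ""
    semantic_type: str = "disease"

    def __post_init__(self):
        if not CUI_RE.match(self.cui):
            raise UsageError(f"malformed CUI {self.cui!r}")
        if self.semantic_type not in SEMANTIC_TYPES:
            raise UsageError(
                f"semantic_type {self.semantic_type!r} not in {SEMANTIC_TYPES}"
            )


@dataclass(frozen=True)
class GeneDiseaseAssociation:
    """A scored link between an NCBI gene and a disease/disorder/finding CUI."""

    gene: int
    cui: str
    score: float
    pmids: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.gene <= 0:
            raise UsageError(f"NCBI gene id must be positive, got {self.gene}")
        if not 0.0 <= self.score <= 1.0:
            raise UsageError(f"GDA score {self.score} outside [0, 1]")
        if any(p <= 0 for p in self.pmids):
            raise UsageError("PubMed ids must be positive integers")


class KnowledgeStore:
    """Indexed collections of associations and the three HPO→CUI mapping paths.

    Attributes
    ----------
    concepts : dict
        ``cui -> Concept``.
    metathesaurus, pda : dict
        ``hpo -> set(cui)`` for mapping paths (a) and (c).
    hoom : set
        ``(hpo, ordo, cui)`` triples for mapping path (b).
    provenance : dict
        Per-source record counts: ``{source: {"loaded", "retained", "dropped"}}``.
    """

    def __init__(
        self,
        concepts: Iterable[Concept] = (),
        gdas: Iterable[GeneDiseaseAssociation] = (),
        metathesaurus: Iterable[tuple[str, str]] = (),
        hoom: Iterable[tuple[str, str, str]] = (),
        pda: Iterable[tuple[str, str]] = (),
        provenance: Mapping[str, Mapping[str, int]] | None = None,
    ):
        self.concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.cui in self.concepts:
                raise RuntimeFailure(f"duplicate concept {c.cui}")
            self.concepts[c.cui] = c

        self._gdas_by_cui: dict[str, dict[int, GeneDiseaseAssociation]] = {}
        for a in gdas:
            self._add_gda(a)

        self.metathesaurus: dict[str, set[str]] = {}
        for hpo, cui in metathesaurus:
            self._check_cui(cui, "metathesaurus mapping")
            self.metathesaurus.setdefault(hpo, set()).add(cui)

        self.hoom: set[tuple[str, str, str]] = set()
        for hpo, ordo, cui in hoom:
            self._check_cui(cui, "HOOM mapping")
            self.hoom.add((hpo, ordo, cui))

        self.pda: dict[str, set[str]] = {}
        for hpo, cui in pda:
            self._check_cui(cui, "PDA mapping")
            self.pda.setdefault(hpo, set()).add(cui)

        self.provenance: dict[str, dict[str, int]] = (
            {k: dict(v) for k, v in provenance.items()} if provenance else {}
        )

    def _check_cui(self, cui: str, context: str) -> None:
        if cui not in self.concepts:
            raise RuntimeFailure(f"{context} references unknown CUI {cui}")

    def _add_gda(self, a: GeneDiseaseAssociation) -> None:
        self._check_cui(a.cui, f"GDA for gene {a.gene}")
        bucket = self._gdas_by_cui.setdefault(a.cui, {})
        prior = bucket.get(a.gene)
        if prior is not None:
            # collapse duplicates: max score wins, evidence is pooled
            a = GeneDiseaseAssociation(
                gene=a.gene,
                cui=a.cui,
                score=max(a.score, prior.score),
                pmids=a.pmids | prior.pmids,
            )
        bucket[a.gene] = a

    # -- queries ---------------------------------------------------------

    @property
    def gdas(self) -> list[GeneDiseaseAssociation]:
        """All associations, sorted by (cui, gene) for determinism."""
        return [
            self._gdas_by_cui[cui][gene]
            for cui in sorted(self._gdas_by_cui)
            for gene in sorted(self._gdas_by_cui[cui])
        ]

    def gdas_for_cui(self, cui: str) -> list[GeneDiseaseAssociation]:
        bucket = self._gdas_by_cui.get(cui, {})
        return [bucket[g] for g in sorted(bucket)]

    def n_gdas(self) -> int:
        return sum(len(b) for b in self._gdas_by_cui.values())

    def hoom_cuis(self, hpo: str) -> set[str]:
        """CUIs reached from ``hpo`` through an ORDO cross-reference."""
        return {cui for h, _ordo, cui in self.hoom if h == hpo}

    def mapped_cuis(self) -> set[str]:
        """Every CUI reachable through at least one mapping path."""
        out: set[str] = set()
        for s in self.metathesaurus.values():
            out |= s
        for s in self.pda.values():
            out |= s
        out |= {cui for _h, _o, cui in self.hoom}
        return out

    # -- equality (contents, not provenance) -----------------------------

    def _contents(self):
        return (
            dict(sorted(self.concepts.items())),
            tuple(self.gdas),
            {h: frozenset(s) for h, s in self.metathesaurus.items()},
            frozenset(self.hoom),
            {h: frozenset(s) for h, s in self.pda.items()},
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, KnowledgeStore):
            return NotImplemented
        return self._contents() == other._contents()

    def __repr__(self) -> str:
        return (
            f"<KnowledgeStore concepts={len(self.concepts)} gdas={self.n_gdas()} "
            f"metathesaurus={sum(len(s) for s in self.metathesaurus.values())} "
            f"hoom={len(self.hoom)} pda={sum(len(s) for s in self.pda.values())}>"
        )


# ---------------------------------------------------------------------------
# loading


class _Prov:
    def __init__(self):
        self.counts: dict[str, dict[str, int]] = {}

    def tally(self, source: str, retained: bool, why: str | None = None) -> None:
        c = self.counts.setdefault(
            source, {"loaded": 0, "retained": 0, "dropped": 0}
        )
        c["loaded"] += 1
        if retained:
            c["retained"] += 1
        else:
            c["dropped"] += 1
            logger.warning("dropped record from %s: %s", source, why)


def _iter_tsv(path: Path, columns: tuple[str, ...]):
    import csv

    with open(path, encoding="utf-8", newline="") as fh:
        rows = (r for r in fh if not r.startswith("#"))
        reader = csv.reader(rows, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise RuntimeFailure(f"{path}: missing header row")
        if tuple(h.strip() for h in header) != columns:
            raise RuntimeFailure(
                f"{path}: expected header {list(columns)}, found {header}"
            )
        yield from reader


def _resolve_tabular_paths(paths: list[Path]) -> dict[str, Path]:
    found: dict[str, Path] = {}
    for p in paths:
        if p.is_dir():
            for name in TABULAR_FILES:
                if (p / name).exists():
                    found[name] = p / name
        elif p.name in TABULAR_FILES:
            found[p.name] = p
        else:
            raise UsageError(
                f"{p} is not one of the tabular store files {sorted(TABULAR_FILES)}"
            )
    return found


def _load_tabular(paths: list[Path]) -> KnowledgeStore:
    files = _resolve_tabular_paths(paths)
    prov = _Prov()

    concepts: list[Concept] = []
    known: set[str] = set()
    if "concepts.tsv" in files:
        src = files["concepts.tsv"].name
        for row in _iter_tsv(files["concepts.tsv"], TABULAR_FILES["concepts.tsv"]):
            try:
                c = Concept(cui=row[0], name=row[1], semantic_type=row[2])
                if c.cui in known:
                    raise UsageError(f"duplicate CUI {c.cui}")
                known.add(c.cui)
                concepts.append(c)
                prov.tally(src, True)
            except (UsageError, IndexError) as exc:
                prov.tally(src, False, f"{row!r}: {exc}")

    gdas: list[GeneDiseaseAssociation] = []
    if "gda.tsv" in files:
        src = files["gda.tsv"].name
        for row in _iter_tsv(files["gda.tsv"], TABULAR_FILES["gda.tsv"]):
            try:
                pmids = frozenset(
                    int(p) for p in row[3].split(",") if p.strip()
                ) if len(row) > 3 else frozenset()
                a = GeneDiseaseAssociation(
                    gene=int(row[0]), cui=row[1], score=float(row[2]), pmids=pmids
                )
                if a.cui not in known:
                    raise UsageError(f"unknown CUI {a.cui}")
                gdas.append(a)
                prov.tally(src, True)
            except (UsageError, ValueError, IndexError) as exc:
                prov.tally(src, False, f"{row!r}: {exc}")

    def load_mapping(name, n_cols, validate):
        out = []
        if name not in files:
            return out
        src = files[name].name
        for row in _iter_tsv(files[name], TABULAR_FILES[name]):
            try:
                vals = tuple(row[:n_cols])
                if len(vals) < n_cols:
                    raise UsageError("too few columns")
                validate(vals)
                out.append(vals)
                prov.tally(src, True)
            except UsageError as exc:
                prov.tally(src, False, f"{row!r}: {exc}")
        return out

    def check2(vals):
        hpo, cui = vals
        if not HPO_RE.match(hpo):
            raise UsageError(f"malformed HPO id {hpo!r}")
        if cui not in known:
            raise UsageError(f"unknown CUI {cui}")

    def check3(vals):
        hpo, ordo, cui = vals
        if not HPO_RE.match(hpo):
            raise UsageError(f"malformed HPO id {hpo!r}")
        if not ORDO_RE.match(ordo):
            raise UsageError(f"malformed ORDO id {ordo!r}")
        if cui not in known:
            raise UsageError(f"unknown CUI {cui}")

    meta = load_mapping("hpo2cui_metathesaurus.tsv", 2, check2)
    hoom = load_mapping("hpo2ordo2cui_hoom.tsv", 3, check3)
    pda = load_mapping("hpo2cui_pda.tsv", 2, check2)

    return KnowledgeStore(
        concepts=concepts,
        gdas=gdas,
        metathesaurus=meta,
        hoom=hoom,
        pda=pda,
        provenance=prov.counts,
    )


def _load_turtle(paths: list[Path]) -> KnowledgeStore:
    import rdflib
    from rdflib.namespace import RDF, RDFS

    PP = rdflib.Namespace(SCHEMA["prefix"])
    g = rdflib.Graph()
    for p in paths:
        files = sorted(p.glob("*.ttl")) if p.is_dir() else [p]
        if not files:
            raise RuntimeFailure(f"no .ttl files found under {p}")
        for f in files:
            try:
                g.parse(str(f), format="turtle")
            except Exception as exc:
                raise RuntimeFailure(f"cannot parse Turtle file {f}: {exc}")

    cui_prefix = SCHEMA["cui_iri"].split("{", 1)[0]
    gene_prefix = SCHEMA["gene_iri"].split("{", 1)[0]
    ordo_prefix = SCHEMA["ordo_iri"].split("{", 1)[0]

    def to_cui(node):
        s = str(node)
        return s[len(cui_prefix):] if s.startswith(cui_prefix) else None

    def to_hpo(node):
        s = str(node)
        if s.startswith(HP_IRI_PREFIX):
            return "HP:" + s[len(HP_IRI_PREFIX):]
        return None

    prov = _Prov()
    src = "turtle"

    concepts = []
    for s in g.subjects(RDF.type, PP.Concept):
        cui = to_cui(s)
        st = g.value(s, PP.semanticType)
        name = g.value(s, RDFS.label)
        try:
            if cui is None:
                raise UsageError(f"bad concept IRI {s}")
            concepts.append(
                Concept(cui=cui, name=str(name) if name else "",
                        semantic_type=str(st) if st else "")
            )
            prov.tally(src, True)
        except UsageError as exc:
            prov.tally(src, False, str(exc))
    known = {c.cui for c in concepts}

    gdas = []
    for s in g.subjects(RDF.type, PP.GeneDiseaseAssociation):
        try:
            gene_node = g.value(s, PP.gene)
            cui = to_cui(g.value(s, PP.disease))
            score = g.value(s, PP.score)
            if gene_node is None or cui is None or score is None:
                raise UsageError(f"incomplete association node {s}")
            if not str(gene_node).startswith(gene_prefix):
                raise UsageError(f"bad gene IRI {gene_node}")
            gene = int(str(gene_node)[len(gene_prefix):])
            pmids = frozenset(int(str(p)) for p in g.objects(s, PP.pmid))
            a = GeneDiseaseAssociation(gene=gene, cui=cui,
                                       score=float(score), pmids=pmids)
            if a.cui not in known:
                raise UsageError(f"unknown CUI {a.cui}")
            gdas.append(a)
            prov.tally(src, True)
        except (UsageError, ValueError) as exc:
            prov.tally(src, False, str(exc))

    meta, pda = [], []
    for pred, out in ((PP.metathesaurusCui, meta), (PP.pdaCui, pda)):
        for s, o in g.subject_objects(pred):
            hpo, cui = to_hpo(s), to_cui(o)
            if hpo and cui and cui in known:
                out.append((hpo, cui))
                prov.tally(src, True)
            else:
                prov.tally(src, False, f"unresolvable mapping {s} -> {o}")

    hoom = []
    for s in g.subjects(RDF.type, PP.HpoOrdoMapping):
        hpo = to_hpo(g.value(s, PP.hpo))
        ordo_node = g.value(s, PP.ordo)
        cui = to_cui(g.value(s, PP.cui))
        ordo = None
        if ordo_node is not None and str(ordo_node).startswith(ordo_prefix):
            ordo = str(ordo_node)[len(ordo_prefix):].replace("Orphanet_", "Orphanet:")
        if hpo and ordo and cui and cui in known and ORDO_RE.match(ordo):
            hoom.append((hpo, ordo, cui))
            prov.tally(src, True)
        else:
            prov.tally(src, False, f"unresolvable HOOM node {s}")

    return KnowledgeStore(
        concepts=concepts, gdas=gdas, metathesaurus=meta,
        hoom=hoom, pda=pda, provenance=prov.counts,
    )


def load_store(
    paths,
    dialect: Literal["turtle", "tabular"] = "tabular",
    allow_empty: bool = False,
) -> KnowledgeStore:
    """Load and index a knowledge store from disk.

    ``paths`` is a single path or a list: directories are scanned for the
    dialect's files. Malformed records are skipped with a logged warning and
    counted in the store's provenance; a store with zero gene-disease
    associations is a fatal error unless ``allow_empty`` is set (useful when
    round-tripping intermediate stores).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    for p in paths:
        if not p.exists():
            raise RuntimeFailure(f"store path does not exist: {p}")
    if dialect == "tabular":
        store = _load_tabular(paths)
    elif dialect == "turtle":
        store = _load_turtle(paths)
    else:
        raise UsageError(f"unknown dialect {dialect!r}")
    if store.n_gdas() == 0 and not allow_empty:
        raise RuntimeFailure(
            "knowledge store contains zero gene-disease associations"
        )
    return store


# ---------------------------------------------------------------------------
# minimization


def minimize_store(store: KnowledgeStore) -> KnowledgeStore:
    """Strip entities unreachable from the HPO→CUI→GDA query paths.

    Keeps every mapping row, every association whose CUI is reachable through
    at least one mapping path, and every concept that still participates in a
    retained association or mapping row. Prioritization results on the
    minimized store are identical to those on the full store for every
    possible HPO input; minimization is idempotent.
    """
    reachable = store.mapped_cuis()
    gdas = [a for a in store.gdas if a.cui in reachable]
    keep_cuis = reachable | {a.cui for a in gdas}
    concepts = [store.concepts[c] for c in sorted(keep_cuis) if c in store.concepts]
    return KnowledgeStore(
        concepts=concepts,
        gdas=gdas,
        metathesaurus=[
            (h, c) for h, cs in sorted(store.metathesaurus.items()) for c in sorted(cs)
        ],
        hoom=sorted(store.hoom),
        pda=[(h, c) for h, cs in sorted(store.pda.items()) for c in sorted(cs)],
        provenance=store.provenance,
    )


# ---------------------------------------------------------------------------
# export


def _ttl_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def export_store(
    store: KnowledgeStore, path, dialect: Literal["turtle", "tabular"] = "tabular"
) -> list[Path]:
    """Write a store to ``path`` so that :func:`load_store` round-trips it.

    Tabular writes the five TSV files into the directory ``path``; Turtle
    writes a single ``store.ttl``. Output is deterministically sorted, so
    identical stores export byte-identical files.
    """
    path = Path(path)
    try:
        if dialect == "tabular":
            return _export_tabular(store, path)
        if dialect == "turtle":
            return _export_turtle(store, path)
    except OSError as exc:
        raise RuntimeFailure(f"cannot write store to {path}: {exc}")
    raise UsageError(f"unknown dialect {dialect!r}")


def _export_tabular(store: KnowledgeStore, outdir: Path) -> list[Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def write(name, rows):
        p = outdir / name
        with open(p, "w", encoding="utf-8", newline="") as fh:
            fh.write("\t".join(TABULAR_FILES[name]) + "\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")
        written.append(p)

    write(
        "concepts.tsv",
        ((c.cui, c.name, c.semantic_type)
         for c in (store.concepts[k] for k in sorted(store.concepts))),
    )
    write(
        "gda.tsv",
        ((str(a.gene), a.cui, format_score(a.score),
          ",".join(str(p) for p in sorted(a.pmids)))
         for a in store.gdas),
    )
    write(
        "hpo2cui_metathesaurus.tsv",
        ((h, c) for h in sorted(store.metathesaurus)
         for c in sorted(store.metathesaurus[h])),
    )
    write("hpo2ordo2cui_hoom.tsv", (t for t in sorted(store.hoom)))
    write(
        "hpo2cui_pda.tsv",
        ((h, c) for h in sorted(store.pda) for c in sorted(store.pda[h])),
    )
    return written


def _export_turtle(store: KnowledgeStore, path: Path) -> list[Path]:
    if path.suffix != ".ttl":
        path.mkdir(parents=True, exist_ok=True)
        path = path / "store.ttl"
    else:
        path.parent.mkdir(parents=True, exist_ok=True)

    def hpo_iri(hpo: str) -> str:
        return HP_IRI_PREFIX + hpo.split(":")[1]

    cui_iri = SCHEMA["cui_iri"].format
    lines = [
        f"@prefix pp: <{SCHEMA['prefix']}> .",
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
        "",
    ]
    for cui in sorted(store.concepts):
        c = store.concepts[cui]
        lines.append(f"<{cui_iri(cui=cui)}> a pp:Concept ;")
        lines.append(f'    rdfs:label "{_ttl_escape(c.name)}" ;')
        lines.append(f'    pp:semanticType "{c.semantic_type}" .')
    for a in store.gdas:
        node = SCHEMA["gda_iri"].format(gene=a.gene, cui=a.cui)
        lines.append(f"<{node}> a pp:GeneDiseaseAssociation ;")
        lines.append(f"    pp:gene <{SCHEMA['gene_iri'].format(gene=a.gene)}> ;")
        lines.append(f"    pp:disease <{cui_iri(cui=a.cui)}> ;")
        lines.append(f"    pp:score {format_score(a.score)}" +
                     (" ;" if a.pmids else " ."))
        for i, pmid in enumerate(sorted(a.pmids)):
            end = " ." if i == len(a.pmids) - 1 else " ;"
            lines.append(f"    pp:pmid {pmid}{end}")
    for h in sorted(store.metathesaurus):
        for c in sorted(store.metathesaurus[h]):
            lines.append(f"<{hpo_iri(h)}> pp:metathesaurusCui <{cui_iri(cui=c)}> .")
    for h, ordo, c in sorted(store.hoom):
        node = SCHEMA["hoom_iri"].format(
            hpo=h.replace(":", "_"), ordo=ordo.replace(":", "_"), cui=c
        )
        lines.append(f"<{node}> a pp:HpoOrdoMapping ;")
        lines.append(f"    pp:hpo <{hpo_iri(h)}> ;")
        lines.append(
            f"    pp:ordo <{SCHEMA['ordo_iri'].format(ordo=ordo.replace(':', '_'))}> ;"
        )
        lines.append(f"    pp:cui <{cui_iri(cui=c)}> .")
    for h in sorted(store.pda):
        for c in sorted(store.pda[h]):
            lines.append(f"<{hpo_iri(h)}> pp:pdaCui <{cui_iri(cui=c)}> .")

    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return [path]
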