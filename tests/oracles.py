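"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's indexes and traversal code: the graph
search works directly on the raw parent sets, and the ranking oracle reads
the exported TSV files back with the csv module and joins them with plain
dictionaries.
"""

import csv
from collections import deque
from pathlib import Path


def bfs_expand(parent_sets: dict, seeds, mode: str, max_distance: int) -> set:
    """Truncated breadth-first search over raw (child -> parents) edges."""
    children = {t: set() for t in parent_sets}
    undirected = {t: set() for t in parent_sets}
    for child, parents in parent_sets.items():
        for p in parents:
            children[p].add(child)
            undirected[p].add(child)
            undirected[child].add(p)
    step = children if mode == "children" else undirected

    seen = set(seeds)
    frontier = deque((s, 0) for s in seeds)
    while frontier:
        node, d = frontier.popleft()
        if d >= max_distance:
            continue
        for nxt in step[node]:
            if nxt not in seen:
                seen.add(nxt)
                frontier.append((nxt, d + 1))
    return seen


def read_tables(tabular_dir) -> dict:
    """Read the exported store TSVs into plain lists of tuples."""
    out = {}
    for name in ("concepts", "gda", "hpo2cui_metathesaurus",
                 "hpo2ordo2cui_hoom", "hpo2cui_pda"):
        path = Path(tabular_dir) / f"{name}.tsv"
        with open(path, encoding="utf-8", newline="") as fh:
            rows = [r for r in csv.reader(fh, delimiter="\t")
                    if r and not r[0].startswith("#")]
        out[name] = rows[1:]  # drop header
    return out


def rank_oracle(tables: dict, hpo_terms) -> list:
    """Flat join-and-sort ranking: [(gene, best_score), ...] best first."""
    terms = set(hpo_terms)
    cuis = set()
    for h, c in tables["hpo2cui_metathesaurus"]:
        if h in terms:
            cuis.add(c)
    for h, _ordo, c in tables["hpo2ordo2cui_hoom"]:
        if h in terms:
            cuis.add(c)
    for h, c in tables["hpo2cui_pda"]:
        if h in terms:
            cuis.add(c)
    best = {}
    for gene, cui, score, _pmids in tables["gda"]:
        if cui in cuis:
            gene, score = int(gene), float(score)
            if gene not in best or score > best[gene]:
                best[gene] = score
    return sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))


def matched_cuis_oracle(tables: dict, hpo_terms) -> set:
    terms = set(hpo_terms)
    cuis = set()
    for h, c in tables["hpo2cui_metathesaurus"]:
        if h in terms:
            cuis.add(c)
    for h, _ordo, c in tables["hpo2ordo2cui_hoom"]:
        if h in terms:
            cuis.add(c)
    for h, c in tables["hpo2cui_pda"]:
        if h in terms:
            cuis.add(c)
    return cuis
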