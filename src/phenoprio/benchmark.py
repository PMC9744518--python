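"""Benchmark harness: causal-gene ranks, clinical-exome spike-in, complementarity.

Three analyses evaluate phenotype-driven gene prioritizers against patient
cases with known (diagnosed) causal genes:

* **Causal rank extraction** — the 1-based position of each causal gene in a
  tool's full output list, or MISSED when absent, together with the output
  size.
* **Clinical-exome spike-in** — simulates an analyst facing a panel of
  candidate genes (by default 19 pseudorandom decoys from a clinical-gene
  pool plus the causal gene) who ranks the panel with a tool and works down
  the list. Panel genes the tool did not return are investigated after the
  returned ones, so a missing causal gene receives a random rank uniform on
  the positions after the tool's returned panel genes. Each rank is
  stabilized as the median of 25 independently redrawn panels.
* **Complementarity** — how often a causal gene is found within a rank cutoff
  by exactly one tool versus by any tool, as counts and percentages.

Decoy panels are seeded per (case, causal gene) and shared across tools, so
tool comparisons are paired; the missing-gene rank draw is seeded per
(tool, case, causal gene, permutation). The whole harness is reproducible
from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import RuntimeFailure, UsageError
from .synthetic_kg import Case

MISSED = "MISSED"


@dataclass(frozen=True)
class RankedGeneList:
    """One tool's ordered gene output (rank 1 first) for one case."""

    tool: str
    case_id: str
    genes: tuple[int, ...]

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise UsageError(
                f"duplicate genes in ranked list for {self.tool}/{self.case_id}"
            )


@dataclass(frozen=True)
class CausalRankRecord:
    """Rank of one causal gene in one tool's full output for one case."""

    tool: str
    case_id: str
    causal_gene: int
    rank: int | None  # None encodes MISSED
    output_size: int

    @property
    def missed(self) -> bool:
        return self.rank is None

    def rank_label(self) -> str:
        return MISSED if self.missed else str(self.rank)


@dataclass(frozen=True)
class SpikeInResult:
    """Stabilized panel rank of one causal gene for one tool and case."""

    tool: str
    case_id: str
    causal_gene: int
    median_rank: int
    permutation_ranks: tuple[int, ...]


def causal_rank(ranked: RankedGeneList, causal: int) -> CausalRankRecord:
    """1-based rank of ``causal`` in the full output list, or MISSED."""
    try:
        rank = ranked.genes.index(causal) + 1
    except ValueError:
        rank = None
    return CausalRankRecord(
        tool=ranked.tool,
        case_id=ranked.case_id,
        causal_gene=causal,
        rank=rank,
        output_size=len(ranked.genes),
    )


def panel_rank(
    full_list: RankedGeneList,
    panel: Iterable[int],
    causal: int,
    rng: np.random.Generator,
) -> int:
    """Rank of the causal gene within a candidate panel, imputing when absent.

    The tool's full output is restricted to the panel, preserving order. If
    the causal gene is among the returned panel genes its position there is
    the rank (independent of ``rng``). Otherwise the analyst investigates the
    ``k`` returned genes first and finds the causal gene somewhere in the
    remaining positions, modeled as a uniform draw on ``{k+1, ..., |panel|}``.
    """
    panel = set(panel)
    if causal not in panel:
        raise UsageError(
            f"causal gene {causal} is not part of the candidate panel"
        )
    restricted = [g for g in full_list.genes if g in panel]
    if causal in restricted:
        return restricted.index(causal) + 1
    k = len(restricted)
    return int(rng.integers(k + 1, len(panel) + 1))


def _median_rank(ranks: Sequence[int]) -> int:
    # lower median: exact for the default odd permutation count, and a
    # documented integer-valued choice if a user overrides it to an even one
    ordered = sorted(ranks)
    return ordered[(len(ordered) - 1) // 2]


def _case_pairs(cases: Sequence[Case]) -> list[tuple[Case, int]]:
    pairs = []
    for case in cases:
        for causal in case.causal_genes:
            pairs.append((case, causal))
    return pairs


def simulate_clinical_exome(
    tool_outputs: Mapping[str, Mapping[str, RankedGeneList]],
    cases: Sequence[Case],
    pool: Sequence[int],
    n_decoys: int = 19,
    n_permutations: int = 25,
    seed: int = 0,
) -> list[SpikeInResult]:
    """Run the spike-in simulation for every tool and (case, causal gene) pair.

    Parameters
    ----------
    tool_outputs : mapping
        ``tool name -> case_id -> RankedGeneList``. A case with no entry for
        a tool is treated as an empty output (the tool returned nothing).
    cases : sequence of Case
        Patient cases; each contributes one pair per causal gene.
    pool : sequence of int
        Clinical-gene pool the decoys are drawn from, without replacement,
        excluding the case's causal genes.
    n_decoys, n_permutations : int
        Panel composition (``n_decoys`` decoys + the causal gene) and the
        number of independently redrawn panels whose ranks are medianed.
    seed : int
        Master seed; identical seeds give identical results. Panels are
        shared across tools for paired comparison.
    """
    if n_permutations < 1 or n_decoys < 1:
        raise UsageError("n_decoys and n_permutations must be >= 1")
    pool = sorted(set(pool))
    pairs = _case_pairs(cases)
    if not pairs:
        raise UsageError("case list contains no (case, causal gene) pairs")

    # pre-draw the shared decoy panels per (case, causal) pair
    panels: list[list[list[int]]] = []
    for p_idx, (case, causal) in enumerate(pairs):
        eligible = np.array(
            [g for g in pool if g not in case.causal_genes], dtype=np.int64
        )
        if len(eligible) < n_decoys:
            raise RuntimeFailure(
                f"gene pool too small: {len(eligible)} eligible decoys for "
                f"case {case.case_id}, need {n_decoys}"
            )
        rng = np.random.default_rng([seed, 11, p_idx])
        panels.append(
            [
                sorted(int(g) for g in
                       rng.choice(eligible, size=n_decoys, replace=False))
                + [causal]
                for _ in range(n_permutations)
            ]
        )

    results: list[SpikeInResult] = []
    for t_idx, tool in enumerate(sorted(tool_outputs)):
        per_case = tool_outputs[tool]
        for p_idx, (case, causal) in enumerate(pairs):
            ranked = per_case.get(
                case.case_id,
                RankedGeneList(tool=tool, case_id=case.case_id, genes=()),
            )
            ranks = []
            for i, panel in enumerate(panels[p_idx]):
                rng = np.random.default_rng([seed, 13, t_idx, p_idx, i])
                ranks.append(panel_rank(ranked, panel, causal, rng))
            results.append(
                SpikeInResult(
                    tool=tool,
                    case_id=case.case_id,
                    causal_gene=causal,
                    median_rank=_median_rank(ranks),
                    permutation_ranks=tuple(ranks),
                )
            )
    return results


def cumulative_detection(
    results: Sequence[SpikeInResult], max_rank: int = 20
) -> pd.DataFrame:
    """Cumulative causal genes detected per tool at each rank 1..max_rank.

    Entry (r, tool) counts spike-in results with ``median_rank <= r``; each
    column is non-decreasing and reaches the tool's pair total at
    ``max_rank``.
    """
    tools = sorted({r.tool for r in results})
    table = pd.DataFrame(
        0, index=pd.RangeIndex(1, max_rank + 1, name="rank"), columns=tools
    )
    for r in results:
        if r.median_rank <= max_rank:
            table.loc[r.median_rank:, r.tool] += 1
    return table


@dataclass(frozen=True)
class UniqueHitsSummary:
    """Complementarity of several tools at one rank cutoff."""

    cutoff: int
    total_pairs: int
    union_count: int
    per_tool_unique: dict = field(default_factory=dict)
    per_tool_hits: dict = field(default_factory=dict)

    @property
    def unique_total(self) -> int:
        return sum(self.per_tool_unique.values())

    @property
    def pct_union_of_total(self) -> float:
        """Share of all pairs detected by at least one tool, in percent."""
        if self.total_pairs == 0:
            return 0.0
        return round(100.0 * self.union_count / self.total_pairs, 2)

    @property
    def pct_unique_of_union(self) -> float:
        """Share of detected pairs found by exactly one tool, in percent."""
        if self.union_count == 0:
            return 0.0
        return round(100.0 * self.unique_total / self.union_count, 2)


def unique_hits(
    per_tool_records: Mapping[str, Sequence[CausalRankRecord]],
    cutoff: int,
) -> UniqueHitsSummary:
    """Count per-tool unique detections and the union at a rank cutoff.

    A (case, causal gene) pair is *hit* by a tool when its rank is within
    ``cutoff``; *unique* when exactly one tool hits it. All tools must cover
    the same pair set.
    """
    if cutoff < 1:
        raise UsageError("cutoff must be >= 1")
    tools = sorted(per_tool_records)
    pair_sets = {
        t: {(r.case_id, r.causal_gene) for r in per_tool_records[t]}
        for t in tools
    }
    reference = pair_sets[tools[0]]
    mismatched = [
        f"{t}: {sorted(pair_sets[t] ^ reference)[:5]}"
        for t in tools
        if pair_sets[t] != reference
    ]
    if mismatched:
        raise RuntimeFailure(
            "tools cover different (case, causal gene) pairs: "
            + "; ".join(mismatched)
        )

    hits = {
        t: {
            (r.case_id, r.causal_gene)
            for r in per_tool_records[t]
            if not r.missed and r.rank <= cutoff
        }
        for t in tools
    }
    union: set = set()
    for s in hits.values():
        union |= s
    unique = {
        t: sum(
            1
            for pair in hits[t]
            if all(pair not in hits[o] for o in tools if o != t)
        )
        for t in tools
    }
    return UniqueHitsSummary(
        cutoff=cutoff,
        total_pairs=len(reference),
        union_count=len(union),
        per_tool_unique=unique,
        per_tool_hits={t: len(hits[t]) for t in tools},
    )


def spikein_hits(
    results: Sequence[SpikeInResult],
) -> dict[str, list[CausalRankRecord]]:
    """Adapt spike-in medians to causal-rank records for complementarity."""
    out: dict[str, list[CausalRankRecord]] = {}
    for r in results:
        out.setdefault(r.tool, []).append(
            CausalRankRecord(
                tool=r.tool,
                case_id=r.case_id,
                causal_gene=r.causal_gene,
                rank=r.median_rank,
                output_size=len(r.permutation_ranks),
            )
        )
    return out


# ---------------------------------------------------------------------------
# readers / writers


def read_genes_only(path, tool: str, case_id: str) -> RankedGeneList:
    """Read the prioritizer's single-line genes-only output for one case."""
    text = Path(path).read_text(encoding="utf-8").strip()
    genes = tuple(int(g) for g in text.split(",")) if text else ()
    return RankedGeneList(tool=tool, case_id=case_id, genes=genes)


def read_tool_outputs(path, tool: str) -> dict[str, RankedGeneList]:
    """Read a generic per-tool TSV: ``case_id <TAB> comma-joined ranked genes``.

    An optional ``case_id``-prefixed header and ``#`` comment lines are
    skipped; an empty second column means the tool returned nothing.
    """
    out: dict[str, RankedGeneList] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("case_id"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = [fields[0], ""]
            cid, genes_txt = fields[0], fields[1]
            genes = tuple(int(g) for g in genes_txt.split(",")) if genes_txt else ()
            out[cid] = RankedGeneList(tool=tool, case_id=cid, genes=genes)
    return out


def write_causal_rank_table(records: Iterable[CausalRankRecord], path) -> Path:
    rows = [
        (r.tool, r.case_id, r.causal_gene, r.rank_label(), r.output_size)
        for r in records
    ]
    df = pd.DataFrame(
        rows, columns=["tool", "case_id", "causal_gene", "rank", "output_size"]
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_spikein_table(results: Iterable[SpikeInResult], path) -> Path:
    rows = [
        (r.tool, r.case_id, r.causal_gene, r.median_rank,
         ",".join(str(x) for x in r.permutation_ranks))
        for r in results
    ]
    df = pd.DataFrame(
        rows,
        columns=["tool", "case_id", "causal_gene", "median_rank",
                 "permutation_ranks"],
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_cumulative_table(table: pd.DataFrame, path) -> Path:
    table.to_csv(path, sep="\t")
    return Path(path)


def write_unique_hits_table(summaries: Iterable[UniqueHitsSummary], path) -> Path:
    rows = []
    for s in summaries:
        for tool in sorted(s.per_tool_unique):
            rows.append(
                (s.cutoff, tool, s.per_tool_hits[tool], s.per_tool_unique[tool],
                 s.union_count, s.total_pairs, s.pct_union_of_total,
                 s.pct_unique_of_union)
            )
    df = pd.DataFrame(
        rows,
        columns=["cutoff", "tool", "hits", "unique_hits", "union_count",
                 "total_pairs", "pct_union_of_total", "pct_unique_of_union"],
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def prioritizer_tool_outputs(
    store, cases: Sequence[Case], expansion=None, tool: str = "phenoprio"
) -> dict[str, dict[str, RankedGeneList]]:
    """Run this package's prioritizer over cases, as benchmark-ready outputs."""
    from .prioritizer import prioritize

    per_case = {}
    for case in cases:
        result = prioritize(store, case.hpo_ids, expansion=expansion)
        per_case[case.case_id] = RankedGeneList(
            tool=tool, case_id=case.case_id, genes=tuple(result.gene_ids())
        )
    return {tool: per_case}
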