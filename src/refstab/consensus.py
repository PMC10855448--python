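"""RefFinder-style consensus ranking of reference-gene candidates.

Each of the four stability methods yields an integer ranking (1 = most
stable).  The consensus score per gene is the geometric mean of its four
ranks; the final order is ascending in that score.

Ranking conventions
-------------------
- ΔCt / BestKeeper / NormFinder: genes are ranked by ascending stability
  value; exact ties are broken by input order and recorded.
- geNorm: the iteratively determined best pair *both* receive rank 1 and the
  next gene receives rank 3 (rank 2 is skipped); the remaining genes follow
  in reverse exclusion order.  This is the convention under which published
  consensus values of the form (2,1,1,1) → 1.19 reproduce exactly.
- Reported geometric means are rounded half-even to 2 decimals.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .qpcr_data import ValidationError
from .stability import METHOD_ORDER, StabilityTable

N_METHODS = 4


@dataclasses.dataclass
class MethodRanking:
    """Integer ranks (1 = most stable) of one method's stability table."""

    method: str
    ranks: pd.Series  # gene -> int
    tie_records: list[str] = dataclasses.field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.ranks.index)


@dataclasses.dataclass
class ConsensusRanking:
    """Per-gene method ranks plus the geometric-mean consensus."""

    ranks: pd.DataFrame        # genes × methods, integer ranks
    geomean: pd.Series         # gene -> geometric mean (full precision)
    condition: str = "ALL"

    @property
    def geomean_rounded(self) -> pd.Series:
        """Geomeans rounded half-even to 2 decimals (reporting convention)."""
        return self.geomean.map(lambda v: float(np.round(v, 2)))

    @property
    def order(self) -> list[str]:
        """Genes from most to least stable (ties keep input order)."""
        return list(self.geomean.sort_values(kind="stable").index)

    @property
    def best(self) -> str:
        return self.order[0]

    @property
    def worst(self) -> str:
        return self.order[-1]

    def to_frame(self) -> pd.DataFrame:
        out = self.ranks.copy()
        out["geomean"] = self.geomean_rounded
        out.index.name = "gene"
        return out.loc[self.order]


def rank_method(t: StabilityTable) -> MethodRanking:
    """Convert a stability table into an integer ranking.

    geNorm tables (recognised by their ``best_pair`` extra) use the
    pair-shares-rank-1 convention; all other methods rank by ascending
    stability value with ties broken by input gene order.
    """
    if t.method == "geNorm" and "best_pair" in t.extras:
        pair = list(t.extras["best_pair"])
        exclusion = list(t.extras["exclusion_order"])
        ranks = {g: 1 for g in pair}
        # Last-excluded gene is next-most stable: rank 3 (2 is skipped).
        for i, g in enumerate(reversed(exclusion)):
            ranks[g] = 3 + i
        series = pd.Series({g: ranks[g] for g in t.genes}, dtype=int)
        return MethodRanking("geNorm", series, t.extras.get("tie_log", []))
    return _rank_by_value(t.method, t.values)


def _rank_by_value(method: str, values: pd.Series) -> MethodRanking:
    order = values.sort_values(kind="stable").index  # stable: ties keep input order
    ranks = pd.Series({g: i + 1 for i, g in enumerate(order)}, dtype=int)
    ties = []
    counts = values.round(12).value_counts()
    for v, c in counts.items():
        if c > 1:
            tied = [g for g in values.index if round(values[g], 12) == v]
            ties.append(f"{method}: tie at {v} among {tied}; broken by input order")
    return MethodRanking(method, ranks.loc[values.index], ties)


def geomean_consensus(
    rankings: Sequence[MethodRanking], condition: str = "ALL"
) -> ConsensusRanking:
    """Aggregate the four method rankings into the consensus.

    The result is invariant to the order in which the methods are supplied;
    the gene sets must agree exactly.
    """
    if len(rankings) != N_METHODS:
        missing = set(METHOD_ORDER) - {r.method for r in rankings}
        raise ValidationError(
            f"consensus needs exactly {N_METHODS} method rankings"
            + (f"; missing {sorted(missing)}" if missing else "")
        )
    by_method = {r.method: r for r in rankings}
    if set(by_method) != set(METHOD_ORDER):
        raise ValidationError(
            f"expected methods {METHOD_ORDER}, got {sorted(by_method)}"
        )
    genes = rankings[0].genes
    for r in rankings:
        if set(r.genes) != set(genes):
            raise ValidationError(f"gene set mismatch in {r.method} ranking")

    ranks = pd.DataFrame(
        {m: by_method[m].ranks.reindex(genes) for m in METHOD_ORDER}, index=genes
    )
    gm = pd.Series(
        np.exp(np.log(ranks.to_numpy(dtype=float)).mean(axis=1)), index=genes
    )
    return ConsensusRanking(ranks=ranks, geomean=gm, condition=condition)


def rank_and_aggregate(
    tables: Sequence[StabilityTable], condition: str | None = None
) -> ConsensusRanking:
    """Convenience: rank four stability tables and aggregate them."""
    rankings = [rank_method(t) for t in tables]
    cond = condition if condition is not None else tables[0].condition
    return geomean_consensus(rankings, condition=cond)


def consensus_from_reported_values(
    block: Mapping[str, Sequence], condition: str = "",
) -> ConsensusRanking:
    """Consensus from published per-method stability values.

    ``block`` maps each method name to a list of ``(gene, value)`` entries in
    reported (ascending-stability) order.  The geNorm entry may start with a
    joint best pair, written ``(("A", "B"), value)`` or ``("A|B", value)``;
    the pair takes rank 1 and the next gene rank 3.  Value ties within the
    other methods are broken by listed order.  This is the golden-file path:
    it reconstructs the consensus from a method-value table alone, without
    the underlying Ct data.
    """
    missing = [m for m in METHOD_ORDER if m not in block]
    if missing:
        raise ValidationError(f"reported block lacks method(s) {missing}")
    rankings = []
    for method in METHOD_ORDER:
        entries = list(block[method])
        if method == "geNorm":
            rankings.append(_rank_reported_genorm(entries))
        else:
            genes, values = _split_entries(entries, method)
            rankings.append(_rank_by_value(method, pd.Series(values, index=genes)))
    gene_sets = [set(r.genes) for r in rankings]
    if any(s != gene_sets[0] for s in gene_sets):
        raise ValidationError("malformed condition block: method gene sets differ")
    return geomean_consensus(rankings, condition=condition)


def _split_entries(entries, method):
    genes, values = [], []
    for e in entries:
        try:
            g, v = e
            values.append(float(v))
            genes.append(str(g))
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"malformed {method} entry {e!r}") from exc
    if len(set(genes)) != len(genes):
        raise ValidationError(f"duplicate gene in {method} block")
    return genes, values


def _rank_reported_genorm(entries) -> MethodRanking:
    first, value = entries[0]
    if isinstance(first, str) and "|" in first:
        pair = tuple(first.split("|"))
    elif isinstance(first, (tuple, list)):
        pair = tuple(first)
    else:
        raise ValidationError(
            f"geNorm block must start with the best pair, got {first!r}"
        )
    if len(pair) != 2:
        raise ValidationError(f"geNorm best pair must have 2 genes, got {pair!r}")
    ranks = {pair[0]: 1, pair[1]: 1}
    for i, (g, _v) in enumerate(entries[1:]):
        ranks[str(g)] = 3 + i
    return MethodRanking("geNorm", pd.Series(ranks, dtype=int))
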