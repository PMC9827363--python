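"""Hypergeometric over-representation analysis (ORA) of gene lists against
GMT gene-set collections.

The universe defaults to the genes measured in the analysis rather than the
genome: enrichment is asked relative to what could have been detected. For
a set with K members in a universe of N, and a query of n genes overlapping
the set in k, the enrichment p-value is the hypergeometric upper tail
P(X >= k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .datasets import DataError
from .diffexpr import bh_adjust


@dataclass
class GeneSet:
    set_id: str
    description: str
    genes: frozenset


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: one tab-separated line per set
    (set id, description, member genes...); duplicate members deduplicated."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            sets.append(GeneSet(fields[0], fields[1], frozenset(fields[2:])))
    if not sets:
        warnings.warn(f"{path}: empty GMT collection")
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *sorted(s.genes)]) + "\n")


def ora(
    query,
    universe,
    collection: list[GeneSet],
    p_cutoff: float = 0.05,
    q_cutoff: float = 0.05,
    min_set_size: int = 5,
    max_set_size: int = 500,
    keep_zero_overlap: bool = False,
) -> pd.DataFrame:
    """Over-representation of the query list in each gene set.

    Genes outside the universe are dropped (count recorded in the
    ``n_query_dropped`` attribute of the result). Sets are restricted to
    universe members and filtered by effective size. Results are BH-adjusted
    across tested sets and sorted by p; ``passes`` marks sets under both the
    p and q cutoffs.
    """
    universe = set(universe)
    query_all = set(query)
    query_set = query_all & universe
    dropped = len(query_all) - len(query_set)
    if not query_set:
        raise DataError("ora: empty query after intersecting with universe")
    n_univ = len(universe)
    n_query = len(query_set)
    rows = []
    for s in collection:
        members = s.genes & universe
        if not (min_set_size <= len(members) <= max_set_size):
            continue
        overlap = sorted(query_set & members)
        k = len(overlap)
        if k == 0 and not keep_zero_overlap:
            continue
        p = float(stats.hypergeom.sf(k - 1, n_univ, len(members), n_query))
        rows.append(
            {
                "set_id": s.set_id,
                "description": s.description,
                "k": k,
                "set_size": len(members),
                "query_size": n_query,
                "universe_size": n_univ,
                "p": min(p, 1.0),
                "genes": ";".join(overlap),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=["set_id", "description", "k", "set_size", "query_size",
                 "universe_size", "p", "genes"],
    )
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
        result["passes"] = (result["p"] < p_cutoff) & (result["q"] < q_cutoff)
        result = result.sort_values(["p", "set_id"]).reset_index(drop=True)
    else:
        result["q"] = []
        result["passes"] = []
    result.attrs["n_query_dropped"] = dropped
    return result
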