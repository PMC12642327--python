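"""Hypergeometric over-representation analysis against GMT gene sets.

For a query list of n genes drawn from a background universe of N genes, a
term annotating K background genes and overlapping the query in k genes is
scored with the upper hypergeometric tail P(X >= k); Benjamini–Hochberg FDR
is computed over all tested terms. The background defaults, upstream in the
pipeline, to the detected proteome (proteins detected in either group)
rather than the whole genome, since the detected proteome is the actual
sampling frame of a presence/absence experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "term",
    "overlap_k",
    "set_size_K",
    "query_size_n",
    "background_N",
    "p_value",
    "fdr",
    "overlap_genes",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets: (term, description, members)."""

    sets: tuple[tuple[str, str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        names = [t for t, _, _ in self.sets]
        if len(names) != len(set(names)):
            raise ValueError("term names must be unique")
        for term, _, members in self.sets:
            if not members:
                raise ValueError(f"term {term!r} has no members")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: term, description, member genes...)."""
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            term, desc, members = fields[0], fields[1], fields[2:]
            members = frozenset(m for m in members if m)
            if not members:
                raise ValueError(f"{path}:{lineno}: term {term!r} has no members")
            sets.append((term, desc, members))
    return GeneSetCollection(tuple(sets))


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"impossible configuration k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def ora(
    query: set[str],
    collection: GeneSetCollection,
    background: set[str],
) -> pd.DataFrame:
    """Over-representation of ``query`` in each term of ``collection``.

    Term memberships are intersected with the background before testing;
    terms empty after intersection are dropped. Results are sorted by
    p-value ascending, term name breaking ties, with BH FDR over all tested
    terms.
    """
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    extra = query - background
    if extra:
        raise ValueError(f"query genes outside background: {sorted(extra)[:10]}")

    N = len(background)
    n = len(query)
    rows = []
    for term, _desc, members in collection.sets:
        in_bg = members & background
        if not in_bg:
            continue
        overlap = in_bg & query
        rows.append(
            {
                "term": term,
                "overlap_k": len(overlap),
                "set_size_K": len(in_bg),
                "query_size_n": n,
                "background_N": N,
                "p_value": hypergeometric_tail(len(overlap), len(in_bg), n, N),
                "overlap_genes": ",".join(sorted(overlap)),
            }
        )
    result = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS if c != "fdr"])
    if result.empty:
        result["fdr"] = pd.Series(dtype=float)
        return result[RESULT_COLUMNS]
    result["fdr"] = multipletests(result["p_value"], method="fdr_bh")[1]
    result = result.sort_values(
        ["p_value", "term"], ascending=[True, True], kind="mergesort"
    ).reset_index(drop=True)
    return result[RESULT_COLUMNS]


def query_from_labels(labeled: pd.DataFrame, labels: set[str]) -> set[str]:
    """Gene-level query from a classified profile table.

    Collapses protein groups to gene symbols, drops empty symbols (logged),
    and keeps genes whose label is in ``labels``.
    """
    sub = labeled[labeled["label"].isin(labels)]
    empty = int((sub["gene"] == "").sum())
    if empty:
        logger.info("excluding %d protein(s) without gene symbol from ORA", empty)
    return set(sub.loc[sub["gene"] != "", "gene"])
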