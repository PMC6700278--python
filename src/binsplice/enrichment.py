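"""Representation-factor functional-category enrichment.

The representation factor (RF) of a gene list against a category is the
observed overlap divided by the overlap expected for independent draws from
the universe, n_list * n_category / N.  RF > 1 means more overlap than
chance; significance comes from the hypergeometric tail.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "representation_factor",
    "hypergeometric_pvalue",
    "enrich_categories",
    "read_gmt",
]


def representation_factor(observed: int, n_list: int, n_category: int, n_universe: int) -> float:
    """Observed overlap over expected overlap n_list*n_category/N."""
    if n_universe <= 0:
        raise ValueError("universe must be non-empty")
    if n_list > n_universe or n_category > n_universe:
        raise ValueError("list/category larger than universe")
    if observed > min(n_list, n_category):
        raise ValueError("overlap exceeds list or category size")
    expected = n_list * n_category / n_universe
    if expected == 0:
        raise ValueError("expected overlap is zero (empty list or category)")
    return observed / expected


def hypergeometric_pvalue(
    observed: int, n_list: int, n_category: int, n_universe: int, tail: str = "over"
) -> float:
    """Exact hypergeometric tail probability of the overlap.

    ``over``: P(X >= observed); ``under``: P(X <= observed), for X the
    overlap of a random ``n_list``-subset with the category.
    """
    if tail == "over":
        return float(hypergeom.sf(observed - 1, n_universe, n_category, n_list))
    if tail == "under":
        return float(hypergeom.cdf(observed, n_universe, n_category, n_list))
    raise ValueError(f"tail must be 'over' or 'under', got {tail!r}")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from GMT (name <tab> description <tab> genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def enrich_categories(
    gene_list: set[str] | list[str],
    gene_sets: dict[str, set[str]],
    universe: set[str] | list[str],
    tail: str = "over",
) -> pd.DataFrame:
    """RF and hypergeometric p for each category, sorted by p-value.

    Genes outside the universe are dropped with a warning; categories are
    intersected with the universe, and categories disjoint from it are
    skipped.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_list = set(gene_list)
    outside = gene_list - universe
    if outside:
        warnings.warn(f"{len(outside)} list genes outside the universe; dropped")
        gene_list &= universe
    rows = []
    for name, members in gene_sets.items():
        cat = members & universe
        if not cat:
            warnings.warn(f"category {name} disjoint from universe; skipped")
            continue
        observed = len(gene_list & cat)
        expected = len(gene_list) * len(cat) / len(universe)
        rows.append(
            {
                "category": name,
                "n_list": len(gene_list),
                "n_category": len(cat),
                "N_universe": len(universe),
                "observed_overlap": observed,
                "expected_overlap": expected,
                "overlap_pct": round(100.0 * observed / len(gene_list), 1)
                if gene_list
                else float("nan"),
                "representation_factor": observed / expected if expected else float("nan"),
                "pvalue": hypergeometric_pvalue(
                    observed, len(gene_list), len(cat), len(universe), tail
                ),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("pvalue").reset_index(drop=True)
    return out
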