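"""Over-representation analysis of gene lists against GMT gene sets.

One-sided hypergeometric (Fisher) upper-tail test per set, BH-FDR across
all sets tested in one call. The background universe defaults to the genes
surviving expression QC; supplied gene-set members outside the universe
are dropped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from modtrait.association import bh_adjust

__all__ = ["GeneSetCollection", "enrich", "read_gmt", "write_gmt"]


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe."""

    sets: dict[str, frozenset] = field(default_factory=dict)
    universe: frozenset = frozenset()

    @classmethod
    def from_dict(
        cls, sets: Mapping[str, Iterable[str]], universe: Iterable[str]
    ) -> "GeneSetCollection":
        universe = frozenset(universe)
        if not universe:
            raise ValueError("universe is empty")
        restricted = {}
        for name, members in sets.items():
            members = frozenset(members)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            outside = members - universe
            if outside:
                warnings.warn(
                    f"set {name!r}: dropping {len(outside)} members outside "
                    "the universe",
                    stacklevel=2,
                )
            kept = members & universe
            if kept:
                restricted[name] = kept
        return cls(sets=restricted, universe=universe)


def read_gmt(path: str | Path) -> dict[str, list]:
    """Parse a GMT file: name <tab> description <tab> member genes..."""
    sets: dict[str, list] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = parts[2:]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *members]) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def enrich(gene_list: Iterable[str], gene_sets: GeneSetCollection) -> pd.DataFrame:
    """One-sided over-representation test of ``gene_list`` against each set.

    For a universe of N genes, a set of K members and a list of n genes
    with h in the set, p = P(X >= h) for X ~ Hypergeom(N, K, n). Returns a
    frame sorted by p with columns set, hits, set_size, list_size,
    universe_size, p, q (BH across the sets tested in this call).
    """
    if not gene_sets.universe:
        raise ValueError("universe is empty")
    genes = frozenset(gene_list)
    outside = genes - gene_sets.universe
    if outside:
        warnings.warn(
            f"dropping {len(outside)} query genes outside the universe",
            stacklevel=2,
        )
        genes = genes & gene_sets.universe
    N = len(gene_sets.universe)
    n = len(genes)
    rows = []
    for name, members in gene_sets.sets.items():
        K = len(members)
        h = len(genes & members)
        p = float(hypergeom.sf(h - 1, N, K, n))
        p = min(max(p, float(np.finfo(float).tiny)), 1.0)  # guard underflow
        rows.append(
            {
                "set": name,
                "hits": h,
                "set_size": K,
                "list_size": n,
                "universe_size": N,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p", kind="mergesort", ignore_index=True)
    return out
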