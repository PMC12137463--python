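"""Over-representation analysis of gene lists against GMT collections.

Hypergeometric (one-tailed Fisher) enrichment per set with
Benjamini-Hochberg FDR across the sets of one collection, plus the plain
rate-ratio arithmetic used to compare hit rates between two gene
universes.  Collections are tested separately, mirroring per-collection
FDR reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSet:
    name: str
    description: str
    members: set[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name} is empty")


def read_gmt(path: str) -> list[GeneSet]:
    """Parse a GMT file (name TAB description TAB gene...), one set per line.

    Duplicate symbols within a line are deduplicated with a warning; lines
    with fewer than three fields raise, naming the line number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs >= 3 tab-separated fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if len(set(genes)) != len(genes):
                warnings.warn(f"{path}:{ln}: duplicate gene symbols in set {name}")
            sets.append(GeneSet(name, desc, set(genes)))
    return sets


def write_gmt(sets, path: str) -> None:
    """Write gene sets ({name: members} dict or GeneSet list) as GMT."""
    if isinstance(sets, dict):
        sets = [GeneSet(n, n, set(m)) for n, m in sets.items()]
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description] + sorted(s.members)) + "\n")


def ora_test(gene_list, sets: list[GeneSet], universe) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    Per set: P(X >= k) with population N = |universe|, K = |set ∩ universe|
    successes and n = |list ∩ universe| draws; enrichment ratio
    (k/n) / (K/N).  BH FDR is computed across the tested sets.  Symbols in
    the gene list outside the universe are dropped (count reported via the
    ``n_dropped`` frame attribute).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("gene universe must be non-empty")
    gene_list = set(gene_list)
    n_dropped = len(gene_list - universe)
    gene_list &= universe
    n_list = len(gene_list)
    n_universe = len(universe)

    rows = []
    for s in sets:
        members = s.members & universe
        if not members:
            continue
        overlap = sorted(gene_list & members)
        k, big_k = len(overlap), len(members)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n_list)) if k > 0 else 1.0
        ratio = ((k / n_list) / (big_k / n_universe)) if n_list else 0.0
        rows.append({
            "set_name": s.name,
            "description": s.description,
            "k_overlap": k,
            "K_set": big_k,
            "n_list": n_list,
            "N_universe": n_universe,
            "p_value": min(p, 1.0),
            "enrichment_ratio": ratio,
            "overlap_genes": ";".join(overlap),
        })
    res = pd.DataFrame(rows)
    if len(res):
        res["fdr"] = multipletests(res["p_value"], method="fdr_bh")[1]
        res = res.sort_values("p_value", kind="stable").reset_index(drop=True)
    res.attrs["n_dropped"] = n_dropped
    return res


def rate_ratio_enrichment(k1: int, n1: int, k2: int, n2: int
                          ) -> tuple[float, float]:
    """Hit-rate ratio (k1/n1)/(k2/n2) between a focal list and a reference
    universe, with a one-tailed Fisher P.

    The 2x2 table treats the focal list as nested in the reference:
    [[k1, n1-k1], [k2-k1, (n2-n1)-(k2-k1)]].  Returns (ratio, p); the
    ratio is NaN when k2 = 0 (undefined baseline rate).
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2 and n1 > 0 and n2 > 0):
        raise ValueError("counts must satisfy 0 <= k <= n with n > 0")
    if k2 == 0:
        return float("nan"), 1.0
    ratio = (k1 / n1) / (k2 / n2)
    table = [[k1, n1 - k1], [k2 - k1, (n2 - n1) - (k2 - k1)]]
    if min(min(row) for row in table) < 0:
        raise ValueError("focal list must be nested in the reference universe")
    p = fisher_exact(table, alternative="greater")[1]
    return ratio, float(p)
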