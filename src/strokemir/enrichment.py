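"""Over-representation analysis of miRNA target-gene unions against gene sets.

The query is the union of validated target genes of a list of miRNAs; each
named gene set is tested for overlap enrichment with the upper-tail
hypergeometric probability P(X >= k), and p-values are adjusted across the
collection by Benjamini-Hochberg.  The universe defaults to the union of all
collection genes and the query, and can be overridden with an explicit
background list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise EnrichmentError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class GeneSetCollection:
    sets: tuple[GeneSet, ...]

    def __post_init__(self):
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise EnrichmentError("gene set names must be unique")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self):
        return len(self.sets)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.genes
        return frozenset(out)


def read_target_map(path) -> dict[str, frozenset[str]]:
    """Two-column tab-separated (mirna, gene) validated-interaction table."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise EnrichmentError("target map needs two columns (mirna, gene)")
    mapping: dict[str, set[str]] = {}
    for mirna, gene in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        if not gene:
            raise EnrichmentError(f"empty gene symbol for {mirna!r}")
        mapping.setdefault(mirna, set()).add(gene)
    return {m: frozenset(g) for m, g in mapping.items()}


def read_gmt(path) -> GeneSetCollection:
    """Standard GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise EnrichmentError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
            sets.append(GeneSet(fields[0], fields[1], frozenset(g for g in fields[2:] if g)))
    return GeneSetCollection(tuple(sets))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


def union_targets(target_map: dict[str, frozenset[str]], mirnas) -> frozenset[str]:
    """Deduplicated union of target genes over the given miRNAs."""
    unknown = [m for m in mirnas if m not in target_map]
    if unknown:
        raise EnrichmentError(f"miRNAs absent from target map: {unknown}")
    out: set[str] = set()
    for m in mirnas:
        out |= target_map[m]
    return frozenset(out)


def hypergeom_test(k: int, m: int, q: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N population, m marked, q drawn)."""
    if not (0 <= k <= min(m, q) <= N):
        raise EnrichmentError(f"inconsistent counts k={k}, m={m}, q={q}, N={N}")
    return float(min(1.0, hypergeom.sf(k - 1, N, m, q)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.min(p) <= 0 or np.max(p) > 1):
        raise EnrichmentError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_ora(
    targets,
    collection: GeneSetCollection,
    universe=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One hypergeometric test per gene set, BH across the collection.

    Query genes and set members are intersected with the universe first, so
    duplicated or out-of-background genes cannot distort the counts.  Rows are
    sorted by adjusted then raw p-value.
    """
    query = frozenset(targets)
    if universe is None:
        universe = collection.all_genes() | query
    universe = frozenset(universe)
    if not query <= universe:
        raise EnrichmentError("universe must contain the query genes")
    for s in collection:
        if not s.genes <= universe:
            raise EnrichmentError(f"universe must contain gene set {s.name!r}")
    N, q = len(universe), len(query & universe)
    rows = []
    for s in collection:
        members = s.genes & universe
        k = len(query & members)
        rows.append({
            "set": s.name,
            "description": s.description,
            "overlap": k,
            "set_size": len(members),
            "query_size": q,
            "universe_size": N,
            "p": hypergeom_test(k, len(members), q, N),
        })
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    df["significant"] = df["p_adj"] < alpha
    return df.sort_values(["p_adj", "p", "set"], kind="mergesort").reset_index(drop=True)
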