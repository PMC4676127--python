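"""Hscore-weighted similarity graphs and constrained gene-family clustering.

Edges exist between genes when more than 1/3 of each gene aligned; the edge
weight is the Hscore, 100 * sc(G1,G2) / max(sc(G1,G1), sc(G2,G2)) with sc
the bit score, clamped to [0, 100].  Families grow by average-linkage
agglomeration constrained by minimum average Hscore (> 5), minimum edge
density (> 1/3), maximum size (500) and an outgroup stop rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


@dataclass
class SimilarityEdge:
    gene1: str
    gene2: str
    bitscore: float
    hscore: float


@dataclass
class FamilyCluster:
    members: list[str]
    species: set[str] = field(default_factory=set)
    contains_outgroup: bool = False
    density: float = 1.0


def build_graph(records: pd.DataFrame, min_aligned_fraction: float = 1 / 3,
                allow_self_fallback: bool = True) -> list[SimilarityEdge]:
    """Hscore-weighted edges from all-vs-all bit-score records.

    ``records`` columns: query, target, bitscore, qalnfrac, talnfrac.  Self
    hits supply the self scores; a gene without one falls back to its
    maximum observed score (when ``allow_self_fallback``) or its pairs are
    skipped with a warning.  An edge requires aligned fraction strictly
    greater than ``min_aligned_fraction`` on both genes.
    """
    self_score: dict[str, float] = {}
    for row in records.itertuples(index=False):
        if row.query == row.target:
            self_score[row.query] = max(self_score.get(row.query, 0.0),
                                        float(row.bitscore))
    fallback: dict[str, float] = {}
    for row in records.itertuples(index=False):
        for g in (row.query, row.target):
            fallback[g] = max(fallback.get(g, 0.0), float(row.bitscore))

    best: dict[tuple[str, str], tuple[float, float, float]] = {}
    for row in records.itertuples(index=False):
        if row.query == row.target:
            continue
        key = tuple(sorted((row.query, row.target)))
        sc = float(row.bitscore)
        qa, ta = float(row.qalnfrac), float(row.talnfrac)
        if key not in best or sc > best[key][0]:
            best[key] = (sc, qa, ta) if key[0] == row.query else (sc, ta, qa)

    edges: list[SimilarityEdge] = []
    for (g1, g2), (sc, f1, f2) in best.items():
        if not (f1 > min_aligned_fraction and f2 > min_aligned_fraction):
            continue
        s1 = self_score.get(g1)
        s2 = self_score.get(g2)
        if s1 is None or s2 is None:
            if not allow_self_fallback:
                warnings.warn(f"no self score for pair ({g1}, {g2}); skipped",
                              stacklevel=2)
                continue
            s1 = s1 if s1 is not None else fallback[g1]
            s2 = s2 if s2 is not None else fallback[g2]
        denom = max(s1, s2)
        h = 100.0 * sc / denom if denom > 0 else 0.0
        h = float(np.clip(h, 0.0, 100.0))
        edges.append(SimilarityEdge(gene1=g1, gene2=g2, bitscore=sc, hscore=h))
    return edges


def _all_genes(records_or_edges, edges: list[SimilarityEdge]) -> list[str]:
    genes = set()
    for e in edges:
        genes.update((e.gene1, e.gene2))
    if isinstance(records_or_edges, pd.DataFrame):
        genes.update(records_or_edges["query"])
        genes.update(records_or_edges["target"])
    return sorted(genes)


def cluster_families(edges: list[SimilarityEdge],
                     genes: Iterable[str] | None = None,
                     species_of: Mapping[str, str] | None = None,
                     min_hscore: float = 5.0, min_density: float = 1 / 3,
                     max_size: int = 500,
                     outgroup_taxa: Iterable[str] = ()) -> list[FamilyCluster]:
    """Average-linkage agglomeration under the published constraints.

    Only edges with Hscore strictly above ``min_hscore`` count.  Clusters
    merge greedily by highest average inter-cluster Hscore (missing edges
    contribute 0), refusing merges whose average weight is not above
    ``min_hscore``, whose merged edge density is not above ``min_density``,
    that would exceed ``max_size``, or that would grow a cluster already
    holding an outgroup-species gene.  Deterministic regardless of edge
    order; isolated genes come out as singleton families.
    """
    outgroups = set(outgroup_taxa)
    species_of = dict(species_of or {})
    weight: dict[tuple[str, str], float] = {}
    for e in edges:
        if e.hscore > min_hscore:
            key = tuple(sorted((e.gene1, e.gene2)))
            weight[key] = max(weight.get(key, 0.0), e.hscore)
    gene_list = sorted(set(genes or [])
                       | {g for k in weight for g in k}
                       | {g for e in edges for g in (e.gene1, e.gene2)})
    clusters: dict[int, set[str]] = {i: {g} for i, g in enumerate(gene_list)}

    def w(a: str, b: str) -> float:
        return weight.get((a, b) if a < b else (b, a), 0.0)

    def has_outgroup(c: set[str]) -> bool:
        return any(species_of.get(g) in outgroups for g in c)

    def n_edges(c: set[str]) -> int:
        return sum(1 for a, b in combinations(sorted(c), 2) if w(a, b) > 0)

    while True:
        candidates = []
        ids = sorted(clusters, key=lambda c: min(clusters[c]))
        for i_pos, ci in enumerate(ids):
            A = clusters[ci]
            if has_outgroup(A):
                continue
            for cj in ids[i_pos + 1:]:
                B = clusters[cj]
                if has_outgroup(B) or len(A) + len(B) > max_size:
                    continue
                cross = [w(a, b) for a in A for b in B]
                avg = sum(cross) / len(cross)
                if avg <= min_hscore:
                    continue
                merged = A | B
                n = len(merged)
                if n_edges(merged) / (n * (n - 1) / 2) <= min_density:
                    continue
                candidates.append((-avg, tuple(sorted(merged)), ci, cj))
        if not candidates:
            break
        _, _, ci, cj = min(candidates)
        clusters[ci] = clusters[ci] | clusters[cj]
        del clusters[cj]

    out = []
    for members in clusters.values():
        members = sorted(members)
        n = len(members)
        possible = n * (n - 1) / 2
        dens = (n_edges(set(members)) / possible) if possible else 1.0
        sp = {species_of[g] for g in members if g in species_of}
        out.append(FamilyCluster(members=members, species=sp,
                                 contains_outgroup=bool(sp & outgroups),
                                 density=dens))
    out.sort(key=lambda c: c.members[0])
    return out


def sharing_summary(families: list[FamilyCluster],
                    combos: Iterable[frozenset[str]] | None = None,
                    known_species: Iterable[str] | None = None
                    ) -> pd.DataFrame:
    """Counts of families per species combination, exclusive and inclusive.

    Exclusive: the family's species set equals the combination.  Inclusive:
    the combination is a subset of the family's species set.  By default
    every distinct species set observed among families is reported.
    """
    if known_species is not None:
        known = set(known_species)
        for fam in families:
            unknown = fam.species - known
            if unknown:
                raise ValueError(f"unknown species labels {sorted(unknown)}")
    if combos is None:
        combos = sorted({frozenset(f.species) for f in families},
                        key=lambda s: (len(s), sorted(s)))
    rows = []
    for combo in combos:
        combo = frozenset(combo)
        rows.append({
            "species": "+".join(sorted(combo)) if combo else "(none)",
            "exclusive": sum(1 for f in families if frozenset(f.species) == combo),
            "inclusive": sum(1 for f in families if combo <= frozenset(f.species)),
        })
    return pd.DataFrame(rows)
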