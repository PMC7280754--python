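"""Target-network rewiring: pair screening, target-set divergence, gain/loss.

A 5'-shifted isomiR carries a *novel seed* and hence a potentially different
target repertoire from the annotated miRNA of the same locus.  This module
implements the screening cascade that turns predicted target sets into a
rewired regulatory network:

1. opposite-deregulation screen — keep (isomiR, target gene) pairs where one
   partner is up- and the other down-regulated;
2. negative-correlation screen — Spearman rho < 0 at FDR < 0.05 across
   matched samples, requiring at least ``min_n`` samples per group;
3. target-set divergence — for each novel seed vs its annotated seed, a
   lower-tail hypergeometric test on the number of shared targets: a small
   p-value means the two seeds share *fewer* targets than expected by
   chance, i.e. the novel seed has rewired the network;
4. gain/loss partition and over-representation of the rewired targets
   against user-supplied gene-set collections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import SeedVariant
from .diffexpr import DeregulationRecord
from .io import GeneSetCollection
from .stats import (
    bh_adjust,
    bonferroni_adjust,
    hypergeometric_lower_tail,
    hypergeometric_upper_tail,
    spearman_correlation,
)
from .targeting import TargetSet

__all__ = [
    "PairScreenRecord",
    "DivergenceResult",
    "RewiredNetwork",
    "EnrichmentResult",
    "screen_opposite_pairs",
    "correlation_screen",
    "overlap_pvalue",
    "variant_pairs",
    "divergence_scan",
    "gain_loss",
    "ora_enrichment",
    "build_rewired_network",
]

MIN_GROUP_N = 50          # minimum tumor and normal sample counts for the correlation screen
CORRELATION_FDR = 0.05
DIVERGENCE_FDR = 0.05
MIN_TARGET_SET_SIZE = 5   # sets smaller than this are excluded from divergence testing


@dataclass(frozen=True)
class PairScreenRecord:
    isomir_id: str
    gene_id: str
    rho: float
    fdr: float
    passes: bool
    n: int = 0


@dataclass(frozen=True)
class DivergenceResult:
    """Outcome of the shared-target hypergeometric test for one seed pair."""

    seed_x: str  # novel seed label
    seed_y: str  # annotated seed label
    N: int       # universe size
    Nx: int      # novel-seed targets in the universe
    Ny: int      # annotated-seed targets in the universe
    Nxy: int     # shared targets
    p: float
    fdr: float = float("nan")

    def __post_init__(self) -> None:
        if self.Nxy > min(self.Nx, self.Ny) or self.Nx > self.N or self.Ny > self.N:
            raise ValueError(f"inconsistent divergence counts: N={self.N}, Nx={self.Nx}, Ny={self.Ny}, Nxy={self.Nxy}")

    @property
    def divergent(self) -> bool:
        return self.fdr < DIVERGENCE_FDR


def screen_opposite_pairs(
    isomir_results: Sequence[DeregulationRecord],
    mrna_results: Sequence[DeregulationRecord],
    isomir_seed_label: Mapping[str, str],
    target_sets: Mapping[str, TargetSet],
) -> list[tuple[str, str]]:
    """Candidate (isomiR, target gene) pairs with opposing deregulation.

    A pair qualifies when the gene is a predicted target of the isomiR's
    seed, both partners are significantly deregulated, and their directions
    are opposite (one up, one down).
    """
    mrna_by_id = {r.feature_id: r for r in mrna_results}
    pairs: list[tuple[str, str]] = []
    for iso in isomir_results:
        if not iso.significant:
            continue
        label = isomir_seed_label.get(iso.feature_id)
        if label is None or label not in target_sets:
            continue
        for gene in sorted(target_sets[label].genes):
            mr = mrna_by_id.get(gene)
            if mr is None or not mr.significant:
                continue
            if {iso.direction, mr.direction} == {"up", "down"}:
                pairs.append((iso.feature_id, gene))
    return pairs


def correlation_screen(
    candidates: Sequence[tuple[str, str]],
    isomir_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    sample_groups: Mapping[str, str],
    min_n: int = MIN_GROUP_N,
    fdr_threshold: float = CORRELATION_FDR,
) -> list[PairScreenRecord]:
    """Negative Spearman co-expression screen over candidate pairs.

    Expression frames are feature x sample; correlation is computed over the
    samples present in both frames.  A pair passes when rho < 0, BH-adjusted
    p (across all tested pairs) < ``fdr_threshold``, and both the tumor and
    normal groups contribute at least ``min_n`` matched samples.
    """
    shared = [s for s in isomir_expr.columns if s in set(mrna_expr.columns)]
    n_tumor = sum(1 for s in shared if sample_groups.get(s) == "tumor")
    n_normal = sum(1 for s in shared if sample_groups.get(s) == "normal")
    groups_ok = n_tumor >= min_n and n_normal >= min_n

    rows: list[tuple[str, str, float, int, bool]] = []
    pvals: list[float] = []
    for isomir_id, gene_id in candidates:
        if isomir_id not in isomir_expr.index or gene_id not in mrna_expr.index:
            continue
        if len(shared) < 3:
            continue
        x = isomir_expr.loc[isomir_id, shared].to_numpy(dtype=float)
        y = mrna_expr.loc[gene_id, shared].to_numpy(dtype=float)
        res = spearman_correlation(x, y)
        rows.append((isomir_id, gene_id, res.statistic, len(shared), res.undefined))
        pvals.append(1.0 if res.undefined else res.p_value)
    fdrs = bh_adjust(pvals) if pvals else np.array([])

    records = []
    for (isomir_id, gene_id, rho, n, undefined), fdr in zip(rows, fdrs):
        passes = (not undefined) and rho < 0 and fdr < fdr_threshold and groups_ok
        records.append(PairScreenRecord(isomir_id=isomir_id, gene_id=gene_id,
                                        rho=float(rho), fdr=float(fdr), passes=passes, n=n))
    return records


def overlap_pvalue(N: int, Nx: int, Ny: int, Nxy: int) -> float:
    """Lower-tail probability of sharing at most ``Nxy - 1`` targets.

    p = F(Nxy - 1 | N, Nx, Ny) = sum_{t=0}^{Nxy-1} C(Nx,t) C(N-Nx, Ny-t) / C(N,Ny),
    evaluated in log-space.  Small p means the observed overlap is smaller
    than expected under random draws — the seeds' target sets are divergent.
    ``Nxy = 0`` gives the empty sum, p = 0.
    """
    if not (0 <= Nx <= N and 0 <= Ny <= N and 0 <= Nxy <= min(Nx, Ny)):
        raise ValueError(f"inconsistent overlap arguments: N={N}, Nx={Nx}, Ny={Ny}, Nxy={Nxy}")
    if Nxy == 0:
        return 0.0
    return hypergeometric_lower_tail(Nxy - 1, N, Nx, Ny)


def variant_pairs(variants: Sequence[SeedVariant]) -> list[tuple[str, str]]:
    """(novel, annotated) label pairs within each locus/arm group."""
    annotated = {v.base_label: v.label for v in variants if v.is_annotated}
    pairs = []
    for v in variants:
        if v.is_annotated:
            continue
        anchor = annotated.get(v.base_label)
        if anchor is not None:
            pairs.append((v.label, anchor))
    return pairs


def divergence_scan(
    target_sets: Mapping[str, TargetSet],
    universe: set[str],
    pairs: Sequence[tuple[str, str]],
    min_set_size: int = MIN_TARGET_SET_SIZE,
    fdr_threshold: float = DIVERGENCE_FDR,
) -> list[DivergenceResult]:
    """Hypergeometric target-set divergence for each (novel, annotated) pair.

    The universe defaults to every gene with a UTR in the input collection;
    target sets are intersected with it.  Sets smaller than ``min_set_size``
    are skipped (an empty set would yield the degenerate p = 0).  BH
    adjustment is applied across all tested pairs and stored as ``fdr``.
    """
    raw: list[DivergenceResult] = []
    for novel_label, annotated_label in pairs:
        tx = target_sets[novel_label].genes & universe
        ty = target_sets[annotated_label].genes & universe
        if len(tx) < min_set_size or len(ty) < min_set_size:
            continue
        result = DivergenceResult(
            seed_x=novel_label, seed_y=annotated_label,
            N=len(universe), Nx=len(tx), Ny=len(ty), Nxy=len(tx & ty),
            p=overlap_pvalue(len(universe), len(tx), len(ty), len(tx & ty)),
        )
        raw.append(result)
    if not raw:
        return []
    fdrs = bh_adjust([r.p for r in raw])
    return [
        DivergenceResult(seed_x=r.seed_x, seed_y=r.seed_y, N=r.N, Nx=r.Nx, Ny=r.Ny,
                         Nxy=r.Nxy, p=r.p, fdr=float(f))
        for r, f in zip(raw, fdrs)
    ]


def gain_loss(novel: TargetSet, annotated: TargetSet) -> tuple[set[str], set[str], set[str]]:
    """(shared, gained, lost) genes of a novel seed relative to the annotated seed."""
    shared = set(novel.genes & annotated.genes)
    gained = set(novel.genes - annotated.genes)
    lost = set(annotated.genes - novel.genes)
    return shared, gained, lost


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    fdr: float
    bonferroni: float


def ora_enrichment(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str],
) -> list[EnrichmentResult]:
    """Over-representation of a query gene set against a GMT collection.

    Per set: hypergeometric upper tail of the overlap given the universe.
    Query genes outside the universe are dropped.  Both BH and Bonferroni
    adjusted p-values are reported, matching the two gating conventions in
    use downstream (FDR < 0.05; Bonferroni p < 0.05 with FDR < 0.2).
    """
    q = query & universe
    names = sorted(collection.sets)
    pvals, rows = [], []
    for name in names:
        members = collection.sets[name] & universe
        k = len(q & members)
        p = hypergeometric_upper_tail(k, len(universe), len(members), len(q)) if members else 1.0
        pvals.append(p)
        rows.append((name, k, len(members)))
    fdrs = bh_adjust(pvals) if pvals else []
    bonf = bonferroni_adjust(pvals) if pvals else []
    return [
        EnrichmentResult(set_name=name, overlap=k, set_size=m, query_size=len(q),
                         universe_size=len(universe), p=float(p), fdr=float(f), bonferroni=float(b))
        for (name, k, m), p, f, b in zip(rows, pvals, fdrs, bonf)
    ]


@dataclass
class RewiredNetwork:
    """Bipartite seed -> gene network with a gene partition.

    Every target gene is classed as ``shared`` (reached by both a novel and
    an annotated seed), ``novel-specific`` or ``annotated-specific``.
    """

    edges: list[dict]
    partition: dict[str, str]
    gene_annotations: dict[str, frozenset[str]]
    seed_annotation_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for edge in self.edges:
            g.add_node(edge["seed_label"], bipartite="seed")
            g.add_node(edge["gene_id"], bipartite="gene",
                       partition=self.partition[edge["gene_id"]])
            g.add_edge(edge["seed_label"], edge["gene_id"], site_type=edge["site_type"])
        return g


def build_rewired_network(
    target_sets: Mapping[str, TargetSet],
    variants: Sequence[SeedVariant],
    screen_results: Sequence[PairScreenRecord] | None = None,
    annotations: GeneSetCollection | None = None,
    isomir_seed_label: Mapping[str, str] | None = None,
    restrict_to_passing: bool = True,
) -> RewiredNetwork:
    """Assemble the rewired seed -> target network.

    When screen results are supplied and ``restrict_to_passing`` is on, edges
    are limited to genes whose (isomiR, gene) pair passed the correlation
    screen for an isomiR carrying that seed.  Genes are partitioned into
    shared / novel-specific / annotated-specific, and per-seed counts of
    annotated-category genes (e.g. hallmark genes) are tallied.
    """
    by_label = {v.label: v for v in variants}
    passing_genes_by_label: dict[str, set[str]] | None = None
    if screen_results is not None and restrict_to_passing:
        passing_genes_by_label = {label: set() for label in target_sets}
        for rec in screen_results:
            if not rec.passes:
                continue
            label = (isomir_seed_label or {}).get(rec.isomir_id)
            if label in passing_genes_by_label:
                passing_genes_by_label[label].add(rec.gene_id)

    edges: list[dict] = []
    novel_genes: set[str] = set()
    annotated_genes: set[str] = set()
    for label, tset in sorted(target_sets.items()):
        variant = by_label.get(label)
        if variant is None:
            continue
        genes = set(tset.genes)
        if passing_genes_by_label is not None:
            genes &= passing_genes_by_label.get(label, set())
        (annotated_genes if variant.is_annotated else novel_genes).update(genes)
        best_site = {}
        for site in tset.sites:
            if site.gene_id in genes and site.gene_id not in best_site:
                best_site[site.gene_id] = site.site_type
        for gene in sorted(genes):
            sets_for_gene = sorted(
                name for name, members in (annotations.sets.items() if annotations else []) if gene in members
            )
            edges.append({"seed_label": label, "gene_id": gene,
                          "site_type": best_site.get(gene, ""),
                          "gene_sets": ",".join(sets_for_gene)})

    partition: dict[str, str] = {}
    for gene in novel_genes | annotated_genes:
        if gene in novel_genes and gene in annotated_genes:
            partition[gene] = "shared"
        elif gene in novel_genes:
            partition[gene] = "novel-specific"
        else:
            partition[gene] = "annotated-specific"

    gene_annotations = {
        gene: frozenset(name for name, members in (annotations.sets.items() if annotations else []) if gene in members)
        for gene in partition
    }
    seed_counts: dict[str, dict[str, int]] = {}
    for edge in edges:
        tally = seed_counts.setdefault(edge["seed_label"], {})
        for name in gene_annotations.get(edge["gene_id"], ()):  # per-seed annotated-gene counts
            tally[name] = tally.get(name, 0) + 1
    return RewiredNetwork(edges=edges, partition=partition,
                          gene_annotations=gene_annotations, seed_annotation_counts=seed_counts)
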