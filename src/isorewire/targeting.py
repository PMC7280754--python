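"""Canonical seed-match target prediction on 3'UTR sequences.

Target recognition is driven by the miRNA seed (nucleotides 2-8).  The three
canonical site types on the target strand are:

* ``7mer-m8`` — perfect Watson-Crick match to miRNA positions 2-8
  (the reverse complement of the seed heptamer);
* ``8mer``    — the 7mer-m8 followed by an A opposite miRNA position 1;
* ``7mer-A1`` — match to miRNA positions 2-7 followed by an A.

When an 8mer is present, its embedded 7mer-m8 (same start) and 7mer-A1
(start + 1) are not reported separately; precedence is
8mer > 7mer-m8 > 7mer-A1.  UTR positions are 1-based and inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import SeedVariant, normalize_rna

__all__ = [
    "SiteMatch",
    "TargetSet",
    "SITE_TYPES",
    "DEFAULT_SITE_TYPES",
    "reverse_complement",
    "site_patterns",
    "scan_sites",
    "build_target_sets",
]

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")
#: site types counted as targets by default; 7mer-A1 sites are the weakest
#: class and are opt-in
DEFAULT_SITE_TYPES = ("8mer", "7mer-m8")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(rna: str) -> str:
    """Reverse complement of an RNA string (involution)."""
    return normalize_rna(rna).translate(_COMPLEMENT)[::-1]


def site_patterns(seed: str) -> dict[str, str]:
    """Target-strand patterns for the three canonical site types of a seed."""
    s = normalize_rna(seed)
    if len(s) != 7:
        raise ValueError(f"seed must be 7 nt, got {len(s)}")
    m8 = reverse_complement(s)
    return {
        "8mer": m8 + "A",
        "7mer-m8": m8,
        "7mer-A1": reverse_complement(s[:6]) + "A",
    }


@dataclass(frozen=True, order=True)
class SiteMatch:
    gene_id: str
    site_type: str
    utr_start: int  # 1-based, inclusive
    utr_end: int

    def __post_init__(self) -> None:
        expected = 8 if self.site_type == "8mer" else 7
        if self.utr_end - self.utr_start + 1 != expected:
            raise ValueError(f"{self.site_type} site must span {expected} nt")


@dataclass(frozen=True)
class TargetSet:
    """Predicted targets of one seed: the distinct genes with a qualifying site."""

    seed_label: str
    genes: frozenset[str]
    sites: tuple[SiteMatch, ...]

    def __post_init__(self) -> None:
        if self.genes != frozenset(s.gene_id for s in self.sites):
            raise ValueError("genes must equal the distinct gene ids of the sites")


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def scan_sites(
    seed: str | SeedVariant,
    utrs: Mapping[str, str],
    seed_label: str | None = None,
    site_types: Sequence[str] = SITE_TYPES,
) -> TargetSet:
    """Scan 3'UTRs for canonical seed-match sites of one seed.

    Overlap resolution: an 8mer at position i suppresses the 7mer-m8 at i and
    the 7mer-A1 at i+1 that it contains.  ``site_types`` restricts which
    site classes count (the scan itself always honours the precedence rule).
    """
    if isinstance(seed, SeedVariant):
        seed_label = seed_label or seed.label
        seed = seed.seed
    label = seed_label or seed
    patterns = site_patterns(seed)
    wanted = set(site_types)
    unknown = wanted - set(SITE_TYPES)
    if unknown:
        raise ValueError(f"unknown site types: {sorted(unknown)}")
    sites: list[SiteMatch] = []
    for gene_id, raw in utrs.items():
        utr = normalize_rna(raw)
        eightmer_starts = set(_find_all(utr, patterns["8mer"]))
        per_type = {
            "8mer": eightmer_starts,
            "7mer-m8": {i for i in _find_all(utr, patterns["7mer-m8"]) if i not in eightmer_starts},
            "7mer-A1": {i for i in _find_all(utr, patterns["7mer-A1"]) if i - 1 not in eightmer_starts},
        }
        for site_type in SITE_TYPES:
            if site_type not in wanted:
                continue
            width = len(patterns[site_type])
            for i in sorted(per_type[site_type]):
                sites.append(SiteMatch(gene_id=gene_id, site_type=site_type,
                                       utr_start=i + 1, utr_end=i + width))
    sites.sort()
    return TargetSet(seed_label=label, genes=frozenset(s.gene_id for s in sites), sites=tuple(sites))


def build_target_sets(
    variants: Sequence[SeedVariant],
    utrs: Mapping[str, str],
    site_types: Sequence[str] = DEFAULT_SITE_TYPES,
) -> dict[str, TargetSet]:
    """One TargetSet per seed variant label; variants sharing a seed share sites.

    The scan is performed once per distinct seed string, so 3'-only variants
    (same seed as the annotated form) receive identical target sets.
    """
    by_seed: dict[str, TargetSet] = {}
    out: dict[str, TargetSet] = {}
    for variant in variants:
        if variant.seed not in by_seed:
            by_seed[variant.seed] = scan_sites(variant.seed, utrs, site_types=site_types)
        base = by_seed[variant.seed]
        out[variant.label] = TargetSet(seed_label=variant.label, genes=base.genes, sites=base.sites)
    return out
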