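"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the shape of the real inputs — multi-locus isomiR
repertoires with 5'/3' end heterogeneity, negative-binomial tumor/normal
count matrices with planted log2 fold changes, 3'UTR collections with
planted seed-match sites (and a guarantee of no unplanned matches), mRNA
counts negatively coupled to targeting isomiRs via a Gaussian copula,
exponential survival with a planted hazard ratio under a median expression
split, and [0, 1] drug-sensitivity values with a planted group shift.

Every generated artifact is accompanied by a plant ledger sufficient to
score the corresponding analysis stage, and identical configurations yield
byte-identical outputs.

Default parameter values describe a deliberately simple cohort: 60 tumor
and 60 normal samples (large enough to satisfy the n >= 50 per-group rule
of the correlation screen), gene-wise constant NB dispersion 0.1, planted
|log2FC| of 2.5 for deregulated features, Spearman coupling of -0.6 for
planted isomiR:mRNA pairs, a survival hazard ratio of 3 and a drug-response
mean shift of 0.2.  3' end variation is made more frequent than 5'
variation (0.6 vs 0.2), reflecting how isomiR repertoires are dominated by
3' heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clinical import median_split
from .core import GenomicSpan, IsomirRecord, MirnaLocus, extract_seed
from .io import CountMatrix
from .targeting import scan_sites, site_patterns

__all__ = [
    "SimulationConfig",
    "PlantedSite",
    "SyntheticDataset",
    "Repertoire",
    "generate_isomir_repertoire",
    "generate_count_matrix",
    "generate_utr_collection",
    "generate_coupled_mrna_counts",
    "generate_survival_data",
    "generate_drug_response_data",
    "generate_dataset",
    "rewiring_scenario",
]

_RNA = np.array(list("ACGU"))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort; same config => identical outputs."""

    rng_seed: int = 0
    # repertoire
    n_loci: int = 4
    mean_isomirs_per_locus: float = 6.0
    prob_shift5: float = 0.2
    prob_shift3: float = 0.6
    max_end_offset: int = 2  # |5'| and |3'| offsets drawn from +-this window
    # counts
    n_tumor: int = 60
    n_normal: int = 60
    nb_mean_log_range: tuple[float, float] = (1.5, 3.0)  # log10 of NB mean
    nb_dispersion: float = 0.1
    planted_de: tuple[tuple[str, float], ...] = ()        # isomiR features
    mrna_planted_de: tuple[tuple[str, float], ...] = ()   # mRNA genes
    # targeting / coupling
    utr_length: int = 500
    n_decoy_genes: int = 40
    planted_sites: tuple[tuple[str, str, str], ...] = ()  # (gene, seed, site_type)
    planted_pairs: tuple[tuple[str, str, float], ...] = ()  # (isomir, gene, spearman rho)
    # clinical
    survival_hazard_ratio: float = 3.0
    base_hazard: float = 0.1
    censoring_rate: float = 0.2
    drug_effect: float = 0.2
    drug_base_sensitivity: float = 0.4
    drug_sd: float = 0.1
    n_cell_lines_per_group: int = 40

    def __post_init__(self) -> None:
        if not (0.0 <= self.prob_shift5 <= 1.0 and 0.0 <= self.prob_shift3 <= 1.0):
            raise ValueError("shift probabilities must lie in [0, 1]")
        if self.prob_shift3 < self.prob_shift5:
            raise ValueError("prob_shift3 must be >= prob_shift5 (3' heterogeneity dominates)")
        if self.nb_dispersion < 0:
            raise ValueError("NB dispersion must be nonnegative")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring rate must lie in [0, 1]")

    def gene_ids(self) -> list[str]:
        """Deterministic gene universe: planted genes first, then decoys."""
        planted = sorted(
            {g for g, _, _ in self.planted_sites}
            | {g for _, g, _ in self.planted_pairs}
            | {g for g, _ in self.mrna_planted_de}
        )
        decoys = [f"GENE{i:03d}" for i in range(self.n_decoy_genes)]
        return planted + [d for d in decoys if d not in planted]


@dataclass(frozen=True)
class PlantedSite:
    gene: str
    seed: str
    site_type: str
    utr_start: int  # 1-based inclusive, matching the scanner convention
    utr_end: int


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # each stage gets an independent, reproducible stream
    return np.random.default_rng(np.random.SeedSequence((config.rng_seed, stage)))


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_RNA, size=length))


def _mature_span(pre_start: int, pre_end: int, strand: str, chrom: str,
                 o5: int, o3: int, offset_in_pre: int, mature_len: int) -> GenomicSpan:
    # transcript positions offset_in_pre+o5 .. offset_in_pre+mature_len-1+o3 (0-based in pre)
    lo = offset_in_pre + o5
    hi = offset_in_pre + mature_len - 1 + o3
    if strand == "+":
        return GenomicSpan("hg38", chrom, pre_start + lo, pre_start + hi, "+")
    return GenomicSpan("hg38", chrom, pre_end - hi, pre_end - lo, "-")


@dataclass(frozen=True)
class Repertoire:
    """Generated loci and isomiR templates plus the shift ledger.

    ``offsets`` maps each kept template to its (offset5, offset3);
    ``draws`` records every raw per-template shift draw *before* duplicate
    templates were collapsed, so marginal shift frequencies can be tallied
    against the configured probabilities.
    """

    loci: tuple[MirnaLocus, ...]
    templates: tuple[IsomirRecord, ...]
    offsets: dict[str, tuple[int, int]]
    draws: tuple[tuple[int, int], ...]

    def __iter__(self):  # tuple-style unpacking: loci, templates, offsets
        return iter((list(self.loci), list(self.templates), self.offsets))


def generate_isomir_repertoire(config: SimulationConfig) -> Repertoire:
    """Random multi-locus isomiR templates with 5'/3' end heterogeneity.

    Each locus draws a Poisson(``mean_isomirs_per_locus``) number of
    templates; a template acquires a nonzero 5' offset with probability
    ``prob_shift5`` and a nonzero 3' offset with probability ``prob_shift3``
    (independently), offsets drawn uniformly from the +-``max_end_offset``
    window.  The canonical (0, 0) template is always present and duplicate
    (offset5, offset3) draws collapse to one template.
    """
    rng = _rng(config, 1)
    loci: list[MirnaLocus] = []
    templates: list[IsomirRecord] = []
    offsets: dict[str, tuple[int, int]] = {}
    draws: list[tuple[int, int]] = []
    pre_len, offset_in_pre, mature_len = 80, 12, 22
    for i in range(config.n_loci):
        family = ("let-7" if i % 2 == 0 else "mir-10") + chr(ord("a") + i // 2)
        locus_id = family
        chrom = f"chr{(i % 22) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        pre_start = int(rng.integers(1_000_000, 50_000_000))
        pre_end = pre_start + pre_len - 1
        pre_seq = _random_rna(rng, pre_len)
        canonical_span = _mature_span(pre_start, pre_end, strand, chrom, 0, 0, offset_in_pre, mature_len)
        locus = MirnaLocus(
            locus_id=locus_id, family=family, pre_mirna_sequence=pre_seq,
            mature_5p=canonical_span,
            annotated_mature_sequences={"5p": pre_seq[offset_in_pre:offset_in_pre + mature_len]},
        )
        loci.append(locus)

        n_draws = int(rng.poisson(config.mean_isomirs_per_locus))
        nonzero = [o for o in range(-config.max_end_offset, config.max_end_offset + 1) if o != 0]
        wanted: list[tuple[int, int]] = [(0, 0)]
        for _ in range(n_draws):
            o5 = int(rng.choice(nonzero)) if rng.random() < config.prob_shift5 else 0
            o3 = int(rng.choice(nonzero)) if rng.random() < config.prob_shift3 else 0
            wanted.append((o5, o3))
            draws.append((o5, o3))
        for o5, o3 in dict.fromkeys(wanted):  # collapse duplicate templates, keep order
            seq = pre_seq[offset_in_pre + o5 : offset_in_pre + mature_len + o3]
            span = _mature_span(pre_start, pre_end, strand, chrom, o5, o3, offset_in_pre, mature_len)
            isomir_id = f"{locus_id}-5p({o5:+d},{o3:+d})"
            templates.append(IsomirRecord(isomir_id=isomir_id, locus_id=locus_id, arm="5p",
                                          span=span, sequence=seq, counts={}))
            offsets[isomir_id] = (o5, o3)
    return Repertoire(loci=tuple(loci), templates=tuple(templates),
                      offsets=offsets, draws=tuple(draws))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion < 1e-8:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


def _sample_ids(config: SimulationConfig) -> tuple[list[str], dict[str, str], dict[str, str]]:
    tumor = [f"T{i:03d}" for i in range(config.n_tumor)]
    normal = [f"N{i:03d}" for i in range(config.n_normal)]
    groups = {**{s: "tumor" for s in tumor}, **{s: "normal" for s in normal}}
    pairs = {s: f"P{i:03d}" for i, s in enumerate(tumor)} | {s: f"P{i:03d}" for i, s in enumerate(normal)}
    return tumor + normal, groups, pairs


def generate_count_matrix(
    templates: Sequence[IsomirRecord] | Sequence[str],
    config: SimulationConfig,
    planted_de: Mapping[str, float] | None = None,
    stage: int = 2,
) -> CountMatrix:
    """Negative-binomial tumor/normal counts with planted fold changes.

    Per-feature base means are log-uniform over ``nb_mean_log_range``
    (log10); per-sample size factors are log-uniform in [0.5, 2]; planted
    features get a tumor/normal mean ratio of 2**log2FC.
    """
    feature_ids = [t if isinstance(t, str) else t.isomir_id for t in templates]
    planted = dict(planted_de if planted_de is not None else config.planted_de)
    unknown = set(planted) - set(feature_ids)
    if unknown:
        raise ValueError(f"planted DE features not among templates: {sorted(unknown)[:5]}")
    rng = _rng(config, stage)
    samples, groups, pairs = _sample_ids(config)
    lo, hi = config.nb_mean_log_range
    base = 10 ** rng.uniform(lo, hi, size=len(feature_ids))
    size = np.exp(rng.uniform(math.log(0.5), math.log(2.0), size=len(samples)))
    is_tumor = np.array([groups[s] == "tumor" for s in samples])
    counts = np.empty((len(feature_ids), len(samples)), dtype=np.int64)
    for i, fid in enumerate(feature_ids):
        mu = np.full(len(samples), base[i])
        if fid in planted:
            mu = np.where(is_tumor, base[i] * 2.0 ** planted[fid], base[i])
        counts[i] = _nb_draw(rng, mu * size, config.nb_dispersion)
    frame = pd.DataFrame(counts, index=feature_ids, columns=samples)
    return CountMatrix(counts=frame, sample_groups=groups, pair_id=pairs)


def generate_utr_collection(
    config: SimulationConfig,
    monitored_seeds: Sequence[str],
    max_attempts: int = 200,
) -> tuple[dict[str, str], list[PlantedSite]]:
    """Random 3'UTRs containing exactly the planted seed-match sites.

    Rejection sampling guarantees that, for every monitored seed, a scan of
    the collection finds the planted sites and nothing else.  Raises if a
    clean UTR cannot be found within ``max_attempts`` (advice: lengthen the
    UTRs or plant fewer sites).
    """
    rng = _rng(config, 3)
    seeds = list(dict.fromkeys(monitored_seeds))
    unknown = {s for _, s, _ in config.planted_sites} - set(seeds)
    if unknown:
        raise ValueError(f"planted sites reference unmonitored seeds: {sorted(unknown)[:3]}")
    plants_by_gene: dict[str, list[tuple[str, str]]] = {}
    for gene, seed, site_type in config.planted_sites:
        plants_by_gene.setdefault(gene, []).append((seed, site_type))

    utrs: dict[str, str] = {}
    ledger: list[PlantedSite] = []
    for gene in config.gene_ids():
        plants = plants_by_gene.get(gene, [])
        for attempt in range(max_attempts):
            chars = list(_random_rna(rng, config.utr_length))
            placed: list[PlantedSite] = []
            occupied: list[tuple[int, int]] = []
            ok = True
            for seed, site_type in plants:
                pattern = site_patterns(seed)[site_type]
                w = len(pattern)
                # leave one spare base on each side to pin the flanks
                pos = None
                for _ in range(50):
                    cand = int(rng.integers(1, config.utr_length - w - 1))
                    if all(cand + w <= a or cand >= b for a, b in occupied):
                        pos = cand
                        break
                if pos is None:
                    ok = False
                    break
                chars[pos:pos + w] = list(pattern)
                occupied.append((pos - 1, pos + w + 1))
                placed.append(PlantedSite(gene=gene, seed=seed, site_type=site_type,
                                          utr_start=pos + 1, utr_end=pos + w))
            if not ok:
                continue
            utr = "".join(chars)
            expected = {
                (p.seed, p.site_type, p.utr_start, p.utr_end) for p in placed
            }
            observed = set()
            for seed in seeds:
                tset = scan_sites(seed, {gene: utr})
                observed |= {(seed, s.site_type, s.utr_start, s.utr_end) for s in tset.sites}
            if observed == expected:
                utrs[gene] = utr
                ledger.extend(placed)
                break
        else:
            raise RuntimeError(
                f"could not generate a clean UTR for {gene} in {max_attempts} attempts; "
                "use longer UTRs or fewer planted sites/monitored seeds"
            )
    return utrs, ledger


def generate_coupled_mrna_counts(
    isomir_matrix: CountMatrix,
    config: SimulationConfig,
    genes: Sequence[str] | None = None,
    stage: int = 4,
) -> CountMatrix:
    """mRNA counts with planted negative rank-coupling to targeting isomiRs.

    For each planted (isomiR, gene, rho) pair the gene's counts are drawn
    through a Gaussian copula against the isomiR's expression ranks, with the
    copula correlation set to 2 sin(pi rho / 6) so that the *Spearman*
    correlation targets rho without constraining the NB marginals.  Genes in
    ``mrna_planted_de`` additionally get a tumor/normal mean shift; decoy
    genes are independent NB noise.
    """
    gene_list = list(genes) if genes is not None else config.gene_ids()
    rng = _rng(config, stage)
    samples = isomir_matrix.sample_ids
    groups = isomir_matrix.sample_groups
    is_tumor = np.array([groups[s] == "tumor" for s in samples])
    pair_by_gene = {gene: (iso, rho) for iso, gene, rho in config.planted_pairs}
    de = dict(config.mrna_planted_de)
    lo, hi = config.nb_mean_log_range
    alpha = max(config.nb_dispersion, 1e-8)
    r = 1.0 / alpha
    counts = np.empty((len(gene_list), len(samples)), dtype=np.int64)
    for i, gene in enumerate(gene_list):
        base = 10 ** rng.uniform(lo, hi)
        mu = np.where(is_tumor, base * 2.0 ** de.get(gene, 0.0), base)
        if gene in pair_by_gene:
            iso, rho_s = pair_by_gene[gene]
            if iso not in isomir_matrix.counts.index:
                raise ValueError(f"planted pair references unknown isomiR {iso!r}")
            expr = isomir_matrix.counts.loc[iso].to_numpy(dtype=float)
            ranks = sps.rankdata(expr, method="average")
            z_iso = sps.norm.ppf((ranks - 0.5) / len(ranks))
            rho_p = 2.0 * math.sin(math.pi * rho_s / 6.0)
            z_gene = rho_p * z_iso + math.sqrt(1.0 - rho_p**2) * rng.standard_normal(len(samples))
            u = np.clip(sps.norm.cdf(z_gene), 1e-12, 1 - 1e-12)
            counts[i] = sps.nbinom.ppf(u, r, r / (r + mu)).astype(np.int64)
        else:
            counts[i] = _nb_draw(rng, mu, alpha)
    frame = pd.DataFrame(counts, index=gene_list, columns=samples)
    return CountMatrix(counts=frame, sample_groups=dict(groups), pair_id=isomir_matrix.pair_id)


def generate_survival_data(
    expression: Mapping[str, float],
    config: SimulationConfig,
    stage: int = 5,
) -> pd.DataFrame:
    """Exponential survival with the hazard scaled for the high-expression stratum.

    Samples strictly above the median expression get hazard
    ``base_hazard * survival_hazard_ratio``; the rest ``base_hazard``.  Each
    observation is independently censored with probability
    ``censoring_rate`` at a uniform fraction of its event time.
    """
    rng = _rng(config, stage)
    strata = median_split(expression)
    rows = []
    for sample in expression:
        hazard = config.base_hazard * (config.survival_hazard_ratio if strata[sample] == "high" else 1.0)
        t = rng.exponential(1.0 / hazard)
        if config.censoring_rate > 0 and rng.random() < config.censoring_rate:
            rows.append({"sample_id": sample, "time": t * rng.uniform(), "event": 0})
        else:
            rows.append({"sample_id": sample, "time": t, "event": 1})
    return pd.DataFrame(rows, columns=["sample_id", "time", "event"])


def generate_drug_response_data(
    groups: Mapping[str, str] | None,
    config: SimulationConfig,
    drug: str = "drug-1",
    stage: int = 6,
) -> pd.DataFrame:
    """[0, 1] drug-sensitivity values with a planted shift for one group.

    ``groups`` maps cell line -> {shifted, comparison}; by default
    ``n_cell_lines_per_group`` lines are created per group.  Sensitivity is
    Gaussian around ``drug_base_sensitivity`` (sd ``drug_sd``), plus
    ``drug_effect`` for the shifted group, clipped to [0, 1].
    """
    rng = _rng(config, stage)
    if groups is None:
        groups = {f"CL{i:03d}": ("shifted" if i < config.n_cell_lines_per_group else "comparison")
                  for i in range(2 * config.n_cell_lines_per_group)}
    rows = []
    for cell_line, label in groups.items():
        shift = config.drug_effect if label == "shifted" else 0.0
        value = float(np.clip(rng.normal(config.drug_base_sensitivity + shift, config.drug_sd), 0.0, 1.0))
        expr = float(rng.normal(10.0 + (5.0 if label == "shifted" else 0.0), 1.0))
        rows.append({"cell_line": cell_line, "drug": drug, "sensitivity": value,
                     "isomir_expression": expr, "group": label})
    return pd.DataFrame(rows, columns=["cell_line", "drug", "sensitivity", "isomir_expression", "group"])


@dataclass
class SyntheticDataset:
    """A full synthetic cohort plus the ledger of everything planted."""

    config: SimulationConfig
    loci: list[MirnaLocus]
    isomir_records: list[IsomirRecord]
    isomir_matrix: CountMatrix
    mrna_matrix: CountMatrix
    utrs: dict[str, str]
    planted_sites: list[PlantedSite]
    planted_offsets: dict[str, tuple[int, int]]
    clinical: pd.DataFrame
    drug: pd.DataFrame
    gene_sets: object | None = None  # optional GeneSetCollection for enrichment

    def ledger(self) -> dict:
        return {
            "planted_de": {f: lfc for f, lfc in self.config.planted_de},
            "mrna_planted_de": {g: lfc for g, lfc in self.config.mrna_planted_de},
            "planted_pairs": [list(p) for p in self.config.planted_pairs],
            "planted_sites": [asdict(s) for s in self.planted_sites],
            "planted_offsets": {k: list(v) for k, v in self.planted_offsets.items()},
            "survival_hazard_ratio": self.config.survival_hazard_ratio,
            "drug_effect": self.config.drug_effect,
        }


def generate_dataset(
    config: SimulationConfig,
    loci: list[MirnaLocus] | None = None,
    templates: list[IsomirRecord] | None = None,
    planted_offsets: dict[str, tuple[int, int]] | None = None,
) -> SyntheticDataset:
    """Assemble a full synthetic cohort from a configuration.

    When ``loci``/``templates`` are omitted a random repertoire is drawn;
    a scenario builder such as :func:`rewiring_scenario` can supply an
    explicit repertoire instead.
    """
    if loci is None or templates is None:
        loci, templates, planted_offsets = generate_isomir_repertoire(config)
    isomir_matrix = generate_count_matrix(templates, config)
    records = [
        IsomirRecord(isomir_id=t.isomir_id, locus_id=t.locus_id, arm=t.arm, span=t.span,
                     sequence=t.sequence,
                     counts=dict(isomir_matrix.counts.loc[t.isomir_id]))
        for t in templates
    ]
    monitored = sorted({extract_seed(t.sequence) for t in templates})
    utrs, planted_sites = generate_utr_collection(config, monitored)
    mrna_matrix = generate_coupled_mrna_counts(isomir_matrix, config)
    anchor = templates[0].isomir_id
    expression = {s: float(v) for s, v in isomir_matrix.counts.loc[anchor].items()}
    clinical = generate_survival_data(expression, config)
    drug = generate_drug_response_data(None, config)
    return SyntheticDataset(
        config=config, loci=loci, isomir_records=records, isomir_matrix=isomir_matrix,
        mrna_matrix=mrna_matrix, utrs=utrs, planted_sites=planted_sites,
        planted_offsets=planted_offsets or {}, clinical=clinical, drug=drug,
    )


def rewiring_scenario(
    rng_seed: int = 0,
    n_targets_per_seed: int = 10,
    coupling_rho: float = -0.6,
    n_background_loci: int = 5,
    **overrides,
) -> tuple[SimulationConfig, list[MirnaLocus], list[IsomirRecord], dict[str, tuple[int, int]]]:
    """An explicit end-to-end scenario with one planted divergent novel seed.

    One let-7-like 5p locus with three isomiR templates: the canonical form,
    a +1 5'-shift variant (novel seed) and a 3'-only variant (+2 at the 3'
    end, same seed as the canonical).  The annotated seed gets
    ``n_targets_per_seed`` planted 8mer targets disjoint from the novel
    seed's planted targets, all isomiRs are planted up-regulated and their
    targets down-regulated with negative expression coupling, so the full
    screening cascade has a known answer: the novel seed's target set is
    divergent, the 3'-only variant's is identical to the annotated one.

    ``n_background_loci`` extra loci contribute canonical and 3'-variant
    isomiRs with no planted effect; they anchor the median-of-ratios
    normalization (which assumes most features are not deregulated) and make
    the multiplicity correction realistic.
    """
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed, 99)))
    pre_len, offset_in_pre, mature_len = 80, 12, 22
    chrom, strand = "chr22", "+"
    pre_start = 46_112_739
    pre_end = pre_start + pre_len - 1
    # redraw the hairpin until the annotated and +1-shifted seeds have
    # mutually non-containing site patterns; otherwise a planted site for one
    # seed would always carry an unplanned match for the other and the UTR
    # rejection sampler could never satisfy its exactness guarantee
    for _ in range(1000):
        pre_seq = _random_rna(rng, pre_len)
        mature = pre_seq[offset_in_pre:offset_in_pre + mature_len]
        seed_a, seed_b = extract_seed(mature), extract_seed(mature[1:])
        pats_a, pats_b = site_patterns(seed_a), site_patterns(seed_b)
        clash = any(p in q for p in pats_a.values() for q in pats_b.values()) or any(
            p in q for p in pats_b.values() for q in pats_a.values()
        )
        if seed_a != seed_b and not clash:
            break
    else:
        raise RuntimeError("could not draw a hairpin with non-overlapping seed patterns")
    canonical_span = _mature_span(pre_start, pre_end, strand, chrom, 0, 0, offset_in_pre, mature_len)
    locus = MirnaLocus(
        locus_id="let-7a", family="let-7a", pre_mirna_sequence=pre_seq,
        mature_5p=canonical_span,
        annotated_mature_sequences={"5p": pre_seq[offset_in_pre:offset_in_pre + mature_len]},
    )
    offsets = {"let-7a-5p(+0,+0)": (0, 0), "let-7a-5p(+1,+1)": (1, 1), "let-7a-5p(+0,+2)": (0, 2)}
    templates = []
    for isomir_id, (o5, o3) in offsets.items():
        templates.append(IsomirRecord(
            isomir_id=isomir_id, locus_id="let-7a", arm="5p",
            span=_mature_span(pre_start, pre_end, strand, chrom, o5, o3, offset_in_pre, mature_len),
            sequence=pre_seq[offset_in_pre + o5 : offset_in_pre + mature_len + o3], counts={},
        ))
    annotated_seed = extract_seed(templates[0].sequence)
    novel_seed = extract_seed(templates[1].sequence)
    if annotated_seed == novel_seed:  # astronomically unlikely, but keep the guarantee
        raise RuntimeError("degenerate scenario: shifted seed equals annotated seed")
    planted_patterns = [site_patterns(annotated_seed)["8mer"], site_patterns(novel_seed)["8mer"]]

    loci = [locus]
    for b in range(n_background_loci):
        b_start = int(rng.integers(1_000_000, 50_000_000))
        b_end = b_start + pre_len - 1
        b_chrom = f"chr{(b % 22) + 1}"
        for _ in range(1000):
            b_pre = _random_rna(rng, pre_len)
            b_seed = extract_seed(b_pre[offset_in_pre:offset_in_pre + mature_len])
            if b_seed in (annotated_seed, novel_seed):
                continue
            # a background seed whose pattern sits inside a planted site would
            # break the UTR exactness guarantee; redraw until clean
            if any(p in q for p in site_patterns(b_seed).values() for q in planted_patterns):
                continue
            break
        else:
            raise RuntimeError("could not draw a clean background hairpin")
        b_locus = MirnaLocus(
            locus_id=f"bg-{b + 1}", family=f"bg-{b + 1}", pre_mirna_sequence=b_pre,
            mature_5p=_mature_span(b_start, b_end, "+", b_chrom, 0, 0, offset_in_pre, mature_len),
            annotated_mature_sequences={"5p": b_pre[offset_in_pre:offset_in_pre + mature_len]},
        )
        loci.append(b_locus)
        for o5, o3 in ((0, 0), (0, 1), (0, -1)):
            isomir_id = f"bg-{b + 1}-5p({o5:+d},{o3:+d})"
            templates.append(IsomirRecord(
                isomir_id=isomir_id, locus_id=b_locus.locus_id, arm="5p",
                span=_mature_span(b_start, b_end, "+", b_chrom, o5, o3, offset_in_pre, mature_len),
                sequence=b_pre[offset_in_pre + o5 : offset_in_pre + mature_len + o3], counts={},
            ))
            offsets[isomir_id] = (o5, o3)

    ann_genes = [f"ANN{i:02d}" for i in range(n_targets_per_seed)]
    nov_genes = [f"NOV{i:02d}" for i in range(n_targets_per_seed)]
    planted_sites = tuple((g, annotated_seed, "8mer") for g in ann_genes) + tuple(
        (g, novel_seed, "8mer") for g in nov_genes
    )
    planted_de = tuple((t.isomir_id, 2.5) for t in templates if t.locus_id == "let-7a")
    mrna_planted_de = tuple((g, -2.5) for g in ann_genes + nov_genes)
    planted_pairs = (
        tuple(("let-7a-5p(+0,+0)", g, coupling_rho) for g in ann_genes)
        + tuple(("let-7a-5p(+0,+2)", g, coupling_rho) for g in ann_genes)
        + tuple(("let-7a-5p(+1,+1)", g, coupling_rho) for g in nov_genes)
    )
    # a gene can only be copula-coupled to one isomiR; later entries override
    # earlier ones in generate_coupled_mrna_counts, which is fine here because
    # the canonical and 3'-only isomiRs share targets and expression patterns
    config = SimulationConfig(
        rng_seed=rng_seed,
        planted_de=planted_de,
        mrna_planted_de=mrna_planted_de,
        planted_sites=planted_sites,
        planted_pairs=planted_pairs,
        **overrides,
    )
    return config, loci, templates, offsets
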