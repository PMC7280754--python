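"""End-to-end orchestration: filters -> DE -> variants -> targets -> screen
-> divergence -> gain/loss -> enrichment -> network -> survival -> drug
response.

``run_pipeline`` consumes a :class:`Dataset` (either generated synthetically
with a known plant ledger, or assembled from files) and a
:class:`RunConfig` holding every threshold, writes the per-stage result
tables into the output directory, and returns a JSON-serializable run
summary with input/output counts, the thresholds used, the seed and
per-stage wall times.  Identical config and seed produce identical outputs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io as iof
from .clinical import drug_response_test, logrank_test, median_split
from .core import MirnaLocus, IsomirRecord, SeedVariant, dedup_multicopy, enumerate_seed_variants
from .diffexpr import (
    differential_expression,
    detection_filter,
    expression_filters,
    normalized_counts,
    results_frame,
    rpm_normalize,
)
from .rewiring import (
    build_rewired_network,
    correlation_screen,
    divergence_scan,
    gain_loss,
    ora_enrichment,
    screen_opposite_pairs,
    variant_pairs,
)
from .simulate import SimulationConfig, SyntheticDataset, generate_dataset, rewiring_scenario
from .targeting import DEFAULT_SITE_TYPES, build_target_sets

__all__ = ["RunConfig", "Dataset", "run_pipeline", "load_dataset", "write_dataset", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Every tunable threshold of the cascade, with the published presets."""

    rng_seed: int = 0
    outdir: str = "isorewire-out"
    log2fc_threshold: float = 1.5
    adjusted_p_threshold: float = 0.05
    detection_fraction: float = 0.5
    min_rpm: float = 50.0
    min_base_mean: float = 500.0
    correlation_fdr: float = 0.05
    min_group_n: int = 50
    divergence_fdr: float = 0.05
    min_target_set_size: int = 5
    dr_threshold: float = 0.1
    site_types: tuple[str, ...] = DEFAULT_SITE_TYPES
    dedup_mode: str = "collapse"

    def __post_init__(self) -> None:
        for name in ("log2fc_threshold", "adjusted_p_threshold", "detection_fraction",
                     "min_rpm", "min_base_mean", "correlation_fdr", "divergence_fdr",
                     "dr_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# a file-assembled dataset carries the same fields; the ledger is then empty
Dataset = SyntheticDataset


def load_dataset(indir: str | Path) -> Dataset:
    """Assemble a Dataset from the file layout written by :func:`write_dataset`."""
    indir = Path(indir)
    for name in ("loci.tsv", "isomirs.tsv", "mrna_counts.tsv", "samples.tsv",
                 "utrs.fasta", "clinical.tsv", "drug.tsv"):
        if not (indir / name).exists():
            raise FileNotFoundError(f"missing input file: {indir / name}")
    loci = iof.read_locus_table(indir / "loci.tsv")
    records = iof.read_isomir_table(indir / "isomirs.tsv")
    mrna = iof.read_count_matrix(indir / "mrna_counts.tsv", indir / "samples.tsv")
    counts = pd.DataFrame({r.isomir_id: pd.Series(r.counts) for r in records}).T
    counts = counts[mrna.sample_ids]
    isomir_matrix = iof.CountMatrix(counts=counts.astype(int),
                                    sample_groups=mrna.sample_groups, pair_id=mrna.pair_id)
    utrs = iof.read_fasta(indir / "utrs.fasta")
    clinical = iof.read_clinical_table(indir / "clinical.tsv")
    drug = iof.read_drug_table(indir / "drug.tsv")
    gene_sets = iof.read_gmt(indir / "gene_sets.gmt") if (indir / "gene_sets.gmt").exists() else None
    ds = Dataset(config=SimulationConfig(), loci=loci, isomir_records=records,
                 isomir_matrix=isomir_matrix, mrna_matrix=mrna, utrs=utrs,
                 planted_sites=[], planted_offsets={}, clinical=clinical, drug=drug)
    ds.gene_sets = gene_sets
    return ds


def write_dataset(dataset: Dataset, outdir: str | Path) -> None:
    """Persist a dataset in the pipeline's input file layout (plus ledger)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    iof.write_locus_table(dataset.loci, outdir / "loci.tsv")
    iof.write_isomir_table(dataset.isomir_records, outdir / "isomirs.tsv")
    iof.write_count_matrix(dataset.mrna_matrix, outdir / "mrna_counts.tsv", outdir / "samples.tsv")
    iof.write_fasta(dataset.utrs, outdir / "utrs.fasta")
    iof.write_clinical_table(dataset.clinical, outdir / "clinical.tsv")
    iof.write_drug_table(dataset.drug, outdir / "drug.tsv")
    gene_sets = getattr(dataset, "gene_sets", None)
    if gene_sets is not None:
        iof.write_gmt(gene_sets, outdir / "gene_sets.gmt")
    iof.write_run_summary(dataset.ledger(), outdir / "plant_ledger.json")


def _default_gene_sets(dataset: Dataset) -> iof.GeneSetCollection | None:
    existing = getattr(dataset, "gene_sets", None)
    if existing is not None:
        return existing
    planted = sorted({s.gene for s in dataset.planted_sites})
    if not planted:
        return None
    decoys = sorted(set(dataset.utrs) - set(planted))[:10]
    sets = {"planted_targets": frozenset(planted)}
    if decoys:
        sets["decoy_set"] = frozenset(decoys)
    return iof.GeneSetCollection(sets=sets, description={k: "" for k in sets})


def run_pipeline(dataset: Dataset | None = None, config: RunConfig | None = None) -> dict:
    """Run the full cascade; returns the run summary (also written to disk).

    With no dataset, the default synthetic rewiring scenario for
    ``config.rng_seed`` is generated first.
    """
    config = config or RunConfig()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.rng_seed, "thresholds": asdict(config), "stages": {}}
    timings: dict[str, float] = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 4)
                if exc is not None:
                    raise PipelineError(name, exc) from exc
        return _Timer()

    if dataset is None:
        with stage("simulate"):
            sim_cfg, loci, templates, offsets = rewiring_scenario(config.rng_seed)
            dataset = generate_dataset(sim_cfg, loci, templates, offsets)

    with stage("dedup"):
        kept, dropped = dedup_multicopy(dataset.isomir_records, mode=config.dedup_mode)
        summary["stages"]["dedup"] = {"input": len(dataset.isomir_records),
                                      "kept": len(kept), "dropped": len(dropped)}

    with stage("filters"):
        kept_ids = [r.isomir_id for r in kept]
        iso_matrix = iof.CountMatrix(counts=dataset.isomir_matrix.counts.loc[kept_ids],
                                     sample_groups=dataset.isomir_matrix.sample_groups,
                                     pair_id=dataset.isomir_matrix.pair_id)
        iso_matrix = detection_filter(iso_matrix, config.detection_fraction)
        mrna_matrix = detection_filter(dataset.mrna_matrix, config.detection_fraction)
        summary["stages"]["filters"] = {
            "isomirs_after_detection": len(iso_matrix.feature_ids),
            "mrnas_after_detection": len(mrna_matrix.feature_ids),
        }

    with stage("diffexpr"):
        iso_de = differential_expression(iso_matrix, log2fc_threshold=config.log2fc_threshold,
                                         alpha=config.adjusted_p_threshold)
        mrna_de = differential_expression(mrna_matrix, log2fc_threshold=config.log2fc_threshold,
                                          alpha=config.adjusted_p_threshold)
        results_frame(iso_de).to_csv(outdir / "isomir_de.tsv", sep="\t", index=False)
        results_frame(mrna_de).to_csv(outdir / "mrna_de.tsv", sep="\t", index=False)
        rpm = rpm_normalize(iso_matrix)
        base_means = pd.Series({r.feature_id: r.base_mean for r in iso_de})
        expressed = expression_filters(base_means, rpm, config.min_rpm, config.min_base_mean)
        summary["stages"]["diffexpr"] = {
            "isomirs_significant": sum(r.significant for r in iso_de),
            "mrnas_significant": sum(r.significant for r in mrna_de),
            "isomirs_expressed": len(expressed),
        }

    with stage("variants"):
        by_locus: dict[str, list[IsomirRecord]] = {}
        for rec in kept:
            if rec.isomir_id in set(iso_matrix.feature_ids):
                by_locus.setdefault(rec.locus_id, []).append(rec)
        variants: list[SeedVariant] = []
        excluded = 0
        isomir_seed_label: dict[str, str] = {}
        for locus in dataset.loci:
            if locus.locus_id not in by_locus:
                continue
            enum = enumerate_seed_variants(by_locus[locus.locus_id], locus)
            variants.extend(enum.variants)
            excluded += len(enum.excluded)
            for v in enum.variants:
                for isomir_id in v.isomir_ids:
                    isomir_seed_label[isomir_id] = v.label
        summary["stages"]["variants"] = {"n_variants": len(variants), "excluded": excluded}

    with stage("targets"):
        target_sets = build_target_sets(variants, dataset.utrs, site_types=config.site_types)
        summary["stages"]["targets"] = {
            label: len(ts.genes) for label, ts in sorted(target_sets.items())
        }

    with stage("screen"):
        candidates = screen_opposite_pairs(iso_de, mrna_de, isomir_seed_label, target_sets)
        screen = correlation_screen(
            candidates, normalized_counts(iso_matrix), normalized_counts(mrna_matrix),
            iso_matrix.sample_groups, min_n=config.min_group_n,
            fdr_threshold=config.correlation_fdr,
        )
        pd.DataFrame([asdict(r) for r in screen]).to_csv(outdir / "pair_screen.tsv", sep="\t", index=False)
        summary["stages"]["screen"] = {"candidates": len(candidates),
                                       "passing": sum(r.passes for r in screen)}

    with stage("divergence"):
        pairs = variant_pairs(variants)
        universe = set(dataset.utrs)
        div = divergence_scan(target_sets, universe, pairs,
                              min_set_size=config.min_target_set_size,
                              fdr_threshold=config.divergence_fdr)
        pd.DataFrame([asdict(r) for r in div]).to_csv(outdir / "divergence.tsv", sep="\t", index=False)
        gains = {}
        for r in div:
            shared, gained, lost = gain_loss(target_sets[r.seed_x], target_sets[r.seed_y])
            gains[r.seed_x] = {"shared": sorted(shared), "gained": sorted(gained), "lost": sorted(lost)}
        summary["stages"]["divergence"] = {
            "tested": len(div), "divergent": sum(r.divergent for r in div),
            "gain_loss": {k: {kk: len(vv) for kk, vv in v.items()} for k, v in gains.items()},
        }

    with stage("enrichment"):
        gene_sets = _default_gene_sets(dataset)
        enrichments = {}
        if gene_sets is not None:
            for label, parts in gains.items():
                query = set(parts["gained"]) | set(parts["lost"])
                if query:
                    enrichments[label] = ora_enrichment(query, gene_sets, universe)
            rows = [
                {"seed_label": label, **asdict(e)}
                for label, results in enrichments.items() for e in results
            ]
            pd.DataFrame(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        summary["stages"]["enrichment"] = {"queries": len(enrichments)}

    with stage("network"):
        network = build_rewired_network(target_sets, variants, screen, gene_sets,
                                        isomir_seed_label, restrict_to_passing=True)
        iof.write_edge_list(network.edges, outdir / "network_edges.tsv")
        summary["stages"]["network"] = {
            "edges": len(network.edges),
            "partition": {k: sum(1 for v in network.partition.values() if v == k)
                          for k in ("shared", "novel-specific", "annotated-specific")},
        }

    with stage("survival"):
        clinical = dataset.clinical.set_index("sample_id")
        norm = normalized_counts(iso_matrix)
        surv_rows = []
        for isomir_id in iso_matrix.feature_ids:
            shared_samples = [s for s in norm.columns if s in clinical.index]
            expr = {s: float(norm.loc[isomir_id, s]) for s in shared_samples}
            try:
                strata = median_split(expr)
            except ValueError:
                continue
            res = logrank_test(
                clinical.loc[shared_samples, "time"].to_numpy(),
                clinical.loc[shared_samples, "event"].to_numpy().astype(bool),
                [strata[s] for s in shared_samples], isomir_id=isomir_id,
            )
            surv_rows.append(asdict(res))
        pd.DataFrame(surv_rows).to_csv(outdir / "survival.tsv", sep="\t", index=False)
        summary["stages"]["survival"] = {
            "tested": len(surv_rows),
            "significant": sum(1 for r in surv_rows if r["p"] < 0.05),
        }

    with stage("drugresponse"):
        drug_rows = []
        for drug_name, sub in dataset.drug.groupby("drug"):
            sens = dict(zip(sub["cell_line"], sub["sensitivity"]))
            if "group" in sub.columns:
                groups = {c: ("shifted" if g == "shifted" else "comparison")
                          for c, g in zip(sub["cell_line"], sub["group"])}
            else:
                strata = median_split(dict(zip(sub["cell_line"], sub["isomir_expression"])))
                groups = {c: ("shifted" if strata[c] == "high" else "comparison") for c in strata}
            rec = drug_response_test(sens, groups, drug=str(drug_name),
                                     dr_threshold=config.dr_threshold)
            drug_rows.append(asdict(rec))
        pd.DataFrame(drug_rows).to_csv(outdir / "drug_response.tsv", sep="\t", index=False)
        summary["stages"]["drugresponse"] = {
            "drugs": len(drug_rows),
            "calls": sum(1 for r in drug_rows if r["call"] != "ns"),
        }

    summary["timings_s"] = timings
    summary["stages_completed"] = list(timings)
    iof.write_run_summary(summary, outdir / "run_summary.json")
    return summary
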