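"""Synthetic-data generator: determinism and planted-structure guarantees."""

import numpy as np
import pytest
from scipy import stats as sps

from isorewire.core import classify_shift, extract_seed
from isorewire.simulate import (
    SimulationConfig,
    generate_count_matrix,
    generate_coupled_mrna_counts,
    generate_drug_response_data,
    generate_isomir_repertoire,
    generate_survival_data,
    generate_utr_collection,
    rewiring_scenario,
    generate_dataset,
)


class TestRepertoire:
    def test_canonical_only_when_probabilities_zero(self):
        config = SimulationConfig(rng_seed=0, n_loci=5, mean_isomirs_per_locus=8,
                                  prob_shift5=0.0, prob_shift3=0.0)
        rep = generate_isomir_repertoire(config)
        assert all(off == (0, 0) for off in rep.offsets.values())
        assert len(rep.templates) == 5

    def test_deterministic_under_same_seed(self):
        config = SimulationConfig(rng_seed=9, n_loci=6)
        assert generate_isomir_repertoire(config) == generate_isomir_repertoire(config)

    def test_shift_fractions_match_probabilities(self):
        config = SimulationConfig(rng_seed=7, n_loci=500, mean_isomirs_per_locus=20,
                                  prob_shift5=0.2, prob_shift3=0.6)
        draws = np.array(generate_isomir_repertoire(config).draws)
        assert len(draws) > 9000
        assert abs((draws[:, 1] != 0).mean() - 0.6) < 0.02
        assert abs((draws[:, 0] != 0).mean() - 0.2) < 0.02

    def test_offsets_recoverable_from_spans(self):
        config = SimulationConfig(rng_seed=3, n_loci=8)
        rep = generate_isomir_repertoire(config)
        by_locus = {lc.locus_id: lc for lc in rep.loci}
        for t in rep.templates:
            shift = classify_shift(t.span, by_locus[t.locus_id].mature_5p)
            assert (shift.offset5, shift.offset3) == rep.offsets[t.isomir_id]

    def test_shift_order_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(prob_shift5=0.5, prob_shift3=0.2)


class TestCountMatrix:
    def test_near_poisson_limit_at_fixed_mean(self):
        from isorewire.simulate import _nb_draw
        rng = np.random.default_rng(0)
        mu = np.full(10_000, 500.0)
        poisson_like = _nb_draw(rng, mu, 1e-10).astype(float)
        assert poisson_like.var() / poisson_like.mean() == pytest.approx(1.0, abs=0.1)
        overdispersed = _nb_draw(np.random.default_rng(0), mu, 0.1).astype(float)
        # NB variance mu + alpha mu^2 => ratio ~ 1 + 0.1*500 = 51
        assert overdispersed.var() / overdispersed.mean() > 20

    def test_null_config_group_means_equal(self):
        config = SimulationConfig(rng_seed=1, n_tumor=200, n_normal=200,
                                  nb_mean_log_range=(2.5, 2.5), nb_dispersion=0.05)
        m = generate_count_matrix([f"f{i}" for i in range(20)], config)
        t = m.counts[m.samples_in_group("tumor")].mean(axis=1)
        n = m.counts[m.samples_in_group("normal")].mean(axis=1)
        assert np.abs(np.log2(t / n)).max() < 0.25

    def test_planted_fold_change_recovered(self):
        planted = {f"f{i}": 2.5 for i in range(50)}
        config = SimulationConfig(rng_seed=2, n_tumor=30, n_normal=30, nb_dispersion=0.1)
        m = generate_count_matrix(list(planted) + ["bg"], config, planted_de=planted)
        t = m.counts[m.samples_in_group("tumor")].mean(axis=1)
        n = m.counts[m.samples_in_group("normal")].mean(axis=1)
        ratios = np.log2(t.loc[list(planted)] / n.loc[list(planted)])
        assert abs(ratios.mean() - 2.5) < 0.3

    def test_unknown_planted_feature_rejected(self):
        with pytest.raises(ValueError, match="planted"):
            generate_count_matrix(["f0"], SimulationConfig(), planted_de={"ghost": 2.0})


class TestUtrCollection:
    def test_no_plants_no_matches(self):
        from isorewire.targeting import scan_sites
        config = SimulationConfig(rng_seed=0, n_decoy_genes=20)
        utrs, ledger = generate_utr_collection(config, ["GAGGUAG"])
        assert ledger == []
        assert scan_sites("GAGGUAG", utrs).sites == ()

    def test_single_planted_8mer_found_at_recorded_position(self):
        from isorewire.targeting import scan_sites
        config = SimulationConfig(rng_seed=1, n_decoy_genes=5,
                                  planted_sites=(("G1", "GAGGUAG", "8mer"),))
        utrs, ledger = generate_utr_collection(config, ["GAGGUAG"])
        (site,) = scan_sites("GAGGUAG", utrs).sites
        (plant,) = ledger
        assert (site.gene_id, site.utr_start, site.utr_end) == (plant.gene, plant.utr_start, plant.utr_end)

    def test_unmonitored_seed_rejected(self):
        config = SimulationConfig(planted_sites=(("G1", "ACGUACG", "8mer"),))
        with pytest.raises(ValueError, match="unmonitored"):
            generate_utr_collection(config, ["GAGGUAG"])


class TestCoupledMrna:
    def test_planted_coupling_hits_target_rho(self):
        config = SimulationConfig(
            rng_seed=4, n_tumor=60, n_normal=0, n_decoy_genes=0,
            planted_pairs=tuple((f"i{k}", f"g{k}", -0.6) for k in range(20)),
        )
        iso = generate_count_matrix([f"i{k}" for k in range(20)], config)
        mrna = generate_coupled_mrna_counts(iso, config)
        rhos = [sps.spearmanr(iso.counts.loc[f"i{k}"], mrna.counts.loc[f"g{k}"]).statistic
                for k in range(20)]
        assert abs(np.mean(rhos) + 0.6) < 0.15

    def test_decoys_uncorrelated(self):
        config = SimulationConfig(rng_seed=5, n_tumor=60, n_normal=0, n_decoy_genes=40)
        iso = generate_count_matrix(["i0"], config)
        mrna = generate_coupled_mrna_counts(iso, config)
        rhos = np.array([sps.spearmanr(iso.counts.loc["i0"], mrna.counts.loc[g]).statistic
                         for g in mrna.feature_ids])
        assert (np.abs(rhos) < 0.3).mean() >= 0.95

    def test_deterministic(self):
        config = SimulationConfig(rng_seed=6, n_decoy_genes=5)
        iso = generate_count_matrix(["i0"], config)
        a = generate_coupled_mrna_counts(iso, config)
        b = generate_coupled_mrna_counts(iso, config)
        assert a.counts.equals(b.counts)


class TestSurvivalAndDrug:
    def test_hazard_ratio_orders_median_survival(self):
        expr = {f"s{i}": float(i) for i in range(200)}
        config = SimulationConfig(rng_seed=1, survival_hazard_ratio=3.0, censoring_rate=0.0)
        clinical = generate_survival_data(expr, config)
        strata = {s: ("high" if float(s[1:]) > 99.5 else "low") for s in expr}
        times = clinical.set_index("sample_id")["time"]
        high = times[[s for s in expr if strata[s] == "high"]]
        low = times[[s for s in expr if strata[s] == "low"]]
        assert high.median() < low.median()
        assert (clinical["event"] == 1).all()  # censoring rate 0

    def test_censoring_rate_honoured(self):
        expr = {f"s{i}": float(i) for i in range(400)}
        config = SimulationConfig(rng_seed=2, censoring_rate=0.3)
        clinical = generate_survival_data(expr, config)
        assert abs((clinical["event"] == 0).mean() - 0.3) < 0.08

    def test_drug_shift_and_null(self):
        shifted = generate_drug_response_data(None, SimulationConfig(rng_seed=3, drug_effect=0.2))
        by_group = shifted.groupby("group")["sensitivity"].mean()
        assert abs((by_group["shifted"] - by_group["comparison"]) - 0.2) < 0.05
        null = generate_drug_response_data(None, SimulationConfig(rng_seed=3, drug_effect=0.0))
        by_group = null.groupby("group")["sensitivity"].mean()
        assert abs(by_group["shifted"] - by_group["comparison"]) < 0.05

    def test_drug_deterministic(self):
        config = SimulationConfig(rng_seed=4)
        assert generate_drug_response_data(None, config).equals(
            generate_drug_response_data(None, config))


class TestScenario:
    def test_novel_seed_differs_and_3prime_variant_shares(self, scenario_dataset):
        rec = {r.isomir_id: r for r in scenario_dataset.isomir_records}
        ann = extract_seed(rec["let-7a-5p(+0,+0)"].sequence)
        nov = extract_seed(rec["let-7a-5p(+1,+1)"].sequence)
        three_prime = extract_seed(rec["let-7a-5p(+0,+2)"].sequence)
        assert ann != nov and three_prime == ann

    def test_full_dataset_deterministic(self):
        cfg, loci, templates, offsets = rewiring_scenario(17)
        a = generate_dataset(cfg, loci, templates, offsets)
        cfg2, loci2, templates2, offsets2 = rewiring_scenario(17)
        b = generate_dataset(cfg2, loci2, templates2, offsets2)
        assert a.isomir_matrix.counts.equals(b.isomir_matrix.counts)
        assert a.utrs == b.utrs and a.clinical.equals(b.clinical) and a.drug.equals(b.drug)
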