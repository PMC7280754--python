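"""Pair screening, target-set divergence, gain/loss, enrichment, networks."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from isorewire.core import SeedVariant
from isorewire.diffexpr import DeregulationRecord
from isorewire.io import GeneSetCollection
from isorewire.rewiring import (
    build_rewired_network,
    correlation_screen,
    divergence_scan,
    gain_loss,
    ora_enrichment,
    overlap_pvalue,
    screen_opposite_pairs,
    variant_pairs,
)
from isorewire.targeting import SiteMatch, TargetSet


def exact_overlap_cdf(N, Nx, Ny, Nxy):
    """Integer-exact factorial enumeration of the lower-tail overlap CDF."""
    total = math.comb(N, Ny)
    num = sum(math.comb(Nx, t) * math.comb(N - Nx, Ny - t)
              for t in range(Nxy) if Ny - t <= N - Nx)
    return num / total


def dereg(feature_id, direction):
    sig = direction in ("up", "down")
    lfc = {"up": 2.0, "down": -2.0, "ns": 0.1}[direction]
    return DeregulationRecord(feature_id=feature_id, base_mean=100.0, log2fc=lfc,
                              p_value=0.001 if sig else 0.5,
                              adjusted_p=0.01 if sig else 0.6,
                              direction=direction, significant=sig)


def tset(label, genes):
    sites = tuple(SiteMatch(gene_id=g, site_type="7mer-m8", utr_start=1, utr_end=7)
                  for g in sorted(genes))
    return TargetSet(seed_label=label, genes=frozenset(genes), sites=sites)


class TestOverlapPvalue:
    @pytest.mark.parametrize("args,expected", [
        ((10, 5, 4, 2), 55 / 210),
        ((10, 4, 4, 4), 209 / 210),
        ((10, 5, 4, 0), 0.0),
    ])
    def test_hand_factorial_values(self, args, expected):
        assert overlap_pvalue(*args) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_small_universe(self):
        for N in range(1, 13):
            for Nx in range(N + 1):
                for Ny in range(N + 1):
                    for Nxy in range(min(Nx, Ny) + 1):
                        assert overlap_pvalue(N, Nx, Ny, Nxy) == pytest.approx(
                            exact_overlap_cdf(N, Nx, Ny, Nxy), abs=1e-10)

    def test_monotone_in_shared_count(self):
        vals = [overlap_pvalue(30, 12, 9, k) for k in range(10)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_inconsistent_rejected(self):
        with pytest.raises(ValueError):
            overlap_pvalue(10, 5, 4, 5)


class TestOppositeScreen:
    def test_direction_and_target_rules(self):
        iso = [dereg("i_up", "up"), dereg("i_ns", "ns")]
        mrna = [dereg("g_down", "down"), dereg("g_up", "up"), dereg("g_nt", "down")]
        sets = {"s+1": tset("s+1", {"g_down", "g_up"})}
        pairs = screen_opposite_pairs(iso, mrna, {"i_up": "s+1", "i_ns": "s+1"}, sets)
        assert pairs == [("i_up", "g_down")]  # same-direction and non-target excluded


class TestCorrelationScreen:
    def _expr(self, n_per_group, rho, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"T{i}" for i in range(n_per_group)] + [f"N{i}" for i in range(n_per_group)]
        groups = {s: ("tumor" if s.startswith("T") else "normal") for s in samples}
        x = rng.normal(size=len(samples))
        y = rho * x + math.sqrt(1 - rho**2) * rng.normal(size=len(samples))
        iso = pd.DataFrame([x], index=["iso1"], columns=samples)
        mrna = pd.DataFrame([y], index=["g1"], columns=samples)
        return iso, mrna, groups

    def test_strong_negative_pair_passes(self):
        iso, mrna, groups = self._expr(60, -0.7)
        (rec,) = correlation_screen([("iso1", "g1")], iso, mrna, groups)
        assert rec.passes and rec.rho < 0

    def test_group_size_boundary(self):
        iso, mrna, groups = self._expr(49, -0.9)
        (rec,) = correlation_screen([("iso1", "g1")], iso, mrna, groups, min_n=50)
        assert not rec.passes and rec.rho < -0.5  # fails on n alone

    def test_positive_correlation_fails(self):
        iso, mrna, groups = self._expr(60, 0.7)
        (rec,) = correlation_screen([("iso1", "g1")], iso, mrna, groups)
        assert not rec.passes


class TestDivergence:
    def test_disjoint_sets_flagged(self):
        universe = {f"g{i}" for i in range(2000)}
        sets = {"s+1": tset("s+1", {f"g{i}" for i in range(20)}),
                "s+0": tset("s+0", {f"g{i}" for i in range(20, 40)})}
        (res,) = divergence_scan(sets, universe, [("s+1", "s+0")])
        assert res.p < 1e-3 and res.divergent and res.Nxy == 0

    def test_identical_sets_not_flagged(self):
        universe = {f"g{i}" for i in range(100)}
        genes = {f"g{i}" for i in range(10)}
        sets = {"s+1": tset("s+1", genes), "s+0": tset("s+0", genes)}
        (res,) = divergence_scan(sets, universe, [("s+1", "s+0")])
        assert res.p > 0.9 and not res.divergent

    def test_small_sets_skipped(self):
        universe = {f"g{i}" for i in range(100)}
        sets = {"s+1": tset("s+1", {"g1"}), "s+0": tset("s+0", {f"g{i}" for i in range(10)})}
        assert divergence_scan(sets, universe, [("s+1", "s+0")]) == []

    def test_variant_pairs_by_locus(self):
        def v(seed, shift, base):
            return SeedVariant(seed=seed, shift=shift, is_annotated=(shift == 0),
                               label=f"{base}{shift:+d}", base_label=base)
        variants = [v("AAAAAAA", 0, "let-7-5p"), v("CCCCCCC", 1, "let-7-5p"),
                    v("GGGGGGG", -1, "let-7-5p"), v("UUUUUUU", 0, "mir-10-5p"),
                    v("ACGUACG", 2, "orphan-5p")]  # no annotated anchor
        assert variant_pairs(variants) == [("let-7-5p+1", "let-7-5p+0"),
                                           ("let-7-5p-1", "let-7-5p+0")]


class TestGainLoss:
    def test_set_algebra(self):
        novel, annotated = tset("n", {"A", "B", "C"}), tset("a", {"B", "C", "D"})
        shared, gained, lost = gain_loss(novel, annotated)
        assert (shared, gained, lost) == ({"B", "C"}, {"A"}, {"D"})

    def test_conservation(self):
        rng = np.random.default_rng(0)
        pool = [f"g{i}" for i in range(30)]
        for _ in range(10):
            novel = tset("n", set(rng.choice(pool, 12, replace=False)))
            annotated = tset("a", set(rng.choice(pool, 9, replace=False)))
            shared, gained, lost = gain_loss(novel, annotated)
            assert len(shared) + len(gained) == len(novel.genes)
            assert len(shared) + len(lost) == len(annotated.genes)


class TestOra:
    universe = {f"g{i}" for i in range(20)}
    collection = GeneSetCollection(sets={"hall": frozenset({f"g{i}" for i in range(5)})},
                                   description={"hall": ""})

    def test_hand_value(self):
        query = {"g0", "g1", "g2", "g10", "g11"}  # overlap 3 with the 5-gene set
        (res,) = ora_enrichment(query, self.collection, self.universe)
        assert res.p == pytest.approx(1126 / 15504, abs=1e-9)

    def test_zero_overlap_p_one(self):
        (res,) = ora_enrichment({"g10", "g11"}, self.collection, self.universe)
        assert res.p == 1.0

    def test_query_equal_set_is_minimal_p(self):
        set_genes = {f"g{i}" for i in range(5)}
        best = ora_enrichment(set_genes, self.collection, self.universe)[0].p
        for combo in itertools.combinations(sorted(self.universe), 5):
            p = ora_enrichment(set(combo), self.collection, self.universe)[0].p
            assert p >= best - 1e-12

    def test_outside_universe_dropped(self):
        (res,) = ora_enrichment({"g0", "not_in_universe"}, self.collection, self.universe)
        assert res.query_size == 1


class TestRewiredNetwork:
    def _variants(self):
        return [
            SeedVariant(seed="AAAAAAA", shift=0, is_annotated=True, label="x+0", base_label="x"),
            SeedVariant(seed="CCCCCCC", shift=1, is_annotated=False, label="x+1", base_label="x"),
        ]

    def test_partition_classes(self):
        sets = {"x+0": tset("x+0", {"A", "B"}), "x+1": tset("x+1", {"B", "C"})}
        net = build_rewired_network(sets, self._variants(), screen_results=None)
        assert net.partition == {"A": "annotated-specific", "B": "shared", "C": "novel-specific"}

    def test_annotation_counts_hand_tally(self):
        sets = {"x+0": tset("x+0", {"A", "B", "C"}), "x+1": tset("x+1", {"C", "D"})}
        annotations = GeneSetCollection(sets={"hallmark": frozenset({"A", "C", "D"})},
                                        description={"hallmark": ""})
        net = build_rewired_network(sets, self._variants(), screen_results=None,
                                    annotations=annotations)
        assert net.seed_annotation_counts == {"x+0": {"hallmark": 2}, "x+1": {"hallmark": 2}}

    def test_restriction_to_passing_pairs(self):
        sets = {"x+0": tset("x+0", {"A"}), "x+1": tset("x+1", {"B"})}
        net = build_rewired_network(sets, self._variants(), screen_results=[],
                                    isomir_seed_label={}, restrict_to_passing=True)
        assert net.edges == [] and net.partition == {}
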