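"""Target-set divergence and gain/loss between a novel and annotated seed.

The planted scenario contains one locus whose +1-shifted isomiR carries a
novel seed with 10 planted targets disjoint from the annotated seed's 10.
The lower-tail hypergeometric test asks: do the two seeds share fewer
targets than random draws from the gene universe would?
"""

from isorewire import (
    build_target_sets,
    divergence_scan,
    enumerate_seed_variants,
    gain_loss,
    overlap_pvalue,
    variant_pairs,
)
from isorewire.simulate import generate_dataset, rewiring_scenario

config, loci, templates, offsets = rewiring_scenario(rng_seed=0)
dataset = generate_dataset(config, loci, templates, offsets)

by_locus = {}
for rec in dataset.isomir_records:
    by_locus.setdefault(rec.locus_id, []).append(rec)
variants = []
for locus in dataset.loci:
    variants.extend(enumerate_seed_variants(by_locus[locus.locus_id], locus).variants)

target_sets = build_target_sets(variants, dataset.utrs)
pairs = variant_pairs(variants)
results = divergence_scan(target_sets, set(dataset.utrs), pairs)
for r in results:
    print(f"{r.seed_x} vs {r.seed_y}: N={r.N}, Nx={r.Nx}, Ny={r.Ny}, shared={r.Nxy}, "
          f"p={r.p:.3g}, FDR={r.fdr:.3g} -> {'DIVERGENT' if r.divergent else 'not divergent'}")
    shared, gained, lost = gain_loss(target_sets[r.seed_x], target_sets[r.seed_y])
    print(f"  gained {len(gained)} targets, lost {len(lost)}, kept {len(shared)}")

print(f"\nidentical sets for comparison: p = "
      f"{overlap_pvalue(60, 10, 10, 10):.4f} (overlap as large as possible)")
# Zero shared targets out of 10+10 in a 60-gene universe gives p = 0: the
# novel seed has completely rewired the locus's target repertoire.  A seed
# identical to the annotated one would sit at p ~ 1.
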