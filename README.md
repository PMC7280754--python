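# isorewire

**IsomiR seed-shift classification and target-network rewiring analysis.**

A mature miRNA locus produces a repertoire of isoforms (isomiRs) with
heterogeneous 5' and 3' ends. Because targeting is driven by the seed
(miRNA nucleotides 2-8), a 5'-shifted isomiR carries a *novel seed* and can
regulate a different set of mRNAs than the annotated miRNA from the same
locus — rewiring the coding/non-coding regulatory network. `isorewire` is
a library for asking, end to end, whether that rewiring is real and what
it touches:

1. **Seed-shift classification** — strand-aware end-offset arithmetic on
   1-based inclusive spans (`hg38:chr22:46112751-46112773:+`), seed-variant
   enumeration within a +-5-nt window, multicopy collapse.
2. **Differential expression** — median-of-ratios normalization, Wilcoxon
   rank-sum, BH adjustment; deregulated = |log2FC| > 1.5 and adjusted
   p < 0.05, with detection (>= 50% of samples) and abundance (RPM >= 50,
   baseMean >= 500) filters.
3. **Target prediction** — canonical 8mer / 7mer-m8 / 7mer-A1 seed-match
   scanning of 3'UTRs with deterministic overlap precedence.
4. **Pair screening** — opposite deregulation plus negative Spearman
   correlation (FDR < 0.05, n >= 50 per group).
5. **Divergence** — for a novel seed *x* vs its annotated seed *y*, the
   lower-tail hypergeometric probability of the shared-target count,

   p = F(N<sub>xy</sub>−1 | N, N<sub>x</sub>, N<sub>y</sub>) =
   Σ<sub>t=0</sub><sup>N<sub>xy</sub>−1</sup>
   C(N<sub>x</sub>,t)·C(N−N<sub>x</sub>,N<sub>y</sub>−t)/C(N,N<sub>y</sub>),

   small p = fewer shared targets than chance = rewired; gain/loss
   partitions and gene-set over-representation follow.
6. **Clinical read-outs** — median-expression-split log-rank survival and
   drug-response calls (|DR| > 0.1 and p < 0.05).

A first-class synthetic-data module generates every input with planted
ground truth (NB counts with planted fold changes, UTRs with planted sites
and a no-unplanned-match guarantee, copula-coupled mRNA expression,
exponential survival with a planted hazard ratio, shifted drug
sensitivities) so each stage can be scored against a ledger.

## Worked example

```python
from isorewire import (enumerate_seed_variants, build_target_sets,
                       divergence_scan, gain_loss, variant_pairs)
from isorewire.simulate import generate_dataset, rewiring_scenario

config, loci, templates, offsets = rewiring_scenario(rng_seed=0)
ds = generate_dataset(config, loci, templates, offsets)

by_locus = {}
for rec in ds.isomir_records:
    by_locus.setdefault(rec.locus_id, []).append(rec)
variants = [v for locus in ds.loci
            for v in enumerate_seed_variants(by_locus[locus.locus_id], locus).variants]
target_sets = build_target_sets(variants, ds.utrs)
for r in divergence_scan(target_sets, set(ds.utrs), variant_pairs(variants)):
    shared, gained, lost = gain_loss(target_sets[r.seed_x], target_sets[r.seed_y])
    print(f"{r.seed_x} vs {r.seed_y}: N={r.N}, Nx={r.Nx}, Ny={r.Ny}, "
          f"shared={r.Nxy}, p={r.p:.3g}, FDR={r.fdr:.3g}")
    print(f"  gained {len(gained)} targets, lost {len(lost)}, kept {len(shared)}")
```

prints

```
let-7a-5p+1 vs let-7a-5p+0: N=60, Nx=10, Ny=10, shared=0, p=0, FDR=0
  gained 10 targets, lost 10, kept 0
```

i.e. the +1-shifted isomiR's novel seed shares none of the annotated
seed's 10 targets in a 60-gene universe (p ~ 0: maximal divergence), and
gains 10 targets of its own — exactly the planted structure. The
`examples/` directory has one short script per capability (shift
classification, UTR scanning, differential expression, the divergence
screen, survival/drug response, and the full pipeline), and
`isorewire simulate` / `isorewire run` expose the simulate-then-analyze
workflow from the shell.

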