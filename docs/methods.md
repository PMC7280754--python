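# Methods

## Background and model

A mature miRNA locus does not produce a single sequence: alternative and
imprecise Drosha/Dicer cleavage and 3'-end modification generate a
repertoire of isoforms (isomiRs) differing at the 5' and/or 3' end.
Because target recognition is dominated by the seed (miRNA nucleotides
2-8), a 5'-end offset shifts the seed window and can change the target
repertoire — a *novel seed* — while 3'-only variation leaves targeting
unchanged. `isorewire` quantifies this rewiring: which isomiRs carry novel
seeds, whether their target sets diverge from the annotated seed's, which
targets are gained or lost, and whether individual isomiRs associate with
survival or drug response.

## Coordinate and shift conventions

Genomic spans are 1-based and inclusive (`hg38:chr22:46112751-46112773:+`
has length 23). End offsets are defined in transcript (5'->3')
orientation: `offset5 > 0` means the 5' end moved downstream, `offset3 > 0`
means the 3' end is extended. On the minus strand the genomic *end* of a
span is the transcript 5' end, so `offset5 = annotated.end - isomir.end`
and `offset3 = annotated.start - isomir.start`; this convention is fixed by
construction and exercised by dedicated minus-strand tests.

Seed-variant identity is the pair (seed string, 5' offset): isomiRs that
differ only at the 3' end share the annotated seed variant. Variants with
|5' offset| > 5 nt fall outside the considered window and are excluded but
reported. Repeated isomiRs from multicopy/homologous pre-miRNAs collapse
by default to one representative (lexicographically smallest locus id),
preserving expression while avoiding double counting; a `drop_all` mode
removes every copy instead.

## Differential expression

The DE stage is deliberately lightweight: median-of-ratios size factors
(computed over features with all-positive counts), a two-sided Wilcoxon
rank-sum test on normalized counts per feature, Benjamini-Hochberg
adjustment across features, and
`log2FC = log2((mean_T + 0.5) / (mean_N + 0.5))` of normalized group means
(pseudocount 0.5 guards zero means). A feature is deregulated when
|log2FC| > 1.5 **and** adjusted p < 0.05. No dispersion shrinkage,
covariates or batch terms are modelled; the stage's contract is recovery of
planted effects on simulated data, not numerical equality with a
negative-binomial GLM fitter. "Detected" means raw count > 0; the
detection filter (applied to raw counts, before normalization) keeps
features detected in at least ceil(0.5 x n_samples) samples. Abundance
filters are inclusive: max RPM >= 50 and baseMean >= 500 by default, with a
500-RPM preset for dominant isomiRs.

Note that median-of-ratios normalization assumes most features are not
deregulated. If nearly all features in a matrix carry a common planted
fold change, the size factors absorb it and log2FC estimates shrink toward
zero — the synthetic scenarios therefore always include background
features.

## Target prediction

Canonical seed-match site types on the target strand: `7mer-m8` is the
reverse complement of the seed; `8mer` is the 7mer-m8 followed by A;
`7mer-A1` is the reverse complement of seed positions 1-6 followed by A.
An 8mer always contains its own 7mer-m8 (same start) and 7mer-A1
(start + 1); overlap resolution reports only the 8mer, with deterministic
precedence 8mer > 7mer-m8 > 7mer-A1. By default 8mer and 7mer-m8 sites
count as targets and the weaker 7mer-A1 class is opt-in. No context
scoring, conservation, free energy or 3'-supplementary pairing is
computed: the seed determines the target set, which is exactly the quantity
the divergence analysis needs.

## Screening cascade and divergence test

Candidate isomiR:mRNA pairs require (1) the gene to be a predicted target
of the isomiR's seed, (2) both partners significantly deregulated in
opposite directions, and (3) a negative Spearman correlation across
matched samples with BH-FDR < 0.05, computed only when both the tumor and
normal groups contribute at least 50 samples.

For a novel seed x and its annotated seed y with target sets of sizes Nx
and Ny in a universe of N genes, the divergence p-value is the lower tail
of the hypergeometric overlap distribution evaluated at the observed
shared count Nxy:

    p = F(Nxy - 1 | N, Nx, Ny) = sum_{t=0}^{Nxy-1} C(Nx,t) C(N-Nx,Ny-t) / C(N,Ny)

computed in log space. Small p means fewer shared targets than random
draws would give — the seeds' repertoires have diverged. The universe N is
all genes with a UTR in the input collection (a union-of-predicted-targets
alternative is a config option); BH adjustment runs across all tested
(novel, annotated) pairs and divergence is called at FDR < 0.05. Because
an empty target set gives the degenerate p = 0, sets smaller than 5 genes
are excluded from testing. Gain/loss is plain set algebra
(gained = novel \ annotated, lost = annotated \ novel) and satisfies
|shared| + |gained| = |novel|.

Enrichment of gained/lost targets against user-supplied GMT collections is
a hypergeometric upper-tail over-representation test with both BH and
Bonferroni adjustments emitted, matching the two gating conventions used
downstream (FDR < 0.05; Bonferroni p < 0.05 with FDR < 0.2).

## Survival and drug response

Samples are split at the median expression of one isomiR: strictly above
the median is "high", ties at the median go to "low"; fewer than two
distinct values is a degenerate split and an error. The two-group log-rank
test uses the standard O/E/V table over distinct event times,
chi^2 = (sum (O1j - E1j))^2 / sum Vj with 1 df; a group without events
yields a result flagged unreliable. Drug response compares
[0, 1]-pre-scaled sensitivity between the shifted-seed (or high) group and
the comparison group: DR = mean difference, p from the Wilcoxon rank-sum,
and a sensitive/resistant call only when |DR| > 0.1 and p < 0.05 jointly
(positive DR = resistant). The test behind the drug-response p and the
exact grouping rule are package choices (rank-sum; median split by isomiR
expression), both config-exposed.

## Statistical primitives

The Wilcoxon rank-sum uses exact enumeration when the smaller group has at
most 10 observations and there are no ties, otherwise the normal
approximation with tie and continuity corrections. Spearman correlation
uses midranks; a constant vector leaves rho undefined and is flagged
rather than raised. Hypergeometric tails are summed in log space
(logsumexp of log-pmf terms), keeping gene-set-scale arguments stable. The
ordered-group trend test is Jonckheere-Terpstra (cross-group concordant
pairs, ties counting one half), chosen because seed shifts form naturally
ordered groups; its p-value comes from a seeded permutation null by
default (n = 2000) with a no-ties normal approximation as an alternative.

## Synthetic cohorts and what they do (not) show

The generator emulates the *shape* of real inputs with planted ground
truth, and every artifact ships with a ledger sufficient to score the
stage that consumes it. Defaults describe the study conditions: 60 tumor
/ 60 normal samples (so the n >= 50 screen rule is satisfiable), NB counts
with gene-wise constant dispersion 0.1 and per-feature means log-uniform
between 10^1.5 and 10^3, per-sample depth factors log-uniform in [0.5, 2],
planted |log2FC| 2.5, 3'-shift probability 0.6 vs 5'-shift 0.2 (3'
heterogeneity dominates real repertoires), Spearman coupling -0.6 for
planted isomiR:mRNA pairs, 500-nt UTRs, survival hazard ratio 3 with 20%
censoring, and a 0.2 drug-sensitivity shift (sd 0.1, 40 cell lines per
group).

Mechanisms worth noting:

* **UTR exactness guarantee.** Planted sites are spliced into random UTRs
  and the whole collection is rejection-sampled until a scan for every
  monitored seed finds exactly the planted sites. This requires the
  monitored seeds' patterns to be mutually non-containing; the end-to-end
  scenario redraws its hairpin until that holds (e.g. when the base 5' of
  the seed is U, the annotated 8mer would always embed the shifted seed's
  7mer-A1 and no clean UTR could exist).
* **Copula coupling.** Planted gene counts are drawn through a Gaussian
  copula against the isomiR's expression ranks with copula correlation
  2 sin(pi rho / 6), so the *Spearman* correlation targets rho without
  constraining the NB marginals.
* **Censoring.** With probability equal to the censoring rate an
  observation is censored at a uniform fraction of its event time;
  censoring is independent of the group, which is what the log-rank
  calibration checks rely on.

The generator does not attempt real-cohort library-size, batch or
tumor-purity artifacts, gene-gene correlation beyond the planted pairs, UTR composition
bias, or informative censoring. Passing tests therefore demonstrate that
the *method* recovers known structure under clean conditions; they say
nothing about robustness to those real-data complications.

## Problem sizes

The shipped checks use: the full (N <= 25) divergence-formula enumeration
(~44k tuples, integer-exact oracle, tolerance 1e-10); 1,000 random 500-nt
UTRs x 20 seeds for the scanner oracle (exact match); 300 features with 30
planted effects at n = 30/30 for DE recovery; 20 planted pairs among 200
decoys at n = 60/60 for the correlation screen; 100 simulations at hazard
ratio 3 (n = 100/100, 20% censoring) plus 200 null simulations for
log-rank power and calibration; and 100 null simulations for the
drug-response call rate.
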