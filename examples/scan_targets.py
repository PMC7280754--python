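"""Predict canonical seed-match target sites on 3'UTR sequences.

For a seed (miRNA nucleotides 2-8) the three canonical site types on the
target strand are the 8mer (perfect match + A), 7mer-m8 (perfect match) and
7mer-A1 (match to positions 2-7 + A).  An 8mer suppresses the 7mers it
contains.
"""

from isorewire import scan_sites, site_patterns

seed = "GAGGUAG"  # the let-7 family seed
patterns = site_patterns(seed)
print(f"seed {seed} target-strand patterns:")
for site_type, pattern in patterns.items():
    print(f"  {site_type:8s} {pattern}")

utrs = {
    "gene_8mer": "AAA" + patterns["8mer"] + "GGGG",
    "gene_7mer": "GG" + patterns["7mer-m8"] + "GGGGG" + patterns["7mer-A1"] + "GG",
    "gene_none": "ACGU" * 10,
}
tset = scan_sites(seed, utrs)
print(f"\nsites found in {len(utrs)} UTRs:")
for site in tset.sites:
    print(f"  {site.gene_id}: {site.site_type} at {site.utr_start}-{site.utr_end}")
print(f"target genes: {sorted(tset.genes)}")
# gene_8mer reports a single 8mer (its embedded 7mers are suppressed);
# gene_7mer reports both isolated 7mer sites; gene_none has no match.
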