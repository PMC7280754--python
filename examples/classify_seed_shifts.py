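"""Classify isomiR end shifts and enumerate the seed variants of a locus.

A 5'-end offset moves the seed window (miRNA nucleotides 2-8) and creates a
novel seed; 3'-only offsets leave the seed unchanged.  This script builds a
small repertoire around one annotated mature span and shows how the variant
enumeration groups isomiRs by (seed, 5' shift).
"""

from isorewire import (
    GenomicSpan,
    IsomirRecord,
    MirnaLocus,
    classify_shift,
    enumerate_seed_variants,
    parse_isomir_coordinate,
)

annotated = parse_isomir_coordinate("hg38:chr22:46112751-46112773:+")
print(f"annotated mature: {annotated.format()}  (length {annotated.length} nt)")

pre = "G" * 12 + "UGAGGUAGUAGGUUGUAUAGUUU" + "C" * 45
locus = MirnaLocus(locus_id="let-7a", family="let-7a", pre_mirna_sequence=pre,
                   mature_5p=annotated,
                   annotated_mature_sequences={"5p": pre[12:35]})

repertoire = []
for o5, o3 in [(0, 0), (1, 1), (0, -2), (-1, 0)]:
    span = GenomicSpan("hg38", "chr22", annotated.start + o5, annotated.end + o3, "+")
    seq = pre[12 + o5: 35 + o3]
    rec = IsomirRecord(isomir_id=f"iso({o5:+d},{o3:+d})", locus_id="let-7a", arm="5p",
                       span=span, sequence=seq, counts={})
    shift = classify_shift(rec.span, annotated)
    print(f"{rec.isomir_id}: offset5={shift.offset5:+d}, offset3={shift.offset3:+d}")
    repertoire.append(rec)

enum = enumerate_seed_variants(repertoire, locus)
print("\nseed variants (one per distinct seed x 5' shift):")
for v in enum.variants:
    kind = "annotated" if v.is_annotated else "novel"
    print(f"  {v.label}: seed {v.seed} ({kind}), from {len(v.isomir_ids)} isomiR(s)")
# The (0,0) and (0,-2) isomiRs share the annotated variant: only the 5' end
# determines the seed, so 3'-only heterogeneity cannot rewire targeting.
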