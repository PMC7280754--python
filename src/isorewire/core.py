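"""Core domain model: genomic spans, miRNA loci, isomiRs and seed variants.

An *isomiR* is a sequence variant of a mature miRNA produced from the same
genomic locus, differing from the annotated (canonical) mature sequence at
the 5' and/or 3' end.  A 5'-end offset changes the seed heptamer (miRNA
nucleotides 2-8) and thereby the set of mRNAs the molecule can target; a
3'-only offset leaves the seed intact.  This module provides the coordinate
arithmetic and bookkeeping for classifying those shifts and enumerating the
distinct seed variants of a locus.

Coordinates are 1-based and inclusive at both ends, matching the
``assembly:chrom:start-end:strand`` dialect used throughout (a span
``46112751-46112773`` has length 23).  All end-offset arithmetic is done in
transcript (5'->3') orientation: on the minus strand the *genomic end* of a
span is the transcript 5' end.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomicSpan",
    "MirnaLocus",
    "IsomirRecord",
    "ShiftAnnotation",
    "SeedVariant",
    "SeedVariantEnumeration",
    "PositionFrequencyMatrix",
    "CoordinateParseError",
    "parse_isomir_coordinate",
    "format_coordinate",
    "classify_shift",
    "extract_seed",
    "enumerate_seed_variants",
    "dedup_multicopy",
    "position_frequency_matrix",
    "normalize_rna",
]

RNA_ALPHABET = frozenset("ACGU")

#: Maximum |5' offset| (nt) for which a shifted seed is still enumerated as a
#: seed variant; isomiRs beyond this window are excluded and reported.
MAX_SEED_SHIFT = 5

_COORD_RE = re.compile(r"^(?P<assembly>[^:\s]+):(?P<chrom>[^:\s]+):(?P<start>\d+)-(?P<end>\d+):(?P<strand>.+)$")


class CoordinateParseError(ValueError):
    """Raised when a coordinate string does not follow the expected dialect."""


def normalize_rna(sequence: str) -> str:
    """Uppercase a nucleotide string and convert DNA T to RNA U.

    Raises ``ValueError`` on characters outside {A, C, G, U, T}.
    """
    seq = sequence.strip().upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)!r}")
    return seq


@dataclass(frozen=True, order=True)
class GenomicSpan:
    """A 1-based, inclusive genomic interval on a named assembly."""

    assembly: str
    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise CoordinateParseError(f"coordinates must be positive: start={self.start}, end={self.end}")
        if self.end < self.start:
            raise CoordinateParseError(f"start > end: {self.start} > {self.end}")
        if self.strand not in ("+", "-"):
            raise CoordinateParseError(f"unknown strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def format(self) -> str:
        """Render back to the ``assembly:chrom:start-end:strand`` dialect."""
        return f"{self.assembly}:{self.chromosome}:{self.start}-{self.end}:{self.strand}"


def parse_isomir_coordinate(text: str) -> GenomicSpan:
    """Parse a coordinate string like ``hg38:chr22:46112751-46112773:+``.

    Accepts the Unicode minus sign as a strand synonym for ``-``.  Raises
    :class:`CoordinateParseError` naming the offending field on malformed
    input, start > end, or an unknown strand.
    """
    m = _COORD_RE.match(text.strip())
    if m is None:
        raise CoordinateParseError(f"malformed coordinate string: {text!r} (expected assembly:chrom:start-end:strand)")
    strand = m.group("strand").strip().replace("−", "-").replace("–", "-")
    return GenomicSpan(
        assembly=m.group("assembly"),
        chromosome=m.group("chrom"),
        start=int(m.group("start")),
        end=int(m.group("end")),
        strand=strand,
    )


def format_coordinate(span: GenomicSpan) -> str:
    return span.format()


@dataclass(frozen=True)
class MirnaLocus:
    """A pre-miRNA locus with one or two annotated mature arms."""

    locus_id: str
    family: str
    pre_mirna_sequence: str
    mature_5p: GenomicSpan | None = None
    mature_3p: GenomicSpan | None = None
    annotated_mature_sequences: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mature_5p is None and self.mature_3p is None:
            raise ValueError(f"locus {self.locus_id}: at least one mature arm must be annotated")

    def mature_span(self, arm: str) -> GenomicSpan:
        span = self.mature_5p if arm == "5p" else self.mature_3p if arm == "3p" else None
        if span is None:
            raise KeyError(f"locus {self.locus_id}: arm {arm!r} not annotated")
        return span


@dataclass(frozen=True)
class IsomirRecord:
    """One sequenced isomiR with its genomic span and per-sample counts."""

    isomir_id: str
    locus_id: str
    arm: str
    span: GenomicSpan
    sequence: str
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seq = normalize_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if len(seq) != self.span.length:
            raise ValueError(
                f"isomiR {self.isomir_id}: sequence length {len(seq)} != span length {self.span.length}"
            )
        if not 16 <= len(seq) <= 28:
            raise ValueError(f"isomiR {self.isomir_id}: sequence length {len(seq)} outside [16, 28]")
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"isomiR {self.isomir_id}: arm must be 5p or 3p, got {self.arm!r}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError(f"isomiR {self.isomir_id}: negative count")


@dataclass(frozen=True)
class ShiftAnnotation:
    """Signed end offsets (nt) of an isomiR relative to the annotated mature.

    Offsets are in transcript orientation: ``offset5 > 0`` means the 5' end
    moved toward the 3' end (seed shifted downstream); ``offset3 > 0`` means
    the 3' end is extended.
    """

    offset5: int
    offset3: int


def classify_shift(isomir_span: GenomicSpan, annotated: GenomicSpan) -> ShiftAnnotation:
    """End-offset classification of an isomiR span against the annotated mature.

    On the plus strand the genomic start is the transcript 5' end; on the
    minus strand the genomic *end* is the transcript 5' end and the offsets
    are computed accordingly.
    """
    if isomir_span.chromosome != annotated.chromosome:
        raise ValueError(
            f"chromosome mismatch: {isomir_span.chromosome} vs {annotated.chromosome}"
        )
    if isomir_span.strand != annotated.strand:
        raise ValueError(f"strand mismatch: {isomir_span.strand} vs {annotated.strand}")
    if annotated.strand == "+":
        return ShiftAnnotation(
            offset5=isomir_span.start - annotated.start,
            offset3=isomir_span.end - annotated.end,
        )
    return ShiftAnnotation(
        offset5=annotated.end - isomir_span.end,
        offset3=annotated.start - isomir_span.start,
    )


def extract_seed(sequence: str) -> str:
    """Return the seed heptamer: nucleotides 2-8 (1-based) of a mature RNA."""
    seq = normalize_rna(sequence)
    if len(seq) < 8:
        raise ValueError(f"sequence too short for seed extraction: length {len(seq)} < 8")
    return seq[1:8]


def _shift_suffix(shift: int) -> str:
    return f"{shift:+d}"


@dataclass(frozen=True)
class SeedVariant:
    """A distinct (seed heptamer, 5' shift) pair observed at a locus/arm.

    IsomiRs that differ only at the 3' end share the annotated seed and hence
    the same variant.  ``label`` follows the locus+arm+signed-shift
    convention, e.g. ``"let-7-5p+1"``.
    """

    seed: str
    shift: int
    is_annotated: bool
    label: str
    base_label: str = ""
    isomir_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.seed) != 7:
            raise ValueError(f"seed must be 7 nt, got {len(self.seed)}")
        if abs(self.shift) > MAX_SEED_SHIFT:
            raise ValueError(f"|shift| > {MAX_SEED_SHIFT}: {self.shift}")
        if self.is_annotated != (self.shift == 0):
            raise ValueError("is_annotated must hold exactly when shift == 0")


@dataclass(frozen=True)
class SeedVariantEnumeration:
    variants: tuple[SeedVariant, ...]
    excluded: tuple[IsomirRecord, ...]  # |offset5| beyond the +-5 window


def enumerate_seed_variants(
    repertoire: Sequence[IsomirRecord],
    locus: MirnaLocus,
    base_label: str | None = None,
) -> SeedVariantEnumeration:
    """Enumerate distinct seed variants of a locus from its isomiR repertoire.

    Variant identity is the (seed string, 5' offset) pair; records whose
    |5' offset| exceeds the +-5 window are excluded and reported.  The label
    root defaults to ``family-arm`` (e.g. ``let-7-5p``).
    """
    groups: dict[tuple[str, str, int], list[IsomirRecord]] = defaultdict(list)
    excluded: list[IsomirRecord] = []
    for rec in repertoire:
        if rec.locus_id != locus.locus_id:
            raise ValueError(f"record {rec.isomir_id} belongs to locus {rec.locus_id}, not {locus.locus_id}")
        annotated = locus.mature_span(rec.arm)
        shift = classify_shift(rec.span, annotated).offset5
        if abs(shift) > MAX_SEED_SHIFT:
            excluded.append(rec)
            continue
        seed = extract_seed(rec.sequence)
        groups[(rec.arm, seed, shift)].append(rec)

    variants = []
    for (arm, seed, shift) in sorted(groups, key=lambda k: (k[0], k[2], k[1])):
        root = base_label if base_label is not None else f"{locus.family}-{arm}"
        variants.append(
            SeedVariant(
                seed=seed,
                shift=shift,
                is_annotated=(shift == 0),
                label=f"{root}{_shift_suffix(shift)}",
                base_label=root,
                isomir_ids=tuple(sorted(r.isomir_id for r in groups[(arm, seed, shift)])),
            )
        )
    return SeedVariantEnumeration(variants=tuple(variants), excluded=tuple(excluded))


def dedup_multicopy(
    records: Sequence[IsomirRecord], mode: str = "collapse"
) -> tuple[list[IsomirRecord], list[IsomirRecord]]:
    """Eliminate repeated isomiRs arising from multicopy/homologous pre-miRNAs.

    Records with an identical sequence but different loci either collapse to
    one representative (``mode="collapse"``, the copy with the
    lexicographically smallest locus_id) or are all removed
    (``mode="drop_all"``).  Returns ``(kept, dropped)``; the dropped list
    preserves provenance.
    """
    if mode not in ("collapse", "drop_all"):
        raise ValueError(f"unknown dedup mode: {mode!r}")
    by_seq: dict[str, list[IsomirRecord]] = defaultdict(list)
    for rec in records:
        by_seq[rec.sequence].append(rec)
    kept: list[IsomirRecord] = []
    dropped: list[IsomirRecord] = []
    for rec in records:
        group = by_seq[rec.sequence]
        loci = {r.locus_id for r in group}
        if len(loci) == 1:
            kept.append(rec)
        elif mode == "drop_all":
            dropped.append(rec)
        else:
            representative = min(group, key=lambda r: (r.locus_id, r.isomir_id))
            if rec is representative:
                kept.append(rec)
            else:
                dropped.append(rec)
    return kept, dropped


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position residue fractions of a set of aligned-at-5' sequences."""

    length: int
    freq: tuple[Mapping[str, float], ...]

    def __post_init__(self) -> None:
        for i, col in enumerate(self.freq):
            total = sum(col.values())
            if col and abs(total - 1.0) > 1e-9:
                raise ValueError(f"position {i + 1}: fractions sum to {total}, not 1")


def position_frequency_matrix(sequences: Iterable[str]) -> PositionFrequencyMatrix:
    """Tally per-position nucleotide fractions; ragged lengths allowed.

    The matrix spans the longest sequence; at each position only sequences
    long enough to cover it contribute to the denominator.
    """
    seqs = [normalize_rna(s) for s in sequences]
    if not seqs:
        raise ValueError("cannot build a frequency matrix from no sequences")
    length = max(len(s) for s in seqs)
    columns: list[Mapping[str, float]] = []
    for i in range(length):
        tally = Counter(s[i] for s in seqs if len(s) > i)
        n = sum(tally.values())
        columns.append({base: count / n for base, count in sorted(tally.items())})
    return PositionFrequencyMatrix(length=length, freq=tuple(columns))
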