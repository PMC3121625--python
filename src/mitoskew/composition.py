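"""Base tallies, strand skews, gene-class content and homopolymer censuses.

Skew conventions: AT-skew = (A-T)/(A+T), GC-skew = (G-C)/(G+C), both taken
on the main-coding strand.  A zero denominator yields NaN rather than an
exception so profile code can carry undefined points along.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from .genome_io import AnnotatedGenome, VALID_BASES, coverage_mask, extract_feature_seq

REGION_KINDS = ("whole", "third_codon_positions", "non_protein")


@dataclass(frozen=True)
class BaseCounts:
    a: int = 0
    c: int = 0
    g: int = 0
    t: int = 0
    n_other: int = 0

    @property
    def total(self) -> int:
        """A+C+G+T (Ns excluded from every ratio)."""
        return self.a + self.c + self.g + self.t

    def __add__(self, other: "BaseCounts") -> "BaseCounts":
        return BaseCounts(
            self.a + other.a, self.c + other.c, self.g + other.g,
            self.t + other.t, self.n_other + other.n_other,
        )

    def complement(self) -> "BaseCounts":
        return BaseCounts(a=self.t, c=self.g, g=self.c, t=self.a, n_other=self.n_other)


@dataclass(frozen=True)
class ContentSummary:
    """AT / GT content of one gene class, Table-style (percent + absolute count)."""

    region_label: str
    at_percent: float
    gt_percent: float
    at_count: int
    gt_count: int
    length: int


@dataclass(frozen=True)
class RunCensus:
    """Counts of maximal homopolymer runs of one base, keyed by run length (>=2)."""

    base: str
    counts: dict[int, int]

    @property
    def longest(self) -> int:
        return max(self.counts, default=0)


def base_counts(seq: str) -> BaseCounts:
    """Exact single-pass tallies; characters outside {A,C,G,T,N} are an error."""
    c = Counter(seq)
    bad = set(c) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return BaseCounts(a=c["A"], c=c["C"], g=c["G"], t=c["T"], n_other=c["N"])


def at_skew(counts: BaseCounts) -> float:
    """(A-T)/(A+T); NaN when A+T == 0."""
    denom = counts.a + counts.t
    return (counts.a - counts.t) / denom if denom else math.nan


def gc_skew(counts: BaseCounts) -> float:
    """(G-C)/(G+C); NaN when G+C == 0."""
    denom = counts.g + counts.c
    return (counts.g - counts.c) / denom if denom else math.nan


def region_counts(genome: AnnotatedGenome, region_kind: str) -> BaseCounts:
    """Base tallies over a named genome region.

    ``whole``: the full main strand.
    ``third_codon_positions``: third base of every complete codon pooled over
    all CDS in main-strand orientation (a trailing incomplete stop codon
    contributes nothing).
    ``non_protein``: every position not covered by any CDS, counted once.
    """
    if region_kind not in REGION_KINDS:
        raise ValueError(f"region_kind must be one of {REGION_KINDS}")
    if region_kind == "whole":
        return base_counts(genome.sequence)

    cds = genome.features_of_kind("CDS")
    if not cds:
        raise ValueError(f"genome {genome.id} has no CDS; {region_kind} undefined")
    if region_kind == "third_codon_positions":
        pooled = []
        for f in cds:
            seq = extract_feature_seq(genome, f)
            n_codons = len(seq) // 3
            pooled.append(seq[2 : 3 * n_codons : 3])
        return base_counts("".join(pooled))

    mask = coverage_mask(genome, kinds=("CDS",))
    seq = "".join(b for b, covered in zip(genome.sequence, mask) if not covered)
    return base_counts(seq)


def gene_class_content(genome: AnnotatedGenome, kind: str) -> ContentSummary:
    """AT/GT content over the concatenation of all genes of one kind.

    Genes are concatenated in main-strand orientation; a base shared by two
    overlapping genes is counted in both (per-gene concatenation, unlike the
    position-pooled :func:`region_counts`).
    """
    feats = genome.features_of_kind(kind)
    if not feats:
        raise ValueError(f"genome {genome.id} has no features of kind {kind!r}")
    concat = "".join(extract_feature_seq(genome, f) for f in feats)
    counts = base_counts(concat)
    at = counts.a + counts.t
    gt = counts.g + counts.t
    length = len(concat)
    return ContentSummary(
        region_label=kind,
        at_percent=100.0 * at / length,
        gt_percent=100.0 * gt / length,
        at_count=at,
        gt_count=gt,
        length=length,
    )


def homopolymer_runs(
    seq: str, base: str, circular: bool = True, min_length: int = 2
) -> RunCensus:
    """Census of maximal runs of ``base``.

    A run of exact length L is counted only at L.  With ``circular`` a run
    spanning the origin is joined; a sequence consisting entirely of the base
    is one run of the full length.
    """
    if not seq:
        raise ValueError("empty sequence")
    if base not in "ACGT":
        raise ValueError(f"base must be one of A/C/G/T, got {base!r}")
    runs: list[int] = []
    current = 0
    for ch in seq:
        if ch == base:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)

    if runs and runs[0] == len(seq):
        pass  # uniform sequence: one circular run, leave as-is
    elif circular and len(runs) >= 2 and seq[0] == base and seq[-1] == base:
        first = runs.pop(0)
        runs[-1] += first
    counts = Counter(r for r in runs if r >= min_length)
    return RunCensus(base=base, counts=dict(sorted(counts.items())))


def composition_report_rows(genome: AnnotatedGenome) -> list[dict]:
    """Uniform per-region rows (counts, percents, skews) for TSV export."""
    rows = []
    regions: list[tuple[str, BaseCounts]] = [("whole", region_counts(genome, "whole"))]
    if genome.features_of_kind("CDS"):
        regions.append(("third_codon_positions", region_counts(genome, "third_codon_positions")))
        regions.append(("non_protein", region_counts(genome, "non_protein")))
    for label, counts in regions:
        total = counts.total or 1
        rows.append(
            {
                "genome": genome.id,
                "region": label,
                "a": counts.a,
                "c": counts.c,
                "g": counts.g,
                "t": counts.t,
                "n": counts.n_other,
                "at_percent": round(100.0 * (counts.a + counts.t) / total, 1),
                "gt_percent": round(100.0 * (counts.g + counts.t) / total, 1),
                "at_skew": at_skew(counts),
                "gc_skew": gc_skew(counts),
            }
        )
    return rows
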