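"""Conservation-based genetic-code assignment from reference protein alignments.

For every codon of every target CDS, the aligned reference column is graded
into one of four conservation degrees by its majority amino-acid fraction
(defaults 0.9 / 0.7 / 0.5 for highly conserved / conserved / weakly
conserved; below that, variable).  Per codon, amino-acid frequencies are
tallied within each degree; the call is the majority amino acid at the
most-conserved non-empty degree, provided its fraction clears the call
threshold.  Unresolved codons may fall back to the complement of an
annotated tRNA anticodon or to a donor code, each fallback flagged.

Reference alignments are inputs (aligned FASTA, one per gene, containing a
row for the target); the alignment step itself is out of scope.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

from Bio import SeqIO

from .codon_code import (
    ALL_CODONS,
    GeneticCode,
    reverse_complement_rna,
    rna,
)
from .genome_io import AnnotatedGenome, extract_feature_seq

GAP = "-"
DEGREES = ("highly_conserved", "conserved", "weakly_conserved", "variable")


@dataclass(frozen=True)
class Thresholds:
    high: float = 0.9
    mid: float = 0.7
    low: float = 0.5
    call: float = 0.45

    def __post_init__(self) -> None:
        if not 1.0 >= self.high >= self.mid >= self.low >= 0.0:
            raise ValueError("need 1 >= high >= mid >= low >= 0")
        if not 0.0 <= self.call <= 1.0:
            raise ValueError("call threshold must be in [0, 1]")


@dataclass
class ReferenceAlignment:
    """Aligned amino-acid rows for one gene; the target row is named."""

    gene: str
    rows: dict[str, str]
    target_row: str = "target"

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene}: unequal alignment row lengths {lengths}")
        if self.target_row not in self.rows:
            raise KeyError(f"{self.gene}: no row named {self.target_row!r}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def reference_column(self, i: int) -> str:
        """Column i over the non-target rows, gaps removed."""
        return "".join(
            row[i] for name, row in self.rows.items() if name != self.target_row
        ).replace(GAP, "")


def read_alignment_fasta(path, gene: str, target_row: str = "target") -> ReferenceAlignment:
    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not rows:
        raise ValueError(f"no sequences in {path}")
    return ReferenceAlignment(gene=gene, rows=rows, target_row=target_row)


def map_codon_sites(
    target_cds: str, target_aa: str, alignment: ReferenceAlignment
) -> list[int | None]:
    """Map each target codon to its alignment column (None at target gaps).

    ``target_aa`` is the aligned target row (with gaps); ``target_cds`` is the
    nucleotide CDS whose complete codons must match the row's residue count
    (a terminal stop codon, complete or not, is allowed to be absent from the
    protein row).
    """
    ungapped = target_aa.replace(GAP, "")
    n_codons = len(target_cds) // 3
    if n_codons not in (len(ungapped), len(ungapped) + 1):
        raise ValueError(
            f"frameshift: CDS has {n_codons} codons but aligned row has "
            f"{len(ungapped)} residues"
        )
    columns: list[int | None] = []
    residue = 0
    col_of_residue = [i for i, ch in enumerate(target_aa) if ch != GAP]
    for i in range(n_codons):
        if i < len(col_of_residue):
            columns.append(col_of_residue[i])
        else:
            columns.append(None)    # terminal stop codon: no protein column
        residue += 1
    return columns


def grade_column(column: str, thresholds: Thresholds = Thresholds()) -> str:
    """Conservation degree of one gap-free reference column."""
    if not column:
        raise ValueError("all-gap column cannot be graded")
    counts = Counter(column)
    f = max(counts.values()) / len(column)
    if f >= thresholds.high:
        return "highly_conserved"
    if f >= thresholds.mid:
        return "conserved"
    if f >= thresholds.low:
        return "weakly_conserved"
    return "variable"


@dataclass
class ConservationTally:
    """Per-codon amino-acid frequencies stratified by conservation degree."""

    codon: str
    degree_counts: dict[str, Counter] = field(
        default_factory=lambda: {d: Counter() for d in DEGREES}
    )

    def add_site(self, degree: str, column: str) -> None:
        self.degree_counts[degree].update(column)

    def n_sites(self) -> int:
        return sum(sum(c.values()) for c in self.degree_counts.values())

    def majority(self, degree: str) -> tuple[str | None, float]:
        counts = self.degree_counts[degree]
        total = sum(counts.values())
        if total == 0:
            return None, 0.0
        best = counts.most_common()
        top_count = best[0][1]
        leaders = sorted(aa for aa, n in best if n == top_count)
        if len(leaders) > 1:
            return None, top_count / total    # tie: no majority call
        return leaders[0], top_count / total


@dataclass(frozen=True)
class AssignmentCall:
    codon: str
    amino_acid: str | None      # None => ambiguous or absent
    status: str                 # called | ambiguous | absent | fallback
    support: float = 0.0
    degree: str | None = None
    fallback_source: str | None = None


def call_assignment(
    tally: ConservationTally,
    thresholds: Thresholds = Thresholds(),
) -> AssignmentCall:
    """Call from the most-conserved non-empty degree; ambiguous below threshold.

    Ties between equally frequent amino acids are ambiguous, never broken
    arbitrarily.
    """
    if tally.n_sites() == 0:
        return AssignmentCall(tally.codon, None, "absent")
    for degree in DEGREES:
        aa, support = tally.majority(degree)
        if sum(tally.degree_counts[degree].values()) == 0:
            continue
        if aa is not None and support >= thresholds.call:
            return AssignmentCall(tally.codon, aa, "called", support, degree)
        return AssignmentCall(tally.codon, None, "ambiguous", support, degree)
    return AssignmentCall(tally.codon, None, "absent")


def tally_codon_conservation(
    genome: AnnotatedGenome,
    alignments: dict[str, ReferenceAlignment],
    thresholds: Thresholds = Thresholds(),
) -> dict[str, ConservationTally]:
    """Accumulate conservation tallies for all 64 codons over all CDS."""
    tallies = {c: ConservationTally(c) for c in ALL_CODONS}
    for feature in genome.features_of_kind("CDS"):
        aln = alignments.get(feature.name)
        if aln is None:
            warnings.warn(f"no reference alignment for {feature.name}; gene skipped")
            continue
        cds = rna(extract_feature_seq(genome, feature))
        target_row = aln.rows[aln.target_row]
        columns = map_codon_sites(cds, target_row, aln)
        for i, col_idx in enumerate(columns):
            if col_idx is None:
                continue
            codon = cds[3 * i : 3 * i + 3]
            if len(codon) < 3 or "N" in codon:
                continue
            column = aln.reference_column(col_idx)
            if not column:
                continue    # all-gap reference column: excluded
            degree = grade_column(column, thresholds)
            tallies[codon].add_site(degree, column)
    return tallies


def infer_code(
    genome: AnnotatedGenome,
    alignments: dict[str, ReferenceAlignment],
    thresholds: Thresholds = Thresholds(),
    base_code: GeneticCode | None = None,
    anticodon_fallback: bool = True,
) -> tuple[GeneticCode, list[AssignmentCall]]:
    """Assemble a full 64-codon genetic code from conservation evidence.

    Codons that cannot be called inherit, in order: the complement of an
    annotated tRNA anticodon targeting them, then the ``base_code``
    assignment.  Every fallback is flagged in the returned call list.
    """
    from .codon_code import get_code

    if base_code is None:
        base_code = get_code("invertebrate")
    tallies = tally_codon_conservation(genome, alignments, thresholds)
    calls = [call_assignment(tallies[c], thresholds) for c in ALL_CODONS]

    anticodon_aa: dict[str, str] = {}
    if anticodon_fallback:
        for f in genome.features_of_kind("tRNA"):
            if f.anticodon is None:
                continue
            codon = reverse_complement_rna(f.anticodon)
            from .codon_code import AA_ONE_TO_THREE

            aa = f.name[3:4] if f.name.startswith("trn") else ""
            if aa in AA_ONE_TO_THREE and aa != "*":
                anticodon_aa[codon] = aa

    table: dict[str, str] = {}
    final_calls: list[AssignmentCall] = []
    for call in calls:
        if call.status == "called":
            table[call.codon] = call.amino_acid
            final_calls.append(call)
            continue
        if call.codon in anticodon_aa:
            aa = anticodon_aa[call.codon]
            table[call.codon] = aa
            final_calls.append(
                replace(call, amino_acid=aa, status="fallback", fallback_source="anticodon")
            )
            continue
        aa = base_code.table[call.codon]
        table[call.codon] = aa
        final_calls.append(
            replace(call, amino_acid=aa, status="fallback",
                    fallback_source=f"base_code:{base_code.id}")
        )
    inferred = GeneticCode(
        id=f"inferred_from_{genome.id}", table=table, start_codons=base_code.start_codons
    )
    return inferred, final_calls


def calls_to_tsv(calls: list[AssignmentCall]) -> str:
    lines = ["codon\tamino_acid\tstatus\tsupport\tdegree\tfallback_source"]
    for c in calls:
        lines.append(
            f"{c.codon}\t{c.amino_acid or 'NA'}\t{c.status}\t{c.support:.3f}"
            f"\t{c.degree or 'NA'}\t{c.fallback_source or 'NA'}"
        )
    return "\n".join(lines) + "\n"
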