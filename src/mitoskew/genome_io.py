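"""Reading, validating and slicing annotated circular mitochondrial genomes.

Coordinates are 0-based half-open internally; GenBank I/O converts to and
from the flat file's 1-based inclusive convention.  A feature interval may
wrap the circle origin, in which case ``end > len(genome)`` and positions
are taken modulo the genome length.

The "main-coding strand" is the strand carrying the majority of CDS
nucleotides (all 13 in a typical deuterostome mitogenome).  ``read_genbank``
re-orients the record so that ``genome.sequence`` *is* the main strand;
every downstream statistic is therefore a main-strand statistic unless a
feature is explicitly on the opposite strand.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: canonical symbols for the 13 mitochondrial protein-coding genes
CDS_NAMES = (
    "COX1", "COX2", "COX3", "ND1", "ND2", "ND3", "ND4", "ND4L",
    "ND5", "ND6", "ATP6", "ATP8", "CYTB",
)

_GENE_SYNONYMS = {
    "COI": "COX1", "CO1": "COX1", "COXI": "COX1",
    "COII": "COX2", "CO2": "COX2", "COXII": "COX2",
    "COIII": "COX3", "CO3": "COX3", "COXIII": "COX3",
    "NAD1": "ND1", "NAD2": "ND2", "NAD3": "ND3", "NAD4": "ND4",
    "NAD4L": "ND4L", "NAD5": "ND5", "NAD6": "ND6",
    "NADH1": "ND1", "NADH2": "ND2", "NADH3": "ND3", "NADH4": "ND4",
    "NADH4L": "ND4L", "NADH5": "ND5", "NADH6": "ND6",
    "COB": "CYTB", "CYB": "CYTB", "CYTOCHROMEB": "CYTB",
    "ATPASE6": "ATP6", "ATPASE8": "ATP8", "ATP-6": "ATP6", "ATP-8": "ATP8",
    "12S": "rrnS", "12SRRNA": "rrnS", "RRNS": "rrnS", "SRRNA": "rrnS",
    "S-RRNA": "rrnS", "SSU": "rrnS", "12SRIBOSOMALRNA": "rrnS",
    "16S": "rrnL", "16SRRNA": "rrnL", "RRNL": "rrnL", "LRRNA": "rrnL",
    "L-RRNA": "rrnL", "LSU": "rrnL", "16SRIBOSOMALRNA": "rrnL",
}

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class GenomeParseError(ValueError):
    """Raised when a GenBank/FASTA record cannot be mapped onto the model."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """Half-open interval on a circular sequence.

    ``wraps`` means the interval crosses the origin; then ``end`` exceeds
    the genome length and positions are interpreted modulo the length.
    """

    start: int
    end: int
    wraps: bool = False

    def __len__(self) -> int:
        return self.end - self.start

    def positions(self, genome_length: int):
        """Yield the covered positions in 5'->3' order (mod genome length)."""
        for p in range(self.start, self.end):
            yield p % genome_length


@dataclass
class GeneFeature:
    """One annotated gene: a named, typed, stranded set of intervals."""

    name: str
    kind: str                       # CDS | tRNA | rRNA
    strand: str                     # main | opposite
    intervals: list[Interval]
    frame_offset: int = 0           # bases to skip before the first codon
    anticodon: str | None = None    # RNA 5'->3', tRNA features only

    def __post_init__(self) -> None:
        if self.kind not in ("CDS", "tRNA", "rRNA"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("main", "opposite"):
            raise ValueError(f"strand must be 'main' or 'opposite', got {self.strand!r}")
        if not 0 <= self.frame_offset <= 2:
            raise ValueError("frame_offset must be 0, 1 or 2")

    @property
    def spliced_length(self) -> int:
        return sum(len(iv) for iv in self.intervals) - self.frame_offset

    @property
    def incomplete_stop(self) -> bool:
        return self.kind == "CDS" and self.spliced_length % 3 != 0

    @property
    def start(self) -> int:
        return self.intervals[0].start


@dataclass
class AnnotatedGenome:
    """A circular (or linear) nucleotide sequence plus its gene features."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    reoriented: bool = False    # True if the record was flipped onto the main strand

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeParseError("empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise GenomeParseError(
                f"sequence contains characters outside A/C/G/T/N: {sorted(bad)}"
            )
        seen = set()
        for f in self.features:
            key = (f.name, f.kind)
            if key in seen:
                raise GenomeParseError(f"duplicate feature {key}")
            seen.add(key)
            for iv in f.intervals:
                if not 0 <= iv.start < len(self.sequence):
                    raise GenomeParseError(f"feature {f.name}: start {iv.start} outside genome")
                limit = 2 * len(self.sequence) if iv.wraps else len(self.sequence)
                if not iv.start < iv.end <= limit:
                    raise GenomeParseError(f"feature {f.name}: bad interval {iv}")
                if iv.wraps and not self.circular:
                    raise GenomeParseError(f"feature {f.name} wraps a linear genome")

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, kind: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == kind]

    def get_feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


@dataclass(frozen=True)
class UASRegion:
    """A maximal unassigned (feature-free) region with its flanking genes."""

    interval: Interval
    left_gene: str
    right_gene: str

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class UASReport:
    regions: list[UASRegion]
    fraction: float

    @property
    def longest(self) -> UASRegion | None:
        return max(self.regions, key=lambda r: r.length, default=None)


# ---------------------------------------------------------------------------
# parsing helpers


def canonical_gene_name(raw: str) -> str:
    """Normalize a /gene or /product string to the canonical symbol."""
    token = re.sub(r"[\s_]+", "", raw).upper()
    token = _GENE_SYNONYMS.get(token, token)
    if token in CDS_NAMES or token in ("rrnS", "rrnL"):
        return token
    if token == "RRNS":
        return "rrnS"
    if token == "RRNL":
        return "rrnL"
    # full product names, e.g. "cytochrome c oxidase subunit III"
    m = re.match(r"^CYTOCHROME[CO]*OXIDASE(?:SUBUNIT)?(III|II|I|3|2|1)$", token)
    if m:
        return "COX" + {"I": "1", "II": "2", "III": "3"}.get(m.group(1), m.group(1))
    m = re.match(r"^NADH?DEHYDROGENASE(?:SUBUNIT)?(4L|[1-6])$", token)
    if m:
        return "ND" + m.group(1)
    if re.match(r"^ATP(?:ASE|SYNTHASE)?(?:F0)?(?:SUBUNIT)?6$", token):
        return "ATP6"
    if re.match(r"^ATP(?:ASE|SYNTHASE)?(?:F0)?(?:SUBUNIT)?8$", token):
        return "ATP8"
    if re.match(r"^(12S|SMALL(SUBUNIT)?)RIBOSOMALRNA$", token):
        return "rrnS"
    if re.match(r"^(16S|LARGE(SUBUNIT)?)RIBOSOMALRNA$", token):
        return "rrnL"
    m = re.match(r"^TRN([A-Z])([0-9]?)$", token)
    if m:
        return "trn" + m.group(1) + m.group(2)
    m = re.match(r"^TRNA-?([A-Z]{3})([0-9]?)", token)
    if m and m.group(1) in _AA3_TO_1:
        return "trn" + _AA3_TO_1[m.group(1)] + m.group(2)
    return raw.strip()


def _location_to_intervals(location, genome_length: int, circular: bool) -> list[Interval]:
    parts = list(location.parts)
    if location.strand == -1:
        # Biopython lists complement-join parts in transcript order; we keep
        # genome order here and re-orient at extraction time.
        parts = parts[::-1]
    intervals = [Interval(int(p.start), int(p.end)) for p in parts]
    # merge a two-part origin-spanning join into one wrapping interval
    merged: list[Interval] = []
    for iv in intervals:
        if (
            merged
            and circular
            and merged[-1].end == genome_length
            and iv.start == 0
            and not merged[-1].wraps
        ):
            prev = merged.pop()
            merged.append(Interval(prev.start, genome_length + iv.end, wraps=True))
        else:
            merged.append(iv)
    return merged


def _parse_anticodon(qualifiers) -> str | None:
    for key in ("anticodon", "note", "product"):
        for value in qualifiers.get(key, []):
            m = re.search(r"(?:anticodon[:\s]*|seq:)\s*([ACGUTacgut]{3})\b", value)
            if m:
                return m.group(1).upper().replace("T", "U")
    return None


def _unique_name(name: str, taken: set[str]) -> str:
    if name not in taken:
        return name
    i = 1
    while f"{name}{i}" in taken:
        i += 1
    return f"{name}{i}"


def read_genbank(path, main_strand: str = "auto") -> AnnotatedGenome:
    """Parse a single-record GenBank flat file into an :class:`AnnotatedGenome`.

    Parameters
    ----------
    path : str or Path
        GenBank flat file containing exactly one record.
    main_strand : {"auto", "plus", "minus"}
        Which record strand is the main-coding strand.  ``auto`` picks the
        strand carrying the majority of CDS nucleotides.  If the main strand
        is the record's minus strand the genome is reverse-complemented so
        that ``sequence`` is the main strand (``reoriented`` is set).
    """
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise GenomeParseError(f"malformed GenBank file {path}: {exc}") from exc
    if len(records) != 1:
        raise GenomeParseError(f"expected exactly one record in {path}, found {len(records)}")
    record = records[0]
    sequence = str(record.seq).upper()
    circular = record.annotations.get("topology", "circular") == "circular"
    genome_length = len(sequence)

    features: list[GeneFeature] = []
    taken: set[str] = set()
    raw_strands: dict[int, str] = {}
    for idx, feat in enumerate(record.features):
        if feat.type not in ("CDS", "tRNA", "rRNA"):
            continue
        quals = feat.qualifiers
        raw_name = (quals.get("gene") or quals.get("product") or [feat.type])[0]
        name = _unique_name(canonical_gene_name(raw_name), taken)
        taken.add(name)
        frame_offset = int(quals.get("codon_start", ["1"])[0]) - 1
        anticodon = _parse_anticodon(quals) if feat.type == "tRNA" else None
        raw_strands[len(features)] = "-" if feat.location.strand == -1 else "+"
        features.append(
            GeneFeature(
                name=name,
                kind=feat.type,
                strand="main",  # provisional; fixed below
                intervals=_location_to_intervals(feat.location, genome_length, circular),
                frame_offset=frame_offset,
                anticodon=anticodon,
            )
        )
    if not features:
        warnings.warn(f"no gene features found in {path}")

    main = _resolve_main_strand(features, raw_strands, main_strand)
    # strand relative to the record's plus strand; flip_strand below swaps
    # main/opposite again when the minus strand is the main-coding one
    for i, f in enumerate(features):
        f.strand = "main" if raw_strands[i] == "+" else "opposite"

    genome = AnnotatedGenome(
        id=record.id or record.name, sequence=sequence, circular=circular, features=features
    )
    if main == "-":
        genome = flip_strand(genome)
        genome.reoriented = True
    return genome


def _resolve_main_strand(features, raw_strands, main_strand: str) -> str:
    if main_strand in ("plus", "+"):
        return "+"
    if main_strand in ("minus", "-"):
        return "-"
    if main_strand != "auto":
        raise ValueError(f"main_strand must be auto/plus/minus, got {main_strand!r}")
    plus = minus = 0
    for i, f in enumerate(features):
        if f.kind != "CDS":
            continue
        n = sum(len(iv) for iv in f.intervals)
        if raw_strands[i] == "+":
            plus += n
        else:
            minus += n
    return "-" if minus > plus else "+"


def flip_strand(genome: AnnotatedGenome) -> AnnotatedGenome:
    """Reverse-complement the genome, remapping all features."""
    length = len(genome)
    new_features = []
    for f in genome.features:
        ivs = []
        for iv in reversed(f.intervals):
            if iv.wraps:
                # [s, L) + [0, e-L)  ->  [2L-e, L) + [0, L-s)
                ivs.append(Interval(2 * length - iv.end, 2 * length - iv.start, wraps=True))
            else:
                ivs.append(Interval(length - iv.end, length - iv.start))
        new_features.append(
            replace(
                f,
                strand="opposite" if f.strand == "main" else "main",
                intervals=ivs,
            )
        )
    return AnnotatedGenome(
        id=genome.id,
        sequence=reverse_complement(genome.sequence),
        circular=genome.circular,
        features=new_features,
        reoriented=not genome.reoriented,
    )


def read_fasta(path, genome_id: str | None = None, circular: bool = True) -> AnnotatedGenome:
    """Read a single-sequence FASTA file as an unannotated genome."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise GenomeParseError(f"expected exactly one FASTA record in {path}")
    rec = records[0]
    return AnnotatedGenome(
        id=genome_id or rec.id, sequence=str(rec.seq).upper(), circular=circular
    )


def write_genbank(genome: AnnotatedGenome, path) -> None:
    """Serialize back to a single-record GenBank flat file."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id.split(".")[0][:16],
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
        },
    )
    length = len(genome)
    for f in genome.features:
        strand = 1 if f.strand == "main" else -1
        locs = []
        for iv in f.intervals:
            if iv.wraps:
                locs.append(SimpleLocation(iv.start, length, strand))
                locs.append(SimpleLocation(0, iv.end - length, strand))
            else:
                locs.append(SimpleLocation(iv.start, iv.end, strand))
        if strand == -1:
            locs = locs[::-1]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [f.name]}
        if f.kind == "CDS":
            quals["codon_start"] = [str(f.frame_offset + 1)]
        if f.anticodon is not None:
            quals["note"] = [f"anticodon:{f.anticodon}"]
        record.features.append(SeqFeature(location, type=f.kind, qualifiers=quals))
    SeqIO.write([record], str(path), "genbank")


# ---------------------------------------------------------------------------
# sequence extraction


def extract_feature_seq(genome: AnnotatedGenome, feature: GeneFeature) -> str:
    """Spliced, strand-oriented, frame-corrected sequence of a feature."""
    length = len(genome)
    pieces = []
    for iv in feature.intervals:
        if iv.wraps:
            pieces.append(genome.sequence[iv.start:] + genome.sequence[: iv.end - length])
        else:
            if iv.end > length:
                raise ValueError(f"interval {iv} outside genome of length {length}")
            pieces.append(genome.sequence[iv.start:iv.end])
    seq = "".join(pieces)
    if feature.strand == "opposite":
        seq = reverse_complement(seq)
    return seq[feature.frame_offset:]


def coverage_mask(genome: AnnotatedGenome, kinds: tuple[str, ...] | None = None) -> np.ndarray:
    """Boolean array: position covered by >=1 feature (of the given kinds)."""
    mask = np.zeros(len(genome), dtype=bool)
    for f in genome.features:
        if kinds is not None and f.kind not in kinds:
            continue
        for iv in f.intervals:
            if iv.wraps:
                mask[iv.start:] = True
                mask[: iv.end - len(genome)] = True
            else:
                mask[iv.start:iv.end] = True
    return mask


def unassigned_regions(genome: AnnotatedGenome) -> UASReport:
    """Maximal feature-free intervals (circular complement of the feature union).

    Overlapping features on either strand are merged before taking the
    complement, so the reported fraction counts every position once.
    """
    if not genome.features:
        raise ValueError("genome has no features; UAS census is undefined")
    mask = coverage_mask(genome)
    length = len(genome)
    uncovered = ~mask
    if not uncovered.any():
        return UASReport(regions=[], fraction=0.0)
    if uncovered.all():
        raise ValueError("no position is covered by any feature")

    # walk runs of uncovered positions, joining across the origin when circular
    edges = np.flatnonzero(np.diff(uncovered.astype(np.int8)))
    starts = [int(e) + 1 for e in edges if not uncovered[e]]
    ends = [int(e) + 1 for e in edges if uncovered[e]]
    if uncovered[0]:
        starts.insert(0, 0)
    if uncovered[-1]:
        ends.append(length)
    runs = list(zip(starts, ends))
    if genome.circular and uncovered[0] and uncovered[-1] and len(runs) > 1:
        (s_last, _), (_, e_first) = runs[-1], runs[0]
        runs = runs[1:-1] + [(s_last, length + e_first)]

    regions = []
    for s, e in sorted(runs):
        iv = Interval(s, e, wraps=e > length)
        left = _nearest_feature(genome, s, side="left")
        right = _nearest_feature(genome, e % length if e > length else e, side="right")
        regions.append(UASRegion(iv, left, right))
    fraction = float(uncovered.sum()) / length
    return UASReport(regions=regions, fraction=fraction)


def _nearest_feature(genome: AnnotatedGenome, pos: int, side: str) -> str:
    """Name of the feature whose boundary is closest to ``pos`` on the given side."""
    length = len(genome)
    best_name, best_dist = "", length + 1
    for f in genome.features:
        for iv in f.intervals:
            end = iv.end % length if iv.wraps else iv.end
            if side == "left":
                d = (pos - end) % length
            else:
                d = (iv.start - pos) % length
            if d < best_dist:
                best_dist, best_name = d, f.name
    return best_name


# ---------------------------------------------------------------------------
# reports


def uas_to_bed(report: UASReport, genome: AnnotatedGenome) -> str:
    """UAS census as BED text (0-based half-open; wrapped regions split in two)."""
    lines = []
    length = len(genome)
    for r in report.regions:
        name = f"UAS|{r.left_gene}|{r.right_gene}"
        iv = r.interval
        if iv.wraps:
            lines.append(f"{genome.id}\t{iv.start}\t{length}\t{name}")
            lines.append(f"{genome.id}\t0\t{iv.end - length}\t{name}")
        else:
            lines.append(f"{genome.id}\t{iv.start}\t{iv.end}\t{name}")
    return "\n".join(lines) + ("\n" if lines else "")


def uas_to_tsv(report: UASReport, genome: AnnotatedGenome) -> str:
    header = "genome\tstart\tend\tlength\tleft_gene\tright_gene\tfraction_total"
    lines = [header]
    for r in report.regions:
        lines.append(
            f"{genome.id}\t{r.interval.start}\t{r.interval.end}\t{r.length}"
            f"\t{r.left_gene}\t{r.right_gene}\t{report.fraction:.6f}"
        )
    return "\n".join(lines) + "\n"
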