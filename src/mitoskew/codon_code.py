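"""Codon usage, amino-acid composition and anticodon-versatility analysis.

Codon and anticodon space uses the RNA alphabet (U); genome space uses DNA
(T); conversion happens at this module's boundary.

Codon families are wobble families under the genetic code in force: each of
the 16 first-two-base boxes is one four-fold family when all four sense
codons encode the same amino acid, and otherwise splits into its pyrimidine
(NNY) and purine (NNR) halves, grouped further by amino acid.  A "versatile"
anticodon is the one expected to pair acceptably with every codon of its
family: GNN for pyrimidine-ending families (including Y+A three-codon
families, whose A-ending codon is tolerated by other mechanisms), UNN for
purine-ending and four-fold families.  The deviation count of an anticodon
set is the number of families whose cognate tRNA departs from that scheme
(adapted or otherwise deviant anticodon, or no cognate tRNA at all).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Data import CodonTable as _BioCodonTable

from .genome_io import AnnotatedGenome, extract_feature_seq

RNA_BASES = "UCAG"
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")

AA_ONE_TO_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}
AA_THREE_TO_ONE = {v: k for k, v in AA_ONE_TO_THREE.items()}

ALL_CODONS = tuple(a + b + c for a in RNA_BASES for b in RNA_BASES for c in RNA_BASES)


def rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def reverse_complement_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-codon translation table (stops as '*')."""

    id: str
    table: dict[str, str]
    start_codons: frozenset[str] = frozenset({"AUG", "GUG"})

    def __post_init__(self) -> None:
        if set(self.table) != set(ALL_CODONS):
            raise ValueError("genetic code must map exactly the 64 RNA codons")
        if "*" not in self.table.values():
            raise ValueError("genetic code must have at least one stop codon")

    def translate(self, codon: str) -> str:
        return self.table[rna(codon)]

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.table[c] == "*")

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.table[c] != "*")

    def codons_for(self, amino_acid: str) -> tuple[str, ...]:
        aa = AA_THREE_TO_ONE.get(amino_acid, amino_acid)
        found = tuple(c for c in ALL_CODONS if self.table[c] == aa)
        if not found:
            raise ValueError(f"amino acid {amino_acid!r} not encoded by code {self.id}")
        return found

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted({aa for aa in self.table.values() if aa != "*"}))


def _from_ncbi(table_id: int, label: str) -> GeneticCode:
    bio = _BioCodonTable.unambiguous_rna_by_id[table_id]
    table = {c: bio.forward_table.get(c, "*") for c in ALL_CODONS}
    return GeneticCode(id=label, table=table, start_codons=frozenset(bio.start_codons))


def _pterobranch_code() -> GeneticCode:
    """The pterobranch variant: invertebrate-mito base with AUA->Ile, AGG->Lys."""
    base = _from_ncbi(5, "invertebrate")
    table = dict(base.table)
    table["AUA"] = "I"
    table["AGG"] = "K"
    return GeneticCode(id="rhabdopleura", table=table, start_codons=frozenset({"AUG", "GUG"}))


_CODES: dict[str, GeneticCode] = {}


def get_code(name: str | int) -> GeneticCode:
    """Look up a built-in genetic code by NCBI table number or label."""
    if not _CODES:
        for tid, label in ((2, "vertebrate"), (5, "invertebrate"), (9, "echinoderm"), (13, "ascidian")):
            code = _from_ncbi(tid, label)
            _CODES[str(tid)] = code
            _CODES[label] = code
        ptero = _pterobranch_code()
        _CODES["rhabdopleura"] = ptero
        _CODES["pterobranch"] = ptero
    key = str(name).lower()
    if key not in _CODES:
        raise KeyError(f"unknown genetic code {name!r}; known: {sorted(_CODES)}")
    return _CODES[key]


def load_code(path, label: str | None = None) -> GeneticCode:
    """Read a code from a simple text table: one '<codon><TAB><aa>' row per codon.

    Amino acids may be 1- or 3-letter; stops as '*' or 'Ter'.  Lines starting
    with '#' are comments; an optional 'starts:<codons,...>' line sets starts.
    """
    table: dict[str, str] = {}
    starts: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.lower().startswith("starts:"):
                starts = {rna(c.strip()) for c in line.split(":", 1)[1].split(",")}
                continue
            codon, aa = line.split()[:2]
            table[rna(codon)] = AA_THREE_TO_ONE.get(aa, aa)
    return GeneticCode(
        id=label or str(path),
        table=table,
        start_codons=frozenset(starts) if starts else frozenset({"AUG", "GUG"}),
    )


# ---------------------------------------------------------------------------
# codon usage


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    code: GeneticCode
    source_genes: list[str] = field(default_factory=list)
    incomplete_tails: int = 0   # CDS ending in a 1-2 base incomplete stop

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, codon: str) -> int:
        return self.counts.get(rna(codon), 0)


def codon_usage(genome: AnnotatedGenome, code: GeneticCode | str | int) -> CodonUsageTable:
    """Tally every complete in-frame codon (stops included) over all CDS.

    A trailing incomplete stop (spliced length not divisible by 3) is
    excluded from the counts and tallied separately.  Internal stop codons
    trigger a warning but are counted.
    """
    if isinstance(code, (str, int)):
        code = get_code(code)
    cds = genome.features_of_kind("CDS")
    if not cds:
        raise ValueError(f"genome {genome.id} has no CDS")
    counts = {c: 0 for c in ALL_CODONS}
    incomplete = 0
    genes = []
    for f in cds:
        seq = rna(extract_feature_seq(genome, f))
        n_codons = len(seq) // 3
        if len(seq) % 3:
            incomplete += 1
        codons = [seq[3 * i : 3 * i + 3] for i in range(n_codons)]
        for i, codon in enumerate(codons):
            if "N" in codon:
                continue
            counts[codon] += 1
            if code.table[codon] == "*" and i < n_codons - 1:
                warnings.warn(f"internal stop codon {codon} in {f.name} (position {i})")
        genes.append(f.name)
    return CodonUsageTable(counts=counts, code=code, source_genes=genes, incomplete_tails=incomplete)


def aa_composition(usage: CodonUsageTable) -> dict[str, float]:
    """Amino-acid frequencies over non-stop codons, normalized to sum 1."""
    totals: dict[str, float] = {}
    n = 0
    for codon, count in usage.counts.items():
        aa = usage.code.table[codon]
        if aa == "*":
            continue
        totals[aa] = totals.get(aa, 0) + count
        n += count
    if n == 0:
        raise ValueError("usage contains no non-stop codons")
    return {aa: c / n for aa, c in sorted(totals.items())}


def is_gt_rich(codon: str) -> bool:
    """>=2 of 3 positions in {G, U}."""
    return sum(b in "GU" for b in rna(codon)) >= 2


def classify_codon_strandedness(amino_acid: str, code: GeneticCode) -> str:
    """GT_exclusive / AC_exclusive / mixed, from the amino acid's codon set.

    A codon is GT-rich iff at least two of its three bases are G or U, and
    AC-rich otherwise (the two labels partition the 64 codons).
    """
    codons = code.codons_for(amino_acid)
    rich = [is_gt_rich(c) for c in codons]
    if all(rich):
        return "GT_exclusive"
    if not any(rich):
        return "AC_exclusive"
    return "mixed"


# ---------------------------------------------------------------------------
# codon families and anticodons


@dataclass(frozen=True)
class CodonFamily:
    """Synonymous codons sharing a first-two-base box under a code."""

    prefix: str             # first two codon bases
    amino_acid: str         # one-letter; mixed-assignment purine halves keep
                            # the amino acids of their member codons
    codons: tuple[str, ...]
    kind: str               # fourfold | NNY | NNR | Y+A | singleton

    @property
    def endings(self) -> frozenset[str]:
        return frozenset(c[2] for c in self.codons)


def codon_families(code: GeneticCode) -> list[CodonFamily]:
    """Partition the sense codons into wobble families (see module docstring)."""
    families: list[CodonFamily] = []
    for b1 in RNA_BASES:
        for b2 in RNA_BASES:
            prefix = b1 + b2
            box = [prefix + b3 for b3 in RNA_BASES]
            sense = [c for c in box if code.table[c] != "*"]
            if not sense:
                continue
            aas = {code.table[c] for c in sense}
            if len(sense) == 4 and len(aas) == 1:
                families.append(CodonFamily(prefix, aas.pop(), tuple(sense), "fourfold"))
                continue
            for half, bases in (("NNY", "UC"), ("NNR", "AG")):
                members = [c for c in sense if c[2] in bases]
                if not members:
                    continue
                for aa in sorted({code.table[c] for c in members}):
                    group = tuple(c for c in members if code.table[c] == aa)
                    kind = half if len(group) == 2 else "singleton"
                    families.append(CodonFamily(prefix, aa, group, kind))
    # merge an NNY family with a same-aa singleton NNA codon into a Y+A family
    merged: list[CodonFamily] = []
    by_key = {(f.prefix, f.amino_acid, f.kind): f for f in families}
    consumed = set()
    for f in families:
        if id(f) in consumed:
            continue
        if f.kind == "NNY":
            lone = by_key.get((f.prefix, f.amino_acid, "singleton"))
            if lone is not None and lone.codons[0][2] == "A":
                merged.append(
                    CodonFamily(f.prefix, f.amino_acid, f.codons + lone.codons, "Y+A")
                )
                consumed.add(id(lone))
                continue
        merged.append(f)
    return [f for f in merged if id(f) not in consumed]


def versatile_anticodon(family: CodonFamily) -> str:
    """The maximally versatile anticodon (5'->3' RNA) expected for a family.

    GNN for pyrimidine-ending families (NNY and Y+A), UNN for purine-ending
    and four-fold families.  For singleton families this extends the
    half-box rule rather than using the exact Watson-Crick complement, so a
    lone NNG codon still expects UNN.
    """
    body = reverse_complement_rna(family.prefix)
    if family.endings <= {"U", "C"} or family.endings == {"U", "C", "A"}:
        wobble = "G"
    else:
        wobble = "U"
    return wobble + body


@dataclass(frozen=True)
class TRNAEntry:
    amino_acid: str         # one-letter amino acid served
    anticodon: str          # 5'->3' RNA
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.anticodon) != 3 or set(self.anticodon) - set(RNA_BASES):
            raise ValueError(f"bad anticodon {self.anticodon!r}")


AnticodonSet = list[TRNAEntry]


def versatile_anticodon_set(code: GeneticCode) -> AnticodonSet:
    """One maximally versatile tRNA per sense codon family."""
    out = []
    for fam in codon_families(code):
        ac = versatile_anticodon(fam)
        out.append(TRNAEntry(fam.amino_acid, ac, name=f"trn{fam.amino_acid}-{ac}"))
    return out


def rhabdopleura_anticodon_set() -> AnticodonSet:
    """The 22-tRNA pterobranch set: versatile throughout except the documented
    Met (CAU, matching the start codon) and Lys (CUU) anticodons; no tRNA for
    the reassigned AGG codon."""
    code = get_code("rhabdopleura")
    out = []
    for fam in codon_families(code):
        if fam.prefix == "AG" and fam.amino_acid == "K":
            continue    # AGG family: uncovered
        if fam.prefix == "AU" and fam.amino_acid == "M":
            ac = "CAU"
        elif fam.prefix == "AA" and fam.amino_acid == "K":
            ac = "CUU"
        else:
            ac = versatile_anticodon(fam)
        out.append(TRNAEntry(fam.amino_acid, ac, name=f"trn{fam.amino_acid}-{ac}"))
    return out


def anticodon_set_from_genome(genome: AnnotatedGenome, code: GeneticCode) -> AnticodonSet:
    """Collect tRNA anticodons from annotated trnX features."""
    out = []
    for f in genome.features_of_kind("tRNA"):
        if f.anticodon is None:
            continue
        aa = f.name[3:4] if f.name.startswith("trn") else ""
        if aa not in AA_ONE_TO_THREE:
            aa = code.table.get(reverse_complement_rna(f.anticodon), "")
        if aa in ("", "*"):
            warnings.warn(f"cannot determine amino acid for tRNA {f.name}; skipped")
            continue
        out.append(TRNAEntry(aa, f.anticodon, name=f.name))
    return out


# ---------------------------------------------------------------------------
# pairing classification


@dataclass(frozen=True)
class FamilyPairing:
    family: CodonFamily
    anticodon: str | None
    classification: str     # versatile | adapted | deviant | uncovered
    note: str = ""


@dataclass
class PairingReport:
    families: list[FamilyPairing]

    @property
    def deviation_count(self) -> int:
        """Families departing from the highest-versatility anticodon scheme."""
        return sum(1 for f in self.families if f.classification != "versatile")

    def by_classification(self, label: str) -> list[FamilyPairing]:
        return [f for f in self.families if f.classification == label]


def _cognate(family: CodonFamily, anticodon_set: AnticodonSet) -> TRNAEntry | None:
    """tRNA serving this family: same amino acid, anticodon targeting the box."""
    for entry in anticodon_set:
        if entry.amino_acid != family.amino_acid:
            continue
        if reverse_complement_rna(entry.anticodon)[:2] == family.prefix:
            return entry
    return None


def classify_pairing(
    anticodon_set: AnticodonSet,
    code: GeneticCode,
    usage: CodonUsageTable | None = None,
) -> PairingReport:
    """Classify every sense codon family against its cognate anticodon.

    versatile: the anticodon equals :func:`versatile_anticodon` (the special
    echinoderm-style GCU anticodon on a four-fold AGN serine family is
    accepted as versatile, with a note, since a methylated wobble G enables
    the purine pairings).  adapted: instead the exact complement of the
    family's most frequent codon (requires ``usage``).  deviant: neither.
    uncovered: no cognate tRNA.  ``deviation_count`` totals everything
    non-versatile.
    """
    families = codon_families(code)
    claimed = {c for fam in families for c in fam.codons}
    for entry in anticodon_set:
        target = reverse_complement_rna(entry.anticodon)
        if not any(
            entry.amino_acid == fam.amino_acid and target[:2] == fam.prefix
            for fam in families
        ):
            raise ValueError(
                f"tRNA {entry.name or entry.anticodon} (aa {entry.amino_acid}) "
                f"serves no codon family of code {code.id}"
            )
    assert claimed == set(code.sense_codons)

    rows = []
    for fam in families:
        entry = _cognate(fam, anticodon_set)
        if entry is None:
            rows.append(FamilyPairing(fam, None, "uncovered", "no cognate tRNA"))
            continue
        expected = versatile_anticodon(fam)
        if entry.anticodon == expected:
            rows.append(FamilyPairing(fam, entry.anticodon, "versatile"))
        elif (
            fam.kind == "fourfold"
            and fam.prefix == "AG"
            and fam.amino_acid == "S"
            and entry.anticodon == "GCU"
        ):
            rows.append(
                FamilyPairing(
                    fam, entry.anticodon, "versatile",
                    "GCU reads the purine-ending codons via wobble-G methylation",
                )
            )
        elif usage is not None and _is_adapted(fam, entry.anticodon, usage):
            rows.append(
                FamilyPairing(fam, entry.anticodon, "adapted",
                              "anticodon complements the family's most frequent codon")
            )
        else:
            rows.append(FamilyPairing(fam, entry.anticodon, "deviant",
                                      f"expected {expected}"))
    return PairingReport(families=rows)


def _is_adapted(family: CodonFamily, anticodon: str, usage: CodonUsageTable) -> bool:
    fam_counts = {c: usage[c] for c in family.codons}
    best = max(fam_counts.values())
    argmax = {c for c, n in fam_counts.items() if n == best}
    return reverse_complement_rna(anticodon) in argmax


@dataclass(frozen=True)
class AdaptationResult:
    family: CodonFamily
    anticodon: str | None
    matches_most_frequent: bool | None  # None when the family has zero usage
    tie: bool = False


def adaptation_test(
    anticodon_set: AnticodonSet, code: GeneticCode, usage: CodonUsageTable
) -> list[AdaptationResult]:
    """Per family: does the anticodon complement the most frequent codon?

    Ties count as a match and are flagged; families with zero total usage
    are returned as undefined (None).
    """
    if usage.total == 0:
        raise ValueError("empty usage table")
    out = []
    for fam in codon_families(code):
        entry = _cognate(fam, anticodon_set)
        fam_counts = {c: usage[c] for c in fam.codons}
        total = sum(fam_counts.values())
        if entry is None:
            out.append(AdaptationResult(fam, None, None))
            continue
        if total == 0:
            out.append(AdaptationResult(fam, entry.anticodon, None))
            continue
        best = max(fam_counts.values())
        argmax = {c for c, n in fam_counts.items() if n == best}
        tie = len(argmax) > 1
        match = reverse_complement_rna(entry.anticodon) in argmax
        out.append(AdaptationResult(fam, entry.anticodon, match, tie))
    return out


def usage_to_tsv(usage: CodonUsageTable, anticodon_set: AnticodonSet | None = None) -> str:
    """64-row usage table: codon, count, amino acid, anticodon flag."""
    flagged = set()
    if anticodon_set:
        flagged = {reverse_complement_rna(e.anticodon) for e in anticodon_set}
    lines = ["codon\tcount\tamino_acid\tanticodon_codon"]
    for codon in ALL_CODONS:
        aa = AA_ONE_TO_THREE[usage.code.table[codon]]
        mark = "*" if codon in flagged else ""
        lines.append(f"{codon}\t{usage.counts[codon]}\t{aa}\t{mark}")
    return "\n".join(lines) + "\n"
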