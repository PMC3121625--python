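"""Seeded generator of annotated circular mitogenomes with a planted truth record.

Every sampling call draws from one explicitly passed NumPy generator, so the
same seed reproduces a byte-identical genome and truth record.  The default
layout carries 13 CDS, 2 rRNA and 22 tRNA genes on one strand, resembling a
compact ~16 kb deuterostome mitogenome, so that origin-inference and
codon-usage fixtures have realistic geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from collections import deque

from .codon_code import (
    GeneticCode,
    dna,
    get_code,
    rhabdopleura_anticodon_set,
    versatile_anticodon_set,
)
from .genome_io import AnnotatedGenome, GeneFeature, Interval

DNA_BASES = "ACGT"

#: (name, kind, length) rows of the default single-strand layout
DEFAULT_CDS_LENGTHS = {
    "COX1": 1539, "COX2": 690, "ATP8": 168, "ATP6": 699, "COX3": 786,
    "ND3": 354, "ND4L": 297, "ND4": 1377, "ND5": 1722, "ND6": 480,
    "CYTB": 1140, "ND1": 963, "ND2": 1041,
}
TRNA_AAS = list("FLIMVSPTAYHQNKDECWRG") + ["L", "S"]  # 22 tRNAs, duplicated Leu/Ser


@dataclass
class GeneSpec:
    name: str
    kind: str       # CDS | tRNA | rRNA | spacer
    length: int
    strand: str = "main"


@dataclass
class SimParams:
    """Everything the generator needs; see :func:`generate_genome`."""

    layout: list[GeneSpec]
    code: str = "rhabdopleura"
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)  # A,C,G,T
    ori_l: int | None = None
    ori_h: int | None = None
    gradient_amplitude: float = 0.0
    planted_runs: list[tuple[str, int, int]] = field(default_factory=list)  # base, length, count
    aa_freqs: dict[str, float] | None = None
    synonymous_bias: dict[str, float] | None = None   # third-position base -> weight
    cds_mode: str = "aa"    # "aa": amino-acid-first codon sampling;
                            # "composition": sense codons drawn with probability
                            # proportional to the product of per-position base
                            # probabilities, so the planted composition and
                            # gradient hold genome-wide
    seed: int = 0
    genome_id: str = "synthetic"

    def __post_init__(self) -> None:
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")
        if any(p < 0 for p in self.composition):
            raise ValueError("composition must be non-negative")
        for spec in self.layout:
            if spec.kind == "CDS" and spec.length % 3:
                raise ValueError(f"CDS {spec.name} length {spec.length} not a multiple of 3")

    @property
    def total_length(self) -> int:
        return sum(g.length for g in self.layout)


@dataclass
class TruthRecord:
    genome_id: str
    seed: int
    code_id: str
    length: int
    composition_target: tuple[float, float, float, float]
    realized_counts: dict[str, int]
    ori_l: int | None
    ori_h: int | None
    gradient_amplitude: float
    planted_runs: list[dict]
    gene_layout: list[dict]
    aa_freqs: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def default_layout(
    spacer: int = 18,
    rrn_s: int = 842,
    rrn_l: int = 1342,
    trna_len: int = 68,
    include_trnas: bool = True,
) -> list[GeneSpec]:
    """One-strand layout: CDS blocks interleaved with tRNAs, rRNAs and spacers."""
    trna_names = []
    seen: dict[str, int] = {}
    for aa in TRNA_AAS:
        seen[aa] = seen.get(aa, 0) + 1
        trna_names.append(f"trn{aa}" if seen[aa] == 1 else f"trn{aa}{seen[aa]}")
    layout: list[GeneSpec] = []
    cds_names = list(DEFAULT_CDS_LENGTHS)
    ti = 0
    for i, name in enumerate(cds_names):
        layout.append(GeneSpec(name, "CDS", DEFAULT_CDS_LENGTHS[name]))
        layout.append(GeneSpec(f"spacer{i}", "spacer", spacer))
        if include_trnas and ti < len(trna_names):
            layout.append(GeneSpec(trna_names[ti], "tRNA", trna_len))
            ti += 1
            layout.append(GeneSpec(f"spacer{i}b", "spacer", spacer))
        if name == "COX2":
            layout.append(GeneSpec("rrnS", "rRNA", rrn_s))
            layout.append(GeneSpec("spacerS", "spacer", spacer))
        if name == "ND3":
            layout.append(GeneSpec("rrnL", "rRNA", rrn_l))
            layout.append(GeneSpec("spacerL", "spacer", spacer))
    while include_trnas and ti < len(trna_names):
        layout.append(GeneSpec(trna_names[ti], "tRNA", trna_len))
        layout.append(GeneSpec(f"spacerT{ti}", "spacer", spacer))
        ti += 1
    return layout


def _gradient_factor(pos: int, length: int, ori_l: int, ori_h: int, amplitude: float) -> float:
    """1 + amplitude * d(pos), d linear from -1 at oriL to +1 at oriH along both arcs."""
    arc = (ori_h - ori_l) % length
    if arc == 0:
        return 1.0
    x = (pos - ori_l) % length
    u = x / arc if x <= arc else 1.0 - (x - arc) / (length - arc)
    return 1.0 + amplitude * (2.0 * u - 1.0)


def _position_probs(
    params: SimParams, pos: int, length: int
) -> np.ndarray:
    p = np.array(params.composition, dtype=float)  # A, C, G, T
    if params.gradient_amplitude and params.ori_l is not None and params.ori_h is not None:
        f = _gradient_factor(pos, length, params.ori_l, params.ori_h, params.gradient_amplitude)
        p = p * np.array([1.0, 1.0, f, f])
        p = np.clip(p, 1e-12, None)
        p = p / p.sum()
    return p


def sample_codons(
    protein_length: int,
    code: GeneticCode,
    aa_freqs: dict[str, float] | None,
    synonymous_bias: dict[str, float] | None,
    rng: np.random.Generator,
    third_position_factor=None,
) -> str:
    """Sample an RNA codon string: amino-acid-first, then synonymous codon.

    ``synonymous_bias`` weights the third-position base of synonymous
    alternatives; ``third_position_factor(i)`` optionally scales the G/U
    weight per codon index (used for origin gradients).  A terminal stop
    codon under ``code`` is appended.
    """
    aas = code.amino_acids
    if aa_freqs is None:
        freqs = np.full(len(aas), 1.0 / len(aas))
    else:
        missing = set(aa_freqs) - set(aas)
        if missing:
            raise ValueError(f"amino acids {sorted(missing)} not encoded by code {code.id}")
        freqs = np.array([aa_freqs.get(aa, 0.0) for aa in aas], dtype=float)
        if freqs.sum() <= 0:
            raise ValueError("aa_freqs sum to zero")
        freqs = freqs / freqs.sum()
    bias = synonymous_bias or {}
    chosen_aas = rng.choice(len(aas), size=protein_length, p=freqs)
    codons = []
    for i, ai in enumerate(chosen_aas):
        options = code.codons_for(aas[ai])
        w = np.array([bias.get(c[2], 1.0) for c in options], dtype=float)
        if third_position_factor is not None:
            f = third_position_factor(i)
            w = w * np.array([f if c[2] in "GU" else 1.0 for c in options])
        w = w / w.sum()
        codons.append(options[rng.choice(len(options), p=w)])
    stops = code.stop_codons
    preferred = [s for s in ("UAA", "UAG") if s in stops] or list(stops)
    codons.append(preferred[int(rng.integers(len(preferred)))])
    return "".join(codons)


def _sample_codons_iid(
    n_codons: int,
    code: GeneticCode,
    params: SimParams,
    genome_length: int,
    cds_start: int,
    rng: np.random.Generator,
) -> str:
    """Sense codons with probability ~ product of per-position base probabilities."""
    from .codon_code import rna as _rna

    sense = [dna(c) for c in code.sense_codons]
    codons = []
    base_index = {b: i for i, b in enumerate(DNA_BASES)}
    for i in range(n_codons):
        pos0 = cds_start + 3 * i
        probs = [
            _position_probs(params, (pos0 + k) % genome_length, genome_length)
            for k in range(3)
        ]
        w = np.array(
            [probs[0][base_index[c[0]]] * probs[1][base_index[c[1]]] * probs[2][base_index[c[2]]]
             for c in sense]
        )
        w = w / w.sum()
        codons.append(sense[int(rng.choice(len(sense), p=w))])
    stops = [dna(s) for s in code.stop_codons]
    preferred = [s for s in ("TAA", "TAG") if s in stops] or stops
    codons.append(preferred[int(rng.integers(len(preferred)))])
    return _rna("".join(codons))


def generate_genome(params: SimParams) -> tuple[AnnotatedGenome, TruthRecord]:
    """Emit a deterministic annotated genome plus its truth record."""
    length = params.total_length
    if length <= 0:
        raise ValueError("layout is empty")
    for base, run_len, count in params.planted_runs:
        if base not in DNA_BASES or run_len < 2 or count < 1:
            raise ValueError(f"bad planted run spec {(base, run_len, count)}")
    spacer_total = sum(g.length for g in params.layout if g.kind == "spacer")
    runs_total = sum((ln + 2) * n for _, ln, n in params.planted_runs)
    if runs_total > spacer_total:
        raise ValueError(
            f"planted runs need {runs_total} intergenic bases but layout has {spacer_total}"
        )

    rng = np.random.default_rng(params.seed)
    code = get_code(params.code)
    seq_parts: list[str] = []
    features: list[GeneFeature] = []
    gene_rows: list[dict] = []
    spacer_spans: list[tuple[int, int]] = []
    trna_set = (
        rhabdopleura_anticodon_set()
        if code.id == "rhabdopleura"
        else versatile_anticodon_set(code)
    )
    anticodons: dict[str, deque[str]] = {}
    for e in trna_set:
        anticodons.setdefault(e.amino_acid, deque()).append(e.anticodon)
    cursor = 0
    for spec in params.layout:
        start, end = cursor, cursor + spec.length
        if spec.kind == "CDS":
            n_aa = spec.length // 3 - 1
            if params.cds_mode == "composition":
                codons = _sample_codons_iid(n_aa, code, params, length, start, rng)
            else:

                def factor(i, _start=start):
                    if params.gradient_amplitude and params.ori_l is not None:
                        return _gradient_factor(
                            _start + 3 * i + 2, length, params.ori_l, params.ori_h,
                            params.gradient_amplitude,
                        )
                    return 1.0

                codons = sample_codons(
                    n_aa, code, params.aa_freqs, params.synonymous_bias, rng,
                    third_position_factor=factor,
                )
            seq_parts.append(dna(codons))
        else:
            probs = np.stack(
                [_position_probs(params, p, length) for p in range(start, end)]
            )
            cum = probs.cumsum(axis=1)
            draws = rng.random(spec.length)
            idx = (draws[:, None] > cum).sum(axis=1)
            seq_parts.append("".join(DNA_BASES[i] for i in idx))
            if spec.kind == "spacer":
                spacer_spans.append((start, end))
        if spec.kind in ("CDS", "tRNA", "rRNA"):
            features.append(
                GeneFeature(
                    name=spec.name,
                    kind=spec.kind,
                    strand=spec.strand,
                    intervals=[Interval(start, end)],
                    anticodon=(
                        _next_anticodon(anticodons, spec.name[3:4])
                        if spec.kind == "tRNA"
                        else None
                    ),
                )
            )
        gene_rows.append(
            {"name": spec.name, "kind": spec.kind, "start": start, "end": end,
             "strand": spec.strand}
        )
        cursor = end

    seq = list("".join(seq_parts))
    run_registry = _plant_runs(seq, params.planted_runs, spacer_spans, rng)

    genome = AnnotatedGenome(
        id=params.genome_id, sequence="".join(seq), circular=True, features=features
    )
    counts = {b: genome.sequence.count(b) for b in DNA_BASES}
    aas = code.amino_acids
    truth = TruthRecord(
        genome_id=params.genome_id,
        seed=params.seed,
        code_id=code.id,
        length=length,
        composition_target=params.composition,
        realized_counts=counts,
        ori_l=params.ori_l,
        ori_h=params.ori_h,
        gradient_amplitude=params.gradient_amplitude,
        planted_runs=run_registry,
        gene_layout=gene_rows,
        aa_freqs=params.aa_freqs or {aa: 1.0 / len(aas) for aa in aas},
    )
    return genome, truth


def _next_anticodon(anticodons: dict[str, deque[str]], aa: str) -> str | None:
    queue = anticodons.get(aa)
    return queue.popleft() if queue else None


def _plant_runs(seq, planted, spacer_spans, rng) -> list[dict]:
    """Overwrite homopolymer runs into spacer regions, with non-matching flanks."""
    registry = []
    free = [list(span) for span in spacer_spans]
    for base, run_len, count in planted:
        other = "A" if base != "A" else "C"
        need = run_len + 2
        for _ in range(count):
            candidates = [i for i, (s, e) in enumerate(free) if e - s >= need]
            if not candidates:
                raise ValueError(f"no intergenic room left for run ({base},{run_len})")
            i = candidates[int(rng.integers(len(candidates)))]
            s, e = free[i]
            offset = s + int(rng.integers(e - s - need + 1))
            seq[offset] = other
            for j in range(run_len):
                seq[offset + 1 + j] = base
            seq[offset + 1 + run_len] = other
            registry.append({"base": base, "length": run_len, "position": offset + 1})
            # split the spacer span around the used stretch
            free[i : i + 1] = [
                span for span in ([s, offset], [offset + need, e]) if span[1] > span[0]
            ]
    return registry


def reference_alignments_for(
    genome: AnnotatedGenome,
    code: GeneticCode | str = "rhabdopleura",
    n_taxa: int = 20,
    fidelity: float = 0.85,
    rng: np.random.Generator | None = None,
):
    """Simulate per-gene reference protein alignments faithful to a genome.

    Each reference taxon keeps the target residue with probability
    ``fidelity`` per column and otherwise substitutes a random different
    amino acid, giving gap-free alignments whose column conservation matches
    ``fidelity`` in expectation.  Returns ``{gene: ReferenceAlignment}``.
    """
    from .code_inference import ReferenceAlignment
    from .codon_code import rna as _rna
    from .genome_io import extract_feature_seq

    if isinstance(code, str):
        code = get_code(code)
    if rng is None:
        rng = np.random.default_rng(0)
    aas = code.amino_acids
    alignments = {}
    for f in genome.features_of_kind("CDS"):
        seq = _rna(extract_feature_seq(genome, f))
        protein = []
        for i in range(len(seq) // 3):
            aa = code.table[seq[3 * i : 3 * i + 3]]
            if aa == "*":
                break
            protein.append(aa)
        target = "".join(protein)
        rows = {"target": target}
        for taxon in range(n_taxa):
            keep = rng.random(len(target)) < fidelity
            subs = rng.integers(0, len(aas) - 1, size=len(target))
            row = []
            for i, ch in enumerate(target):
                if keep[i]:
                    row.append(ch)
                else:
                    alternatives = [a for a in aas if a != ch]
                    row.append(alternatives[int(subs[i]) % len(alternatives)])
            rows[f"ref{taxon}"] = "".join(row)
        alignments[f.name] = ReferenceAlignment(gene=f.name, rows=rows)
    return alignments


# ---------------------------------------------------------------------------
# presets


def rhabdopleura_like(seed: int = 0, **overrides) -> SimParams:
    """GT-rich main strand with the published-style composition and tRNA set."""
    defaults = dict(
        layout=default_layout(),
        code="rhabdopleura",
        composition=(0.18, 0.11, 0.23, 0.48),
        synonymous_bias={"U": 8.0, "G": 4.0, "A": 1.0, "C": 0.5},
        cds_mode="composition",
        seed=seed,
        genome_id=f"rhabdopleura-like-{seed}",
    )
    defaults.update(overrides)
    return SimParams(**defaults)


def vertebrate_like(seed: int = 0, **overrides) -> SimParams:
    """AC-rich main strand (mirror-image skews)."""
    defaults = dict(
        layout=default_layout(),
        code="vertebrate",
        composition=(0.33, 0.31, 0.13, 0.23),
        synonymous_bias={"A": 5.0, "C": 4.0, "U": 1.0, "G": 0.5},
        cds_mode="composition",
        seed=seed,
        genome_id=f"vertebrate-like-{seed}",
    )
    defaults.update(overrides)
    return SimParams(**defaults)


def unbiased(seed: int = 0, **overrides) -> SimParams:
    defaults = dict(
        layout=default_layout(),
        code="invertebrate",
        composition=(0.25, 0.25, 0.25, 0.25),
        cds_mode="composition",
        seed=seed,
        genome_id=f"unbiased-{seed}",
    )
    defaults.update(overrides)
    return SimParams(**defaults)


PRESETS = {
    "rhabdopleura-like": rhabdopleura_like,
    "vertebrate-like": vertebrate_like,
    "unbiased": unbiased,
}
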