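"""Shared fixtures: toy genomes, published reference tables, tiny oracles."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

from mitoskew.codon_code import ALL_CODONS, CodonUsageTable, GeneticCode, get_code
from mitoskew.genome_io import AnnotatedGenome, GeneFeature, Interval

# Published codon usage of the pterobranch mitogenome (counts over all 13 CDS,
# stops included) — used as a fixed input table for pairing/adaptation tests.
PTEROBRANCH_CODON_COUNTS = {
    "UUU": 554, "UUC": 35, "UUA": 205, "UUG": 210,
    "UCU": 233, "UCC": 8, "UCA": 32, "UCG": 21,
    "UAU": 159, "UAC": 28, "UAA": 2, "UAG": 9,
    "UGU": 99, "UGC": 10, "UGA": 48, "UGG": 89,
    "CUU": 102, "CUC": 5, "CUA": 19, "CUG": 14,
    "CCU": 93, "CCC": 5, "CCA": 10, "CCG": 11,
    "CAU": 70, "CAC": 8, "CAA": 16, "CAG": 31,
    "CGU": 46, "CGC": 4, "CGA": 15, "CGG": 19,
    "AUU": 175, "AUC": 9, "AUA": 52, "AUG": 96,
    "ACU": 76, "ACC": 3, "ACA": 5, "ACG": 5,
    "AAU": 79, "AAC": 8, "AAA": 10, "AAG": 59,
    "AGU": 87, "AGC": 10, "AGA": 40, "AGG": 20,
    "GUU": 289, "GUC": 17, "GUA": 39, "GUG": 64,
    "GCU": 99, "GCC": 4, "GCA": 12, "GCG": 11,
    "GAU": 60, "GAC": 9, "GAA": 17, "GAG": 59,
    "GGU": 158, "GGC": 8, "GGA": 63, "GGG": 182,
}


def usage_from_counts(code: GeneticCode, counts: dict[str, int]) -> CodonUsageTable:
    full = {c: 0 for c in ALL_CODONS}
    full.update(counts)
    return CodonUsageTable(counts=full, code=code)


@pytest.fixture
def pterobranch_usage() -> CodonUsageTable:
    return usage_from_counts(get_code("rhabdopleura"), PTEROBRANCH_CODON_COUNTS)


def genbank_text(sequence: str, features: list[tuple[str, str, str]],
                 locus: str = "TOY", circular: bool = True) -> str:
    """Hand-rolled single-record GenBank flat file for parser tests.

    ``features`` rows are (type, location string, gene name).
    """
    topology = "circular" if circular else "linear"
    lines = [
        f"LOCUS       {locus:<23}{len(sequence):>7} bp    DNA     {topology:<8} INV 01-JAN-2000",
        "DEFINITION  toy record.",
        f"ACCESSION   {locus}",
        f"VERSION     {locus}.1",
        "FEATURES             Location/Qualifiers",
        f"     source          1..{len(sequence)}",
    ]
    for ftype, location, gene in features:
        lines.append(f"     {ftype:<15} {location}")
        lines.append(f'                     /gene="{gene}"')
    lines.append("ORIGIN")
    for i in range(0, len(sequence), 60):
        chunk = sequence[i : i + 60]
        blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks.lower()}")
    lines.append("//")
    return "\n".join(lines) + "\n"


@pytest.fixture
def write_toy_genbank(tmp_path):
    def _write(sequence, features, name="toy.gb", **kw):
        path = tmp_path / name
        path.write_text(genbank_text(sequence, features, **kw))
        return path

    return _write


def make_genome(sequence: str, features: list[GeneFeature] | None = None,
                genome_id: str = "toy", circular: bool = True) -> AnnotatedGenome:
    return AnnotatedGenome(id=genome_id, sequence=sequence, circular=circular,
                           features=features or [])


def cds(name: str, start: int, end: int, strand: str = "main",
        frame_offset: int = 0, wraps: bool = False) -> GeneFeature:
    return GeneFeature(name=name, kind="CDS", strand=strand,
                       intervals=[Interval(start, end, wraps=wraps)],
                       frame_offset=frame_offset)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_sequence(rng: np.random.Generator, n: int, bases: str = "ACGT") -> str:
    return "".join(bases[i] for i in rng.integers(0, len(bases), size=n))
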