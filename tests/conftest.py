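"""Shared fixtures: toy references, single-exon transcripts, and an
independent codon table for translation oracles."""

from __future__ import annotations

import numpy as np
import pytest

from indeltree import InMemoryReference, TranscriptModel

# Independent standard nuclear codon table (hand-entered; used by oracle
# translations so they do not share code with the implementation).
_TABLE_LAYOUT = """
TTT F  TTC F  TTA L  TTG L   CTT L  CTC L  CTA L  CTG L
ATT I  ATC I  ATA I  ATG M   GTT V  GTC V  GTA V  GTG V
TCT S  TCC S  TCA S  TCG S   CCT P  CCC P  CCA P  CCG P
ACT T  ACC T  ACA T  ACG T   GCT A  GCC A  GCA A  GCG A
TAT Y  TAC Y  TAA *  TAG *   CAT H  CAC H  CAA Q  CAG Q
AAT N  AAC N  AAA K  AAG K   GAT D  GAC D  GAA E  GAG E
TGT C  TGC C  TGA *  TGG W   CGT R  CGC R  CGA R  CGG R
AGT S  AGC S  AGA R  AGG R   GGT G  GGC G  GGA G  GGG G
"""

CODON_TABLE: dict[str, str] = {}
_tokens = _TABLE_LAYOUT.split()
for _i in range(0, len(_tokens), 2):
    CODON_TABLE[_tokens[_i]] = _tokens[_i + 1]
assert len(CODON_TABLE) == 64

SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")

_COMP = str.maketrans("ACGT", "TGCA")


def oracle_revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def oracle_translate(cds: str) -> str:
    return "".join(CODON_TABLE[cds[i:i + 3]] for i in range(0, len(cds), 3))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_reference(seq: str, chrom: str = "chrT",
                   offset: int = 1) -> InMemoryReference:
    return InMemoryReference({chrom: seq}, offsets={chrom: offset})


def make_gene(codons: list[str], *, chrom: str = "chrT", start: int = 11,
              strand: str = "+", tid: str = "TX1",
              pad: str = "G") -> tuple[InMemoryReference, TranscriptModel]:
    """Single-exon transcript whose CDS is ``codons`` laid at ``start``;
    the chromosome is padded with ``pad`` bases on both sides."""
    cds = "".join(codons)
    if strand == "-":
        genomic = oracle_revcomp(cds)
    else:
        genomic = cds
    seq = pad * (start - 1) + genomic + pad * 10
    tx = TranscriptModel(
        transcript_id=tid, chrom=chrom, strand=strand,
        exons=((start, start + len(cds) - 1),),
        cds_start=start, cds_end=start + len(cds) - 1)
    return make_reference(seq, chrom=chrom), tx


def random_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [SENSE_CODONS[i]
            for i in rng.integers(0, len(SENSE_CODONS), size=n)]
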