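"""Genomic data model: indels, transcripts, and protein-level consequences.

This module represents coding insertions/deletions ("indels"), gene models
(transcripts with a CDS), and the reference sequence, and determines what a
"3n indel" — an indel whose length is divisible by 3 — does to the protein:
a clean amino-acid insertion or deletion, a block substitution (net
insertion/deletion plus changed flanking residues), an early stop, or (for
non-3n lengths) a frameshift.

Coordinate conventions
----------------------
External interfaces use 1-based, inclusive genomic positions (the convention
of VCF and of the printed worked examples); internal span arithmetic is
0-based half-open.  ``Indel.pos`` is the position of the *first* inserted or
deleted base; for an insertion the inserted bases come to sit immediately
before the reference base currently at ``pos``.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

from Bio.Seq import Seq


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class InputError(ValueError):
    """A malformed or inconsistent input record."""


class NotAnIndelError(InputError):
    """The variant record is an SNV/MNV or otherwise not a simple indel."""


class ReferenceMismatchError(InputError):
    """The record's REF field disagrees with the reference sequence."""


class ModelError(ValueError):
    """A transcript model violates its invariants."""


class ScopeError(ValueError):
    """The requested operation is outside the 3n amino-acid-indel method."""


# --------------------------------------------------------------------------
# Reference sequence stores
# --------------------------------------------------------------------------

class InMemoryReference:
    """A reference backed by plain strings, optionally placed at an offset.

    ``offsets[chrom]`` gives the 1-based genomic coordinate of the first
    stored base, so a short synthetic region can stand at a realistic
    genomic position (e.g. a 40 bp window around chr12:132,547,070) without
    materialising the whole chromosome.
    """

    def __init__(self, sequences: Mapping[str, str],
                 offsets: Mapping[str, int] | None = None):
        self._seqs = {c: s.upper() for c, s in sequences.items()}
        self._offsets = dict(offsets or {})

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def start(self, chrom: str) -> int:
        return self._offsets.get(chrom, 1)

    def end(self, chrom: str) -> int:
        return self.start(chrom) + len(self._seqs[chrom]) - 1

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return bases ``start..end`` (1-based, inclusive)."""
        if chrom not in self._seqs:
            raise InputError(f"unknown sequence {chrom!r}")
        off = self.start(chrom)
        if start < off or end > self.end(chrom) or start > end:
            raise InputError(
                f"coordinates {chrom}:{start}-{end} outside stored region "
                f"{chrom}:{off}-{self.end(chrom)}")
        return self._seqs[chrom][start - off:end - off + 1]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)


class FastaReference:
    """A reference backed by an indexed FASTA file (via pyfaidx)."""

    def __init__(self, path: str):
        import pyfaidx
        self._fa = pyfaidx.Fasta(str(path))

    def chroms(self) -> list[str]:
        return list(self._fa.keys())

    def start(self, chrom: str) -> int:
        return 1

    def end(self, chrom: str) -> int:
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fa:
            raise InputError(f"unknown sequence {chrom!r}")
        if start < 1 or end > self.end(chrom) or start > end:
            raise InputError(
                f"coordinates {chrom}:{start}-{end} outside sequence bounds")
        return str(self._fa[chrom][start - 1:end]).upper()

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)


# --------------------------------------------------------------------------
# Indel
# --------------------------------------------------------------------------

class IndelKind(str, enum.Enum):
    INSERTION = "insertion"
    DELETION = "deletion"


_BASES = set("ACGTN")


@dataclass(frozen=True)
class Indel:
    """A pure coding insertion or deletion in minimal representation.

    Exactly one of ``ref_allele``/``alt_allele`` is non-empty: the deleted
    bases for a deletion, the inserted bases for an insertion.  ``pos`` is
    the 1-based position of the first inserted/deleted base.  ``normalized``
    is set once the indel has been left-shifted to its leftmost equivalent
    placement.
    """

    chrom: str
    pos: int
    ref_allele: str = ""
    alt_allele: str = ""
    normalized: bool = False

    def __post_init__(self):
        ref = self.ref_allele.upper()
        alt = self.alt_allele.upper()
        object.__setattr__(self, "ref_allele", ref)
        object.__setattr__(self, "alt_allele", alt)
        if bool(ref) == bool(alt):
            raise InputError(
                "exactly one of ref_allele/alt_allele must be non-empty "
                f"(got ref={ref!r}, alt={alt!r})")
        seq = ref or alt
        if not set(seq) <= _BASES:
            raise InputError(f"non-nucleotide characters in allele {seq!r}")
        if self.pos < 1:
            raise InputError(f"position must be >= 1, got {self.pos}")

    @property
    def kind(self) -> IndelKind:
        return IndelKind.DELETION if self.ref_allele else IndelKind.INSERTION

    @property
    def length(self) -> int:
        return max(len(self.ref_allele), len(self.alt_allele))

    @property
    def indel_seq(self) -> str:
        """The inserted or deleted bases."""
        return self.ref_allele or self.alt_allele

    @property
    def is_3n(self) -> bool:
        return self.length % 3 == 0

    @property
    def indel_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref_allele or '-'}>" \
               f"{self.alt_allele or '-'}"

    def end(self) -> int:
        """1-based inclusive end of the affected reference window.

        For an insertion (no reference bases consumed) this is ``pos - 1``.
        """
        return self.pos + len(self.ref_allele) - 1


def parse_indel_record(record, reference) -> Indel:
    """Build a minimal-representation :class:`Indel` from a variant record.

    ``record`` may be a ``(chrom, pos, ref, alt)`` tuple (1-based VCF-style
    coordinates) or a ``pysam.VariantRecord`` with a single ALT.  Shared
    leading/trailing context is trimmed; records that are not pure
    insertions or deletions are rejected.
    """
    if hasattr(record, "alts"):  # pysam VariantRecord
        if record.alts is None or len(record.alts) != 1:
            raise InputError(
                f"multi-allelic or ALT-less record at {record.chrom}:"
                f"{record.pos}; split to one ALT per record first")
        chrom, pos, ref, alt = record.chrom, record.pos, record.ref, record.alts[0]
    else:
        chrom, pos, ref, alt = record
    ref = ref.upper()
    alt = alt.upper()
    if not ref or not alt or not set(ref + alt) <= _BASES:
        raise InputError(f"non-sequence REF/ALT at {chrom}:{pos}")

    observed = reference.fetch(chrom, pos, pos + len(ref) - 1)
    if observed != ref:
        raise ReferenceMismatchError(
            f"REF {ref!r} does not match reference {observed!r} at "
            f"{chrom}:{pos}")

    # Trim shared leading context, then shared trailing context.
    lead = 0
    while lead < min(len(ref), len(alt)) and ref[lead] == alt[lead]:
        lead += 1
    ref_t, alt_t = ref[lead:], alt[lead:]
    trail = 0
    while (trail < min(len(ref_t), len(alt_t))
           and ref_t[len(ref_t) - 1 - trail] == alt_t[len(alt_t) - 1 - trail]):
        trail += 1
    if trail:
        ref_t, alt_t = ref_t[:-trail], alt_t[:-trail]

    if not ref_t and not alt_t:
        raise NotAnIndelError(f"record at {chrom}:{pos} is not a variant")
    if ref_t and alt_t:
        raise NotAnIndelError(
            f"record at {chrom}:{pos} is not an indel (SNV/MNV or complex "
            "substitution)")
    return Indel(chrom=chrom, pos=pos + lead, ref_allele=ref_t,
                 alt_allele=alt_t)


def apply_indel(sequence: str, indel: Indel, offset: int = 1) -> str:
    """Apply ``indel`` to a reference string starting at position ``offset``.

    Used by round-trip invariants and by the left-normalization equivalence
    tests: two placements of the same indel are equivalent iff the mutant
    strings are identical.
    """
    i = indel.pos - offset
    if i < 0 or i > len(sequence):
        raise InputError("indel outside the provided sequence window")
    if indel.kind is IndelKind.DELETION:
        if sequence[i:i + indel.length].upper() != indel.ref_allele:
            raise ReferenceMismatchError(
                f"deleted bases disagree with sequence at {indel.chrom}:"
                f"{indel.pos}")
        return sequence[:i] + sequence[i + indel.length:]
    return sequence[:i] + indel.alt_allele + sequence[i:]


# --------------------------------------------------------------------------
# Transcript model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """A protein-coding transcript with genomic exon structure.

    The CDS (``cds_start``..``cds_end``, 1-based inclusive, including the
    terminal stop codon) must have a total coding length divisible by 3;
    transcripts violating this are rejected as invalid/incomplete.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ModelError(f"strand must be + or -, got {self.strand!r}")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ModelError(f"exon {s}-{e} has start > end")
            if s <= prev_end:
                raise ModelError("exons overlap or are unsorted")
            prev_end = e
        if self.cds_start > self.cds_end:
            raise ModelError("cds_start > cds_end")
        if self.cds_length % 3 != 0:
            raise ModelError(
                f"transcript {self.transcript_id}: coding length "
                f"{self.cds_length} not divisible by 3 "
                "(invalid/incomplete transcript)")

    def coding_segments(self) -> list[tuple[int, int]]:
        """Genomic intervals (1-based inclusive, ascending) of the CDS."""
        segs = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 <= e2:
                segs.append((s2, e2))
        return segs

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.coding_segments())

    @property
    def protein_length(self) -> int:
        """Residue count excluding the terminal stop."""
        return self.cds_length // 3 - 1

    def plus_cds_index(self, pos: int) -> int | None:
        """0-based index of genomic position ``pos`` within the CDS,
        concatenated in ascending genomic (plus-strand) order; ``None`` when
        the position is not coding."""
        cum = 0
        for s, e in self.coding_segments():
            if s <= pos <= e:
                return cum + pos - s
            cum += e - s + 1
        return None

    def plus_cds_sequence(self, reference) -> str:
        return "".join(reference.fetch(self.chrom, s, e)
                       for s, e in self.coding_segments())

    def coding_sequence(self, reference) -> str:
        """CDS in transcript orientation (reverse-complemented on minus)."""
        plus = self.plus_cds_sequence(reference)
        return _revcomp(plus) if self.strand == "-" else plus


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _translate(cds: str) -> str:
    return str(Seq(cds).translate())


# --------------------------------------------------------------------------
# Protein consequence
# --------------------------------------------------------------------------

class ConsequenceCategory(str, enum.Enum):
    AA_INSERTION = "aa_insertion"
    AA_DELETION = "aa_deletion"
    BLOCK_SUBSTITUTION = "block_substitution"
    EARLY_STOP = "early_stop"
    FRAMESHIFT = "frameshift"
    NON_CODING = "non_coding"


#: Consequences the amino-acid-indel method predicts on.
IN_SCOPE_CATEGORIES = frozenset({
    ConsequenceCategory.AA_INSERTION,
    ConsequenceCategory.AA_DELETION,
    ConsequenceCategory.BLOCK_SUBSTITUTION,
})


@dataclass(frozen=True)
class ProteinConsequence:
    """Protein-level effect of an indel on one transcript.

    ``affected_span`` is a 1-based inclusive residue interval on the
    original protein.  For a phase-0 (codon-aligned) insertion the span is
    the single residue immediately N-terminal of the insertion point, with
    ``pure_insertion`` set and the flanking residue pair recorded.
    """

    category: ConsequenceCategory
    transcript_id: str
    affected_span: tuple[int, int] | None = None
    inserted_residues: str = ""
    deleted_residues: str = ""
    pure_insertion: bool = False
    insertion_flanks: tuple[int, int] | None = None


def classify_coding_consequence(indel: Indel, tx: TranscriptModel,
                                reference) -> ProteinConsequence:
    """Determine the protein-level consequence of ``indel`` on ``tx``.

    The mutant CDS is built and translated; an in-frame stop appearing
    before the original terminus gives ``early_stop``, a length not
    divisible by 3 gives ``frameshift``, and otherwise the original and
    mutant proteins are compared after trimming their common prefix and
    suffix to yield an amino-acid insertion, deletion, or block
    substitution.
    """
    if indel.chrom != tx.chrom:
        return ProteinConsequence(ConsequenceCategory.NON_CODING,
                                  tx.transcript_id)

    plus_cds = tx.plus_cds_sequence(reference)

    if indel.kind is IndelKind.DELETION:
        i0 = tx.plus_cds_index(indel.pos)
        i1 = tx.plus_cds_index(indel.end())
        if i0 is None and i1 is None:
            # entirely outside any coding segment (may still straddle one)
            if any(indel.pos < s and indel.end() > e
                   for s, e in tx.coding_segments()):
                raise ModelError(
                    f"deletion {indel.indel_id} spans an entire coding "
                    "segment boundary")
            return ProteinConsequence(ConsequenceCategory.NON_CODING,
                                      tx.transcript_id)
        if i0 is None or i1 is None or i1 - i0 != indel.length - 1:
            raise ModelError(
                f"deletion {indel.indel_id} straddles a coding boundary")
        mut_plus = plus_cds[:i0] + plus_cds[i0 + indel.length:]
    else:
        slot = tx.plus_cds_index(indel.pos)
        if slot is None or slot == 0:
            return ProteinConsequence(ConsequenceCategory.NON_CODING,
                                      tx.transcript_id)
        mut_plus = plus_cds[:slot] + indel.alt_allele + plus_cds[slot:]

    if indel.length % 3 != 0:
        return ProteinConsequence(ConsequenceCategory.FRAMESHIFT,
                                  tx.transcript_id)

    if tx.strand == "-":
        orig_cds, mut_cds = _revcomp(plus_cds), _revcomp(mut_plus)
    else:
        orig_cds, mut_cds = plus_cds, mut_plus

    orig_prot = _translate(orig_cds)
    mut_prot = _translate(mut_cds)
    if "*" in orig_prot[:-1]:
        raise ModelError(
            f"transcript {tx.transcript_id} has an internal stop codon in "
            "the reference CDS")
    orig_body = orig_prot[:-1] if orig_prot.endswith("*") else orig_prot
    mut_body = mut_prot[:-1] if mut_prot.endswith("*") else mut_prot
    if "*" in mut_body:
        return ProteinConsequence(ConsequenceCategory.EARLY_STOP,
                                  tx.transcript_id)

    np_, ns = _prefix_suffix(orig_body, mut_body)
    deleted = orig_body[np_:len(orig_body) - ns]
    inserted = mut_body[np_:len(mut_body) - ns]

    if not deleted and not inserted:  # pragma: no cover - 3n length != 0
        raise ModelError("indel produced no protein change")
    if not deleted:
        anchor = max(np_, 1)
        return ProteinConsequence(
            ConsequenceCategory.AA_INSERTION, tx.transcript_id,
            affected_span=(anchor, anchor), inserted_residues=inserted,
            pure_insertion=True, insertion_flanks=(np_, np_ + 1))
    span = (np_ + 1, len(orig_body) - ns)
    if not inserted:
        return ProteinConsequence(
            ConsequenceCategory.AA_DELETION, tx.transcript_id,
            affected_span=span, deleted_residues=deleted)
    return ProteinConsequence(
        ConsequenceCategory.BLOCK_SUBSTITUTION, tx.transcript_id,
        affected_span=span, inserted_residues=inserted,
        deleted_residues=deleted)


def _prefix_suffix(a: str, b: str) -> tuple[int, int]:
    """Longest common prefix length, then longest common suffix length of
    the remainders (prefix + suffix never exceeds the shorter string)."""
    limit = min(len(a), len(b))
    p = 0
    while p < limit and a[p] == b[p]:
        p += 1
    s = 0
    while s < limit - p and a[len(a) - 1 - s] == b[len(b) - 1 - s]:
        s += 1
    return p, s


def affected_residue_span(indel: Indel, tx: TranscriptModel,
                          reference) -> tuple[int, int]:
    """1-based inclusive residue interval covering the inserted, deleted and
    changed residues; raises :class:`ScopeError` for consequences outside
    the amino-acid-indel method."""
    cons = classify_coding_consequence(indel, tx, reference)
    if cons.category not in IN_SCOPE_CATEGORIES:
        raise ScopeError(
            f"{cons.category.value} indel {indel.indel_id} is out of the "
            "amino-acid-indel method's scope; use the frameshift predictor")
    assert cons.affected_span is not None
    return cons.affected_span


# --------------------------------------------------------------------------
# IO: transcripts from GTF/GFF3, consequence table output
# --------------------------------------------------------------------------

def load_transcripts(path: str, attribute_key: str = "transcript_id",
                     ) -> tuple[dict[str, TranscriptModel], list[str]]:
    """Load transcript models from GTF/GFF3 via gffutils.

    Returns ``(transcripts, rejected_ids)``; transcripts whose coding
    length is not divisible by 3 are rejected as invalid/incomplete.  The
    CDS features are taken as written (this package's GTF dialect includes
    the terminal stop codon in the CDS).
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True, verbose=False)
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        attr = feat.attributes.get(attribute_key)
        if not attr:
            continue
        tid = attr[0]
        meta.setdefault(tid, (feat.seqid, feat.strand))
        bucket = exons if feat.featuretype == "exon" else cds
        bucket.setdefault(tid, []).append((feat.start, feat.end))

    transcripts: dict[str, TranscriptModel] = {}
    rejected: list[str] = []
    for tid, (chrom, strand) in meta.items():
        cds_ivals = sorted(cds.get(tid, []))
        if not cds_ivals:
            rejected.append(tid)
            continue
        exon_ivals = tuple(sorted(exons.get(tid, cds_ivals)))
        try:
            transcripts[tid] = TranscriptModel(
                transcript_id=tid, chrom=chrom, strand=strand,
                exons=exon_ivals, cds_start=cds_ivals[0][0],
                cds_end=cds_ivals[-1][1])
        except ModelError:
            rejected.append(tid)
    return transcripts, rejected


def read_vcf_indels(path: str, reference) -> Iterator[tuple[Indel, object]]:
    """Yield ``(Indel, pysam record)`` pairs from a VCF; records that are
    not simple indels raise per-record errors the caller may catch."""
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            yield parse_indel_record(rec, reference), rec


CONSEQUENCE_COLUMNS = ("chrom", "pos", "ref", "alt", "transcript_id",
                       "category", "affected_span", "inserted_residues",
                       "deleted_residues")


def write_consequences_tsv(rows: Iterable[tuple[Indel, ProteinConsequence]],
                           path: str) -> int:
    """Write consequence calls as TSV; returns the row count."""
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(CONSEQUENCE_COLUMNS) + "\n")
        for indel, cons in rows:
            span = ("%d-%d" % cons.affected_span
                    if cons.affected_span else ".")
            fh.write("\t".join([
                indel.chrom, str(indel.pos), indel.ref_allele or "-",
                indel.alt_allele or "-", cons.transcript_id,
                cons.category.value, span, cons.inserted_residues or ".",
                cons.deleted_residues or ".",
            ]) + "\n")
            n += 1
    return n


def thin_one_per_gene(entries: Iterable[tuple[str, Indel]]) -> list[Indel]:
    """Keep the first indel per gene in genomic order (dataset thinning).

    ``entries`` are ``(gene_id, indel)`` pairs; within each gene the indel
    with the smallest (chrom, pos) is retained.
    """
    best: dict[str, Indel] = {}
    for gene_id, indel in entries:
        cur = best.get(gene_id)
        if cur is None or (indel.chrom, indel.pos) < (cur.chrom, cur.pos):
            best[gene_id] = indel
    return sorted(best.values(), key=lambda i: (i.chrom, i.pos))
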