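"""Indel parsing, transcript validation, and protein-consequence calling."""

from __future__ import annotations

import numpy as np
import pytest

from indeltree import (ConsequenceCategory, Indel, IndelKind, InMemoryReference,
                       ModelError, NotAnIndelError, ReferenceMismatchError,
                       ScopeError, TranscriptModel, affected_residue_span,
                       apply_indel, classify_coding_consequence,
                       parse_indel_record, thin_one_per_gene)

from conftest import (make_gene, make_reference, oracle_revcomp,
                      oracle_translate, random_codons)


# --------------------------------------------------------------------------
# parse_indel_record
# --------------------------------------------------------------------------

class TestParseIndelRecord:
    def test_anchor_base_trimming_yields_pure_deletion(self):
        ref = make_reference("G" * 99 + "ACATGG", offset=1)
        indel = parse_indel_record(("chrT", 100, "ACAT", "A"), ref)
        assert indel.kind is IndelKind.DELETION
        assert (indel.pos, indel.ref_allele) == (101, "CAT")

    def test_insertion_position_is_first_inserted_base(self):
        ref = InMemoryReference({"chr12": "CCTGAACCAT" + "GCA" * 6 + "TGGT"},
                                offsets={"chr12": 132547060})
        indel = parse_indel_record(("chr12", 132547087, "A", "AGCA"), ref)
        assert indel.kind is IndelKind.INSERTION
        assert (indel.pos, indel.alt_allele) == (132547088, "GCA")

    def test_snv_is_rejected(self):
        ref = make_reference("GGAGG")
        with pytest.raises(NotAnIndelError, match="not an indel"):
            parse_indel_record(("chrT", 3, "A", "G"), ref)

    def test_reference_mismatch_names_position(self):
        ref = make_reference("GGGGG")
        with pytest.raises(ReferenceMismatchError, match="chrT:2"):
            parse_indel_record(("chrT", 2, "AC", "A"), ref)

    def test_indel_invariants(self):
        with pytest.raises(ValueError):
            Indel(chrom="c", pos=5, ref_allele="AC", alt_allele="G")
        with pytest.raises(ValueError):
            Indel(chrom="c", pos=5)
        ins = Indel(chrom="c", pos=5, alt_allele="CAT")
        assert ins.length == 3 and ins.is_3n and ins.indel_seq == "CAT"


# --------------------------------------------------------------------------
# Transcript model
# --------------------------------------------------------------------------

class TestTranscriptModel:
    def test_incomplete_cds_rejected(self):
        with pytest.raises(ModelError, match="invalid/incomplete"):
            TranscriptModel(transcript_id="t", chrom="c", strand="+",
                            exons=((1, 10),), cds_start=1, cds_end=10)

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ModelError):
            TranscriptModel(transcript_id="t", chrom="c", strand="+",
                            exons=((1, 10), (5, 12)), cds_start=1, cds_end=12)

    def test_protein_length_excludes_stop(self):
        _, tx = make_gene(["ATG", "AAA", "TAA"])
        assert tx.protein_length == 2


# --------------------------------------------------------------------------
# classify_coding_consequence
# --------------------------------------------------------------------------

class TestClassifyConsequence:
    def test_tga_insertion_is_early_stop(self):
        ref, tx = make_gene(["ATG", "AAA", "CCC", "TAA"])
        indel = Indel(chrom="chrT", pos=tx.cds_start + 3, alt_allele="TGA")
        cons = classify_coding_consequence(indel, tx, ref)
        assert cons.category is ConsequenceCategory.EARLY_STOP

    def test_deletion_of_duplicate_codon_is_aa_deletion(self):
        # (AAG)(AAG) -> AAG: LysLys -> Lys
        ref, tx = make_gene(["ATG", "AAG", "AAG", "CCC", "TAA"])
        indel = Indel(chrom="chrT", pos=tx.cds_start + 3, ref_allele="AAG")
        cons = classify_coding_consequence(indel, tx, ref)
        assert cons.category is ConsequenceCategory.AA_DELETION
        assert cons.deleted_residues == "K"

    def test_non_3n_deletion_is_frameshift(self):
        ref, tx = make_gene(["ATG", "AAA", "CCC", "GGG", "TAA"])
        indel = Indel(chrom="chrT", pos=tx.cds_start + 3,
                      ref_allele="AAAC")
        cons = classify_coding_consequence(indel, tx, ref)
        assert cons.category is ConsequenceCategory.FRAMESHIFT

    def test_indel_outside_cds_is_non_coding(self):
        ref, tx = make_gene(["ATG", "AAA", "TAA"])
        indel = Indel(chrom="chrT", pos=2, alt_allele="CCC")
        cons = classify_coding_consequence(indel, tx, ref)
        assert cons.category is ConsequenceCategory.NON_CODING

    def test_phase1_deletion_changes_one_and_deletes_one(self):
        # 3-base deletion starting inside codon 10: one changed residue
        # plus one deleted -> span [10, 11]; expected derived from the
        # independent translation oracle below.
        codons = (["ATG"] + ["GAA"] * 8
                  + ["CAT", "TGG", "CCA", "GAA", "TAA"])
        ref, tx = make_gene(codons)
        pos = tx.cds_start + 9 * 3 + 1  # second base of codon 10
        indel = Indel(chrom="chrT", pos=pos,
                      ref_allele="".join(codons)[9 * 3 + 1:9 * 3 + 4])
        cons = classify_coding_consequence(indel, tx, ref)
        expected = _oracle_consequence(ref, tx, indel)
        assert (cons.category.value, cons.affected_span,
                cons.inserted_residues, cons.deleted_residues) == expected
        assert cons.affected_span == (10, 11)


# --------------------------------------------------------------------------
# affected_residue_span
# --------------------------------------------------------------------------

class TestAffectedSpan:
    def test_phase0_deletion_span_is_single_residue(self):
        codons = ["ATG"] + ["GAA"] * 8 + ["TGG"] + ["GAA"] * 3 + ["TAA"]
        ref, tx = make_gene(codons)
        indel = Indel(chrom="chrT", pos=tx.cds_start + 9 * 3,
                      ref_allele="TGG")
        assert affected_residue_span(indel, tx, ref) == (10, 10)

    def test_phase0_insertion_anchors_left_residue(self):
        codons = ["ATG", "CAT", "TGG", "CCA", "GAA", "TAC", "TGT", "TAA"]
        ref, tx = make_gene(codons)
        indel = Indel(chrom="chrT", pos=tx.cds_start + 5 * 3,
                      alt_allele="CGT")  # between codons 5 and 6
        cons = classify_coding_consequence(indel, tx, ref)
        assert cons.category is ConsequenceCategory.AA_INSERTION
        assert cons.pure_insertion
        assert cons.affected_span == (5, 5)
        assert cons.insertion_flanks == (5, 6)

    def test_out_of_scope_consequences_raise(self):
        ref, tx = make_gene(["ATG", "AAA", "CCC", "TAA"])
        frameshift = Indel(chrom="chrT", pos=tx.cds_start + 3,
                           ref_allele="AAAC")
        with pytest.raises(ScopeError, match="frameshift"):
            affected_residue_span(frameshift, tx, ref)


# --------------------------------------------------------------------------
# Oracle equivalence and invariants
# --------------------------------------------------------------------------

def _oracle_consequence(reference, tx, indel):
    """Independent consequence call: apply the indel to the chromosome
    string, re-extract the CDS window, translate with a hand-entered codon
    table, and diff the proteins codon-by-codon."""
    chrom_seq = reference.fetch(tx.chrom, reference.start(tx.chrom),
                                reference.end(tx.chrom))
    mutant = apply_indel(chrom_seq, indel, offset=reference.start(tx.chrom))
    delta = len(indel.alt_allele) - len(indel.ref_allele)
    s = tx.cds_start - reference.start(tx.chrom)
    e = tx.cds_end - reference.start(tx.chrom) + 1
    orig_cds = chrom_seq[s:e]
    mut_cds = mutant[s:e + delta]
    if tx.strand == "-":
        orig_cds, mut_cds = oracle_revcomp(orig_cds), oracle_revcomp(mut_cds)
    if indel.length % 3 != 0:
        return ("frameshift", None, "", "")
    orig = oracle_translate(orig_cds).rstrip("*")
    mut = oracle_translate(mut_cds)
    mut = mut[:-1] if mut.endswith("*") else mut
    if "*" in mut:
        return ("early_stop", None, "", "")
    p = 0
    while p < min(len(orig), len(mut)) and orig[p] == mut[p]:
        p += 1
    srt = 0
    while (srt < min(len(orig), len(mut)) - p
           and orig[len(orig) - 1 - srt] == mut[len(mut) - 1 - srt]):
        srt += 1
    deleted = orig[p:len(orig) - srt]
    inserted = mut[p:len(mut) - srt]
    if not deleted:
        a = max(p, 1)
        return ("aa_insertion", (a, a), inserted, "")
    if not inserted:
        return ("aa_deletion", (p + 1, len(orig) - srt), "", deleted)
    return ("block_substitution", (p + 1, len(orig) - srt), inserted, deleted)


@pytest.mark.parametrize("strand", ["+", "-"])
def test_consequences_match_translation_oracle(rng, strand):
    """1,000 random toy indels agree with the brute-force full-translation
    oracle on both strands, including category, residues and span."""
    for _ in range(500):
        n = int(rng.integers(8, 30))
        codons = ["ATG"] + random_codons(rng, n) + ["TAA"]
        ref, tx = make_gene(codons, strand=strand)
        cds_len = 3 * len(codons)
        if rng.random() < 0.5:  # insertion strictly inside the CDS
            pos = tx.cds_start + int(rng.integers(1, cds_len))
            seq = "".join(random_codons(rng, 1)) if rng.random() < 0.8 \
                else "TGA"
            indel = Indel(chrom="chrT", pos=pos, alt_allele=seq)
        else:  # deletion fully inside the CDS, not touching the stop codon
            # (the stop codon sits at the genomic end on +, start on -)
            length = int(rng.choice([3, 6]))
            lo = tx.cds_start + (3 if strand == "-" else 0)
            hi = tx.cds_end - length + 1 - (3 if strand == "+" else 0)
            pos = int(rng.integers(lo, hi))
            deleted = ref.fetch("chrT", pos, pos + length - 1)
            indel = Indel(chrom="chrT", pos=pos, ref_allele=deleted)
        got = classify_coding_consequence(indel, tx, ref)
        want = _oracle_consequence(ref, tx, indel)
        assert (got.category.value, got.affected_span,
                got.inserted_residues, got.deleted_residues) == want


def test_frameshift_iff_length_not_multiple_of_three(rng):
    ref, tx = make_gene(["ATG"] + ["GAA"] * 20 + ["TAA"])
    for length in range(1, 7):
        pos = tx.cds_start + 9
        indel = Indel(chrom="chrT", pos=pos,
                      ref_allele=ref.fetch("chrT", pos, pos + length - 1))
        cons = classify_coding_consequence(indel, tx, ref)
        assert (cons.category is ConsequenceCategory.FRAMESHIFT) == \
            (length % 3 != 0)


def test_round_trip_reported_residues_reapply(rng):
    """Applying the indel to the CDS and re-aligning recovers exactly the
    inserted/deleted residues the consequence reports."""
    for _ in range(200):
        codons = ["ATG"] + random_codons(rng, int(rng.integers(6, 20))) \
            + ["TAA"]
        ref, tx = make_gene(codons)
        k = int(rng.integers(1, len(codons) - 2))
        indel = Indel(chrom="chrT", pos=tx.cds_start + 3 * k,
                      alt_allele="".join(random_codons(rng, 1)))
        cons = classify_coding_consequence(indel, tx, ref)
        if cons.category is not ConsequenceCategory.AA_INSERTION:
            continue
        orig = oracle_translate("".join(codons)).rstrip("*")
        mut_cds = "".join(codons[:k]) + indel.alt_allele \
            + "".join(codons[k:])
        mut = oracle_translate(mut_cds).rstrip("*")
        assert len(mut) == len(orig) + 1
        a = cons.affected_span[0]
        rebuilt = mut[:a] + mut[a + 1:] if cons.pure_insertion else None
        assert rebuilt == orig


def test_thin_one_per_gene_keeps_first_by_genomic_order():
    entries = [
        ("gA", Indel(chrom="chr1", pos=500, alt_allele="CCC")),
        ("gA", Indel(chrom="chr1", pos=100, alt_allele="AAA")),
        ("gB", Indel(chrom="chr1", pos=300, ref_allele="TTT")),
    ]
    # fake ref alleles do not need a reference here
    kept = thin_one_per_gene(entries)
    assert [(i.pos) for i in kept] == [100, 300]
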