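"""Small exact tandem-repeat detection and indel left-normalization.

An indel is "in a repeat" when the indel sequence, or a part of it, tiles as
exact tandem copies across the indel itself and its contiguous flanking
reference sequence — e.g. the deletion CAT in ``ctcctc-CAT-catctg`` is a
repeat of (CAT)2, and the insertion CCC in ``atcgg-CCC-ccacc`` is a repeat
of (C)5.  Minimum repeat lengths are period-specific: 4 bases for
mononucleotide repeats, 6 for trinucleotide repeats, and max(4, 2*period)
in general (at least two full copies, at least 4 bases).

Because an indel inside a repeat can be placed at several coordinates that
all produce the same mutant sequence, indels are shifted to the leftmost
equivalent position before any position-dependent feature is computed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable

from .genomic_model import Indel, IndelKind, InputError

#: Default flank window (bases on each side) searched for tandem copies.
DEFAULT_FLANK_WINDOW = 50


@dataclass(frozen=True)
class RepeatCall:
    """Repeat context of one indel."""

    is_repeat: bool
    unit: str
    period: int
    copies: int

    @property
    def total_length(self) -> int:
        return self.period * self.copies


NO_REPEAT = RepeatCall(is_repeat=False, unit="", period=0, copies=0)


def minimum_repeat_length(period: int) -> int:
    """Minimum total repeat length for a given unit size (4 for period 1,
    6 for period 3, max(4, 2*period) otherwise)."""
    if period == 1:
        return 4
    if period == 3:
        return 6
    return max(4, 2 * period)


def find_repeat(indel_seq: str, left_flank: str, right_flank: str) -> RepeatCall:
    """Find the maximal exact tandem repeat spanning the indel.

    Every substring of ``indel_seq`` is a candidate unit; a candidate
    qualifies when its copies tile contiguously across the indel and the
    adjoining flank bases, with at least two copies and at least the
    period-specific minimum total length.  Among qualifying candidates the
    greatest total length wins; ties prefer the smallest period (so CCC in
    a C-run is called (C)5, not (CCC)1).
    """
    if not indel_seq:
        raise InputError("indel sequence must be non-empty")
    left = left_flank.upper()
    right = right_flank.upper()
    ind = indel_seq.upper()
    s = left + ind + right
    i_lo, i_hi = len(left), len(left) + len(ind)  # indel slice of s

    units = {ind[i:j] for i in range(len(ind))
             for j in range(i + 1, len(ind) + 1)}
    candidates: list[tuple[int, int, str, int]] = []
    for unit in sorted(units):
        p = len(unit)
        for start in range(len(s) - p + 1):
            if s[start:start + p] != unit:
                continue
            # extend the tandem run beginning at this start
            k = 1
            while s[start + k * p:start + (k + 1) * p] == unit:
                k += 1
            end = start + k * p
            if end > i_lo and start < i_hi:  # run overlaps the indel
                total = k * p
                if k >= 2 and total >= minimum_repeat_length(p):
                    candidates.append((total, p, unit, k))
    if not candidates:
        return NO_REPEAT
    # greatest total length; ties -> smallest period, then lexicographic unit
    total, p, unit, copies = min(candidates,
                                 key=lambda c: (-c[0], c[1], c[2]))
    return RepeatCall(is_repeat=True, unit=unit, period=p, copies=copies)


def repeat_flanks(indel: Indel, reference,
                  window: int = DEFAULT_FLANK_WINDOW) -> tuple[str, str]:
    """Reference bases immediately adjacent to the indel site.

    The left flank ends at ``pos - 1``; the right flank starts after the
    deleted window (for deletions) or at ``pos`` (for insertions).  Windows
    are clipped at the stored sequence bounds.
    """
    lo = max(reference.start(indel.chrom), indel.pos - window)
    left = (reference.fetch(indel.chrom, lo, indel.pos - 1)
            if indel.pos - 1 >= lo else "")
    r_start = indel.pos + len(indel.ref_allele)
    hi = min(reference.end(indel.chrom), r_start + window - 1)
    right = (reference.fetch(indel.chrom, r_start, hi)
             if r_start <= hi else "")
    return left, right


def call_repeat(indel: Indel, reference,
                window: int = DEFAULT_FLANK_WINDOW) -> RepeatCall:
    """Repeat context of a genomic indel (flanks taken from the reference)."""
    left, right = repeat_flanks(indel, reference, window)
    return find_repeat(indel.indel_seq, left, right)


def left_normalize(indel: Indel, reference) -> Indel:
    """Shift an indel to the leftmost position producing the same mutant
    sequence.

    The allele is rotated one base at a time while the reference base
    immediately left of the indel equals the allele's last base — the
    standard left-alignment of parsimonious indel representations.  The
    operation is idempotent and a no-op when no shift is possible; the
    returned indel carries ``normalized=True``.
    """
    pos = indel.pos
    allele = indel.indel_seq
    start = reference.start(indel.chrom)
    while pos > start and reference.base(indel.chrom, pos - 1) == allele[-1]:
        pos -= 1
        allele = allele[-1] + allele[:-1]
    if indel.kind is IndelKind.DELETION:
        return replace(indel, pos=pos, ref_allele=allele, normalized=True)
    return replace(indel, pos=pos, alt_allele=allele, normalized=True)


@dataclass(frozen=True)
class RepeatSummary:
    """Distribution of repeat periods, copy numbers and total lengths."""

    by_period_copies: tuple[tuple[tuple[int, int], int], ...]
    by_total_length: tuple[tuple[int, int], ...]
    fraction_period_divisible_by_3: float

    def total_length_histogram(self) -> dict[int, int]:
        return dict(self.by_total_length)

    def period_copies_histogram(self) -> dict[tuple[int, int], int]:
        return dict(self.by_period_copies)

    def modal_total_length(self) -> int:
        return max(self.by_total_length, key=lambda kv: (kv[1], -kv[0]))[0]


def repeat_length_distribution(calls: Iterable[RepeatCall]) -> RepeatSummary:
    """Summarise repeat calls: counts per (period, copies) and per total
    length (= period x copies), plus the fraction of repeat periods
    divisible by 3."""
    pc = Counter()
    tl = Counter()
    div3 = 0
    n = 0
    for call in calls:
        if not call.is_repeat:
            continue
        pc[(call.period, call.copies)] += 1
        tl[call.total_length] += 1
        div3 += call.period % 3 == 0
        n += 1
    if n == 0:
        raise InputError("no repeat calls to summarise")
    return RepeatSummary(
        by_period_copies=tuple(sorted(pc.items())),
        by_total_length=tuple(sorted(tl.items())),
        fraction_period_divisible_by_3=div3 / n)
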