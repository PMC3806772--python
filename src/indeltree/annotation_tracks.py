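"""Annotation resources consumed as files: protein-domain intervals,
disorder intervals, and per-base conservation scores.

Interval tracks are BED-like (3+ columns); protein-space BED uses the
protein/transcript id in column 1 and residue coordinates in columns 2-3
(0-based half-open).  Conservation scores are read from bedGraph (0-based
half-open) or fixed-step wiggle; internally positions are 1-based to match
the indel convention, and missing positions are distinguishable from a
score of 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .genomic_model import Indel, InputError


class TrackError(InputError):
    """Malformed annotation-track input."""


# --------------------------------------------------------------------------
# Interval tracks
# --------------------------------------------------------------------------

@dataclass
class IntervalTrack:
    """A named set of half-open intervals keyed by sequence id."""

    name: str
    coordinate_space: str  # "protein" | "genome"
    _trees: dict[str, IntervalTree] = field(default_factory=dict)

    def add(self, seq_id: str, start: int, end: int) -> None:
        if end <= start:
            raise TrackError(
                f"interval end {end} <= start {start} on {seq_id}")
        tree = self._trees.setdefault(seq_id, IntervalTree())
        # unique payload: identical coordinates stay distinct instances
        tree.addi(start, end, len(tree))

    def n_intervals(self, seq_id: str) -> int:
        tree = self._trees.get(seq_id)
        return len(tree) if tree else 0

    def intervals(self, seq_id: str) -> list[tuple[int, int]]:
        tree = self._trees.get(seq_id)
        return sorted((iv.begin, iv.end) for iv in tree) if tree else []

    def overlapping(self, seq_id: str, start: int, end: int) -> int:
        """Count intervals on ``seq_id`` overlapping [start, end)."""
        tree = self._trees.get(seq_id)
        return len(tree.overlap(start, end)) if tree else 0

    def covered_length(self, seq_id: str, start: int, end: int) -> int:
        """Length of the union of intervals intersected with [start, end)."""
        tree = self._trees.get(seq_id)
        if not tree:
            return 0
        pieces = sorted((max(iv.begin, start), min(iv.end, end))
                        for iv in tree.overlap(start, end))
        covered = 0
        cur_end = start
        for b, e in pieces:
            if e > cur_end:
                covered += e - max(b, cur_end)
                cur_end = e
        return covered


def load_interval_track(path: str, coordinate_space: str,
                        name: str | None = None) -> IntervalTrack:
    """Load a 3+ column BED-like file into an :class:`IntervalTrack`."""
    if coordinate_space not in ("protein", "genome"):
        raise TrackError(f"unknown coordinate space {coordinate_space!r}")
    track = IntervalTrack(name=name or str(path),
                          coordinate_space=coordinate_space)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise TrackError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise TrackError(
                    f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                track.add(cols[0], start, end)
            except TrackError as exc:
                raise TrackError(f"{path}:{lineno}: {exc}") from exc
    return track


def fraction_domains_affected(span: tuple[int, int], protein_id: str,
                              domains: IntervalTrack) -> float:
    """Fraction of this protein's domain intervals overlapping ``span``.

    ``span`` is 1-based inclusive residue coordinates.  A protein with no
    annotated domains yields 0.0 (so rules conditioned on "no domain
    affected" fire for domain-less proteins).
    """
    if domains.coordinate_space != "protein":
        raise TrackError("domain track must be in protein coordinates")
    total = domains.n_intervals(protein_id)
    if total == 0:
        return 0.0
    hit = domains.overlapping(protein_id, span[0] - 1, span[1])
    return hit / total


def in_disordered_region(span: tuple[int, int], protein_id: str,
                         disorder: IntervalTrack) -> bool:
    """True iff strictly more than half of the span's residues lie inside
    disorder intervals."""
    if disorder.coordinate_space != "protein":
        raise TrackError("disorder track must be in protein coordinates")
    n_res = span[1] - span[0] + 1
    covered = disorder.covered_length(protein_id, span[0] - 1, span[1])
    return covered * 2 > n_res


# --------------------------------------------------------------------------
# Score tracks
# --------------------------------------------------------------------------

@dataclass
class ScoreTrack:
    """Per-base scores keyed by (chromosome, 1-based position)."""

    name: str
    _scores: dict[tuple[str, int], float] = field(default_factory=dict)

    def set(self, chrom: str, pos: int, score: float) -> None:
        self._scores[(chrom, pos)] = score

    def get(self, chrom: str, pos: int) -> float | None:
        """Score at a position, or None when absent (never silently 0)."""
        return self._scores.get((chrom, pos))

    def __len__(self) -> int:
        return len(self._scores)


def load_bedgraph(path: str, name: str | None = None) -> ScoreTrack:
    """bedGraph: chrom, start, end (0-based half-open), value."""
    track = ScoreTrack(name=name or str(path))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 4:
                raise TrackError(
                    f"{path}:{lineno}: expected 4 columns in bedGraph")
            try:
                start, end, value = int(cols[1]), int(cols[2]), float(cols[3])
            except ValueError as exc:
                raise TrackError(f"{path}:{lineno}: bad bedGraph line") from exc
            if end <= start:
                raise TrackError(f"{path}:{lineno}: end <= start")
            for pos0 in range(start, end):
                track.set(cols[0], pos0 + 1, value)
    return track


def load_wiggle(path: str, name: str | None = None) -> ScoreTrack:
    """Fixed-step wiggle (``fixedStep chrom=... start=... step=...``);
    wiggle start coordinates are 1-based."""
    track = ScoreTrack(name=name or str(path))
    chrom, pos, step = None, None, 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=", 1) for kv in line.split()[1:])
                try:
                    chrom = fields["chrom"]
                    pos = int(fields["start"])
                    step = int(fields.get("step", 1))
                except (KeyError, ValueError) as exc:
                    raise TrackError(
                        f"{path}:{lineno}: bad fixedStep header") from exc
                continue
            if line.startswith("variableStep"):
                raise TrackError(
                    f"{path}:{lineno}: variableStep wiggle not supported")
            if chrom is None:
                raise TrackError(
                    f"{path}:{lineno}: data before fixedStep header")
            try:
                track.set(chrom, pos, float(line))
            except ValueError as exc:
                raise TrackError(f"{path}:{lineno}: bad value") from exc
            pos += step
    return track


def load_score_track(path: str, name: str | None = None) -> ScoreTrack:
    """Auto-detect bedGraph vs fixed-step wiggle by content."""
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            if stripped.startswith(("fixedStep", "variableStep")):
                return load_wiggle(path, name)
            return load_bedgraph(path, name)
    return ScoreTrack(name=name or str(path))


def left_flank_conservation(indel: Indel, cons: ScoreTrack) -> float | None:
    """Conservation score of the DNA base immediately 5' (left) of the
    allele of a *left-normalized* indel; None when the score is missing or
    the position falls off the chromosome start."""
    if not indel.normalized:
        raise InputError(
            "indel must be left-normalized before the conservation lookup "
            "(coordinates in repeats are ambiguous until shifted left)")
    if indel.pos - 1 < 1:
        return None
    return cons.get(indel.chrom, indel.pos - 1)
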