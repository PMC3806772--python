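"""Self-contained synthetic inputs for every pipeline stage.

The generator emits a toy genome (single-exon genes on one synthetic
chromosome), gene models, protein-space domain and disorder tracks, a
per-base conservation track, and a labeled set of 3n coding indels with
*planted* rule structure:

* each protein is laid out into zones — a domain zone (two domain
  intervals), a disordered zone, and an ordered domain-free zone;
* damaging indels are planted in domains, in repeats, or at conserved
  flanking bases; neutral indels in disordered regions, at non-conserved
  flanking bases, or (at the neutral repeat rate) in repeats inside the
  disordered zone;
* repeat indels are codon duplications (insertion of an identical codon),
  which small-exact-repeat detection recovers with recall 1;
* conservation scores are drawn from class-conditional Gaussians that
  straddle the published 1.405 threshold; in the two strata where the
  threshold decides the class, draws are truncated away from the
  threshold so the planted feature-to-label map is deterministic.

The true label is therefore a deterministic function of the four core
features; the label-noise rate flips observed labels symmetrically, so the
best achievable (Bayes) accuracy is ``1 - noise`` in closed form.  A seed
fully determines the output bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_model import (Indel, InMemoryReference, TranscriptModel,
                            classify_coding_consequence, ConsequenceCategory)
from .repeat_detector import call_repeat, left_normalize
from .feature_extraction import AnnotationBundle, extract_matrix
from .annotation_tracks import load_interval_track, load_score_track

#: Conservation gap around the 1.405 rule threshold: in the strata where
#: conservation decides the planted class, neutral draws are truncated to
#: <= CONS_GAP[0] and damaging draws to >= CONS_GAP[1].  The wide gap keeps
#: data-driven split thresholds inside it, so held-out samples are always
#: on the correct side.
CONS_GAP = (1.0, 1.8)

_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA"))

STRATA_DAMAGING = ("pfam_ordered", "pfam_ordered_repeat", "repeat_ordered",
                   "conserved_ordered")
STRATA_NEUTRAL = ("disordered", "repeat_disordered", "nonconserved_ordered")


class FixtureError(ValueError):
    """An infeasible fixture specification."""


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic study: sizes, planting rates, distributions.

    ``repeat_rate_*`` are the class-conditional fractions of indels planted
    inside small exact repeats (defaults mirror the observed 43% disease
    vs 11% neutral split).  ``cons_*`` are (mean, sd) of the per-class
    conservation-score Gaussians.  ``noise`` is the symmetric label-flip
    rate controlling the Bayes accuracy.
    """

    n_genes: int = 40
    n_damaging: int = 474
    n_neutral: int = 474
    repeat_rate_damaging: float = 0.43
    repeat_rate_neutral: float = 0.11
    cons_damaging: tuple[float, float] = (2.3, 0.45)
    cons_neutral: tuple[float, float] = (0.6, 0.45)
    noise: float = 0.0
    seed: int = 0
    chrom: str = "chrS"
    gene_codons: tuple[int, int] = (400, 900)

    def __post_init__(self):
        for name in ("repeat_rate_damaging", "repeat_rate_neutral", "noise"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise FixtureError(f"{name} must be in [0, 1], got {val}")
        if self.n_genes < 1 or self.n_damaging < 0 or self.n_neutral < 0:
            raise FixtureError("counts must be positive")
        if self.gene_codons[0] < 60:
            raise FixtureError("genes need at least 60 codons for zone "
                               "layout")


def planted_bayes_accuracy(spec: FixtureSpec) -> float:
    """Best achievable accuracy under the planted distributions.

    Features determine the pre-noise label exactly, and observed labels are
    a symmetric flip at rate ``noise``; the Bayes-optimal classifier
    predicts the majority (pre-noise) label, achieving ``1 - noise`` (or
    ``noise`` when the flip rate exceeds one half).
    """
    return max(1.0 - spec.noise, spec.noise)


# --------------------------------------------------------------------------
# Gene layout
# --------------------------------------------------------------------------

@dataclass
class _Gene:
    transcript_id: str
    gene_id: str
    start: int           # 1-based genomic start of ATG
    codons: list[str]    # ATG + body + stop
    domain1: tuple[int, int]
    domain2: tuple[int, int]
    disorder: tuple[int, int]
    pools: dict[str, list[int]] = field(default_factory=dict)

    @property
    def cds_start(self) -> int:
        return self.start

    @property
    def cds_end(self) -> int:
        return self.start + 3 * len(self.codons) - 1

    @property
    def protein_length(self) -> int:
        return len(self.codons) - 1

    def codon_start(self, residue: int) -> int:
        """Genomic start of the codon encoding 1-based ``residue``."""
        return self.start + 3 * (residue - 1)

    def transcript(self, chrom: str) -> TranscriptModel:
        return TranscriptModel(
            transcript_id=self.transcript_id, chrom=chrom, strand="+",
            exons=((self.start, self.cds_end),),
            cds_start=self.start, cds_end=self.cds_end)


def _layout_genes(spec: FixtureSpec, rng: np.random.Generator
                  ) -> tuple[str, list[_Gene]]:
    chrom_parts: list[str] = []
    genes: list[_Gene] = []
    cursor = 1
    for g in range(spec.n_genes):
        spacer = "".join(rng.choice(list("ACGT"), size=100))
        chrom_parts.append(spacer)
        cursor += len(spacer)
        n_body = int(rng.integers(spec.gene_codons[0], spec.gene_codons[1]))
        body = [_SENSE_CODONS[i]
                for i in rng.integers(0, len(_SENSE_CODONS), size=n_body)]
        codons = ["ATG"] + body + ["TAA"]
        length = len(codons) - 1  # residues
        dom1 = (max(2, round(0.10 * length)), round(0.30 * length))
        dom2 = (round(0.34 * length), round(0.42 * length))
        dis = (round(0.50 * length), round(0.78 * length))
        free = (round(0.84 * length), length - 2)
        gene = _Gene(
            transcript_id=f"TX{g:04d}", gene_id=f"G{g:04d}",
            start=cursor, codons=codons, domain1=dom1, domain2=dom2,
            disorder=dis)
        gene.pools = {
            "domain": list(range(dom1[0] + 3, dom1[1] - 2, 4)),
            "disorder": list(range(dis[0] + 3, dis[1] - 2, 4)),
            "free": list(range(free[0] + 3, free[1] - 2, 4)),
        }
        genes.append(gene)
        chrom_parts.append("".join(codons))
        cursor += 3 * len(codons)
    chrom_parts.append("".join(rng.choice(list("ACGT"), size=100)))
    return "".join(chrom_parts), genes


_ZONE_OF_STRATUM = {
    "pfam_ordered": "domain", "pfam_ordered_repeat": "domain",
    "repeat_ordered": "free", "conserved_ordered": "free",
    "disordered": "disorder", "repeat_disordered": "disorder",
    "nonconserved_ordered": "free",
}


def _assign_strata(spec: FixtureSpec, rng: np.random.Generator
                   ) -> list[tuple[str, str]]:
    """(class, stratum) per indel, honouring the repeat planting rates."""
    out: list[tuple[str, str]] = []
    for _ in range(spec.n_damaging):
        if rng.random() < spec.repeat_rate_damaging:
            stratum = ("pfam_ordered_repeat" if rng.random() < 0.5
                       else "repeat_ordered")
        else:
            stratum = ("pfam_ordered" if rng.random() < 0.85
                       else "conserved_ordered")
        out.append(("damaging", stratum))
    for _ in range(spec.n_neutral):
        if rng.random() < spec.repeat_rate_neutral:
            stratum = "repeat_disordered"
        else:
            stratum = "disordered" if rng.random() < 0.8 \
                else "nonconserved_ordered"
        out.append(("neutral", stratum))
    return out


def _draw_conservation(stratum: str, truth: str, spec: FixtureSpec,
                       rng: np.random.Generator) -> float:
    """Class-conditional conservation score.

    Draws are truncated away from the rule threshold class-wide (damaging
    >= CONS_GAP[1], neutral <= CONS_GAP[0]) so the planted label is a
    deterministic function of the features with a wide margin: any
    data-driven split threshold between observed values falls inside the
    gap and held-out samples always land on the correct side.
    """
    mean, sd = (spec.cons_damaging if truth == "damaging"
                else spec.cons_neutral)
    lo, hi = (CONS_GAP[1], np.inf) if truth == "damaging" \
        else (-np.inf, CONS_GAP[0])
    for _ in range(10000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise FixtureError(
        f"conservation distribution for class {truth} places no mass in "
        f"[{lo}, {hi}]")


# --------------------------------------------------------------------------
# Indel planting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedIndel:
    indel: Indel
    transcript_id: str
    stratum: str
    truth: str   # pre-noise class
    label: str   # observed class after label noise
    kind: str    # insertion | deletion
    conservation: float


def _is_repeat_when_normalized(indel: Indel, reference) -> bool:
    # repeat status is judged at the left-normalized placement, matching
    # the feature pipeline (a repeat can hide behind a rotated allele)
    return call_repeat(left_normalize(indel, reference), reference).is_repeat


def _plant_one(gene: _Gene, residue: int, want_repeat: bool,
               reference: InMemoryReference,
               rng: np.random.Generator) -> Indel | None:
    """Plant a 3n indel at a codon boundary; None when the site cannot
    host the requested repeat status."""
    pos = gene.codon_start(residue)
    if want_repeat:
        # duplicate the resident codon: always a tandem repeat of >= 6 bases
        indel = Indel(chrom=reference.chroms()[0], pos=pos,
                      alt_allele=gene.codons[residue - 1])
        assert _is_repeat_when_normalized(indel, reference)
        return indel
    # non-repeat plant: insertion of a foreign codon, or codon deletion
    if rng.random() < 0.5:
        for _ in range(40):
            codon = _SENSE_CODONS[int(rng.integers(0, len(_SENSE_CODONS)))]
            indel = Indel(chrom=reference.chroms()[0], pos=pos,
                          alt_allele=codon)
            if not _is_repeat_when_normalized(indel, reference):
                return indel
        return None
    indel = Indel(chrom=reference.chroms()[0], pos=pos,
                  ref_allele=gene.codons[residue - 1])
    if _is_repeat_when_normalized(indel, reference):
        return None
    return indel


def _plant_indels(spec: FixtureSpec, genes: list[_Gene],
                  reference: InMemoryReference,
                  rng: np.random.Generator) -> list[PlantedIndel]:
    assignments = _assign_strata(spec, rng)
    # demand vs pool capacity, exact after stratum assignment
    demand: dict[str, int] = {}
    for _, stratum in assignments:
        demand[_ZONE_OF_STRATUM[stratum]] = \
            demand.get(_ZONE_OF_STRATUM[stratum], 0) + 1
    capacity = {zone: sum(len(g.pools[zone]) for g in genes)
                for zone in ("domain", "disorder", "free")}
    for zone, need in demand.items():
        if need > capacity[zone]:
            raise FixtureError(
                f"{need} indels requested in the {zone} zone but only "
                f"{capacity[zone]} sites available; increase n_genes or "
                "gene sizes")

    # shuffled global site lists per zone
    sites: dict[str, list[tuple[int, int]]] = {}
    for zone in ("domain", "disorder", "free"):
        pool = [(gi, r) for gi, g in enumerate(genes) for r in g.pools[zone]]
        order = rng.permutation(len(pool))
        sites[zone] = [pool[i] for i in order]

    zone_interval = {
        "domain": lambda g: g.domain1,
        "disorder": lambda g: g.disorder,
        "free": lambda g: (round(0.84 * g.protein_length),
                           g.protein_length - 2),
    }
    used_cons_positions: set[int] = set()
    planted: list[PlantedIndel] = []
    for truth, stratum in assignments:
        zone = _ZONE_OF_STRATUM[stratum]
        want_repeat = "repeat" in stratum
        accepted: Indel | None = None
        gene: _Gene | None = None
        while sites[zone]:
            gi, residue = sites[zone].pop()
            gene = genes[gi]
            indel = _plant_one(gene, residue, want_repeat, reference, rng)
            if indel is None:
                continue
            norm = left_normalize(indel, reference)
            # must stay past the start codon and on a fresh 5' flanking base
            if norm.pos < gene.start + 3 or \
                    norm.pos - 1 in used_cons_positions:
                continue
            cons = classify_coding_consequence(
                norm, gene.transcript(norm.chrom), reference)
            if cons.category not in (ConsequenceCategory.AA_INSERTION,
                                     ConsequenceCategory.AA_DELETION):
                continue
            # identical-residue runs can drift the affected span; keep
            # only plants whose span stays inside the intended zone
            span = cons.affected_span
            lo, hi = zone_interval[zone](gene)
            if span is None or span[0] < lo or span[1] > hi:
                continue
            used_cons_positions.add(norm.pos - 1)
            accepted = indel
            break
        if accepted is None or gene is None:
            raise FixtureError(
                f"ran out of plantable {zone} sites for stratum {stratum}")
        score = _draw_conservation(stratum, truth, spec, rng)
        label = truth
        if rng.random() < spec.noise:
            label = "neutral" if truth == "damaging" else "damaging"
        planted.append(PlantedIndel(
            indel=accepted, transcript_id=gene.transcript_id,
            stratum=stratum, truth=truth, label=label,
            kind=accepted.kind.value, conservation=score))
    return planted


# --------------------------------------------------------------------------
# File bundle
# --------------------------------------------------------------------------

BUNDLE_FILES = ("reference.fa", "genes.gtf", "domains.bed", "disorder.bed",
                "conservation.bedgraph", "indels.vcf", "labels.tsv",
                "manifest.json")


@dataclass(frozen=True)
class FixtureBundle:
    """Paths of a generated fixture plus convenience loaders."""

    directory: Path
    spec: FixtureSpec

    def path(self, name: str) -> Path:
        return self.directory / name

    def reference(self) -> InMemoryReference:
        from .genomic_model import FastaReference
        return FastaReference(str(self.path("reference.fa")))

    def transcripts(self) -> dict[str, TranscriptModel]:
        from .genomic_model import load_transcripts
        transcripts, rejected = load_transcripts(str(self.path("genes.gtf")))
        if rejected:
            raise FixtureError(f"fixture GTF contains invalid transcripts: "
                               f"{rejected}")
        return transcripts

    def tracks(self) -> AnnotationBundle:
        return AnnotationBundle(
            domains=load_interval_track(str(self.path("domains.bed")),
                                        "protein", name="domains"),
            disorder=load_interval_track(str(self.path("disorder.bed")),
                                         "protein", name="disorder"),
            conservation=load_score_track(
                str(self.path("conservation.bedgraph")), name="conservation"))

    def labels_frame(self) -> pd.DataFrame:
        return pd.read_csv(self.path("labels.tsv"), sep="\t")

    def indels(self) -> list[tuple[Indel, str]]:
        """(indel, transcript_id) pairs reconstructed from the label table."""
        out = []
        for row in self.labels_frame().itertuples():
            out.append((Indel(
                chrom=row.chrom, pos=int(row.pos),
                ref_allele="" if row.ref == "-" else row.ref,
                alt_allele="" if row.alt == "-" else row.alt),
                row.transcript_id))
        return out

    def feature_matrix(self, registry=None
                       ) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
        """Extract features for every planted indel.

        Returns ``(X, labels, kinds)`` aligned on indel id; labels are the
        observed (post-noise) classes.
        """
        reference = self.reference()
        transcripts = self.transcripts()
        tracks = self.tracks()
        frame = self.labels_frame()
        entries = [(indel, transcripts[tid])
                   for indel, tid in self.indels()]
        X = extract_matrix(entries, reference, tracks, registry)
        labels = pd.Series(frame["label"].to_numpy(), index=X.index,
                           name="label")
        kinds = pd.Series(frame["kind"].to_numpy(), index=X.index,
                          name="kind")
        return X, labels, kinds


def generate_fixture(spec: FixtureSpec, outdir) -> FixtureBundle:
    """Generate the full file bundle for ``spec`` under ``outdir``.

    Identical spec + seed produce byte-identical files; the manifest
    records the spec and per-file SHA-256 hashes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    chrom_seq, genes = _layout_genes(spec, rng)
    reference = InMemoryReference({spec.chrom: chrom_seq})
    planted = _plant_indels(spec, genes, reference, rng)

    _write_fasta(outdir / "reference.fa", spec.chrom, chrom_seq)
    _write_gtf(outdir / "genes.gtf", spec.chrom, genes)
    _write_domains(outdir / "domains.bed", genes)
    _write_disorder(outdir / "disorder.bed", genes)
    _write_conservation(outdir / "conservation.bedgraph", spec.chrom,
                        planted, reference)
    _write_vcf(outdir / "indels.vcf", spec.chrom, len(chrom_seq), planted,
               reference)
    _write_labels(outdir / "labels.tsv", planted, reference)

    manifest = {
        "spec": dataclasses.asdict(spec),
        "seed": spec.seed,
        "n_indels": len(planted),
        "files": {name: _sha256(outdir / name)
                  for name in BUNDLE_FILES if name != "manifest.json"},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return FixtureBundle(directory=outdir, spec=spec)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_fasta(path: Path, chrom: str, seq: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i:i + 60] + "\n")


def _write_gtf(path: Path, chrom: str, genes: list[_Gene]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = (f'gene_id "{g.gene_id}"; '
                     f'transcript_id "{g.transcript_id}";')
            for feat in ("gene", "transcript", "exon", "CDS"):
                fh.write("\t".join([
                    chrom, "indeltree_synthetic", feat, str(g.start),
                    str(g.cds_end), ".", "+", "0", attrs]) + "\n")


def _write_domains(path: Path, genes: list[_Gene]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for i, (s, e) in enumerate((g.domain1, g.domain2), start=1):
                fh.write(f"{g.transcript_id}\t{s - 1}\t{e}\tSYNDOM{i}\n")


def _write_disorder(path: Path, genes: list[_Gene]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            s, e = g.disorder
            fh.write(f"{g.transcript_id}\t{s - 1}\t{e}\tdisorder\n")


def _write_conservation(path: Path, chrom: str, planted, reference) -> None:
    rows = []
    for p in planted:
        norm = left_normalize(p.indel, reference)
        rows.append((norm.pos - 1, p.conservation))
    rows.sort()
    with open(path, "w") as fh:
        for pos, score in rows:
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{score:.4f}\n")


def _write_vcf(path: Path, chrom: str, chrom_len: int, planted,
               reference) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={chrom_len}>\n")
        fh.write('##INFO=<ID=TX,Number=1,Type=String,'
                 'Description="Transcript id">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        recs = []
        for p in planted:
            ind = p.indel
            anchor = reference.base(chrom, ind.pos - 1)
            if ind.ref_allele:  # deletion
                ref, alt = anchor + ind.ref_allele, anchor
            else:
                ref, alt = anchor, anchor + ind.alt_allele
            recs.append((ind.pos - 1, ref, alt, p.transcript_id))
        recs.sort()
        for pos, ref, alt, tid in recs:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t"
                     f"TX={tid}\n")


def _write_labels(path: Path, planted, reference) -> None:
    # rows are keyed by the *normalized* indel id, matching the id the
    # feature-extraction pipeline assigns after left-shifting
    with open(path, "w") as fh:
        fh.write("indel_id\tchrom\tpos\tref\talt\ttranscript_id\tkind\t"
                 "stratum\ttruth\tlabel\n")
        for p in planted:
            ind = p.indel
            norm_id = left_normalize(ind, reference).indel_id
            fh.write("\t".join([
                norm_id, ind.chrom, str(ind.pos),
                ind.ref_allele or "-", ind.alt_allele or "-",
                p.transcript_id, p.kind, p.stratum, p.truth, p.label,
            ]) + "\n")
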