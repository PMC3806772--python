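"""Per-indel feature vectors.

Four features drive the shipped classifier, in the order they were found
informative: the fraction of the protein's domain intervals affected,
whether the indel resides in a small exact repeat, whether the affected
residues lie in a disordered region, and the conservation score of the DNA
base immediately 5' of the (left-normalized) allele.  An extensible
registry supports additional features such as physiochemical deltas of the
inserted/deleted residues.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import pandas as pd

from .genomic_model import (IN_SCOPE_CATEGORIES, Indel, ProteinConsequence,
                            ScopeError, TranscriptModel,
                            classify_coding_consequence)
from .annotation_tracks import (IntervalTrack, ScoreTrack,
                                fraction_domains_affected,
                                in_disordered_region,
                                left_flank_conservation)
from .repeat_detector import (DEFAULT_FLANK_WINDOW, RepeatCall, call_repeat,
                              left_normalize)

logger = logging.getLogger(__name__)

#: The mandatory feature schema, in selection order.
CORE_FEATURES = ("pfam_fraction_affected", "in_repeat", "in_disorder",
                 "left_base_conservation")


class RegistryError(ValueError):
    """Duplicate or unknown feature registration."""


class ConfigurationError(ValueError):
    """A required annotation track or feature is missing."""


@dataclass(frozen=True)
class AnnotationBundle:
    """The annotation resources feature extraction consumes."""

    domains: IntervalTrack
    disorder: IntervalTrack
    conservation: ScoreTrack

    def validate(self) -> None:
        for attr in ("domains", "disorder", "conservation"):
            if getattr(self, attr) is None:
                raise ConfigurationError(f"missing annotation track: {attr}")


@dataclass(frozen=True)
class FeatureContext:
    """Everything a registered feature extractor may inspect."""

    indel: Indel
    transcript: TranscriptModel
    consequence: ProteinConsequence
    span: tuple[int, int]
    repeat: RepeatCall
    reference: object
    tracks: AnnotationBundle


FeatureExtractor = Callable[[FeatureContext], float]


@dataclass
class FeatureRegistry:
    """Optional named features, applied after the core four."""

    _extractors: dict[str, FeatureExtractor] = field(default_factory=dict)

    def register(self, name: str, extractor: FeatureExtractor) -> None:
        if name in self._extractors or name in CORE_FEATURES:
            raise RegistryError(f"feature name {name!r} already registered")
        self._extractors[name] = extractor

    def names(self) -> tuple[str, ...]:
        return tuple(self._extractors)

    def items(self):
        return self._extractors.items()

    def __len__(self) -> int:
        return len(self._extractors)


@dataclass(frozen=True)
class FeatureVector:
    """Named feature values for one indel; the four core features are
    always present (conservation may be missing, carried as NaN)."""

    indel_id: str
    values: Mapping[str, float]

    @property
    def schema(self) -> tuple[str, ...]:
        return tuple(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def extract_features(indel: Indel, tx: TranscriptModel, reference,
                     tracks: AnnotationBundle,
                     registry: FeatureRegistry | None = None,
                     repeat_window: int = DEFAULT_FLANK_WINDOW,
                     ) -> FeatureVector:
    """Assemble the feature vector for one 3n indel.

    The indel is left-normalized first (coordinates inside repeats are
    otherwise ambiguous), so two variant-file representations of the same
    physical indel yield byte-identical vectors.  Indels whose consequence
    is an early stop or frameshift are out of scope and raise
    :class:`ScopeError`.
    """
    tracks.validate()
    if not indel.normalized:
        indel = left_normalize(indel, reference)
    cons = classify_coding_consequence(indel, tx, reference)
    if cons.category not in IN_SCOPE_CATEGORIES:
        raise ScopeError(
            f"{cons.category.value} indel {indel.indel_id} is outside the "
            "amino-acid-indel method")
    span = cons.affected_span
    assert span is not None
    repeat = call_repeat(indel, reference, window=repeat_window)

    score = left_flank_conservation(indel, tracks.conservation)
    if score is None:
        logger.info("missing conservation score left of %s; the published "
                    "rules treat it as not conserved", indel.indel_id)

    values: dict[str, float] = {
        "pfam_fraction_affected": fraction_domains_affected(
            span, tx.transcript_id, tracks.domains),
        "in_repeat": float(repeat.is_repeat),
        "in_disorder": float(in_disordered_region(
            span, tx.transcript_id, tracks.disorder)),
        "left_base_conservation": math.nan if score is None else score,
    }
    if registry is not None:
        ctx = FeatureContext(indel=indel, transcript=tx, consequence=cons,
                             span=span, repeat=repeat, reference=reference,
                             tracks=tracks)
        for name, extractor in registry.items():
            values[name] = float(extractor(ctx))
    return FeatureVector(indel_id=indel.indel_id, values=values)


def extract_matrix(entries: Iterable[tuple[Indel, TranscriptModel]],
                   reference, tracks: AnnotationBundle,
                   registry: FeatureRegistry | None = None,
                   repeat_window: int = DEFAULT_FLANK_WINDOW) -> pd.DataFrame:
    """Feature matrix (rows = indel ids, columns = schema) for a batch."""
    vectors = [extract_features(i, t, reference, tracks, registry,
                                repeat_window) for i, t in entries]
    return vectors_to_frame(vectors)


def vectors_to_frame(vectors: Iterable[FeatureVector]) -> pd.DataFrame:
    vectors = list(vectors)
    if not vectors:
        return pd.DataFrame(columns=list(CORE_FEATURES))
    schema = vectors[0].schema
    for v in vectors:
        if v.schema != schema:
            raise ConfigurationError(
                "feature vectors from one extraction run must share an "
                f"identical schema ({v.indel_id} differs)")
    frame = pd.DataFrame([dict(v.values) for v in vectors],
                         index=[v.indel_id for v in vectors])
    frame.index.name = "indel_id"
    return frame


def write_feature_matrix(frame: pd.DataFrame, path: str) -> None:
    frame.to_csv(path, sep="\t", na_rep="NA")


def read_feature_matrix(path: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col="indel_id",
                        na_values=["NA"])
    return frame


# --------------------------------------------------------------------------
# Physiochemical registry features
# --------------------------------------------------------------------------
# Scales are package choices: Kyte-Doolittle hydropathy, average residue
# masses (Da), and Zamyatnin residue volumes (A^3).

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

RESIDUE_MASS = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "Q": 128.13, "E": 129.12, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}

RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}


def _scale_delta(scale: Mapping[str, float]) -> FeatureExtractor:
    def extractor(ctx: FeatureContext) -> float:
        ins = sum(scale.get(a, 0.0) for a in ctx.consequence.inserted_residues)
        dele = sum(scale.get(a, 0.0) for a in ctx.consequence.deleted_residues)
        return ins - dele
    return extractor


def physiochemical_registry() -> FeatureRegistry:
    """Registry of inserted-minus-deleted physiochemical deltas."""
    reg = FeatureRegistry()
    reg.register("hydrophobicity_delta", _scale_delta(KYTE_DOOLITTLE))
    reg.register("residue_mass_delta", _scale_delta(RESIDUE_MASS))
    reg.register("residue_volume_delta", _scale_delta(RESIDUE_VOLUME))
    return reg
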