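"""Genome annotations for the footprinting pipeline.

Coordinates are 0-based, half-open throughout. A :class:`GenomeAnnotation`
carries the features the analysis anchors on (silencers, promoters, telomeric
TG repeats and X elements, boundary elements, control regions), nucleosome
dyad positions, and the per-strand adenine positions that are eligible for
m6A methylation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

FEATURE_KINDS = frozenset(
    {
        "silencer",
        "promoter",
        "tg_repeat",
        "x_element",
        "boundary",
        "gene_body",
        "control_region",
    }
)

#: Feature kinds that nucleate protein recruitment (sequence-specific binding).
RECRUITMENT_KINDS = frozenset({"silencer", "promoter", "tg_repeat", "x_element"})

MIN_DYAD_SPACING = 100


def derive_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic child RNG for a (seed, purpose-label) pair.

    All randomness in the package flows through one top-level seed; substreams
    are derived by hashing the purpose label (crc32, platform-stable) into a
    :class:`numpy.random.SeedSequence` spawn key.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


@dataclass(frozen=True)
class Feature:
    """A half-open genomic interval with a functional kind."""

    contig: str
    start: int
    end: int
    strand: str
    kind: str
    name: str = ""

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Contigs, features, nucleosome dyads and adenine positions.

    Parameters
    ----------
    contigs
        Mapping of contig name to length in bp.
    features
        Features, each within its contig's bounds.
    nucleosome_dyads
        Mapping of contig name to a sorted array of dyad positions, pairwise
        at least 100 bp apart.
    adenines
        Mapping of (contig, strand) to a sorted array of adenine positions.
    """

    contigs: dict[str, int]
    features: list[Feature] = field(default_factory=list)
    nucleosome_dyads: dict[str, np.ndarray] = field(default_factory=dict)
    adenines: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for feat in self.features:
            if feat.contig not in self.contigs:
                raise ValueError(f"feature on unknown contig {feat.contig!r}")
            if feat.end > self.contigs[feat.contig]:
                raise ValueError(
                    f"feature [{feat.start}, {feat.end}) exceeds {feat.contig} length"
                )
        self.features.sort(key=lambda f: (f.contig, f.start, f.end, f.kind))
        for contig, dyads in self.nucleosome_dyads.items():
            dyads = np.asarray(dyads, dtype=np.int64)
            if dyads.size and not np.all(np.diff(dyads) >= MIN_DYAD_SPACING):
                raise ValueError(f"dyads on {contig} closer than {MIN_DYAD_SPACING} bp")
            self.nucleosome_dyads[contig] = dyads
        for key, pos in self.adenines.items():
            pos = np.asarray(pos, dtype=np.int64)
            if pos.size and not np.all(np.diff(pos) > 0):
                raise ValueError(f"adenine positions for {key} not strictly sorted")
            self.adenines[key] = pos

    def require_contig(self, contig: str) -> int:
        if contig not in self.contigs:
            raise KeyError(f"unknown contig {contig!r}")
        return self.contigs[contig]

    def features_on(self, contig: str, kind: str | None = None) -> list[Feature]:
        return [
            f
            for f in self.features
            if f.contig == contig and (kind is None or f.kind == kind)
        ]

    def adenines_on(self, contig: str, strand: str) -> np.ndarray:
        return self.adenines.get((contig, strand), np.empty(0, dtype=np.int64))


def random_adenines(
    length: int, density: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample adenine positions as a Bernoulli(density) mask over [0, length)."""
    if not 0 < density <= 1:
        raise ValueError("adenine density must be in (0, 1]")
    return np.flatnonzero(rng.random(length) < density).astype(np.int64)


def make_annotation(
    contigs: dict[str, int],
    features: list[Feature] | None = None,
    dyad_spacing: dict[str, int] | None = None,
    adenine_density: float = 0.31,
    seed: int = 0,
) -> GenomeAnnotation:
    """Build an annotation with Bernoulli adenines and regularly spaced dyads.

    ``dyad_spacing`` maps contig name to a nucleosome repeat length; contigs
    absent from it get no dyads (uniform accessibility downstream).
    """
    dyads = {}
    for contig, nrl in (dyad_spacing or {}).items():
        length = contigs[contig]
        dyads[contig] = np.arange(nrl // 2, length, nrl, dtype=np.int64)
    adenines = {}
    for contig, length in contigs.items():
        for strand in "+-":
            rng = derive_rng(seed, f"adenines/{contig}/{strand}")
            adenines[(contig, strand)] = random_adenines(length, adenine_density, rng)
    return GenomeAnnotation(
        contigs=dict(contigs),
        features=list(features or []),
        nucleosome_dyads=dyads,
        adenines=adenines,
    )


def toy_genome(seed: int = 0, adenine_density: float = 0.31, nrl: int = 165) -> GenomeAnnotation:
    """The default desk-scale genome: one 60 kb contig.

    Mirrors the windows the analysis plots: an HML-like locus (two silencers
    3.3 kb apart flanking a promoter), an HMR-like locus (two silencers 2.4 kb
    apart), two telomere-like ends (TG repeat + X element + boundary) and a
    control region with no recruitment features.
    """
    contig = "chrS"
    length = 60_000
    feats = [
        # left telomere-like end
        Feature(contig, 0, 300, ".", "tg_repeat", "tg_L"),
        Feature(contig, 400, 1_100, ".", "x_element", "x_L"),
        Feature(contig, 3_000, 3_100, ".", "boundary", "bnd_L"),
        # HML-like locus: silencers E/I flanking a promoter
        Feature(contig, 8_000, 8_500, ".", "silencer", "silencer_E_hml"),
        Feature(contig, 9_700, 10_000, ".", "promoter", "prom_hml"),
        Feature(contig, 11_800, 12_300, ".", "silencer", "silencer_I_hml"),
        Feature(contig, 8_500, 9_700, ".", "gene_body", "gene_hml1"),
        Feature(contig, 10_000, 11_800, ".", "gene_body", "gene_hml2"),
        # HMR-like locus
        Feature(contig, 30_000, 30_500, ".", "silencer", "silencer_E_hmr"),
        Feature(contig, 31_300, 31_600, ".", "promoter", "prom_hmr"),
        Feature(contig, 32_900, 33_400, ".", "silencer", "silencer_I_hmr"),
        Feature(contig, 30_500, 31_300, ".", "gene_body", "gene_hmr1"),
        # control region, far from any recruitment site
        Feature(contig, 44_000, 50_000, ".", "control_region", "control"),
        # right telomere-like end
        Feature(contig, 56_900, 57_000, ".", "boundary", "bnd_R"),
        Feature(contig, 58_900, 59_600, ".", "x_element", "x_R"),
        Feature(contig, 59_700, 60_000, ".", "tg_repeat", "tg_R"),
    ]
    return make_annotation(
        {contig: length},
        feats,
        dyad_spacing={contig: nrl},
        adenine_density=adenine_density,
        seed=seed,
    )
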