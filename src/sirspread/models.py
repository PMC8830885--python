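"""Parametric occupancy, accessibility and emission models.

The occupancy model formalizes recruitment-and-spread of a chromatin protein:
sequence-specific recruitment intervals carry a peak occupancy; away from a
recruitment interval occupancy decays exponentially with distance (decay
length ``lambda``); each boundary element crossed on the path from the site
multiplies the spread term by an attenuation factor; a constant background
occupancy models nonspecific visits. Methylation of an adenine on a molecule
is Bernoulli(occupancy x accessibility x per-visit rate), and the base
caller's probability output is drawn from class-conditional emission
distributions calibrated to a true/false-positive rate at the binarization
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotation import Feature, GenomeAnnotation

#: Default halftimes (minutes) for establishment time courses: recruitment
#: sites saturate quickly, spread into the interior is slow.
DEFAULT_HALFTIMES = {
    "silencer": 10.0,
    "promoter": 10.0,
    "tg_repeat": 10.0,
    "x_element": 10.0,
    "spread": 120.0,
}


@dataclass
class OccupancyModel:
    """Recruitment/spread/boundary/accessibility model.

    Parameters
    ----------
    recruitment_sites
        (feature, peak_occupancy) pairs; occupancy inside the feature interval
        equals ``background + peak`` (clamped to 1).
    decay_length
        Spread decay length lambda in bp; distance is measured from the
        nearest edge of the recruitment interval (0 inside it).
    boundary_attenuation
        Factor in [0, 1] applied once per boundary feature crossed between a
        site and a position; 0 annihilates spread past the boundary, 1 makes
        boundaries inert.
    background_occupancy
        Occupancy far from any site (nonspecific visits), in [0, 1).
    methylation_rate
        Per-visit methylation efficiency r in (0, 1].
    linker_accessibility, core_accessibility, core_halfwidth
        Accessibility of linker DNA and of positions within +-core_halfwidth
        of a nucleosome dyad (147 bp occluded core by default).
    establishment_halftime
        Per-feature-kind halftimes in minutes plus a ``"spread"`` key, used
        when occupancy is evaluated at a finite time after induction.
    """

    recruitment_sites: list[tuple[Feature, float]] = field(default_factory=list)
    decay_length: float = 2500.0
    boundary_attenuation: float = 0.0
    background_occupancy: float = 0.005
    methylation_rate: float = 0.8
    linker_accessibility: float = 1.0
    core_accessibility: float = 0.25
    core_halfwidth: int = 73
    establishment_halftime: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HALFTIMES)
    )

    def __post_init__(self):
        for feat, peak in self.recruitment_sites:
            if not 0 <= peak <= 1:
                raise ValueError(f"peak occupancy {peak} outside [0, 1]")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be > 0")
        if not 0 <= self.boundary_attenuation <= 1:
            raise ValueError("boundary_attenuation outside [0, 1]")
        if not 0 <= self.background_occupancy < 1:
            raise ValueError("background_occupancy outside [0, 1)")
        if not 0 < self.methylation_rate <= 1:
            raise ValueError("methylation_rate outside (0, 1]")
        if not 0 < self.linker_accessibility <= 1:
            raise ValueError("linker_accessibility outside (0, 1]")
        if not 0 < self.core_accessibility <= self.linker_accessibility:
            raise ValueError("need 0 < core_accessibility <= linker_accessibility")
        for kind, ht in self.establishment_halftime.items():
            if ht < 0:
                raise ValueError(f"halftime for {kind!r} must be >= 0")

    def _halftime(self, kind: str) -> float:
        return self.establishment_halftime.get(kind, 0.0)


def sites_from_annotation(
    annotation: GenomeAnnotation,
    peak_occupancy: float = 0.9,
    kinds: tuple[str, ...] = ("silencer", "promoter", "tg_repeat", "x_element"),
) -> list[tuple[Feature, float]]:
    """Recruitment sites at every feature of the given kinds, uniform peak."""
    return [(f, peak_occupancy) for f in annotation.features if f.kind in kinds]


def _time_scale(time: float | None, halftime: float) -> float:
    if time is None:
        return 1.0
    if halftime == 0:
        return 1.0
    return time / (time + halftime)


def occupancy_field(
    model: OccupancyModel,
    annotation: GenomeAnnotation,
    contig: str,
    time: float | None = None,
    positions: np.ndarray | None = None,
) -> np.ndarray:
    """Per-position occupancy in [0, 1] on ``contig``.

    occupancy(x) = clamp(background
                         + sum_sites peak * exp(-d(x, site)/lambda)
                                          * attenuation^(boundaries crossed),
                         0, 1)

    Distance d is from the nearest edge of the site interval (0 inside it).
    When ``time`` is given, the in-interval (recruitment) part of each site
    term is scaled by t/(t + halftime_kind) and the decayed (spread) part by
    t/(t + halftime_spread); the background term is not scaled, so at t = 0
    occupancy equals background everywhere.
    """
    length = annotation.require_contig(contig)
    if time is not None and time < 0:
        raise ValueError("negative time")
    if positions is None:
        positions = np.arange(length, dtype=np.int64)
    else:
        positions = np.asarray(positions, dtype=np.int64)
    occ = np.full(positions.shape, model.background_occupancy, dtype=float)

    bnd_mid = np.sort(
        [
            (f.start + f.end) / 2.0
            for f in annotation.features_on(contig, "boundary")
        ]
    )
    # cumulative count of boundary midpoints below each query position
    pos_rank = np.searchsorted(bnd_mid, positions)

    spread_scale = _time_scale(time, model._halftime("spread"))
    for feat, peak in model.recruitment_sites:
        if feat.contig != contig:
            continue
        d = np.maximum(
            0, np.maximum(feat.start - positions, positions - (feat.end - 1))
        ).astype(float)
        inside = d == 0
        with np.errstate(under="ignore"):
            decay = np.exp(-d / model.decay_length)
        if bnd_mid.size and model.boundary_attenuation != 1.0:
            lo = np.searchsorted(bnd_mid, feat.start)
            hi = np.searchsorted(bnd_mid, feat.end - 1)
            # boundaries strictly between the site interval and x
            crossed = np.where(
                positions >= feat.end, pos_rank - hi, np.maximum(lo - pos_rank, 0)
            )
            crossed = np.where(inside, 0, np.maximum(crossed, 0))
            decay = decay * model.boundary_attenuation ** crossed
        term = peak * decay
        if time is not None:
            rec_scale = _time_scale(time, model._halftime(feat.kind))
            term = term * np.where(inside, rec_scale, spread_scale)
        occ += term
    return np.clip(occ, 0.0, 1.0)


def accessibility_field(
    annotation: GenomeAnnotation,
    model: OccupancyModel,
    contig: str,
    positions: np.ndarray | None = None,
) -> np.ndarray:
    """Per-position accessibility in (0, 1].

    Positions within +-core_halfwidth of a nucleosome dyad get
    ``core_accessibility``; all others get ``linker_accessibility``. With no
    dyads the field is uniformly at linker accessibility.
    """
    length = annotation.require_contig(contig)
    if positions is None:
        positions = np.arange(length, dtype=np.int64)
    else:
        positions = np.asarray(positions, dtype=np.int64)
    acc = np.full(positions.shape, model.linker_accessibility, dtype=float)
    dyads = annotation.nucleosome_dyads.get(contig)
    if dyads is None or dyads.size == 0:
        return acc
    idx = np.searchsorted(dyads, positions)
    d_right = np.where(idx < dyads.size, dyads[np.minimum(idx, dyads.size - 1)] - positions, np.iinfo(np.int64).max)
    d_left = np.where(idx > 0, positions - dyads[np.maximum(idx - 1, 0)], np.iinfo(np.int64).max)
    nearest = np.minimum(np.abs(d_right), np.abs(d_left))
    acc[nearest <= model.core_halfwidth] = model.core_accessibility
    return acc


@dataclass
class EmissionModel:
    """Class-conditional base-caller emission distributions on [0, 1].

    Methylated adenines emit probabilities from Beta(a, 1) (right-skewed,
    mass near 1); unmethylated from Beta(1, b) (left-skewed, mass near 0).
    The shapes a and b are solved so that P(p > threshold) equals the
    configured true-positive rate for the methylated class and the
    false-positive rate for the unmethylated class:

        a = log(1 - TPR) / log(threshold),  b = log(FPR) / log(1 - threshold)
    """

    p_true_positive: float = 0.9
    p_false_positive: float = 0.01
    threshold: float = 0.8

    def __post_init__(self):
        if not 0 < self.p_false_positive < self.p_true_positive < 1:
            raise ValueError("need 0 < FPR < TPR < 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold outside (0, 1)")

    @property
    def beta_a(self) -> float:
        return math.log(1.0 - self.p_true_positive) / math.log(self.threshold)

    @property
    def beta_b(self) -> float:
        return math.log(self.p_false_positive) / math.log(1.0 - self.threshold)

    def sample(self, methylated: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw emitted probabilities for a boolean methylation-state vector."""
        methylated = np.asarray(methylated, dtype=bool)
        out = np.empty(methylated.shape, dtype=float)
        n_m = int(methylated.sum())
        out[methylated] = rng.beta(self.beta_a, 1.0, n_m)
        out[~methylated] = rng.beta(1.0, self.beta_b, methylated.size - n_m)
        return np.clip(out, 1e-12, 1.0 - 1e-12)


@dataclass
class ReadSamplerConfig:
    """Long-read placement parameters.

    ``target_coverage`` is total read depth; read lengths are gamma with the
    given coefficient of variation, floored at ``min_read_length``.
    """

    mean_read_length: int = 8000
    length_dispersion: float = 0.3
    target_coverage: float = 30.0
    min_read_length: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.target_coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.mean_read_length < 1:
            raise ValueError("mean read length must be >= 1")
        if self.length_dispersion < 0:
            raise ValueError("length dispersion must be >= 0")
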