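"""Canned simulation scenarios: the study conditions in code.

Each scenario builds a small genome (a simulated contig plus a featureless
``ctrl`` contig for background estimation), an occupancy model and the
default emission/read-sampler configurations. They are the single source of
the conditions under which the pipeline's recovery properties are measured:
the computational recruitment-without-spread contrast, boundary fixity under
overexpression, establishment time courses, periodicity and spread-length
recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .aggregate import (
    AggregateTrack,
    aggregate_fraction,
    filter_coverage,
    smooth_track,
)
from .annotation import Feature, GenomeAnnotation, make_annotation
from .calls import PerReadCallSet
from .models import EmissionModel, OccupancyModel, ReadSamplerConfig, sites_from_annotation
from .perread import binarize_calls
from .simulate import simulate_reads

SIM = "chrSim"
CTRL = "ctrl"

#: time points (minutes) of the establishment time course
TIMECOURSE_TIMES = [0.0, 15.0, 45.0, 90.0]


@dataclass
class Scenario:
    """A simulation configuration plus the anchors downstream analysis uses."""

    annotation: GenomeAnnotation
    model: OccupancyModel
    emission: EmissionModel
    sampler: ReadSamplerConfig
    anchors: dict[str, Feature] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def with_seed(self, seed: int) -> "Scenario":
        return replace(self, sampler=replace(self.sampler, seed=seed))

    def simulate(self) -> PerReadCallSet:
        return simulate_reads(self.annotation, self.model, self.emission, self.sampler)


def methylation_track(
    calls: PerReadCallSet,
    contig: str = SIM,
    threshold: float = 0.8,
    min_coverage: int = 10,
    enp: float = 100.0,
    span: float | None = None,
    smooth: bool = True,
) -> AggregateTrack:
    """Standard processing: binarize, aggregate (strand-merged), filter, smooth."""
    binary = calls if calls.is_binarized else binarize_calls(calls, threshold)
    track = aggregate_fraction(binary, region=contig, merge_strands=True)
    track = filter_coverage(track, min_coverage)
    if smooth:
        track = smooth_track(track, effective_parameters=enp, span=span)
    return track


def _with_ctrl(contigs: dict[str, int], ctrl_length: int = 6000) -> dict[str, int]:
    out = dict(contigs)
    out[CTRL] = ctrl_length
    return out


def control_scenario(
    seed: int = 0, coverage: float = 30.0, length: int = 20_000, fpr: float = 0.01
) -> Scenario:
    """Zero occupancy everywhere: binarized methylation measures the FPR."""
    ann = make_annotation(_with_ctrl({SIM: length}), [], seed=0)
    model = OccupancyModel(recruitment_sites=[], background_occupancy=0.0)
    return Scenario(
        ann,
        model,
        EmissionModel(p_false_positive=fpr),
        ReadSamplerConfig(target_coverage=coverage, seed=seed),
    )


def boundary_scenario(
    seed: int = 0, coverage: float = 50.0, boundary_offset: int = 5000
) -> Scenario:
    """One anchor with a fully attenuating boundary element downstream.

    The boundary element sits ``boundary_offset`` bp from the anchor's
    distal edge; past it the spread term is annihilated, so the true spread
    extent equals the offset.
    """
    anchor = Feature(SIM, 500, 1000, ".", "silencer", "anchor")
    bnd = Feature(SIM, 1000 + boundary_offset, 1010 + boundary_offset, ".", "boundary", "bnd")
    ann = make_annotation(_with_ctrl({SIM: 12_000}), [anchor, bnd], seed=0)
    model = OccupancyModel(
        recruitment_sites=sites_from_annotation(ann, peak_occupancy=0.9),
        boundary_attenuation=0.0,
    )
    return Scenario(
        ann,
        model,
        EmissionModel(),
        ReadSamplerConfig(target_coverage=coverage, seed=seed),
        anchors={"anchor": anchor},
        params={"true_extent": float(boundary_offset)},
    )


def contrast_scenarios(seed: int = 0, coverage: float = 50.0) -> tuple[Scenario, Scenario]:
    """Wild-type-like vs spread-deficient (recruitment intact, no spread).

    The spread-deficient configuration keeps the same recruitment peaks but
    collapses the spread decay length to 1 bp, the computational analogue of
    a nucleosome-binding mutant: recruited, unable to spread.
    """
    a1 = Feature(SIM, 4000, 4500, ".", "silencer", "anchor_left")
    a2 = Feature(SIM, 15_500, 16_000, ".", "x_element", "anchor_right")
    ann = make_annotation(_with_ctrl({SIM: 20_000}), [a1, a2], seed=0)
    sites = sites_from_annotation(ann, peak_occupancy=0.9)
    wt = Scenario(
        ann,
        OccupancyModel(recruitment_sites=sites),
        EmissionModel(),
        ReadSamplerConfig(target_coverage=coverage, seed=seed),
        anchors={"anchor_left": a1, "anchor_right": a2},
        params={"directions": {"anchor_left": -1, "anchor_right": 1}},
    )
    mut = replace(
        wt,
        model=OccupancyModel(recruitment_sites=sites, decay_length=1.0),
    )
    return wt, mut


def overexpression_scenarios(seed: int = 0, coverage: float = 50.0) -> tuple[Scenario, Scenario]:
    """Single-copy vs doubled peak occupancy with a fixed boundary element."""
    anchor = Feature(SIM, 1000, 1500, ".", "silencer", "anchor")
    bnd = Feature(SIM, 4500, 4510, ".", "boundary", "bnd")
    ann = make_annotation(_with_ctrl({SIM: 12_000}), [anchor, bnd], seed=0)
    base = Scenario(
        ann,
        OccupancyModel(
            recruitment_sites=sites_from_annotation(ann, peak_occupancy=0.45),
            boundary_attenuation=0.0,
        ),
        EmissionModel(),
        ReadSamplerConfig(target_coverage=coverage, seed=seed),
        anchors={"anchor": anchor},
        params={"true_extent": 3000.0},
    )
    over = replace(
        base,
        model=OccupancyModel(
            recruitment_sites=sites_from_annotation(ann, peak_occupancy=0.9),
            boundary_attenuation=0.0,
        ),
    )
    return base, over


def lambda_scenario(
    seed: int = 0, coverage: float = 50.0, decay_length: float = 800.0
) -> Scenario:
    """A single unbounded anchor for spread-length recovery."""
    anchor = Feature(SIM, 1000, 1600, ".", "silencer", "anchor")
    ann = make_annotation(_with_ctrl({SIM: 12_000}), [anchor], seed=0)
    return Scenario(
        ann,
        OccupancyModel(
            recruitment_sites=sites_from_annotation(ann, peak_occupancy=0.9),
            decay_length=decay_length,
        ),
        EmissionModel(),
        ReadSamplerConfig(target_coverage=coverage, seed=seed),
        anchors={"anchor": anchor},
        params={"true_lambda": float(decay_length)},
    )


def periodicity_scenario(
    seed: int = 0, coverage: float = 100.0, nrl: int = 165, with_dyads: bool = True
) -> Scenario:
    """Uniform high occupancy with (or without) a nucleosome repeat.

    With dyads every ``nrl`` bp the accessibility field oscillates
    (147 bp occluded cores, short linkers); without dyads the detrended
    track is pure counting noise — the white-noise control.
    """
    length = 26_000
    site = Feature(SIM, 500, length - 500, ".", "silencer", "domain")
    ann = make_annotation(
        _with_ctrl({SIM: length}),
        [site],
        dyad_spacing={SIM: nrl} if with_dyads else None,
        seed=0,
    )
    return Scenario(
        ann,
        OccupancyModel(recruitment_sites=[(site, 0.9)]),
        EmissionModel(),
        ReadSamplerConfig(target_coverage=coverage, seed=seed),
        anchors={"domain": site},
        params={"nrl": nrl},
    )


def timecourse_scenario(seed: int = 0, coverage: float = 30.0) -> Scenario:
    """HML-like locus for establishment-onset mapping.

    Recruitment sites (silencers, promoter) saturate with a 10 min halftime;
    spread into the interior has a 120 min halftime.
    """
    s_e = Feature(SIM, 2000, 2400, ".", "silencer", "silencer_E")
    prom = Feature(SIM, 10_000, 10_300, ".", "promoter", "prom")
    s_i = Feature(SIM, 18_000, 18_400, ".", "silencer", "silencer_I")
    ann = make_annotation(_with_ctrl({SIM: 21_000}), [s_e, prom, s_i], seed=0)
    model = OccupancyModel(
        recruitment_sites=sites_from_annotation(ann, peak_occupancy=0.9),
        establishment_halftime={
            "silencer": 10.0,
            "promoter": 10.0,
            "spread": 120.0,
        },
    )
    return Scenario(
        ann,
        model,
        EmissionModel(),
        ReadSamplerConfig(target_coverage=coverage, seed=seed),
        anchors={"silencer_E": s_e, "prom": prom, "silencer_I": s_i},
        params={
            # interior intervals >= 2.5 kb from the nearest recruitment edge,
            # so the spread (not recruitment) term dominates them
            "interior": [(4_900, 5_900), (12_900, 13_900)],
            "recruitment": [(2000, 2400), (10_000, 10_300), (18_000, 18_400)],
            "times": list(TIMECOURSE_TIMES),
        },
    )
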