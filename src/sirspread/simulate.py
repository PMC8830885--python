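"""Simulate per-read m6A call sets from an explicit occupancy model.

Reads are placed uniformly (contig edges included) at a target depth, each
read is assigned a strand and reports one call per adenine of that strand
under its footprint. The true methylation state of each adenine on each
molecule is Bernoulli(occupancy x accessibility x per-visit rate); the
emitted probability is drawn from the class-conditional emission model.
Everything is deterministic for a fixed sampler seed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, derive_rng
from .calls import PerReadCallSet
from .models import (
    EmissionModel,
    OccupancyModel,
    ReadSamplerConfig,
    accessibility_field,
    occupancy_field,
)


def _sample_read_layout(
    length: int, sampler: ReadSamplerConfig, rng: np.random.Generator
):
    """Read (start, end, strand) triples giving ~uniform depth over [0, length)."""
    mean_len = min(sampler.mean_read_length, length)
    span = length + mean_len - 1
    n_reads = int(round(sampler.target_coverage * span / mean_len))
    if n_reads == 0:
        return (np.empty(0, np.int64),) * 2 + (np.empty(0, dtype="U1"),)
    if sampler.length_dispersion > 0:
        shape = 1.0 / sampler.length_dispersion**2
        lengths = rng.gamma(shape, mean_len / shape, n_reads)
    else:
        lengths = np.full(n_reads, float(mean_len))
    lengths = np.maximum(lengths, min(sampler.min_read_length, length)).astype(np.int64)
    starts = rng.integers(-(lengths - 1), length, n_reads)
    ends = np.minimum(starts + lengths, length)
    starts = np.maximum(starts, 0)
    keep = ends > starts
    strands = np.where(rng.random(n_reads) < 0.5, "+", "-")
    return starts[keep], ends[keep], strands[keep]


def simulate_reads(
    annotation: GenomeAnnotation,
    model: OccupancyModel,
    emission: EmissionModel,
    sampler: ReadSamplerConfig,
    time: float | None = None,
    read_prefix: str = "read",
    return_truth: bool = False,
) -> PerReadCallSet | tuple[PerReadCallSet, pd.DataFrame]:
    """Simulate a :class:`PerReadCallSet` over every contig in the annotation.

    With ``return_truth`` the simulated true per-call methylation states are
    returned alongside, for oracle comparisons.
    """
    frames = []
    truths = []
    for contig, length in annotation.contigs.items():
        if length == 0:
            raise ValueError(f"zero-length contig {contig!r}")
        rng = derive_rng(sampler.seed, f"reads/{contig}")
        starts, ends, strands = _sample_read_layout(length, sampler, rng)
        if starts.size == 0:
            warnings.warn(f"coverage too low: no reads produced on {contig}")
            continue
        read_ids = np.array(
            [f"{read_prefix}_{contig}_{i:06d}" for i in range(starts.size)]
        )
        for strand in "+-":
            adenines = annotation.adenines_on(contig, strand)
            sel = strands == strand
            if adenines.size == 0 or not sel.any():
                continue
            occ = occupancy_field(model, annotation, contig, time=time, positions=adenines)
            acc = accessibility_field(annotation, model, contig, positions=adenines)
            p_meth = occ * acc * model.methylation_rate

            lo = np.searchsorted(adenines, starts[sel])
            hi = np.searchsorted(adenines, ends[sel])
            counts = hi - lo
            total = int(counts.sum())
            if total == 0:
                continue
            # ragged gather: adenine indices under each read, concatenated
            head = np.repeat(np.cumsum(counts) - counts, counts)
            a_idx = np.arange(total) - head + np.repeat(lo, counts)
            row = np.repeat(np.flatnonzero(sel), counts)

            meth = rng.random(total) < p_meth[a_idx]
            prob = emission.sample(meth, rng)
            frames.append(
                pd.DataFrame(
                    {
                        "read_id": read_ids[row],
                        "contig": contig,
                        "strand": strand,
                        "position": adenines[a_idx],
                        "mod_log_prob": np.log(prob),
                        "can_log_prob": np.log1p(-prob),
                        "mod_code": "Y",
                    }
                )
            )
            if return_truth:
                truths.append(
                    pd.DataFrame(
                        {
                            "read_id": read_ids[row],
                            "contig": contig,
                            "strand": strand,
                            "position": adenines[a_idx],
                            "true_methylated": meth,
                        }
                    )
                )
    if not frames:
        calls = PerReadCallSet.empty()
    else:
        calls = PerReadCallSet(
            pd.concat(frames, ignore_index=True)
            .sort_values(["contig", "position", "read_id"], kind="mergesort")
            .reset_index(drop=True),
            meta={"seed": sampler.seed, "time": time},
        )
    if return_truth:
        truth = (
            pd.concat(truths, ignore_index=True)
            .sort_values(["contig", "position", "read_id"], kind="mergesort")
            .reset_index(drop=True)
            if truths
            else pd.DataFrame(
                columns=["read_id", "contig", "strand", "position", "true_methylated"]
            )
        )
        return calls, truth
    return calls


def simulate_timecourse(
    annotation: GenomeAnnotation,
    model: OccupancyModel,
    emission: EmissionModel,
    sampler: ReadSamplerConfig,
    times: list[float],
) -> list[tuple[float, PerReadCallSet]]:
    """One call set per time point, with time-scaled occupancy.

    Each time point uses a seed derived deterministically from the sampler's
    base seed and the time index.
    """
    if list(times) != sorted(times):
        raise ValueError("times must be sorted ascending")
    out = []
    for i, t in enumerate(times):
        sub_seed = int(
            derive_rng(sampler.seed, f"timecourse/{i}").integers(0, 2**31 - 1)
        )
        sub = ReadSamplerConfig(
            mean_read_length=sampler.mean_read_length,
            length_dispersion=sampler.length_dispersion,
            target_coverage=sampler.target_coverage,
            min_read_length=sampler.min_read_length,
            seed=sub_seed,
        )
        out.append(
            (t, simulate_reads(annotation, model, emission, sub, time=t, read_prefix=f"t{i}"))
        )
    return out
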