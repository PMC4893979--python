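"""Synthetic ChIP-seq mapped-read generator.

Emulates the two enrichment phenotypes that matter for subsampling-based
QC: locally confined "sharp" peaks (H3K4me3-like, ~1 kb) and extended
"broad" domains (H3K27me3-like, ~50 kb), on top of a uniform background.
Each read is placed independently: with probability
``enrichment_fraction`` its start is uniform within a randomly chosen
enriched interval, otherwise uniform on the genome.  Reads are i.i.d. —
no PCR-duplicate or mappability model — so the per-bin counting
distributions are exactly binomial/hypergeometric and test oracles stay
closed-form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genome import GenomeLayout, MappedReadSet

__all__ = [
    "SimulationConfig",
    "plan_landscape",
    "simulate_reads",
    "simulate_dataset",
    "default_genome",
    "SHARP_REGION_WIDTH",
    "BROAD_REGION_WIDTH",
]

SHARP_REGION_WIDTH = 1_000
BROAD_REGION_WIDTH = 50_000


def default_genome(
    total_length: int = 100_000_000, bin_width: int = 500
) -> GenomeLayout:
    """A two-chromosome synthetic genome (60% / 40% of ``total_length``)."""
    l1 = int(round(0.6 * total_length))
    return GenomeLayout((("chr1", l1), ("chr2", total_length - l1)), bin_width=bin_width)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic ChIP-seq dataset.

    ``enrichment_fraction`` is the share of reads drawn from enriched
    regions; the remainder is uniform background.  ``region_width``
    defaults by mark type: 1 kb for sharp peaks, 50 kb for broad domains.
    """

    genome: GenomeLayout
    mark_type: str = "sharp"
    n_regions: int = 1_000
    region_width: Optional[int] = None
    enrichment_fraction: float = 0.5
    total_reads: int = 1_000_000
    read_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mark_type not in ("sharp", "broad"):
            raise ValueError(f"mark_type must be 'sharp' or 'broad', got {self.mark_type!r}")
        if self.region_width is None:
            width = SHARP_REGION_WIDTH if self.mark_type == "sharp" else BROAD_REGION_WIDTH
            object.__setattr__(self, "region_width", width)
        if self.region_width <= 0:
            raise ValueError("region_width must be positive")
        if not (0.0 <= self.enrichment_fraction <= 1.0):
            raise ValueError("enrichment_fraction must lie in [0, 1]")
        if self.total_reads < 0:
            raise ValueError("total_reads must be non-negative")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.n_regions < 0:
            raise ValueError("n_regions must be non-negative")
        if self.n_regions * self.region_width >= self.genome.total_length:
            raise ValueError(
                f"total region footprint ({self.n_regions} x {self.region_width} bp) "
                f"does not fit the genome ({self.genome.total_length} bp); "
                "reduce n_regions or region_width"
            )

    def as_dict(self) -> dict:
        return {
            "genome": {
                "chromosomes": [[n, int(l)] for n, l in self.genome.chromosomes],
                "bin_width": self.genome.bin_width,
            },
            "mark_type": self.mark_type,
            "n_regions": self.n_regions,
            "region_width": self.region_width,
            "enrichment_fraction": self.enrichment_fraction,
            "total_reads": self.total_reads,
            "read_length": self.read_length,
            "seed": self.seed,
        }


def _stream(seed: int, label: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(label,)))


def plan_landscape(config: SimulationConfig) -> np.ndarray:
    """Place the enriched regions: disjoint, uniform, deterministic per seed.

    Returns an array of ``(chrom_idx, start, end)`` rows sorted by
    position.  Placement uses the exact spacing construction: regions
    are allocated to chromosomes proportionally to length, and on each
    chromosome ``n`` sorted uniform draws on ``[0, L - n*width]`` plus
    staggered offsets yield ``n`` disjoint intervals distributed
    uniformly among all non-overlapping configurations.
    """
    rng = _stream(config.seed, 1)
    w = config.region_width
    lengths = config.genome.lengths
    if config.n_regions == 0:
        return np.empty((0, 3), dtype=np.int64)

    probs = lengths / lengths.sum()
    alloc = rng.multinomial(config.n_regions, probs)
    # a multinomial draw can overload a short chromosome; spill the excess
    # to the largest chromosome rather than failing
    for ci in range(len(alloc)):
        max_fit = max(int(lengths[ci] // w) - 1, 0)
        if alloc[ci] > max_fit:
            excess = alloc[ci] - max_fit
            alloc[ci] = max_fit
            alloc[int(np.argmax(lengths))] += excess
    for ci in range(len(alloc)):
        if alloc[ci] * w >= lengths[ci]:
            raise ValueError(
                f"cannot place {alloc[ci]} regions of {w} bp on "
                f"{config.genome.names[ci]} ({int(lengths[ci])} bp); reduce n_regions"
            )

    rows = []
    for ci, n in enumerate(alloc):
        if n == 0:
            continue
        slack = int(lengths[ci]) - n * w
        anchors = np.sort(rng.integers(0, slack + 1, size=n))
        starts = anchors + np.arange(n, dtype=np.int64) * w
        rows.append(
            np.column_stack(
                [np.full(n, ci, dtype=np.int64), starts, starts + w]
            )
        )
    landscape = np.concatenate(rows)
    order = np.lexsort((landscape[:, 1], landscape[:, 0]))
    return landscape[order]


def simulate_reads(config: SimulationConfig, landscape: np.ndarray) -> MappedReadSet:
    """Draw ``total_reads`` mapped reads over the landscape.

    Reads are sorted by genomic position in the returned set; strand is
    uniform.  All reads lie fully within chromosome bounds.
    """
    rng = _stream(config.seed, 2)
    n = config.total_reads
    rl = config.read_length
    lengths = config.genome.lengths
    if (lengths < rl).any():
        raise ValueError("read_length exceeds a chromosome length")

    if len(landscape) and config.enrichment_fraction > 0:
        enriched = rng.random(n) < config.enrichment_fraction
    else:
        enriched = np.zeros(n, dtype=bool)
    n_enr = int(enriched.sum())
    n_bg = n - n_enr

    chrom_idx = np.empty(n, dtype=np.int32)
    start = np.empty(n, dtype=np.int64)

    # background: start uniform per chromosome chosen proportionally to
    # placeable length, so density is uniform over the mappable genome
    placeable = (lengths - rl + 1).astype(np.float64)
    ci_bg = rng.choice(len(lengths), size=n_bg, p=placeable / placeable.sum())
    s_bg = rng.integers(0, (lengths - rl + 1)[ci_bg])
    chrom_idx[~enriched] = ci_bg
    start[~enriched] = s_bg

    if n_enr:
        ri = rng.integers(0, len(landscape), size=n_enr)
        reg = landscape[ri]
        s_enr = reg[:, 1] + rng.integers(0, config.region_width, size=n_enr)
        # keep the read inside the chromosome near right edges
        s_enr = np.minimum(s_enr, lengths[reg[:, 0]] - rl)
        chrom_idx[enriched] = reg[:, 0]
        start[enriched] = s_enr

    strand = rng.integers(0, 2, size=n).astype(np.int8)
    reads = MappedReadSet(
        config.genome, chrom_idx, start, start + rl, strand, validate=False
    )
    return reads.sorted()


def simulate_dataset(config: SimulationConfig) -> tuple[MappedReadSet, np.ndarray]:
    """Convenience: plan the landscape and simulate reads in one call."""
    landscape = plan_landscape(config)
    return simulate_reads(config, landscape), landscape
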