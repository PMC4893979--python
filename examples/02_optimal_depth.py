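"""Extrapolate the optimal sequencing depth of a dataset.

Recomputes quality at 20-100% of the total mapped reads and locates the
read count where the first grade letter crosses the A/B boundary.
"""

from chipqc import (
    GradeBoundaries,
    SimulationConfig,
    SubsamplePlan,
    default_genome,
    depth_profile,
    simulate_dataset,
)

genome = default_genome(10_000_000)
config = SimulationConfig(
    genome=genome,
    mark_type="sharp",
    n_regions=300,
    enrichment_fraction=1.0,
    total_reads=2_000_000,
    seed=5,
)
reads, _ = simulate_dataset(config)

# a reference A/B line at score 60% for the demonstration
boundaries = GradeBoundaries({t: (20.0, 40.0, 60.0) for t in (2.5, 5.0, 10.0)}, "demo")
curve = depth_profile(reads, genome, SubsamplePlan(seed=2), boundaries)
for p in curve.points:
    print(
        f"{p.outer_fraction:>4.0%} of reads ({p.tmr:>9,}): "
        f"score_2.5 = {p.score.score_2_5:5.1f}%  grade {p.grade}"
    )
print(f"optimal sequencing depth: {curve.optimal}")
# The optimal depth is the interpolated read count where the score at
# dRCI 2.5% crosses the A/B boundary (Q3 of the reference distribution):
# sequencing deeper than this no longer changes the top grade letter.
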