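"""Grade-boundary calibration from a simulated dataset collection.

The letter grades discretise QC scores against the quartiles of a
reference score distribution.  The reference distribution shipped with
the package is produced here: a documented grid of simulated datasets
over mark type (sharp/broad) x sequencing depth x enrichment fraction,
several seeds each, whose per-threshold score quartiles become the
boundaries.  Users working against their own score collection (e.g. a
public database export) can instead derive boundaries with
:meth:`chipqc.qc.GradeBoundaries.from_scores` or load them from JSON.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .genome import GenomeLayout
from .qc import GradeBoundaries, QCScore, SubsamplePlan, compute_scores
from .simulate import (
    BROAD_REGION_WIDTH,
    SHARP_REGION_WIDTH,
    SimulationConfig,
    default_genome,
    simulate_dataset,
)

__all__ = ["calibration_grid", "calibrate_boundaries", "DEFAULT_DEPTHS", "DEFAULT_ENRICHMENTS"]

DEFAULT_DEPTHS: tuple[int, ...] = (1_000_000, 5_000_000, 20_000_000)
DEFAULT_ENRICHMENTS: tuple[float, ...] = (0.1, 0.3, 0.55, 0.8)
#: matched 20 Mb enrichment footprint on the default 100 Mb genome
SHARP_N_REGIONS = 20_000
BROAD_N_REGIONS = 400


def calibration_grid(
    genome: Optional[GenomeLayout] = None,
    depths: Sequence[int] = DEFAULT_DEPTHS,
    enrichments: Sequence[float] = DEFAULT_ENRICHMENTS,
    n_seeds: int = 3,
    base_seed: int = 20_16,
) -> list[SimulationConfig]:
    """The simulation configurations behind the shipped boundaries."""
    genome = genome or default_genome()
    configs = []
    run = 0
    for mark, n_regions in (("sharp", SHARP_N_REGIONS), ("broad", BROAD_N_REGIONS)):
        for depth in depths:
            for enr in enrichments:
                for s in range(n_seeds):
                    configs.append(
                        SimulationConfig(
                            genome=genome,
                            mark_type=mark,
                            n_regions=n_regions,
                            enrichment_fraction=enr,
                            total_reads=int(depth),
                            seed=base_seed + run,
                        )
                    )
                    run += 1
    return configs


def calibrate_boundaries(
    configs: Optional[Sequence[SimulationConfig]] = None,
    plan: Optional[SubsamplePlan] = None,
    progress: bool = False,
) -> GradeBoundaries:
    """Run the calibration grid and take score quartiles as boundaries."""
    configs = list(configs) if configs is not None else calibration_grid()
    plan = plan or SubsamplePlan()
    scores: list[QCScore] = []
    for i, cfg in enumerate(configs):
        reads, _ = simulate_dataset(cfg)
        point_plan = SubsamplePlan(
            fractions=plan.fractions,
            seed=cfg.seed + 1,
            draws_per_fraction=plan.draws_per_fraction,
            grading_fraction=plan.grading_fraction,
            thresholds=plan.thresholds,
        )
        per_fraction = compute_scores(reads, cfg.genome, point_plan)
        scores.append(per_fraction[plan.grading_fraction])
        if progress:
            print(
                f"[{i + 1}/{len(configs)}] {cfg.mark_type} depth={cfg.total_reads:,} "
                f"enr={cfg.enrichment_fraction} -> "
                f"{['%.2f' % s for s in scores[-1].scores]}",
                flush=True,
            )
    provenance = (
        f"quartiles of {len(configs)} simulated datasets "
        f"(sharp/broad x depths x enrichments, grading fraction {plan.grading_fraction})"
    )
    return GradeBoundaries.from_scores(scores, provenance)
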