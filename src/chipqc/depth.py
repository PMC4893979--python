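"""Optimal-sequencing-depth extrapolation.

Quality grades are recomputed on outer subsamples of the dataset (20, 40,
60, 80 and 100% of the total mapped reads by default) and the read count
at which the most stringent grade letter (dRCI threshold 2.5%) crosses
the A/B boundary is located by piecewise-linear interpolation on
(TMR, score).  Outer and inner subsampling use independent seeded RNG
streams, so depth points are mutually independent given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome import GenomeLayout, MappedReadSet
from .qc import GradeBoundaries, QCGrade, QCResult, QCScore, SubsamplePlan, run_qc

__all__ = [
    "DEFAULT_OUTER_FRACTIONS",
    "DepthPoint",
    "DepthCurve",
    "OptimalDepth",
    "depth_profile",
    "optimal_depth",
]

DEFAULT_OUTER_FRACTIONS: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)

#: status values for :class:`OptimalDepth`
INTERPOLATED = "interpolated"
BELOW_MINIMUM = "below_minimum_tested"
NOT_REACHED = "not_reached"


@dataclass(frozen=True)
class DepthPoint:
    """QC outcome on one outer subsample of the dataset."""

    outer_fraction: float
    tmr: int
    score: QCScore
    grade: QCGrade
    inner_seed: int
    flagged: bool = False  # set when this point had no populated bins


@dataclass(frozen=True)
class OptimalDepth:
    """Interpolated A->B transition depth, or a sentinel.

    ``status`` is ``"interpolated"`` (``reads`` holds the crossing),
    ``"below_minimum_tested"`` (every point already grades A; ``reads``
    holds the smallest tested TMR) or ``"not_reached"`` (no point grades
    A; ``reads`` is None).
    """

    status: str
    reads: Optional[int]
    noisy: bool = False

    def __str__(self) -> str:
        if self.status == INTERPOLATED:
            return f"{self.reads} reads"
        if self.status == BELOW_MINIMUM:
            return f"below minimum tested ({self.reads} reads)"
        return "not reached"


@dataclass
class DepthCurve:
    """Score-vs-depth curve over increasing outer fractions."""

    points: list[DepthPoint]
    grading_threshold: float = 2.5
    optimal: Optional[OptimalDepth] = None

    def tmrs(self) -> np.ndarray:
        return np.array([p.tmr for p in self.points], dtype=np.int64)

    def scores(self) -> np.ndarray:
        return np.array([p.score.score_at(self.grading_threshold) for p in self.points])


def depth_profile(
    reads: MappedReadSet,
    layout: GenomeLayout,
    plan: SubsamplePlan,
    boundaries: GradeBoundaries,
    outer_fractions: Sequence[float] = DEFAULT_OUTER_FRACTIONS,
    seed: Optional[int] = None,
) -> DepthCurve:
    """Run the full QC at each outer fraction and locate the optimal depth.

    ``outer_fractions`` must be sorted ascending within (0, 1] and
    contain 1.0; at 1.0 no outer draw happens, so that point reproduces a
    direct :func:`chipqc.qc.run_qc` on the full set with the same inner
    seed (recorded on every point as ``inner_seed``).
    """
    fr = tuple(float(f) for f in outer_fractions)
    if any(not (0.0 < f <= 1.0) for f in fr):
        raise ValueError(f"outer fractions must lie in (0, 1], got {fr}")
    if tuple(sorted(fr)) != fr or len(set(fr)) != len(fr):
        raise ValueError("outer fractions must be strictly increasing")
    if 1.0 not in fr:
        raise ValueError("outer fractions must contain 1.0")

    base_seed = plan.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed, spawn_key=(0xD3,))
    children = ss.spawn(2 * len(fr))

    points: list[DepthPoint] = []
    for i, f in enumerate(fr):
        outer_rng = np.random.default_rng(children[2 * i])
        inner_seed = int(children[2 * i + 1].generate_state(1)[0] % (2**31))
        if f == 1.0:
            sub = reads
            inner_seed = plan.seed  # identity point: exactly a direct run_qc
        else:
            k = int(round(f * reads.tmr))
            sub = reads.subset(outer_rng.permutation(reads.tmr)[:k])
        point_plan = SubsamplePlan(
            fractions=plan.fractions,
            seed=inner_seed,
            draws_per_fraction=plan.draws_per_fraction,
            grading_fraction=plan.grading_fraction,
            thresholds=plan.thresholds,
        )
        try:
            res: QCResult = run_qc(sub, layout, point_plan, boundaries)
        except ValueError:
            # outer subsample with no populated bins: flag, do not fail
            points.append(
                DepthPoint(
                    outer_fraction=f,
                    tmr=sub.tmr,
                    score=QCScore(plan.thresholds, tuple(0.0 for _ in plan.thresholds), plan.grading_fraction, sub.tmr),
                    grade=QCGrade(tuple("D" for _ in plan.thresholds)),
                    inner_seed=inner_seed,
                    flagged=True,
                )
            )
            continue
        points.append(
            DepthPoint(
                outer_fraction=f,
                tmr=sub.tmr,
                score=res.score,
                grade=res.grade,
                inner_seed=inner_seed,
            )
        )

    curve = DepthCurve(points=points, grading_threshold=plan.thresholds[0])
    curve.optimal = optimal_depth(curve, boundaries)
    return curve


def optimal_depth(
    curve: DepthCurve,
    boundaries: GradeBoundaries,
    *,
    smooth: bool = False,
) -> OptimalDepth:
    """Locate the A/B grade transition on the depth curve.

    Uses the first-letter score (most stringent dRCI threshold) and the
    A/B boundary value Q3.  The crossing is linearly interpolated on
    (TMR, score) between the two adjacent points straddling Q3.  With
    several straddles the lowest-TMR crossing is used and the result is
    flagged noisy.  ``smooth=True`` first smooths the scores with LOWESS
    (for noisy curves).
    """
    pts = [p for p in curve.points if not p.flagged]
    if len(pts) < 2:
        raise ValueError("depth curve needs at least two usable points")
    tmrs = np.array([p.tmr for p in pts], dtype=np.float64)
    scores = np.array([p.score.score_at(curve.grading_threshold) for p in pts])
    if smooth and len(pts) >= 4:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        scores = lowess(scores, tmrs, frac=0.8, return_sorted=False)
    q3 = boundaries.ab_boundary(curve.grading_threshold)

    above = scores > q3  # grade A (ties resolve downward, i.e. not A)
    if above.all():
        return OptimalDepth(status=BELOW_MINIMUM, reads=int(tmrs.min()))
    if not above.any():
        return OptimalDepth(status=NOT_REACHED, reads=None)

    # ascending crossings: below-or-at Q3 followed by above Q3
    crossings = np.flatnonzero(~above[:-1] & above[1:])
    noisy = len(crossings) > 1 or bool(above[0])
    if len(crossings) == 0:
        # curve starts above Q3 and dips below: use the descending crossing
        crossings = np.flatnonzero(above[:-1] & ~above[1:])
        noisy = True
    i = int(crossings[0])
    s0, s1 = scores[i], scores[i + 1]
    t0, t1 = tmrs[i], tmrs[i + 1]
    if s1 == s0:
        reads = int(round(t1))
    else:
        reads = int(round(t0 + (q3 - s0) / (s1 - s0) * (t1 - t0)))
    return OptimalDepth(status=INTERPOLATED, reads=reads, noisy=bool(noisy))
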