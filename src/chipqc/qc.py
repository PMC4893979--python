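"""The subsampling-robustness quality indicator.

The procedure: randomly subsample the total mapped reads (TMRs) at fixed
fractions (90, 70 and 50% by default), recompute per-bin read counts, and
measure for every populated bin the percentage deviation of the
subsampled count from its theoretically expected proportional value
``s * c_b`` (sampling fraction ``s``, original count ``c_b``):

    dRCI_b = 100 * |c_sub,b - s * c_b| / (s * c_b)

Bins with ``c_b = 0`` carry no information about proportionality and are
excluded from the profile and from all denominators.  The quality score
at a dispersion threshold θ is the percentage of populated bins with
``dRCI <= θ``; the three canonical thresholds are θ = 2.5, 5 and 10%.
Scores are discretised into letters A-D against the quartiles of a
reference score distribution, giving a three-letter grade (one letter
per threshold, most stringent first) from AAA down to DDD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .binning import BinnedProfile, bin_reads, read_bin_ids
from .genome import GenomeLayout, MappedReadSet

__all__ = [
    "DEFAULT_FRACTIONS",
    "DEFAULT_THRESHOLDS",
    "GRADING_FRACTION",
    "SubsamplePlan",
    "DispersionProfile",
    "QCScore",
    "QCGrade",
    "GradeBoundaries",
    "QCResult",
    "subsample_reads",
    "compute_dispersion",
    "qc_score",
    "assign_grade",
    "run_qc",
    "compute_scores",
]

DEFAULT_FRACTIONS: tuple[float, ...] = (0.9, 0.7, 0.5)
DEFAULT_THRESHOLDS: tuple[float, ...] = (2.5, 5.0, 10.0)
#: subsampling fraction whose dispersion profile feeds the headline grade
GRADING_FRACTION: float = 0.5

LETTERS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class SubsamplePlan:
    """How to subsample a read set for the QC computation.

    ``grading_fraction`` selects which fraction's dispersion profile
    yields the reported score and grade (the 50% subsample by default —
    the most stringent of the three canonical fractions).
    """

    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    seed: int = 0
    draws_per_fraction: int = 1
    grading_fraction: float = GRADING_FRACTION
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.fractions)
        object.__setattr__(self, "fractions", fr)
        object.__setattr__(self, "thresholds", tuple(float(t) for t in self.thresholds))
        if not fr:
            raise ValueError("at least one subsampling fraction is required")
        if any(not (0.0 < f <= 1.0) for f in fr):
            raise ValueError(f"fractions must lie in (0, 1], got {fr}")
        if len(set(fr)) != len(fr):
            raise ValueError(f"fractions must be distinct, got {fr}")
        if self.draws_per_fraction < 1:
            raise ValueError("draws_per_fraction must be >= 1")
        if self.grading_fraction not in fr:
            raise ValueError(
                f"grading_fraction {self.grading_fraction} is not one of the plan fractions {fr}"
            )
        if tuple(sorted(self.thresholds)) != self.thresholds:
            raise ValueError("thresholds must be sorted ascending")


@dataclass(frozen=True)
class DispersionProfile:
    """Per-bin dRCI (%) at one subsampling fraction.

    Defined only on bins whose original count is positive; ``bins`` holds
    their global bin indices, aligned with ``drci``.
    """

    fraction: float
    bins: np.ndarray
    drci: np.ndarray
    layout: GenomeLayout

    def __post_init__(self) -> None:
        if len(self.bins) != len(self.drci):
            raise ValueError("bins and drci have unequal lengths")
        if len(self.drci) and float(self.drci.min()) < 0:
            raise ValueError("negative dRCI")

    @property
    def eligible_bins(self) -> int:
        return len(self.bins)


@dataclass(frozen=True)
class QCScore:
    """Fractions (%) of populated bins under each dRCI threshold."""

    thresholds: tuple[float, ...]
    scores: tuple[float, ...]
    fraction_used: float
    tmr: int
    eligible_bins: int = 0

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.scores):
            raise ValueError("thresholds and scores have unequal lengths")

    def score_at(self, threshold: float) -> float:
        for t, s in zip(self.thresholds, self.scores):
            if t == threshold:
                return s
        raise KeyError(f"no score at threshold {threshold}")

    @property
    def score_2_5(self) -> float:
        return self.score_at(2.5)

    @property
    def score_5(self) -> float:
        return self.score_at(5.0)

    @property
    def score_10(self) -> float:
        return self.score_at(10.0)

    def as_dict(self) -> dict:
        return {
            "thresholds": list(self.thresholds),
            "scores": [round(s, 6) for s in self.scores],
            "fraction_used": self.fraction_used,
            "tmr": self.tmr,
            "eligible_bins": self.eligible_bins,
        }


@dataclass(frozen=True)
class QCGrade:
    """Three-letter quality grade, one letter per dRCI threshold (ascending)."""

    letters: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(l not in LETTERS for l in self.letters):
            raise ValueError(f"letters must be from {LETTERS}, got {self.letters}")

    def __str__(self) -> str:
        return "".join(self.letters)


class GradeBoundaries:
    """Score cut points mapping a QC score to a letter per threshold level.

    For each dRCI threshold θ the three cut points ``(Q1, Q2, Q3)`` are
    the quartiles of a reference score distribution: a score above Q3 is
    grade A, above Q2 is B, above Q1 is C, else D.  Ties at a boundary
    resolve downward (a score exactly equal to Q3 grades B).
    """

    def __init__(
        self,
        cuts: Mapping[float, tuple[float, float, float]],
        provenance: str = "unspecified",
    ) -> None:
        self.cuts = {float(t): tuple(float(q) for q in qs) for t, qs in cuts.items()}
        self.provenance = provenance
        for t, (q1, q2, q3) in self.cuts.items():
            if not (q1 < q2 < q3):
                raise ValueError(f"cut points must satisfy Q1 < Q2 < Q3 at threshold {t}: {(q1, q2, q3)}")

    def letter(self, threshold: float, score: float) -> str:
        q1, q2, q3 = self.cuts[float(threshold)]
        if score > q3:
            return "A"
        if score > q2:
            return "B"
        if score > q1:
            return "C"
        return "D"

    def ab_boundary(self, threshold: float) -> float:
        """The A/B transition score (Q3) at ``threshold``."""
        return self.cuts[float(threshold)][2]

    # -- construction / serialisation ----------------------------------
    @classmethod
    def from_scores(
        cls, scores: Sequence[QCScore], provenance: str = "quartiles of supplied score collection"
    ) -> "GradeBoundaries":
        """Quartiles of a collection of scores, per threshold level."""
        if not scores:
            raise ValueError("cannot derive boundaries from an empty score collection")
        thresholds = scores[0].thresholds
        cuts = {}
        for t in thresholds:
            vals = np.array([s.score_at(t) for s in scores])
            q1, q2, q3 = np.percentile(vals, [25, 50, 75])
            if not (q1 < q2 < q3):  # degenerate collection; nudge minimally
                eps = max(1e-9, 1e-9 * max(abs(q3), 1.0))
                q2 = max(q2, q1 + eps)
                q3 = max(q3, q2 + eps)
            cuts[t] = (float(q1), float(q2), float(q3))
        return cls(cuts, provenance)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "provenance": self.provenance,
            "cuts": {str(t): list(qs) for t, qs in sorted(self.cuts.items())},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "GradeBoundaries":
        payload = json.loads(Path(path).read_text())
        return cls(
            {float(t): tuple(qs) for t, qs in payload["cuts"].items()},
            payload.get("provenance", "unspecified"),
        )

    @classmethod
    def load_default(cls) -> "GradeBoundaries":
        """Boundaries shipped with the package (simulator calibration run)."""
        from importlib.resources import files

        path = files("chipqc.data").joinpath("default_boundaries.json")
        payload = json.loads(path.read_text())
        return cls(
            {float(t): tuple(qs) for t, qs in payload["cuts"].items()},
            payload.get("provenance", "packaged default"),
        )


@dataclass
class QCResult:
    """Everything one QC run produces.

    ``score``/``grade``/``dispersion`` refer to the grading fraction; the
    scores for every fraction in the plan are kept in
    ``scores_by_fraction``.
    """

    score: QCScore
    grade: QCGrade
    dispersion: DispersionProfile
    scores_by_fraction: dict[float, QCScore]
    plan: SubsamplePlan
    tmr: int


# ----------------------------------------------------------------------
def subsample_reads(reads: MappedReadSet, fraction: float, seed: int) -> MappedReadSet:
    """Draw ``round(fraction * tmr)`` reads without replacement, seeded.

    ``fraction=1.0`` returns the input unchanged.  Output preserves the
    input record order.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    if fraction == 1.0:
        return reads
    k = int(round(fraction * reads.tmr))
    rng = np.random.default_rng(seed)
    idx = rng.permutation(reads.tmr)[:k]
    return reads.subset(idx)


def compute_dispersion(
    original: BinnedProfile, subsampled: BinnedProfile, fraction: float
) -> DispersionProfile:
    """Per-bin dRCI of a subsampled profile against the original.

    ``dRCI_b = 100 * |c_sub,b - s*c_b| / (s*c_b)`` on bins with
    ``c_b > 0``; empty bins are excluded entirely.
    """
    if original.layout != subsampled.layout:
        raise ValueError("original and subsampled profiles are on different layouts")
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must lie strictly in (0, 1), got {fraction}")
    eligible = np.flatnonzero(original.counts)
    expected = fraction * original.counts[eligible]
    drci = 100.0 * np.abs(subsampled.counts[eligible] - expected) / expected
    return DispersionProfile(
        fraction=fraction, bins=eligible, drci=drci, layout=original.layout
    )


def qc_score(
    disp: DispersionProfile,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    tmr: int = 0,
) -> QCScore:
    """Percentage of eligible bins with dRCI at or below each threshold."""
    thresholds = tuple(float(t) for t in thresholds)
    if tuple(sorted(thresholds)) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    if disp.eligible_bins == 0:
        raise ValueError("profile has no populated bins")
    scores = tuple(
        float(100.0 * np.count_nonzero(disp.drci <= t) / disp.eligible_bins)
        for t in thresholds
    )
    return QCScore(
        thresholds=thresholds,
        scores=scores,
        fraction_used=disp.fraction,
        tmr=tmr,
        eligible_bins=disp.eligible_bins,
    )


def assign_grade(score: QCScore, boundaries: GradeBoundaries) -> QCGrade:
    """Discretise a score into one letter per threshold level."""
    return QCGrade(
        letters=tuple(boundaries.letter(t, s) for t, s in zip(score.thresholds, score.scores))
    )


# ----------------------------------------------------------------------
def _dispersion_from_bin_ids(
    bin_ids: np.ndarray,
    counts: np.ndarray,
    eligible: np.ndarray,
    fraction: float,
    n_draws: int,
    rng: np.random.Generator,
    total_bins: int,
) -> np.ndarray:
    """Mean per-bin dRCI over ``n_draws`` seeded subsampling draws.

    Fast path used by :func:`run_qc`: subsampling a read set and
    re-binning is equivalent to subsampling the precomputed per-read bin
    assignments, because binning treats reads independently.
    """
    n = len(bin_ids)
    k = int(round(fraction * n))
    expected = fraction * counts[eligible]
    acc = np.zeros(len(eligible))
    for _ in range(n_draws):
        idx = rng.permutation(n)[:k]
        sub_counts = np.bincount(bin_ids[idx], minlength=total_bins)
        acc += np.abs(sub_counts[eligible] - expected) / expected
    return 100.0 * acc / n_draws


def _fraction_rng(base_seed: int, fraction_index: int) -> np.random.Generator:
    # independent, reproducible stream per plan fraction
    ss = np.random.SeedSequence(base_seed, spawn_key=(fraction_index,))
    return np.random.default_rng(ss)


def run_qc(
    reads: MappedReadSet,
    layout: GenomeLayout,
    plan: SubsamplePlan = SubsamplePlan(),
    boundaries: Optional[GradeBoundaries] = None,
    *,
    extension: int = 0,
) -> QCResult:
    """Full QC: bin, subsample at each plan fraction, score, grade.

    With ``draws_per_fraction > 1`` the per-bin dRCI is averaged across
    draws before scoring.  Deterministic for a given plan seed.
    """
    if boundaries is None:
        boundaries = GradeBoundaries.load_default()
    if reads.tmr == 0:
        raise ValueError("empty read set")
    bin_ids = read_bin_ids(reads, layout, extension=extension)
    counts = np.bincount(bin_ids, minlength=layout.total_bins)
    eligible = np.flatnonzero(counts)
    if eligible.size == 0:
        raise ValueError("profile has no populated bins")

    scores_by_fraction: dict[float, QCScore] = {}
    grading_disp: Optional[DispersionProfile] = None
    for i, frac in enumerate(plan.fractions):
        rng = _fraction_rng(plan.seed, i)
        if frac == 1.0:
            drci = np.zeros(eligible.size)
        else:
            drci = _dispersion_from_bin_ids(
                bin_ids, counts, eligible, frac, plan.draws_per_fraction, rng, layout.total_bins
            )
        disp = DispersionProfile(fraction=frac, bins=eligible, drci=drci, layout=layout)
        scores_by_fraction[frac] = qc_score(disp, plan.thresholds, tmr=reads.tmr)
        if frac == plan.grading_fraction:
            grading_disp = disp

    assert grading_disp is not None  # plan validation guarantees membership
    headline = scores_by_fraction[plan.grading_fraction]
    grade = assign_grade(headline, boundaries)
    return QCResult(
        score=headline,
        grade=grade,
        dispersion=grading_disp,
        scores_by_fraction=scores_by_fraction,
        plan=plan,
        tmr=reads.tmr,
    )


def compute_scores(
    reads: MappedReadSet,
    layout: GenomeLayout,
    plan: SubsamplePlan = SubsamplePlan(),
    *,
    extension: int = 0,
) -> dict[float, QCScore]:
    """Per-fraction QC scores without grading (used for calibration)."""

    class _NoGrade(GradeBoundaries):
        def __init__(self) -> None:
            super().__init__({t: (25.0, 50.0, 75.0) for t in plan.thresholds}, "internal")

    return run_qc(reads, layout, plan, _NoGrade(), extension=extension).scores_by_fraction
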