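"""Two-replicate antibody certification.

Runs the full quality assessment on two biological replicates — global
QC scores and grades, optimal-sequencing-depth extrapolation for each,
and the local QC-IDR concordance across them — and assembles a single
reproducible certificate.  The certification grade takes, at each
threshold position, the worse of the two replicates' letters (the
conservative aggregation; stated in the report).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .depth import DEFAULT_OUTER_FRACTIONS, DepthCurve, depth_profile
from .genome import GenomeLayout, MappedReadSet
from .idr import IDRCurve, IDRPairTable, idr_curve, pair_windows
from .qc import GradeBoundaries, QCGrade, QCResult, QCScore, SubsamplePlan, run_qc

__all__ = ["Certificate", "certify", "compare_with_reference", "worse_grade"]

_LETTER_RANK = {"A": 0, "B": 1, "C": 2, "D": 3}


def worse_grade(g1: QCGrade, g2: QCGrade) -> QCGrade:
    """Per-position lower-quality letter of two grades (A best, D worst)."""
    letters = tuple(
        a if _LETTER_RANK[a] >= _LETTER_RANK[b] else b
        for a, b in zip(g1.letters, g2.letters)
    )
    return QCGrade(letters=letters)


@dataclass
class Certificate:
    """The aggregate certification record for one antibody (two replicates)."""

    replicate_results: tuple[QCResult, QCResult]
    depth_curves: tuple[Optional[DepthCurve], Optional[DepthCurve]]
    idr_pairs: IDRPairTable
    idr: IDRCurve
    certification_grade: QCGrade
    provenance: dict

    def to_dict(self) -> dict:
        reps = []
        for i, res in enumerate(self.replicate_results):
            curve = self.depth_curves[i]
            entry = {
                "grade": str(res.grade),
                "score": res.score.as_dict(),
                "scores_by_fraction": {
                    str(f): s.as_dict() for f, s in res.scores_by_fraction.items()
                },
                "tmr": res.tmr,
            }
            if curve is not None:
                entry["depth_curve"] = [
                    {
                        "outer_fraction": p.outer_fraction,
                        "tmr": p.tmr,
                        "score_first_letter": round(
                            p.score.score_at(curve.grading_threshold), 6
                        ),
                        "grade": str(p.grade),
                    }
                    for p in curve.points
                ]
                entry["optimal_depth"] = {
                    "status": curve.optimal.status,
                    "reads": curve.optimal.reads,
                    "noisy": curve.optimal.noisy,
                }
            reps.append(entry)
        return {
            "certificate_version": 1,
            "certification_grade": str(self.certification_grade),
            "replicates": reps,
            "idr": {
                **self.idr.summary(),
                "n_pairs": self.idr_pairs.n_pairs,
                "n_penalty_pairs": self.idr_pairs.n_penalty_pairs,
                "penalty_fraction": round(self.idr_pairs.penalty_fraction, 6),
            },
            "provenance": self.provenance,
        }

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        """Deterministic JSON (sorted keys, no timestamps)."""
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary_text(self) -> str:
        lines = [
            f"certification grade: {self.certification_grade}",
            "  (per-position worse letter of the two replicate grades)",
        ]
        for i, res in enumerate(self.replicate_results, start=1):
            curve = self.depth_curves[i - 1]
            opt = f", optimal depth {curve.optimal}" if curve is not None else ""
            lines.append(
                f"replicate {i}: grade {res.grade} "
                f"(scores {['%.2f' % s for s in res.score.scores]} % at "
                f"dRCI <= {list(res.score.thresholds)} %, TMR {res.tmr:,}){opt}"
            )
        s = self.idr.summary()
        lines.append(
            f"local QC-IDR: {self.idr_pairs.n_penalty_pairs:,} penalty pairs of "
            f"{self.idr_pairs.n_pairs:,} ({100 * self.idr_pairs.penalty_fraction:.2f}%), "
            f"{s['n_windows_below_threshold']:,} windows in groups with "
            f"local QC-IDR <= {s['threshold']}"
        )
        return "\n".join(lines)


def certify(
    rep1: MappedReadSet,
    rep2: MappedReadSet,
    layout: GenomeLayout,
    plan: SubsamplePlan = SubsamplePlan(),
    boundaries: Optional[GradeBoundaries] = None,
    *,
    outer_fractions: Optional[Sequence[float]] = DEFAULT_OUTER_FRACTIONS,
    idr_group_size: int = 5000,
    idr_step: int = 500,
    idr_threshold: float = 0.1,
) -> Certificate:
    """Certify an antibody from two biological replicates.

    ``outer_fractions=None`` skips the per-replicate depth extrapolation.
    Replicate-specific failures are re-raised naming the replicate.
    """
    if boundaries is None:
        boundaries = GradeBoundaries.load_default()
    if rep1.tmr == 0 or rep2.tmr == 0:
        raise ValueError("both replicates must be non-empty")

    results: list[QCResult] = []
    curves: list[Optional[DepthCurve]] = []
    for i, reads in enumerate((rep1, rep2), start=1):
        rep_plan = SubsamplePlan(
            fractions=plan.fractions,
            seed=plan.seed + i,
            draws_per_fraction=plan.draws_per_fraction,
            grading_fraction=plan.grading_fraction,
            thresholds=plan.thresholds,
        )
        try:
            results.append(run_qc(reads, layout, rep_plan, boundaries))
            if outer_fractions is not None:
                curves.append(
                    depth_profile(
                        reads, layout, rep_plan, boundaries, outer_fractions
                    )
                )
            else:
                curves.append(None)
        except Exception as exc:
            raise type(exc)(f"replicate {i}: {exc}") from exc

    pairs = pair_windows(results[0].dispersion, results[1].dispersion)
    curve = idr_curve(pairs, group_size=idr_group_size, step=idr_step, threshold=idr_threshold)

    provenance = {
        "package_version": __version__,
        "seed": plan.seed,
        "replicate_seeds": [plan.seed + 1, plan.seed + 2],
        "fractions": list(plan.fractions),
        "grading_fraction": plan.grading_fraction,
        "thresholds": list(plan.thresholds),
        "bin_width": layout.bin_width,
        "boundaries_provenance": boundaries.provenance,
        "boundaries_cuts": {str(t): list(q) for t, q in sorted(boundaries.cuts.items())},
        "input_checksums": [rep1.checksum(), rep2.checksum()],
        "tmr": [rep1.tmr, rep2.tmr],
    }
    return Certificate(
        replicate_results=(results[0], results[1]),
        depth_curves=(curves[0], curves[1]),
        idr_pairs=pairs,
        idr=curve,
        certification_grade=worse_grade(results[0].grade, results[1].grade),
        provenance=provenance,
    )


def compare_with_reference(
    scores: Sequence[QCScore],
    reference: pd.DataFrame,
    *,
    threshold: float = 2.5,
    tmr_window: float = 2.0,
) -> pd.DataFrame:
    """Merge certified scores with a public score-vs-TMR reference cloud.

    ``reference`` needs columns ``tmr`` and ``score`` (score at the same
    dRCI threshold, in %).  The output stacks both sources with a
    ``source`` tag ("certified"/"reference"), adds a LOWESS trend of the
    reference cloud evaluated at every row's TMR (for two reference
    points the trend degenerates to their connecting line), and flags
    certified scores sitting above every reference score at comparable
    TMR (within a factor of ``tmr_window``).
    """
    if not {"tmr", "score"}.issubset(reference.columns):
        raise ValueError("reference table needs 'tmr' and 'score' columns")
    if len(reference) < 2:
        raise ValueError("reference table needs at least 2 rows")
    cert = pd.DataFrame(
        {
            "tmr": [s.tmr for s in scores],
            "score": [s.score_at(threshold) for s in scores],
            "source": "certified",
        }
    )
    ref = reference[["tmr", "score"]].copy()
    ref["source"] = "reference"
    merged = pd.concat([cert, ref], ignore_index=True)

    rx = ref["tmr"].to_numpy(np.float64)
    ry = ref["score"].to_numpy(np.float64)
    if len(ref) == 2:
        # two points: the trend is their connecting line
        order = np.argsort(rx)
        merged["trend"] = np.interp(merged["tmr"], rx[order], ry[order])
    else:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        fit = lowess(ry, rx, frac=2 / 3)
        merged["trend"] = np.interp(merged["tmr"], fit[:, 0], fit[:, 1])

    flags = []
    for _, row in merged.iterrows():
        if row["source"] != "certified":
            flags.append(False)
            continue
        near = ref[
            (ref["tmr"] >= row["tmr"] / tmr_window) & (ref["tmr"] <= row["tmr"] * tmr_window)
        ]
        pool = near if len(near) else ref
        flags.append(bool(row["score"] > pool["score"].max()))
    merged["above_reference_cloud"] = flags
    return merged
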