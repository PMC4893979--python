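"""Local QC-IDR: replicate concordance of subsampling-robust windows.

Genomic windows with dRCI < 10% in both biological replicates are paired;
windows robust in only one replicate are paired with a *penalty window*
carrying dRCI = 15%.  Pairs are ranked by the absolute difference of
their paired dRCI values, subdivided into sliding groups of 5,000 ranked
entries advanced by 500, and each group's local QC-IDR is the fraction
of its entries that involve a penalty window.  Windows belonging to at
least one group with local QC-IDR at or below 0.1 are counted as
reproducibly robust.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .qc import DispersionProfile

__all__ = [
    "ELIGIBILITY_DRCI",
    "PENALTY_DRCI",
    "IDRPairTable",
    "IDRCurve",
    "pair_windows",
    "idr_curve",
]

#: windows must show dRCI below this (%) in a replicate to count as robust
ELIGIBILITY_DRCI: float = 10.0
#: dRCI (%) allocated to the missing side of a one-replicate window
PENALTY_DRCI: float = 15.0


@dataclass
class IDRPairTable:
    """Paired per-window dRCI values across two replicates.

    ``entries`` columns: ``bin`` (global bin index), ``chrom``, ``start``,
    ``drci_rep1``, ``drci_rep2``, ``penalty_rep1``, ``penalty_rep2``,
    ``abs_diff``.  Non-penalty sides always carry dRCI < 10; penalty
    sides carry exactly 15.
    """

    entries: pd.DataFrame
    fraction: float

    @property
    def n_pairs(self) -> int:
        return len(self.entries)

    @property
    def n_penalty_pairs(self) -> int:
        return int((self.entries["penalty_rep1"] | self.entries["penalty_rep2"]).sum())

    @property
    def penalty_fraction(self) -> float:
        return self.n_penalty_pairs / self.n_pairs if self.n_pairs else 0.0


@dataclass
class IDRCurve:
    """Local QC-IDR per sliding group of ranked window pairs."""

    group_starts: np.ndarray
    local_idr: np.ndarray
    group_size: int
    step: int
    threshold: float
    n_windows_below_threshold: int
    single_group: bool = False  # fewer entries than group_size
    cumulative: bool = False

    @property
    def n_groups(self) -> int:
        return len(self.group_starts)

    def summary(self) -> dict:
        return {
            "n_groups": self.n_groups,
            "group_size": self.group_size,
            "step": self.step,
            "threshold": self.threshold,
            "n_windows_below_threshold": int(self.n_windows_below_threshold),
            "max_local_idr": float(self.local_idr.max()) if len(self.local_idr) else 0.0,
            "mean_local_idr": float(self.local_idr.mean()) if len(self.local_idr) else 0.0,
        }


def pair_windows(
    disp1: DispersionProfile,
    disp2: DispersionProfile,
    *,
    eligibility: float = ELIGIBILITY_DRCI,
    penalty: float = PENALTY_DRCI,
) -> IDRPairTable:
    """Pair robust windows of two replicate dispersion profiles.

    The universe is the union of windows with dRCI < ``eligibility`` in
    either replicate.  Windows robust in both replicates form real
    pairs; windows robust in exactly one get a penalty partner with
    dRCI = ``penalty`` on the missing side.
    """
    if disp1.layout != disp2.layout:
        raise ValueError("dispersion profiles are on different layouts")
    if disp1.fraction != disp2.fraction:
        raise ValueError(
            f"dispersion profiles use different subsampling fractions "
            f"({disp1.fraction} vs {disp2.fraction})"
        )

    el1_bins = disp1.bins[disp1.drci < eligibility]
    el1_drci = disp1.drci[disp1.drci < eligibility]
    el2_bins = disp2.bins[disp2.drci < eligibility]
    el2_drci = disp2.drci[disp2.drci < eligibility]

    universe = np.union1d(el1_bins, el2_bins)
    d1 = np.full(len(universe), penalty)
    d2 = np.full(len(universe), penalty)
    pos1 = np.searchsorted(universe, el1_bins)
    d1[pos1] = el1_drci
    pos2 = np.searchsorted(universe, el2_bins)
    d2[pos2] = el2_drci
    pen1 = np.ones(len(universe), dtype=bool)
    pen1[pos1] = False
    pen2 = np.ones(len(universe), dtype=bool)
    pen2[pos2] = False

    coords = disp1.layout.bin_intervals(universe)
    entries = pd.DataFrame(
        {
            "bin": universe,
            "chrom": coords["chrom"],
            "start": coords["start"],
            "drci_rep1": d1,
            "drci_rep2": d2,
            "penalty_rep1": pen1,
            "penalty_rep2": pen2,
            "abs_diff": np.abs(d1 - d2),
        }
    )
    return IDRPairTable(entries=entries, fraction=disp1.fraction)


def idr_curve(
    pairs: IDRPairTable,
    group_size: int = 5000,
    step: int = 500,
    threshold: float = 0.1,
    *,
    cumulative: bool = False,
) -> IDRCurve:
    """Local QC-IDR along the ranked pair table.

    Entries are sorted ascending by ``abs_diff`` (ties broken by genomic
    coordinate for determinism) and scanned in sliding groups of
    ``group_size`` entries advanced by ``step``.  A group's local QC-IDR
    is the fraction of its entries involving a penalty window; with
    ``cumulative=True`` it is instead the penalty fraction among all
    entries up to the group's end (the cumulative reading).
    ``n_windows_below_threshold`` counts entries belonging to at least
    one group with local QC-IDR <= ``threshold``.
    """
    if pairs.n_pairs == 0:
        raise ValueError("empty pair table")
    ranked = pairs.entries.sort_values(
        ["abs_diff", "chrom", "start"], kind="mergesort"
    ).reset_index(drop=True)
    is_penalty = (ranked["penalty_rep1"] | ranked["penalty_rep2"]).to_numpy()
    n = len(ranked)

    single_group = n < group_size
    if single_group:
        warnings.warn(
            f"only {n} pairs for group size {group_size}; using a single group",
            stacklevel=2,
        )
        starts = np.array([0], dtype=np.int64)
        sizes = np.array([n], dtype=np.int64)
    else:
        starts = np.arange(0, n - group_size + 1, step, dtype=np.int64)
        sizes = np.full(len(starts), group_size, dtype=np.int64)

    cum = np.concatenate([[0], np.cumsum(is_penalty)])
    ends = starts + sizes
    if cumulative:
        local = cum[ends] / ends
    else:
        local = (cum[ends] - cum[starts]) / sizes

    # entries covered by >=1 sub-threshold group
    covered = np.zeros(n + 1, dtype=np.int64)
    good = local <= threshold
    np.add.at(covered, starts[good], 1)
    np.add.at(covered, ends[good], -1)
    n_below = int(np.count_nonzero(np.cumsum(covered[:-1]) > 0))

    return IDRCurve(
        group_starts=starts,
        local_idr=local,
        group_size=group_size,
        step=step,
        threshold=threshold,
        n_windows_below_threshold=n_below,
        single_group=single_group,
        cumulative=cumulative,
    )
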