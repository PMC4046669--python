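"""Nucleosome peak calling, positioning classification and spacing arithmetic.

A nucleosome call is a local maximum of the normalized occupancy track whose
height exceeds the genome average (1.0 after normalization).  A call is
"well positioned" when its midpoint lies more than ``min_separation``
(default 100) nt from both flanking calls; a missing neighbour at a
chromosome end imposes no constraint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from ._util import percent
from .profiles import OccupancyTrack

CALL_COLUMNS = ["chrom", "midpoint", "height", "well_positioned",
                "dist_left", "dist_right"]


@dataclass
class CallSummary:
    total_peaks: int
    well_positioned: int
    percent_well_positioned: float
    mean_spacing: Optional[float]
    expected_nucleosomes: Optional[int]

    @classmethod
    def from_counts(cls, total: int, well: int,
                    mean_spacing: Optional[float] = None,
                    expected: Optional[int] = None) -> "CallSummary":
        if well > total:
            raise ValueError("well-positioned count exceeds total")
        return cls(total_peaks=total, well_positioned=well,
                   percent_well_positioned=percent(well, total),
                   mean_spacing=mean_spacing, expected_nucleosomes=expected)


def _plateau_maxima(x: np.ndarray, min_height: float):
    """Local maxima with plateau handling: one call at each plateau centre.

    A run of equal values is a maximum when both neighbouring runs are lower
    (a missing neighbour at an array end counts as lower).  The call lands at
    floor of the plateau midpoint.
    """
    n = len(x)
    if n == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    change = np.flatnonzero(np.diff(x)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    vals = x[starts]
    left_ok = np.concatenate(([True], vals[1:] > vals[:-1]))
    right_ok = np.concatenate((vals[:-1] > vals[1:], [True]))
    keep = left_ok & right_ok & (vals > min_height)
    mids = (starts[keep] + ends[keep] - 1) // 2
    return mids.astype(np.int64), vals[keep]


def call_peaks(track: OccupancyTrack, min_height: float = 1.0) -> pd.DataFrame:
    """Call nucleosomes: occupancy maxima strictly above ``min_height``."""
    rows = []
    for chrom in sorted(track.data):
        mids, heights = _plateau_maxima(track.data[chrom], min_height)
        rows.append(pd.DataFrame({"chrom": chrom, "midpoint": mids,
                                  "height": heights}))
    calls = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=["chrom", "midpoint", "height"]))
    calls["well_positioned"] = False
    calls["dist_left"] = np.nan
    calls["dist_right"] = np.nan
    return classify_positioning(calls)


def classify_positioning(calls: pd.DataFrame,
                         min_separation: int = 100) -> pd.DataFrame:
    """Flag calls whose midpoint is > ``min_separation`` nt from both neighbours."""
    calls = calls.copy()
    if calls.empty:
        return calls
    for _, idx in calls.groupby("chrom", sort=False).groups.items():
        mids = calls.loc[idx, "midpoint"].to_numpy()
        order = np.argsort(mids, kind="stable")
        mids = mids[order]
        dl = np.concatenate(([np.nan], np.diff(mids).astype(float)))
        dr = np.concatenate((np.diff(mids).astype(float), [np.nan]))
        ok = (np.isnan(dl) | (dl > min_separation)) & (np.isnan(dr) | (dr > min_separation))
        pos = np.asarray(idx)[order]
        calls.loc[pos, "dist_left"] = dl
        calls.loc[pos, "dist_right"] = dr
        calls.loc[pos, "well_positioned"] = ok
    return calls.sort_values(["chrom", "midpoint"], kind="stable").reset_index(drop=True)


def mean_spacing(calls: pd.DataFrame) -> float:
    """Mean midpoint-to-midpoint distance, pooled over chromosomes by pair count."""
    total, pairs = 0.0, 0
    for _, sub in calls.groupby("chrom", sort=False):
        mids = np.sort(sub["midpoint"].to_numpy())
        if len(mids) >= 2:
            total += float(mids[-1] - mids[0])
            pairs += len(mids) - 1
    if pairs == 0:
        raise ValueError("need at least two calls on one chromosome")
    return total / pairs


def expected_nucleosome_count(effective_genome_length: float, spacing: float) -> int:
    """floor(effective genome length / spacing): how many nucleosomes fit."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if effective_genome_length < 0:
        raise ValueError("genome length must be non-negative")
    return int(math.floor(effective_genome_length / spacing))


def summarize_calls(calls: pd.DataFrame,
                    effective_genome_length: Optional[float] = None,
                    spacing_for_expected: Optional[float] = None) -> CallSummary:
    total = len(calls)
    well = int(calls["well_positioned"].sum()) if total else 0
    try:
        spacing = mean_spacing(calls)
    except ValueError:
        spacing = None
    expected = None
    if effective_genome_length is not None:
        expected = expected_nucleosome_count(
            effective_genome_length,
            spacing_for_expected if spacing_for_expected is not None else spacing)
    return CallSummary.from_counts(total, well, spacing, expected)


def center_recovery(true_centers: Dict[str, np.ndarray], calls: pd.DataFrame,
                    tolerance: int = 20) -> float:
    """Fraction of ground-truth midpoints matched by a call within ±tolerance."""
    matched = 0
    total = 0
    for chrom, cents in true_centers.items():
        total += len(cents)
        mids = np.sort(calls.loc[calls.chrom == chrom, "midpoint"].to_numpy())
        if len(mids) == 0:
            continue
        idx = np.searchsorted(mids, cents)
        for c, i in zip(cents, idx):
            best = min((abs(int(mids[j]) - int(c)) for j in (i - 1, i)
                        if 0 <= j < len(mids)), default=tolerance + 1)
            matched += best <= tolerance
    return matched / total if total else float("nan")
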