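"""Nucleosome-depleted region (NDR) detection and cross-condition classes.

An NDR is a maximal run of at least ``min_length`` (150) consecutive bases
whose normalized occupancy is strictly below ``max_occupancy`` (0.4).  Given
calls from several conditions, an NDR is *constitutive* when, in every other
condition, some called NDR covers at least half of its length, and
*condition-specific* otherwise; overlapping specific calls from several
conditions of the same regime are unioned into one region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._util import round_half_away
from .profiles import OccupancyTrack

NDR_COLUMNS = ["chrom", "start", "end", "length", "min_occupancy", "condition_class"]


@dataclass
class NDRSummary:
    n: int
    mean_length: float
    sd_length: float
    evicted_estimate: float
    evicted_rounded: int


def call_ndrs(track: OccupancyTrack, min_length: int = 150,
              max_occupancy: float = 0.4) -> pd.DataFrame:
    """Maximal sub-threshold runs of length >= ``min_length`` (strict < threshold)."""
    rows = []
    for chrom in sorted(track.data):
        occ = track.data[chrom]
        below = occ < max_occupancy
        padded = np.concatenate(([False], below, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for start, end in zip(edges[::2], edges[1::2]):
            if end - start >= min_length:
                rows.append((chrom, int(start), int(end), int(end - start),
                             float(occ[start:end].min()), ""))
    return pd.DataFrame(rows, columns=NDR_COLUMNS)


def _covered_fraction(start: int, end: int, others: pd.DataFrame) -> float:
    """Largest fraction of [start, end) covered by a single interval of ``others``."""
    if others.empty:
        return 0.0
    o_start = others["start"].to_numpy()
    o_end = others["end"].to_numpy()
    overlap = np.minimum(o_end, end) - np.maximum(o_start, start)
    return float(overlap.max()) / (end - start) if len(overlap) else 0.0


def classify_conditions(ndr_sets: Dict[str, pd.DataFrame],
                        min_overlap_fraction: float = 0.5) -> pd.DataFrame:
    """Partition NDRs into constitutive and condition-specific regions.

    Returns one merged table: constitutive regions (unioned across the
    conditions that called them) and specific regions labelled
    ``specific:<cond>`` (or ``specific:<c1>+<c2>`` when overlapping specific
    calls from several conditions union into one region).
    """
    conds = sorted(ndr_sets)
    if len(conds) < 2:
        raise ValueError("cross-condition classification needs >= 2 conditions")
    pieces: List[Tuple[str, int, int, str]] = []   # (chrom, start, end, cond or "")
    for cond in conds:
        own = ndr_sets[cond]
        for row in own.itertuples():
            constitutive = True
            for other in conds:
                if other == cond:
                    continue
                others = ndr_sets[other]
                others = others[others["chrom"] == row.chrom]
                if _covered_fraction(row.start, row.end, others) < min_overlap_fraction:
                    constitutive = False
                    break
            pieces.append((row.chrom, int(row.start), int(row.end),
                           "" if constitutive else cond))

    out = []
    for is_specific in (False, True):
        group = [p for p in pieces if bool(p[3]) == is_specific]
        group.sort(key=lambda p: (p[0], p[1], p[2]))
        merged: List[List] = []
        for chrom, start, end, cond in group:
            if merged and merged[-1][0] == chrom and start < merged[-1][2]:
                merged[-1][2] = max(merged[-1][2], end)
                if cond:
                    merged[-1][3].add(cond)
            else:
                merged.append([chrom, start, end, {cond} if cond else set()])
        for chrom, start, end, cs in merged:
            label = ("specific:" + "+".join(sorted(cs))) if cs else "constitutive"
            out.append((chrom, start, end, end - start, np.nan, label))
    df = pd.DataFrame(out, columns=NDR_COLUMNS)
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def ndr_summary(ndrs: pd.DataFrame, spacing: float = 152.0) -> NDRSummary:
    """Count, length moments and the implied number of evicted nucleosomes.

    evicted = n * mean_length / spacing, reported raw and rounded to the
    nearest hundred (total depleted span divided by one nucleosomal repeat).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    n = len(ndrs)
    if n == 0:
        return NDRSummary(0, float("nan"), float("nan"), 0.0, 0)
    lengths = ndrs["length"].to_numpy(dtype=float)
    mean = float(lengths.mean())
    sd = float(lengths.std(ddof=1)) if n >= 2 else float("nan")
    evicted = n * mean / spacing
    return NDRSummary(n=n, mean_length=mean, sd_length=sd,
                      evicted_estimate=evicted,
                      evicted_rounded=int(round_half_away(evicted / 100.0, 0) * 100))


def evicted_nucleosomes(n: int, mean_length: float, spacing: float = 152.0) -> float:
    """Closed-form evicted-nucleosome estimate from printed summary statistics."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    return n * mean_length / spacing


def match_ndrs(truth: pd.DataFrame, called: pd.DataFrame,
               min_overlap_fraction: float = 0.5) -> Tuple[float, float, Optional[float]]:
    """(precision, recall, median boundary error) of called vs ground-truth NDRs.

    A true NDR is recovered when a call covers >= ``min_overlap_fraction``
    of it; a call is correct when it covers >= that fraction of some truth.
    Boundary error is the absolute start/end offset of matched pairs.
    """
    def hit(a_row, b: pd.DataFrame) -> Optional[pd.Series]:
        b = b[b["chrom"] == a_row.chrom]
        if b.empty:
            return None
        ov = np.minimum(b["end"].to_numpy(), a_row.end) - \
            np.maximum(b["start"].to_numpy(), a_row.start)
        i = int(np.argmax(ov))
        if ov[i] / (a_row.end - a_row.start) >= min_overlap_fraction:
            return b.iloc[i]
        return None

    recovered, errors = 0, []
    for row in truth.itertuples():
        m = hit(row, called)
        if m is not None:
            recovered += 1
            errors += [abs(int(m["start"]) - row.start), abs(int(m["end"]) - row.end)]
    correct = sum(hit(row, truth) is not None for row in called.itertuples())
    precision = correct / len(called) if len(called) else float("nan")
    recall = recovered / len(truth) if len(truth) else float("nan")
    med = float(np.median(errors)) if errors else None
    return precision, recall, med
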