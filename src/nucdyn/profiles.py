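"""Strand-specific boundary profiles and smoothed occupancy tracks.

Mononucleosomal read 5' ends pile up on the two strands at the left and
right boundaries of each nucleosome.  The pipeline: (1) tally 5' ends per
base and strand, (2) estimate the strand shift — the lag maximising the
plus/minus cross-correlation, which approximates the protected fragment
length — (3) move each strand shift/2 toward the other so both pile up at
the nucleosome midpoint, sum them, smooth with a multilevel biorthogonal
wavelet approximation, and (4) divide by the genome-wide mean so occupancy
is expressed relative to average coverage (genome mean == 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pywt

from .simulate import ReadSet

log = logging.getLogger(__name__)

DEFAULT_WAVELET = "bior3.5"
DEFAULT_LEVEL = 5
DEFAULT_SHIFT_WINDOW = (100, 250)


@dataclass
class StrandProfiles:
    """Per-base 5'-end counts on each strand, one vector pair per chromosome."""

    plus: Dict[str, np.ndarray]
    minus: Dict[str, np.ndarray]
    n_reads: int
    n_rejected: int = 0

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(v) for c, v in self.plus.items()}


@dataclass
class ShiftEstimate:
    """Estimated strand shift (even, bp) and the cross-correlation curve."""

    shift: int
    lags: np.ndarray
    curve: np.ndarray


@dataclass
class OccupancyTrack:
    """Normalized smoothed nucleosome occupancy; genome-wide mean is 1.0."""

    data: Dict[str, np.ndarray]
    condition: str = ""
    shift: int = 0
    wavelet: str = DEFAULT_WAVELET
    level: int = DEFAULT_LEVEL
    raw_mean: float = field(default=float("nan"))

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}

    def genome_mean(self) -> float:
        total = sum(float(v.sum()) for v in self.data.values())
        n = sum(len(v) for v in self.data.values())
        return total / n


def build_strand_profiles(reads: ReadSet) -> StrandProfiles:
    """Tally 5' ends per base and strand; out-of-bounds reads are rejected and counted."""
    plus = {c: np.zeros(n, dtype=np.int64) for c, n in reads.chrom_sizes.items()}
    minus = {c: np.zeros(n, dtype=np.int64) for c, n in reads.chrom_sizes.items()}
    rejected = 0
    kept = 0
    for chrom, sub in reads.reads.groupby("chrom", sort=False):
        if chrom not in plus:
            raise ValueError(f"read on unknown chromosome {chrom!r}")
        n = len(plus[chrom])
        pos = sub["pos"].to_numpy()
        ok = (pos >= 0) & (pos < n)
        rejected += int((~ok).sum())
        sub = sub[ok]
        for strand, target in (("+", plus), ("-", minus)):
            p = sub.loc[sub["strand"] == strand, "pos"].to_numpy()
            target[chrom] += np.bincount(p, minlength=n).astype(np.int64)
            kept += len(p)
    if rejected:
        log.warning("rejected %d reads outside chromosome bounds", rejected)
    return StrandProfiles(plus=plus, minus=minus, n_reads=kept, n_rejected=rejected)


def estimate_shift(profiles: StrandProfiles,
                   search_window: Tuple[int, int] = DEFAULT_SHIFT_WINDOW) -> ShiftEstimate:
    """Lag maximising the pooled plus/minus cross-correlation, rounded to even.

    The cross-correlation is pooled over chromosomes (a single genome-wide
    shift).  Ties go to the smallest lag; an odd best lag is resolved to the
    better-scoring even neighbour so that shift/2 is integral.  A maximum on
    the window boundary means the optimum lies outside the window and is an
    error.
    """
    lo, hi = int(search_window[0]), int(search_window[1])
    if not 0 < lo < hi:
        raise ValueError("invalid search window")
    for d in (profiles.plus, profiles.minus):
        if sum(int(v.sum()) for v in d.values()) == 0:
            raise ValueError("cannot estimate shift from an empty strand")
    lags = np.arange(lo, hi + 1)
    curve = np.zeros(len(lags))
    any_var = False
    for chrom in profiles.plus:
        p = profiles.plus[chrom].astype(np.float64)
        m = profiles.minus[chrom].astype(np.float64)
        if p.std() > 0 and m.std() > 0:
            any_var = True
        for i, lag in enumerate(lags):
            if lag < len(p):
                curve[i] += float(p[:len(p) - lag] @ m[lag:])
    if not any_var or np.ptp(curve) == 0:
        raise ValueError("flat strand profiles: shift is undefined")
    best = int(lags[int(np.argmax(curve))])
    if best in (lo, hi):
        raise ValueError(
            f"cross-correlation maximum at window edge ({best}); widen the window")
    if best % 2:
        left, right = best - 1, best + 1
        lv = curve[left - lo] if left >= lo else -np.inf
        rv = curve[right - lo] if right <= hi else -np.inf
        best = left if lv >= rv else right
    return ShiftEstimate(shift=best, lags=lags, curve=curve)


def wavelet_smooth(signal: np.ndarray, family: str = DEFAULT_WAVELET,
                   level: int = DEFAULT_LEVEL) -> np.ndarray:
    """Reconstruction from the level-``level`` wavelet approximation.

    Detail coefficients are zeroed, so the result is the low-frequency
    approximation at scale ~2**level bp, same length as the input.  Linear
    in the input; symmetric boundary padding avoids edge spikes.
    """
    x = np.asarray(signal, dtype=np.float64)
    if level < 1:
        raise ValueError("level must be >= 1")
    if x.size <= 2 ** level:
        raise ValueError(f"signal of length {x.size} too short for level {level}")
    coeffs = pywt.wavedec(x, family, mode="symmetric", level=level)
    coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    return pywt.waverec(coeffs, family, mode="symmetric")[: x.size]


def combine_and_normalize(profiles: StrandProfiles, shift: ShiftEstimate,
                          family: str = DEFAULT_WAVELET, level: int = DEFAULT_LEVEL,
                          condition: str = "") -> OccupancyTrack:
    """Converge the strands onto nucleosome midpoints and normalize.

    The plus profile moves +shift/2, the minus profile -shift/2; the sum is
    wavelet-smoothed, clipped at zero, and divided by its genome-wide mean
    so the final track has mean exactly 1.  Positions shifted off a
    chromosome end are dropped and logged.
    """
    s2 = shift.shift // 2
    data: Dict[str, np.ndarray] = {}
    dropped = 0
    for chrom in profiles.plus:
        p = profiles.plus[chrom]
        m = profiles.minus[chrom]
        n = len(p)
        comb = np.zeros(n, dtype=np.float64)
        if s2 < n:
            comb[s2:] += p[: n - s2]
            comb[: n - s2] += m[s2:]
            dropped += int(p[n - s2:].sum()) + int(m[:s2].sum())
        smoothed = wavelet_smooth(comb, family, level) if n > 2 ** level else comb
        data[chrom] = np.clip(smoothed, 0.0, None)
    if dropped:
        log.info("dropped %d 5' ends shifted past chromosome ends", dropped)
    total = sum(float(v.sum()) for v in data.values())
    nbases = sum(len(v) for v in data.values())
    raw_mean = total / nbases
    if raw_mean == 0:
        raise ValueError("no coverage: genome-wide mean is zero")
    for chrom in data:
        data[chrom] /= raw_mean
    return OccupancyTrack(data=data, condition=condition, shift=shift.shift,
                          wavelet=family, level=level, raw_mean=raw_mean)


def profile_correlation(a: OccupancyTrack, b: OccupancyTrack) -> float:
    """Pearson correlation of two tracks over all genome positions."""
    if a.chrom_sizes != b.chrom_sizes:
        raise ValueError("tracks cover different chromosomes")
    x = np.concatenate([a.data[c] for c in sorted(a.data)])
    y = np.concatenate([b.data[c] for c in sorted(b.data)])
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance track: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def track_from_reads(reads: ReadSet, family: str = DEFAULT_WAVELET,
                     level: int = DEFAULT_LEVEL,
                     search_window: Tuple[int, int] = DEFAULT_SHIFT_WINDOW,
                     condition: str = "") -> Tuple[OccupancyTrack, ShiftEstimate]:
    """Reads -> strand profiles -> shift -> normalized occupancy, in one call."""
    profiles = build_strand_profiles(reads)
    shift = estimate_shift(profiles, search_window)
    track = combine_and_normalize(profiles, shift, family, level, condition)
    return track, shift
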