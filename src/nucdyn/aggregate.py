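"""Anchor-aligned (metagene) occupancy profiles and expression gene sets.

Every gene contributes its occupancy window read in transcription direction,
aligned at one of six anchors: the +1 nucleosome (closest call downstream of
the TSS), the -1 nucleosome (closest upstream), the central nucleosome CN
(closest to the TSS-TTS midpoint), the terminal nucleosome TN (closest
upstream of the TTS), or the annotated TSS/TTS coordinate itself.
Anchoring on called nucleosomes realigns arrays whose phase relative to the
TSS varies between genes, which is why +1N-aligned profiles oscillate with
larger amplitude than TSS-aligned ones.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .profiles import OccupancyTrack

log = logging.getLogger(__name__)

ANCHOR_KINDS = ("+1N", "-1N", "CN", "TN", "TSS", "TTS")

#: expression presets: minimum fold over background defining "overexpressed"
FOLD_PRESETS = {"overexpressed": 1.5, "strong": 4.0}

#: gene-length preset: ~1800 bp +/- 20%
LENGTH_WINDOW_1800 = (1440, 2160)


def _direction(strand: str) -> int:
    if strand not in "+-":
        raise ValueError(f"bad strand {strand!r}")
    return 1 if strand == "+" else -1


def select_anchor(genes: pd.DataFrame, calls: pd.DataFrame,
                  kind: str) -> Tuple[pd.DataFrame, List[str]]:
    """Per-gene anchor coordinate of the requested kind.

    Returns (anchors, skipped_gene_ids).  Anchors columns: gene_id, chrom,
    strand, anchor, kind.  Distance ties between two candidate nucleosomes
    go to the upstream one (in transcription direction).
    """
    if kind not in ANCHOR_KINDS:
        raise ValueError(f"unknown anchor kind {kind!r}")
    by_chrom = {c: np.sort(s["midpoint"].to_numpy())
                for c, s in calls.groupby("chrom", sort=False)} if len(calls) else {}
    rows, skipped = [], []
    for g in genes.itertuples():
        d = _direction(g.strand)
        if kind == "TSS":
            anchor = int(g.tss)
        elif kind == "TTS":
            anchor = int(g.tts)
        else:
            mids = by_chrom.get(g.chrom, np.empty(0, dtype=int))
            anchor = _nucleosome_anchor(mids, kind, int(g.tss), int(g.tts), d)
            if anchor is None:
                skipped.append(g.gene_id)
                continue
        rows.append((g.gene_id, g.chrom, g.strand, anchor, kind))
    if skipped:
        log.info("%d genes lack a qualifying %s nucleosome and were skipped",
                 len(skipped), kind)
    return (pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "anchor", "kind"]),
            skipped)


def _nucleosome_anchor(mids: np.ndarray, kind: str, tss: int, tts: int,
                       d: int) -> Optional[int]:
    if len(mids) == 0:
        return None
    rel_tss = (mids - tss) * d     # >0 downstream of TSS in transcription direction
    if kind == "+1N":
        cand = mids[rel_tss >= 0]
        return int(cand[np.argmin(np.abs((cand - tss) * d))]) if len(cand) else None
    if kind == "-1N":
        cand = mids[rel_tss < 0]
        return int(cand[np.argmin(np.abs((cand - tss) * d))]) if len(cand) else None
    if kind == "TN":
        cand = mids[(mids - tts) * d < 0]
        return int(cand[np.argmin(np.abs((cand - tts) * d))]) if len(cand) else None
    # CN: closest to the TSS-TTS midpoint; tie -> upstream candidate
    target = (tss + tts) / 2.0
    dist = np.abs(mids - target)
    best = dist.min()
    tied = mids[dist == best]
    return int(tied[0] if d == 1 else tied[-1])


def aggregate_profile(track: OccupancyTrack, anchors: pd.DataFrame,
                      flank: int = 1000) -> pd.DataFrame:
    """Mean occupancy per offset in [-flank, flank], oriented by gene strand.

    Offsets that fall off a chromosome are excluded from that gene's
    contribution; the per-offset gene count ``n_genes`` tracks the attrition.
    Columns: offset, mean_occupancy, n_genes.
    """
    if anchors.empty:
        raise ValueError("empty anchor set")
    offsets = np.arange(-flank, flank + 1)
    total = np.zeros(len(offsets))
    count = np.zeros(len(offsets), dtype=np.int64)
    for a in anchors.itertuples():
        occ = track.data[a.chrom]
        pos = a.anchor + _direction(a.strand) * offsets
        ok = (pos >= 0) & (pos < len(occ))
        total[ok] += occ[pos[ok]]
        count[ok] += 1
    mean = np.full(len(offsets), np.nan)
    nz = count > 0
    mean[nz] = total[nz] / count[nz]
    return pd.DataFrame({"offset": offsets, "mean_occupancy": mean, "n_genes": count})


def select_genes_by_expression(genes: pd.DataFrame, fold_bin: Tuple[float, float],
                               length_window: Optional[Tuple[float, float]] = None,
                               n: Optional[int] = None) -> pd.DataFrame:
    """Genes with expression_fold in [lo, hi) and length in the window.

    Ordered closest-to-bin-centre first (ties by gene id) and truncated to
    ``n``; if fewer than ``n`` match, all matches are returned with a warning.
    Gene length is measured TSS to TTS.
    """
    if "expression_fold" not in genes.columns:
        raise ValueError("gene table lacks an expression_fold column")
    lo, hi = fold_bin
    sel = genes[(genes["expression_fold"] >= lo) & (genes["expression_fold"] < hi)].copy()
    sel["__length"] = (sel["tts"] - sel["tss"]).abs() + 1
    if length_window is not None:
        sel = sel[(sel["__length"] >= length_window[0]) &
                  (sel["__length"] <= length_window[1])]
    centre = (lo + hi) / 2.0
    sel["__dist"] = (sel["expression_fold"] - centre).abs()
    sel = sel.sort_values(["__dist", "gene_id"], kind="stable")
    if n is not None:
        if len(sel) < n:
            log.warning("only %d genes match the bin [%g, %g); %d requested",
                        len(sel), lo, hi, n)
        sel = sel.head(n)
    return sel.drop(columns=["__dist", "__length"]).reset_index(drop=True)


def oscillation_amplitude(profile: pd.DataFrame,
                          offset_range: Tuple[int, int] = (0, 800)) -> float:
    """Standard deviation of the mean profile over an offset range."""
    lo, hi = offset_range
    sub = profile[(profile["offset"] >= lo) & (profile["offset"] <= hi)]
    vals = sub["mean_occupancy"].to_numpy()
    return float(np.nanstd(vals))


def profile_periodicity(profile: pd.DataFrame,
                        offset_range: Tuple[int, int] = (0, 1000),
                        lag_range: Tuple[int, int] = (100, 250)) -> int:
    """Autocorrelation-peak lag of the aggregated profile (the array repeat)."""
    lo, hi = offset_range
    sub = profile[(profile["offset"] >= lo) & (profile["offset"] <= hi)]
    x = sub["mean_occupancy"].to_numpy()
    x = x[~np.isnan(x)]
    x = x - x.mean()
    lags = np.arange(lag_range[0], lag_range[1] + 1)
    ac = np.array([float(x[:len(x) - k] @ x[k:]) for k in lags])
    return int(lags[int(np.argmax(ac))])
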