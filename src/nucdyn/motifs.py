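"""Degenerate consensus motif scanning and motif/NDR colocalization.

Consensus binding sites are IUPAC strings (R = A/G, D = A/G/T, ...).  The
scanner reports every (optionally both-strand) overlapping occurrence; `N`
in the subject sequence never matches.  Colocalization follows two rules:
a motif occurrence counts *inside* an NDR only when its full match window is
contained in the interval, while a binding-site feature *overlaps* an NDR as
soon as one base does.

``CONSENSUS_MOTIFS`` bundles the fission-yeast regulators most relevant to
promoter NDRs: Ste11 and Mei4 (meiotic induction), Rsv1, the CRE element and
its variant bound by ATF/CREB factors (Atf1/Pcr1), and the Php4 CCAAT box.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product
from typing import Dict, Iterable, List, Tuple

import pandas as pd

from ._util import percent

IUPAC: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C",
               "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
               "B": "V", "V": "B", "D": "H", "H": "D", "N": "N"}

#: bundled consensus binding sites (bracket notation normalized to IUPAC)
CONSENSUS_MOTIFS: Dict[str, str] = {
    "Ste11": "AACAAAGRA",
    "Mei4": "GTAAACAAA",
    "Rsv1": "CCCCDC",
    "CRE": "TGACGT",
    "CRE_variant": "TGACATCAT",
    "Php4": "CCAATCA",
}

HIT_COLUMNS = ["motif", "chrom", "start", "end", "strand"]


@dataclass
class MotifDefinition:
    name: str
    consensus: str
    both_strands: bool = True

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        if not self.consensus:
            raise ValueError("empty consensus")
        bad = set(self.consensus) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC letters {sorted(bad)} in {self.name}")

    def reverse_complement(self) -> str:
        return "".join(_COMPLEMENT[c] for c in reversed(self.consensus))

    def words(self) -> List[str]:
        """All concrete DNA words matching the consensus."""
        return ["".join(w) for w in product(*(IUPAC[c] for c in self.consensus))]


@dataclass
class OverlapReport:
    n_features: int
    n_overlapping: int
    percent: float

    @classmethod
    def from_counts(cls, n_features: int, n_overlapping: int) -> "OverlapReport":
        if n_overlapping > n_features:
            raise ValueError("overlap count exceeds feature count")
        return cls(n_features, n_overlapping, percent(n_overlapping, n_features))


def _pattern(consensus: str) -> re.Pattern:
    # character classes never include N, so N in the subject never matches
    return re.compile("".join(c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]"
                              for c in consensus))


def scan_motif(sequences: Dict[str, str], motif: MotifDefinition) -> pd.DataFrame:
    """All (overlapping) occurrences of the consensus, optionally both strands."""
    fwd = _pattern(motif.consensus)
    rev = _pattern(motif.reverse_complement()) if motif.both_strands else None
    k = len(motif.consensus)
    rows: List[Tuple] = []
    for chrom in sorted(sequences):
        seq = sequences[chrom].upper()
        for pat, strand in ((fwd, "+"),) + (((rev, "-"),) if rev else ()):
            pos = 0
            while True:
                m = pat.search(seq, pos)
                if m is None:
                    break
                rows.append((motif.name, chrom, m.start(), m.start() + k, strand))
                pos = m.start() + 1     # step one base: report overlapping matches
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return df.sort_values(["chrom", "start", "strand"], kind="stable").reset_index(drop=True)


def scan_motifs(sequences: Dict[str, str],
                motifs: Iterable[MotifDefinition]) -> pd.DataFrame:
    frames = [scan_motif(sequences, m) for m in motifs]
    return (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=HIT_COLUMNS))


def count_motifs_in_ndrs(ndrs: pd.DataFrame,
                         hits: pd.DataFrame) -> Tuple[pd.Series, Dict[int, int]]:
    """Per-NDR count of hits whose full window lies within [start, end).

    Returns (counts aligned to the NDR index, histogram of counts).
    """
    counts = []
    for row in ndrs.itertuples():
        sub = hits[(hits["chrom"] == row.chrom) &
                   (hits["start"] >= row.start) & (hits["end"] <= row.end)]
        counts.append(len(sub))
    series = pd.Series(counts, index=ndrs.index, name="motif_count")
    hist: Dict[int, int] = {}
    for c in counts:
        hist[c] = hist.get(c, 0) + 1
    return series, hist


def overlap_fraction(features: pd.DataFrame, ndrs: pd.DataFrame) -> OverlapReport:
    """Fraction of features sharing >= 1 bp with any NDR.

    ``features`` needs chrom/start/end (half-open); a point feature is a
    1-bp interval.
    """
    if features.empty:
        raise ValueError("overlap percentage undefined for an empty feature list")
    n_overlap = 0
    for f in features.itertuples():
        sub = ndrs[ndrs["chrom"] == f.chrom]
        if ((sub["start"] < f.end) & (sub["end"] > f.start)).any():
            n_overlap += 1
    return OverlapReport.from_counts(len(features), n_overlap)


def load_motif_table(path) -> List[MotifDefinition]:
    """Read a motif TSV with columns name, consensus[, both_strands]."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        both = bool(row["both_strands"]) if "both_strands" in df.columns else True
        out.append(MotifDefinition(str(row["name"]), str(row["consensus"]), both))
    return out
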