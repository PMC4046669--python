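"""Synthetic MNase-seq benchmark generator.

Builds an annotated random genome, a ground-truth chromatin configuration
(phased nucleosome arrays interrupted by promoter nucleosome-depleted
regions), and strand-specific mononucleosomal read sets for one or more
conditions.  The second and later conditions differ from the first only in a
configurable fraction of "toggled" promoter NDRs that are filled with
nucleosomes there — the situation arising when a developmental programme
(e.g. meiotic induction) opens promoters that are closed during vegetative
growth.

The generator is fully deterministic given ``SimConfig.seed`` and uses one
pseudorandom stream per (seed, chromosome, purpose[, condition]) so that
adding chromosomes or conditions never perturbs previously generated data.

Defaults encode the structure of a fission-yeast mononucleosomal dataset:
nucleosome midpoints spaced 152 bp apart, core-particle fragments of
~147 bp, promoter NDRs with lengths Normal(214.68, 71.06) truncated at
150 nt, and sequencing coverage in the 46-177x range (default 50x).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import stream

# stream-purpose tags (second element of the RNG key)
_GENOME, _GENES, _CHROMATIN, _READS = 1, 2, 3, 4


class PlacementError(ValueError):
    """Raised when the requested genes cannot be placed on the genome."""


@dataclass
class SimConfig:
    """Parameters of the synthetic genome, chromatin and sequencing run.

    All lengths are in base pairs.  ``fuzziness_sd`` is the cell-to-cell
    positional jitter of each nucleosome's midpoint; ``phase_jitter`` is the
    gene-to-gene variability of where the nucleosome array restarts after a
    barrier (chromosome start or NDR), which makes anchor-aligned profiles
    sharper than TSS-aligned ones, as in real data.
    """

    n_chromosomes: int = 1
    chrom_length: int = 100_000
    gc_content: float = 0.36
    n_genes: int = 20
    gene_length_mean: int = 1500
    spacing: int = 152
    fragment_length_mean: int = 147
    fragment_length_sd: float = 10.0
    fuzziness_sd: float = 30.0
    phase_jitter: int = 60
    ndr_length_mean: float = 214.68
    ndr_length_sd: float = 71.06
    ndr_min: int = 150
    coverage: float = 50.0
    toggled_ndr_fraction: float = 0.2
    seed: int = 0

    # geometry constants: half of a core particle, rounded up
    _half_nuc: int = field(default=74, init=False, repr=False)

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.chrom_length, self.gene_length_mean,
               self.spacing, self.fragment_length_mean, self.ndr_min) <= 0:
            raise ValueError("all lengths and counts must be positive")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie strictly between 0 and 1")
        if self.ndr_min < 150:
            raise ValueError("ndr_min below 150 cannot evict a full nucleosome")
        if self.coverage < 0:
            raise ValueError("coverage must be non-negative")
        if not 0.0 <= self.toggled_ndr_fraction <= 1.0:
            raise ValueError("toggled_ndr_fraction must be a fraction")
        if self.n_genes < 0 or self.fragment_length_sd < 0 or self.fuzziness_sd < 0:
            raise ValueError("negative parameter")


@dataclass
class TrueChromatin:
    """Ground truth: per-condition nucleosome midpoints and NDR intervals.

    ``ndrs`` has one row per planted NDR with 0-based half-open coordinates,
    the owning gene, a ``toggled`` flag and one boolean ``present_<cond>``
    column per condition.
    """

    conditions: List[str]
    centers: Dict[str, Dict[str, np.ndarray]]
    ndrs: pd.DataFrame
    chrom_sizes: Dict[str, int]

    def present_ndrs(self, condition: str) -> pd.DataFrame:
        return self.ndrs[self.ndrs[f"present_{condition}"]].reset_index(drop=True)


@dataclass
class ReadSet:
    """Strand-specific 5' read ends; the only coordinates used downstream.

    ``reads`` columns: chrom, pos (0-based 5' end), strand (+/-),
    fragment_length.  Each simulated fragment contributes one plus-strand
    record at its leftmost covered base and one minus-strand record at its
    rightmost covered base.
    """

    reads: pd.DataFrame
    chrom_sizes: Dict[str, int]

    def __len__(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# genome


def generate_genome(config: SimConfig) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Random genome at the configured GC content plus a gene table.

    Genes are non-overlapping, strand-assigned intervals separated by
    intergenic gaps wide enough to host a promoter NDR.  Returns
    ``(sequences, genes)`` where ``genes`` has columns gene_id, chrom,
    strand, start, end (0-based half-open), tss, tts.
    """
    margin = 600          # clearance at chromosome ends for promoter NDRs
    bases = np.array(list("ACGT"))
    p = np.array([(1 - config.gc_content) / 2, config.gc_content / 2,
                  config.gc_content / 2, (1 - config.gc_content) / 2])

    seqs: Dict[str, str] = {}
    rows = []
    per_chrom = _split_counts(config.n_genes, config.n_chromosomes)
    gid = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        rng = stream(config.seed, _GENOME, ci)
        seqs[chrom] = "".join(bases[rng.choice(4, size=config.chrom_length, p=p)])

        grng = stream(config.seed, _GENES, ci)
        cursor = margin
        for _ in range(per_chrom[ci]):
            length = max(300, int(round(grng.normal(config.gene_length_mean,
                                                    0.2 * config.gene_length_mean))))
            start, end = cursor, cursor + length
            if end > config.chrom_length - margin:
                raise PlacementError(
                    f"cannot place {per_chrom[ci]} genes of ~{config.gene_length_mean} bp "
                    f"on a {config.chrom_length} bp chromosome")
            strand = "+" if grng.random() < 0.5 else "-"
            tss, tts = (start, end - 1) if strand == "+" else (end - 1, start)
            gid += 1
            rows.append((f"g{gid:04d}", chrom, strand, start, end, tss, tts))
            cursor = end + int(grng.integers(900, 1400))

    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand",
                                        "start", "end", "tss", "tts"])
    return seqs, genes


def _split_counts(total: int, parts: int) -> List[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


# ---------------------------------------------------------------------------
# chromatin


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= lower:
            return x
    return lower


def place_chromatin(genome: Dict[str, str], genes: pd.DataFrame,
                    config: SimConfig,
                    conditions: Sequence[str] = ("cond1", "cond2")) -> TrueChromatin:
    """Plant promoter NDRs and tile phased nucleosome arrays around them.

    One NDR is placed immediately upstream of each TSS (abutting it on the
    gene's transcriptional orientation) with length drawn from
    Normal(ndr_length_mean, ndr_length_sd) truncated at ``ndr_min``.  A
    ``toggled_ndr_fraction`` of NDRs per chromosome is present only in the
    first condition and filled with nucleosomes elsewhere.  Arrays restart
    after every barrier (chromosome start or present NDR) at half-nucleosome
    clearance plus a per-barrier phase offset shared across conditions.
    """
    conditions = list(conditions)
    if len(conditions) < 1:
        raise ValueError("need at least one condition")
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    half = config._half_nuc

    ndr_rows = []
    offsets: Dict[Tuple[str, int], int] = {}   # (chrom, barrier id) -> phase offset
    for ci, chrom in enumerate(sorted(genome)):
        rng = stream(config.seed, _CHROMATIN, ci)
        L = chrom_sizes[chrom]
        offsets[(chrom, -1)] = int(rng.integers(0, config.phase_jitter + 1))
        sub = genes[genes.chrom == chrom]
        chrom_ndrs = []
        for g in sub.itertuples():
            length = int(round(_truncated_normal(rng, config.ndr_length_mean,
                                                 config.ndr_length_sd, config.ndr_min)))
            if g.strand == "+":
                start, end = g.tss - length, g.tss
            else:
                start, end = g.tss + 1, g.tss + 1 + length
            start, end = max(0, start), min(L, end)
            if end - start >= config.ndr_min:
                chrom_ndrs.append([chrom, start, end, g.gene_id])
        chrom_ndrs.sort(key=lambda r: r[1])
        # drop rare overlaps so planted NDRs are disjoint ground truth
        pruned = []
        for r in chrom_ndrs:
            if pruned and r[1] < pruned[-1][2]:
                continue
            pruned.append(r)
        n_toggle = int(round(config.toggled_ndr_fraction * len(pruned)))
        toggle_idx = set(rng.choice(len(pruned), size=n_toggle, replace=False)
                         ) if n_toggle else set()
        for i, r in enumerate(pruned):
            offsets[(chrom, len(ndr_rows))] = int(rng.integers(0, config.phase_jitter + 1))
            ndr_rows.append(r + [i in toggle_idx])

    ndrs = pd.DataFrame(ndr_rows,
                        columns=["chrom", "zone_start", "zone_end", "gene_id", "toggled"])
    ndrs.insert(0, "ndr_id", [f"ndr{i:04d}" for i in range(len(ndrs))])
    for j, cond in enumerate(conditions):
        # toggled NDRs exist only in the first condition
        ndrs[f"present_{cond}"] = True if j == 0 else ~ndrs["toggled"]

    centers: Dict[str, Dict[str, np.ndarray]] = {c: {} for c in conditions}
    for cond in conditions:
        for chrom in sorted(genome):
            L = chrom_sizes[chrom]
            present = ndrs[(ndrs.chrom == chrom) & ndrs[f"present_{cond}"]]
            barrier_ids = [i for i in ndrs.index[ndrs.chrom == chrom]
                           if ndrs.at[i, f"present_{cond}"]]
            segs = []   # (segment start incl. clearance+offset, segment end limit)
            prev_end, prev_off = 0, offsets[(chrom, -1)]
            for bid, row in zip(barrier_ids, present.itertuples()):
                segs.append((prev_end + half + prev_off, row.zone_start - half))
                prev_end, prev_off = row.zone_end, offsets[(chrom, bid)]
            segs.append((prev_end + half + prev_off, L - half))
            pos = []
            for a, b in segs:
                c = a
                while c <= b:
                    pos.append(c)
                    c += config.spacing
            centers[cond][chrom] = np.asarray(pos, dtype=np.int64)

    # ground-truth NDR interval = the realized nucleosome-free gap between the
    # DNA edges of the flanking nucleosomes in the first condition (where all
    # NDRs are present); it contains the drawn exclusion zone plus the array
    # phase slack on each side.
    ref = conditions[0]
    starts, ends = [], []
    for row in ndrs.itertuples():
        cents = centers[ref][row.chrom]
        before = cents[cents < row.zone_start]
        after = cents[cents > row.zone_end]
        starts.append(int(before.max()) + half if len(before) else row.zone_start)
        ends.append(int(after.min()) - half + 1 if len(after) else row.zone_end)
    ndrs["start"] = starts
    ndrs["end"] = ends
    ndrs = ndrs[["ndr_id", "chrom", "start", "end", "zone_start", "zone_end",
                 "gene_id", "toggled"] +
                [f"present_{c}" for c in conditions]]
    return TrueChromatin(conditions=conditions, centers=centers, ndrs=ndrs,
                         chrom_sizes=chrom_sizes)


# ---------------------------------------------------------------------------
# reads


def simulate_reads(chromatin: TrueChromatin, condition: str,
                   config: SimConfig) -> ReadSet:
    """Sample mononucleosomal fragments and emit their boundary 5' ends.

    Per-nucleosome fragment counts are Poisson with a rate set so the mean
    per-base coverage matches ``config.coverage``.  Each fragment has
    midpoint = center + Normal(0, fuzziness_sd) (resampled to stay outside
    present NDRs) and length Normal(fragment_length_mean, fragment_length_sd)
    truncated to [100, 200]; it contributes a plus-strand 5' end at its
    leftmost base and a minus-strand 5' end at its rightmost base.
    """
    if condition not in chromatin.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    cond_idx = chromatin.conditions.index(condition)

    frames = []
    for ci, chrom in enumerate(sorted(chromatin.chrom_sizes)):
        L = chromatin.chrom_sizes[chrom]
        cents = chromatin.centers[condition][chrom]
        if config.coverage == 0 or len(cents) == 0:
            continue
        rng = stream(config.seed, _READS, ci, cond_idx)
        n_frag = int(round(config.coverage * L / config.fragment_length_mean))
        counts = rng.poisson(n_frag / len(cents), size=len(cents))
        mids = np.repeat(cents, counts).astype(float)
        n = len(mids)
        if n == 0:
            continue
        if config.fuzziness_sd > 0:
            jitter = rng.normal(0.0, config.fuzziness_sd, size=n)
            mids = np.rint(mids + jitter)
            # keep fragment midpoints out of nucleosome-free ground truth
            present = chromatin.present_ndrs(condition)
            present = present[present.chrom == chrom]
            starts = present["start"].to_numpy()
            ends = present["end"].to_numpy()
            if len(starts):
                idx = np.searchsorted(starts, mids, side="right") - 1
                bad = (idx >= 0) & (mids < ends[np.clip(idx, 0, None)])
                mids[bad] = np.repeat(cents, counts).astype(float)[bad]
        lengths = np.rint(rng.normal(config.fragment_length_mean,
                                     config.fragment_length_sd, size=n))
        lengths = np.clip(lengths, 100, 200).astype(np.int64)
        # even-length fragments place their extra base on a random side of the
        # midpoint so the boundary pile-ups stay symmetric
        side = rng.integers(0, 2, size=n)
        left = mids.astype(np.int64) - (lengths - 1 + side) // 2
        right = left + lengths - 1
        ok = (left >= 0) & (right < L)
        left, right, lengths = left[ok], right[ok], lengths[ok]
        frames.append(pd.DataFrame({"chrom": chrom, "pos": left,
                                    "strand": "+", "fragment_length": lengths}))
        frames.append(pd.DataFrame({"chrom": chrom, "pos": right,
                                    "strand": "-", "fragment_length": lengths}))

    if frames:
        reads = pd.concat(frames, ignore_index=True)
    else:
        reads = pd.DataFrame(columns=["chrom", "pos", "strand", "fragment_length"])
    return ReadSet(reads=reads, chrom_sizes=dict(chromatin.chrom_sizes))


def simulate_dataset(config: SimConfig,
                     conditions: Sequence[str] = ("cond1", "cond2")):
    """Convenience: genome + annotations + chromatin + one ReadSet per condition."""
    genome, genes = generate_genome(config)
    chromatin = place_chromatin(genome, genes, config, conditions)
    reads = {c: simulate_reads(chromatin, c, config) for c in chromatin.conditions}
    return genome, genes, chromatin, reads
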