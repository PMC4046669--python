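"""Readers and writers for the standard formats the pipeline speaks.

Internal coordinates are 0-based half-open everywhere; conversions happen
only at format boundaries (GFF3 is 1-based inclusive, SAM POS is 1-based).
All emitted BED/bedGraph files are 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import ReadSet, TrueChromatin

log = logging.getLogger(__name__)

BED6 = ["chrom", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------------------
# FASTA / GFF3 / gene tables


def write_fasta(sequences: Dict[str, str], path) -> None:
    records = [SeqRecord(Seq(sequences[c]), id=c, description="")
               for c in sorted(sequences)]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: pd.DataFrame, chrom_sizes: Dict[str, int], path) -> None:
    """Gene features, 1-based inclusive, one ``gene`` line per record."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(chrom_sizes):
            fh.write(f"##sequence-region {chrom} 1 {chrom_sizes[chrom]}\n")
        for g in genes.itertuples():
            fh.write(f"{g.chrom}\tnucdyn\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")


def read_gff3(path) -> pd.DataFrame:
    """Parse gene lines back into the internal 0-based gene table."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: malformed GFF3 record at line {ln}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "gene":
                continue
            gid = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                       ).get("ID", f"gene_at_line_{ln}")
            start0, end0 = int(start) - 1, int(end)
            tss, tts = (start0, end0 - 1) if strand == "+" else (end0 - 1, start0)
            rows.append((gid, chrom, strand, start0, end0, tss, tts))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand",
                                       "start", "end", "tss", "tts"])


def write_gene_tsv(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_gene_tsv(path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "strand", "tss", "tts"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene table lacks columns {sorted(missing)}")
    return genes


# ---------------------------------------------------------------------------
# reads: BED6 and SAM


def write_reads_bed(reads: ReadSet, path, read_length: int = 40) -> None:
    """Reads as BED6 with the 5' end at start (+) or end-1 (-)."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads.reads.itertuples()):
            if r.strand == "+":
                start, end = r.pos, r.pos + read_length
            else:
                start, end = r.pos - read_length + 1, r.pos + 1
            start = max(0, start)
            end = min(reads.chrom_sizes[r.chrom], end)
            fh.write(f"{r.chrom}\t{start}\t{end}\tr{i}\t0\t{r.strand}\n")


def write_reads_sam(reads: ReadSet, path, read_length: int = 40) -> None:
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": c, "LN": reads.chrom_sizes[c]}
                     for c in sorted(reads.chrom_sizes)]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, r in enumerate(reads.reads.itertuples()):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"r{i}"
            a.flag = 0 if r.strand == "+" else 16
            a.reference_name = r.chrom
            start = r.pos if r.strand == "+" else r.pos - read_length + 1
            start = max(0, start)
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{read_length}M"
            a.query_sequence = "N" * read_length
            out.write(a)


def parse_alignments(path, fmt: Optional[str] = None) -> ReadSet:
    """Load aligned reads from SAM or 6-column BED into a ReadSet.

    The 5' coordinate is the BED start (+) / end-1 (-), or the SAM
    reference_start (+) / reference_end-1 (-).  Malformed BED records raise
    with their line number.
    """
    path = Path(path)
    if fmt is None:
        fmt = "sam" if path.suffix.lower() in {".sam", ".bam"} else "bed"
    if fmt == "sam":
        return _parse_sam(path)
    if fmt == "bed":
        return _parse_bed(path)
    raise ValueError(f"unknown alignment format {fmt!r}")


def _parse_bed(path) -> ReadSet:
    rows = []
    maxpos: Dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}: truncated BED record at line {ln}")
            chrom, start, end, _, _, strand = parts[:6]
            if strand not in "+-":
                raise ValueError(f"{path}: bad strand at line {ln}")
            start, end = int(start), int(end)
            pos = start if strand == "+" else end - 1
            rows.append((chrom, pos, strand, end - start))
            maxpos[chrom] = max(maxpos.get(chrom, 0), end)
    reads = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "fragment_length"])
    return ReadSet(reads=reads, chrom_sizes=maxpos)


def _parse_sam(path) -> ReadSet:
    rows = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        sizes = {sam.get_reference_name(i): sam.get_reference_length(sam.get_reference_name(i))
                 for i in range(sam.nreferences)}
        if not sizes:
            raise ValueError(f"{path}: SAM header lists no reference sequences")
        for a in sam:
            if a.is_unmapped:
                continue
            strand = "-" if a.is_reverse else "+"
            pos = a.reference_start if strand == "+" else a.reference_end - 1
            rows.append((a.reference_name, pos, strand, a.query_length))
    reads = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "fragment_length"])
    return ReadSet(reads=reads, chrom_sizes=sizes)


# ---------------------------------------------------------------------------
# tracks, calls, NDRs, truth


def write_bedgraph(track_data: Dict[str, np.ndarray], path,
                   precision: int = 6) -> None:
    """Run-length-compressed bedGraph (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom in sorted(track_data):
            v = np.round(np.asarray(track_data[chrom], dtype=float), precision)
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(v)]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:.{precision}g}\n")


def read_bedgraph(path, chrom_sizes: Dict[str, int]) -> Dict[str, np.ndarray]:
    data = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split()
            if chrom not in data:
                raise ValueError(f"{path}: unknown chromosome {chrom!r} at line {ln}")
            data[chrom][int(start):int(end)] = float(value)
    return data


def write_calls_bed(calls: pd.DataFrame, path) -> None:
    """Nucleosome calls as BED6: 1-bp midpoint interval, score = height*1000 capped."""
    with open(path, "w") as fh:
        for c in calls.itertuples():
            score = min(1000, int(round(c.height * 1000)))
            name = "well_positioned" if c.well_positioned else "fuzzy"
            fh.write(f"{c.chrom}\t{c.midpoint}\t{c.midpoint + 1}\t{name}\t{score}\t.\n")


def write_ndrs_bed(ndrs: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(ndrs.itertuples()):
            name = r.condition_class if r.condition_class else f"ndr{i}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t.\n")


def write_truth_beds(chromatin: TrueChromatin, outdir) -> List[Path]:
    """Ground truth as BED: 1-bp nucleosome centers per condition, NDRs with flags."""
    outdir = Path(outdir)
    written = []
    for cond in chromatin.conditions:
        p = outdir / f"truth_centers_{cond}.bed"
        with open(p, "w") as fh:
            for chrom in sorted(chromatin.centers[cond]):
                for c in chromatin.centers[cond][chrom]:
                    fh.write(f"{chrom}\t{c}\t{c + 1}\tcenter\t0\t.\n")
        written.append(p)
    p = outdir / "truth_ndrs.bed"
    with open(p, "w") as fh:
        for r in chromatin.ndrs.itertuples():
            flags = "+".join(c for c in chromatin.conditions
                             if getattr(r, f"present_{c}"))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.ndr_id}:{flags}\t0\t.\n")
    written.append(p)
    return written


def read_bed_intervals(path) -> pd.DataFrame:
    """Generic BED reader (>=3 columns) into chrom/start/end[/name/score/strand]."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: truncated BED record at line {ln}")
            rows.append((parts[0], int(parts[1]), int(parts[2]),
                         parts[3] if len(parts) > 3 else ".",
                         parts[4] if len(parts) > 4 else "0",
                         parts[5] if len(parts) > 5 else "."))
    return pd.DataFrame(rows, columns=BED6)


def write_tsv(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
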