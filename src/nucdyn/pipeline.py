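"""End-to-end workflow: simulate/load reads -> tracks -> calls -> NDRs ->
cross-condition classes -> anchor-aligned profile -> motif colocalization.

Every run writes a manifest (parameter echo, seed, SHA-256 of each output)
so identical configurations produce byte-identical artifact bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import aggregate as agg
from . import io as nio
from . import motifs as mot
from . import ndr as ndrmod
from . import nucleosomes as nuc
from . import profiles as prof
from .config import RunConfig
from .simulate import ReadSet, simulate_dataset

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig, outdir) -> Dict[str, object]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, object] = {}
    files = []

    def emit(path: Path):
        files.append(path)
        return path

    # ---- inputs: simulate or load -------------------------------------
    genome = genes = chromatin = None
    reads: Dict[str, ReadSet] = {}
    try:
        if config.simulate is not None:
            genome, genes, chromatin, reads = simulate_dataset(
                config.simulate, config.conditions)
            nio.write_fasta(genome, emit(outdir / "genome.fa"))
            nio.write_gff3(genes, {c: len(s) for c, s in genome.items()},
                           emit(outdir / "genes.gff3"))
            nio.write_gene_tsv(genes, emit(outdir / "genes.tsv"))
            for cond in config.conditions:
                nio.write_reads_bed(reads[cond], emit(outdir / f"reads_{cond}.bed"))
            for p in nio.write_truth_beds(chromatin, outdir):
                emit(p)
        else:
            if config.genome:
                genome = nio.read_fasta(config.genome)
            if config.annotations:
                genes = (nio.read_gff3(config.annotations)
                         if str(config.annotations).endswith((".gff", ".gff3"))
                         else nio.read_gene_tsv(config.annotations))
            for cond in config.conditions:
                if cond not in config.reads:
                    raise ValueError(f"no read file configured for condition {cond!r}")
                reads[cond] = nio.parse_alignments(config.reads[cond])
    except Exception as e:                                    # noqa: BLE001
        raise StageError("input", e) from e

    if config.expression is not None and genes is not None:
        expr = pd.read_csv(config.expression, sep="\t")
        genes = genes.merge(expr, on="gene_id", how="left")

    # ---- per-condition signal + calls ---------------------------------
    tracks: Dict[str, prof.OccupancyTrack] = {}
    calls: Dict[str, pd.DataFrame] = {}
    ndrs: Dict[str, pd.DataFrame] = {}
    summary_rows = []
    for cond in config.conditions:
        try:
            track, shift = prof.track_from_reads(
                reads[cond], config.wavelet, config.level,
                config.shift_window, condition=cond)
        except Exception as e:                                # noqa: BLE001
            raise StageError(f"profile[{cond}]", e) from e
        tracks[cond] = track
        nio.write_bedgraph(track.data, emit(outdir / f"occupancy_{cond}.bedgraph"))
        try:
            cond_calls = nuc.classify_positioning(
                nuc.call_peaks(track, config.min_height), config.min_separation)
            cond_ndrs = ndrmod.call_ndrs(track, config.ndr_min_length,
                                         config.ndr_max_occupancy)
        except Exception as e:                                # noqa: BLE001
            raise StageError(f"calling[{cond}]", e) from e
        calls[cond], ndrs[cond] = cond_calls, cond_ndrs
        nio.write_calls_bed(cond_calls, emit(outdir / f"nucleosomes_{cond}.bed"))
        nio.write_ndrs_bed(cond_ndrs, emit(outdir / f"ndrs_{cond}.bed"))

        genome_len = sum(track.chrom_sizes.values())
        s = nuc.summarize_calls(cond_calls, effective_genome_length=genome_len)
        nsum = ndrmod.ndr_summary(cond_ndrs)
        summary_rows.append({
            "condition": cond, "n_reads": len(reads[cond]), "shift": shift.shift,
            "n_peaks": s.total_peaks, "well_positioned": s.well_positioned,
            "percent_well_positioned": s.percent_well_positioned,
            "mean_spacing": s.mean_spacing,
            "expected_nucleosomes": s.expected_nucleosomes,
            "n_ndrs": nsum.n, "ndr_mean_length": nsum.mean_length,
            "ndr_sd_length": nsum.sd_length,
            "evicted_estimate": nsum.evicted_estimate,
            "evicted_rounded": nsum.evicted_rounded,
        })

    # ---- cross-condition classification -------------------------------
    classified = None
    if len(config.conditions) >= 2:
        try:
            classified = ndrmod.classify_conditions(ndrs, config.min_overlap_fraction)
        except Exception as e:                                # noqa: BLE001
            raise StageError("diff-ndrs", e) from e
        nio.write_ndrs_bed(classified, emit(outdir / "ndrs_classified.bed"))

    # ---- aggregation ---------------------------------------------------
    profile = None
    first = config.conditions[0]
    if genes is not None and len(genes):
        try:
            anchors, _ = agg.select_anchor(genes, calls[first], config.anchor)
            profile = agg.aggregate_profile(tracks[first], anchors, config.flank)
        except Exception as e:                                # noqa: BLE001
            raise StageError("aggregate", e) from e
        nio.write_tsv(profile, emit(outdir / f"aggregate_{first}.tsv"))

    # ---- motifs --------------------------------------------------------
    hits = None
    if genome is not None:
        try:
            motif_defs = (mot.load_motif_table(config.motif_file)
                          if config.motif_file else
                          [mot.MotifDefinition(n, c, config.both_strands)
                           for n, c in mot.CONSENSUS_MOTIFS.items()])
            hits = mot.scan_motifs(genome, motif_defs)
        except Exception as e:                                # noqa: BLE001
            raise StageError("scan-motifs", e) from e
        nio.write_tsv(hits, emit(outdir / "motif_hits.tsv"))
        if len(hits) and len(ndrs[first]):
            report = mot.overlap_fraction(hits, ndrs[first])
            summary_rows[0]["percent_motif_hits_in_ndrs"] = report.percent

    summary = pd.DataFrame(summary_rows)
    nio.write_tsv(summary, emit(outdir / "summary.tsv"))

    manifest = {
        "seed": config.seed,
        "config": config.echo(),
        "files": {p.name: _sha256(p) for p in sorted(files, key=lambda p: p.name)},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    artifacts.update(tracks=tracks, calls=calls, ndrs=ndrs, classified=classified,
                     profile=profile, hits=hits, summary=summary,
                     chromatin=chromatin, genes=genes, manifest=manifest)
    return artifacts


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
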