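# nucdyn

Nucleosome occupancy, nucleosome-depleted regions (NDRs) and promoter
chromatin dynamics from strand-specific mononucleosomal sequencing
(MNase-seq), for chromatin biologists mapping where nucleosomes sit, where
promoters are open, and how that changes between physiological conditions
(e.g. vegetative growth versus meiotic induction in fission yeast).

## The method

MNase digestion leaves ~147 bp nucleosome-protected fragments.  Sequencing
their ends produces two 5′-end pile-ups per nucleosome — one per strand, at
the particle's two boundaries.  The pipeline:

1. **Boundary profiles.** Count 5′ ends per nucleotide on each strand,
   `P⁺(x)` and `P⁻(x)`.
2. **Strand shift.** Estimate the lag `s = argmax_k Σₓ P⁺(x)·P⁻(x+k)`
   over a search window (default 100–250 bp), rounded to the nearest even
   integer; `s` approximates the protected fragment length.
3. **Occupancy track.** Translate each strand `s/2` toward the other so
   both pile up at the nucleosome midpoint, sum, smooth with a multilevel
   1-D biorthogonal wavelet approximation (default `bior3.5`, level 5,
   ≈32 bp scale), clip at zero and divide by the genome-wide mean, so
   occupancy is expressed relative to average coverage (mean ≡ 1).
4. **Nucleosome calls.** Local maxima with height > 1.0; a call is *well
   positioned* when its midpoint is more than 100 nt from both flanking
   calls.  Spacing is the mean midpoint-to-midpoint distance, and the
   expected genome-wide nucleosome count is ⌊L/spacing⌋.
5. **NDRs.** Maximal runs of ≥150 nt with occupancy < 0.4.  Across
   conditions an NDR is *constitutive* if every other condition has a call
   covering ≥50% of it, otherwise *condition-specific*; the evicted-
   nucleosome estimate is `n · mean_length / spacing`.
6. **Metagene profiles.** Per-gene occupancy windows aligned, in
   transcription direction, at the +1/−1/central/terminal nucleosome or at
   the annotated TSS/TTS, optionally stratified by expression fold.
7. **Motif colocalization.** IUPAC consensus scanning (Ste11 `AACAAAGRA`,
   Mei4 `GTAAACAAA`, Rsv1 `CCCCDC`, CRE `TGACGT`, CRE variant `TGACATCAT`,
   Php4 `CCAATCA` are bundled) and feature/NDR overlap percentages.

A first-class synthetic-data module generates an annotated genome, a
ground-truth chromatin configuration (phased 152 bp arrays, promoter NDRs
with lengths Normal(214.68, 71.06) truncated at 150 nt, condition-specific
"toggled" NDRs) and strand-specific reads, so every stage is testable
against known truth without any downloads.  See `docs/methods.md` for model
details and assumptions.

## Worked example

The bundled demo simulates a 60 kb chromosome with 15 genes in two
conditions ("meiosis" and "mitosis") in which 20% of promoter NDRs are
meiosis-specific, then runs the full analysis:

```sh
nucdyn run-all --config src/nucdyn/data/demo.yaml --outdir demo_out --seed 7
```

`demo_out/summary.tsv` (transposed):

```
condition                   meiosis  mitosis
n_reads                       32578    32688
shift                           148      148
n_peaks                         387      395
well_positioned                 331      337
percent_well_positioned        85.5     85.3
mean_spacing                154.601  151.416
n_ndrs                           16       13
ndr_mean_length             373.062  376.538
```

Both conditions recover a strand shift of 148 bp (the ~147 bp protected
fragment), ~390 nucleosome peaks at the simulated 152 bp repeat, and ~85%
well-positioned calls.  The meiosis sample has 16 NDRs against 13 in
mitosis; `demo_out/ndrs_classified.bed` labels 13 shared regions
`constitutive` and the 3 meiosis-only promoters `specific:meiosis`:

```
chr1    321     678     constitutive    0       .
chr1    2607    3006    specific:meiosis        0       .
```

All artifacts (FASTA, GFF3, BED, bedGraph, TSV) plus a manifest with the
full parameter echo and SHA-256 checksums are written to the output
directory; rerunning the same configuration and seed is byte-identical.

Each stage is also available as a library function (`nucdyn.track_from_reads`,
`nucdyn.call_peaks`, `nucdyn.call_ndrs`, `nucdyn.classify_conditions`,
`nucdyn.aggregate_profile`, `nucdyn.scan_motif`, …) and as an individual
subcommand (`simulate`, `profile`, `call-nucleosomes`, `call-ndrs`,
`diff-ndrs`, `aggregate`, `scan-motifs`).

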