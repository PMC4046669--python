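# Methods

## Signal model

Mononucleosomal fragments protect ~147 bp; sequencing their ends yields,
for each nucleosome, a plus-strand 5′-end peak at the left boundary and a
minus-strand peak at the right boundary.  Only the 5′ coordinate and strand
of each read are used analytically — read length never enters the model, so
short sequencing reads (36–40 nt) and full fragments are equivalent inputs.

The strand shift is estimated once per experiment, genome-wide, as the lag
maximising the pooled raw cross-correlation (dot product) between the plus
and minus profiles inside a search window (default 100–250 bp, valid range
50–300 bp).  Pooling across chromosomes is a deliberate choice: the shift
is a property of the fragment-size selection, not of a chromosome.  The
best lag is rounded to the nearest even integer (ties to the smaller lag,
and an odd argmax resolves to its better-scoring even neighbour) so each
strand can be translated an integral `shift/2`.  An argmax on the window
edge is rejected as an error — it means the true optimum lies outside the
window, as when both strands are identical (optimum at lag 0).

For a fragment whose leftmost and rightmost covered bases are `l` and `r`,
the two 5′ ends sit `r − l = length − 1` apart, so the estimated shift for
147 bp fragments is ≈146; both conventions agree to within 1 bp and the
downstream translation recentres both strands onto the midpoint either way.

## Smoothing and normalization

The combined midpoint profile is smoothed by a multilevel 1-D biorthogonal
wavelet decomposition/reconstruction: decompose to level `L` (symmetric
padding), zero every detail band, reconstruct from the approximation.  The
operator is linear, preserves constants, and suppresses features below
~`2^L` bp.  Defaults: `bior3.5`, level 5 (≈32 bp scale) — small enough to
preserve the ~150 bp nucleosomal features, large enough to remove
base-level shot noise.  Both are configurable; analyses of deliberately
jitter-free synthetic data use level 3 (≈8 bp), because a level-5
approximation stores coefficients on a 32 bp grid and can misplace the apex
of a near-delta peak by up to ~8 bp (an aliasing effect absent for
realistically fuzzy peaks).

The smoothed track is clipped at zero (the reconstruction can undershoot
near sharp transitions) and divided by its genome-wide mean, so occupancy
is expressed relative to average coverage and the final track has mean
exactly 1.  Positions translated past a chromosome end are dropped and
counted; the loss is bounded by `shift/2` bases per chromosome end.

## Calling rules and tie-breaks

* **Nucleosome**: strict local maximum with occupancy strictly > 1.0 (the
  genome average).  A plateau of equal values produces one call at
  `floor((first + last)/2)`.  A run touching a chromosome end is a peak if
  it exceeds its single neighbour.  No prominence filter is applied beyond
  the height threshold; smoothing is assumed to have removed sub-scale
  jitter.
* **Well positioned**: strictly more than 100 nt from both flanking calls
  ("more than" read literally, so exactly 100 fails).  A missing neighbour
  at a chromosome end imposes no constraint.  The flag is idempotent and
  independent of input row order.
* **Spacing**: mean of successive midpoint differences per chromosome,
  pooled weighted by pair count (equivalently, total span over total
  pairs).
* **NDR**: maximal run of occupancy strictly < 0.4 spanning ≥ 150 nt.  A
  single base at or above threshold splits a run — no gap-tolerant merging,
  since smoothing already bridges shot noise.
* **Cross-condition class**: an NDR is constitutive when, in every other
  condition, a single called NDR covers at least `min_overlap_fraction`
  (default 0.5) of its length; the fractional rule absorbs ±20 bp boundary
  jitter between conditions.  Specific NDRs called in several conditions
  whose intervals overlap are unioned into one region labelled with the
  condition set.  Whether "specific" requires absence in one designated
  reference condition or in all others is configurable through which
  condition sets are passed in.
* **Anchors**: +1N is the call closest downstream of the TSS (a call
  exactly at the TSS counts as downstream), −1N closest strictly upstream,
  TN closest strictly upstream of the TTS, CN closest to the TSS–TTS
  midpoint; all in transcription direction, distance ties resolved to the
  upstream candidate.  Genes lacking a qualifying call are skipped and
  reported.
* **Percentages** (well-positioned fraction, overlap fractions) are rounded
  half-away-from-zero to one decimal.  The evicted-nucleosome estimate
  `n·mean_length/spacing` is reported raw and rounded to the nearest
  hundred.
* **Motifs**: IUPAC consensus matching; `N` in the subject never matches;
  overlapping occurrences are all reported; both strands are scanned by
  default (configurable).  A motif occurrence counts *inside* an NDR only
  if fully contained; a binding-site feature *overlaps* an NDR with ≥1
  shared bp — containment keeps per-NDR counts unambiguous while near-point
  sites need only touch the open region.

## Synthetic data generator

The generator emulates the structure of a deep (46–177×) fission-yeast
mononucleosomal dataset.  Per chromosome: a random sequence at the
configured GC content (default 0.36); non-overlapping strand-assigned genes
with intergenic gaps of 900–1400 bp (wide enough that two divergent
promoter NDRs cannot collide); one NDR immediately upstream of each TSS
(the exclusion zone `[TSS − L, TSS)` in transcription direction) with
`L ~ Normal(214.68, 71.06)` truncated at 150 nt; nucleosome midpoints tiled
at a 152 bp repeat between barriers (chromosome start and every present
NDR), restarting after each barrier at 74 bp clearance plus a per-barrier
phase offset `U{0..60}` bp.  The phase offset reproduces the gene-to-gene
variability of the TSS→+1 nucleosome distance, which is the mechanism that
makes +1N-aligned metagene profiles sharper than TSS-aligned ones; the
ground truth records, per NDR, both the drawn exclusion zone and the
*realized* nucleosome-free gap (between the DNA edges of the flanking
nucleosomes) — boundary accuracy is audited against the realized gap, the
only interval the occupancy signal can reveal.

A configurable fraction of NDRs (default 0.2) is "toggled": present in the
first condition only and tiled over with nucleosomes elsewhere, emulating
promoters opened by a developmental programme.  Reads: per-nucleosome
fragment counts are Poisson with rate set by the target coverage (default
50×); each fragment has midpoint `center + Normal(0, fuzziness_sd)`
(default 30 bp, the cell-to-cell positional heterogeneity of bulk yeast
nucleosomes — it also yields a realistic non-trivial fraction of calls that
fail the well-positioned criterion) and length
`Normal(147, 10)` truncated to [100, 200]; even-length fragments place
their extra base on a random side of the midpoint.  Midpoints that would
fall inside a present NDR are reset to their nucleosome center, enforcing
the ground-truth invariant exactly.  One pseudorandom stream per
(seed, chromosome, purpose, condition) makes every artifact reproducible
and stable under adding chromosomes or conditions.

What the generator does **not** model: sequence-dependent nucleosome
affinity (e.g. poly(dA:dT) exclusion), MNase sequence bias, dinucleosome
contamination, replication or transcription-coupled repositioning.
Passing recovery tests therefore demonstrate the pipeline's correctness on
idealized array-with-NDR chromatin at matched coverage, not robustness to
those biases in real libraries.

## Problem sizes used in tests and the acceptance script

Recovery analyses run on 50–600 kb of simulated genome at 50× coverage:
ten 50 kb simulations for shift recovery, one 100 kb NDR-free chromosome
(positional jitter 10 bp) for center recovery and spacing, one 300 kb
chromosome with 100 genes (20 toggled) for NDR precision/recall and
condition classification, and two 300 kb chromosomes with 200 genes for
metagene periodicity.  These sizes give tight statistics (hundreds of
nucleosomes and NDRs per measurement) while keeping any single analysis in
the seconds range.

## Known limitations

* NDR boundaries on a midpoint-density track are systematically wider than
  the nucleosome-free DNA by roughly the flanking-peak half-width minus the
  threshold-crossing distance; at default fuzziness the median boundary
  error against the realized gap is ~16–19 bp.
* Replicate tracks simulated at 50× correlate at r ≈ 0.85–0.89 under the
  default smoothing — pure counting noise at that depth; deeper coverage or
  heavier smoothing raises it, at the cost of resolution.
* The caller has no sub-threshold peak model: closely spaced alternative
  nucleosome configurations (fuzzy/overlapping positions) are represented
  by a single broad call.
* Multi-mapping reads, duplicates and mapping quality are not modelled or
  filtered; inputs are taken as aligned.
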