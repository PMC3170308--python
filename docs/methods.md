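# Methods

## Coordinates and conventions

All internal coordinates are 0-based; BED input/output is half-open, GFF is
converted from 1-based inclusive on read. Interval records are reduced to
their floor midpoint `(start + end − 1) // 2` (0-based), so even-length
footprints resolve deterministically toward the lower coordinate. Offsets
around a TSS are transcript-oriented: `pos − tss` on the plus strand,
`tss − pos` on the minus strand, so "downstream" always means in the
direction of transcription. Windows written as `a..b` are inclusive at both
ends. Duplicate point positions are kept (tag-depth data can repeat a
coordinate).

## Promoter classification and annotation

Width is the inclusive span `max(tags) − min(tags) + 1` of the CAGE tag 5′
ends; a promoter is *peak* iff width ≤ threshold (default 4 bp), else
*broad*. This span definition makes "initiates within 1–4 bp" land exactly
on the 4 bp threshold. Classification is monotone in the threshold by
construction.

TATA annotation scans the promoter's sense strand over every motif start
that fits fully within the 50 bp upstream of the TSS (minus-strand
promoters scan the reverse complement of the genomically downstream 50 bp).
A window's score is the min–max relative score
`(S − S_min) / (S_max − S_min)` of the summed per-position log-odds, with
`N` contributing the column mean; the call is positive iff some window
scores strictly above 0.75. This relative score is invariant under a common
positive rescale-and-shift of the matrix, so count matrices with different
pseudocounts give consistent calls. Counts are converted to log-odds with a
pseudocount of 0.8 split by a uniform 0.25 background. The package ships a
small **synthetic** TATA-box count matrix encoding the TATAWAWR consensus
as its default (curated matrices are external resources; any JASPAR-format
count file can be supplied instead). At the 0.75 cutoff an 8-column matrix
also fires on a few percent of random 50-mers, so annotated TATA
frequencies sit above the planted rates for both classes while preserving
the peak ≫ broad ordering — the permissiveness is a property of
threshold-based PWM scanning, not of the planting.

CpG annotation is a pure interval-overlap query: positive iff any island
interval overlaps (≥ 1 bp) the inclusive window `[tss − 200, tss]` in
transcript orientation. Island provenance is deliberately opaque — any
BED-like source is accepted.

## Profiles and enrichment

Nucleosome centers are smeared to `[center − 15, center + 15]` (31 bp)
before profiling; TFBS sites are unsmeared points. Two profile statistics
are implemented because both are meaningful: `per_nucleosome` (smeared-
center coverage events per offset / number of TSSs; the default for
figure-style tracks) and `per_tss` (proportion of TSSs with ≥ 1 covering
center; never exceeds the former). Promoters whose flank runs past a
chromosome end are kept and simply accumulate nothing there — no
renormalization. The implementation uses sorted-array range addition and is
tested for exact equality against a naive per-base scan.

The relative-abundance contrast implements exactly
`(B_j − P_j) / Σ_i B_i` with the denominator summed over the stated window
(default −2000..+2000); it errors when the denominator is zero rather than
guessing a normalization.

Window enrichment builds the 2×2 table class × (≥ 1 smeared center
overlapping `a..b`, none) — a smear overlaps the window iff the center
offset lies in `[a − 15, b + 15]` — and applies Pearson's χ² with 1 df and
no Yates correction. A degenerate table (empty column) is reported as
statistic 0, p 1 with a warning; expected cells below 1 attach a warning
without failing.

## Positional stability

For each resting-condition center within +1..+200 of a promoter (a center
shared by several promoters counts once), the signed distance to the
nearest activated-condition center on the same chromosome is computed in
genomic orientation; ties between equally near neighbors break toward the
negative side (any fixed rule suffices for the |d| statistics, but
determinism keeps the signed distribution reproducible). Centers on
chromosomes lacking activated data are dropped and counted. The binned
distribution uses `[x, x + 15)` bins anchored at 0. The mean absolute
distance excludes |d| strictly greater than 100 bp (|d| = 100 is kept),
since larger jumps are more plausibly different nucleosomes than one that
slid. Classes are compared with Welch's t-test (two-sided) on the filtered
|d|; the pooled-variance form is available via a flag, but the group
variances differ by construction, so Welch is the default. A genome-wide
background distribution is computed without the promoter-proximal filter
and labelled as such.

## Expression analysis

The modified/unmodified split uses the activation-linked methylation family
H3K4me1/2/3 by default (repressive marks are accepted inputs but never
folded into "modified"); a promoter is modified iff any family center lies
within the inclusive ±500 bp window. Genes join promoters one-to-one by
gene id; when several promoters share a gene, the one with the most CAGE
tags wins (tie → lowest coordinate). Only genes flagged present are used.
The two-sided Mann–Whitney U test uses exact enumeration when both groups
have ≤ 20 tie-free values and the normal approximation with tie correction
otherwise. The expression-matched subset keeps promoters whose gene
intensity lies in the inclusive 250..750 band, and the enrichment test
re-run on that subset checks that the class contrast is not an expression
artifact.

## Synthetic data: what it emulates, and what it does not

The generator plants, per class, exactly the structures the analyses are
designed to detect, with defaults chosen once as field-plausible values:

| parameter | default | rationale |
|---|---|---|
| promoters per class | 500 / 500 | enough for every test statistic to be well-powered at desk scale |
| chromosome length | 12 Mb | ≥ 2 × 5 kb flanks between neighbors |
| peak / broad width | 1–4 / 5–60 bp | consistent with the 4 bp class boundary |
| first downstream center | +115 bp | its ±15 bp smear spans +100..+130 |
| phasing period | 185 bp | 147 bp core + typical linker; literature-typical, not fitted |
| phased centers | 5 down + 3 up | array flanking an NFR at −50 ± 70 bp |
| placement jitter (broad) | sd 10 bp | array alignment imperfect but phased |
| condition jitter | sd 8 (broad) / 15 (peak) bp | encodes broad > peak stability |
| mark enrichment (H3K4me3) | 0.8 / 0.1 | strong broad-biased mark carriership |
| TFBS at NFR | 0.7 / 0.1, sd 10 bp | Sp1-like concentration near −50 |
| expression | LogNormal(6, 1) | median ≈ 400, inside the 250–750 matched band |
| modification effect | ×e (broad), ×1 (peak) | broad-only upregulation |
| CpG / TATA planting | 0.9/0.2 and 0.1/0.7 | broad-CpG, peak-TATA associations |

Peak promoters receive the same number of centers as broad ones, scattered
uniformly over the phased array's reach, so class contrasts reflect
*arrangement*, not abundance. Mark carriership is drawn once per
(promoter, mark) so both conditions describe the same nucleosomes, and the
activated condition is the resting centers plus rounded Gaussian jitter.
Every generator is a pure function of (config, seed, condition tag); seeds
feed `numpy` PCG64 streams keyed by stage name.

What the generator does **not** emulate: read-level noise and nucleosome-
calling error, sequence-dependent positioning, copy-number variation in tag
depth, correlated marks on the same nucleosome, repressive-mark biology,
and real microarray Present/Absent structure (all genes are present).
Passing tests therefore demonstrate that the statistics recover planted
structure of realistic magnitude — not that real ChIP-Seq/CAGE data would
show these effect sizes.

## Numerical and design choices

- χ² on 2×2 tables uses 1 df and no continuity correction; "chi-squared
  test" alone does not imply Yates, and the uncorrected form matches the
  closed-form oracle exactly.
- Profile/enrichment/distance code paths are integer-count based and
  compared to brute-force oracles for exact equality, not tolerance.
- Pearson correlations return NaN (reported as missing) on zero-variance
  windows rather than raising.
- Profile TSVs print full-precision `repr` floats and are re-read with
  round-trip float parsing, so write→read is bit-exact.
- GFF point features can be interpreted as span midpoints (default) or
  site starts via a reader flag, since TFBS dumps are ambiguous about this.
- The pipeline logs every threshold in effect (classification width, PWM
  score floor, windows, exclusion cutoff) at INFO level, and the manifest
  records a hash of the fully-resolved config.

## Problem sizes

The shipped study conditions (500 promoters per class, one 12 Mb
chromosome, ~8,000 nucleosomes per condition) run the full pipeline in
seconds and give every test its power; the calibration check uses 200
expression replicates over fixed seed streams. All sizes are configurable
upward through `SimConfig`.

## Known limitations

- Nearest-neighbor matching does not track nucleosome identity; a resting
  center may pair with a neighbor's activated copy when jitter exceeds half
  the local spacing, slightly shrinking large-jitter class means.
- The synthetic TATA matrix is a consensus stand-in; absolute TATA
  frequencies depend on the matrix and cutoff supplied.
- The NFR argmin is reported on a window where occupancy may be identically
  zero; the first offset wins ties, which is informative only together with
  the depletion check also performed.
- Expression joins assume one gene per promoter id in the synthetic data;
  real many-to-many probe mappings must be resolved upstream.
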