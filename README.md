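# promnuc

Promoter architecture vs. nucleosome behavior: a tested pipeline relating
CAGE-defined promoter shape (peak vs. broad) to nucleosome positioning,
positional stability across cellular conditions, histone-mark enrichment,
and downstream gene expression.

## The problem

Mammalian promoters fall into two architectural classes by the dispersion of
their transcription start sites (TSSs): **peak** promoters initiate within a
narrow span (width ≤ 4 bp, where width = max − min + 1 over CAGE tag 5′
ends), are TATA-associated and tissue-specific; **broad** promoters initiate
over a wider span (> 4 bp), are CpG-island-associated and broadly expressed.
This package quantifies how the two classes differ in chromatin terms:

- **Occupancy profiles.** For a promoter class with TSS set *T* and
  nucleosome centers smeared ±15 bp, the profile at offset *j* (transcript
  orientation, 0 = TSS) is the number of smeared centers covering *j*
  divided by |*T*| (a per-TSS variant counts promoters with ≥ 1 covering
  center instead). Broad promoters show a phased downstream array and an
  upstream nucleosome-free region (NFR) hosting TFBS sites near −50 bp.
- **Class contrast.** The relative abundance at offset *j* is
  (*B*<sub>j</sub> − *P*<sub>j</sub>) / Σ<sub>i</sub>*B*<sub>i</sub>, with
  *B*, *P* the broad/peak proportions and the sum over −2000..+2000.
- **Window enrichment.** A 2×2 Pearson χ² (1 df, no continuity correction)
  of class × presence of a smeared mark center overlapping +100..+130.
- **Positional stability.** For each nucleosome center in the resting
  condition within +1..+200 of a promoter, the signed distance to the
  nearest activated-condition center; mean |d| after excluding |d| > 100 bp,
  classes compared by Welch's t-test.
- **Expression stratification.** Promoters with ≥ 1 H3K4me1/2/3 center
  within ±500 bp are "modified"; modified vs. unmodified expression is
  compared per class with a two-sided Wilcoxon rank-sum test.

A deterministic synthetic-data generator emulates all of these structures
(phasing, NFR, class-specific condition jitter, mark enrichment,
broad-only expression effects), so the full pipeline runs and is tested
without any external download.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
default synthetic conditions (500 promoters per class on a 12 Mb
chromosome):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_classify_promoters.py
python analysis/03_profile_nucleosomes.py
python analysis/04_stability.py
python analysis/05_expression.py
python analysis/06_threshold_robustness.py
```

Selected output (seed 1):

```
peak  n= 500  TATA 78.8%  CpG 21.2%
broad n= 500  TATA 31.0%  CpG 90.6%
H3K4me3  +100..+130 enrichment chi2=   596.1  p=1.2e-131
broad H3 profile: first downstream maximum at +114 bp, NFR minimum at -100 bp
broad mean |d| =   6.38 bp (n_used=500, excluded 0)
peak  mean |d| =  11.12 bp (n_used=476, excluded 0)
Welch t = -10.37, p = 1.39e-23
broad modified n=459 median=   1052 | unmodified n= 41 median=    344 | p=5.06e-08
peak  modified n= 94 median=    421 | unmodified n=406 median=    483 | p=0.247
broad H3 profile correlation (4 bp vs 10 bp threshold): r = 1.000
```

Reading: peak promoters are TATA-rich and broad promoters CpG-rich; the
broad-class first nucleosome sits in the +100..+130 window with a depleted
NFR upstream; activating marks are strongly enriched at broad promoters;
broad-promoter nucleosomes move less between conditions; and histone
modification is associated with higher expression at broad promoters only.

The same stages are available as a CLI (`promnuc simulate/classify/profiles/
stability/expression/run-all`) driven by a YAML config; `run-all` writes a
JSON run manifest with the config hash, per-stage files and summaries.

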