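# sermir — serum small-RNA analysis with spike-in calibrator normalization

`sermir` is a Python toolkit for the analysis of circulating small
RNAs profiled by small RNA-seq in patient serum — the setting of
liquid-biopsy biomarker studies in rectal cancer, where miRNAs,
isomiRs and fragments of other ncRNA classes (scRNA, tRNA, Y-RNA,
snoRNA, lncRNA) are screened for association with metastasis,
treatment and survival. It is written for computational biologists who
want every stage of such an analysis as a tested, seedable library:

* **read processing** — 3' adapter trimming, collapsing to unique
  sequences, exact-match genome alignment with a bounded 3' soft-clip;
* **hierarchical annotation** — mature-miRNA loci first (strand-aware
  genomic overlap), an ncRNA database second (substring containment);
* **isomiR classification** — 5'/3' trimming, templated tailing and
  non-templated addition (NTA), with Figure-style labels (lower case =
  trimmed, upper case = tailed bases);
* **spike-in normalization** — TMM factors computed on a 10-oligo
  calibrator matrix and applied as effective library sizes:
  `cpm = count / (N_s · f_s) · 10⁶`, with
  `f_s = 2^{Σ w_g M_g / Σ w_g}` the weighted trimmed mean of M-values
  `M_g = log₂[(y_gs/N_s)/(y_gr/N_r)]` against a reference sample;
* **differential expression** — voom precision weights
  `w = s(μ̂)⁻⁴` from the fitted mean–variance trend, weighted least
  squares, empirical-Bayes moderated t with
  `s²_post = (d₀s₀² + d s²)/(d₀+d)`, BH correction;
* **survival screening** — per-feature Cox proportional hazards
  (Efron ties) with median-dichotomized expression plus age, sex and
  metastasis covariates, Bonferroni correction, Kaplan–Meier curves;
* **qPCR support** — NormFinder stability
  `ρ_g = |δ̃_g| + se(δ̃_g)` for reference-gene selection, and the
  ΔCt → RQ = 2^(−ΔCt) → fold-change → t-test chain;
* **synthetic data** — a generator for toy references, a 96-patient
  cohort with staged survival, and FASTQ reads with planted class
  mixtures, isomiR compositions and expression effects, so the whole
  pipeline is testable offline with known ground truth.

## Worked example

Run the end-to-end pipeline on a simulated 24-patient cohort
(4,000 reads per sample; every stage writes TSVs plus a checksum
manifest under `demo/`):

```bash
sermir pipeline run --outdir demo --seed 1   # or: --config my.yaml
```

equivalently in Python:

```python
from sermir.pipeline import PipelineConfig, run_all

cfg = PipelineConfig(outdir="demo", seed=1, n_patients=24, library_size=4000)
res = run_all(cfg)
```

Printed summaries from this exact run:

```text
isomiR composition (unique isomiRs): 3p-trim 0.32  nta 0.39  3p-tail 0.15  5p-mod 0.14
mean class composition: miRNA 0.35  scRNA 0.28  lncRNA 0.15  ...
DE metastasis (miRNA), top of table:
              lfc        t       p   p_adj
miR-sim-04  1.054  10.152  0.0000  0.0000
miR-sim-02  0.981   9.108  0.0000  0.0000
miR-sim-03  1.075   6.487  0.0000  0.0000
miR-sim-05 -0.848  -6.267  0.0000  0.0000
significant at BH<0.05: metastasis/miRNA 6, metastasis/isomiR 23,
                        treatment/miRNA 1, treatment/isomiR 5
reference genes (NormFinder): miR-sim-07, miR-sim-15, miR-sim-19
qPCR target miR-sim-04: fold change 2.19, t = -6.54, p = 4e-6
```

Reading this: the generator planted six miRNAs with |log2 fold
change| = 1 between M1 and M0 patients and one treatment-responsive
miRNA — the DE stage recovers exactly those six (estimated lfc ≈ ±1)
and the one treatment hit; unique-isomiR composition was planted at
32/39/15/14% across 3'-trim/NTA/tail/5'-mod and is recovered exactly;
the NormFinder stage picks stable, non-DE, highly expressed miRNAs as
qPCR internal controls; and the simulated qPCR validation of the top
DE miRNA (one planted ΔCt cycle ≈ 2-fold) returns a fold change of
2.19. At this mini-cohort size the survival screen finds no
Bonferroni-significant feature, as expected for 24 patients.

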