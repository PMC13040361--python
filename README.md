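# cinpipe

Chromosomal instability (CIN) — the persistent gain and loss of large
genomic segments — marks aggressive disease in many solid tumors, and in
non-muscle-invasive bladder cancer it is a candidate biomarker for
recurrence risk after transurethral resection. `cinpipe` is a tested,
reusable implementation of the read-depth analysis that turns low-coverage
whole-genome sequencing (~0.5×, FFPE-compatible) of tumor tissue into a
prognostic CIN call:

1. **Binning & normalization.** Coverage is counted in fixed 200-kb bins
   and standardized per bin against a panel of healthy controls:

   *Z*<sub>bin</sub> = (cov<sub>raw</sub> − mean(cov<sub>controls</sub>)) / sd(cov<sub>controls</sub>)

2. **QC gates.** Samples failing sequencing metadata thresholds
   (≥10 M reads, ≥85 % Q30, ≥70 % uniquely mapped) or whose genome-wide
   median absolute deviation of the per-bin log2 copy ratio exceeds 0.38
   are excluded as too noisy to segment.

3. **Segmentation.** Circular binary segmentation (CBS): recursive
   change-point search maximizing the circular two-sample t-statistic, with
   permutation significance, run per chromosome arm.

4. **CIN score.** CIN = Σ<sub>seg</sub> *L*<sub>seg</sub> × |*Z*<sub>seg</sub>|,
   with *L* in megabases and a |Z| ≥ 2 inclusion gate, so the score is a
   genome-wide burden of confidently altered sequence.

5. **Dichotomization & prognostics.** The high/low CIN cutoff is chosen by
   maximally selected rank statistics against recurrence-free survival
   (RFS), with a Lausen–Schumacher selection-adjusted p-value. The
   statistical battery covers Kaplan–Meier/log-rank, Cox proportional
   hazards (with the Grambsch–Therneau PH diagnostic), time-dependent ROC
   with IPCW, Harrell's C-index, likelihood-ratio tests, NRI, and
   ROC-derived per-arm Z cutoffs (e.g. chr8q+, chr16p+, chr19q+ calls).

Because patient-level sequence data of this kind are rarely deposited, the
package ships a first-class synthetic-data module — control panels with
shared per-bin capture bias, tumors with implanted arm-level CNAs, and
cohorts whose recurrence hazard depends on the latent CNA burden — so every
stage is testable end-to-end against known ground truth.

## Worked example

A fully synthetic run — 11 controls, 50 tumors on a compact four-chromosome
genome at 1-Mb bins:

```python
from cinpipe.pipeline import RunConfig, run_pipeline, report

cfg = RunConfig(outdir="demo_run", seed=7, genome_path="demo_genome.tsv",
                bin_size=1_000_000, n_controls=11, n_tumors=50,
                n_perm=300, n_boot=100)
manifest = run_pipeline(cfg)
print(report(manifest))
```

prints

```
# cinpipe run summary

samples scored: 49  (high CIN: 31, low CIN: 18)
CIN cutoff: 32.860 (derived)
excluded from analysis: tumor_037 [reads]
median RFS (months): high=35.1, low=-
log-rank: chi2=7.092, p=0.007743
Cox high-vs-low CIN: HR=3.50 (95% CI 1.31-9.32), p=0.01233
C-index (CIN score): 0.624
...
```

One simulated tumor failed the read-count gate and is excluded with its
reason. The derived cutoff splits the cohort into 31 high- and 18 low-CIN
samples; high-CIN patients reach median RFS at 35.1 months while the
low-CIN curve never crosses 0.5 (`-`), the log-rank test rejects equality
(p = 0.008), and the Cox hazard ratio of the derived class is 3.50 — the
generating model gave high-burden tumors a five-fold hazard, and 5 lies
inside the 95 % CI. The same stages are available as CLI subcommands
(`cinpipe simulate | normalize | segment | score | cutoff | survival |
run | report`) operating on plain TSV/CSV/SEG/JSON files.

On real data, point the config at a coverage TSV (`sample chrom start end
coverage`), a control-panel coverage TSV, and a clinical CSV (see
`cinpipe.io.CLINICAL_COLUMNS`); the shipped genome model is an hg19-like
table of the 22 autosomes with centromere intervals
(`src/cinpipe/data/hg19_autosomes.tsv`), replaceable by any TSV with the
same columns.

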