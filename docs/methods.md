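# Methods

This note records the models, conventions and numerical choices behind
`cinpipe`, and what the synthetic-data studies do and do not demonstrate.

## Coordinate system and genome model

All profiles are indexed against a `BinGrid`: fixed-width windows
(default 200 kb) tiled left-to-right per chromosome, 0-based half-open,
with the last window truncated at the chromosome end. SEG output converts
to 1-based inclusive starts per that format's convention.

The shipped genome model contains the 22 autosomes with hg19-like lengths
and centromere intervals. Sex chromosomes are excluded by default because
the control panel is mixed-sex urine-sediment DNA, so X/Y coverage is not
comparable across donors. Bins overlapping the centromere interval are
flagged and excluded from normalization, segmentation, scoring and arm
assignment: pericentromeric short-read coverage is dominated by mapping
artifacts. No further mappability blacklist is applied; a hook for a
GC/LOESS corrector exists but is off by default, since the control-panel
standardization already removes any bias that is shared across samples
(the synthetic generator creates exactly this structure — see below).

## Normalization and QC

Per bin, `Z = (cov_raw − mean_controls) / sd_controls` with the *sample*
standard deviation (ddof = 1) across ≥ 2 controls. Bins with zero control
variance are masked. Leave-one-out calibration on a simulated Poisson
panel (11 controls × 2000 bins) gives pooled Z mean ≈ 0 and sd ≈ 1.0–1.2;
the inflation above 1 is expected with 10-control panels (finite-sample
variance of the estimated mean and sd) and is measured, not corrected.

Two gates exclude samples before analysis:

- **Sequencing metadata**: total reads ≥ 1e7, Q30 ≥ 85 %, unique mapping
  ≥ 70 %; every violated criterion is reported.
- **Noise (MAD)**: the median absolute deviation of per-bin
  `log2(cov / panel_mean)`, *unscaled* (no 1.4826 consistency factor),
  fails a sample only when strictly exceeding 0.38. Zero-coverage bins get
  a 0.5 pseudo-count before the log; bins with non-positive panel mean are
  left out. Whether the operating threshold refers to scaled or raw MAD,
  natural or base-2 logs, is the largest numerical ambiguity in this
  pipeline family; the choice here (raw MAD, log2) is explicit and
  configurable rather than inferred.

## Segmentation (CBS)

Per chromosome arm, the masked bins are excised and the compacted Z series
is segmented by the circular binary segmentation recursion: find the arc
maximizing the two-sample t-statistic between the arc and its complement
(contiguous arcs suffice — arc/complement symmetry covers wrap-around),
test it by permutation, split, recurse. Conventions:

- Candidate splits are restricted to those whose resulting pieces all have
  ≥ `min_width` (default 3) bins, so degenerate slivers are never emitted.
- Ties in the max-t search resolve toward the smaller left boundary, then
  the shorter arc, making output deterministic.
- The permutation p-value is exact, `(1 + #{t* ≥ t}) / (1 + n_perm)`
  (default `n_perm` = 1000, `alpha` = 0.01), from the module's own seeded
  generator. Permutations are processed in blocks and stop early once the
  exceedance count guarantees p ≥ alpha; the accept/reject decision is
  identical to the full run.
- Adjacent segments whose mean difference is below
  `merge_sd × pooled within-segment sd` (default 1.5) are merged
  iteratively, an undo step that stabilizes over-segmented output.
- The segmented statistic is the Z profile, so segment means are in Z
  units and feed the CIN score directly; log-ratio segmentation is
  available by flag.

With a noiseless step the breakpoint is recovered exactly; with an
inserted +4 arc (bins 80–120 of 200, unit noise) both boundaries land
within ±2 bins in ≥ 95 % of replicates.

## CIN score and dichotomization

`CIN = Σ L_seg × |Z_seg|` over segments with |Z_seg| ≥ z_min, where
`L_seg` is the genomic segment length in **megabases** and `Z_seg` the
unweighted mean bin Z in the segment. Two deliberate conventions, both
configurable:

- **|Z| rather than signed Z** — a signed sum lets gains cancel losses,
  contradicting the burden interpretation (both directions of copy change
  are instability).
- **z_min = 2 inclusion gate** — without a gate, panel-level noise
  accumulates linearly with genome size and the score of a perfectly
  neutral genome would grow with the number of segments.

Class assignment: *high* strictly above the cutoff, *low* at or below
("above threshold" semantics). Arm-level calls use the *mean bin Z per
arm* and are positive at or above their cutoff (boundary inclusive).

The cutoff is derived by maximally selected rank statistics: candidates
are midpoints between consecutive ordered unique scores whose induced
group proportions lie in [ε, 1−ε] (default ε = 0.1); each candidate's
standardized two-group log-rank statistic |Z| is computed (vectorized
across candidates); the maximizing candidate wins, ties toward the smaller
cutpoint. The selection-adjusted p-value is the Lausen–Schumacher
improved-Bonferroni bound
`φ(b)(b − 1/b)·log[ε₂(1−ε₁)/((1−ε₂)ε₁)] + 4φ(b)/b`, clipped to [0, 1];
its null size measured over 1000 exchangeable-score replicates is ≤ 0.05
at nominal 0.05 (slightly conservative, as the bound intends).

## Statistical battery

Conventions pinned by the reproduction suite: Pearson χ² without
continuity correction; Fisher two-sided by summing hypergeometric
probabilities ≤ the observed table's; pooled-variance t-test by default
(Welch by flag); Mann–Whitney with normal approximation and tie
correction. Survival: Kaplan–Meier product-limit (median = first time
S(t) ≤ 0.5, undefined — rendered "–" — if never reached); log-rank with
hypergeometric variance; Cox partial likelihood with Efron ties (Breslow
by flag), Wald CIs with the 1.96 normal quantile. The proportional-hazards
diagnostic is the Grambsch–Therneau score test on Schoenfeld residuals
against KM-transformed time, per covariate and global (df = p); it was
checked against an independent R implementation during development and is
calibration-tested in the suite. Time-dependent ROC is the IPCW
cumulative/dynamic AUC (cases: event by t; controls: event-free past t)
with a seeded percentile bootstrap CI (default 500 resamples). C-index is
Harrell's with marker ties counting 0.5. NRI is categorical over
user-supplied thresholds. ROC cutoffs use Youden's J (ties toward the
lower cutoff) with a DeLong CI.

Standard routines are delegated: scipy (contingency/rank tests), lifelines
(KM, Cox, concordance), scikit-survival (IPCW AUC), statsmodels (Breslow
Cox), scikit-learn (ROC curves). The log-rank Z used in cutpoint scans,
the selection bound, NRI, DeLong, and the PH test are implemented here.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the mechanism the normalization presupposes:
reads per bin are drawn around `depth × bias_i × copy_ratio`, where
`bias_i` is a lognormal per-bin capture bias (sd 0.1) **shared by all
samples** — the correlated structure that panel standardization must, and
does, remove. Counts are negative-binomial (var = μ + φμ²) with φ = 0.05
by default: at the default depth of 667 reads per 200-kb bin (~0.5× with
150-bp reads) this puts a neutral sample's log2-ratio MAD near 0.23 and
CNA-bearing samples near 0.28 — FFPE-like noise that still passes the 0.38
exclusion gate, as a QC-passing cohort must. (φ = 0.1 is settable but
makes typical samples straddle the gate.) Poisson and noiseless modes
exist for calibration tests.

CNA events are multiplicative coverage factors over intervals (1.5 =
single-copy gain at purity 1); bins straddling an event boundary get the
length-weighted ratio. The default event menu implants the arm-level
lesions recurrent in urothelial tumors (8q+, 16p+, 19q+, chromosome-9
loss, 17p−) with weights giving ~70 % high-burden tumors; event lengths
scale so the heaviest set alters ≤ 20 % of whatever genome is used — the
altered *fraction* is the study condition, and without the cap a compact
test genome would have most of its bins inside events, which inflates
genome-wide MAD and misrepresents the regime the pipeline targets.

Outcomes follow an exponential proportional-hazards model on the *latent*
burden class (threshold: implanted Σ|log2 ratio|×Mb > 10): baseline
0.0025/month, HR 5 for high burden, administrative censoring at 96 months —
giving ~55–60 % relapse and a 70/30 burden split, the margins of the
intended application. Latent class is defined by implanted burden, never
by the pipeline's own cutoff, so classification accuracy is a real
measurement.

Not modeled: read-level artifacts (the adapter from aligned read starts to
bin counts is provided, alignment is not), GC waves not shared across
samples, subclonality, purity/ploidy. Passing tests therefore demonstrate
the pipeline's logic — normalization removes shared bias, CBS finds the
implanted breakpoints, the score ranks burden, the cutoff machinery and
survival statistics behave as specified — not robustness to every artifact
of real FFPE libraries.

## Replicated validation studies

`cinpipe.validate` packages the calibration experiments (also run by
`scripts/acceptance.py`). The end-to-end study uses a two-arm cohort
design — 25 quiet vs 25 heavy-CNA tumors per replicate, HR 5 — on a
four-chromosome 320-Mb genome at 1-Mb bins with `n_perm` = 300, sizes
chosen so a 50-replicate study runs in minutes on one CPU while every
pipeline stage still operates at realistic per-arm bin counts. Across 50
replicates the derived CIN classes agree with latent classes with mean
accuracy ≈ 0.92 and the Cox 95 % CI covers the generating HR in ≈ 98 % of
replicates. The residual misclassification is a property of
survival-driven dichotomization itself at n = 50 — in a minority of
replicates the outcome noise makes a cutpoint inside the high-score
cluster the genuine log-rank maximizer — not of score separation, which is
complete at these effect sizes.

## Known limitations

- The CIN score's absolute scale depends on panel size and noise through
  Z; scores are comparable within a cohort normalized against one panel,
  not across panels.
- The Lausen–Schumacher bound is conservative for small candidate sets;
  with < 10 samples no cutoff is attempted.
- Breslow-ties Cox fits do not provide Schoenfeld residuals here, so the
  PH diagnostic requires the (default) Efron fit.
- `reads_to_bins` uses read start positions only; fragment-length effects
  at bin boundaries are ignored (negligible at 200-kb bins).
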