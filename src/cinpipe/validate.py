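"""Self-validation studies: replicated simulation experiments that measure
how well the pipeline recovers known ground truth.

These are the package's own calibration checks — boundary recovery of the
segmenter, leave-one-out calibration of control normalization, the null
size of the cutpoint-selection p-value, and full end-to-end class/hazard
recovery on synthetic cohorts.  The problem sizes are compact by design
(a four-chromosome 320-Mb genome at 1-Mb bins for replicated runs) so a
full study runs on one CPU in minutes; the conclusions are about the
pipeline's logic, not about any particular genome size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import BinGrid, GenomeModel, build_bin_grid
from .normalize import build_panel, mad_qc, zscore
from .scoring import cin_score, classify_cin, max_sel_rank_cutoff, segment_z
from .segment import SegmentParams, cbs_segment, segment_genome
from .simulate import CohortSpec, simulate_cohort, simulate_panel
from .stats import SurvivalData, cox_fit

__all__ = [
    "compact_genome",
    "cbs_noisy_recovery",
    "loo_z_calibration",
    "maxstat_null_rate",
    "e2e_replicate",
    "e2e_study",
]


def compact_genome(n_chrom: int = 4, length: int = 80_000_000) -> GenomeModel:
    """Four metacentric 80-Mb chromosomes: the replicated-study genome."""
    return GenomeModel(
        tuple((f"chr{i + 1}", length) for i in range(n_chrom)),
        {f"chr{i + 1}": (int(length * 0.475), int(length * 0.525)) for i in range(n_chrom)},
    )


def cbs_noisy_recovery(
    n_reps: int = 100,
    seed: int = 0,
    n_perm: int = 1000,
    tol_bins: int = 2,
) -> float:
    """Fraction of replicates where CBS recovers an inserted +4 arc
    (bins 80-120 of a 200-bin unit-noise series) with both boundaries
    within ``tol_bins`` bins and exactly three segments."""
    ss = np.random.SeedSequence([seed, 303])
    hits = 0
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        x = rng.normal(0, 1, 200)
        x[80:121] += 4.0
        segs = cbs_segment(x, alpha=0.01, n_perm=n_perm, seed=rng)
        cps = sorted({s.start_bin for s in segs} - {0})
        if len(segs) == 3 and len(cps) == 2:
            if abs(cps[0] - 80) <= tol_bins and abs(cps[1] - 121) <= tol_bins:
                hits += 1
    return hits / n_reps


def loo_z_calibration(seed: int = 0, n_bins: int = 2000) -> tuple[float, float]:
    """Leave-one-out Z of each control against the panel of the others:
    pooled mean and sd on an 11-control Poisson panel."""
    genome = GenomeModel(((("chr1"), n_bins * 200_000),))
    grid = build_bin_grid(genome, 200_000)
    spec = CohortSpec(noise_model="poisson", bin_bias_sd=0.1, depth_mean=100.0)
    controls = simulate_panel(spec, grid, np.random.default_rng([seed, 404]))
    pooled = []
    for i in range(len(controls)):
        rest = [c for j, c in enumerate(controls) if j != i]
        zp = zscore(controls[i], build_panel(rest), grid)
        pooled.append(zp.z[zp.mask])
    pooled = np.concatenate(pooled)
    return float(pooled.mean()), float(pooled.std())


def maxstat_null_rate(
    n_reps: int = 1000, seed: int = 0, n: int = 50, alpha: float = 0.05
) -> float:
    """P(approx_p < alpha) when scores are exchangeable with survival —
    the selection-adjusted bound should keep this at or below nominal."""
    rng = np.random.default_rng([seed, 505])
    hits = 0
    for _ in range(n_reps):
        times = rng.exponential(30, n).round(2) + 0.5
        events = (rng.random(n) < 0.7).astype(int)
        scores = rng.normal(0, 1, n)
        res = max_sel_rank_cutoff(scores, times, events)
        hits += res.approx_p < alpha
    return hits / n_reps


def e2e_replicate(
    seed: int,
    grid: BinGrid | None = None,
    n_tumors: int = 50,
    n_perm: int = 300,
    true_hr: float = 5.0,
) -> dict:
    """One full pipeline pass on a synthetic cohort with known truth.

    Simulates a two-arm cohort — half quiet tumors, half carrying the
    heavy arm-level CNA set — whose recurrence hazard is ``true_hr``-fold
    higher in the latent high-burden arm, runs QC -> normalization -> CBS ->
    CIN scoring -> survival-driven dichotomization, and measures (a)
    agreement of derived CIN classes with the latent classes and (b) the
    Cox hazard ratio of the derived class with its 95% CI.
    """
    if grid is None:
        grid = build_bin_grid(compact_genome(), 1_000_000)
    from .simulate import default_cna_menu

    full_menu = default_cna_menu(grid.genome)
    heavy = max(full_menu, key=lambda ew: sum(e.end - e.start for e in ew[0]))[0]
    spec = CohortSpec(n_tumors=n_tumors, cna_menu=[((), 0.5), (heavy, 0.5)])
    cohort = simulate_cohort(spec, grid, seed)
    panel = build_panel(cohort.controls)
    truth = cohort.truth.set_index("sample_id")
    rows = []
    rng_seeds = np.random.SeedSequence([seed, 606]).spawn(len(cohort.tumors))
    for prof, child in zip(cohort.tumors, rng_seeds):
        _, mad_ok = mad_qc(prof, panel, grid=grid)
        if not mad_ok:
            continue
        zp = zscore(prof, panel, grid)
        params = SegmentParams(n_perm=n_perm, seed=int(child.generate_state(1)[0] % 2**31))
        segset = segment_genome(zp, grid, params)
        score = cin_score(segment_z(zp, segset))
        rows.append(
            {
                "sample_id": prof.sample_id,
                "score": score,
                "latent_high": bool(truth.loc[prof.sample_id, "latent_high"]),
                "time": float(truth.loc[prof.sample_id, "rfs_months"]) + 1e-9,
                "event": int(truth.loc[prof.sample_id, "relapse"]),
            }
        )
    df = pd.DataFrame(rows)
    res = max_sel_rank_cutoff(
        df["score"].to_numpy(), df["time"].to_numpy(), df["event"].to_numpy()
    )
    df["high"] = [classify_cin(s, res.cutoff) == "high" for s in df["score"]]
    accuracy = float((df["high"] == df["latent_high"]).mean())
    out = {"n": len(df), "cutoff": res.cutoff, "accuracy": accuracy}
    data = SurvivalData(
        df["time"].to_numpy(), df["event"].to_numpy(),
        pd.DataFrame({"high": df["high"].astype(float)}),
    )
    try:
        fit = cox_fit(data, ["high"])
        out["hr"] = float(fit.hr[0])
        out["covered"] = bool(fit.ci_low[0] <= true_hr <= fit.ci_high[0])
    except (RuntimeError, ValueError):
        out["hr"] = float("nan")
        out["covered"] = False
    return out


def e2e_study(n_reps: int = 50, seed: int = 0, **kw) -> pd.DataFrame:
    """Replicated end-to-end recovery study; one row per replicate."""
    base = np.random.SeedSequence([seed, 707]).generate_state(n_reps) % (2**31)
    return pd.DataFrame([e2e_replicate(int(s), **kw) for s in base])
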