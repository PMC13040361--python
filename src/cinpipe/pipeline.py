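"""End-to-end orchestration: simulate/load -> QC -> normalize -> segment ->
score -> cutoff/classify -> survival report.

Every stage writes plain text artifacts (TSV/CSV/SEG/JSON) into the run
directory and records itself in a manifest, so any stage can be re-run or
consumed from R or the shell.  One global seed fans out deterministically to
per-stage child seeds; a rerun with the same config and seed reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .genome import build_bin_grid, default_genome, load_genome_tsv
from .normalize import QCConfig, build_panel, mad_qc, seq_qc_gate, zscore
from .scoring import arm_z, cin_score, classify_cin, max_sel_rank_cutoff, segment_z
from .segment import SegmentParams, segment_genome
from .simulate import CohortSpec, HazardSpec, simulate_cohort
from .stats import SurvivalData, c_index, cox_fit, km_estimate, logrank_test, td_roc

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "report"]


@dataclass
class RunConfig:
    outdir: str = "cinpipe_run"
    seed: int = 0
    # genome / grid
    genome_path: str | None = None  # None -> shipped hg19-like autosomes
    bin_size: int = 200_000
    # inputs: simulate, or read from files
    simulate: bool = True
    n_controls: int = 11
    n_tumors: int = 50
    depth_mean: float = 667.0
    noise_model: str = "negbin"
    dispersion: float = 0.05
    bin_bias_sd: float = 0.1
    baseline_rate: float = 0.0025
    log_hr_high: float = float(np.log(5.0))
    censor_time: float = 96.0
    tumor_coverage: str | None = None
    control_coverage: str | None = None
    clinical: str | None = None
    # QC
    mad_threshold: float = 0.38
    min_reads: float = 10_000_000
    min_pct_q30: float = 85.0
    min_pct_unique: float = 70.0
    # CBS
    alpha: float = 0.01
    n_perm: int = 1000
    min_width: int = 3
    merge_sd: float = 1.5
    # CIN
    z_min: float = 2.0
    signed: bool = False
    # cutoff
    cutoff_mode: str = "derive"  # derive | fixed
    cutoff_value: float | None = None
    cutoff_eps: float = 0.1
    # survival
    horizons: tuple[float, ...] = (24.0, 36.0, 48.0, 60.0)
    n_boot: int = 200

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def qc_config(self) -> QCConfig:
        return QCConfig(self.mad_threshold, self.min_reads, self.min_pct_q30, self.min_pct_unique)

    def segment_params(self, seed: int | None = None) -> SegmentParams:
        return SegmentParams(self.alpha, self.n_perm, self.min_width, self.merge_sd, seed)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_controls=self.n_controls,
            n_tumors=self.n_tumors,
            depth_mean=self.depth_mean,
            bin_bias_sd=self.bin_bias_sd,
            noise_model=self.noise_model,
            dispersion=self.dispersion,
            hazard=HazardSpec(self.baseline_rate, self.log_hr_high, self.censor_time),
        )


def _child_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": [],
        "excluded": [],
        "outputs": {},
    }
    genome = load_genome_tsv(config.genome_path) if config.genome_path else default_genome()
    grid = build_bin_grid(genome, config.bin_size)

    # ---- inputs -----------------------------------------------------
    if config.simulate:
        cohort = simulate_cohort(config.cohort_spec(), grid, _child_seed(config.seed, 0))
        controls, tumors, metas = cohort.controls, cohort.tumors, cohort.metas
        cov_path = out / "coverage.tsv"
        cio.write_coverage_table(controls + tumors, grid, cov_path)
        clin_path = out / "clinical.csv"
        cio.write_clinical_csv([m for m in metas if m.role == "tumor"], clin_path)
        cohort.truth.to_csv(out / "truth.csv", index=False)
        manifest["outputs"]["truth"] = str(out / "truth.csv")
        manifest["stages"].append("simulate")
    else:
        for key in ("tumor_coverage", "control_coverage", "clinical"):
            p = getattr(config, key)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config.{key} missing or not found: {p}")
        controls = cio.read_coverage_table(config.control_coverage, grid)
        tumors = cio.read_coverage_table(config.tumor_coverage, grid)
        metas = cio.read_clinical_csv(config.clinical)
        cov_path, clin_path = Path(config.tumor_coverage), Path(config.clinical)
    manifest["outputs"]["coverage"] = str(cov_path)
    manifest["outputs"]["clinical"] = str(clin_path)
    meta_by_id = {m.sample_id: m for m in metas}

    # ---- QC + normalization ----------------------------------------
    qc_cfg = config.qc_config()
    panel = build_panel(controls)
    qc_rows, kept, zprofiles = [], [], {}
    for prof in tumors:
        reasons: list[str] = []
        meta = meta_by_id.get(prof.sample_id)
        if meta is not None and meta.total_reads is not None:
            ok, seq_reasons = seq_qc_gate(meta, qc_cfg)
            reasons += seq_reasons
        mad, mad_ok = mad_qc(prof, panel, qc_cfg, grid)
        if not mad_ok:
            reasons.append("mad")
        qc_rows.append(
            {
                "sample_id": prof.sample_id,
                "mad": mad,
                "reads": getattr(meta, "total_reads", None),
                "q30": getattr(meta, "pct_q30", None),
                "unique": getattr(meta, "pct_unique_map", None),
                "verdict": "pass" if not reasons else "fail:" + "+".join(reasons),
            }
        )
        if reasons:
            manifest["excluded"].append({"sample_id": prof.sample_id, "rules": reasons})
            logger.warning("excluded %s (%s)", prof.sample_id, ",".join(reasons))
            continue
        kept.append(prof)
        zprofiles[prof.sample_id] = zscore(prof, panel, grid)
    pd.DataFrame(qc_rows).to_csv(out / "qc.csv", index=False)
    manifest["outputs"]["qc"] = str(out / "qc.csv")
    manifest["stages"] += ["qc", "normalize"]
    if not kept:
        raise RuntimeError("QC excluded every sample")

    # ---- segmentation + scoring ------------------------------------
    seg_frames, score_rows = [], []
    for i, prof in enumerate(kept):
        params = config.segment_params(_child_seed(config.seed, 1000 + i))
        zp = zprofiles[prof.sample_id]
        segset = segment_genome(zp, grid, params)
        segz = segment_z(zp, segset)
        score = cin_score(segz, config.z_min, config.signed)
        arms = arm_z(zp, grid)
        seg_frames.append(
            pd.DataFrame(
                [
                    {
                        "sample_id": s.sample_id,
                        "chrom": s.chrom,
                        "start_bp": s.start_bp,
                        "end_bp": s.end_bp,
                        "n_marks": s.n_marks,
                        "seg_mean": s.seg_mean,
                    }
                    for s in segset
                ]
            )
        )
        score_rows.append({"sample_id": prof.sample_id, "cin_score": score, **{f"z_{a}": v for a, v in arms.items()}})
    cio.write_segments_seg(pd.concat(seg_frames, ignore_index=True), out / "segments.seg")
    scores = pd.DataFrame(score_rows)
    manifest["outputs"]["segments"] = str(out / "segments.seg")
    manifest["stages"] += ["segment", "score"]

    # ---- cutoff + classification -----------------------------------
    clin = pd.read_csv(clin_path, dtype={"sample_id": str})
    merged = scores.merge(clin, on="sample_id", how="inner")
    if config.cutoff_mode == "fixed":
        if config.cutoff_value is None:
            raise ValueError("cutoff_mode=fixed requires cutoff_value")
        cutoff, cutoff_info = float(config.cutoff_value), {"mode": "fixed"}
    else:
        res = max_sel_rank_cutoff(
            merged["cin_score"].to_numpy(),
            merged["rfs_months"].to_numpy(),
            merged["relapse"].to_numpy(),
            eps=config.cutoff_eps,
        )
        cutoff = res.cutoff
        cutoff_info = {
            "mode": "derived",
            "max_statistic": res.max_statistic,
            "approx_p": res.approx_p,
        }
    cutoff_info["cutoff"] = cutoff
    merged["cin_class"] = [classify_cin(s, cutoff) for s in merged["cin_score"]]
    scores = scores.merge(merged[["sample_id", "cin_class"]], on="sample_id")
    scores.to_csv(out / "scores.csv", index=False)
    (out / "cutoff.json").write_text(json.dumps(cutoff_info, indent=2))
    manifest["outputs"]["scores"] = str(out / "scores.csv")
    manifest["outputs"]["cutoff"] = str(out / "cutoff.json")
    manifest["stages"] += ["cutoff"]

    # ---- survival ---------------------------------------------------
    data = SurvivalData(
        merged["rfs_months"].to_numpy(), merged["relapse"].to_numpy()
    )
    high = (merged["cin_class"] == "high").to_numpy().astype(float)
    surv: dict = {"n": int(len(merged)), "n_high": int(high.sum())}
    km = km_estimate(data, np.where(high == 1, "high", "low"))
    surv["km_median"] = {k: (None if np.isinf(v.median) else v.median) for k, v in km.items()}
    if 0 < high.sum() < len(high):
        chi2, p = logrank_test(data, high == 1)
        surv["logrank"] = {"chi2": chi2, "p": p}
        fit = cox_fit(
            SurvivalData(data.time, data.event, pd.DataFrame({"high_cin": high})),
            ["high_cin"],
        )
        s = fit.summary().loc["high_cin"]
        surv["cox_high_cin"] = {
            "HR": s["HR"], "ci_low": s["ci_low"], "ci_high": s["ci_high"], "p": s["p"],
        }
        surv["c_index"] = c_index(merged["cin_score"].to_numpy(), data)
        # an AUC(t) needs at least one case (event by t) and one control
        horizons = [
            h
            for h in config.horizons
            if h < data.time.max()
            and np.any((data.time <= h) & (data.event == 1))
            and np.any(data.time > h)
        ]
        if horizons:
            roc = td_roc(
                merged["cin_score"].to_numpy(), data, horizons,
                n_boot=config.n_boot, seed=_child_seed(config.seed, 2),
            )
            roc.to_csv(out / "td_auc.csv", index=False)
            manifest["outputs"]["td_auc"] = str(out / "td_auc.csv")
    else:
        surv["note"] = "single CIN class; survival contrasts skipped"
    (out / "survival.json").write_text(json.dumps(surv, indent=2, default=float))
    manifest["outputs"]["survival"] = str(out / "survival.json")
    manifest["stages"] += ["survival"]

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    manifest["outputs"]["manifest"] = str(out / "manifest.json")
    return manifest


def report(manifest: dict | str | Path) -> str:
    """Human-readable run summary, reproducible from stored artifacts."""
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    outs = manifest["outputs"]
    scores = pd.read_csv(outs["scores"], dtype={"sample_id": str})
    clin = pd.read_csv(outs["clinical"], dtype={"sample_id": str})
    surv = json.loads(Path(outs["survival"]).read_text())
    cutoff = json.loads(Path(outs["cutoff"]).read_text())
    lines = ["# cinpipe run summary", ""]
    n_high = int((scores["cin_class"] == "high").sum())
    lines.append(f"samples scored: {len(scores)}  (high CIN: {n_high}, low CIN: {len(scores) - n_high})")
    lines.append(f"CIN cutoff: {cutoff['cutoff']:.3f} ({cutoff['mode']})")
    if manifest["excluded"]:
        for e in manifest["excluded"]:
            lines.append(f"excluded from analysis: {e['sample_id']} [{'+'.join(e['rules'])}]")
    med = surv.get("km_median", {})
    if med:
        fmt = {k: ("-" if v is None else f"{v:.1f}") for k, v in med.items()}
        lines.append(f"median RFS (months): " + ", ".join(f"{k}={v}" for k, v in sorted(fmt.items())))
    if "logrank" in surv:
        lines.append(f"log-rank: chi2={surv['logrank']['chi2']:.3f}, p={surv['logrank']['p']:.4g}")
    if "cox_high_cin" in surv:
        c = surv["cox_high_cin"]
        lines.append(
            f"Cox high-vs-low CIN: HR={c['HR']:.2f} (95% CI {c['ci_low']:.2f}-{c['ci_high']:.2f}), p={c['p']:.4g}"
        )
    if "c_index" in surv:
        lines.append(f"C-index (CIN score): {surv['c_index']:.3f}")
    # covariate association tables, Table-1 style
    merged = scores.merge(clin, on="sample_id", how="inner")
    if "cin_class" in merged and merged["relapse"].notna().all():
        from .stats import pearson_chi2

        lines.append("")
        lines.append("covariate x CIN-class association (uncorrected chi-square):")
        for cov in ("sex", "smoking", "tumor_count", "grade", "stage"):
            if cov not in merged or merged[cov].isna().any():
                continue
            tab = pd.crosstab(merged[cov], merged["cin_class"])
            if tab.shape[0] < 2 or (tab.values.sum(axis=0) == 0).any():
                continue
            try:
                _, p = pearson_chi2(tab.values)
                lines.append(f"  {cov}: p={p:.3f}")
            except ValueError:
                continue
    return "\n".join(lines) + "\n"
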