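"""Control-panel normalization and sample QC.

Each bin of a tumor profile is standardized against the healthy-control
panel:

    Z_bin = (coverage_raw - mean(coverage_controls)) / sd(coverage_controls)

with the per-bin mean and sample standard deviation (ddof=1) taken across
control samples.  Bins that cannot be standardized — centromeric bins and
bins whose control variance is zero — are masked and stay masked through
segmentation and scoring.

Two QC gates decide whether a sample enters the analysis at all: a
sequencing-metadata gate (read count, Q30, unique-mapping fractions) and a
noise gate on the median absolute deviation of the per-bin log2 copy ratio
(raw MAD, no 1.4826 consistency factor; samples whose MAD exceeds the
threshold are excluded as too noisy to segment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import BinGrid
from .io import CoverageProfile, SampleMeta

__all__ = ["ControlPanel", "ZProfile", "QCConfig", "build_panel", "zscore", "mad_qc", "seq_qc_gate"]


@dataclass
class QCConfig:
    mad_threshold: float = 0.38
    min_reads: float = 10_000_000
    min_pct_q30: float = 85.0
    min_pct_unique: float = 70.0

    def __post_init__(self) -> None:
        if min(self.mad_threshold, self.min_reads, self.min_pct_q30, self.min_pct_unique) <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass
class ControlPanel:
    """Per-bin control statistics; the normalization reference."""

    mean_raw: np.ndarray
    stdev_raw: np.ndarray  # sample sd, ddof=1
    n_controls: int
    matrix: np.ndarray | None = None  # controls x bins, kept for leave-one-out

    @property
    def usable(self) -> np.ndarray:
        """Bins with positive control variance (standardizable)."""
        return self.stdev_raw > 0


@dataclass
class ZProfile:
    """Standardized per-bin profile; NaN and ``mask == False`` off usable bins."""

    sample_id: str
    z: np.ndarray
    mask: np.ndarray  # True where usable

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.z[self.mask])):
            raise ValueError("non-finite Z on usable bins")


def build_panel(controls: list[CoverageProfile]) -> ControlPanel:
    """Per-bin mean and sample sd across >= 2 controls on a common grid."""
    if len(controls) < 2:
        raise ValueError("need >= 2 controls")
    lengths = {len(c.values) for c in controls}
    if len(lengths) != 1:
        raise ValueError("control profiles are not on a common grid")
    m = np.vstack([c.values for c in controls])
    return ControlPanel(
        mean_raw=m.mean(axis=0),
        stdev_raw=m.std(axis=0, ddof=1),
        n_controls=len(controls),
        matrix=m,
    )


def zscore(
    profile: CoverageProfile, panel: ControlPanel, grid: BinGrid | None = None
) -> ZProfile:
    """Standardize one profile against the panel.

    Masked: zero-variance panel bins, and centromeric bins when a grid is
    supplied.
    """
    if len(profile.values) != len(panel.mean_raw):
        raise ValueError("profile/panel length mismatch")
    mask = panel.usable.copy()
    if grid is not None:
        if len(grid) != len(panel.mean_raw):
            raise ValueError("grid/panel length mismatch")
        mask &= ~grid.centromeric
    z = np.full(len(profile.values), np.nan)
    z[mask] = (profile.values[mask] - panel.mean_raw[mask]) / panel.stdev_raw[mask]
    return ZProfile(profile.sample_id, z, mask)


def mad_qc(
    profile: CoverageProfile,
    panel: ControlPanel,
    cfg: QCConfig | None = None,
    grid: BinGrid | None = None,
) -> tuple[float, bool]:
    """Noise gate: MAD of per-bin log2 copy ratio vs the panel mean.

    Zero-coverage bins get a 0.5 pseudo-count before the log; bins with a
    non-positive panel mean (or centromeric, when a grid is supplied) are
    left out.  Returns ``(mad, passed)``; the sample fails only when the MAD
    strictly exceeds the threshold.
    """
    cfg = cfg or QCConfig()
    mask = panel.mean_raw > 0
    if grid is not None:
        mask &= ~grid.centromeric
    if not mask.any():
        raise ValueError("no usable bins for MAD QC")
    v = profile.values[mask]
    v = np.where(v > 0, v, 0.5)
    r = np.log2(v / panel.mean_raw[mask])
    mad = float(np.median(np.abs(r - np.median(r))))
    return mad, mad <= cfg.mad_threshold


def seq_qc_gate(meta: SampleMeta, cfg: QCConfig | None = None) -> tuple[bool, list[str]]:
    """Sequencing-metadata gate; returns (passed, violated criteria)."""
    cfg = cfg or QCConfig()
    for name in ("total_reads", "pct_q30", "pct_unique_map"):
        if getattr(meta, name) is None:
            raise ValueError(f"{meta.sample_id}: missing seq QC field {name}")
    reasons = []
    if meta.total_reads < cfg.min_reads:
        reasons.append("reads")
    if meta.pct_q30 < cfg.min_pct_q30:
        reasons.append("q30")
    if meta.pct_unique_map < cfg.min_pct_unique:
        reasons.append("unique_map")
    return not reasons, reasons
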