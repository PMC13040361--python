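"""Chromosomal-instability scoring and survival-driven dichotomization.

The CIN score aggregates segmented copy-number signal into one burden
statistic per sample:

    CIN = sum over segments of  L_seg x |Z_seg|

where ``L_seg`` is the segment length in megabases and ``Z_seg`` the mean
per-bin Z-score over the segment.  Two conventions matter and are both
configurable: the sum uses |Z| by default (a signed sum would let gains
cancel losses, contradicting CIN-as-burden), and only segments with
``|Z_seg| >= z_min`` (default 2) contribute, so panel-level noise does not
accumulate with genome size.

Samples are dichotomized at a cutoff chosen by maximally selected rank
statistics: the candidate threshold maximizing the standardized two-group
log-rank statistic on recurrence-free survival, with the Lausen–Schumacher
improved-Bonferroni bound as the selection-adjusted p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .genome import BinGrid, GenomeModel
from .normalize import ZProfile
from .segment import Segment, SegmentSet
from .stats import logrank_z

__all__ = [
    "SegmentZ",
    "CINResult",
    "CutoffResult",
    "segment_z",
    "cin_score",
    "arm_z",
    "arm_positive",
    "classify_cin",
    "max_sel_rank_cutoff",
    "segment_group_test",
]


@dataclass(frozen=True)
class SegmentZ:
    """A segment reduced to the two numbers the CIN score needs."""

    segment: Segment
    length_mb: float  # L: genomic length in Mb
    zseg: float  # mean per-bin Z over the segment

    def __post_init__(self) -> None:
        if not self.length_mb > 0:
            raise ValueError("segment length must be positive")


@dataclass
class CINResult:
    sample_id: str
    cin_score: float
    arm_z: dict[str, float]
    cin_class: str | None = None  # "high" | "low" once a cutoff is applied
    qc_pass: bool = True
    qc_reasons: list[str] = field(default_factory=list)
    mad: float | None = None


@dataclass
class CutoffResult:
    cutoff: float
    max_statistic: float
    candidates: np.ndarray
    statistics: np.ndarray
    approx_p: float


def segment_z(zprofile: ZProfile, segset: SegmentSet) -> list[SegmentZ]:
    """Per-segment (L, Z): L from bp coordinates, Z the unweighted mean of
    usable bin Z inside the segment."""
    out = []
    for seg in segset:
        sel = np.zeros(len(zprofile.z), dtype=bool)
        sel[seg.start_bin : seg.end_bin + 1] = True
        sel &= zprofile.mask
        if not sel.any():
            raise ValueError(f"segment {seg} has no usable bins")
        out.append(
            SegmentZ(
                segment=seg,
                length_mb=(seg.end_bp - seg.start_bp) / 1e6,
                zseg=float(zprofile.z[sel].mean()),
            )
        )
    return out


def cin_score(
    segments: list[SegmentZ], z_min: float = 2.0, signed: bool = False
) -> float:
    """CIN = sum of L x |Z| over segments with |Z| >= z_min.

    ``signed=True`` drops the absolute value (the formula as a literal
    signed sum), in which case the result may be negative.
    """
    total = 0.0
    for s in segments:
        if abs(s.zseg) >= z_min:
            total += s.length_mb * (s.zseg if signed else abs(s.zseg))
    return total


def arm_z(zprofile: ZProfile, grid: BinGrid) -> dict[str, float]:
    """Mean usable-bin Z per chromosome arm (e.g. ``chr8q``); arms with no
    usable bins are absent."""
    out: dict[str, float] = {}
    arms = grid.arm
    for label in dict.fromkeys(arms[arms != ""]):
        sel = (arms == label) & zprofile.mask
        if sel.any():
            out[label] = float(zprofile.z[sel].mean())
    return out


def arm_positive(arm_z_value: float, cutoff: float) -> bool:
    """Arm call is positive at or above the cutoff (boundary inclusive)."""
    return bool(arm_z_value >= cutoff)


def classify_cin(score: float, cutoff: float) -> str:
    """High CIN strictly above the cutoff, low at or below."""
    return "high" if score > cutoff else "low"


def _lausen_schumacher_p(b: float, eps_low: float, eps_high: float) -> float:
    """Improved-Bonferroni bound for the maximally selected rank statistic
    restricted to candidate quantiles in [eps_low, eps_high]."""
    if b <= 1e-8:
        return 1.0
    phi = sps.norm.pdf(b)
    log_term = np.log((eps_high * (1 - eps_low)) / ((1 - eps_high) * eps_low))
    p = phi * (b - 1.0 / b) * log_term + 4.0 * phi / b
    return float(np.clip(p, 0.0, 1.0))


def max_sel_rank_cutoff(
    scores: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    eps: float = 0.1,
) -> CutoffResult:
    """Optimal survival cutpoint by maximally selected rank statistics.

    Candidates are midpoints between consecutive unique ordered scores whose
    induced group proportions lie in [eps, 1-eps]; for each, the two-group
    standardized log-rank statistic |Z| is computed and the maximizing
    candidate returned (ties toward the smaller cutpoint).
    """
    scores = np.asarray(scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    n = scores.size
    if n < 10:
        raise ValueError("need >= 10 samples")
    if events.sum() == 0 or events.sum() == n:
        raise ValueError("need both events and censored observations")
    if not 0 < eps < 0.5:
        raise ValueError("eps must be in (0, 0.5)")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2
    props = np.array([(scores > c).mean() for c in mids])
    adm = (props >= eps) & (props <= 1 - eps)
    if not adm.any():
        raise ValueError("no admissible candidate cutpoints")
    cands = mids[adm]
    stats_ = np.abs(_logrank_z_cutpoints(scores, times, events, cands))
    i = int(np.argmax(stats_))  # first max -> smaller cutpoint on ties
    b = float(stats_[i])
    return CutoffResult(
        cutoff=float(cands[i]),
        max_statistic=b,
        candidates=cands,
        statistics=stats_,
        approx_p=_lausen_schumacher_p(b, eps, 1 - eps),
    )


def _logrank_z_cutpoints(
    scores: np.ndarray, times: np.ndarray, events: np.ndarray, cands: np.ndarray
) -> np.ndarray:
    """Standardized log-rank Z for every candidate cutpoint at once.

    Equivalent to calling :func:`cinpipe.stats.logrank_z` per candidate with
    group ``scores > c``, vectorized across candidates for the cutpoint scan
    and its permutation studies.
    """
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    g = scores[order][None, :] > cands[:, None]  # (candidates, subjects)
    n = t.size
    suffix = np.cumsum(g[:, ::-1], axis=1)[:, ::-1]  # in-group at risk from i on
    oe = np.zeros(len(cands))
    var = np.zeros(len(cands))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d > 0:
            at = n - i
            n1 = suffix[:, i]
            d1 = g[:, i:j][:, e[i:j] == 1].sum(axis=1)
            oe += d1 - d * n1 / at
            if at > 1:
                var += d * (n1 / at) * (1 - n1 / at) * (at - d) / (at - 1)
        i = j
    with np.errstate(divide="ignore", invalid="ignore"):
        z = oe / np.sqrt(var)
    return np.where(var > 0, z, 0.0)


def segment_group_test(
    seg_matrix: np.ndarray,
    relapse: np.ndarray,
    seg_index=None,
) -> "pd.DataFrame":
    """Relapse vs non-relapse comparison per common segment.

    ``seg_matrix``: samples x segments of per-sample mean Z over a shared
    segment grid.  Per segment: two-sided Wilcoxon rank-sum between groups;
    reports the group mean difference and log10(p), flagging segments with
    log10(p) < -1.3 (p < 0.05).
    """
    import pandas as pd

    seg_matrix = np.asarray(seg_matrix, float)
    relapse = np.asarray(relapse).astype(bool)
    if relapse.sum() < 2 or (~relapse).sum() < 2:
        raise ValueError("need >= 2 samples per group")
    rows = []
    for j in range(seg_matrix.shape[1]):
        a = seg_matrix[relapse, j]
        b = seg_matrix[~relapse, j]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append(
            {
                "segment": seg_index[j] if seg_index is not None else j,
                "seg_mean_diff": float(a.mean() - b.mean()),
                "log10_p": float(np.log10(p)) if p > 0 else -np.inf,
                "significant": np.log10(p) < -1.3 if p > 0 else True,
            }
        )
    return pd.DataFrame(rows)
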