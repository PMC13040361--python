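"""Circular binary segmentation (CBS) of per-bin Z-score series.

The segmenter is the Olshen–Venkatraman recursion: for the current interval
find the arc whose mean differs most from its complement (the circular
two-sample t-statistic, computed over all contiguous arcs — arc/complement
symmetry makes wrap-around arcs redundant), assess the split by permutation,
and recurse until no interval splits.  Significance is the exact permutation
p-value ``(1 + #{perm t >= obs t}) / (1 + n_perm)``; permutation processing
stops early once enough exceedances have accumulated that the verdict
cannot change, which leaves accept/reject decisions identical to the full
run.

Chromosomes are segmented one arm at a time — masked (centromeric or
zero-variance) bins are excised before segmentation, so segments never span
the centromere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .genome import BinGrid

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "SegmentSet",
    "SegmentParams",
    "cbs_segment",
    "prune_segments",
    "segment_genome",
    "max_circular_t",
]


@dataclass(frozen=True)
class Segment:
    """One constant-level segment (inclusive bin indices into the grid)."""

    chrom: str
    start_bin: int
    end_bin: int
    seg_mean: float
    start_bp: int
    end_bp: int
    n_marks: int  # usable bins contributing to the mean
    sample_id: str = ""

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1

    @property
    def length_mb(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6


@dataclass
class SegmentParams:
    alpha: float = 0.01
    n_perm: int = 1000
    min_width: int = 3
    merge_sd: float = 1.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")


@dataclass
class SegmentSet:
    sample_id: str
    segments: list[Segment]
    params: SegmentParams = field(default_factory=SegmentParams)

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)


# ------------------------------------------------------------- core search


def _t_for_arcs(cum: np.ndarray, tot2: float, n: int, k: int) -> np.ndarray:
    """|t| for every arc of length k.

    ``cum`` has shape (..., n+1) (leading axis = permutations).  Uses the
    identity SS_within = sum(x^2) - k*m1^2 - (n-k)*m2^2, so only the running
    sum of the (permuted) series is needed.
    """
    arc = cum[..., k:] - cum[..., :-k]
    tot = cum[..., -1:]
    m1 = arc / k
    m2 = (tot - arc) / (n - k)
    ss_within = np.clip(tot2 - k * m1**2 - (n - k) * m2**2, 0.0, None)
    denom = np.sqrt(ss_within / max(n - 2, 1) * (1.0 / k + 1.0 / (n - k)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(m1 - m2) / denom
    return np.nan_to_num(t, nan=0.0, posinf=np.inf)


def _admissible(n: int, k: int, min_width: int) -> np.ndarray:
    """Mask over arc starts s (0..n-k) whose split pieces all satisfy
    min_width: arc length k, left piece s, right piece n-s-k (empty ok)."""
    s = np.arange(n - k + 1)
    left_ok = (s == 0) | (s >= min_width)
    right = n - s - k
    right_ok = (right == 0) | (right >= min_width)
    return left_ok & right_ok


def max_circular_t(x: np.ndarray, min_width: int = 1) -> tuple[float, int, int]:
    """Best split of ``x``: returns (|t|, s, k) for the maximizing arc
    ``[s, s+k)``; ties resolved toward smaller s, then smaller k.

    Returns (0.0, 0, n) when no admissible split exists.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return 0.0, 0, n
    cum = np.concatenate([[0.0], np.cumsum(x)])
    tot2 = float(np.sum(x * x))
    best_t, best_s, best_k = -1.0, 0, n
    k_range = range(min_width, n - min_width + 1) if n >= 2 * min_width else range(0)
    for k in k_range:
        adm = _admissible(n, k, min_width)
        if not adm.any():
            continue
        t = _t_for_arcs(cum, tot2, n, k)
        t = np.where(adm, t, -1.0)
        s = int(np.argmax(t))  # first (= smallest s) maximum
        tv = float(t[s])
        if tv > best_t or (tv == best_t and s < best_s):
            best_t, best_s, best_k = tv, s, k
    if best_t < 0:
        return 0.0, 0, n
    return best_t, best_s, best_k


def _perm_max_t(
    x: np.ndarray,
    t_obs: float,
    n_perm: int,
    alpha: float,
    min_width: int,
    rng: np.random.Generator,
    block: int = 100,
) -> float:
    """Permutation p-value of the observed max |t|, with early stopping.

    Processes permutations in blocks; once the exceedance count guarantees
    p >= alpha the remaining permutations cannot change the accept/reject
    decision and a (conservative) p-value is returned.
    """
    n = x.size
    tot2 = float(np.sum(x * x))
    reject_at = math.ceil(alpha * (1 + n_perm))  # count making p >= alpha certain
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perms = rng.permuted(np.broadcast_to(x, (b, n)).copy(), axis=1)
        cum = np.concatenate([np.zeros((b, 1)), np.cumsum(perms, axis=1)], axis=1)
        pmax = np.zeros(b)
        for k in range(min_width, n - min_width + 1):
            adm = _admissible(n, k, min_width)
            if not adm.any():
                continue
            t = _t_for_arcs(cum, tot2, n, k)
            np.maximum(pmax, np.max(np.where(adm, t, -1.0), axis=1), out=pmax)
        exceed += int(np.sum(pmax >= t_obs))
        done += b
        if exceed >= reject_at:
            return (1 + exceed) / (1 + n_perm)
    return (1 + exceed) / (1 + n_perm)


def _cbs_boundaries(
    x: np.ndarray, params: SegmentParams, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Recursive CBS on one series; returns half-open (lo, hi) pieces."""
    out: list[tuple[int, int]] = []

    def rec(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = hi - lo
        if n < 2 * params.min_width:
            out.append((lo, hi))
            return
        t_obs, s, k = max_circular_t(seg, params.min_width)
        if t_obs <= 0 or k >= n:
            out.append((lo, hi))
            return
        p = _perm_max_t(seg, t_obs, params.n_perm, params.alpha, params.min_width, rng)
        if p >= params.alpha:
            out.append((lo, hi))
            return
        for a, b in ((lo, lo + s), (lo + s, lo + s + k), (lo + s + k, hi)):
            if b > a:
                rec(a, b)

    rec(0, len(x))
    out.sort()
    return out


def prune_segments(
    boundaries: list[tuple[int, int]], x: np.ndarray, merge_sd: float = 1.5
) -> list[tuple[int, int]]:
    """Merge adjacent pieces whose mean difference is small relative to the
    pooled within-segment sd; iterate until stable (DNAcopy-undo style)."""
    bounds = sorted(boundaries)
    while len(bounds) > 1:
        means = np.array([x[a:b].mean() for a, b in bounds])
        ss = sum(float(np.sum((x[a:b] - m) ** 2)) for (a, b), m in zip(bounds, means))
        df = len(x) - len(bounds)
        sd = math.sqrt(ss / df) if df > 0 else 0.0
        diffs = np.abs(np.diff(means))
        i = int(np.argmin(diffs))
        if diffs[i] < merge_sd * sd or sd == 0 and diffs[i] == 0:
            bounds[i] = (bounds[i][0], bounds[i + 1][1])
            del bounds[i + 1]
        else:
            break
    return bounds


def cbs_segment(
    series: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 3,
    seed: int | np.random.Generator | None = None,
    chrom: str = "",
    starts: np.ndarray | None = None,
    ends: np.ndarray | None = None,
    sample_id: str = "",
) -> list[Segment]:
    """Segment a single chromosome(-arm) series into constant-mean pieces.

    ``starts``/``ends`` give per-bin bp coordinates (default: bin indices),
    used only to fill the Segment bp fields.  Deterministic under a fixed
    seed.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 1:
        raise ValueError("series must be non-empty")
    params = SegmentParams(alpha=alpha, n_perm=n_perm, min_width=min_width)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if starts is None:
        starts = np.arange(series.size, dtype=np.int64)
        ends = starts + 1
    bounds = _cbs_boundaries(series, params, rng)
    return [
        Segment(
            chrom=chrom,
            start_bin=a,
            end_bin=b - 1,
            seg_mean=float(series[a:b].mean()),
            start_bp=int(starts[a]),
            end_bp=int(ends[b - 1]),
            n_marks=b - a,
            sample_id=sample_id,
        )
        for a, b in bounds
    ]


def segment_genome(
    zprofile, grid: BinGrid, params: SegmentParams | None = None
) -> SegmentSet:
    """Per-arm CBS over a whole Z-profile, with pruning.

    Masked bins (centromeric, zero-variance) are excised; each maximal arm
    block is segmented on its compacted series and segment bin indices are
    mapped back onto the grid.
    """
    params = params or SegmentParams()
    ss = np.random.SeedSequence(params.seed)
    z = zprofile.z
    usable = zprofile.mask
    segments: list[Segment] = []
    chroms = grid.chrom
    arms = grid.arm
    blocks: list[tuple[str, np.ndarray]] = []
    for name in grid.genome.names:
        csel = chroms == name
        for arm_label in dict.fromkeys(arms[csel & (arms != "")]):
            idx = np.flatnonzero(csel & (arms == arm_label) & usable)
            if idx.size == 0:
                logger.info("%s: no usable bins, skipped", arm_label)
                continue
            blocks.append((name, idx))
    rngs = [np.random.default_rng(c) for c in ss.spawn(len(blocks))]
    for (name, idx), rng in zip(blocks, rngs):
        x = z[idx]
        bounds = _cbs_boundaries(x, params, rng)
        bounds = prune_segments(bounds, x, params.merge_sd)
        for a, b in bounds:
            gi, gj = int(idx[a]), int(idx[b - 1])
            segments.append(
                Segment(
                    chrom=name,
                    start_bin=gi,
                    end_bin=gj,
                    seg_mean=float(x[a:b].mean()),
                    start_bp=int(grid.start[gi]),
                    end_bp=int(grid.end[gj]),
                    n_marks=b - a,
                    sample_id=zprofile.sample_id,
                )
            )
    return SegmentSet(zprofile.sample_id, segments, params)
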