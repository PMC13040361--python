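"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
coverage TSV
    ``sample  chrom  start  end  coverage`` — one row per (sample, bin),
    0-based half-open coordinates that must match the grid exactly.
BED
    0-based half-open; used for per-bin value tracks and for read start
    positions fed to :func:`reads_to_bins`.
SEG
    ``sample  chrom  loc_start  loc_end  num_mark  seg_mean`` with 1-based
    inclusive starts, the convention of segmentation output consumed by IGV.
clinical CSV
    One row per tumor sample; see :data:`CLINICAL_COLUMNS`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import BinGrid

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageProfile",
    "SampleMeta",
    "read_coverage_table",
    "write_coverage_table",
    "reads_to_bins",
    "read_bed_starts",
    "write_bins_bed",
    "read_bins_bed",
    "write_segments_seg",
    "read_segments_seg",
    "read_clinical_csv",
    "write_clinical_csv",
    "CLINICAL_COLUMNS",
]


@dataclass
class CoverageProfile:
    """Raw per-bin coverage for one sample, aligned to a :class:`BinGrid`."""

    sample_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.sample_id}: non-finite coverage values")
        if np.any(self.values < 0):
            raise ValueError(f"{self.sample_id}: negative coverage values")


@dataclass
class SampleMeta:
    """Per-sample metadata: sequencing QC plus (for tumors) clinical fields."""

    sample_id: str
    role: str = "tumor"  # tumor | control
    total_reads: float | None = None
    pct_q30: float | None = None
    pct_unique_map: float | None = None
    age: float | None = None
    sex: str | None = None  # male | female
    smoking: str | None = None  # yes | no
    tumor_size: float | None = None  # cm
    tumor_count: str | None = None  # single | multiple
    grade: str | None = None  # low | high
    stage: str | None = None  # Ta | T1
    intravesical_drug: str | None = None
    relapse: int | None = None  # 1 event, 0 censored
    rfs_months: float | None = None
    extra: dict = field(default_factory=dict)

    _GRADES = {"low", "high"}
    _STAGES = {"Ta", "T1"}

    def __post_init__(self) -> None:
        if self.role not in ("tumor", "control"):
            raise ValueError(f"role must be tumor|control, got {self.role!r}")
        if self.grade is not None and self.grade not in self._GRADES:
            raise ValueError(f"grade must be one of {sorted(self._GRADES)}")
        if self.stage is not None and self.stage not in self._STAGES:
            raise ValueError(f"stage must be one of {sorted(self._STAGES)}")
        if self.rfs_months is not None and not self.rfs_months > 0:
            raise ValueError("rfs_months must be positive")
        if self.relapse is not None and self.relapse not in (0, 1):
            raise ValueError("relapse must be 0 or 1")


# ---------------------------------------------------------------- coverage

_COV_COLS = ["sample", "chrom", "start", "end", "coverage"]


def read_coverage_table(path: str | Path, grid: BinGrid) -> list[CoverageProfile]:
    """Read a coverage TSV into one profile per sample (file order).

    Every row must match a grid bin by exact ``(chrom, start, end)``; bins a
    sample never mentions are left at NaN and reported via a warning so
    truncated inputs are not silently treated as zero coverage.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = [c for c in _COV_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"coverage table missing columns {missing}")
    if not pd.api.types.is_numeric_dtype(df["coverage"]):
        bad = df[pd.to_numeric(df["coverage"], errors="coerce").isna()]
        raise ValueError(
            f"non-numeric coverage values, first at row {bad.index[0] + 1}"
        )
    profiles: list[CoverageProfile] = []
    for sample in df["sample"].unique():
        sub = df[df["sample"] == sample]
        values = np.full(len(grid), np.nan)
        seen = set()
        for row in sub.itertuples():
            try:
                i = grid.index_of(row.chrom, row.start, row.end)
            except KeyError:
                raise ValueError(
                    f"sample {sample}: coordinate ({row.chrom}, {row.start}, "
                    f"{row.end}) is not a grid bin"
                ) from None
            if i in seen:
                raise ValueError(f"sample {sample}: duplicate bin index {i}")
            seen.add(i)
            values[i] = row.coverage
        n_missing = len(grid) - len(seen)
        if n_missing:
            logger.warning("sample %s: %d grid bins absent from file", sample, n_missing)
            values = np.nan_to_num(values, nan=0.0)
        profiles.append(CoverageProfile(str(sample), values))
    return profiles


def write_coverage_table(
    profiles: Iterable[CoverageProfile], grid: BinGrid, path: str | Path
) -> None:
    frames = []
    for p in profiles:
        if len(p.values) != len(grid):
            raise ValueError(f"{p.sample_id}: profile length != grid length")
        frames.append(
            pd.DataFrame(
                {
                    "sample": p.sample_id,
                    "chrom": grid.chrom,
                    "start": grid.start,
                    "end": grid.end,
                    "coverage": p.values,
                }
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- reads


def reads_to_bins(
    positions: Sequence[tuple[str, int]] | pd.DataFrame,
    grid: BinGrid,
    sample_id: str = "sample",
) -> CoverageProfile:
    """Bin aligned-read start positions into per-bin counts.

    ``positions`` is either an iterable of ``(chrom, start)`` or a DataFrame
    with ``chrom``/``start`` columns (e.g. from :func:`read_bed_starts`).
    Only the start coordinate is used; a read whose start falls in the
    half-open bin ``[s, e)`` counts toward that bin.  Reads on chromosomes
    absent from the grid are skipped and counted in the log.
    """
    if isinstance(positions, pd.DataFrame):
        chroms = positions["chrom"].to_numpy()
        starts = positions["start"].to_numpy()
    else:
        pos = list(positions)
        chroms = np.array([c for c, _ in pos], dtype=object)
        starts = np.array([s for _, s in pos], dtype=np.int64)
    values = np.zeros(len(grid))
    skipped = 0
    slices = grid.chrom_slices()
    gstart = grid.start
    for name in np.unique(chroms) if len(chroms) else []:
        sel = starts[chroms == name]
        if name not in slices:
            skipped += sel.size
            continue
        sl = slices[name]
        length = grid.genome.length(name)
        inside = sel[(sel >= 0) & (sel < length)]
        skipped += sel.size - inside.size
        # uniform bins except a possibly short terminal bin -> index by division
        idx = np.minimum(inside // grid.bin_size, sl.stop - sl.start - 1)
        np.add.at(values, sl.start + idx, 1)
    if skipped:
        logger.warning("%s: skipped %d reads off the grid", sample_id, skipped)
    return CoverageProfile(sample_id, values)


def read_bed_starts(path: str | Path) -> pd.DataFrame:
    """Read a BED-like file of read intervals; returns chrom/start columns."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=[0, 1],
        names=["chrom", "start"], dtype={"chrom": str, "start": np.int64},
    )
    return df


# --------------------------------------------------------------- BED / SEG


def write_bins_bed(grid: BinGrid, values: np.ndarray, path: str | Path, name: str = "value") -> None:
    if len(values) != len(grid):
        raise ValueError("values length != grid length")
    pd.DataFrame(
        {"chrom": grid.chrom, "start": grid.start, "end": grid.end, name: values}
    ).to_csv(path, sep="\t", index=False, header=False)


def read_bins_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )


def write_segments_seg(segments, path: str | Path) -> None:
    """Write segments as SEG (1-based inclusive starts).

    ``segments`` is an iterable of objects with ``sample_id, chrom, start_bp,
    end_bp, n_marks, seg_mean`` attributes (see :mod:`cinpipe.segment`), or a
    DataFrame with those columns.  Overlapping segments on one chromosome of
    one sample are rejected.
    """
    if isinstance(segments, pd.DataFrame):
        df = segments.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "chrom": s.chrom,
                    "start_bp": s.start_bp,
                    "end_bp": s.end_bp,
                    "n_marks": s.n_marks,
                    "seg_mean": s.seg_mean,
                }
                for s in segments
            ]
        )
    for (_, _), sub in df.groupby(["sample_id", "chrom"], sort=False):
        sub = sub.sort_values("start_bp")
        if np.any(sub["start_bp"].to_numpy()[1:] < sub["end_bp"].to_numpy()[:-1]):
            raise ValueError("overlapping segments")
    out = pd.DataFrame(
        {
            "sample": df["sample_id"],
            "chrom": df["chrom"],
            "loc_start": df["start_bp"].astype(np.int64) + 1,
            "loc_end": df["end_bp"].astype(np.int64),
            "num_mark": df["n_marks"].astype(np.int64),
            "seg_mean": df["seg_mean"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_segments_seg(path: str | Path) -> pd.DataFrame:
    """Read SEG back to 0-based half-open ``start_bp``/``end_bp`` columns."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    return pd.DataFrame(
        {
            "sample_id": df["sample"],
            "chrom": df["chrom"],
            "start_bp": df["loc_start"].astype(np.int64) - 1,
            "end_bp": df["loc_end"].astype(np.int64),
            "n_marks": df["num_mark"].astype(np.int64),
            "seg_mean": df["seg_mean"],
        }
    )


# ---------------------------------------------------------------- clinical

CLINICAL_COLUMNS = [
    "sample_id", "age", "sex", "smoking", "tumor_size", "tumor_count",
    "grade", "stage", "intravesical_drug", "relapse", "rfs_months",
    "total_reads", "pct_q30", "pct_unique_map",
]


def write_clinical_csv(metas: Iterable[SampleMeta], path: str | Path) -> None:
    rows = []
    for m in metas:
        rows.append({c: getattr(m, c) for c in CLINICAL_COLUMNS})
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, index=False)


def read_clinical_csv(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, dtype={"sample_id": str})
    metas = []
    for row in df.to_dict("records"):
        kw = {
            k: (None if pd.isna(v) else v)
            for k, v in row.items()
            if k in CLINICAL_COLUMNS
        }
        if kw.get("relapse") is not None:
            kw["relapse"] = int(kw["relapse"])
        metas.append(SampleMeta(role="tumor", **kw))
    return metas
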