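"""Genome model and fixed-width bin grid.

The pipeline measures read depth in fixed 200-kb windows tiled across the
autosomes.  A :class:`GenomeModel` holds chromosome lengths and centromere
intervals (which split each chromosome into a p and a q arm); a
:class:`BinGrid` is the ordered list of windows that every coverage and
Z-score profile is indexed against.

Coordinates are 0-based half-open throughout.  Bins overlapping the declared
centromere interval are flagged centromeric and take no part in arm
assignment, normalization, segmentation or scoring: pericentromeric coverage
in short-read data is dominated by mapping artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenomeModel",
    "BinGrid",
    "build_bin_grid",
    "load_genome_tsv",
    "default_genome",
]


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosomes with lengths (bp) and centromere intervals.

    Parameters
    ----------
    chromosomes
        List of ``(name, length_bp)`` in the order profiles are laid out.
    centromeres
        Map ``name -> (start_bp, end_bp)`` delimiting the p arm (left of
        start) from the q arm (right of end).
    """

    chromosomes: tuple[tuple[str, int], ...]
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        lengths = dict(self.chromosomes)
        for name, (cs, ce) in self.centromeres.items():
            if name not in lengths:
                raise ValueError(f"centromere for unknown chromosome {name!r}")
            if not (0 < cs < ce < lengths[name]):
                raise ValueError(
                    f"centromere ({cs}, {ce}) out of bounds for {name} "
                    f"(length {lengths[name]})"
                )

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    def arms(self) -> list[str]:
        """Arm labels like ``chr8q`` in genome order (only centromere-bearing
        chromosomes have distinguishable arms)."""
        out = []
        for name, _ in self.chromosomes:
            if name in self.centromeres:
                out += [f"{name}p", f"{name}q"]
            else:
                out.append(name)
        return out


class BinGrid:
    """Fixed-width tiling of a genome; the coordinate system for profiles.

    Attributes
    ----------
    bins : pandas.DataFrame
        Columns ``chrom, start, end, arm, centromeric`` — one row per bin in
        genome order.  ``arm`` is e.g. ``"chr8q"`` (empty string for
        centromeric bins or chromosomes without a declared centromere, which
        keep the bare chromosome name as their arm label).
    bin_size : int
        Nominal bin width in bp; the last bin of each chromosome may be
        shorter.
    """

    def __init__(self, genome: GenomeModel, bins: pd.DataFrame, bin_size: int):
        self.genome = genome
        self.bins = bins.reset_index(drop=True)
        self.bin_size = int(bin_size)

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def chrom(self) -> np.ndarray:
        return self.bins["chrom"].to_numpy()

    @property
    def start(self) -> np.ndarray:
        return self.bins["start"].to_numpy()

    @property
    def end(self) -> np.ndarray:
        return self.bins["end"].to_numpy()

    @property
    def arm(self) -> np.ndarray:
        return self.bins["arm"].to_numpy()

    @property
    def centromeric(self) -> np.ndarray:
        return self.bins["centromeric"].to_numpy()

    def index_of(self, chrom: str, start: int, end: int) -> int:
        """Exact-match lookup of a bin; raises KeyError if off-grid."""
        key = (chrom, int(start), int(end))
        try:
            return self._lookup[key]
        except AttributeError:
            self._lookup = {
                (c, s, e): i
                for i, (c, s, e) in enumerate(
                    zip(self.bins["chrom"], self.bins["start"], self.bins["end"])
                )
            }
            return self.index_of(chrom, start, end)
        except KeyError:
            raise KeyError(f"coordinate ({chrom}, {start}, {end}) not on grid")

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice per chromosome, in genome order."""
        out: dict[str, slice] = {}
        chroms = self.chrom
        for name in self.genome.names:
            idx = np.flatnonzero(chroms == name)
            if idx.size:
                out[name] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out


def build_bin_grid(genome: GenomeModel, bin_size: int = 200_000) -> BinGrid:
    """Tile each chromosome left to right with ``bin_size`` windows.

    The final window of a chromosome is truncated to the chromosome end.
    Bins overlapping the centromere interval are flagged ``centromeric`` and
    excluded from arm assignment; all other bins lie wholly on one arm.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not genome.chromosomes:
        raise ValueError("genome has no chromosomes")
    rows = []
    for name, length in genome.chromosomes:
        cen = genome.centromeres.get(name)
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        for s, e in zip(starts, ends):
            if cen is None:
                rows.append((name, int(s), int(e), name, False))
                continue
            cs, ce = cen
            if e <= cs:
                rows.append((name, int(s), int(e), f"{name}p", False))
            elif s >= ce:
                rows.append((name, int(s), int(e), f"{name}q", False))
            else:
                rows.append((name, int(s), int(e), "", True))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "arm", "centromeric"])
    return BinGrid(genome, bins, bin_size)


def load_genome_tsv(path: str | Path) -> GenomeModel:
    """Read a genome model table: ``chrom  length  cen_start  cen_end``.

    ``cen_start``/``cen_end`` may be empty for chromosomes without a declared
    centromere (the whole chromosome then behaves as a single arm).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    chroms = tuple((r.chrom, int(r.length)) for r in df.itertuples())
    cens = {}
    for r in df.itertuples():
        if "cen_start" in df.columns and pd.notna(r.cen_start):
            cens[r.chrom] = (int(r.cen_start), int(r.cen_end))
    return GenomeModel(chroms, cens)


def default_genome() -> GenomeModel:
    """The shipped hg19-like model: 22 autosomes with centromere intervals.

    Sex chromosomes are excluded by default — the control panel is mixed-sex,
    so X/Y coverage is not comparable across samples.
    """
    with resources.as_file(
        resources.files("cinpipe").joinpath("data/hg19_autosomes.tsv")
    ) as p:
        return load_genome_tsv(p)
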