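"""Sliding-window detection of runs of homozygosity (ROH).

The scan follows the classical sliding-window paradigm: a window of fixed SNP
count slides one marker at a time along each chromosome; a window is called
homozygous when it contains at most ``max_opp_window`` heterozygous and at most
``max_miss_window`` missing calls.  Each marker's *support* is the fraction of
windows overlapping it that were called homozygous (the denominator shrinks
near chromosome ends, so edge markers remain reachable); markers with support
at or above ``threshold`` are in-run.  Maximal stretches of in-run markers are
split where the physical gap between adjacent markers exceeds ``max_gap_bp``
and kept when they contain at least ``min_snp`` markers and span at least
``min_length_bp``.

Defaults reproduce a conservative SNP-array configuration for ~1 Mb+
autozygous segments: window of 50 SNPs, 100-SNP and 1 Mb minima, 100 kb gap
limit, one opposing and one missing call tolerated per window, 5% support.

Run length is ``end_bp - start_bp`` with boundaries at the outermost in-run
markers; hets or missing calls inside a called run are permitted (they are
controlled at window level only).  Runs never cross chromosome boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SNPMap


@dataclass(frozen=True)
class ROHParams:
    """Sliding-window ROH parameters."""

    window_size: int = 50
    min_snp: int = 100
    threshold: float = 0.05
    max_gap_bp: int = 100_000
    min_length_bp: int = 1_000_000
    max_opp_window: int = 1
    max_miss_window: int = 1
    strict_threshold: bool = False  # if True, require support > threshold

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")
        for name in ("min_snp", "max_gap_bp", "min_length_bp", "max_opp_window", "max_miss_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ROHSegment:
    """One run of homozygosity for one individual."""

    individual_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def window_flags(row: np.ndarray, params: ROHParams) -> np.ndarray:
    """Homozygous-window indicator for every window position on one chromosome.

    Window ``i`` covers markers ``[i, i + window_size)``.  A chromosome shorter
    than one window yields an empty array.
    """
    row = np.asarray(row)
    n = row.size
    w = params.window_size
    if n < w:
        return np.zeros(0, dtype=bool)
    het = np.concatenate(([0], np.cumsum(row == 1)))
    mis = np.concatenate(([0], np.cumsum(row == MISSING)))
    het_in = het[w:] - het[:-w]
    mis_in = mis[w:] - mis[:-w]
    return (het_in <= params.max_opp_window) & (mis_in <= params.max_miss_window)


def snp_support(flags: np.ndarray, n_markers: int, params: ROHParams) -> np.ndarray:
    """Per-marker in-run indicator from window flags.

    Support = flagged windows covering the marker / windows covering it; the
    marker is in-run when support meets ``threshold`` (inclusive by default).
    """
    w = params.window_size
    n_win = flags.size
    if n_win == 0:
        return np.zeros(n_markers, dtype=bool)
    # windows covering marker m: i in [max(0, m-w+1), min(m, n_win-1)]
    m = np.arange(n_markers)
    lo = np.maximum(0, m - w + 1)
    hi = np.minimum(m, n_win - 1)
    covering = (hi - lo + 1).astype(float)
    cum = np.concatenate(([0], np.cumsum(flags)))
    flagged = cum[hi + 1] - cum[lo]
    support = flagged / covering
    if params.strict_threshold:
        return support > params.threshold
    return support >= params.threshold


def call_runs(
    in_run: np.ndarray,
    snpmap_slice: pd.DataFrame,
    params: ROHParams,
    individual_id: str,
) -> list[ROHSegment]:
    """Turn per-marker indicators on one chromosome into filtered segments.

    ``snpmap_slice`` is the map table restricted to that chromosome, aligned
    with ``in_run``.
    """
    pos = snpmap_slice["pos"].to_numpy()
    chrom = str(snpmap_slice["chrom"].iloc[0]) if len(snpmap_slice) else ""
    in_run = np.asarray(in_run, dtype=bool)
    if in_run.size != pos.size:
        raise ValueError("in_run indicators not aligned with map slice")

    segments: list[ROHSegment] = []
    idx = np.flatnonzero(in_run)
    if idx.size == 0:
        return segments
    # break where markers stop being consecutive or the bp gap is too large
    breaks = np.flatnonzero(
        (np.diff(idx) != 1) | (np.diff(pos[idx]) > params.max_gap_bp)
    )
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        first, last = idx[s], idx[e]
        n_snps = last - first + 1
        length = int(pos[last] - pos[first])
        if n_snps >= params.min_snp and length >= params.min_length_bp:
            segments.append(
                ROHSegment(individual_id, chrom, int(pos[first]), int(pos[last]), int(n_snps))
            )
    return segments


def detect_roh(
    gm: GenotypeMatrix, snpmap: SNPMap, params: ROHParams | None = None
) -> list[ROHSegment]:
    """Detect ROH for every individual on every chromosome.

    Deterministic given its inputs; expects QC-filtered genotypes.
    """
    params = params or ROHParams()
    segments: list[ROHSegment] = []
    for chrom in snpmap.chromosomes():
        sl = snpmap.chrom_slice(chrom)
        map_slice = snpmap.table.iloc[sl]
        n_markers = sl.stop - sl.start
        for iid, row in zip(gm.individual_ids, gm.codes):
            sub = row[sl]
            flags = window_flags(sub, params)
            in_run = snp_support(flags, n_markers, params)
            segments.extend(call_runs(in_run, map_slice, params, iid))
    return segments


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """Tabulate segments (individual_id, chrom, start_bp, end_bp, n_snps, length_bp)."""
    return pd.DataFrame(
        [
            {
                "individual_id": s.individual_id,
                "chrom": s.chromosome,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "n_snps": s.n_snps,
                "length_bp": s.length_bp,
            }
            for s in segments
        ],
        columns=["individual_id", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"],
    )


def write_segments(segments: list[ROHSegment], path) -> None:
    segments_to_frame(segments).to_csv(path, sep="\t", index=False)


def read_segments(path) -> list[ROHSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "individual_id": str})
    return [
        ROHSegment(r.individual_id, r.chrom, int(r.start_bp), int(r.end_bp), int(r.n_snps))
        for r in df.itertuples()
    ]
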