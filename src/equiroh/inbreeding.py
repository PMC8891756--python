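"""Molecular inbreeding coefficients (F_ROH) at genome and chromosome level.

F_ROH is the fraction of the genome covered by an individual's runs of
homozygosity.  The default denominator is the SNP-covered span per chromosome
(last minus first marker position), the usual convention for array data; a
user-supplied per-chromosome length table (e.g. assembly lengths) can be used
instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import SNPMap
from .roh_scan import ROHSegment


def genome_denominator(
    snpmap: SNPMap, chrom_lengths: Mapping[str, int] | None = None
) -> tuple[dict[str, int], int]:
    """Per-chromosome and total denominator in bp.

    Default: last minus first marker position per chromosome.  Chromosomes
    with fewer than two markers are excluded with a warning.  Passing
    ``chrom_lengths`` overrides the denominator per chromosome.
    """
    per_chrom: dict[str, int] = {}
    for chrom in snpmap.chromosomes():
        sl = snpmap.chrom_slice(chrom)
        pos = snpmap.pos[sl]
        if pos.size < 2:
            warnings.warn(f"chromosome {chrom} has < 2 markers; excluded from denominator")
            continue
        if chrom_lengths is not None:
            per_chrom[chrom] = int(chrom_lengths[chrom])
        else:
            per_chrom[chrom] = int(pos[-1] - pos[0])
    return per_chrom, sum(per_chrom.values())


@dataclass(frozen=True)
class FrohTable:
    """Per-individual genome-wide and per-chromosome F_ROH."""

    table: pd.DataFrame  # index: individual_id; columns: froh_genome, chromosome labels

    @property
    def froh_genome(self) -> pd.Series:
        return self.table["froh_genome"]

    def froh_by_chromosome(self, chrom: str) -> pd.Series:
        return self.table[str(chrom)]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="individual_id")

    @classmethod
    def from_tsv(cls, path) -> "FrohTable":
        return cls(pd.read_csv(path, sep="\t", index_col="individual_id"))


def compute_froh(
    segments: Sequence[ROHSegment],
    snpmap: SNPMap,
    individuals: Sequence[str],
    chrom_lengths: Mapping[str, int] | None = None,
) -> FrohTable:
    """F_ROH per individual: segment bp on each chromosome over its denominator.

    Segments are assumed non-overlapping within individual x chromosome (the
    sliding-window caller guarantees this).  Individuals without segments get
    zero everywhere.  A segment outside the map span raises ``ValueError``.
    """
    per_chrom, total = genome_denominator(snpmap, chrom_lengths)
    chroms = list(per_chrom)
    span: dict[str, tuple[int, int]] = {}
    for chrom in snpmap.chromosomes():
        sl = snpmap.chrom_slice(chrom)
        pos = snpmap.pos[sl]
        span[chrom] = (int(pos[0]), int(pos[-1]))

    covered = pd.DataFrame(0.0, index=list(individuals), columns=chroms)
    for seg in segments:
        c = seg.chromosome
        if c not in span:
            raise ValueError(f"segment chromosome {c!r} not in map")
        lo, hi = span[c]
        if seg.start_bp < lo or seg.end_bp > hi:
            raise ValueError(
                f"segment {seg.start_bp}-{seg.end_bp} outside map span {lo}-{hi} on {c}"
            )
        if seg.individual_id in covered.index and c in covered.columns:
            covered.loc[seg.individual_id, c] += seg.length_bp

    denom = np.array([per_chrom[c] for c in chroms], dtype=float)
    froh = covered.to_numpy() / denom
    table = pd.DataFrame(froh, index=covered.index, columns=chroms)
    table.insert(0, "froh_genome", covered.to_numpy().sum(axis=1) / total)
    return FrohTable(table)
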