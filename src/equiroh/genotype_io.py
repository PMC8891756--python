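"""Genotype and marker I/O, marker-level QC, and shared coordinate conventions.

Genotypes are held as an individuals x markers matrix of small integer codes:
``0`` homozygous for the reference (major) allele, ``1`` heterozygous, ``2``
homozygous for the alternate (minor) allele, and :data:`MISSING` (``-1``) for
no-calls.  All physical coordinates are 1-based inclusive, matching the PLINK
MAP and VCF dialects; BED export converts to 0-based half-open at the boundary.

Downstream homozygosity logic only distinguishes het / non-het / missing, so
the major-allele reference convention cannot influence any result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: Genotype code for a missing call.
MISSING: int = -1

_VALID_ALLELES = frozenset("ACGT0")


class ParseError(ValueError):
    """Raised when an input genotype file is malformed."""


def _chrom_sort_key(label: str):
    """Sort chromosomes numerically where possible, lexically otherwise."""
    s = str(label)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


@dataclass(frozen=True)
class SNPMap:
    """Ordered marker catalogue: chromosome, identifier, 1-based bp position.

    The table is strictly sorted by (chromosome, position); positions are
    strictly increasing within a chromosome and marker ids are unique.
    """

    table: pd.DataFrame = field(repr=False)  # columns: chrom, marker_id, pos

    def __post_init__(self) -> None:
        t = self.table
        required = ["chrom", "marker_id", "pos"]
        if list(t.columns[:3]) != required:
            raise ValueError(f"SNPMap table must have columns {required}")
        if t["marker_id"].duplicated().any():
            dups = t.loc[t["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker id: {dups!r}")
        if (t["pos"] < 1).any():
            raise ValueError("marker positions must be >= 1 (1-based)")
        for _, pos in t.groupby("chrom", sort=False)["pos"]:
            if not pos.is_monotonic_increasing or pos.duplicated().any():
                raise ValueError("positions must be strictly increasing within a chromosome")

    @classmethod
    def from_arrays(
        cls,
        chrom: Sequence,
        marker_id: Sequence[str],
        pos: Sequence[int],
        sort: bool = True,
    ) -> "SNPMap":
        t = pd.DataFrame(
            {
                "chrom": pd.Series(chrom, dtype=str),
                "marker_id": pd.Series(marker_id, dtype=str),
                "pos": pd.Series(pos, dtype=np.int64),
            }
        )
        if sort:
            t = t.sort_values(
                ["chrom", "pos"],
                key=lambda c: c.map(_chrom_sort_key) if c.name == "chrom" else c,
                kind="mergesort",
            ).reset_index(drop=True)
        return cls(t)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    @property
    def marker_id(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    def chromosomes(self) -> list[str]:
        """Chromosome labels in map order."""
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_slice(self, chromosome: str) -> slice:
        """Contiguous index slice of the markers on one chromosome."""
        idx = np.flatnonzero(self.chrom == str(chromosome))
        if idx.size == 0:
            raise KeyError(f"chromosome {chromosome!r} not in map")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset(self, keep: np.ndarray) -> "SNPMap":
        return SNPMap(self.table.loc[np.asarray(keep)].reset_index(drop=True))

    def whitelist(self, chromosomes: Iterable[str]) -> "SNPMap":
        """Restrict to a chromosome whitelist (e.g. autosomes only)."""
        wanted = {str(c) for c in chromosomes}
        return self.subset(np.isin(self.chrom, list(wanted)))


@dataclass
class GenotypeMatrix:
    """Individuals x markers genotype codes aligned to a :class:`SNPMap`."""

    individual_ids: list[str]
    codes: np.ndarray  # int8, shape (n_individuals, n_markers)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.individual_ids):
            raise ValueError("codes must be 2-D with one row per individual")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual ids must be unique")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid genotype code {self.codes[bad][0]}")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def row(self, individual_id: str) -> np.ndarray:
        return self.codes[self.individual_ids.index(individual_id)]


@dataclass(frozen=True)
class QCReport:
    """Per-marker call rates and keep decisions from :func:`qc_filter`."""

    table: pd.DataFrame  # columns: marker_id, chrom, pos, call_rate, kept
    min_call_rate: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK classic PED/MAP
# ---------------------------------------------------------------------------

def read_plink(map_source, ped_source) -> tuple[SNPMap, GenotypeMatrix]:
    """Read classic PLINK MAP (4 columns) + PED (6 leading columns, allele pairs).

    Allele pairs are recoded against the major allele per marker; markers are
    re-sorted to (chromosome, position) order; individual order is preserved.
    """
    map_rows = []
    with open(map_source) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ParseError(f"{map_source}:{ln}: expected 4 MAP columns, got {len(parts)}")
            map_rows.append((parts[0], parts[1], int(parts[3])))
    n_markers = len(map_rows)

    ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_source) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise ParseError(
                    f"{ped_source}:{ln}: expected {6 + 2 * n_markers} fields "
                    f"for {n_markers} markers, got {len(parts)}"
                )
            ids.append(parts[1])
            alleles = parts[6:]
            for a in alleles:
                if a not in _VALID_ALLELES:
                    raise ParseError(f"{ped_source}:{ln}: invalid allele symbol {a!r}")
            allele_rows.append(np.array(alleles, dtype="U1").reshape(n_markers, 2))

    n_ind = len(ids)
    codes = np.full((n_ind, n_markers), MISSING, dtype=np.int8)
    if n_ind:
        stack = np.stack(allele_rows)  # (n_ind, n_markers, 2)
        for j in range(n_markers):
            pair = stack[:, j, :]
            called = pair[:, 0] != "0"
            # missing requires both alleles '0'; a half-call is malformed
            half = (pair[:, 0] == "0") != (pair[:, 1] == "0")
            if half.any():
                raise ParseError(f"{ped_source}: half-missing genotype at marker column {j + 1}")
            if called.any():
                alleles, counts = np.unique(pair[called].ravel(), return_counts=True)
                major = alleles[np.argmax(counts)]
                codes[called, j] = (pair[called] != major).sum(axis=1)

    snpmap = SNPMap.from_arrays(
        [r[0] for r in map_rows], [r[1] for r in map_rows], [r[2] for r in map_rows]
    )
    # re-order genotype columns to the sorted map order
    original_ids = [r[1] for r in map_rows]
    order = [original_ids.index(m) for m in snpmap.marker_id]
    return snpmap, GenotypeMatrix(ids, codes[:, order])


def write_plink(snpmap: SNPMap, gm: GenotypeMatrix, map_path, ped_path) -> None:
    """Write classic PED/MAP.  Codes 0/1/2 become A A / A B / B B with A, B = A, G."""
    with open(map_path, "w") as fh:
        for c, m, p in zip(snpmap.chrom, snpmap.marker_id, snpmap.pos):
            fh.write(f"{c}\t{m}\t0\t{p}\n")
    pair_for = {0: "A A", 1: "A G", 2: "G G", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for iid, row in zip(gm.individual_ids, gm.codes):
            genos = " ".join(pair_for[int(c)] for c in row)
            fh.write(f"FAM {iid} 0 0 0 -9 {genos}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(vcf_source) -> tuple[SNPMap, GenotypeMatrix]:
    """Read a (plain or bgzipped) VCF with GT calls at biallelic SNP sites.

    Multiallelic sites are skipped with a logged count.  Diploid GT values map
    0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> MISSING.
    """
    vf = pysam.VariantFile(str(vcf_source))
    if "GT" not in vf.header.formats:
        raise ParseError(f"{vcf_source}: VCF has no GT format field")
    samples = list(vf.header.samples)
    chroms: list[str] = []
    mids: list[str] = []
    poss: list[int] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for i, rec in enumerate(vf):
        if rec.alts is None or len(rec.alts) != 1:
            n_skipped += 1
            continue
        col = np.full(len(samples), MISSING, dtype=np.int8)
        for s_i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or None in gt:
                continue
            col[s_i] = int(sum(gt))
        chroms.append(rec.chrom)
        mids.append(rec.id if rec.id else f"{rec.chrom}_{rec.pos}")
        poss.append(rec.pos)  # pysam reports 1-based
        columns.append(col)
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic site(s)", n_skipped)
    snpmap = SNPMap.from_arrays(chroms, mids, poss)
    codes = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    order = [mids.index(m) for m in snpmap.marker_id]
    return snpmap, GenotypeMatrix(samples, codes[:, order])


def write_vcf(snpmap: SNPMap, gm: GenotypeMatrix, path) -> None:
    """Write a minimal plain-text VCF with GT-only genotype columns."""
    gt_for = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in snpmap.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individual_ids)
            + "\n"
        )
        for j, (c, m, p) in enumerate(zip(snpmap.chrom, snpmap.marker_id, snpmap.pos)):
            gts = "\t".join(gt_for[int(x)] for x in gm.codes[:, j])
            fh.write(f"{c}\t{p}\t{m}\tA\tG\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(
    gm: GenotypeMatrix, snpmap: SNPMap, min_call_rate: float = 0.95
) -> tuple[GenotypeMatrix, SNPMap, QCReport]:
    """Drop markers whose call rate is not strictly above ``min_call_rate``.

    The strictly-greater-than rule mirrors the common array QC convention
    (SNP CR > 95%).  Returns the filtered matrix/map and a full report.
    """
    if not 0.0 <= min_call_rate <= 1.0:
        raise ValueError("min_call_rate must lie in [0, 1]")
    call_rate = (gm.codes != MISSING).mean(axis=0) if gm.n_individuals else np.ones(gm.n_markers)
    kept = call_rate > min_call_rate
    if not kept.any():
        raise ValueError(
            f"qc_filter removed all {gm.n_markers} markers at call-rate threshold "
            f"{min_call_rate}; review the threshold"
        )
    report = QCReport(
        pd.DataFrame(
            {
                "marker_id": snpmap.marker_id,
                "chrom": snpmap.chrom,
                "pos": snpmap.pos,
                "call_rate": call_rate,
                "kept": kept,
            }
        ),
        min_call_rate,
    )
    gm_out = GenotypeMatrix(list(gm.individual_ids), gm.codes[:, kept])
    return gm_out, snpmap.subset(kept), report


# ---------------------------------------------------------------------------
# BED export (boundary conversion lives here, nowhere else)
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[tuple[str, int, int, str]], path) -> None:
    """Write (chrom, start_bp, end_bp, name) 1-based inclusive intervals as BED."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")
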