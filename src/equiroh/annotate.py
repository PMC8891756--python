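"""Gene annotation of validated ROH islands.

Reads gene intervals from GFF3 or BED, normalizes to the package's 1-based
inclusive convention, and intersects them with islands either by any overlap
(default) or full containment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .rohi import ROHIsland


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    symbol: str
    chromosome: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_id}: start > end")


def _gff3_attr(attrs: str, key: str) -> str | None:
    for part in attrs.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def read_annotation(source, feature_type: str = "gene") -> list[GeneInterval]:
    """Read gene intervals from a GFF3 (rows of ``feature_type``) or BED4+ file.

    BED's 0-based half-open coordinates are converted to 1-based inclusive.
    The dialect is chosen by file suffix (.gff/.gff3 vs .bed).
    """
    path = Path(source)
    suffix = path.suffix.lower()
    genes: list[GeneInterval] = []
    if suffix in (".gff", ".gff3"):
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9:
                    raise ValueError(f"{path}:{ln}: GFF3 row has {len(parts)} columns, need 9")
                if parts[2] != feature_type:
                    continue
                try:
                    start, end = int(parts[3]), int(parts[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
                gid = _gff3_attr(parts[8], "ID") or f"{parts[0]}:{start}-{end}"
                symbol = _gff3_attr(parts[8], "Name") or gid
                genes.append(GeneInterval(gid, symbol, parts[0], start, end, parts[6]))
    elif suffix == ".bed":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    raise ValueError(f"{path}:{ln}: BED row needs >= 4 columns")
                try:
                    start0, end0 = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
                strand = parts[5] if len(parts) > 5 else "."
                genes.append(GeneInterval(parts[3], parts[3], parts[0], start0 + 1, end0, strand))
    else:
        raise ValueError(f"unsupported annotation format: {path.name}")
    return genes


def write_annotation_bed(genes: Sequence[GeneInterval], path) -> None:
    """Write gene intervals as BED6 (converting back to 0-based half-open)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start_bp - 1}\t{g.end_bp}\t{g.symbol}\t0\t{g.strand}\n")


def intersect(
    islands: Sequence[ROHIsland],
    genes: Sequence[GeneInterval],
    mode: str = "any-overlap",
    chrom_rename: Mapping[str, str] | None = None,
) -> list[list[str]]:
    """Per-island gene symbol lists, ordered by gene start position.

    ``any-overlap`` reports every gene whose span intersects the island's
    1-based inclusive span; ``contained`` requires the gene to lie fully
    inside.  ``chrom_rename`` maps annotation chromosome labels onto island
    labels when the two sources disagree.
    """
    if mode not in ("any-overlap", "contained"):
        raise ValueError("mode must be 'any-overlap' or 'contained'")
    rename = dict(chrom_rename or {})
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        chrom = rename.get(g.chromosome, g.chromosome)
        # store half-open [start, end+1) so inclusive endpoints overlap
        trees.setdefault(chrom, IntervalTree()).addi(g.start_bp, g.end_bp + 1, g)
    out: list[list[str]] = []
    for isl in islands:
        tree = trees.get(isl.chromosome)
        hits: list[GeneInterval] = []
        if tree is not None:
            for iv in tree.overlap(isl.start_bp, isl.end_bp + 1):
                g = iv.data
                if mode == "contained" and not (
                    g.start_bp >= isl.start_bp and g.end_bp <= isl.end_bp
                ):
                    continue
                hits.append(g)
        hits.sort(key=lambda g: (g.start_bp, g.end_bp, g.symbol))
        out.append([g.symbol for g in hits])
    return out


def annotate_islands_frame(
    island_frame: pd.DataFrame, gene_lists: Iterable[Sequence[str]]
) -> pd.DataFrame:
    """Attach comma-joined gene symbols to an island report table."""
    out = island_frame.copy()
    out["genes"] = [", ".join(genes) for genes in gene_lists]
    return out
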