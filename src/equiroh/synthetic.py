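"""Synthetic SNP-array cohorts with known autozygosity and fertility structure.

The generator composes genotypes directly from an autozygosity process rather
than gene-dropping through a pedigree: each individual receives background
autozygous segments (Poisson count calibrated to an expected genome coverage,
exponential lengths floored at 1 Mb, uniform placement, overlaps merged) plus
optional planted "island" segments whose carrier probability (penetrance)
differs between a latent low-fertility stratum and the rest of the cohort.
Inside autozygous segments genotypes are homozygous with the allele drawn by
site frequency; outside they are Hardy-Weinberg draws at a site-specific minor
allele frequency.  Genotyping error (hom -> het flips, the error mode that
breaks homozygosity runs) and missingness are applied last; the truth table
records everything pre-error.

Fertility pseudophenotypes follow

    re_debv = intercept + beta_froh * true_autozygosity
              + sum_islands island_effect * carrier_flag + Normal(0, noise_sd)

Default dimensions are a desk-scale rendering of a large mare cohort (~862
individuals x ~540 k SNPs on 31 autosomes): 300 individuals, 3 chromosomes of
2,000 markers at ~5 kb spacing, expected background autozygosity 0.13, and a
negative phenotype slope on autozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .association import PhenotypeTable
from .genotype_io import MISSING, GenotypeMatrix, SNPMap


@dataclass(frozen=True)
class PlantedIsland:
    """A region made autozygous with group-dependent probability."""

    chromosome: str
    start_bp: int
    end_bp: int
    penetrance_low_fert: float
    penetrance_other: float
    effect: float = -5.0  # phenotype shift for carriers, Re_dEBV units

    def __post_init__(self) -> None:
        for p in (self.penetrance_low_fert, self.penetrance_other):
            if not 0.0 <= p <= 1.0:
                raise ValueError("penetrance must lie in [0, 1]")
        if self.penetrance_low_fert < self.penetrance_other and self.effect < 0:
            raise ValueError(
                "a depressive island must be at least as penetrant in the low-fertility stratum"
            )


@dataclass(frozen=True)
class SimConfig:
    n_individuals: int = 300
    n_chromosomes: int = 3
    markers_per_chromosome: int = 2_000
    mean_spacing_bp: int = 5_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    base_autozygosity: float = 0.13
    segment_length_mean_bp: float = 2_000_000.0
    segment_length_floor_bp: int = 1_000_000
    islands: tuple[PlantedIsland, ...] = ()
    beta_froh: float = -30.0
    intercept: float = 5.0
    noise_sd: float = 3.0
    genotyping_error_rate: float = 0.002
    missing_rate: float = 0.02
    low_fert_fraction: float = 0.25
    low_fert_autozygosity_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_autozygosity", "genotyping_error_rate", "missing_rate",
                     "low_fert_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")

    def echo(self) -> dict:
        """Full parameter echo for run logs."""
        d = asdict(self)
        d["islands"] = [asdict(i) for i in self.islands]
        return d


@dataclass
class TruthTable:
    """Ground truth recorded by the generator, pre-error."""

    individual_ids: list[str]
    # per individual: {chrom: list of (start_bp, end_bp)} merged true segments
    true_segments: list[dict[str, list[tuple[int, int]]]]
    true_autozygosity: np.ndarray
    island_carrier_flags: np.ndarray  # (n_individuals, n_islands) bool
    low_fert_stratum: np.ndarray  # bool per individual
    true_phenotype_mean: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_ids,
                "true_autozygosity": self.true_autozygosity,
                "low_fert_stratum": self.low_fert_stratum,
                "true_phenotype_mean": self.true_phenotype_mean,
                **{
                    f"carrier_island_{k}": self.island_carrier_flags[:, k]
                    for k in range(self.island_carrier_flags.shape[1])
                },
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def simulate_map(cfg: SimConfig) -> SNPMap:
    """Marker map with spacings uniform in [0.5, 1.5] x mean_spacing_bp."""
    if cfg.markers_per_chromosome < 2:
        raise ValueError("markers_per_chromosome must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    chroms, mids, poss = [], [], []
    for c in range(1, cfg.n_chromosomes + 1):
        spacing = rng.uniform(
            0.5 * cfg.mean_spacing_bp, 1.5 * cfg.mean_spacing_bp, cfg.markers_per_chromosome
        )
        pos = np.cumsum(np.maximum(1, spacing.round().astype(np.int64)))
        chroms.extend([str(c)] * cfg.markers_per_chromosome)
        mids.extend(f"snp_{c}_{j}" for j in range(cfg.markers_per_chromosome))
        poss.extend(pos.tolist())
    return SNPMap.from_arrays(chroms, mids, poss)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for a, b in intervals[1:]:
        la, lb = merged[-1]
        if a <= lb:
            merged[-1] = (la, max(lb, b))
        else:
            merged.append((a, b))
    return merged


def simulate_cohort(snpmap: SNPMap, cfg: SimConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """Draw genotypes and the matching truth table."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    chroms = snpmap.chromosomes()
    spans = {}
    for c in chroms:
        sl = snpmap.chrom_slice(c)
        pos = snpmap.pos[sl]
        spans[c] = (int(pos[0]), int(pos[-1]))
    for isl in cfg.islands:
        if isl.chromosome not in spans:
            raise ValueError(f"island chromosome {isl.chromosome!r} not in map")
        lo, hi = spans[isl.chromosome]
        if isl.end_bp - isl.start_bp > hi - lo:
            raise ValueError("island longer than its chromosome")

    n = cfg.n_individuals
    m = len(snpmap)
    ids = [f"mare_{i:04d}" for i in range(n)]
    low_stratum = rng.random(n) < cfg.low_fert_fraction

    genome_bp = sum(hi - lo for lo, hi in spans.values())
    mean_len = max(cfg.segment_length_mean_bp, cfg.segment_length_floor_bp)
    # expected covered fraction ~ n_seg * mean_len / genome (overlaps make this
    # an upper bound; coverage targets the configured expectation closely at
    # modest autozygosity)
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], m)

    codes = np.empty((n, m), dtype=np.int8)
    true_segments: list[dict[str, list[tuple[int, int]]]] = []
    true_auto = np.zeros(n)
    carrier_flags = np.zeros((n, len(cfg.islands)), dtype=bool)

    chrom_weights = np.array([spans[c][1] - spans[c][0] for c in chroms], dtype=float)
    chrom_weights /= chrom_weights.sum()

    for i in range(n):
        target = cfg.base_autozygosity * (
            cfg.low_fert_autozygosity_factor if low_stratum[i] else 1.0
        )
        target = min(target, 1.0)
        lam = target * genome_bp / mean_len
        n_seg = rng.poisson(lam)
        per_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
        if n_seg:
            seg_chroms = rng.choice(len(chroms), size=n_seg, p=chrom_weights)
            lengths = np.maximum(
                rng.exponential(mean_len, n_seg), cfg.segment_length_floor_bp
            ).astype(np.int64)
            for ci, ln in zip(seg_chroms, lengths):
                c = chroms[ci]
                lo, hi = spans[c]
                ln = min(int(ln), hi - lo)
                start = int(rng.integers(lo, hi - ln + 1))
                per_chrom[c].append((start, start + ln))
        for k, isl in enumerate(cfg.islands):
            pen = isl.penetrance_low_fert if low_stratum[i] else isl.penetrance_other
            if rng.random() < pen:
                carrier_flags[i, k] = True
                per_chrom[isl.chromosome].append((isl.start_bp, isl.end_bp))
        per_chrom = {c: _merge(v) for c, v in per_chrom.items()}
        true_segments.append(per_chrom)
        covered = sum(b - a for v in per_chrom.values() for a, b in v)
        true_auto[i] = covered / genome_bp

        # genotype row: HWE draws outside, frequency-weighted homozygotes inside
        u = rng.random(m)
        p_alt = maf  # alt = minor allele
        row = np.where(
            u < (1 - p_alt) ** 2, 0, np.where(u < (1 - p_alt) ** 2 + 2 * p_alt * (1 - p_alt), 1, 2)
        ).astype(np.int8)
        auto_mask = np.zeros(m, dtype=bool)
        for c in chroms:
            sl = snpmap.chrom_slice(c)
            pos = snpmap.pos[sl]
            for a, b in per_chrom[c]:
                lo_i = np.searchsorted(pos, a, side="left")
                hi_i = np.searchsorted(pos, b, side="right")
                auto_mask[sl.start + lo_i : sl.start + hi_i] = True
        hom_alt = rng.random(m) < p_alt  # one ancestral allele copied to both
        row[auto_mask] = np.where(hom_alt[auto_mask], 2, 0)
        codes[i] = row

    # genotyping error: hom -> het flips; then missingness
    err = rng.random((n, m)) < cfg.genotyping_error_rate
    hom = (codes == 0) | (codes == 2)
    codes[err & hom] = 1
    miss = rng.random((n, m)) < cfg.missing_rate
    codes[miss] = MISSING

    effects = np.array([isl.effect for isl in cfg.islands], dtype=float)
    phen_mean = cfg.intercept + cfg.beta_froh * true_auto + carrier_flags @ effects
    truth = TruthTable(ids, true_segments, true_auto, carrier_flags, low_stratum, phen_mean)
    return GenotypeMatrix(ids, codes), truth


def simulate_phenotypes(truth: TruthTable, cfg: SimConfig) -> PhenotypeTable:
    """Pseudophenotypes: linear in true autozygosity plus island effects and noise."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    y = truth.true_phenotype_mean + rng.normal(0.0, cfg.noise_sd, len(truth.individual_ids))
    return PhenotypeTable(
        pd.DataFrame({"re_debv": y}, index=pd.Index(truth.individual_ids, name="individual_id"))
    )


def default_recovery_config(seed: int = 0, n_islands: int = 5) -> SimConfig:
    """The standard planted-island recovery scenario.

    Five 1.5 Mb islands spread over three 2,000-marker chromosomes, penetrant
    at 0.4 in the low-fertility stratum versus 0.05 elsewhere, each depressing
    carrier fertility by 5 Re_dEBV units.
    """
    cfg0 = SimConfig(seed=seed)
    snpmap = simulate_map(cfg0)
    islands = []
    placements = [("1", 0.25), ("1", 0.65), ("2", 0.3), ("2", 0.7), ("3", 0.5)][:n_islands]
    for chrom, frac in placements:
        sl = snpmap.chrom_slice(chrom)
        pos = snpmap.pos[sl]
        start = int(pos[0] + frac * (pos[-1] - pos[0]))
        islands.append(
            PlantedIsland(chrom, start, start + 1_500_000, 0.4, 0.05, effect=-5.0)
        )
    return SimConfig(seed=seed, islands=tuple(islands))


def simulate_all(cfg: SimConfig) -> tuple[SNPMap, GenotypeMatrix, TruthTable, PhenotypeTable]:
    """Map, genotypes, truth and phenotypes in one call."""
    snpmap = simulate_map(cfg)
    gm, truth = simulate_cohort(snpmap, cfg)
    phen = simulate_phenotypes(truth, cfg)
    return snpmap, gm, truth, phen
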