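"""Association between genomic inbreeding and fertility pseudophenotypes.

Fertility enters as a deregressed breeding value per individual (Re_dEBV, a
percent-deviation scale).  The module provides rank (Spearman) and segmented
(piecewise-linear) correlations between F_ROH and the pseudophenotype, genome
wide and per chromosome; divergent-tail selection (High-Fert / Low-Fert
extremes); and Welch t-tests comparing group F_ROH.

The segmented estimator splits the F_ROH axis into k equal-frequency segments
(k = 1..max_segments), computes the Pearson correlation within each, and
scores k by the sample-size-weighted mean of the absolute within-segment
correlations; larger k is accepted only when it improves the score by a
configurable margin.  The reported estimate carries the sign of the weighted
*signed* correlation sum, so with one segment it equals Pearson's r exactly.
Significance is assessed by permuting the phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .inbreeding import FrohTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhenotypeTable:
    """Per-individual fertility pseudophenotype (and optional accuracy)."""

    table: pd.DataFrame  # index: individual_id; columns: re_debv [, accuracy]

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("individual ids must be unique")
        if not np.isfinite(self.table["re_debv"]).all():
            raise ValueError("re_debv must be finite")

    @property
    def re_debv(self) -> pd.Series:
        return self.table["re_debv"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="individual_id")

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
        return cls(df.set_index("individual_id"))


@dataclass(frozen=True)
class TailSelection:
    """High- and low-fertility extremes of the phenotype distribution."""

    high_fert: list[str]
    low_fert: list[str]

    @property
    def reduced_ids(self) -> list[str]:
        return list(self.high_fert) + list(self.low_fert)


@dataclass(frozen=True)
class CorrelationResult:
    scope: str  # "genome" or a chromosome label
    method: str  # "rank" or "segmented"
    estimate: float
    p_value: float
    n: int
    defined: bool = True
    segments: int = field(default=1)


def select_tails(phen: PhenotypeTable, q: float = 0.10) -> TailSelection:
    """Top and bottom fraction ``q`` of individuals by phenotype.

    Each tail holds ``round(q * N)`` individuals; ties are broken by lexical
    individual id so the selection is deterministic.
    """
    if not 0.0 < q < 0.5:
        raise ValueError("q must lie in (0, 0.5)")
    n = len(phen.table)
    k = round(q * n)
    if k < 2:
        raise ValueError(f"tail size round(q*N) = {k} < 2; increase q or N")
    # stable sort on value after sorting index lexically => ties broken by id
    ordered = phen.table.sort_index().sort_values("re_debv", kind="mergesort")
    low = list(ordered.index[:k])
    high = list(ordered.index[-k:][::-1])
    return TailSelection(high_fert=high, low_fert=low)


def rank_correlation(x: np.ndarray, y: np.ndarray, scope: str = "genome") -> CorrelationResult:
    """Spearman rank correlation with tie handling and t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need >= 5 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(scope, "rank", np.nan, np.nan, x.size, defined=False)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(scope, "rank", float(rho), float(p), x.size)


def _segment_score(x_sorted: np.ndarray, y_sorted: np.ndarray, k: int, min_points: int = 4):
    """Weighted |r| score and signed score over k equal-frequency segments.

    Returns (score, signed) or None when some segment is too small or degenerate.
    """
    n = x_sorted.size
    bounds = np.linspace(0, n, k + 1).round().astype(int)
    score = signed = 0.0
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < min_points:
            return None
        xs, ys = x_sorted[a:b], y_sorted[a:b]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            return None
        r = np.corrcoef(xs, ys)[0, 1]
        w = (b - a) / n
        score += w * abs(r)
        signed += w * r
    return score, signed


def segmented_correlation(
    x: np.ndarray,
    y: np.ndarray,
    max_segments: int = 5,
    n_perm: int = 500,
    seed: int = 0,
    margin: float = 0.05,
    scope: str = "genome",
) -> CorrelationResult:
    """Piecewise-linear (segmented) correlation with a permutation p-value.

    With ``max_segments=1`` the estimate equals Pearson's r to machine
    tolerance.  Larger k must beat the incumbent score by ``margin``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if max_segments < 1:
        raise ValueError("max_segments must be >= 1")
    if x.size != y.size or x.size < 5:
        raise ValueError("need >= 5 paired observations")
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]

    def best_estimate(y_vec: np.ndarray) -> tuple[float, int]:
        best_score, best_signed, best_k = -np.inf, 0.0, 1
        for k in range(1, max_segments + 1):
            res = _segment_score(xs, y_vec, k)
            if res is None:
                continue
            score, signed = res
            need = best_score + margin if k > best_k else best_score
            if score > (need if best_score > -np.inf else -np.inf):
                best_score, best_signed, best_k = score, signed, k
        if not np.isfinite(best_score):
            return np.nan, 1
        sign = 1.0 if best_signed >= 0 else -1.0
        return sign * best_score, best_k

    est, k_used = best_estimate(ys)
    if not np.isfinite(est):
        return CorrelationResult(scope, "segmented", np.nan, np.nan, x.size, defined=False)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm_est, _k = best_estimate(rng.permutation(ys))
        if np.isfinite(perm_est) and abs(perm_est) >= abs(est):
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return CorrelationResult(scope, "segmented", float(est), float(p), x.size, segments=k_used)


def correlations_by_chromosome(
    froh: FrohTable,
    phen: PhenotypeTable,
    method: str = "rank",
    **kwargs,
) -> list[CorrelationResult]:
    """Genome-wide plus one correlation per chromosome, on shared individuals."""
    shared = froh.table.index.intersection(phen.table.index)
    if len(shared) < 5:
        raise ValueError(f"only {len(shared)} shared individuals; need >= 5")
    logger.info("correlations computed on %d shared individuals", len(shared))
    y = phen.table.loc[shared, "re_debv"].to_numpy()

    def one(x: np.ndarray, scope: str) -> CorrelationResult:
        if np.ptp(x) == 0:
            return CorrelationResult(scope, method, np.nan, np.nan, len(shared), defined=False)
        if method == "rank":
            return rank_correlation(x, y, scope=scope)
        if method == "segmented":
            return segmented_correlation(x, y, scope=scope, **kwargs)
        raise ValueError(f"unknown method {method!r}")

    results = [one(froh.table.loc[shared, "froh_genome"].to_numpy(), "genome")]
    for chrom in froh.table.columns:
        if chrom == "froh_genome":
            continue
        results.append(one(froh.table.loc[shared, chrom].to_numpy(), str(chrom)))
    return results


def compare_group_froh(
    froh: FrohTable,
    tails: TailSelection,
    adjust: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test of F_ROH between High-Fert and Low-Fert, per scope.

    One row per chromosome plus a genome row; ``t`` is High minus Low, so
    a negative t means the high-fertility group is less inbred.  Per-scope
    p-values are unadjusted by default; ``adjust=True`` adds a
    Benjamini-Hochberg column.
    """
    hi = froh.table.loc[[i for i in tails.high_fert if i in froh.table.index]]
    lo = froh.table.loc[[i for i in tails.low_fert if i in froh.table.index]]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("both tails need >= 2 individuals with F_ROH values")
    rows = []
    for scope in froh.table.columns:
        a = hi[scope].to_numpy(dtype=float)
        b = lo[scope].to_numpy(dtype=float)
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            t = p = np.nan
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "scope": "genome" if scope == "froh_genome" else str(scope),
                "mean_high_fert": a.mean(),
                "mean_low_fert": b.mean(),
                "mean_diff": a.mean() - b.mean(),
                "t": t,
                "p_value": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    out = pd.DataFrame(rows)
    if adjust:
        ok = np.isfinite(out["p_value"])
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
        out["p_bh"] = adj
    return out
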