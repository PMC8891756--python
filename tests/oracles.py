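"""Independent brute-force oracles used to cross-check the optimized code.

Everything here is written for clarity, not speed: explicit loops, no shared
code with the package internals beyond the public data types.
"""

from __future__ import annotations

import numpy as np

from equiroh.genotype_io import MISSING
from equiroh.roh_scan import ROHParams, ROHSegment


def brute_window_flags(row, params: ROHParams):
    """Enumerate every window and count hets/missings directly."""
    row = list(row)
    w = params.window_size
    flags = []
    for i in range(len(row) - w + 1):
        window = row[i : i + w]
        het = sum(1 for c in window if c == 1)
        mis = sum(1 for c in window if c == MISSING)
        flags.append(het <= params.max_opp_window and mis <= params.max_miss_window)
    return np.array(flags, dtype=bool)


def brute_in_run(flags, n_markers, params: ROHParams):
    """Per-marker support by explicit window membership enumeration."""
    n_win = len(flags)
    out = np.zeros(n_markers, dtype=bool)
    for m in range(n_markers):
        covering = [i for i in range(n_win) if i <= m <= i + params.window_size - 1]
        if not covering:
            continue
        support = sum(flags[i] for i in covering) / len(covering)
        out[m] = support > params.threshold if params.strict_threshold else support >= params.threshold
    return out


def brute_call_runs(in_run, pos, chrom, params: ROHParams, iid):
    """Linear scan over markers, splitting at large gaps, then filtering."""
    runs = []
    current: list[int] = []
    for j, flag in enumerate(in_run):
        if flag:
            if current and pos[j] - pos[current[-1]] > params.max_gap_bp:
                runs.append(current)
                current = []
            current.append(j)
        else:
            if current:
                runs.append(current)
            current = []
    if current:
        runs.append(current)
    segments = []
    for r in runs:
        n_snps = r[-1] - r[0] + 1
        length = pos[r[-1]] - pos[r[0]]
        if n_snps >= params.min_snp and length >= params.min_length_bp:
            segments.append(ROHSegment(iid, chrom, int(pos[r[0]]), int(pos[r[-1]]), int(n_snps)))
    return segments


def brute_detect_roh(gm, snpmap, params: ROHParams):
    """Naive whole-cohort caller built only from the three brute steps."""
    segments = []
    for chrom in snpmap.chromosomes():
        sl = snpmap.chrom_slice(chrom)
        pos = snpmap.pos[sl]
        for iid, row in zip(gm.individual_ids, gm.codes):
            sub = row[sl]
            flags = brute_window_flags(sub, params)
            in_run = brute_in_run(flags, len(sub), params)
            segments.extend(brute_call_runs(in_run, pos, chrom, params, iid))
    return segments


def brute_incidence(segments, snpmap, cohort_ids):
    """Per-marker membership test against every segment of every individual."""
    counts = np.zeros(len(snpmap), dtype=int)
    for j in range(len(snpmap)):
        chrom, pos = snpmap.chrom[j], snpmap.pos[j]
        for iid in cohort_ids:
            if any(
                s.individual_id == iid
                and s.chromosome == chrom
                and s.start_bp <= pos <= s.end_bp
                for s in segments
            ):
                counts[j] += 1
    return counts


def brute_overlap_bp(intervals, lo, hi):
    """Total bp of the union of ``intervals`` clipped to [lo, hi]."""
    points = set()
    for a, b in intervals:
        a, b = max(a, lo), min(b, hi)
        if b > a:
            points.update(range(a, b))
    return len(points)
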