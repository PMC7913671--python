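"""Distance from genes to the nearest feature of a class, and the DE vs
NDE comparison of those distances.

Tandem-repeat regions are classed by motif (period) length: short if the
motif is under 7 bp, long otherwise. Distance is the interval-to-interval
gap in bp (0 on overlap). Group comparison uses the two-sided
Mann-Whitney U rank test; fold-change vs distance association uses
Spearman rank correlation with midranks for ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io import GenomicInterval, TandemRepeatRecord

LONG_MIN_MOTIF = 7  # motif length (bp) at and above which a repeat is "long"


@dataclass(frozen=True)
class DistanceSummary:
    """Per-group distances with medians, quartiles and the rank test."""

    de_distances: np.ndarray
    nde_distances: np.ndarray
    de_median: float
    nde_median: float
    de_quartiles: tuple[float, float]
    nde_quartiles: tuple[float, float]
    statistic: float
    p: float


def merge_repeat_records(records: Sequence[TandemRepeatRecord]) -> list[TandemRepeatRecord]:
    """Merge same-chromosome overlapping raw records into regions; a
    merged region takes the motif length of its highest-scoring
    constituent (score ties broken by the shorter motif)."""
    by_chrom: dict[str, list[TandemRepeatRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    merged: list[TandemRepeatRecord] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda r: (r.interval.start, r.interval.end))
        cur_start, cur_end = group[0].interval.start, group[0].interval.end
        cur_members = [group[0]]
        for rec in group[1:]:
            if rec.interval.start < cur_end:  # half-open overlap
                cur_end = max(cur_end, rec.interval.end)
                cur_members.append(rec)
            else:
                merged.append(_merged_record(chrom, cur_start, cur_end, cur_members))
                cur_start, cur_end, cur_members = rec.interval.start, rec.interval.end, [rec]
        merged.append(_merged_record(chrom, cur_start, cur_end, cur_members))
    return merged


def _merged_record(
    chrom: str, start: int, end: int, members: list[TandemRepeatRecord]
) -> TandemRepeatRecord:
    best = max(members, key=lambda r: (r.score, -r.motif_length))
    return TandemRepeatRecord(
        GenomicInterval(chrom, start, end, label="tandem_repeat"),
        motif_length=best.motif_length,
        score=best.score,
    )


def classify_repeats(
    records: Sequence[TandemRepeatRecord],
    long_min_motif: int = LONG_MIN_MOTIF,
    merge: bool = True,
) -> list[TandemRepeatRecord]:
    """Partition repeat records into short (motif < ``long_min_motif``)
    and long classes, optionally merging overlapping raw records into
    regions first. The partition is exhaustive and exclusive."""
    recs = merge_repeat_records(records) if merge else list(records)
    out = []
    for r in recs:
        cls = "short" if r.motif_length < long_min_motif else "long"
        out.append(TandemRepeatRecord(r.interval, r.motif_length, r.score, repeat_class=cls))
    return out


def nearest_distance(
    genes: Sequence[GenomicInterval], features: Sequence[GenomicInterval]
) -> dict[str, float]:
    """Distance (bp) from each gene to its nearest feature on the same
    chromosome: 0 on overlap, else the minimal boundary gap. Genes on
    chromosomes with no features map to NaN (excluded from summaries,
    counted by callers)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
    # union of features per chromosome: merged disjoint intervals preserve
    # the min gap and allow a sorted search
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, feats in by_chrom.items():
        ivs = sorted((f.start, f.end) for f in feats)
        starts, ends = [ivs[0][0]], [ivs[0][1]]
        for s, e in ivs[1:]:
            if s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.array(starts), np.array(ends))

    distances: dict[str, float] = {}
    for g in genes:
        if g.chrom not in merged:
            distances[g.id] = np.nan
            continue
        starts, ends = merged[g.chrom]
        i = int(np.searchsorted(starts, g.end))  # first feature starting at/after gene end
        best = np.inf
        if i < len(starts):
            best = min(best, starts[i] - g.end)
        if i > 0:
            prev_gap = g.start - ends[i - 1]
            best = min(best, max(prev_gap, 0))
            if starts[i - 1] < g.end and ends[i - 1] > g.start:
                best = 0.0
        distances[g.id] = float(max(best, 0.0))
    return distances


def compare_distance_distributions(
    de_distances: Sequence[float], nde_distances: Sequence[float]
) -> DistanceSummary:
    """Two-sided Mann-Whitney U comparison of DE vs NDE distance
    distributions, with medians and quartiles per group."""
    de = np.asarray(de_distances, dtype=float)
    nde = np.asarray(nde_distances, dtype=float)
    de = de[~np.isnan(de)]
    nde = nde[~np.isnan(nde)]
    if len(de) < 2 or len(nde) < 2:
        raise ValueError("each group needs at least 2 finite distances")
    if np.all(de == de[0]) and np.all(nde == nde[0]) and de[0] == nde[0]:
        stat, p = len(de) * len(nde) / 2.0, 1.0
    else:
        stat, p = stats.mannwhitneyu(de, nde, alternative="two-sided")
    return DistanceSummary(
        de_distances=de,
        nde_distances=nde,
        de_median=float(np.median(de)),
        nde_median=float(np.median(nde)),
        de_quartiles=(float(np.percentile(de, 25)), float(np.percentile(de, 75))),
        nde_quartiles=(float(np.percentile(nde, 25)), float(np.percentile(nde, 75))),
        statistic=float(stat),
        p=float(p),
    )


def distance_fc_correlation(
    distances: Sequence[float], fold_changes: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties) between distance to
    a feature class and transcript fold change; returns (rho, p)."""
    d = np.asarray(distances, dtype=float)
    f = np.asarray(fold_changes, dtype=float)
    keep = ~(np.isnan(d) | np.isnan(f))
    d, f = d[keep], f[keep]
    if len(d) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(d == d[0]) or np.all(f == f[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(d, f)
    return float(rho), float(p)
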