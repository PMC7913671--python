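"""TSS-anchored average nucleosome-occupancy profiles.

Signal around every TSS is extracted into an anchored matrix
(minus-strand rows orientation-flipped so downstream is always right),
averaged into a mean profile, summarised by NDR depth/width and the
-2/-1/+1 peak positions and amplitudes, and compared between genotypes
with a two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.signal import argrelextrema

from .io import CoverageTrack, GenomicInterval


@dataclass
class AnchoredMatrix:
    """Signal rows anchored at loci; columns are positions relative to
    the anchor (bp, upstream negative, at track bin resolution)."""

    values: np.ndarray  # (n_loci, n_cols)
    positions: np.ndarray  # column centres in bp relative to anchor
    anchor_ids: list[str]
    n_dropped: int = 0  # anchors whose window left the chromosome

    @property
    def n_loci(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ProfileMetrics:
    """NDR and flanking-peak summary of a TSS profile.

    Positions in bp relative to the anchor; amplitudes in profile units.
    """

    ndr_position: float
    ndr_depth: float
    ndr_width: float
    peak_positions: dict[str, float]  # keys "-2", "-1", "+1"
    peak_amplitudes: dict[str, float]


def normalize_track_depth(track: CoverageTrack, target_mean: float = 1.0) -> CoverageTrack:
    """Scale a replicate track to a common genome-wide mean so replicate
    libraries contribute equally to the averaged profile."""
    mean = track.mean()
    if mean <= 0:
        raise ValueError("cannot depth-normalise a track with non-positive mean")
    out = track.copy()
    for chrom in out.values:
        out.values[chrom] = out.values[chrom] * (target_mean / mean)
    return out


def anchor_matrix(
    track: CoverageTrack,
    anchors: Sequence[GenomicInterval],
    upstream: int = 1000,
    downstream: int = 1500,
) -> AnchoredMatrix:
    """Extract per-anchor signal windows [-upstream, +downstream) around
    each anchor's TSS, strand-oriented (minus-strand rows reversed).
    Anchors whose window exceeds the chromosome are dropped and counted.
    """
    bs = track.bin_size
    n_up, n_down = upstream // bs, downstream // bs
    n_cols = n_up + n_down
    if n_cols < 1:
        raise ValueError("window shorter than one bin")
    rows, ids = [], []
    dropped = 0
    for a in anchors:
        vec = track.values[a.chrom]
        tss_bin = a.tss() // bs
        if a.strand == "-":
            lo, hi = tss_bin + 1 - n_down, tss_bin + 1 + n_up
        else:
            lo, hi = tss_bin - n_up, tss_bin + n_down
        if lo < 0 or hi > len(vec):
            dropped += 1
            continue
        row = vec[lo:hi]
        if a.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(a.id)
    if not rows:
        raise ValueError("no anchor produced a valid window")
    positions = (np.arange(n_cols) - n_up) * bs + bs / 2.0
    return AnchoredMatrix(np.vstack(rows), positions, ids, n_dropped=dropped)


def mean_profile(matrices: Sequence[AnchoredMatrix] | AnchoredMatrix) -> np.ndarray:
    """Column-mean profile: average over anchored rows within each
    replicate matrix, then equally over replicates."""
    if isinstance(matrices, AnchoredMatrix):
        matrices = [matrices]
    shapes = {m.values.shape[1] for m in matrices}
    if len(shapes) != 1:
        raise ValueError(f"replicate matrices have mismatched widths {shapes}")
    return np.mean([m.values.mean(axis=0) for m in matrices], axis=0)


def profile_metrics(
    profile: np.ndarray,
    positions: np.ndarray,
    spacing_hint: float = 165.0,
) -> ProfileMetrics:
    """Locate the NDR and the -2/-1/+1 nucleosome peaks on a mean
    profile.

    NDR = minimum within [-spacing_hint, +spacing_hint/2] of the anchor;
    +1 = first local maximum downstream of the NDR, -1 and -2 the
    successive maxima upstream. NDR width = span of the contiguous
    region around the NDR where the profile stays below the midpoint
    between NDR depth and the mean of the -1/+1 amplitudes.
    """
    profile = np.asarray(profile, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if profile.ndim != 1 or profile.shape != positions.shape:
        raise ValueError("profile and positions must be equal-length 1-D arrays")

    search = (positions >= -spacing_hint) & (positions <= spacing_hint / 2.0)
    if not search.any():
        raise ValueError("profile does not cover the NDR search window")
    seg = np.where(search, profile, np.inf)
    ndr_idx = int(np.argmin(seg))
    if ndr_idx in (0, len(profile) - 1) or (
        profile[ndr_idx] >= profile[ndr_idx - 1] and profile[ndr_idx] >= profile[ndr_idx + 1]
    ):
        raise ValueError("no interior occupancy minimum around the anchor (flat or monotone profile)")
    ndr_pos, ndr_depth = float(positions[ndr_idx]), float(profile[ndr_idx])

    bin_bp = float(positions[1] - positions[0]) if len(positions) > 1 else 1.0
    # a genuine nucleosome peak must dominate roughly half a spacing
    order = max(1, int(round(spacing_hint / 2.0 / bin_bp)))
    maxima = argrelextrema(profile, np.greater_equal, order=order)[0]
    # drop plateau duplicates
    maxima = maxima[np.insert(np.diff(maxima) > 1, 0, True)]
    down = maxima[maxima > ndr_idx]
    up = maxima[maxima < ndr_idx][::-1]
    if len(down) < 1 or len(up) < 1:
        raise ValueError("could not locate nucleosome peaks flanking the NDR")

    peaks_pos: dict[str, float] = {"+1": float(positions[down[0]])}
    peaks_amp: dict[str, float] = {"+1": float(profile[down[0]])}
    peaks_pos["-1"] = float(positions[up[0]])
    peaks_amp["-1"] = float(profile[up[0]])
    if len(up) > 1:
        peaks_pos["-2"] = float(positions[up[1]])
        peaks_amp["-2"] = float(profile[up[1]])

    flank_mean = (peaks_amp["-1"] + peaks_amp["+1"]) / 2.0
    midpoint = (ndr_depth + flank_mean) / 2.0
    below = profile < midpoint
    lo = ndr_idx
    while lo > 0 and below[lo - 1]:
        lo -= 1
    hi = ndr_idx
    while hi < len(profile) - 1 and below[hi + 1]:
        hi += 1
    ndr_width = (hi - lo + 1) * bin_bp

    return ProfileMetrics(
        ndr_position=ndr_pos,
        ndr_depth=ndr_depth,
        ndr_width=float(ndr_width),
        peak_positions=peaks_pos,
        peak_amplitudes=peaks_amp,
    )


def ks_profile_compare(
    profile_a,
    profile_b,
    mode: str = "rows",
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of two genotypes'
    anchored signal.

    ``mode="rows"`` (default) takes an AnchoredMatrix per genotype (or a
    list of replicate matrices, averaged locus-wise) and compares the
    per-locus mean signal distributions — loci are the exchangeable
    sampling units. ``mode="values"`` takes two equal-length mean
    profiles and compares their value distributions, the literal result
    of handing two curve arrays to a stock KS implementation; it is kept
    for comparability but has little power against localized occupancy
    changes. Returns (D, asymptotic p).
    """
    if mode == "rows":
        a = _row_means(profile_a)
        b = _row_means(profile_b)
    else:
        a = np.asarray(profile_a, dtype=float)
        b = np.asarray(profile_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("profiles must have equal length")
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need at least 5 points per sample for the KS test")
    if np.array_equal(a, b):
        return 0.0, 1.0
    d, p = stats.ks_2samp(a, b, method="asymp")
    return float(d), float(p)


def _row_means(x) -> np.ndarray:
    if isinstance(x, AnchoredMatrix):
        return x.values.mean(axis=1)
    if isinstance(x, (list, tuple)):
        return np.mean([m.values.mean(axis=1) for m in x], axis=0)
    return np.asarray(x, dtype=float)
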