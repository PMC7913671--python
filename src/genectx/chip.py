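"""H3K9me2/H3 ratio normalisation and anchored-locus analysis.

Each H3K9me2 coverage track is normalised to its matched total-H3 track
as a per-bin log2 ratio; mutant log-ratios are then normalised to the
wild-type log-ratio of the corresponding biological replicate
(subtraction, i.e. the log of a ratio of ratios). Heterochromatin
domains are called on the wild-type ratio with a robust
median + z*MAD threshold, and LTR-local enrichment is quantified
against matched random control loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import CoverageTrack, GenomeLayout, GenomicInterval


@dataclass
class RatioTrack:
    """A log2(H3K9me2 / H3) track with provenance metadata."""

    track: CoverageTrack  # is_ratio=True; finite everywhere
    pseudocount: float
    replicate: str = ""
    genotype: str = ""

    @property
    def bin_size(self) -> int:
        return self.track.bin_size

    @property
    def layout(self) -> GenomeLayout:
        return self.track.layout


@dataclass(frozen=True)
class EnrichedDomain:
    interval: GenomicInterval
    mean_enrichment: float
    threshold: float


@dataclass
class AnchoredSummary:
    """Scaled-body anchored matrices for features and matched controls.

    Columns are flank bins (real bp) + ``body_bins`` rescaled body
    columns + flank bins. ``center_excess`` is the mean log2 ratio over
    feature bodies minus the mean over control bodies.
    """

    feature_matrix: np.ndarray
    control_matrix: np.ndarray
    feature_profile: np.ndarray
    control_profile: np.ndarray
    body_columns: slice
    center_excess: float
    n_dropped: int = 0


def ratio_track(
    k9: CoverageTrack,
    h3: CoverageTrack,
    pseudocount: float = 1.0,
    replicate: str = "",
    genotype: str = "",
) -> RatioTrack:
    """Per-bin log2((k9 + pc) / (h3 + pc)); the pseudocount keeps the
    ratio finite over uncovered bins."""
    if not k9.same_grid(h3):
        raise ValueError("H3K9me2 and H3 tracks are on different bin grids")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    out = CoverageTrack.zeros(k9.layout, k9.bin_size, is_ratio=True)
    for chrom in k9.layout.names:
        out.values[chrom] = np.log2(
            (k9.values[chrom] + pseudocount) / (h3.values[chrom] + pseudocount)
        )
    return RatioTrack(out, pseudocount, replicate=replicate, genotype=genotype)


def normalize_to_wt(mutant: RatioTrack, wt: RatioTrack) -> RatioTrack:
    """Mutant log2 ratio minus the wild-type log2 ratio of the same
    biological replicate (double normalisation)."""
    if not mutant.track.same_grid(wt.track):
        raise ValueError("mutant and WT ratio tracks are on different bin grids")
    if mutant.replicate != wt.replicate:
        raise ValueError(
            f"replicate pairing mismatch: {mutant.replicate!r} vs {wt.replicate!r}"
        )
    out = CoverageTrack.zeros(mutant.layout, mutant.bin_size, is_ratio=True)
    for chrom in mutant.layout.names:
        out.values[chrom] = mutant.track.values[chrom] - wt.track.values[chrom]
    return RatioTrack(
        out, mutant.pseudocount, replicate=mutant.replicate,
        genotype=f"{mutant.genotype}-vs-{wt.genotype}",
    )


def call_enriched_domains(
    wt_ratio: RatioTrack,
    z_threshold: float = 2.0,
    min_len: int = 2000,
    merge_gap: int = 1000,
    min_seed_len: int = 150,
) -> list[EnrichedDomain]:
    """Segments of sustained enrichment on a ratio track.

    Bins above genome median + ``z_threshold`` x MAD are flagged; runs
    shorter than ``min_seed_len`` bp are dropped (isolated noise bins
    must not be chained by gap merging), surviving runs separated by
    gaps <= ``merge_gap`` bp are merged, and merged runs >= ``min_len``
    bp are kept. Invariant to adding a constant to the whole track.
    """
    track = wt_ratio.track
    genome = track.genome_values()
    med = float(np.median(genome))
    mad = float(np.median(np.abs(genome - med)))
    if mad == 0:
        warnings.warn("ratio track is (near-)constant; no domains callable", stacklevel=2)
        return []
    threshold = med + z_threshold * mad
    bs = track.bin_size
    gap_bins = merge_gap // bs
    min_bins = max(1, min_len // bs)
    seed_bins = max(1, min_seed_len // bs)

    domains: list[EnrichedDomain] = []
    for chrom, length in track.layout.chromosomes:
        above = track.values[chrom] > threshold
        runs = [(b0, b1) for b0, b1 in _runs(above) if b1 - b0 >= seed_bins]
        runs = _merge_runs(runs, gap_bins)
        for b0, b1 in runs:
            if b1 - b0 < min_bins:
                continue
            seg = track.values[chrom][b0:b1]
            domains.append(
                EnrichedDomain(
                    GenomicInterval(
                        chrom, b0 * bs, min(b1 * bs, length),
                        label="enriched_domain", id=f"{chrom}:{b0 * bs}",
                    ),
                    mean_enrichment=float(seg.mean()),
                    threshold=threshold,
                )
            )
    return domains


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def _merge_runs(runs: list[tuple[int, int]], gap_bins: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for b0, b1 in runs[1:]:
        if b0 - merged[-1][1] <= gap_bins:
            merged[-1] = (merged[-1][0], b1)
        else:
            merged.append((b0, b1))
    return merged


def matched_random_controls(
    features: Sequence[GenomicInterval],
    layout: GenomeLayout,
    exclusions: Sequence[GenomicInterval] = (),
    seed: int | np.random.Generator = 0,
    max_tries: int = 1000,
) -> list[GenomicInterval]:
    """Random control loci matching each feature's length and
    chromosome, avoiding overlap with the features, the exclusions and
    each other; deterministic per seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    taken: dict[str, list[tuple[int, int]]] = {}
    for iv in list(features) + list(exclusions):
        taken.setdefault(iv.chrom, []).append((iv.start, iv.end))
    controls: list[GenomicInterval] = []
    for i, f in enumerate(features):
        length = len(f)
        chrom_len = layout.length(f.chrom)
        if length > chrom_len:
            raise ValueError(f"feature {f.id!r} longer than its chromosome")
        placed = False
        occupied = taken.setdefault(f.chrom, [])
        for _ in range(max_tries):
            start = int(rng.integers(0, chrom_len - length + 1))
            end = start + length
            if any(start < e and s < end for s, e in occupied):
                continue
            controls.append(
                GenomicInterval(f.chrom, start, end, strand=f.strand, label="control", id=f"ctrl_{i}")
            )
            occupied.append((start, end))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a control for feature {f.id!r} after {max_tries} tries"
            )
    return controls


def anchored_summary(
    ratio: RatioTrack,
    features: Sequence[GenomicInterval],
    controls: Sequence[GenomicInterval],
    flank: int = 1000,
    body_bins: int = 20,
) -> AnchoredSummary:
    """Scaled-body anchored matrices (feature body rescaled to
    ``body_bins`` columns, flanks in real bp) for features and controls,
    with the centre-excess statistic."""
    if len(features) == 0:
        raise ValueError("empty feature set")
    fm, f_drop = _scaled_matrix(ratio, features, flank, body_bins)
    cm, c_drop = _scaled_matrix(ratio, controls, flank, body_bins)
    n_flank = flank // ratio.bin_size
    body = slice(n_flank, n_flank + body_bins)
    center_excess = float(fm[:, body].mean() - cm[:, body].mean()) if len(cm) else float("nan")
    return AnchoredSummary(
        feature_matrix=fm,
        control_matrix=cm,
        feature_profile=fm.mean(axis=0),
        control_profile=cm.mean(axis=0) if len(cm) else np.array([]),
        body_columns=body,
        center_excess=center_excess,
        n_dropped=f_drop + c_drop,
    )


def _scaled_matrix(
    ratio: RatioTrack,
    loci: Sequence[GenomicInterval],
    flank: int,
    body_bins: int,
) -> tuple[np.ndarray, int]:
    bs = ratio.bin_size
    n_flank = flank // bs
    rows = []
    dropped = 0
    for iv in loci:
        vec = ratio.track.values[iv.chrom]
        b0, b1 = iv.start // bs, (iv.end - 1) // bs + 1
        if b0 - n_flank < 0 or b1 + n_flank > len(vec):
            dropped += 1
            continue
        left = vec[b0 - n_flank : b0]
        right = vec[b1 : b1 + n_flank]
        body_src = vec[b0:b1]
        body = np.interp(
            np.linspace(0, len(body_src) - 1, body_bins),
            np.arange(len(body_src)),
            body_src,
        )
        rows.append(np.concatenate([left, body, right]))
    if not rows:
        return np.empty((0, 2 * n_flank + body_bins)), dropped
    return np.vstack(rows), dropped
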