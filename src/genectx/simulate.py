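"""Synthetic genome, expression and coverage generator.

Emulates, at desk scale, the statistical structure the pipeline is built
to detect: a small multi-chromosome genome with genes, LTRs, tandem
repeats (motif lengths straddling the short/long 7 bp threshold) and
G-quadruplex motifs; 4-replicate expression tables in which a planted
fraction of genes is upregulated preferentially near a repeat class;
phased nucleosome occupancy around TSSs with genotype-dependent peak
amplitudes; and paired H3 / H3K9me2 coverage for two genotypes with
planted heterochromatin domains and LTR-local enrichment in the mutant.

Every draw is fixed by the seed (PCG64 streams spawned per stage), and
every planted effect size is recoverable by the corresponding
downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr
from .distance import nearest_distance
from .io import (
    CoverageTrack,
    GenomeLayout,
    GenomicInterval,
    TandemRepeatRecord,
    write_bed,
    write_bedgraph,
    write_gff3,
    write_tandem_repeat_table,
)

WT = "wt"
MUTANT = "mut"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic bundle.

    Sizes mirror the real system scaled to a 3 Mb toy genome: feature
    densities per Mb track the fission-yeast annotation (repeat regions
    split ~1:5 short:long, ~20 LTRs/Mb), four expression replicates,
    three nucleosome replicates and two ChIP replicates per genotype.
    """

    # genome
    chromosomes: tuple[tuple[str, int], ...] = (
        ("chrI", 1_000_000),
        ("chrII", 1_000_000),
        ("chrIII", 1_000_000),
    )
    n_genes: int = 500
    n_antisense: int = 150
    gene_length_min: int = 300
    gene_length_max: int = 5000
    gene_length_log_mean: float = 7.1  # ln bp, median ~1200 bp
    gene_length_log_sd: float = 0.45
    n_tf2: int = 13  # near-identical retrotransposon copies, analysed summed
    n_ltrs: int = 60
    ltr_length: int = 350
    n_tandem_short: int = 64
    n_tandem_long: int = 340
    n_g4: int = 100
    # expression
    n_replicates: int = 4
    de_fraction: float = 0.1
    proximity_effect: float = 10_000.0  # logistic scale (bp); 0 disables the bias
    proximity_width: float = 1.0  # logistic width on log-distance
    proximity_target: str = "LTR"
    baseline_log2_mean: float = 6.6
    baseline_log2_sd: float = 1.5
    min_fold_change: float = 2.0  # planted lower bound for DE genes
    fold_change_log2_sd: float = 0.5
    expression_noise_sd: float = 0.25  # sd of log2 replicate noise
    biotype_fractions: tuple[tuple[str, float], ...] = (
        ("protein_coding", 0.42),
        ("ncRNA", 0.40),
        ("pseudogene", 0.04),
        ("snoRNA", 0.03),
        ("snRNA", 0.01),
        ("tRNA", 0.05),
        ("rRNA", 0.05),
    )
    # nucleosome occupancy (1 bp bins resolve the 165 bp phasing)
    nuc_bin_size: int = 1
    n_nuc_replicates: int = 3
    nucleosome_spacing: float = 165.0  # NDR centre to adjacent peak (bp)
    ndr_offset: float = -60.0  # NDR centre relative to TSS (bp)
    ndr_depth: float = 0.4
    ndr_width: float = 80.0
    peak_amplitude: float = 1.0
    nucleosome_decay: float = 700.0  # damping length (bp)
    nucleosome_amplitude: tuple[tuple[str, float], ...] = ((WT, 1.0), (MUTANT, 1.1))
    occupancy_depth: float = 100.0  # Poisson counts per occupancy unit; 0 = noise-free
    template_upstream: int = 1200
    template_downstream: int = 1800
    # ChIP
    chip_bin_size: int = 50
    n_chip_replicates: int = 2
    chip_base_coverage: float = 100.0
    chip_noise_sd: float = 0.3  # sd of log2 noise per channel; 0 = noise-free
    domain_log2: float = 2.0  # planted heterochromatin enrichment (both genotypes)
    ltr_enrichment: float = 1.0  # extra log2 at LTR bodies in the mutant only
    domain_end_span: int = 30_000  # planted end-domains on the first two chromosomes
    interior_domain: tuple[str, int, int] | None = ("chrIII", 500_000, 520_000)

    def layout(self) -> GenomeLayout:
        return GenomeLayout(self.chromosomes)

    def planted_domains(self) -> tuple[GenomicInterval, ...]:
        out = []
        layout = self.layout()
        for chrom in layout.names[:2]:
            length = layout.length(chrom)
            span = min(self.domain_end_span, length)
            out.append(GenomicInterval(chrom, 0, span, label="heterochromatin", id=f"{chrom}_dom_L"))
            out.append(
                GenomicInterval(chrom, length - span, length, label="heterochromatin", id=f"{chrom}_dom_R")
            )
        if self.interior_domain is not None:
            c, s, e = self.interior_domain
            if c in layout:
                out.append(GenomicInterval(c, s, e, label="heterochromatin", id=f"{c}_dom_I"))
        return tuple(out)


@dataclass
class SyntheticTruth:
    """Everything planted by the generator, for downstream recovery checks."""

    seed: int
    config: SimConfig
    de_gene_ids: frozenset[str] = frozenset()
    target_distances: dict[str, float] = field(default_factory=dict)
    planted_de_median: float = float("nan")
    planted_nde_median: float = float("nan")
    chip_domain_set: tuple[GenomicInterval, ...] = ()

    @property
    def de_fraction(self) -> float:
        return self.config.de_fraction

    @property
    def proximity_effect(self) -> float:
        return self.config.proximity_effect

    @property
    def ltr_enrichment(self) -> float:
        return self.config.ltr_enrichment

    @property
    def nucleosome_amplitude(self) -> dict[str, float]:
        return dict(self.config.nucleosome_amplitude)


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage]))


def _place_nonoverlapping(
    rng: np.random.Generator,
    layout: GenomeLayout,
    lengths: Sequence[int],
    occupied: dict[str, list[tuple[int, int]]] | None = None,
    max_tries: int = 500,
) -> list[tuple[str, int, int]]:
    """Place intervals of the given lengths uniformly, avoiding overlap
    with each other and with ``occupied``; bounded retries per interval."""
    occupied = occupied if occupied is not None else {}
    chrom_names = layout.names
    chrom_lens = np.array([layout.length(c) for c in chrom_names], dtype=float)
    probs = chrom_lens / chrom_lens.sum()
    placed: list[tuple[str, int, int]] = []
    for length in lengths:
        ok = False
        for _ in range(max_tries):
            ci = int(rng.choice(len(chrom_names), p=probs))
            chrom = chrom_names[ci]
            limit = int(chrom_lens[ci]) - length
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit + 1))
            end = start + length
            spans = occupied.setdefault(chrom, [])
            if any(start < e and s < end for s, e in spans):
                continue
            spans.append((start, end))
            placed.append((chrom, start, end))
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place an interval of {length} bp after {max_tries} tries; "
                "reduce feature counts or lengths"
            )
    return placed


def simulate_genome(
    config: SimConfig, seed: int
) -> tuple[GenomeLayout, dict[str, list], SyntheticTruth]:
    """Toy genome: disjoint stranded genes (a subset marked as Tf2
    retrotransposon copies), antisense transcripts mirroring random
    sense genes, and LTR / tandem-repeat / G4 features."""
    layout = config.layout()
    rng = _stage_rng(seed, 0)

    gene_lengths = np.exp(
        rng.normal(config.gene_length_log_mean, config.gene_length_log_sd, config.n_genes)
    )
    gene_lengths = np.clip(gene_lengths, config.gene_length_min, config.gene_length_max).astype(int)
    occupied: dict[str, list[tuple[int, int]]] = {}
    placed = _place_nonoverlapping(rng, layout, gene_lengths.tolist(), occupied)
    strands = rng.choice(["+", "-"], size=config.n_genes)

    n_tf2 = min(config.n_tf2, config.n_genes)
    tf2_idx = set(rng.choice(config.n_genes, size=n_tf2, replace=False).tolist()) if n_tf2 else set()
    bio_names = [b for b, _ in config.biotype_fractions]
    bio_probs = np.array([p for _, p in config.biotype_fractions], dtype=float)
    bio_probs /= bio_probs.sum()
    genes: list[GenomicInterval] = []
    tf2_counter = 0
    for i, ((chrom, start, end), strand) in enumerate(zip(placed, strands)):
        if i in tf2_idx:
            tf2_counter += 1
            gid, biotype = f"Tf2_{tf2_counter}", "retrotransposon"
        else:
            gid = f"gene_{i + 1:04d}"
            biotype = str(rng.choice(bio_names, p=bio_probs))
        genes.append(GenomicInterval(chrom, start, end, strand, biotype, gid))

    antisense: list[GenomicInterval] = []
    if config.n_antisense:
        sense_pool = [g for g in genes if g.label != "retrotransposon"]
        chosen = rng.choice(len(sense_pool), size=min(config.n_antisense, len(sense_pool)), replace=False)
        for j, gi in enumerate(sorted(chosen.tolist())):
            g = sense_pool[gi]
            antisense.append(
                GenomicInterval(
                    g.chrom, g.start, g.end,
                    "-" if g.strand == "+" else "+",
                    "antisense", f"AS_{g.id}",
                )
            )

    ltrs = [
        GenomicInterval(c, s, e, ".", "LTR", f"LTR_{i + 1:03d}")
        for i, (c, s, e) in enumerate(
            _place_nonoverlapping(rng, layout, [config.ltr_length] * config.n_ltrs, {})
        )
    ]

    repeats: list[TandemRepeatRecord] = []
    motifs = np.concatenate([
        rng.integers(1, 7, size=config.n_tandem_short),
        (6 + rng.geometric(0.12, size=config.n_tandem_long)).astype(np.int64),
    ])
    copies = rng.integers(2, 9, size=len(motifs))
    rep_lengths = np.maximum(motifs * copies, 24)
    rep_placed = _place_nonoverlapping(rng, layout, rep_lengths.tolist(), {})
    for i, ((c, s, e), motif) in enumerate(zip(rep_placed, motifs)):
        repeats.append(
            TandemRepeatRecord(
                GenomicInterval(c, s, e, ".", "tandem_repeat", f"TR_{i + 1:04d}"),
                motif_length=int(motif),
                score=float(rng.integers(30, 300)),
            )
        )

    g4s = [
        GenomicInterval(c, s, e, str(rng.choice(["+", "-"])), "G4", f"G4_{i + 1:03d}")
        for i, (c, s, e) in enumerate(
            _place_nonoverlapping(rng, layout, (rng.integers(20, 40, size=config.n_g4)).tolist(), {})
        )
    ]

    features = {
        "gene": genes,
        "antisense": antisense,
        "LTR": ltrs,
        "tandem_repeat": repeats,
        "G4": g4s,
    }
    truth = SyntheticTruth(seed=seed, config=config, chip_domain_set=config.planted_domains())
    return layout, features, truth


def _target_features(config: SimConfig, features: dict[str, list]) -> list[GenomicInterval]:
    if config.proximity_target == "tandem_long":
        return [r.interval for r in features["tandem_repeat"] if r.motif_length >= 7]
    if config.proximity_target == "tandem_short":
        return [r.interval for r in features["tandem_repeat"] if r.motif_length < 7]
    return list(features[config.proximity_target])


def simulate_expression(
    truth: SyntheticTruth,
    features: dict[str, list],
    n_replicates: int | None = None,
) -> pd.DataFrame:
    """Replicate expression table with a planted upregulated fraction.

    DE genes are drawn without replacement with weights logistic in
    log-distance to the target feature class (scale =
    ``proximity_effect``; zero scale gives uniform weights, the null).
    DE genes receive log-normal fold changes bounded below by
    ``min_fold_change``; replicate noise is Gaussian on log2 signal, so
    null p-values from the two-sample t-test are uniform.
    """
    cfg = truth.config
    n_rep = n_replicates if n_replicates is not None else cfg.n_replicates
    if n_rep < 2:
        raise ValueError("need at least 2 replicates")
    rng = _stage_rng(truth.seed, 1)

    records = list(features["gene"]) + list(features.get("antisense", []))
    n = len(records)
    targets = _target_features(cfg, features)
    dist = nearest_distance(records, targets)
    d = np.array([dist[r.id] for r in records], dtype=float)
    d = np.where(np.isnan(d), np.nanmax(d) if np.isfinite(np.nanmax(d)) else 0.0, d)

    n_de = int(round(cfg.de_fraction * n))
    if n_de > 0:
        if cfg.proximity_effect > 0:
            z = (np.log(d + 1.0) - np.log(cfg.proximity_effect + 1.0)) / cfg.proximity_width
            w = 1.0 / (1.0 + np.exp(z))
        else:
            w = np.ones(n)
        de_idx = rng.choice(n, size=n_de, replace=False, p=w / w.sum())
    else:
        de_idx = np.array([], dtype=int)
    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True

    truth.de_gene_ids = frozenset(records[i].id for i in de_idx)
    truth.target_distances = {r.id: float(x) for r, x in zip(records, d)}
    if is_de.any() and (~is_de).any():
        truth.planted_de_median = float(np.median(d[is_de]))
        truth.planted_nde_median = float(np.median(d[~is_de]))

    baseline = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, n)
    log2_fc = np.zeros(n)
    log2_fc[is_de] = np.log2(cfg.min_fold_change) + np.abs(
        rng.normal(0.0, cfg.fold_change_log2_sd, int(is_de.sum()))
    )
    noise1 = rng.normal(0.0, cfg.expression_noise_sd, (n, n_rep))
    noise2 = rng.normal(0.0, cfg.expression_noise_sd, (n, n_rep))
    cond1 = baseline[:, None] * 2.0 ** noise1
    cond2 = (baseline * 2.0 ** log2_fc)[:, None] * 2.0 ** noise2

    l1, l2 = np.log2(cond1 + 0.5), np.log2(cond2 + 0.5)
    p = stats.ttest_ind(l1, l2, axis=1, equal_var=False).pvalue
    p = np.where(np.isnan(p), 1.0, p)

    table = pd.DataFrame({"gene_id": [r.id for r in records], "biotype": [r.label for r in records]})
    for j in range(n_rep):
        table[f"cond1_r{j + 1}"] = cond1[:, j]
    for j in range(n_rep):
        table[f"cond2_r{j + 1}"] = cond2[:, j]
    table["fold_change"] = cond2.mean(axis=1) / cond1.mean(axis=1)
    table["p_value"] = p
    table["fdr"] = bh_fdr(p)
    table["de_call"] = "none"
    return table


def nucleosome_template(config: SimConfig, multiplier: float) -> np.ndarray:
    """Closed-form occupancy added around each TSS (1 bp resolution,
    ``template_upstream`` bp before to ``template_downstream`` after):
    damped phased peaks at the NDR centre +/- k*spacing, scaled by the
    genotype multiplier, minus a Gaussian NDR dip that the multiplier
    does not touch (the genotype effect is an occupancy gain at peaks).
    """
    rel = np.arange(-config.template_upstream, config.template_downstream, dtype=float)
    u = rel - config.ndr_offset
    damp = np.exp(-np.abs(u) / config.nucleosome_decay)
    phased = 0.5 * (1.0 - np.cos(np.pi * u / config.nucleosome_spacing))
    dip = config.ndr_depth * np.exp(-((u / config.ndr_width) ** 2))
    return multiplier * config.peak_amplitude * damp * phased - dip


def _add_template(arr: np.ndarray, template: np.ndarray, tss: int, strand: str, up: int, down: int) -> None:
    if strand == "-":
        lo, hi = tss - down + 1, tss + up + 1
        tpl = template[::-1]
    else:
        lo, hi = tss - up, tss + down
        tpl = template
    a, b = max(lo, 0), min(hi, len(arr))
    if a >= b:
        return
    arr[a:b] += tpl[a - lo : b - lo]


def simulate_coverage(
    truth: SyntheticTruth,
    layout: GenomeLayout,
    genes: Sequence[GenomicInterval],
    features: dict[str, list],
) -> dict:
    """Nucleosome occupancy tracks (per genotype x replicate) and paired
    H3 / H3K9me2 ChIP tracks (per genotype x replicate).

    Occupancy = 1 + TSS-anchored template per gene, Poisson-resampled at
    ``occupancy_depth``. ChIP: H3 is flat base coverage with log-normal
    noise; H3K9me2 carries the same base plus planted log2 enrichment
    inside the heterochromatin domain set (both genotypes) and
    ``ltr_enrichment`` over LTR bodies (mutant only).
    """
    cfg = truth.config
    rng = _stage_rng(truth.seed, 2)
    sense = [g for g in genes if g.label != "antisense"]

    nucleosome: dict[str, list[CoverageTrack]] = {}
    for genotype, mult in cfg.nucleosome_amplitude:
        template = nucleosome_template(cfg, mult)
        base: dict[str, np.ndarray] = {}
        for chrom, length in layout.chromosomes:
            arr = np.ones(length)
            for g in (g for g in sense if g.chrom == chrom):
                _add_template(arr, template, g.tss(), g.strand, cfg.template_upstream, cfg.template_downstream)
            base[chrom] = np.maximum(arr, 0.0)  # stacked NDR dips cannot go negative
        # occupancy is relative (sequencing fixes total signal): a genotype
        # gaining occupancy at arrays loses it in linkers, so each genotype's
        # true signal is scaled to genome mean 1
        gmean = np.mean(np.concatenate([base[c] for c in layout.names]))
        for chrom in layout.names:
            base[chrom] = base[chrom] / gmean
        reps = []
        for _ in range(cfg.n_nuc_replicates):
            vals = {}
            for chrom in layout.names:
                if cfg.occupancy_depth > 0:
                    vals[chrom] = rng.poisson(
                        np.maximum(base[chrom], 0.0) * cfg.occupancy_depth
                    ) / cfg.occupancy_depth
                else:
                    vals[chrom] = base[chrom].copy()
            reps.append(CoverageTrack(layout, cfg.nuc_bin_size, vals))
        nucleosome[genotype] = reps

    bs = cfg.chip_bin_size
    enrich: dict[str, dict[str, np.ndarray]] = {WT: {}, MUTANT: {}}
    for chrom, length in layout.chromosomes:
        nb = -(-length // bs)
        e_wt = np.zeros(nb)
        for dom in truth.chip_domain_set:
            if dom.chrom == chrom:
                e_wt[dom.start // bs : (dom.end - 1) // bs + 1] += cfg.domain_log2
        e_mut = e_wt.copy()
        for ltr in features.get("LTR", ()):
            if ltr.chrom == chrom:
                e_mut[ltr.start // bs : (ltr.end - 1) // bs + 1] += cfg.ltr_enrichment
        enrich[WT][chrom] = e_wt
        enrich[MUTANT][chrom] = e_mut

    chip: dict[str, list[dict]] = {WT: [], MUTANT: []}
    for genotype in (WT, MUTANT):
        for r in range(cfg.n_chip_replicates):
            h3_vals, k9_vals = {}, {}
            for chrom, length in layout.chromosomes:
                nb = -(-length // bs)
                noise_h3 = rng.normal(0.0, cfg.chip_noise_sd, nb) if cfg.chip_noise_sd > 0 else 0.0
                noise_k9 = rng.normal(0.0, cfg.chip_noise_sd, nb) if cfg.chip_noise_sd > 0 else 0.0
                h3_vals[chrom] = cfg.chip_base_coverage * 2.0 ** np.asarray(noise_h3)
                h3_vals[chrom] = np.broadcast_to(h3_vals[chrom], (nb,)).astype(float).copy()
                k9_vals[chrom] = cfg.chip_base_coverage * 2.0 ** (
                    enrich[genotype][chrom] + np.asarray(noise_k9)
                )
            chip[genotype].append(
                {
                    "replicate": f"r{r + 1}",
                    "h3": CoverageTrack(layout, bs, h3_vals),
                    "k9": CoverageTrack(layout, bs, k9_vals),
                }
            )
    return {"nucleosome": nucleosome, "chip": chip}


@dataclass
class Bundle:
    """A complete synthetic (or loaded) input set for the pipeline."""

    layout: GenomeLayout
    features: dict[str, list]
    expression: pd.DataFrame
    coverage: dict
    truth: SyntheticTruth | None = None


def simulate_bundle(config: SimConfig | None = None, seed: int = 0) -> Bundle:
    config = config or SimConfig()
    layout, features, truth = simulate_genome(config, seed)
    expression = simulate_expression(truth, features)
    coverage = simulate_coverage(truth, layout, features["gene"], features)
    return Bundle(layout, features, expression, coverage, truth)


def write_bundle(bundle: Bundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the pipeline's on-disk input formats
    (GFF3/BED/TSV/bedGraph) so the real input path can be exercised."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["chrom_sizes"] = outdir / "chrom_sizes.tsv"
    with open(paths["chrom_sizes"], "w") as fh:
        for name, length in bundle.layout.chromosomes:
            fh.write(f"{name}\t{length}\n")

    paths["genes"] = outdir / "genes.gff3"
    write_gff3(paths["genes"], list(bundle.features["gene"]) + list(bundle.features.get("antisense", [])))
    paths["ltrs"] = outdir / "ltrs.bed"
    write_bed(paths["ltrs"], bundle.features["LTR"])
    paths["g4"] = outdir / "g4.bed"
    write_bed(paths["g4"], bundle.features["G4"])
    paths["repeats"] = outdir / "repeats.tsv"
    write_tandem_repeat_table(paths["repeats"], bundle.features["tandem_repeat"])
    paths["expression"] = outdir / "expression.tsv"
    bundle.expression.to_csv(paths["expression"], sep="\t", index=False)

    for genotype, reps in bundle.coverage["nucleosome"].items():
        for i, track in enumerate(reps):
            key = f"nuc_{genotype}_r{i + 1}"
            paths[key] = outdir / f"{key}.bedgraph"
            write_bedgraph(paths[key], track, precision=3)
    for genotype, reps in bundle.coverage["chip"].items():
        for rep in reps:
            for ab in ("h3", "k9"):
                key = f"chip_{genotype}_{rep['replicate']}_{ab}"
                paths[key] = outdir / f"{key}.bedgraph"
                write_bedgraph(paths[key], rep[ab], precision=3)
    return paths
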