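"""End-to-end orchestration: one reproducible run over a synthetic or
on-disk input bundle, producing a machine-readable report.

Stage order follows the data dependencies: DE-set construction feeds the
overlap/enrichment and distance stages; coverage tracks feed the
metagene and ChIP stages; the WT-defined enriched domains from the ChIP
stage feed the domain-overlap test.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import chip as chip_mod
from . import de as de_mod
from . import distance as dist_mod
from . import metagene as mg_mod
from . import overlap as ov_mod
from .io import (
    GenomeLayout,
    GenomicInterval,
    parse_gff3,
    read_bed,
    read_tandem_repeat_table,
    read_track,
)
from .simulate import MUTANT, WT, Bundle, SimConfig, simulate_bundle

log = logging.getLogger("genectx")

ALL_STAGES = ("de", "overlap", "distance", "metagene", "chip")


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and toggles for one pipeline run; serialisable."""

    seed: int = 0
    min_fc: float = 1.5
    max_fdr: float = 0.05
    expression_floor: float = 0.0
    tf2_prefix: str = "Tf2_"
    long_min_motif: int = 7
    merge_repeats: bool = True
    subtelomere_span: int = 100_000
    centromere_span: int = 40_000  # central span labelled centromeric per chromosome
    upstream: int = 1000
    downstream: int = 1500
    spacing_hint: float = 165.0
    ks_mode: str = "rows"
    pseudocount: float = 1.0
    z_threshold: float = 2.0
    min_domain_len: int = 2000
    domain_merge_gap: int = 1000
    flank: int = 1000
    body_bins: int = 20
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}")
        if not (self.min_fc >= 1 and 0 < self.max_fdr <= 1 and self.pseudocount > 0):
            raise ValueError("threshold out of documented range")


def default_centromeres(layout: GenomeLayout, span: int = 40_000) -> list[GenomicInterval]:
    """Central ``span`` bp of each chromosome, the positional stand-in
    for interior centromeres when no coordinates are configured."""
    out = []
    for chrom, length in layout.chromosomes:
        mid = length // 2
        half = min(span, length) // 2
        out.append(GenomicInterval(chrom, mid - half, mid + half, label="centromere", id=f"cen_{chrom}"))
    return out


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_bundle(bundle: Bundle, config: RunConfig | None = None) -> dict[str, Any]:
    """Execute every enabled stage on a bundle and return the report."""
    config = config or RunConfig()
    report: dict[str, Any] = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
        "significance": [],
    }
    sig = report["significance"]
    genes_by_id = {
        g.id: g
        for g in list(bundle.features["gene"]) + list(bundle.features.get("antisense", []))
    }

    table = None
    up = down = None
    if "de" in config.stages:
        try:
            table, up, down, de_info = _stage_de(bundle.expression, config)
        except Exception as exc:  # noqa: BLE001
            raise StageError("de", exc) from exc
        report["stages"]["de"] = de_info
        log.info("de: %d genes in, %d up, %d down", len(table), len(up), len(down))

    wt_domains: list | None = None
    if "chip" in config.stages:
        try:
            chip_info, wt_domains = _stage_chip(bundle, config)
        except Exception as exc:  # noqa: BLE001
            raise StageError("chip", exc) from exc
        report["stages"]["chip"] = chip_info
        log.info("chip: %d enriched domains called", chip_info["n_domains"])

    if "overlap" in config.stages and table is not None:
        try:
            report["stages"]["overlap"] = _stage_overlap(
                table, up, down, genes_by_id, bundle.layout, config, wt_domains, sig
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("overlap", exc) from exc

    if "distance" in config.stages and table is not None:
        try:
            report["stages"]["distance"] = _stage_distance(
                table, up, down, genes_by_id, bundle.features, config, sig
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("distance", exc) from exc

    if "metagene" in config.stages:
        try:
            report["stages"]["metagene"] = _stage_metagene(bundle, config, sig)
        except Exception as exc:  # noqa: BLE001
            raise StageError("metagene", exc) from exc
        mg = report["stages"]["metagene"]
        first = next(iter(bundle.coverage["nucleosome"]), None)
        if first is not None:
            log.info(
                "metagene: %d anchors, %d dropped",
                mg[first]["n_anchors"], mg[first]["n_dropped"],
            )

    return _jsonable(report)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_de(expression: pd.DataFrame, config: RunConfig):
    table = expression.copy()
    tf2_ids = [g for g in table["gene_id"] if str(g).startswith(config.tf2_prefix)]
    n_tf2 = len(tf2_ids)
    if n_tf2 > 1:
        table = de_mod.aggregate_tf2(table, tf2_ids)
        table = de_mod.recompute_statistics(table)
    table, excluded_counts = de_mod.exclude_biotypes(table)
    up, down = de_mod.call_de(
        table, min_fc=config.min_fc, max_fdr=config.max_fdr, expression_floor=config.expression_floor
    )
    table = de_mod.annotate_de_calls(table, up, down)
    info = {
        "n_input": int(len(expression)),
        "n_tf2_aggregated": n_tf2,
        "excluded_biotype_counts": excluded_counts,
        "n_tested": int(len(table)),
        "n_up": len(up),
        "n_down": len(down),
    }
    return table, up, down, info


def _stage_overlap(table, up, down, genes_by_id, layout, config, wt_domains, sig):
    universe = set(table["gene_id"])
    located = [genes_by_id[g] for g in universe if g in genes_by_id]
    domain_cfg = ov_mod.DomainConfig(
        subtelomere_span=config.subtelomere_span,
        centromeres=tuple(default_centromeres(layout, config.centromere_span)),
    )
    domains = ov_mod.assign_chromosomal_domains(located, layout, domain_cfg)
    de_ids = set(up.members) | set(down.members)
    info: dict[str, Any] = {"n_de": len(de_ids)}
    for name in ("subtelomeric", "centromeric"):
        res = ov_mod.chi2_domain_enrichment(de_ids, domains[name], universe)
        info[name] = {
            "table": [list(r) for r in res.table],
            "chi2": res.statistic,
            "p": res.p,
            "low_expected": res.low_expected,
        }
        sig.append({"stage": "overlap", "name": f"chi2_{name}", "p": res.p})

    if wt_domains is not None:
        dom_iv = [d.interval for d in wt_domains]
        in_dom = ov_mod.genes_in_domains(located, dom_iv)
        res = ov_mod.hypergeom_overlap(up.members, in_dom.members, universe)
        info["up_vs_enriched_domain_genes"] = dataclasses.asdict(res)
        sig.append({"stage": "overlap", "name": "hypergeom_up_vs_domains", "p": res.p})

    try:
        antisense_up = [
            genes_by_id[g] for g in up.members
            if g in genes_by_id and genes_by_id[g].label == "antisense"
        ]
        sense = [g for g in genes_by_id.values() if g.label != "antisense"]
        if antisense_up:
            info["antisense_convergent_fraction"] = de_mod.convergent_fraction(antisense_up, sense)
    except ValueError:
        pass
    return info


def _stage_distance(table, up, down, genes_by_id, features, config, sig):
    repeats = dist_mod.classify_repeats(
        features["tandem_repeat"], long_min_motif=config.long_min_motif, merge=config.merge_repeats
    )
    classes = {
        "LTR": list(features["LTR"]),
        "tandem_long": [r.interval for r in repeats if r.repeat_class == "long"],
        "tandem_short": [r.interval for r in repeats if r.repeat_class == "short"],
        "G4": list(features["G4"]),
    }
    universe = [genes_by_id[g] for g in table["gene_id"] if g in genes_by_id]
    de_ids = set(up.members) | set(down.members)
    fc = dict(zip(table["gene_id"], table["fold_change"]))
    info: dict[str, Any] = {}
    for cname, feats in classes.items():
        entry: dict[str, Any] = {"n_features": len(feats)}
        if feats:
            dists = dist_mod.nearest_distance(universe, feats)
            de_d = [dists[g.id] for g in universe if g.id in de_ids]
            nde_d = [dists[g.id] for g in universe if g.id not in de_ids]
            entry["n_missing"] = int(sum(np.isnan(list(dists.values()))))
            if len(de_d) >= 2 and len(nde_d) >= 2:
                summ = dist_mod.compare_distance_distributions(de_d, nde_d)
                entry.update(
                    de_median=summ.de_median,
                    nde_median=summ.nde_median,
                    statistic=summ.statistic,
                    p=summ.p,
                )
                sig.append({"stage": "distance", "name": f"mannwhitney_{cname}", "p": summ.p})
                de_fc = [fc[g.id] for g in universe if g.id in de_ids]
                try:
                    rho, rp = dist_mod.distance_fc_correlation(de_d, de_fc)
                    entry["fc_spearman_rho"] = rho
                    entry["fc_spearman_p"] = rp
                except ValueError:
                    pass
            else:
                entry["skipped"] = "fewer than 2 genes in a group"
        info[cname] = entry
    return info


def _stage_metagene(bundle: Bundle, config: RunConfig, sig):
    anchors = [g for g in bundle.features["gene"] if g.strand in ("+", "-")]
    profiles: dict[str, np.ndarray] = {}
    matrices: dict[str, list] = {}
    info: dict[str, Any] = {}
    for genotype, reps in bundle.coverage["nucleosome"].items():
        mats = [
            mg_mod.anchor_matrix(
                mg_mod.normalize_track_depth(t), anchors, config.upstream, config.downstream
            )
            for t in reps
        ]
        prof = mg_mod.mean_profile(mats)
        profiles[genotype] = prof
        matrices[genotype] = mats
        positions = mats[0].positions
        entry: dict[str, Any] = {
            "n_anchors": mats[0].n_loci,
            "n_dropped": mats[0].n_dropped,
            "n_replicates": len(mats),
        }
        try:
            m = mg_mod.profile_metrics(prof, positions, spacing_hint=config.spacing_hint)
            entry["metrics"] = dataclasses.asdict(m)
        except ValueError as exc:
            entry["metrics_error"] = str(exc)
        info[genotype] = entry
    genotypes = list(profiles)
    if len(genotypes) >= 2:
        a, b = genotypes[0], genotypes[1]
        if config.ks_mode == "rows":
            d, p = mg_mod.ks_profile_compare(matrices[a], matrices[b], mode="rows")
        else:
            d, p = mg_mod.ks_profile_compare(profiles[a], profiles[b], mode="values")
        info["ks"] = {"pair": [a, b], "D": d, "p": p}
        sig.append({"stage": "metagene", "name": f"ks_{a}_vs_{b}", "p": p})
    return info


def _stage_chip(bundle: Bundle, config: RunConfig):
    chip = bundle.coverage["chip"]
    ratios: dict[str, list[chip_mod.RatioTrack]] = {}
    for genotype, reps in chip.items():
        ratios[genotype] = [
            chip_mod.ratio_track(
                rep["k9"], rep["h3"], pseudocount=config.pseudocount,
                replicate=rep["replicate"], genotype=genotype,
            )
            for rep in reps
        ]
    wt_mean = _mean_ratio(ratios[WT])
    domains = chip_mod.call_enriched_domains(
        wt_mean, z_threshold=config.z_threshold,
        min_len=config.min_domain_len, merge_gap=config.domain_merge_gap,
    )

    info: dict[str, Any] = {
        "n_domains": len(domains),
        "domains": [
            {
                "chrom": d.interval.chrom,
                "start": d.interval.start,
                "end": d.interval.end,
                "mean_enrichment": d.mean_enrichment,
            }
            for d in domains
        ],
    }

    if MUTANT in ratios:
        wt_by_rep = {t.replicate: t for t in ratios[WT]}
        double = [
            chip_mod.normalize_to_wt(mt, wt_by_rep[mt.replicate]) for mt in ratios[MUTANT]
        ]
        double_mean = _mean_ratio(double)
        ltrs = list(bundle.features.get("LTR", ()))
        if ltrs:
            exclusions = [d.interval for d in domains]
            controls = chip_mod.matched_random_controls(
                ltrs, bundle.layout, exclusions, seed=np.random.default_rng(
                    np.random.SeedSequence([config.seed, 3])
                ),
            )
            summ = chip_mod.anchored_summary(
                double_mean, ltrs, controls, flank=config.flank, body_bins=config.body_bins
            )
            info["ltr_anchored"] = {
                "n_features": len(ltrs),
                "n_controls": len(controls),
                "n_dropped": summ.n_dropped,
                "center_excess": summ.center_excess,
                "feature_profile_mean": float(summ.feature_profile.mean()),
                "control_profile_mean": float(summ.control_profile.mean()),
            }
    return info, domains


def _mean_ratio(tracks: list[chip_mod.RatioTrack]) -> chip_mod.RatioTrack:
    first = tracks[0]
    out = first.track.copy()
    for chrom in out.values:
        out.values[chrom] = np.mean([t.track.values[chrom] for t in tracks], axis=0)
    return chip_mod.RatioTrack(out, first.pseudocount, replicate="mean", genotype=first.genotype)


# ---------------------------------------------------------------------------
# on-disk bundles and reports
# ---------------------------------------------------------------------------


def load_bundle(indir: str | Path) -> Bundle:
    """Load a bundle written by :func:`genectx.simulate.write_bundle`
    (or assembled by hand in the same layout)."""
    indir = Path(indir)
    pairs = []
    with open(indir / "chrom_sizes.tsv") as fh:
        for line in fh:
            if line.strip():
                name, length = line.split("\t")
                pairs.append((name, int(length)))
    layout = GenomeLayout(tuple(pairs))

    records = parse_gff3(indir / "genes.gff3", layout)
    genes = [g for g in records if g.label != "antisense"]
    antisense = [g for g in records if g.label == "antisense"]
    features = {
        "gene": genes,
        "antisense": antisense,
        "LTR": read_bed(indir / "ltrs.bed", layout, label="LTR"),
        "G4": read_bed(indir / "g4.bed", layout, label="G4"),
        "tandem_repeat": read_tandem_repeat_table(indir / "repeats.tsv"),
    }
    expression = pd.read_csv(indir / "expression.tsv", sep="\t")

    nucleosome: dict[str, list] = {}
    chip: dict[str, list] = {}
    for path in sorted(indir.glob("nuc_*_r*.bedgraph")):
        genotype = path.stem.split("_")[1]
        nucleosome.setdefault(genotype, []).append(read_track(path, layout, bin_size=1))
    by_key: dict[tuple[str, str], dict] = {}
    for path in sorted(indir.glob("chip_*_*.bedgraph")):
        _, genotype, rep, ab = path.stem.split("_")
        entry = by_key.setdefault((genotype, rep), {"replicate": rep})
        entry[ab] = read_track(path, layout, bin_size=50)
    for (genotype, _rep), entry in sorted(by_key.items()):
        chip.setdefault(genotype, []).append(entry)

    return Bundle(layout, features, expression, {"nucleosome": nucleosome, "chip": chip})


def run_synthetic(
    sim_config: SimConfig | None = None,
    run_config: RunConfig | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """Simulate a bundle and run every enabled stage on it."""
    run_config = run_config or RunConfig()
    if seed is None:
        seed = run_config.seed
    bundle = simulate_bundle(sim_config or SimConfig(), seed=seed)
    return run_bundle(bundle, run_config)


def file_checksums(paths: dict[str, Path]) -> dict[str, str]:
    out = {}
    for key, path in sorted(paths.items()):
        path = Path(path)
        if not path.is_file():
            continue
        out[key] = hashlib.md5(path.read_bytes()).hexdigest()
    return out


def write_report(report: dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    return obj
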