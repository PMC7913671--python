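"""Differential-expression set construction.

Turns per-gene expression statistics into DE gene sets using three
conditions: a >=1.5-fold change between conditions, FDR <= 0.05, and
detectable expression in every biological replicate of the higher
condition. Includes the aggregation rule for the near-identical Tf2
retrotransposon copies (replicate counts summed across all copies before
testing) and the tRNA/rRNA exclusion applied before set construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GenomicInterval

BIOTYPES = (
    "protein_coding",
    "ncRNA",
    "antisense",
    "pseudogene",
    "snoRNA",
    "snRNA",
    "tRNA",
    "rRNA",
    "retrotransposon",
)

#: columns of an expression table; replicate columns are cond1_r*/cond2_r*
CORE_COLUMNS = ("gene_id", "biotype", "fold_change", "p_value", "fdr", "de_call")

DEFAULT_EXCLUDED_BIOTYPES = frozenset({"tRNA", "rRNA"})


@dataclass(frozen=True)
class GeneSet:
    """A subset of a gene universe with a direction tag."""

    universe: frozenset[str]
    members: frozenset[str]
    direction: str = "none"  # "up", "down" or "none"

    def __post_init__(self) -> None:
        if not self.members <= self.universe:
            raise ValueError("GeneSet members must be a subset of the universe")

    def __len__(self) -> int:
        return len(self.members)


def replicate_columns(table: pd.DataFrame) -> tuple[list[str], list[str]]:
    c1 = sorted(c for c in table.columns if c.startswith("cond1_r"))
    c2 = sorted(c for c in table.columns if c.startswith("cond2_r"))
    return c1, c2


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    Raises ``ValueError`` on NaN or out-of-range input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_fdr")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log_t_test(values1: np.ndarray, values2: np.ndarray, pseudocount: float = 0.5) -> float:
    """Welch t-test on log2(x + pseudocount); the stand-in significance
    test for synthetic replicate tables (real dispersion modelling is
    upstream of this package)."""
    a = np.log2(np.asarray(values1, dtype=float) + pseudocount)
    b = np.log2(np.asarray(values2, dtype=float) + pseudocount)
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        return 1.0
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return float(1.0 if np.isnan(p) else p)


def recompute_statistics(table: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Recompute fold change, p-value and BH FDR from replicate columns
    (used after aggregation changes the rows being tested)."""
    c1, c2 = replicate_columns(table)
    out = table.copy()
    m1 = out[c1].mean(axis=1).to_numpy()
    m2 = out[c2].mean(axis=1).to_numpy()
    out["fold_change"] = (m2 + pseudocount) / (m1 + pseudocount)
    out["p_value"] = [
        log_t_test(row[c1].to_numpy(dtype=float), row[c2].to_numpy(dtype=float), pseudocount)
        for _, row in out.iterrows()
    ]
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    return out


def call_de(
    table: pd.DataFrame,
    min_fc: float = 1.5,
    max_fdr: float = 0.05,
    expression_floor: float = 0.0,
) -> tuple[GeneSet, GeneSet]:
    """Apply the three DE conditions and return (up, down) gene sets.

    A gene is up if fold change >= ``min_fc``, down if <= 1/``min_fc``;
    in either case FDR must be <= ``max_fdr`` and every replicate of the
    higher condition must exceed ``expression_floor`` ("expression
    observed in each biological replicate"). The table's ``de_call``
    column is set as a side effect on the returned copy via
    :func:`annotate_de_calls`.
    """
    c1, c2 = replicate_columns(table)
    if not c1 or not c2:
        raise ValueError("expression table lacks replicate columns (cond1_r*/cond2_r*)")
    if table[c1 + c2].isna().any().any():
        raise ValueError("missing replicate value in expression table")

    fc = table["fold_change"].to_numpy(dtype=float)
    fdr = table["fdr"].to_numpy(dtype=float)
    expr1 = (table[c1].to_numpy(dtype=float) > expression_floor).all(axis=1)
    expr2 = (table[c2].to_numpy(dtype=float) > expression_floor).all(axis=1)

    sig = fdr <= max_fdr
    up = sig & (fc >= min_fc) & expr2
    down = sig & (fc <= 1.0 / min_fc) & expr1

    universe = frozenset(table["gene_id"])
    ids = table["gene_id"].to_numpy()
    return (
        GeneSet(universe, frozenset(ids[up]), "up"),
        GeneSet(universe, frozenset(ids[down]), "down"),
    )


def annotate_de_calls(table: pd.DataFrame, up: GeneSet, down: GeneSet) -> pd.DataFrame:
    out = table.copy()
    out["de_call"] = [
        "up" if g in up.members else ("down" if g in down.members else "none")
        for g in out["gene_id"]
    ]
    return out


def aggregate_tf2(table: pd.DataFrame, tf2_ids: Sequence[str], merged_id: str = "Tf2") -> pd.DataFrame:
    """Collapse the Tf2 retrotransposon copies into one record by
    summing replicate values element-wise; the merged fold change is the
    ratio of summed condition means (recomputed, never averaged).

    The merged p-value is recomputed from the summed replicates; callers
    must re-adjust FDR over the whole table afterwards (see
    :func:`recompute_statistics`).
    """
    tf2_ids = list(tf2_ids)
    if not tf2_ids:
        raise ValueError("tf2_ids is empty")
    missing = set(tf2_ids) - set(table["gene_id"])
    if missing:
        raise ValueError(f"tf2 ids absent from table: {sorted(missing)}")

    c1, c2 = replicate_columns(table)
    mask = table["gene_id"].isin(tf2_ids)
    group = table[mask]
    merged = {col: group[col].sum() for col in c1 + c2}
    merged["gene_id"] = merged_id
    merged["biotype"] = "retrotransposon"
    s1 = np.array([merged[c] for c in c1], dtype=float)
    s2 = np.array([merged[c] for c in c2], dtype=float)
    merged["fold_change"] = s2.mean() / s1.mean() if s1.mean() > 0 else np.inf
    merged["p_value"] = log_t_test(s1, s2)
    merged["fdr"] = np.nan  # requires re-adjustment over the full table
    merged["de_call"] = "none"

    rest = table[~mask]
    merged_row = pd.DataFrame([merged]).reindex(columns=table.columns)
    return pd.concat([rest, merged_row], ignore_index=True)


def exclude_biotypes(
    table: pd.DataFrame,
    excluded: Iterable[str] = DEFAULT_EXCLUDED_BIOTYPES,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop records of the excluded biotypes (default tRNA and rRNA,
    removed for paralogue cross-mapping and rRNA-depletion artefacts);
    returns the filtered table and per-biotype removal counts."""
    excluded = set(excluded)
    mask = table["biotype"].isin(excluded)
    counts = table.loc[mask, "biotype"].value_counts().to_dict()
    return table[~mask].reset_index(drop=True), {str(k): int(v) for k, v in counts.items()}


# ---------------------------------------------------------------------------
# convergent-gene fraction for antisense transcripts
# ---------------------------------------------------------------------------


def convergent_pairs(
    genes: Sequence[GenomicInterval], max_gap: int = 1000
) -> frozenset[str]:
    """IDs of genes belonging to a convergent pair: adjacent genes on
    opposite strands whose 3' ends face each other with an intergenic
    gap <= ``max_gap`` (overlapping 3' ends count as gap 0)."""
    convergent: set[str] = set()
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: (g.start, g.end))
        for a, b in zip(chrom_genes, chrom_genes[1:]):
            if a.strand == "+" and b.strand == "-" and b.start - a.end <= max_gap:
                convergent.add(a.id)
                convergent.add(b.id)
    return frozenset(convergent)


def convergent_fraction(
    antisense: Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
    max_gap: int = 1000,
) -> float:
    """Fraction of antisense transcripts whose sense gene lies in a
    convergent pair.

    The sense gene of an antisense transcript is the opposite-strand
    gene with the largest overlap. Antisense records with no overlapping
    opposite-strand gene are excluded from the denominator; an empty
    antisense set (or none mappable) is an error since the fraction is
    undefined.
    """
    if len(antisense) == 0:
        raise ValueError("convergent_fraction undefined for an empty antisense set")
    conv = convergent_pairs(genes, max_gap=max_gap)
    n_mapped = 0
    n_convergent = 0
    for a in antisense:
        best, best_len = None, 0
        for g in genes:
            if g.strand in ("+", "-") and a.strand in ("+", "-") and g.strand != a.strand:
                ov = a.overlap_length(g)
                if ov > best_len:
                    best, best_len = g, ov
        if best is None:
            continue
        n_mapped += 1
        if best.id in conv:
            n_convergent += 1
    if n_mapped == 0:
        raise ValueError("no antisense transcript maps to a sense gene")
    return n_convergent / n_mapped


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------


def qpcr_relative(
    ct_table: pd.DataFrame,
    reference_genes: Sequence[str] = ("act1", "tbp1"),
    control_condition: str = "control",
) -> pd.Series:
    """Per-gene expression relative to the control condition by
    2^(-ddCt), with dCt taken against the arithmetic mean Ct of the
    reference genes (equivalently, the geometric mean of their
    expression levels).

    ``ct_table`` needs columns ``gene``, ``condition``, ``ct``;
    replicate rows are averaged. Returns a Series indexed by gene for
    every non-reference gene, for every non-control condition (a
    MultiIndex (gene, condition) if several conditions are present).
    """
    for col in ("gene", "condition", "ct"):
        if col not in ct_table.columns:
            raise ValueError(f"ct_table missing column {col!r}")
    mean_ct = ct_table.groupby(["condition", "gene"])["ct"].mean()
    conditions = ct_table["condition"].unique()
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} absent")

    def ref_mean(cond: str) -> float:
        try:
            return float(np.mean([mean_ct[(cond, r)] for r in reference_genes]))
        except KeyError as exc:
            raise ValueError(f"reference gene {exc.args[0]!r} missing in condition {cond!r}") from None

    targets = [g for g in ct_table["gene"].unique() if g not in reference_genes]
    rows = {}
    for cond in conditions:
        if cond == control_condition:
            continue
        d_ref_ctrl = ref_mean(control_condition)
        d_ref_cond = ref_mean(cond)
        for gene in targets:
            if (cond, gene) not in mean_ct or (control_condition, gene) not in mean_ct:
                raise ValueError(f"gene {gene!r} missing Ct in one condition")
            dct_cond = mean_ct[(cond, gene)] - d_ref_cond
            dct_ctrl = mean_ct[(control_condition, gene)] - d_ref_ctrl
            rows[(gene, cond)] = 2.0 ** (-(dct_cond - dct_ctrl))
    result = pd.Series(rows, name="relative_level")
    n_other = len([c for c in conditions if c != control_condition])
    if n_other == 1:
        result.index = [g for g, _ in result.index]
    return result
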