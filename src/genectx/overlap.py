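"""Gene-set overlap significance and chromosomal-domain enrichment.

Overlap between two gene lists is scored with the upper-tail
hypergeometric test: k successes (genes in both sets) in n draws (set 1)
from a population of N genes containing K members of set 2. Positional
enrichment (subtelomeric / centromeric) is a 2x2 chi-squared contingency
test of DE membership against domain membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .de import GeneSet
from .io import GenomeLayout, GenomicInterval, ValidationError


@dataclass(frozen=True)
class OverlapResult:
    """The hypergeometric quadruple and its upper-tail probability."""

    k: int
    n: int
    K: int
    N: int
    p: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K) and max(self.n, self.K) <= self.N):
            raise ValueError(f"inconsistent hypergeometric counts {self}")


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 chi-squared result for DE-set x domain membership."""

    table: tuple[tuple[int, int], tuple[int, int]]  # rows: in/out set; cols: in/out domain
    statistic: float
    dof: int
    p: float
    low_expected: bool = False  # any expected cell < 1


def hypergeom_overlap(
    set1: Iterable[str], set2: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """Exact upper-tail P(X >= k) for the overlap of two gene sets.

    Both sets are intersected with the universe first, so only genes
    included in both analyses are compared.
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    s1 = frozenset(set1) & uni
    s2 = frozenset(set2) & uni
    k, n, K, N = len(s1 & s2), len(s1), len(s2), len(uni)
    # survival function at k-1 gives P(X >= k); scipy sums exact pmf terms
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapResult(k=k, n=n, K=K, N=N, p=min(p, 1.0))


def genes_in_domains(
    genes: Sequence[GenomicInterval],
    domains: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> GeneSet:
    """Genes overlapping any domain by at least ``min_overlap`` bp
    (half-open intervals: abutting features share no base)."""
    members = set()
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    for g in genes:
        for d in by_chrom.get(g.chrom, ()):
            if g.overlap_length(d) >= min_overlap:
                members.add(g.id)
                break
    return GeneSet(frozenset(g.id for g in genes), frozenset(members))


def chi2_domain_enrichment(
    de_set: GeneSet | Iterable[str],
    domain_gene_set: GeneSet | Iterable[str],
    universe: Iterable[str],
    continuity_correction: bool = True,
) -> EnrichmentResult:
    """Chi-squared (df=1, Yates correction by default) on the 2x2 table
    of DE membership x domain membership over the shared universe."""
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    de = frozenset(de_set.members if isinstance(de_set, GeneSet) else de_set) & uni
    dom = frozenset(
        domain_gene_set.members if isinstance(domain_gene_set, GeneSet) else domain_gene_set
    ) & uni
    a = len(de & dom)
    b = len(de - dom)
    c = len(dom - de)
    d = len(uni) - a - b - c
    table = ((a, b), (c, d))
    arr = np.array(table, dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        # degenerate margin: no association measurable
        return EnrichmentResult(table, 0.0, 1, 1.0, low_expected=True)
    chi2, p, dof, expected = stats.chi2_contingency(arr, correction=continuity_correction)
    return EnrichmentResult(table, float(chi2), int(dof), float(p), bool((expected < 1).any()))


@dataclass(frozen=True)
class DomainConfig:
    """Positional domain definitions over a genome layout.

    ``subtelomere_span`` bp from each end of the chromosomes named in
    ``subtelomere_chroms`` (default: the first two, matching the two
    fission-yeast chromosomes with canonical subtelomeric
    heterochromatin; chromosome III ends in rDNA arrays instead).
    Centromere intervals are configuration, not computed.
    """

    subtelomere_span: int = 100_000
    subtelomere_chroms: tuple[str, ...] | None = None
    centromeres: tuple[GenomicInterval, ...] = ()

    def subtelomere_intervals(self, layout: GenomeLayout) -> list[GenomicInterval]:
        chroms = self.subtelomere_chroms
        if chroms is None:
            chroms = layout.names[: min(2, len(layout.names))]
        out = []
        for chrom in chroms:
            if chrom not in layout:
                raise ValidationError(f"subtelomere chromosome {chrom!r} not in layout")
            length = layout.length(chrom)
            span = min(self.subtelomere_span, length)
            out.append(GenomicInterval(chrom, 0, span, label="subtelomere", id=f"{chrom}_subtel_L"))
            if length > span:
                out.append(
                    GenomicInterval(chrom, length - span, length, label="subtelomere", id=f"{chrom}_subtel_R")
                )
        return out


def assign_chromosomal_domains(
    genes: Sequence[GenomicInterval],
    layout: GenomeLayout,
    config: DomainConfig | None = None,
) -> dict[str, GeneSet]:
    """Label each gene subtelomeric / centromeric / other (any overlap
    counts; subtelomere wins if a gene touches both)."""
    config = config or DomainConfig()
    for cen in config.centromeres:
        cen.validate(layout)
    subtel = genes_in_domains(genes, config.subtelomere_intervals(layout))
    centro = genes_in_domains(genes, list(config.centromeres)) if config.centromeres else GeneSet(
        frozenset(g.id for g in genes), frozenset()
    )
    universe = frozenset(g.id for g in genes)
    centro_only = centro.members - subtel.members
    other = universe - subtel.members - centro_only
    return {
        "subtelomeric": GeneSet(universe, subtel.members),
        "centromeric": GeneSet(universe, frozenset(centro_only)),
        "other": GeneSet(universe, frozenset(other)),
    }
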