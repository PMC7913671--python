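# genectx

Genomic-context analysis of differentially expressed (DE) gene sets in
fission yeast, built for studies that ask *where* misregulated genes sit
in the genome rather than just *which* genes move. The package turns
per-gene expression statistics, annotations and coverage tracks into a
reproducible battery of context analyses:

- **DE-set construction** with the field's compound rule — fold change
  ≥ 1.5, FDR ≤ 0.05 (Benjamini–Hochberg), and detectable expression in
  every replicate of the higher condition — plus the aggregation rule
  for near-identical retrotransposon copies (Tf2 replicate counts
  summed across all 13 copies before testing) and tRNA/rRNA exclusion.
- **Gene-set overlap significance** by the exact upper-tail
  hypergeometric test: for an overlap of *k* genes between a set of *n*
  and a set of *K* drawn from a shared universe of *N*,
  *P* = P(X ≥ k), X ~ Hypergeom(N, K, n).
- **Chromosomal-domain enrichment** (subtelomeric = 100 kb from each
  end of chromosomes I and II; centromeres from configuration) by a
  2×2 chi-squared contingency test with Yates correction.
- **Distance-to-feature statistics**: tandem repeats classed by motif
  length (short < 7 bp ≤ long), interval-gap distance from each gene to
  the nearest LTR / tandem-repeat / G-quadruplex feature, DE vs NDE
  compared by two-sided Mann–Whitney U, and Spearman correlation of
  distance with fold change.
- **TSS metagene profiles** from MNase-type occupancy tracks:
  strand-oriented anchored matrices, replicate-averaged mean profiles,
  NDR position/depth/width and −2/−1/+1 peak quantification, and a
  Kolmogorov–Smirnov comparison between genotypes.
- **ChIP ratio analysis**: per-bin log2(H3K9me2/H3) with a pseudocount,
  mutant-minus-WT double normalisation per biological replicate,
  heterochromatin-domain calling (median + z·MAD threshold), and
  LTR-anchored scaled-body matrices scored against matched random
  control loci (same count, lengths and chromosomes).

A first-class synthetic-data generator (`genectx.simulate`) produces a
3 Mb toy genome with genes, LTRs, tandem repeats, G4 motifs, replicate
expression tables, phased nucleosome tracks and paired ChIP tracks with
*known planted structure*, so the whole pipeline is testable end to end
without any downloads.

## Worked example

```python
import genectx as gx

bundle = gx.simulate_bundle(seed=1)          # default study conditions
report = gx.run_bundle(bundle, gx.RunConfig(seed=1))

st = report["stages"]
print(st["de"]["n_up"], "genes up of", st["de"]["n_tested"], "tested")
print("DE median distance to LTR:", st["distance"]["LTR"]["de_median"], "bp")
print("NDE median distance to LTR:", st["distance"]["LTR"]["nde_median"], "bp")
print("Mann-Whitney p:", st["distance"]["LTR"]["p"])
print("WT enriched domains:", st["chip"]["n_domains"])
print("LTR centre excess:", round(st["chip"]["ltr_anchored"]["center_excess"], 3), "log2")
```

prints

```
54 genes up of 588 tested
DE median distance to LTR: 6391.5 bp
NDE median distance to LTR: 16138.0 bp
Mann-Whitney p: 6.0095135956286776e-05
WT enriched domains: 5
LTR centre excess: 1.002 log2
```

Reading: of 588 tested loci (650 simulated records, minus tRNA/rRNA and
with the 13 Tf2 copies collapsed to one), 54 are called up. Upregulated
genes sit at a median 6.4 kb from the nearest LTR versus 16.1 kb for
unchanged genes — the planted proximity bias, detected at
p ≈ 6×10⁻⁵. The five wild-type H3K9me2-enriched domains are exactly the
five planted heterochromatin blocks, and the mutant's LTR-local gain is
recovered as a centre excess of 1.00 log2 over matched random controls
(planted value: 1.0).

The same analyses run from the shell on on-disk inputs
(GFF3/BED/TSV/bedGraph):

```bash
genectx simulate --seed 1 --out bundle/
genectx run-all --bundle-dir bundle/ --seed 1 --out report.json
genectx de-call bundle/expression.tsv --min-fc 1.5 --max-fdr 0.05
```

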