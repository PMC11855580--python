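# pepperbsa

Bulked-segregant analysis (BSA-seq) of immature-fruit color in pepper
(*Capsicum annuum*), packaged as a tested, fully simulatable pipeline.

Green versus yellow pericarp at the mature-green stage is a
chlorophyll-driven quantitative trait. In an F2 of 423 plants from a
green × yellow cross it segregates into six color grades and maps to two
loci: a major *CaGLK2*-like locus on chromosome 10 and a minor
*CaAPRR2*-like locus on chromosome 1, acting with dominant and additive
effects. `pepperbsa` implements every computational stage of that
mapping study and a forward simulator of the cross, so the whole
analysis can be exercised and verified without any sequencing data.

## What it computes

For each parental-informative marker (homozygous in both parents,
different alleles), with read depths from an extreme-yellow bulk D1 and
an extreme-green bulk D2:

* **SNP/InDel index** — the fraction of a bulk's reads carrying the
  yellow-parent allele; **Δ index** = |index(D1) − index(D2)|, which
  approaches 1 near a causal locus and 0 elsewhere.
* **ED²** — squared Euclidean distance between the bulks' nucleotide
  frequency vectors (A, C, G, T), an orientation-free analogue.

Per-site values are averaged in 3 Mb sliding windows stepping 300 kb,
smoothed with LOESS, thresholded at the top 1% of window values per
chromosome, and merged into candidate intervals. Around the scan sit:

* `f2sim` — forward F2 simulation: Haldane meiosis (Poisson crossovers,
  no interference), a two-locus genotype → green-score → grade color
  model, extreme-bulk selection (13 yellow / 20 green), and pooled
  sequencing as Poisson depth + binomial allele sampling.
* `varianteffect` — CDS consequence annotation (synonymous / missense /
  stop-gained) with truncated-protein lengths and domain overlap.
* `phenostats` — the green index 2G − R − B, chlorophyll quantification
  (Ca = 13.95·D665 − 6.8·D649, Cb = 24.96·D649 − 7.32·D665,
  Ct = 18.16·D649 + 6.63·D665, content = C·V·D/W), normality reports
  (mean, SD, adjusted skewness/kurtosis, Shapiro–Wilk), genotype × grade
  tables, segregation chi-square and accession-panel association
  (odds ratio + Fisher exact).

## Worked example

Simulate the default study (2 × 50 Mb chromosomes, 50 markers/Mb,
n = 423, bulks 13/20, mean depth 40×) and scan it:

```sh
pepperbsa all --out-dir demo --seed 42 --verbose
```

which logs, among other stages:

```
INFO pepperbsa.bsascan: delta_index: 2 candidate interval(s), thresholds {'chr1': 0.8371, 'chr10': 0.9394}
INFO pepperbsa: interval delta_index chr1:17100001-20400001 peak 0.8380
INFO pepperbsa: interval delta_index chr10:15000001-18300001 peak 0.9410
INFO pepperbsa.bsascan: delta-index / ED^2 interval concordance (Jaccard): 0.833
```

Both called Δ-index intervals contain their true simulated causal
positions (chr10:16,450,000 major, chr1:17,650,000 minor — recorded in
`demo/truth.json`), the Δ-index peaks (0.94, 0.84) reflect near-fixation
of the bulks for opposite parental alleles, and the ED² intervals agree
with the Δ-index intervals (Jaccard 0.83). `demo/` also contains the
per-site and per-window tracks (TSV), candidate intervals (BED,
0-based half-open), the phenotype table, a grade-distribution report
and a `manifest.json` echoing the full effective configuration and seed.

Library use mirrors the CLI:

```python
import pepperbsa as pb

pop, bulks, table = pb.simulate_dataset(seed=42)
filtered = pb.filter_parental_informative(table)
result = pb.run_scan(filtered)
print(result.intervals_delta)
```

Phenotype-side example — the six grade counts of the real F2
(16, 12, 54, 149, 159, 33 plants from yellow to green):

```python
>>> rep = pb.normality_report([16, 12, 54, 149, 159, 33])
>>> round(rep.mean, 3), round(rep.sd, 3), round(rep.skewness, 3)
(70.5, 66.431, 0.775)
>>> round(rep.kurtosis, 3), round(rep.w, 3)
(-1.868, 0.81)
```

i.e. the grade distribution is compatible with normality, the signature
of a polygenic trait.

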