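# panploid

Analyses for plant pangenomes and allopolyploid subgenome evolution, built
around the kind of multi-genome study done for water caltrop (*Trapa*):
several diploid genomes plus the two subgenomes of an allotetraploid,
compared for gene content, structural variation and expression.

It is a library plus a `panploid` CLI for people who already have the heavy
upstream products — orthogroup tables, windowed depth tracks, SV calls,
expression counts — and need the downstream population/comparative analyses
to be reproducible and testable:

* **Pangenome classification.** With *N* accessions, a gene cluster present
  in all *N* is *core*, in exactly 1 is *private*, in 2..*N*−1 is
  *dispensable*; the three labels partition the cluster set. Pan/core
  saturation curves average the union/intersection cluster counts over
  genome subsets of each size (exhaustive when feasible, uniform subset
  sampling otherwise), and per-genome composition propagates cluster labels
  to gene level.
* **Homeologous-exchange (HE) calling.** From mean read depth in 10-kb
  non-overlapping windows: windows ≥ 1.5× the genome mean are duplication
  candidates, ≤ 0.25× are deletion candidates; same-kind windows within
  50 kb are linked and merged segments longer than 80 kb are kept. A
  duplication on one parental genome that reciprocally overlaps (via a
  syntenic interval map) a deletion on the other becomes a directional HE
  call, donor → recipient.
* **PAV analysis.** Presence–absence variants (≥ 50 bp insertions or
  deletions) are merged into a non-redundant set, filtered, tested for
  fixed differences between two lineages, annotated to genes within a 2-kb
  cis flank, and scored for DEG enrichment with a permutation test
  (p = (1 + #{null ≥ obs}) / (n_perm + 1)).
* **Homeolog expression bias (HEB).** Counts are normalized by
  median-of-ratios (RLE): factor_j = median_g count_gj / (∏_k count_gk)^(1/n).
  Per homeolog pair and tissue, log2FC = log2((mean B + 0.5)/(mean A + 0.5))
  with a two-sided paired test on per-replicate log ratios (exact sign
  permutation for ≤ 6 replicates), BH-FDR across pairs, biased iff
  q < 0.05. Chromosome-level direction uses a Wilcoxon test of per-pair
  log2FC against zero.
* **Molecular evolution.** Nei–Gojobori (1986) Ka/Ks with pathway averaging
  and Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3); LTR insertion ages
  T = K/(2μ); TE-family size contrasts between lineages.
* **Synthetic data.** Every input can be simulated with exact ground truth
  (`panploid.simulate`), so the whole pipeline is testable without any
  sequencing data.

## Worked example

Classify a simulated 500-cluster orthogroup matrix and print the category
breakdown:

```sh
panploid sim --kind orthogroups --out-prefix og --seed 1 --n-clusters 500
panploid classify og.orthogroups.tsv --out classes.tsv
```

```
   category  n_clusters  percent
       core         240     48.0
dispensable         145     29.0
    private         115     23.0
   variable         260     52.0
      total         500    100.0
```

`variable` is the dispensable + private share — the headline figure for
gene-content variability. From raw published-style counts directly:

```sh
panploid classify-summary --core 18859 --dispensable 11352 --private 9041
```

```
   category  n_clusters    percent
       core       18859  48.045959
dispensable       11352  28.920819
    private        9041  23.033221
   variable       20393  51.954041
      total       39252 100.000000
```

Call an HE from a pair of simulated depth tracks (a 100-kb duplication on
parent B matched by a deletion on parent A) — the caller reports one
B→A exchange of 0.1 Mb:

```sh
panploid hecall --depth-a a.bed --depth-b b.bed --map map.tsv --out-prefix he1
```

```
direction  n_calls  total_bp  total_mb
     B->A        1    100000       0.1
unresolved segments: 0
```

NG86 Ka/Ks on a simulated codon alignment with 3 implanted synonymous and
3 nonsynonymous changes recovers the counts exactly (`Sd = Nd = 3`):

```sh
panploid sim --kind seqpair --out-prefix sq --seed 4 --n-syn 3 --n-nonsyn 3
panploid kaks sq.fasta --out kaks.tsv
```

```
pair    Ka       Ks       Ka_Ks    Sd   Nd   S     N
pair0_1 0.04479  0.15848  0.28262  3.0  3.0  21.0  69.0
```

Other subcommands: `saturate`, `pav-filter`, `pav-lineage`, `pav-annotate`,
`permtest`, `heb`, `chrom-bias`, `deg`, `ltrage`, `tediff`. Every
stochastic subcommand takes `--seed`; thresholds can come from a YAML
config (`RunConfig`) or per-command flags.

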