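# Methods

This note documents the models and procedures panploid implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the problem was genuinely
open.

## Coordinates and containers

All in-memory coordinates are 0-based half-open (BED convention); GFF3 is
converted at the I/O boundary (1-based closed on disk) and is the only
place that convention appears. PAV genotypes carry an explicit MISSING
code; nothing imputes them — each downstream filter decides how to treat
missingness, and its rule is stated on the function.

## Pangenome classification and saturation

With presence defined as ≥ 1 gene of a cluster in an accession, labels are
assigned by presence count *n* out of *N* accessions: *n* = *N* → core,
*n* = 1 → private, 2 ≤ *n* ≤ *N*−1 → dispensable. The common verbal
definition of dispensable ("missing in at least one accession") overlaps
the private class; the 2..*N*−1 reading is used so that the three
categories partition the cluster set and the summary percentages are
additive.

Saturation curves evaluate, for each subset size *k*, the pan count
(clusters present in ≥ 1 subset member) and core count (present in all
members) over genome subsets: all C(*N*, *k*) subsets when that number is
at most `max_exhaustive` (default 1000), otherwise `n_samples` uniform
draws (default 200). Averaging is over subsets, not orderings — with
per-*k* means the two conventions coincide, and subsets are cheaper. The
`exhaustive` flag is carried in the output so consumers know which mode
produced each row. SDs are population SDs over the evaluated subsets.

Category comparisons (CDS length, expression, Ka/Ks) use the two-sided
Wilcoxon rank-sum test: exact enumeration when the combined sample is
≤ 20 without ties, otherwise the tie-corrected normal approximation.

## HE calling

Inputs are windowed mean-depth tracks (default 10-kb non-overlapping
windows) for the two parental genomes, both produced by mapping the
allotetraploid's reads to the concatenated parents upstream. The genome
mean is length-weighted. Thresholds:

| parameter | default | meaning |
|---|---|---|
| `dup_factor` | 1.5 | window ≥ 1.5 × mean → duplication candidate (inclusive) |
| `del_factor` | 0.25 | window ≤ 0.25 × mean → deletion candidate (inclusive) |
| `link_gap_bp` | 50 000 | same-kind windows with gap ≤ 50 kb are linked |
| `min_he_len_bp` | 80 000 | merged segments must be **strictly** longer |

The duplication threshold is inclusive so the stated factor is itself
actionable; "low or no coverage" for deletions is quantified as ≤ 0.25×
(configurable — no canonical number exists); the length rule reads
"extended beyond 80 kb" literally, so an exactly-80-kb segment is
discarded; the gap is measured end-of-run to start-of-next, making a
50-kb gap (five 10-kb windows) the boundary case that still links.

Pairing into directional calls requires an explicit homeolog interval map
(syntenic blocks between the parents; coordinates project affinely within
a block). A duplication whose projection reciprocally overlaps a deletion
on the partner genome by ≥ 0.5 (both directions, configurable) yields one
HE with direction donor → recipient and length equal to the recipient
deletion. Segments that pair with nothing are reported separately as
unresolved rather than dropped, since depth alone cannot distinguish an
HE from an ordinary CNV.

## PAV analysis

Merging is greedy in input order: records merge iff same SV type and
chromosome, start positions within `pos_tol_bp` (default 1000) and
min/max length ratio ≥ `size_ratio` (default 0.8); the first-seen record
keeps its coordinates and genotypes take the union with
present > absent > missing. The tolerances are declared defaults, not
inferred from any published pipeline, and the operation is idempotent.

Filtering drops records with missing fraction > `max_missing` (default
0.2) or minor presence-frequency < `min_minor_freq` (default 0, i.e. off),
frequencies over non-missing genotypes.

Lineage differentiation reports records with |freq_A − freq_B| ≥
`min_freq_diff`, default 1.0 (a fixed difference). With only ~3 samples
per lineage, fixation is the only call robust to a single mis-genotyped
sample; the threshold is surfaced for larger designs.

Gene annotation associates a PAV with every gene whose interval extended
by `cis_flank_bp` (default 2000) on **both** sides it overlaps; the flank
is strand-agnostic because the rule is "upstream and downstream".

The DEG-overlap permutation test draws |target| genes uniformly without
replacement from the universe and uses the add-one estimator
p = (1 + #{null ≥ obs}) / (n_perm + 1), so p is never zero and the test
is conservative (super-uniform under the null).

## Expression normalization and tests

RLE size factors: reference = per-gene geometric mean over samples,
computed on genes positive in every sample; factor = median ratio to the
reference. Factors are defined up to a common scale; ratios between
factors are scale-equivariant. If no gene is positive everywhere the
function fails loudly and suggests a pseudo-reference.

Per-pair HEB: log2FC = log2((mean normalized B + c)/(mean normalized A +
c)) with pseudocount c = 0.5 (configurable) to absorb zeros. The p-value
comes from a two-sided paired test on per-replicate log2 ratios: exact
sign permutation when the tissue has ≤ 6 replicates, one-sample t
otherwise. BH correction is applied across pairs within each tissue;
biased ⇔ q < α (default 0.05). With 3 replicates the sign-permutation
p-value cannot go below 0.25, so *counts* of biased pairs at α = 0.05 are
conservative at that depth — detection performance is therefore assessed
by ranking pairs on |log2FC| (ROC AUC against simulated truth), which
does not depend on the p-value floor. A full negative-binomial GLM was
deliberately not used: the package's validation surface is recovery of
simulated truth, and a paired test on log ratios of RLE-normalized counts
is sufficient, exactly specifiable and brute-force checkable.

Tissue breadth counts pairs biased in ≥ 1 tissue and in all tissues;
pairs with an undefined p in some tissue are excluded from the "all
tissues" count only.

Chromosome-level bias: one-sample Wilcoxon signed-rank of per-pair log2FC
against zero, per chromosome pair and genome-wide; direction follows the
median sign. The two-sample rank-sum variant (B-homeolog means vs
A-homeolog means) is also implemented (`mode="ranksum"`); the paired form
is the default because the data are paired by construction.

DEGs between sample groups are tested on log2(normalized + 0.5) with a
moderated t-test: the per-gene pooled variance is shrunk toward the
median variance across genes with a fixed prior of 4 degrees of freedom
(a simplified empirical-Bayes scheme in the spirit of limma). Per-gene
Welch t at 3 vs 3 replicates has essentially no power after FDR
correction; sharing variance information across genes is the standard
remedy in this field. Plain Welch (`method="t"`) and exact label
permutation (`method="permutation"`) remain available.

## Molecular evolution

NG86 Ka/Ks. Synonymous sites per codon are 3 × (synonymous fraction of
the nine single-nucleotide mutations), averaged over the two sequences;
mutations creating stops count as nonsynonymous in site counting, which
keeps S + N = 3 × codons exactly. Differences in multi-hit codons are
averaged over all orderings of single steps with equal weight; orderings
passing through a stop codon are excluded and the weights renormalized
(if every ordering crosses a stop, all are used). Proportions pS = Sd/S
and pN = Nd/N each receive the Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3); p ≥ 0.75 maps to an infinite distance and
Ka/Ks is flagged undefined whenever Ks = 0 or a distance is infinite.
NG86 was chosen because it is fully specifiable and has an exhaustively
enumerable oracle; only the universal genetic code is supported.

LTR ages. The two LTRs of an element are identical at insertion, so their
JC69 distance K dates it: T = K/(2μ). The substitution rate μ is a
**required** parameter with no default — any default would silently
fabricate ages.

TE contrasts. Per family, the difference of mean total length between the
A- and B-lineage genomes; flagged when |difference| ≥ 10 kb (inclusive).

## Synthetic data: what it emulates and what it does not

All generators are deterministic given a seed and return a truth object
whose consistency with the emitted data is tested by re-derivation.

* **Orthogroup matrices** place core clusters everywhere, private
  clusters in one uniform accession, dispensable clusters in k
  accessions with k uniform on [2, N−1]; present cells carry
  1 + Poisson(0.3) genes. Real orthogroup inference noise (fragmented
  gene models, paralog collapse) is not modeled, so truth-recovery tests
  validate the classification rule, not robustness to clustering error.
* **Depth tracks** draw windows from a normal distribution clipped at
  zero (background at the base depth, duplications at 2×, deletions at
  0.05×). Normal rather than Poisson noise because the caller thresholds
  window means, so only location and scale matter; deletions sit at a
  small residual depth, not zero, so the deletion threshold is genuinely
  exercised. Mappability artifacts and GC waves are not simulated. The
  packaged validation sweep uses a 20-Mb genome, 10-kb windows, base
  depth 30, noise SD 3, and one duplication plus one deletion of
  90–500 kb per replicate. At these settings a deletion window exceeds
  the 0.25× threshold with probability ~0.02, so a 9-window (90-kb)
  implant occasionally loses an end window and falls under the strict
  80-kb rule — the expected behavior of the stated thresholds, visible
  as a recovery rate slightly under 100% for some seeds.
* **PAV matrices** fix a chosen fraction of records as present in one
  lineage and absent in the other (direction by fair coin); the rest
  share a uniform presence probability across all samples, with draws
  that would mimic a fixed difference redrawn so the truth set is exact.
  Missingness is applied uniformly at random, not clustered by sample.
* **Homeolog counts** are negative binomial (variance m + α·m²) with
  per-pair log-uniform base means (5–500 by default); biased pairs
  multiply the B-homeolog mean by 2^log2fc in every tissue. Real
  tissue-specific bias, batch effects and library-size drift are not
  modeled (size factors are still estimated, not assumed).
* **Sequence pairs** apply exactly the requested synonymous and
  nonsynonymous single-nucleotide changes in distinct codons of a random
  stop-free sequence, so pathway counting has a closed truth; multi-hit
  codons arise only in separately generated random pairs.

## Numerical choices

Exact tests switch to approximations at conventional sizes (rank-sum:
combined n > 20 or ties; signed-rank: scipy's auto rule; sign
permutation: > 6 replicates). BH q-values pass NaN p-values through
untouched. Tie comparisons in permutation tests use a 1e-12 slack so
floating-point noise cannot break ties inconsistently. All stochastic
functions take explicit seeds; nothing reads global RNG state.

## Known limitations

Depth-based HE calling cannot see copy-neutral exchanges and reports
unpaired segments as unresolved rather than deciding. The PAV merge rule
is positional, not sequence-aware. The moderated-variance prior (4 df)
is fixed, not estimated. Ka/Ks supports the universal code only. The
chromosome-level bias test treats pairs as independent, which real
linkage violates.
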