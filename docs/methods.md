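# Methods

Statistical models, parameter defaults, numerical choices, and known
limitations of `neosexscan`. All empirical numbers quoted here were
computed with this package (the acceptance suite or
`scripts/acceptance.py --seed 1`).

## Coverage analysis

**Normalization.** Depth tracks are binned (default 1 kb bins) and
divided by the sample's library size (total mapped bases, or a supplied
scalar), so values are comparable across samples with different
sequencing depth. Two per-chromosome mean conventions are provided and
both are reported by the pipeline: mean over covered positions only
(default; robust to assembly gaps) and mean over the full chromosome
length. The choice matters when coverage is sparse, and neither is
canonically correct — the exclusion stage for repeat masking is not
uniquely determined — so both are exposed.

**Degeneration test.** Each candidate chromosome's normalized mean is
Grubbs-tested against the autosomes separately per sample (two-sided,
alpha 0.05, at least 4 autosomes required for the test to be defined). A
chromosome is called degenerate when it is a significant **low** outlier
in **every** male and in **no** female. With one male and one female the
female side has a ~2.5% false-trigger rate (one two-sided test at alpha
0.05, low direction), which bounds the whole-rule false-block rate.

**Windows.** Male-minus-female normalized depth in sliding windows of
500 kb with 100 kb step. Windows are full-length only; a chromosome
shorter than one window contributes a single truncated window flagged
`partial`. Windows where either sample has no covered position are NaN
("unusable") rather than zero-filled. The midpoint-crossing of the
window profile localizes a hemizygous-deletion boundary to one step:
across 100 simulated replicates of a 6-Mb deletion (0.5× male depth,
50× mean coverage), the worst boundary error was 50 kb — the
window-center quantization, with Poisson window noise ~0.3%.

## Divergence and SNP patterns

**Site masks.** A site is usable when every required sample's depth is
inside inclusive bounds: preset `strict` = (20, 200), `loose` =
(10, 500), chosen as round cut-offs bracketing 0.4–4× of 50× coverage.
Masks from multiple samples AND together; strict ⊆ loose by
construction.

**X/Y SNP rules.** Per site, with zero missing genotypes among the
focal males, focal females and other-species females (otherwise
`unclassified`): all focal males heterozygous with focal females and
other females homozygous for opposite alleles → `X_specific`; all focal
males heterozygous with both female groups homozygous for the same
allele → `Y_specific`; focal males and females homozygous for one
allele, other females for the other → `shared` (a fixed difference that
predates the fusion). Exactly one label per site, so the four categories
always partition the input. Note the rules quantify over the *sampled*
females: a site truly polymorphic in the sister species whose sampled
females all carry the derived homozygote is observationally a fixed
difference and classifies as `shared`. This is correct behavior, not an
error; the acceptance suite scores the rules against that observational
truth and finds exact agreement over 916,867 simulated sites.

**Fusion gradient.** Heterozygous-site counts per 1-kb bin (default)
are modeled as binomial with a logit link against the bin midpoint's
distance from the fusion end, fitted by IRLS (tolerance 1e-8, ≤ 100
iterations; separation is flagged, not raised). The generator's decay is
exponential in the probability, not in the logit, so the fit is
deliberately mis-specified the same way the analysis of real data would
be; for p ≤ 0.01 the two differ negligibly and the fitted slope
approaches −1/scale. Acceptance: the fitted slope is within 2 SE of the
matched-model value (the same fit applied to exact expected counts) in
96/100 replicates, and a uniform null is significant in 3.5% of 200
runs at nominal alpha 0.05.

## Codon evolution

**NG86 counting.** Synonymous/nonsynonymous site and difference counts
follow Nei & Gojobori (1986): per-codon site fractions from all nine
single-base mutations (mutations to stop codons count as nonsynonymous
sites at the site-counting stage), pairwise differences averaged over
the orderings of the differing positions. Orderings passing through a
stop codon are excluded from the average (if all orderings are blocked,
they are all used with stop-involving steps counted nonsynonymous).
Distances are Jukes–Cantor corrected; Ka/Ks is reported as undefined
when Ks = 0. The acceptance suite verifies exact agreement (rational
arithmetic, 1e-12) with an independent exhaustive enumeration over all
61×61 sense-codon pairs. At Ks = 0.05 the JC ratio bias is about −3%
for dN/dS = 0.2 (pooled recovery error measured at 2.2%).

**Two-ratio omega.** With focal, sister and outgroup sequences, each
variable codon is assigned by parsimony: a difference unique to the
focal sequence is a focal-branch change; differences shared by sister
and outgroup against focal are also focal-branch; sister-specific and
outgroup-specific changes belong to the background. Codons with three
alleles or conflicting patterns are excluded and counted. Pooling sums
Nd/N and Sd/S across genes before the ratio (per-gene ratios are
unstable at low divergence). This is a counting approximation to
likelihood codon models: adequate for rank and ratio comparisons at low
divergence (the regime here, Ks ≤ 0.05 per branch), not a substitute
for ML estimates. Acceptance: simulated omega 0.5 vs 0.1 recovered as
0.500 / 0.100 on average with correct ordering in 100/100 replicates of
200 genes.

**Virtual haplotypes.** For Ka/Ks between X and Y without phasing, each
male heterozygous site contributes its alternate allele to a "Y-like"
haplotype and reference to "X-like" (direction chosen by the X/Y
pattern call); consensus sequences take the majority allele per site.
Indel-overlapping and reference-mismatching genes raise `GeneExcluded`.

## Statistics

- **Mann–Whitney U:** exact permutation distribution (midrank ties,
  two-sided p = doubled smaller tail) when the smaller group has ≤ 8
  observations and total n ≤ 40; otherwise the tie-corrected normal
  approximation without continuity correction (matches the large-sample
  convention in common software). The exact path is verified against
  full split enumeration for every tie structure up to n = 12.
- **Fisher exact:** two-sided by summation of hypergeometric
  probabilities ≤ the observed one; an empty margin returns NaN.
- **Grubbs:** G = |x − mean|/sd over the full sample; p = min(1,
  2n·T(√((n−2)G²/((n−1)²/n − G²)), n−2)), a Bonferroni upper bound on
  the two-sided max-deviation tail, essentially tight in the far tail.
  Monte-Carlo checks (10⁵ reps at n ∈ {5, 10, 21}) confirm the bound is
  never exceeded beyond 3 MC standard errors. The iterative scan removes
  each detected outlier and retests until none is found or fewer than 4
  values remain; its family-wise null rate is ≈ alpha (measured 4.5%
  over 400 null enrichment simulations at alpha 0.05).
- Grubbs assumes approximate normality of the scanned values. With
  strongly skewed values it is anticonservative: scanning per-chromosome
  flagged-gene proportions built from only 100 genes (false flags
  ~Poisson(1)) gives a measured 15.8% null rate at nominal 5%. At the
  microarray scale the package targets (~1100 genes per chromosome) the
  proportions are near-normal and calibration holds. Users applying the
  enrichment scan to sparse gene sets should be aware of this.

## Expression

Normalization divides each array by its 75th percentile
(linear-interpolation quantile), log2-transforms (signals floored at
1e-6 and counted), then divides each probe by its median log value.
Probes whose log2 median is within ±0.05 of zero are numerically
unstable under that division and are excluded (and counted). Per-gene
values average a gene's probes. Bias calls are per-gene one-way ANOVA
(alpha 0.01); tissue specificity uses presence calls (external table or
a signal-vs-background t-test at P < 0.001). Percentile normalization
carries a compositional artifact: if one chromosome holds many truly
biased genes, the array-level percentile shifts and autosomal null
rates inflate (measured 1–5% at nominal 1% under the full study
conditions, vs 0.99% on pure-null matrices). This mirrors the behavior
of the real protocol and is reported, not corrected.

## Synthetic-study generator

Defaults encode the study design: 5 focal males, 5 focal females, 1
sister male, 5 sister females, 1 outgroup female; 10 autosomes of 2 Mb;
a 10-Mb neo-sex chromosome fused at position 1; a 4-Mb ancestral sex
chromosome with a 3-Mb non-recombining region containing a 1.5-Mb
hemizygous deletion (male depth × 0.5). Key rates (per bp): fixed
differences 0.002, within-species polymorphism 0.002 (halved on the
focal neo-sex chromosome), outgroup divergence 0.02, ancestral X–Y
heterozygosity 0.004 in the non-recombining region. Neo X–Y
heterozygosity decays from p_max = 0.01 with a 5-Mb exponential scale
(logistic alternative available); each X–Y site is Y-specific or
X-specific with probability 0.5. Depth is Poisson around 50× per 1-kb
bin with ±15% per-sample library scaling. Coding genes receive branch
substitutions at Ks 0.025 (focal, sister) and 0.05 (outgroup), with
dN/dS 0.5 on the neo-Y and 0.2 on the neo-X. Expression plants sex-bias
in 15% of sex-chromosome genes vs 5% of autosomal genes (Bernoulli per
gene), effect 1 log2 unit, noise SD 0.25.

Realism limits, by design:

- Sites are independent: no linkage disequilibrium, no recombination
  maps, no mutation-rate heterogeneity along chromosomes.
- Genotypes are error-free; allele frequencies for polymorphic sites
  follow a neutral 1/k sampling-frequency spectrum.
- Coding substitutions are placed on distinct codons (no multiple hits
  within a codon across branches), with stochastic rounding of expected
  counts, so parsimony branch assignment is exact by construction.
- Depth is Poisson (no GC or mappability structure); the deletion is a
  sharp interval, not a mosaic.
- Expression noise is Gaussian in log2 space with a single global SD.
- Focal-polymorphism draws that would exactly replicate an X/Y/shared
  genotype pattern are redrawn (~0.2% of draws) so truth labels are
  unambiguous.

These simplifications make power measurable and truth exact; they also
mean measured detection rates are upper bounds relative to real data
with genotyping error and correlated sites.

## Reproducibility

Every stochastic routine takes an explicit seed or NumPy `Generator`;
the pipeline driver derives per-stage seeds (< 2³¹) by hashing the run
seed with the stage name, and writes a manifest with content digests of
every output. The same seed yields byte-identical outputs.
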