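# Methods

`pinegbs` re-implements, as a tested reusable pipeline, the SNP quality
control, pedigree reconstruction and clone identification workflow used in
conifer exome-capture genotype-by-sequencing (GBS): two ordered filtering
pipelines over per-allele read depths, a four-criterion pedigree-panel SNP
selection, exclusion-analysis trio parentage, random-panel robustness
experiments, and a pairwise-mismatch gap statistic for clone
discrimination.  Because the genotype data this workflow was developed on
is not publicly deposited, every analysis is driven by a synthetic-data
generator that encodes the study design: the generator's defaults *are* the
study conditions, and all end-to-end properties are demonstrated on data it
produces.

## Data model

* **VariantTable** — pre-call records: per site an identifier, capture
  probe, gene model, position, a site-quality value and a per-sample
  per-allele read-depth vector.  The VCF QUAL column stands in for the
  genotyping provider's proprietary quality score.  A boolean *mask* marks
  data points forced missing by the per-individual filter stages; masked
  points keep their depths so that depth statistics are stable under
  re-filtering (this is what makes the site-level stages idempotent).
* **GenotypeMatrix** — called genotypes as unordered allele multisets
  (sorted index pairs, `(-1,-1)` missing).  Haploids (megagametophytes)
  store a duplicated single allele; the sample sheet's ploidy column
  disambiguates.  Phase is never represented.
* **SampleSheet** — ploidy, role (`parent`, `offspring`, `unrelated`,
  `megagametophyte`, `replicate`), family and replicate-group annotations.
  The "putatively unrelated" cohort used for MAF estimation and the
  unrelated relationship class comprises the `unrelated` **and** `parent`
  roles, since the study's 135-tree cohort included the mapping-population
  parents.

## Genotype calling

A data point is called only when total depth reaches `min_depth`
(default 10; depth exactly at the threshold survives, matching the strict
`< T` wording of the published filters).  Haploids receive their single
deepest allele (depth ties break to the lower allele index).  Diploids are
heterozygous when the minor-read ratio `d2/(d1+d2)` is at least
`min_allele_ratio` (default 0.1).  An *observed but weak* minor allele
(`1 <= d2`, ratio below threshold) is ambiguous in the published
description between "call homozygous" and "set missing"; both behaviours
are exposed: plain calling demotes to the homozygous major call
(`low_ratio_action="demote"`), while the published per-individual
allele-ratio filter stage sets the point missing (`"missing"`).  A clean
homozygote (zero minor reads) is never touched by the ratio rule — reading
the rule literally would blank every homozygous data point.

## Filtering pipelines

**Pilot (80K) pipeline**, five stages in published order: (1) remove whole
probes heterozygous in strictly more than 5% of megagametophytes; (2)
remove SNPs with site quality < 10; (3) remove SNPs with mean depth < 5X;
(4) remove SNPs listing more than two alleles; (5) remove SNPs whose
population-average alt/(ref+alt) read ratio is < 0.1 or > 0.9.  The
population ratio is averaged over informative *diploid* individuals only —
a haploid legitimately sits at ratio 0 or 1 and would bias the mean.

**Revised (49K) pipeline**, seven stages in published order: (1) remove
SNPs with mean depth across all individuals < 10; (2) at sites listing more
than two alleles, keep the deepest alternate; if any individual supports an
extra alternate at depth > 10 the site is a true triallelic and moves to a
separate table, otherwise the extra alleles are dropped and the site
reclassified biallelic (an extra allele at exactly depth 10 is treated as
weak and dropped — neither published inequality covers the boundary); (3)
mask data points with individual depth < 10; (4) mask data points with an
observed minor-read ratio < 0.1; (5) remove paralogous probes as in the
pilot; (6) remove SNPs monomorphic over all non-missing calls in all
samples, haploids included; (7) retain SNPs with MAF >= 0.03 in the
putatively unrelated cohort.  The MAF row of the published pipeline table
reads as removing *common* SNPs, which contradicts the accompanying text
and the MAF-spectrum figure; the text's reading (retain MAF >= 0.03) is
implemented.  The filter report tracks genes/probes/SNPs per stage *and*
masked data-point counts, because the per-individual stages change data
points, not site counts.

A megagametophyte counts as heterozygous at a site when its depth vector
supports two or more alleles with at least 2 reads each; single-read
alternative observations are ignored (they are overwhelmingly sequencing
error, and were the dominant cause of probe loss under the pilot pipeline).
The denominator is megagametophytes with any reads at the site.

## Pedigree-panel selection

Candidates must have call rate > 0.75, MAF in [0.35, 0.5] (inclusive), and
a Hardy-Weinberg chi-square goodness-of-fit p-value > 0.10 — expected
counts from the estimated allele frequency, 1 degree of freedom, no
continuity correction — all computed over the unrelated reference cohort.
Surviving SNPs are greedily LD-pruned so that every retained pair has
squared genotypic (dosage) correlation r² < 0.02; SNPs are visited in
descending call rate (ties by site order), which is deterministic and
favours complete data.  Undefined correlations (zero variance, too few
complete pairs) are treated as unlinked.

The r² computation uses its own cohort, defaulting to *every diploid
sample*.  Two effects make a tight r² ceiling hard to satisfy between
truly unlinked loci: sampling noise (the null expectation of r² is ~1/n,
so at n = 135 an 0.02 ceiling rejects ~10% of unlinked pairs), and
family-structure-induced composite LD when the cohort includes large
full-sib families.  Either way, a greedy mutually-unlinked pool at the
0.02 ceiling saturates near 50 SNPs at desk-scale cohort sizes — below the
110-SNP panel size.  The panel-robustness experiments therefore draw
panels from the marginal-criteria pool (call rate, MAF, HWE; LD pruning at
ceiling 1.0, which removes only duplicated columns): simulated sites are
unlinked by construction, so this changes nothing about the independence
the experiments rely on, while keeping the published panel geometry
(60 panels of 110) intact.

## Parentage by exclusion

For a trio, the compatible offspring genotypes are the unordered pairs
formed by one gamete from each candidate parent (at most 4 ordered
combinations, realised by het x het).  A panel SNP with all three genotypes
present is an *exclusion* when the offspring genotype is not in that set;
SNPs with any missing genotype are skipped and not counted as comparable.
The candidate pair with the fewest exclusions wins; ties are reported as
ambiguous, never silently broken (the runner-up margin is reported, 0 under
a tie).  Raw exclusion counts are compared, not rates, matching the
published ranking; self-pairs are excluded by default.  An offspring is
dropped from a panel-size experiment when its own non-missing call count in
the truncated panel falls below half the panel size (the published
behaviour for low-call-rate individuals; the floor fraction is
configurable).

The 60-panel experiments use a vectorised engine that builds one
(candidate-pair x SNP) boolean exclusion matrix per offspring over the
pooled SNPs; each panel and nested prefix truncation is then a column
segment sum.  This keeps the full study geometry (135 candidates = 9,045
pairs, 180 offspring, 60 panels, 7 truncation sizes) to roughly a minute on
one CPU.

## Clone identification

Pairs of diploid samples are compared genotype-for-genotype over a panel;
a mismatch is whole-genotype inequality (heterozygote vs either homozygote
counts once; no allele-sharing partial credit).  Pairs with fewer than 80
comparable SNPs out of 110 are excluded; for other panel sizes the floor
scales proportionally (ceil(size * 80/110)).  Mismatch percentages are
profiled within the four declared relationship classes — ramet (shared
replicate group), full-sib, parent-offspring, unrelated — in that
precedence order; pairs in any other relationship are labelled "other" and
excluded from the profiles.  Panels are ranked by the gap statistic
(minimum full-sib % minus maximum ramet %), with the analogous
parent-offspring and unrelated gaps also reported; a negative gap flags
overlapping profiles.

Under Hardy-Weinberg with allele frequencies (p, q), two unrelated
individuals mismatch at a SNP with probability
`1 - (p²)² - (2pq)² - (q²)²`; the simulated unrelated-class mismatch
frequency is checked against this closed form.

## Synthetic-data generator

The generator emulates the study design; defaults (units in parentheses):

| parameter | default | meaning |
|---|---|---|
| `n_unrelated` | 135 | putatively unrelated diploid founders |
| `families` | 2 x 90 | full-sib families (mother, father, n offspring) |
| `n_mega_mothers` x per | 104 x 1 | haploid megagametophytes, one maternal gamete each |
| `n_replicate_copies` | 2 per family parent | ramets re-rendered from one true genotype |
| `maf_distribution` | Beta(0.25, 5), folded | rare-variant-skewed MAF spectrum; `uniform(lo, hi)` for panel work |
| `mean_depth` (reads) | 60 | negative-binomial mean, the achieved depth regime |
| `depth_dispersion` | 6 | NB size; variance mu + mu²/k, spanning roughly 6-200X |
| `substitution_error` | 0.002 | per-read substitution to a uniformly chosen other allele |
| `paralog_probe_fraction` | 0.05 | probes co-capturing a duplicated locus |
| `triallelic_artifact_rate` | 0.01 | sites segregating a rare third allele |
| `snps_per_probe` | geometric, mean ~1.3 | sites per capture probe |

Founders are drawn under Hardy-Weinberg proportions, independently across
sites (all sites unlinked; linkage is out of scope).  Offspring receive one
uniformly chosen allele from each parent per site; megagametophytes one
maternal allele.  Read rendering: total depth ~ NB(mean, dispersion) per
data point; reads are drawn from the true alleles (uniformly for
heterozygotes) and substituted with the error probability into one of the
other two alleles of the site's 3-slot universe — so sequencing error
creates spurious 2nd/3rd-allele depths, including single-read alternative
observations, which are listed in the emitted VCF exactly as a caller
reports them.  A paralogous probe adds an independent NB-deep read stream
fixed for one allele at each of its sites, producing pseudo-heterozygous
haploids.  Replicates re-render depth and error from the same true
genotype.  Site quality is a gamma(2, 30) stand-in (~4.5% of sites below
the pilot quality threshold), rounded to 2 decimals so VCF text
round-trips bit-exactly.  Everything is driven by one `numpy` Generator
seeded from the config; identical seeds give byte-identical output.

Missingness arises *only* through the depth threshold at calling, which
reproduces the published depth/missingness relationship qualitatively but
is an assumption: real data also lose points to mapping and capture
failures.  The generator likewise omits linkage, inbreeding, population
structure beyond the declared families, and index-hopping-style
cross-sample contamination — so passing tests demonstrate the *methods*,
not the full error structure of real GBS data.

A separate utility injects post-call genotype noise (a missing rate and an
error rate that replaces a call with a uniformly chosen different
genotype) for the panel-size robustness experiments.

## Numerical and design choices

* Thresholds are strict as printed: depth exactly at a `< T` bound
  survives; haploid-het fractions must strictly exceed 5%.
* Genotype calling tie-breaks (equal depths) go to the lower allele index.
* MAF from calls counts alleles over non-missing genotypes; sites with no
  cohort calls are removed by the MAF stage (MAF undefined).
* Greedy LD pruning order and the LD cohort are package choices where the
  published description is silent (see above).
* `reduction_experiment` classifies each offspring as true / false /
  ambiguous / dropped; accuracy in the degradation experiments is
  true / (true + false + ambiguous).
* Exclusion counts are non-decreasing in prefix length by construction;
  panel truncation takes the first k SNPs of the stored order.

## Problem sizes

End-to-end property tests and the acceptance script run at the study's
pedigree geometry (135 founders, 2 x 90 offspring, 60 panels of 110 SNPs
drawn from a ~630-SNP pool over 704 simulated sites) and use 800-site
datasets with the full sample complement (megagametophytes, replicates)
for the filtering post-conditions; the HWE test-size check uses 5,000
simulated sites at n = 135.  These sizes make every experiment reproducible
in minutes on one CPU while preserving the study's sample geometry; the
published headline counts (1.5M raw SNPs, 80,160 filtered, the 704-SNP
pool) derive from the unreleased full dataset and are not reproduced at
this scale.
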