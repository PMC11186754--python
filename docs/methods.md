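# Methods

## Scope and data model

`clonedyn` analyzes one patient at a time from paired somatic variant calls:
a pre-treatment biopsy and a post-treatment resection sequenced against a
matched normal, delivered as one multi-sample VCF per patient with per-sample
depth (`DP`) and allelic depth (`AD`) and a somatic-posterior INFO tag
(default `PROB_SOMATIC`, phred-scaled; a configurable linear scale is also
accepted — the caller's posterior is treated as data, not recomputed).
Multi-allelic records are split into atomic (ref, alt) variants before any
analysis, and coordinates follow the VCF convention (1-based, inclusive).
Two single-sample call sets can be joined on (chrom, pos, ref, alt) upstream;
the joint multi-sample file is canonical because somatic callers on paired
designs emit joint records.

## Purity

**Convention.** Purity is defined on the allele scale throughout: the maximal
VAF a somatic variant can attain in the sample. Under copy-neutral
heterozygosity this is half the cell-fraction purity. The estimators, the
VAF adjustment and the simulator all share this single scale, and the
VAF-derived value is compared directly with the pathologist estimates
without a ploidy correction; the convention is deliberately uniform rather
than "corrected", and is recorded with every output.

**Resection.** The robust maximal VAF *v* is the 0.98 quantile
(`numpy.quantile`, linear interpolation; configurable) of the VAFs of
variants with somatic posterior ≥ 0.95 and depth ≥ 30 in the resection. A
quantile rather than the literal maximum makes the estimate deterministic
and robust to isolated copy-number-inflated outliers, which can push single
VAFs beyond the purity. *v* is accepted as the posterior purity iff
p₁ ≤ *v* ≤ p₂ and p₂ − p₁ ≤ 0.2, where p₁ ≤ p₂ are the two pathologists'
estimates; otherwise purity is **unknown** and the patient is excluded from
subclone dynamics. The decision rule is transcribed literally, including the
degenerate corner *v* = 0 (possible only when p₁ = 0): the decision is
representable, but a zero purity carries no analyzable tumor signal, so the
pipeline downgrades it to unknown before purity is ever used as a divisor.

**Biopsy.** With the resection purity known, a scaling factor *s* maps
biopsy VAFs onto resection VAFs. When ≥ 10 variants are observed (VAF > 0)
in both samples, *s* is the median per-variant ratio (exact under shared
clonal composition); with (nearly) disjoint sets, *s* minimizes the
1-Wasserstein distance between {s·biopsy VAFs} and {resection VAFs} over the
grid s ∈ [0.1, 10], step 0.05. Biopsy purity = resection purity / *s*,
clipped to 1. Fewer than 3 nonzero biopsy VAFs → unknown. The median-ratio
path is exactly scale-equivariant (shrinking all biopsy VAFs by c multiplies
*s* by 1/c); the grid path is equivariant to within the grid step.

## Subclone dynamics

Each somatic variant represents the subclone it founded (one nonlethal
mutation, one new subclone), so subclone counts are variant counts after
filtering. The purity-adjusted VAF, min(1, f/purity), estimates the
variant's cellular prevalence among tumor cells. A variant **qualifies**
when

1. somatic posterior ≥ 0.95 (in biopsy or resection),
2. adjusted VAF ≥ 0.1 in **at least one** sample — the one-sample reading is
   forced, because lost/gained subclones have VAF 0.0 in one sample by
   definition, and
3. it is certainly detectable in the respective other sample: either the
   other sample actually shows alt reads, or the expected read count at the
   same cellular frequency — adjusted VAF × other purity × other depth — is
   at least 2 (inclusive bound). The expectation test applies only toward a
   zero-alt other sample; this refinement is what makes qualification
   monotone in both thresholds (raising the VAF floor or the read
   requirement can only shrink the qualifying set), a property the test
   suite asserts. Requiring the expectation in every observed direction is
   non-monotone: raising the VAF floor can delete a failing obligation and
   re-admit a variant.

Qualifying variants with **zero alt reads** in the resection and adjusted
biopsy VAF ≥ 0.1 are *lost*; zero alt reads in the biopsy with adjusted
resection VAF ≥ 0.1 are *gained*; the rest *retained*. "VAF = 0.0" means
literally zero observed alt reads, not merely sub-threshold: a variant at
0 < adjusted VAF < 0.1 in one sample and ≥ 0.1 in the other is retained.
Both fractions use the qualifying union `n_total` as denominator, so
lost/gained/retained partition it; a resection-restricted count
`n_resection` is reported alongside for users who prefer that denominator.
Patients with an empty qualifying set, or with unknown purity, are omitted
from the cohort table and written to the exclusion log with their reason.
A gained subclone is not distinguishable from enrichment of a variant the
biopsy spatially missed; the simulator models this explicitly.

## Mutational spectrum

At each threshold t of an ascending minimal-VAF grid, the count of somatic
variants with VAF ≥ t is accumulated per substitution class and divided by
the target footprint in megabases. Single-base substitutions fold onto the
pyrimidine strand (G>T → C>A, ...), giving six SNV classes; equal-length
multi-base substitutions are MNV; all remaining shapes, including indels,
are "complex". `region_mb` defaults to 1.94 Mb, a typical coding footprint
of a ~500-gene panel, and is recorded in every output because densities are
only comparable at a fixed denominator.

## Prioritization

The reportability filter is a conjunction: nonsynonymous consequence;
pathogenicity score > 0.5 *when a score is available* (unscored variants
pass this clause — the score exists mainly for missense variants); population
allele frequency < 0.2 (absent treated as 0); clinical-significance label
not benign/likely-benign; gene in the user-supplied list when one is given.
A stricter policy (score > 0.7) is provided as `STRICT_POLICY`. Every
rejection is tallied by clause.

Two transparent probability models replace the external caller's scores with
the same decision semantics:

- **Absence in normal** — two binomial hypotheses under equal priors:
  alt ~ Bin(depth, 0.001) (sequencing noise) versus alt ~ Bin(depth, 0.5)
  (germline het); the posterior of the noise hypothesis is reported, and
  zero depth returns the uninformative 0.5.
- **VAF change** — each sample's VAF receives an independent Jeffreys-prior
  Beta posterior, Beta(alt + ½, depth − alt + ½); 20,000 seeded Monte-Carlo
  draws estimate P(|f_b/purity_b − f_r/purity_r| > δ), δ = 0.05 by default.
  Adjusted draws are deliberately not clipped at 1 so the score is exactly
  invariant under jointly rescaling both purities (with δ rescaled).
  Decision thresholds on these probabilities are left to configuration; raw
  values are always reported.

## Simulator

The generator emulates exactly the structure the inference assumes. Clone 0
is the truncal root; each later clone attaches to a uniformly random earlier
clone (or to the root under the `star` topology used in validation).
Per-clone mutation counts are Poisson (default mean 10; the root's mean is
separately configurable since truncal burden is usually larger). Subclone
population fractions φ are Dirichlet (concentration 5 per clone by default —
clones of broadly comparable but unequal size); a mutation's cellular
prevalence is the φ-sum over the subtree of its founding clone, so child
prevalence never exceeds parent prevalence by construction. Therapy
multiplies φ by per-clone survival factors (or kills a random fraction of
non-root clones) and renormalizes; a killed clone's descendants survive
unless also killed. Spatial sampling drops each non-root clone from the
biopsy with probability 0.05 by default, removing its whole subtree —
descendant cells are co-located with their ancestor, and a mutation is
absent from the biopsy only if no carrying clone was sampled. Expected VAF
is prevalence × allele-scale purity (defaults 0.4/0.4), depth is Poisson
(default 150× — routine FFPE exome coverage), alt reads Binomial, so
alt ≤ depth and expected VAF ≤ purity always hold. Pathologist priors are
the true resection purity perturbed by ±Uniform(0, 0.1). A few germline-like
contaminants (VAF ≈ 0.5, somatic posterior < 0.95) exercise the posterior
filter. Degenerate draws (no mutations, all prevalence annihilated) are
retried a bounded number of times. One master seed spawns independent
per-patient substreams (`numpy.random.SeedSequence`), making cohorts
bit-reproducible.

What the simulator does **not** model — copy-number events (except an
optional robustness check for the purity quantile), trinucleotide context,
base-level sequencing error, FFPE artifacts, sampling of multiple regions —
bounds what passing tests show: recovery results demonstrate correctness of
the inference under its own assumptions, not robustness to CNV-driven VAF
inflation or artifact-driven false calls in real FFPE exomes.

## Validation conditions and numerical choices

- *Purity recovery*: 200 replicates with ~205 variants including a
  ~30-variant truncal cluster, 400× depth, purities 0.3/0.4, no CNV or
  spatial miss. A high quantile of a noisy bounded spectrum sits slightly
  above the truth (order-statistics bias ≈ +0.03 at this depth), so depth
  and cluster size were chosen once such that the ±0.05 recovery bound holds
  with margin; both the resection quantile and the biopsy transfer recover
  within ±0.05 in ≥ 95% of replicates.
- *Selection recovery*: star trees with balanced prevalences (Dirichlet
  concentration 50), no truncal mutations, 300× depth, purity 0.5, killing
  clones that carry 20/50/80% of the mutations; mean inferred fraction-lost
  tracks the killed fraction within ±0.1 over 100 replicates.
- *Null control*: zero selection, zero spatial miss, equal purities and
  depths; mean lost/gained fractions stay below the noise ceiling of an
  independently coded brute-force draw from the same binomial model
  (both are ~10⁻³ at 150×: a lost call needs literally zero alt reads).
- Monte-Carlo agreement for the VAF-change score is asserted against a
  10⁶-draw oracle within 3 standard errors.
- Ties and corners: the quantile uses numpy's linear interpolation; the
  detectability bound is inclusive (expected reads = 2.0 passes); VAF at
  zero depth is NaN and such a variant can qualify only through the other
  sample; the retry bound for degenerate simulations is 20.

These problem sizes were chosen as the smallest at which the binomial noise
floor stops dominating the quantities being validated.

## Known limitations

Purity is biased upward at modest depth (quantile of a bounded noisy
maximum) and unavailable whenever pathologists disagree by more than 0.2 or
the VAF evidence contradicts them — in realistic simulated cohorts a
substantial minority of patients is excluded this way, matching the method's
conservative intent. The one-variant-one-subclone proxy overcounts subclones
in proportion to the mutation rate and is only comparable across samples
under similar rates. No attempt is made to deconvolve copy number, cluster
variants into clones, or assign phylogenies.
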