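# clonedyn

Inference of subclonal-diversity dynamics between a pre-treatment tumor
biopsy and the post-treatment surgical resection of the same patient, from
paired somatic variant calls.

## The problem

Neoadjuvant therapy (for example immune checkpoint blockade before surgery)
reshapes a tumor's clonal architecture: some subclones are depleted, others
enriched. With a diagnostic biopsy before therapy and the resected tumor
after it, the shift can be read off the somatic variant allele frequencies
(VAFs) — provided two confounders are handled: the unequal **tumor purity**
of the two specimens, and the limited **detectability** of low-frequency
variants at finite sequencing depth.

`clonedyn` implements this analysis for anyone with paired multi-sample
somatic VCFs (biopsy, resection, optional matched normal) plus pathologist
purity estimates of the resection:

1. **Purity estimation.** Without copy-number variation, no somatic variant
   can exceed a VAF equal to the (allele-scale) tumor purity, so the top of
   the somatic VAF distribution estimates purity. Let *v* be a robust
   maximum of the resection's somatic VAFs (a high quantile, default 0.98,
   over variants with depth ≥ 30). If *v* lies within the two pathologist
   estimates [*p₁*, *p₂*] and they agree (*p₂* − *p₁* ≤ 0.2), *v* is the
   posterior purity; otherwise purity is unknown and the patient is
   excluded. The biopsy purity is transferred from the resection by scaling
   the biopsy VAF distribution onto the resection one (median per-variant
   VAF ratio on shared variants, Wasserstein grid search otherwise).
2. **Subclone counting.** Each somatic variant proxies the subclone it
   founded. A variant qualifies if it is confidently somatic (posterior
   ≥ 0.95), its purity-adjusted VAF *f*/purity reaches 0.1 in at least one
   sample, and — at the same cellular frequency — it would be expected to
   collect at least 2 reads in the other sample. Qualifying variants with
   zero alt reads in the resection are **lost** subclones; zero alt reads
   in the biopsy, **gained**; the rest retained. Fractions use the
   qualifying union as denominator, so lost + gained + retained is a
   partition.
3. **Mutational spectrum.** Mutations per megabase above a minimal-VAF
   threshold, per substitution class (C>A, C>G, C>T, T>A, T>C, T>G in the
   pyrimidine-reference convention, plus MNV and complex).
4. **Resistance-variant prioritization.** Nonsynonymous, predicted
   pathogenic (REVEL-style score > 0.5 when available), population AF
   < 0.2, not (likely) benign, in a supplied cancer-gene list; scored with
   the posterior probability of absence in the matched normal and the
   probability that the purity-adjusted cellular frequency changed
   (difference of Jeffreys-prior Beta posteriors, Monte-Carlo).
5. **Simulation.** A clonal-evolution generator (clone tree, Dirichlet
   prevalences, therapy selection, spatial biopsy sampling, Binomial reads
   at Poisson depths) provides ground truth for every estimator above.

## Worked example

```python
from clonedyn import PairedTumorModel, SimParams, simulate_case

case, truth = simulate_case(
    SimParams(n_clones=6, mutations_per_clone=12, truncal_mutations=25,
              selection=0.3, purity_biopsy=0.35, purity_resection=0.4,
              mean_depth_biopsy=150, mean_depth_resection=200,
              p_error=0.08, seed=0),
    patient_id="SIM-000",
)
print(PairedTumorModel(case).fit().summary())
```

```
Paired tumor subclonal dynamics
===============================================
patient:              SIM-000
variants:             92
pathologist priors:   [0.35, 0.46]
purity (resection):   0.422 [vaf_max_consistent] (v=0.422)
purity (biopsy):      0.375 [scaled_from_resection] (s=1.125)
subclones (total):    74
subclones (resection):   54
lost / gained / kept: 17 / 0 / 57
fraction lost:        0.230
fraction gained:      0.000
```

The VAF-quantile purity (0.422) lands inside the pathologist window and is
accepted; the biopsy distribution is a factor 1.125 below the resection one,
giving biopsy purity 0.375 (simulated truth: 0.40 and 0.35). Of 74
qualifying subclones, 17 vanished after therapy (fraction lost 0.23; 30% of
the simulated clones were killed, so with read noise and the 0.1 prevalence
floor this is the expected order).

The same analysis runs from the shell on whole cohorts:

```bash
clonedyn simulate --n-patients 8 --seed 1 --out-dir inputs   # or your own VCFs
clonedyn demo --seed 1 --workspace demo                      # end-to-end demo
clonedyn run config.yaml                                     # full pipeline
```

producing `purity.tsv`, `cohort_dynamics.tsv` (one row per analyzable
patient), `exclusions.tsv`, per-sample spectrum tables, a prioritization
report and a run manifest.

## Limitations

Purity estimation assumes a copy-number-neutral genome; no CCF clustering or
phylogeny reconstruction is attempted (one variant = one subclone proxy);
and a "gained" subclone cannot be distinguished from enrichment of a variant
the biopsy spatially missed. See `docs/methods.md` for the full model
description and design choices.
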