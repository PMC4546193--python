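# Methods

## Assay model and fraction arithmetic

The MSRE qPCR assay runs four reactions per sample × gene: mock (Mo),
methylation-sensitive enzyme (Ms, cuts unmethylated sites), methylation-
dependent enzyme (Md, cuts methylated sites), and double digest (Msd).
Relative input DNA is `2^-Ct`, i.e. amplification efficiency is fixed at 2;
no efficiency calibration is applied. A reaction that never crosses
threshold is treated as zero input (the Ct → ∞ limit), not imputed at a
maximum cycle.

Fractions are normalized by digestible DNA, `C_Mo − C_Msd`:
`F_HM = C_Ms/(C_Mo − C_Msd)`, `F_UM = C_Md/(C_Mo − C_Msd)`, and the
intermediately methylated fraction is defined as the complement
`1 − F_HM − F_UM`. Because measurement noise can push raw values outside
[0, 1], each raw fraction is first clipped to [0, 1] (`CLIPPED` flag), then,
if the pair still sums above 1, both are rescaled by the sum
(`SUM_GT_ONE_RESCALED`), so the reported triple always sums to exactly 1.
Raw values are retained alongside. A non-positive denominator (refractory
DNA at or above the mock signal) or a missing mock digest aborts the assay
with `NEG_DENOM` / `NO_MOCK`; the refractory fraction `C_Msd/C_Mo` is
reported but never enters calls.

Known estimator property: with refractory fraction `r`, the noise-free
measured fraction is `(m(1−r) + r)/(1−r)` for true methylation `m`; after
the sum-rescale this leaves an upward bias of roughly `r` percentage points
at low `m` (≈ 1 pp at the default 1% refractory). This matters only where
true methylation and its dispersion are both small.

## Calls, prevalence, signature, classes

A gene is hypermethylated in a sample iff `F_HM > τ` with τ = 0.15; the
inequality is strict so exactly-threshold noise stays negative. Missing
fractions propagate as missing calls and leave the denominator. Per-group
prevalence is count/n; pooled tumor penetrance pools counts over
LGD + HGD + CRC (metastatic CRC excluded by default, configurable), which
makes it exactly the count-weighted mean of the group prevalences. The
signature is all genes with penetrance ≥ 0.85 ("at least 85%" read as ≥),
sorted by penetrance then name. Commonly-methylated genes (class A) are
excluded from signature membership by default: a gene prevalent across
normals and tumors alike carries no tumor-specific information.

Gene classes are operationalized as: A — pooled prevalence over all samples
> 0.95 (legend wording taken literally over per-cell bolding); else B —
prevalence > 0.5 in every tumor group including metastatic CRC and in no
non-tumor group; else C — the same but failing in metastatic CRC; else D —
prevalent in at least one group; else NONE.

The data-driven threshold scan maximizes mean Youden's J (tumor
sensitivity + normal specificity − 1) across genes over a 5-percentage-
point grid, ties toward the smaller threshold; the objective is this
package's choice and is recorded in the output table. On default synthetic
cohorts the scan selects 10%, one grid step from the 15% operating
threshold — with many low-prevalence panel genes, a lower threshold trades
a little specificity for sensitivity.

Printed prevalence percentages are tied back to integer counts by
enumeration (the unique k in [0, n] minimizing |100k/n − printed|);
ambiguity is an error, never a silent pick.

## Mutations

KRAS codon 12/13 genotypes derive from mutagenic PCR-RFLP fragment sizes:
codon 12 (162 bp amplicon, BstNI) → 113 bp wild type / 142 bp mutant;
codon 13 (174 bp, BglI) → 165 bp wild type / 125 bp mutant. Sizes match
within ±3 bp (chip electrophoresis sizing error; the diagnostics are > 6 bp
apart, so windows cannot collide). The mutant diagnostic dominates when
both fragments appear (heterozygosity / tumor heterogeneity). BRAF V600E is
a status import (pyrosequencing readout); no pyrogram analysis. Frequencies
are tabulated per group with all normal-histology samples pooled, plus a
pooled tumor total. The penetrance contrast tests each (gene, mutation)
pair with Fisher's exact test, Bonferroni-corrected, which stays valid for
zero-count mutations.

## Synthetic cohorts

The generator emulates the reference cohort: 75 samples in ten histological
groups (5/5/5/5 young-normal/adult-normal/cancer-adjacent-10 cm/1 cm,
17 LGD, 6 HGD, 17 CRC, 7 metastatic CRC, 4/4 inactive/active ulcerative
colitis), a 55-gene panel with per-gene × group mean ± SD methylation
targets, seven synchronous LGD–CRC pairs, and Bernoulli KRAS/BRAF mutations
at the observed group rates.

**Level distributions.** Per gene × group the true fraction follows a Beta
distribution matched to the reported mean ± SD (closed-form moment
inversion; an infeasible SD is shrunk to 0.95× the Bernoulli bound and
logged; zero-mean or zero-SD cells become point masses).

**Prevalence anchoring.** A two-parameter Beta matched to mean and SD alone
misstates tail mass at the 15% threshold — computed expected penetrances
of the ten reference signature genes come out 0.69–0.93 rather than
≥ 0.85, and several commonly-methylated genes would dominate any derived
signature. Where the study reports the per-group fraction of methylated
cases, the generator therefore also anchors prevalence: the printed
percentage is inverted to its integer count k, exactly k samples of the
cell are assigned methylated status, and levels are drawn from the
moment-matched Beta truncated above (methylated) or below (unmethylated)
the threshold. Cells without a printed prevalence fall back to the pure
moment-matched Beta. A Bernoulli(π) mode replaces exact counts on request.
Anchoring shifts cell means by at most a few percentage points where the
printed prevalence and the Beta tail disagree most (e.g. TMEFF2 in LGD,
≈ +6 pp), well inside 3 standard errors at the cohort's group sizes.

**Pairs.** Synchronous lesion pairs share a patient-level Gaussian latent
(copula correlation 0.7, a design choice — only the direction of the pair
effect is documented) in both methylated status and level. A dedicated
pair generator draws LGD lesions from the LGD margins and the synchronous
CRC lesion from a Beta with the mean lowered by a configurable shift
(default +15 pp LGD excess, same SD, floored at 0.5%).

**Forward model.** For true fraction m, refractory fraction
r ~ Beta(1, 99) (mean 1%), and base cycle b ~ Normal(24, 1):
`ct_mo = b`, `ct_ms = b − log2(m(1−r)+r)`, `ct_md = b − log2((1−m)(1−r)+r)`,
`ct_msd = b − log2(r)`, each plus independent Normal(0, 0.15) cycle noise
(typical qPCR replicate scatter; the protocol itself states none).
Relative amounts below 2^-40 of the mock — the 40-cycle protocol's
detection floor — are emitted as no-amplification. With noise and
refractory DNA switched off the fraction formulas invert this model
exactly (verified to < 1e-9), and the hidden truth table is emitted
alongside for recovery tests.

**What the simulator does not emulate.** Technical replicates,
plate/batch effects, amplification-efficiency variation, primer failure,
within-patient correlation of the cancer-adjacent samples with the index
tumor (no field effect is simulated, mirroring the reference finding), and
any bisulfite/HRM chemistry. Passing recovery tests therefore demonstrates
correctness of the pipeline arithmetic and sampling design, not robustness
to those real-data artifacts.

## Test and verification choices

* The fraction formulas are checked against a 50-digit mpmath
  re-evaluation on 10⁴ random quadruples (1e-9 absolute, relative above
  magnitude one, before clipping).
* Truth-level cell means are compared to the generator's analytic cell
  means at 3 SE per cell; with ~550 cells, up to 1% exceedances are
  tolerated (the expected 3-sigma exceedance rate is 0.27%). Measured
  (noisy) means are checked for the signature genes in the pooled tumor
  groups, where the refractory bias is far inside 3 SE.
* Signature recovery is evaluated on the 17 prevalence-anchored candidate
  genes: the derived signature contains ≥ 8 of the 10 configured
  high-penetrance genes and at most 12 genes in ≥ 90% of 100 seeds. Genes
  without a printed prevalence have no configured penetrance to recover.
* Paired-comparison detection uses the hypermethylated-gene count measure
  and the union-gene-set level measure. The per-sample level measure
  ("mean methylation over genes methylated in that lesion") conditions the
  shifted CRC lesion on exceeding the threshold, which raises its
  conditional mean and absorbs most of a mean shift — a selection effect
  inherent to that summary, documented here rather than hidden; the union
  convention is available via `union_genes=True`.
* Duplicate Ct wells are averaged with a flag (least destructive default;
  how the assay combined technical replicates, if any, is unstated).
* Sample SD uses the n−1 denominator throughout.

## Problem sizes

Default test and acceptance runs use the full 75-sample, 55-gene cohort;
recovery statistics use 100 seeds in the test suite and 30 in the
acceptance script, and the paired power property uses 200 replicates of 7
pairs × 10 genes. One cohort simulation plus the full pipeline takes about
0.2 s.
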