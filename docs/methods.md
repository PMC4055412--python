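# Methods

`bowtievar` analyses how protein abundance, cross-cell-line abundance
variability, and phylogenetic conservation distribute over the
functional layers of human signaling pathways, and how disease
mutations track those features.  The pipeline is exercised end-to-end
on synthetic data whose planted structure the analysis stages must
recover; this note describes the statistical models, the generator, the
numerical conventions, and the known limitations.

## The F statistic for expression variability

Input is a protein × sample intensity matrix from label-free
quantification over multiple cell lines with technical replicates.
Processing:

1. **Detection filter.** A protein is kept when it is quantified in at
   least 50% of the MS runs (inclusive boundary; `min_detect`
   configurable).
2. **Standardization.** Intensities are log10-transformed (they are
   approximately log-normal and span decades; `log10: false` disables
   this) and each sample column is z-scored over its detected entries.
   Missing values stay missing and are never imputed.
3. **Mean abundance** is the row mean of the standardized values.
4. **Variability.** For each protein a one-way ANOVA is computed with
   cell lines as groups on the detected standardized values:
   F = MSB / MSW, the between-cell-line mean square over the
   within-cell-line mean square, with the actual (unbalanced) per-group
   counts.  We use the df-normalized mean squares rather than a plain
   variance ratio because this yields a calibrated null: for k lines
   and r replicates of pure noise, F ~ F(k−1, k(r−1)), which the test
   suite verifies by simulation (10,000 proteins, KS test, and the
   closed-form mean df2/(df2−2) = 1.1 for k=11, r=3).

Rationale for the ratio: MS noise is larger for lowly abundant
proteins, so the raw standard deviation is negatively confounded with
abundance.  Both MSB and MSW carry the same per-protein noise scale, so
their ratio cancels it; `confound_check` reports Spearman(raw sd, mean
abundance) and Spearman(log F, mean abundance) as the diagnostic pair
(strongly negative / near zero on the synthetic worlds).

Edge cases: proteins with fewer than 2 detected lines, or fewer than 2
lines with ≥ 2 detected replicates, are excluded with a logged reason;
zero within-line variance yields an infinite sentinel F flagged
`undefined_msw_zero` and excluded from downstream distributions.  All
downstream displays and tests use log10 F.

Validation comparisons are provided for externally prepared reference
sets: a rank-sum test of log F between a housekeeping-like set and the
rest, and between the low- and high-variability quartiles of a
replicate-free tissue atlas (`mouse_quartile_sets`: proteins detected
in all tissues, mean log abundance above the global mean, split at the
sd quartiles, mapped through an ortholog table).

## Tree-based conservation score

Given a weighted species tree T with edge set E and branch lengths
w(e), and for protein i the set of species with a detectable homolog
(the reference species, human, always included), the score is

    c_i = Σ_{e ∈ E_i} w(e) / Σ_{e ∈ E} w(e)

where E_i is the edge set of the minimal unrooted (Steiner) subtree
spanning the retained tips.  An edge belongs to E_i exactly when both
components of the tree minus that edge contain a retained tip, so the
score is invariant to root placement and to rescaling all branch
lengths, and is monotone in the homology set.  The path from the
spanning subtree up to an arbitrary root is *not* counted; a protein
conserved only in the reference species scores 0, one conserved
everywhere scores 1.  The implementation indexes each edge by the tip
bipartition it induces (bitmask per edge) and scores all proteins with
one integer matrix product; the test suite checks it exactly against an
independent brute force (union of all pairwise tip-to-tip paths) on
random trees.

The loader requires branch lengths on every non-root edge and rejects
duplicate tip labels; homology tables listing species absent from the
tree are an error rather than a silent prune.

## Functional classes and bow-tie layers

Pathway annotation rows (protein, pathway, source, raw class) are
reduced to a unique functional class per protein; proteins supported by
two or more distinct classes are `ambiguous` and excluded from layer
analyses.  Classes pool into layers: receptors → input;
kinases, phosphatases, adaptors, GTPase-binding proteins, mediators and
cofactors → transmission; transcription factors → output; ligands and
ambiguous/unclassified proteins stay unassigned.  Because of the
uniqueness rule, a mediator or cofactor that is also a receptor or
transcription factor never reaches the transmission layer.

Comparisons are two-sided Wilcoxon–Mann–Whitney throughout
(threshold 0.01 by default), reported with direction, group sizes,
medians and IQRs.  The exclusive-vs-multiple analysis partitions
proteins by pathway count (=1 vs >1), compares the three features, and
reports per-class overrepresentation among multi-pathway proteins as
observed / (class frequency × set size).

Quantile binning (used for the binned conservation and variability
displays) is rank-based with ties assigned as a block to the lower bin.
Each bin boundary therefore moves by less than one tie group, so every
bin's occupancy deviates from n/k by less than the largest tie group
(two tie groups straddling both boundaries of one bin can make the
max–min spread exceed a single tie group; the per-bin bound is the one
that holds).  Binning requires at least k distinct values.

## PPI pair resampling

Six pair categories are sampled (default n = 1000 pairs): interacting
input–transmission (PPI-IT), transmission–output (PPI-TO), within-layer
(PPI-W), random interacting pairs within the annotated signaling
universe (PPI-Rand), non-interacting input–transmission pairs (Rand-IT,
rejection-sampled against the edge set with a 10n attempt cap), and the
permutation control Perm-IT (transmission endpoints of the PPI-IT
sample shuffled among pairs, preserving both endpoint multisets).  PPI
categories sample uniformly without replacement when enough eligible
pairs exist, with replacement (logged) otherwise.  Per pair the
statistic is |Δ log10 F|; distributions are compared with the rank-sum
test.  Rand-IT controls for layer membership alone; Perm-IT keeps the
marginals of the interacting sample and isolates the within-pair wiring
preference.  Proteins without a finite log F or without a unique layer
are excluded before sampling.

## The synthetic-data generator

All six inputs are generated jointly and consistently from one seeded
configuration; per-table seed streams are spawned from the master seed
so regenerating one table never perturbs another.

* **Latents.** log10 abundance a_i ~ N(7, 1) (arbitrary intensity
  decades).  Layers are drawn with fractions
  input/transmission/output/other = 0.25/0.35/0.15/0.25; each protein's
  variance factor is v_i = m_layer · exp(η), η ~ N(0, 1), with default
  multipliers 4/1/1/2 — the planted input-layer excess variability.
* **Intensities.** Replicate noise sd σ_i = 0.25 ·
  10^(−0.3·(a_i−7)) log10 units: lowly abundant proteins are noisier
  (the technical confound).  Between-cell-line offsets have sd
  τ_i = √v_i · σ_i — i.e. the biological between-line dispersion is
  expressed in units of the measurement scale, so the variance ratio F
  recovers the layer multipliers free of the abundance confound.  This
  is a deliberate generator design choice: it makes "F eliminates the
  technical confound" an exact property of the planted world rather
  than an approximation.  With r replicates, E[F] ≈ 1 + r·v_i.
* **Missingness** emulates a detection limit: below a latent-abundance
  threshold (placed so the overall missing-cell rate matches
  `missing_fraction`, default 0.08) proteins drop out of ~95% of runs
  and are subsequently removed by the 50% detection filter; the
  logistic transition is sharp (scale 0.1 abundance-sd), so partial
  detection is confined to a narrow boundary band.  A smooth
  missingness ramp is *not* used: it makes effective ANOVA group sizes
  drift with abundance and thereby re-introduces a spurious
  abundance–F association through the estimator's degrees of freedom.
* **Species tree and homology.** A random rooted binary tree over
  human + 13 species (uniform branch lengths 0.02–0.25).  Homolog
  retention per species is Bernoulli with a logistic probability:
  base 1.0, + 0.8 per abundance z-score (conservation–abundance
  coupling), + per-layer offsets (transmission +1.5, input/output −0.8
  — the planted bell shape), − 2.5 × the species' normalized tree
  distance from human (distant species retain fewer homologs).
* **Pathways.** Each protein joins one of ten pathway labels; the
  probability of joining additional pathways is logistic in the
  protein's conservation z-score around a base rate of 0.19, planting
  the "re-used proteins are more conserved" effect.  A 2% fraction
  carries a conflicting second class to exercise the ambiguity rule.
* **PPI edges** (4 per protein overall; 30% input–transmission, 15%
  transmission–output, 25% within-layer, the rest unstructured but
  excluding input–transmission combinations so the realized
  input–transmission mixture is exactly as configured).  With
  probability `wiring_assortativity` (default 0.8) an
  input–transmission edge is variability-discordant: it joins a
  top-5%-variability protein of one layer to a bottom-5% protein of the
  other, orientation by fair coin.  Coupled pairs are therefore
  extreme-unlike; permuting endpoints recombines half of them into
  concordant extreme pairs whose |Δ log F| collapses to the
  between-layer gap.  This realizes all three required contrasts
  simultaneously (interacting ≫ non-interacting, interacting ≫
  permuted, and exact null at assortativity 0).  A one-sided stratum
  bias cannot do this — permutation preserves marginals, and w² of the
  recombined pairs remain discordant — and a full-layer antithetic
  coupling is too weak once the layer gap and the F-estimation noise
  (log10 sd ≈ 0.28 at 11×3) are taken into account.
* **Mutations.** Conservation scores are binned into quintiles and
  per-protein counts drawn as Poisson with per-bin class rates:
  somatic [0.2, 0.6, 1.2, 2.0, 1.2] (peaking at high conservation),
  germline [0.5, 1.4, 2.0, 1.0, 0.3] (intermediate), SNP background
  [2.2, 1.8, 1.4, 1.1, 0.9] (declining).  Profile recovery is then a
  clean parameter-recovery test, and somatic carriers come out more
  conserved (and, through the layer structure, less variable) than
  germline carriers.

What the generator does **not** emulate: peptide-level artifacts,
shared-peptide protein inference, batch effects, realistic pathway or
PPI topology (no scale-free degree structure; the discordant strata
form dense bipartite blocks), sequence evolution, or linkage between
mutations.  Passing tests therefore demonstrate that the *statistical
machinery* recovers planted effects of realistic size under realistic
noise — not that the biological conclusions transfer to any particular
real data set.

## Statistical conventions

All tests are two-sided Wilcoxon–Mann–Whitney with mid-rank ties:
exact null when the smaller group has ≤ 10 observations and no ties,
otherwise normal approximation with tie and continuity correction.  At
the switch boundary the approximation agrees with the exact null to
within ~0.01 (and within 0.005 wherever p < 0.05).  p-values are never
clipped to zero: underflow is reported at the smallest positive float
with an `underflow` flag.  Correlations are Spearman by default
(Pearson on request) with pairwise deletion and a 10-pair minimum;
zero-variance inputs are flagged undefined rather than erroring.

Directions are only reported when the p-value clears the configured
threshold, and describe the first sample relative to the second.

## Problem sizes and determinism

The shipped demo configuration simulates 2,000 proteins; the test suite
uses 800–5,000-protein worlds, 50 seeded replicates for the
layer-gradient recovery and 200 seeded replicates at 4,000 proteins for
the wiring type-I calibration (4,000 keeps sampled pairs nearly
disjoint; in much smaller worlds the 1,000 sampled pairs share
endpoints, which correlates the |Δ| values and visibly inflates the
rank-sum type-I rate).  Every random choice flows from explicit seeds
— per-stage streams derived from one master seed by stable hashing — and
rerunning any configuration reproduces its report byte-for-byte
(timestamps are confined to the manifest).

## Known limitations

* The ANOVA F is undefined for proteins without replicate structure and
  is noisy at 11×3 (log10 sd ≈ 0.28 under the null); analyses that rank
  proteins by F inherit this noise.
* With heavy missingness the effective group sizes vary per protein;
  the F null then holds only approximately.
* The conservation score treats homolog presence as binary and ignores
  alignment quality or partial homology.
* The enrichment test is a plain hypergeometric with Bonferroni
  correction; it does not replicate EASE-style adjusted scores.
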