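# Methods

## Study design emulated

The pipeline targets whole-blood miRNA read counts from feedlot cattle in two
arms: a pre-treatment cross-section at week 0 (W0) with five groups — healthy
controls (HC, n = 12) and four lameness phenotypes, digital dermatitis
(DD, n = 24), foot rot (FR, n = 40), toe tip necrosis (TTN, n = 13), and FR
combined with DD (FRDD, n = 17) — and a longitudinal arm in which animals with
DD (n = 59), TTN (n = 31), or FRDD (n = 50) are sampled at W0, W1, and W2
after diagnosis and treatment. Each animal carries a 0–3 gait score per week;
an animal is *recovered* (RE) when its last gait score is strictly below its
first, otherwise *unrecovered* (UNR) — ties count as unrecovered, so the label
is a deterministic function of the trajectory.

## Expression calling and specificity rules

Counts are normalized to reads per million mapped reads with the per-sample
column total of the count matrix as denominator (the count matrix is the only
observable proxy for "mapped reads" once quantification has produced it):
rpm(i, s) = counts(i, s) / total(s) × 10⁶. A miRNA is *expressed* in a sample
when rpm > 1, with a deliberately strict inequality: an exact 1.0 is not
expressed. Group-level rules use the prevalence of that call:

* **group-expressed**: prevalence ≥ 0.6 within the group (`min_prevalence`);
* **phenotype-specific**: group-expressed in one phenotype and called in no
  sample of any other (`max_other_prevalence`, default 0 — the strictest
  defensible reading of "not in other groups"; both thresholds are
  parameters). With non-default thresholds one miRNA could formally qualify
  for two groups; it is then assigned to the group with the higher prevalence
  and dropped on a tie, so the per-group sets stay disjoint by construction;
* **time-point-specific**: group-expressed (same 0.6 rule applied within the
  phenotype-week stratum) at exactly one of W0/W1/W2.

Raising `min_prevalence` can only shrink a specific set and raising
`max_other_prevalence` can only grow it; this monotonicity is property-tested.

## Differential expression

For a two-group contrast (A, B) the model is a per-miRNA negative binomial
with log link and Var(Y) = μ + αμ². Depth is removed by median-of-ratios size
factors: with the geometric mean of miRNA i across samples as reference,
s_j = median_i exp(log c_ij − log-geomean_i) over miRNAs positive in every
sample, rescaled so the size factors have geometric mean 1. When no miRNA is
positive everywhere a poscounts-style fallback ignores zeros within each
miRNA's ratio set.

Dispersion is estimated by pooled method of moments on normalized counts,
α̂ = max(0, (s² − μ̄)/μ̄²) with s² the within-group pooled variance, then shrunk
50/50 toward a trend fitted by regressing α̂ on 1/μ̄. This is a deliberately
simplified stand-in for full RNA-seq dispersion machinery (no Cox–Reid
adjustment, no outlier handling); calibration rather than bit-equivalence to
any particular tool is the acceptance standard.

For the saturated two-level design fitted by quasi-likelihood on normalized
counts, the MLE of each group mean is its arithmetic mean of normalized
counts, so

  log2FC = log2(μ̂_B / μ̂_A),  Var(log μ̂_g) = (1/μ̂_g + α)/n_g,

and the Wald statistic log2FC/SE is referred to a standard normal, two-sided.
A group mean of exactly zero is replaced by a pseudo-mean of 0.5 normalized
counts, keeping fold changes finite while preserving direction. P-values are
Benjamini–Hochberg adjusted, and the DE call is |log2FC| > 1 and FDR < 0.05.
miRNAs with zero counts in every retained sample are excluded from testing.

Measured calibration (recomputed by `scripts/acceptance.py` on synthetic
counts, n = 20/group, α = 0.2): the type-I error at p < 0.05 sits near the
nominal level over thousands of null miRNAs, and a planted log2FC of 2 at
baseMean ≥ 50 is recovered with absolute bias well under 0.3. With strongly
asymmetric planted effects, part of the planted signal is absorbed into the
size factors (an inherent property of ratio normalization), which is the main
contributor to that residual bias.

Direction-wise summaries average log2FC over DE miRNAs split by sign and
round half-away-from-zero, which reproduces the reported per-phenotype
averages from the published fold-change tables at their printed precision
(−1.32, −1.15, −1.23/+3.31, −1.24/+1.26 for the W0 contrasts; −2.4/+3.7 for
unrecovered vs recovered). The published FR upregulated values average 1.58,
not the reported 1.68; that inconsistent value is excluded from the checks.

## Temporal patterns

Per stratum (phenotype × recovery status) the time course of each miRNA is
its average RPM at W0/W1/W2. Profiles are z-scored across time (population
standard deviation; flat profiles are flagged and excluded) and clustered by
fuzzy C-means: memberships u_ik ∝ d_ik^(−2/(m−1)) normalized per profile,
centroids v_k = Σ u^m x / Σ u^m, iterated until the largest centroid shift is
below 1e-6 or 1000 iterations. Membership rows sum to 1 and the objective
Σ u^m d² is non-increasing across iterations (both property-tested, and the
converged objective is checked against an independent plain-loop
implementation). Defaults: c = 9 clusters — one per nominal pattern category —
and fuzzifier m = 2, the FCM convention; both are parameters, since neither is
dictated by the data. Initial memberships come from a seeded generator, so
fits are reproducible; a *signature* miRNA has membership strictly above 0.7
in its argmax cluster (ties broken toward the lowest cluster index).

Discrete trends are called per consecutive-week interval with the same rule
as the DE stage (the only thresholds defined anywhere in the workflow):
U if log2FC > 1 and FDR < 0.05, D if log2FC < −1 and FDR < 0.05, else N.
Weeks are compared with the unpaired two-group machinery (animals treated as
independent per week; no pairing model is assumed). The two interval calls
concatenate into one of the nine patterns {D,N,U}² — the mapping is total and
injective, which is verified by exhaustive enumeration.

## Marker evaluation

The AUC of one miRNA for a two-class contrast is the Mann–Whitney U statistic
divided by n₀n₁, i.e. the concordance probability with ties counted ½
(verified against exhaustive pair counting). Orientation is resolved
automatically so AUC ≥ 0.5, and the chosen direction is reported so the
decision is auditable. Bands partition [0, 1] with lower-inclusive intervals —
excellent [0.9, 1], good [0.8, 0.9), fair [0.7, 0.8), weak [0.6, 0.7),
fail [0.5, 0.6), below [0, 0.5) — resolving the shared printed endpoints in
favour of the higher band, consistent with 0.8 being called "good". No
confidence intervals are computed; the evaluation reports point AUCs only.

## ΔΔCt quantification

Per sample, ΔCt = Ct_target − mean(Ct_ref1, Ct_ref2) (arithmetic mean of two
reference Ct values, equivalent to a geometric mean of linear quantities);
ΔΔCt subtracts the calibrator group's mean ΔCt; fold change = 2^−ΔΔCt with
amplification efficiency fixed at 2. The calibrator group's geometric-mean
fold change is 1 by construction, and a per-sample additive Ct offset cancels
exactly. Concordance with sequencing is judged on direction only: the sign of
the log2 ratio of group geometric-mean fold changes against the sign of the
sequencing log2FC.

## Synthetic data generator

The generator is the package's test bed and defines the conditions under
which every property is demonstrated:

* **Abundance profile**: ten dominant miRNAs share 85% of the mass
  (Zipf-weighted), matching the observation that the top-10 miRNAs carry more
  than 80% of reads; the tail is log-normal (σ = 1.2). Planted specific
  miRNAs are inserted at their target RPM (1–10 RPM is the realistic range
  for such markers) and zeroed in all non-target groups — the strictest
  reading of "not in other groups".
* **Depth**: log-normal library sizes, mean 6.7 × 10⁶ reads/sample (the
  study's 709 M reads over 106 W0 samples), CV 0.3 (not reported; a typical
  depth spread, stated here as an assumption).
* **Noise**: NB dispersion α = 0.2 (not reported; a typical bulk blood
  small-RNA value), single global α — Var = μ + αμ², the standard RNA-seq
  convention.
* **Effects**: planted DE multiplies one group's mean by 2^log2FC; planted
  patterns apply cumulative per-week multipliers with interval |log2FC| = 2
  (comfortably above the |log2FC| > 1 call threshold); gait trajectories are
  monotone consistent with the planted recovery label, so the label is
  recoverable from the scores.
* **Truth**: every planted effect is recorded in truth tables; nothing else
  in the generative model is differential, specific, or patterned.

What passing tests do *not* show about real data: the synthetic tail contains
no miRNAs hovering at the RPM ≈ 1 expression boundary (the log-normal tail at
this depth sits well above it), so the measured perfect precision of the
specificity rules reflects clean separation that real low-abundance miRNAs
will not always offer; per-miRNA dispersion variation, batch structure,
within-animal correlation across weeks, and compositional effects of a few
dominant miRNAs changing are all absent. Real-data quantities that depend on
the original sequencing cohort (total expressed miRNA counts, per-group Venn
overlaps, specific marker identities, observed AUCs) are therefore outside
what this package can or does reproduce.

## Problem sizes and numerical choices

Calibration runs use 2 500 miRNAs × 20 samples/group for the Wald test,
10 independent seeds for specificity recovery at the study's group sizes, and
1 000 random instances (n₀n₁ ≤ 400) for the AUC oracle — sizes chosen so the
whole suite and the acceptance script each finish in seconds while leaving
Monte-Carlo error far smaller than the acceptance margins. Ties in argmax
operations break toward the lowest index; FCM distances of exactly zero give
one-hot memberships split over the zero-distance centroids; BH adjustment is
permutation-invariant and capped at 1 (it is not idempotent in general — a
second application can change already-adjusted values — so no such claim is
tested). All randomness flows through explicit integer seeds.
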