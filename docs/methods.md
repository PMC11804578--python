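# Methods

## Study design and data model

The analysis assumes two bulk RNA-seq experiments on the same four
populations: two coast/mine ecotype pairs ("W" and "E"), three individuals
per population, two treatments per experiment (control + 0.1 M NaCl in the
salt experiment; control + zinc in the zinc experiment), one pooled sample
per individual per treatment — 24 samples per experiment. Counts are
genes × samples integer matrices; a sample sheet records population,
ecotype, pair, individual, treatment and experiment. Coastal populations
are treated as a proxy for the ancestors of the mine populations.

## Low-count filtering and cross-experiment comparability

A gene is retained only if **every** sample count is at least `min_count`
(default 10) within its experiment's matrix. This is the stricter of two
defensible readings of a per-sample count floor; the alternative — drop
genes whose *total* count is below the floor — is available via
`filter_mode="total"`. The strict reading keeps matrices rectangular and
makes the filter idempotent.

Because the two experiments were grown and sequenced separately, genes are
further restricted to a *comparable* set: those with no significant
control-vs-control difference between experiments. The default demands a
non-significant cross-experiment call in **all four** populations
(`comparability_mode="per_population"`); a pooled-controls contrast is
available as `"pooled"`. Both modes exist because either reading is
compatible with a filter defined as "no significant DE in control
conditions between experiments".

## Differential expression engine

The engine is a deliberately reduced NB Wald workflow:

- **Normalization** — median-of-ratios size factors. Reference genes are
  those with no zero count; `pseudo_reference=True` switches the geometric
  mean to positive counts only when no such gene exists.
- **Dispersion** — per-gene method of moments on normalized counts pooled
  within conditions, `alpha_mom = max(0, (s² − m)/m²)`; a least-squares
  trend `alpha(mu) = a0 + a1/mu` over positive estimates; final dispersion
  `w·alpha_mom + (1 − w)·trend` with `w = df/(df + 4)` (df = samples −
  groups). The prior weight 4 is a simple stabilizer for n = 3 designs and
  is configurable (`shrink_prior_df`).
- **Testing** — under a cell-means NB model the MLE of each condition mean
  is the average of normalized counts, so log2 fold changes are closed
  form. The Wald SE comes from the delta method on the NB variance
  `mu/s_j + alpha·mu²`; p = 2(1 − Φ(|lfc/se|)). Genes with all-zero counts
  in both conditions get lfc = 0, p = 1. Condition means are floored at
  0.5 normalized counts so fold changes stay finite.
- **Paired designs** — treatment-vs-control within a population uses the
  mean per-individual log-ratio, which removes additive individual effects
  exactly; this implements within-population individual blocking without a
  full nested-factor GLM solver (`paired_plasticity=False` disables it).
- **Multiple testing** — Benjamini–Hochberg over exactly the tested gene
  set (statsmodels backend); direction calls are up/down when
  padj ≤ alpha with a matching log2fc sign, ns otherwise, with
  padj = alpha counted as significant.

There is no Cox–Reid adjustment, no fold-change shrinkage, no independent
filtering and no outlier replacement. Correctness is argued by
calibration, not numerical identity with any reference package: on a
2,000-gene null simulation at the study design (3 vs 3, dispersion 0.05)
raw p-values sit within KS distance 0.05 of uniform and BH discoveries at
alpha = 0.05 are ≤ 0.5% of genes (the acceptance suite re-runs this).

## Contrast catalog and classification

Per comparable gene the catalog holds 8 plasticity calls P(pop, cue), 6
divergence calls D(pair, treatment ∈ {control, salt, zinc}) and the 4
comparability calls X(pop). Divergence is signed mine-over-coast;
plasticity is treatment-over-control. Constitutive divergence
D(pair, control) is computed from the zinc experiment's control samples by
default (matching the experiment in which constitutive divergence was
originally defined); `control_divergence_from="salt_expt"` switches it.

A call is *shared* for an ecotype when both of its populations are
significant in the same direction. Categories:

- **evolved zinc plasticity** — shared mine zinc response AND
  D(pair, zinc) significant in both pairs; the subset whose shared coastal
  zinc call differs from the shared mine zinc call (in direction or
  significance) counts as having a *changed* plasticity and is the
  cue-transfer denominator.
- **cue transfer** — shared coastal salt direction d_s; shared coastal
  zinc call ≠ d_s (not shared, or shared in another direction); member of
  the evolved-zinc-plasticity set; shared mine zinc direction = d_s.
- **constitutive EC** — D(W, control) and D(E, control) significant in the
  same direction.
- **genetic adoption** — shared coastal salt direction d_s; constitutive
  EC direction = d_s; zinc call ns in *both* mines; shared coastal zinc
  call ≠ d_s.
- **genetic assimilation** — constitutive EC direction equal to the shared
  coastal zinc direction, zinc call ns in both mines. Disjoint from
  adoption by construction (coastal zinc ≠ vs = the EC direction).
- **preadaptive** — all eight P calls significant in one common direction.

"Not the same response" is evaluated on *shared* coastal calls: a gene
whose two coasts disagree on the zinc direction counts as "not the same".
The four principal categories are pairwise disjoint; this is re-verified
at run time and any overlap aborts with a diagnostic. Genes in the
evolved-plasticity or constitutive-EC sets but no principal category are
labelled `evolved_plasticity_unclassified` / `constitutive_unclassified`
(in that precedence), everything else `none`.

Headline percentages use exact decimal arithmetic with ties rounded away
from zero — integer percentages at 0 decimals, transcriptome fractions and
the plasticity-loss percentage at 2 decimals.

## Resampling statistics

- **Overlap randomization** — observed count of direction-matched shared
  genes; the null reassigns one call set's up- and down-labels to random
  distinct genes of the universe (the other set fixed);
  p = (1 + #{perm ≥ obs})/(n_perm + 1), so the smallest attainable p is
  1/(n_perm + 1). Permutations are unstratified (no expression matching).
- **Chance proportion** — the probability a gene satisfies a category rule
  when every contrast's calls are independently permuted across genes,
  with its Monte-Carlo SE; this feeds a one-proportion chi-square
  `(x − n p0)²/(n p0 (1 − p0))` on 1 df (optional continuity correction).
  The permutation estimate is used because no closed-form null proportion
  is assumed; the chi-square accepts any user-supplied p0. In the
  pipeline, p0 is floored at one pseudo-count to keep the statistic
  defined when no permutation satisfies the rule.
- **P_ST** — for a trait y with two populations,
  σ²_B = variance of the population means about their unweighted grand
  mean (df = 1), σ²_W = pooled within-population variance, and
  P_ST = (c/h²·σ²_B)/(c/h²·σ²_B + 2σ²_W). `c_over_h2` defaults to 1, the
  conservative common convention when neither c nor h² is estimated.
  Traits: log2 normalized control expression for constitutive candidates;
  the per-individual log2(zinc/control) normalized ratio for plastic
  candidates (a variance-stabilized version of the fraction of zinc over
  control expression; the untransformed ratio is one `np.exp2` away).
  Bootstrap CIs resample within populations with replacement and take the
  2.5/97.5 percentiles; the point estimate is appended to the bootstrap
  sample so the interval always contains it. A gene "exceeds neutrality"
  when its P_ST point estimate is above the (1 − alpha) empirical quantile
  of the pair's genome-wide F_ST distribution; comparing `ci_low` instead
  is a stricter variant left to the caller.

## Synthetic data generator

Counts are NB with variance mu + alpha·mu² drawn per condition mean;
baseline means are log-normal (default log-mean 6.5, log-sd 1.0, i.e.
median ≈ 665 counts — high enough that two-fold down-regulated planted
genes rarely fall under the count floor); gene dispersion follows
alpha(mu) = a0 + a1/mu with defaults a0 = 0.05, a1 = 0 (the dispersion at
which the recovery and calibration suites are specified); per-sample
library depth is multiplicative log-normal with sd 0.15, exercising the
normalization. Planted classes (defaults: 2% each of preadaptive, cue
transfer, genetic adoption, genetic assimilation, mine-only evolved
plasticity and lineage-specific response; 4% coastal-only salt plastic;
84% null) receive signed effects of |log2fc| = 2 with directions
randomized per gene; cue-transfer and adoption genes get a coastal zinc
response that is absent or opposite with probability ½ each. Individuals
are exchangeable — no planted individual effect — so the paired design is
exercised for its variance behaviour, not for confounder removal. The
generator does not emulate: count outliers, correlated genes, GC/length
biases, partial parallelism of effect sizes between pairs, or mappability
artifacts. Passing recovery tests therefore shows the decision rules and
engine are correct under the declared model, not that real-data power
equals the synthetic power. A synthetic neutral F_ST null is drawn from
Beta(0.8, 3) (right-skewed, mean ≈ 0.21, a plausible genome-wide profile
for recently diverged pairs); real genome-wide F_ST values can be supplied
as single-column TSVs instead.

## Reproducibility and problem sizes

A single master seed is fanned out to per-stage child seeds through a
`SeedSequence`, so stages are individually reproducible and a repeated run
is byte-identical (tables are written with 12-significant-digit floats,
"NA" for missing). `relaxed_fdr_rerun` re-thresholds the stored adjusted
p-values at a new alpha and reclassifies without re-simulating; the
comparable universe is kept fixed, since the comparability filter is part
of data assembly rather than of the hypothesis tests.

Default problem sizes: the acceptance script simulates 20,000 genes;
recovery suites use 10,000; calibration suites 2,000 null genes;
randomization tests 10⁴ permutations (200–2,000 where only calibration,
not resolution, is at stake). These sizes give Monte-Carlo error well
inside the asserted tolerances while keeping a full run in seconds on one
CPU.

## Known limitations

- The Wald normal approximation with n = 3 per group is slightly
  anti-conservative in the extreme tail; BH at alpha = 0.05 keeps realized
  false positive rates within the calibration bounds above, but raw
  p-values below ~1e-4 should not be over-interpreted.
- The chance-proportion permutation destroys between-contrast dependence;
  if calls are positively dependent under the null the chi-square against
  the permutation p0 is anti-conservative. The test object here is the
  planted, strongly non-null structure, where this is immaterial.
- P_ST with three individuals per population estimates σ²_W on 4 df; the
  point-estimate exceedance criterion is therefore optimistic for single
  genes and is meant for set-level fractions.
- Generalization beyond two population pairs is structurally possible but
  untested.
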