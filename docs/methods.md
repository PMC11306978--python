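# Methods

This note documents the models, parameter defaults and numerical choices
behind `fractiomics`, and what the synthetic-data tests do and do not show
about real data.

## Ks mixture model and WGD dating

Synonymous substitutions accumulate roughly clock-like, so paralog pairs
created by one WGD share a common Ks mode and a genome's paralog Ks
distribution is modelled as a k-component Gaussian mixture. The fitter
(`fractiomics.dating.fit_ks_mixture`) is a standard EM implementation with:

- 10 random restarts, means initialised at jittered spread quantiles of the
  data, uniform weights, common initial variance;
- convergence at a relative log-likelihood change of 1e-8, capped at 1,000
  iterations (the `converged` flag records whether the cap was hit);
- a σ floor of 1e-4 to prevent variance collapse onto duplicated values;
- a per-iteration assertion that the log-likelihood never decreases — an EM
  implementation error, not a data problem, if it fires.

Ks is nonnegative, so the Gaussian model is truncated at zero in reality.
The default fit ignores truncation (adequate when peaks sit several σ above
zero); `truncated=True` switches to zero-truncated component densities with
moment-matched M-step updates solved numerically. For a mixture with modes
0.34 (σ 0.15) and 0.96 (σ 0.42) the untruncated fit biases the upper mean
upward by roughly +0.04; the truncated variant removes most of that bias and
is the right choice when accuracy of the older peak matters. The number of
components is the caller's (two for a genome with a lineage-specific WGD on
top of the shared α event); `select_k_bic` offers a BIC scan.

Peak-to-age conversion is linear through a calibration point,
`T = μ · T_calib / Ks_calib`, with the α-WGD anchor (Ks 0.96, 32.42 Ma) as
default. With these defaults a peak at 0.34 dates to 11.48 Ma. The estimate
is a *minimum* age in the same sense as the calibration is.

TE copies are dated as `T = d / r` from divergence-to-consensus *d* with
`r = 8.22e-9` substitutions/site/year. A `pairwise` mode (`d / 2r`) is also
provided: the single-lineage reading treats the consensus as the ancestral
state (appropriate for divergence-to-consensus data) while the pairwise
reading halves ages; which one a published age range used is not always
recoverable, so the mode is explicit in the model object and recorded in
outputs. Burst detection histograms divergences (bin width 0.005), smooths
with a 3-bin moving average using edge-replicated padding (a flat histogram
stays flat, so boundaries cannot fake peaks), and reports local maxima above
a prominence threshold (default 10% of the tallest bin).

## Syntenic windows

Anchors are one row per reference gene in order, with 0–2 retained copies on
two "copy tracks". A window opens at a run of ≥ 10 consecutive anchors with
*both* copies present and extends left-to-right to 100 reference genes.
Extension stops early when either track accumulates a run of more than 20
consecutive anchors without that copy. The nonsyntenic limit is a *run*
(max-gap) rule, not a cumulative count: at realistic fractionation rates
(~0.43 retention on the MF side) a cumulative count of missing copies would
exceed 20 in essentially every 100-gene window and no windows could exist;
a gap rule is also the standard collinearity-scan convention. Placement is
greedy left-to-right, windows never overlap or cross reference-chromosome
boundaries, and a trailing run of anchors with no copy at all is trimmed.

## Subgenome assignment

Each retained pair has a gene tree containing both copies and three
outgroup-side taxa, two of which (`progenitor_1`, `progenitor_2`) mark the
two progenitor lineages. A tree votes for an orientation when a copy is the
immediate sister of an anchor taxon; per window the majority orientation
wins, support is the winning vote fraction, ties break deterministically
(copy track a to the first anchor's side) and are flagged low-confidence, as
is any window below the support threshold (default 0.6). Genome-wide, the
side with more retained genes is labelled LF, which makes the invariant
"LF total ≥ MF total" true by construction — the biological claim being
tested downstream is the *per-window* retention asymmetry, not the label.

## Bias partitioning

Per window, a 2×2 χ² test (no continuity correction by default; Yates
behind a flag) on (retained, lost) × (LF, MF). p > α (default 0.05) is
low-bias; p ≤ α with an MF retention deficit is high-bias; a significant LF
deficit is reported separately as inverse-bias rather than folded into
either class. Windows with a zero margin (all retained or all lost on both
sides) carry no evidence and default to p = 1. The per-window α is
deliberately not multiplicity-adjusted — the partition is a descriptive
classification, not a family of hypotheses — but a BH-adjusted variant is
available behind a flag. Note the consequence: at 100 genes per window a
0.57 vs 0.43 retention contrast has roughly 50% power, so the detected
high-bias count underestimates the planted one; the type-I rate at equal
retention is calibrated (≈ 5%) and tested.

## Selection, expression and DE

Ka/Ks bands: purifying ω ≤ 0.787, neutral 0.787 < ω ≤ 1.213, positive
ω > 1.213, undefined when Ks = 0 or missing. The 0.213 half-width is a
printed convention carried as the default; `sd_width` is a parameter.

"Expressed" means mean TPM > 1 in at least one condition (the replicate
aggregation had to be fixed somewhere; the mean is the least surprising
choice). DE per treatment: log₂FC on pseudo-counted condition means
(c = 1), two-sided Welch t on log₂(TPM+1) replicates, BH across genes
within a treatment, flag = |log₂FC| > 1 ∧ q ≤ 0.05 ∧ expressed. This is a
deliberately simple, fully specified replacement for count-model DE
machinery: what downstream stages consume is only the flag contract. With
triplicates and a 2-log₂ effect the rule reaches ≥ 90% sensitivity at
replicate noise of 0.15 log₂ units, the generator's default; at noisier
replicates (≥ 0.3) sensitivity degrades steeply because 3-replicate
variance estimates are unstable — a real limitation of any t-based rule at
n = 3.

TE proximity: per gene, the minimum distance over all TEs and both flanks
(0 if overlapping), strand-agnostic, binned 0 / 1–200 / 201–2,000 /
> 2,000 bp; the per-bin effect is the median-expression reduction versus the
far bin, reported both as a percentage and as log₂(median_far/median_bin),
with a rank-sum test per bin. The percentage and the log₂ value answer
slightly different questions and are intentionally reported separately.

## Duplicate fates

The cascade (neutral → neofunctionalization → dosage-balance without /
with shared trigger → both lost → one conserved + one constitutive →
gain → other) is evaluated in a fixed order; a pair that both lost an
ancestral trigger and gained a novel one counts as a gain. "Same trigger"
means set equality with the progenitor by default; a relaxed
nonempty-intersection mode exists. "Constitutively expressed" means
expressed with an empty trigger set. The residual `other_change` bucket is
explicit: partial trigger retention without gain does not fit the named
categories and is not silently reassigned.

`summarize_fates` reports per-category proportions (summing to 1) and two
headline shares: the dosage-balance share (no-trigger + same-trigger
categories) and the trigger-change share defined as its complement, so the
two headline numbers always sum to 100%. The rare neutral and
neofunctionalization pairs are therefore inside the complement as well as
reported separately — the convention that makes the headline pair of
numbers self-consistent.

## The synthetic generator

`simulate_dataset` plants, per window: a bias class (36/122 windows
low-bias by default), a random track-to-subgenome orientation, retention
draws (LF 0.57 / MF 0.43 in high-bias windows, the midpoint 0.50 in
low-bias ones), and a 12-anchor fully retained seed run at the window start
with the remaining genes' retention probabilities adjusted so the expected
window-level retention still equals the configured values. The seed run
reflects that detectable windows are, by construction of the window rules,
conditioned on containing a collinear seed; without it, independent
per-gene retention would almost never produce 10 consecutive intact pairs
and the window detector would correctly find nothing.

Other planted structure:

- paralog Ks per pair from the two-mode mixture (0.34/0.15, 0.96/0.42),
  zero-truncated by resampling;
- per-gene ω by selection class (99.65% purifying / 0.2% neutral / 0.15%
  positive per gene); purifying ω is linearly coupled to baseline log₂
  expression (slope −0.10, intercept 0.45, noise σ 0.08, clipped to the
  purifying band) so the expression–selection regression has a planted
  negative slope;
- TE proximity: each gene draws a distance bin
  (5% overlap / 15% near / 30% mid / 50% far) and gets a TE placed at an
  explicit distance; genes with a TE within 2,000 bp have baseline
  expression reduced by 1.83 log₂ units. Additional distal "filler" TEs
  (≥ 2,500 bp from any gene, so they can never change a bin assignment)
  realise the per-subgenome TE density targets (LF 150,000 / MF 250,000
  bp/Mb — gene-space values chosen as realistic for a TE-rich mesopolyploid
  whose syntenic windows are gene-rich, with the MF > LF contrast being the
  qualitative condition of interest);
- TE divergences from a bimodal mixture at 6% and 10% (σ 1%), planting two
  amplification bursts;
- progenitor triggers: 20% of reference genes are responsive (1–2 of cold,
  heat, drought, herbivory); each retained copy then conserves (0.20),
  loses (0.70) or gains (0.10) relative to the progenitor, and triggerless
  progenitors' copies gain at 0.10. Gains on the LF track of high-bias
  windows prefer cold (probability 0.6), planting the enrichment of
  cold-responsive genes in high-bias LF regions;
- expression: baseline log₂ TPM ~ N(3, 2) with a 10% silent fraction at
  N(−3, 1); triggered conditions add 2 log₂ units; replicate noise
  N(0, 0.15) per replicate (three replicates per condition); TPM is assumed
  normalised upstream — the generator emits no library-size distortion;
- gene trees: one 5-taxon Newick per pair with the subgenome-1 copy sister
  to `progenitor_1`; 10% of trees are flipped to emulate phylogenetic error;
- conserved-orthogroup presence: independent Bernoulli at 0.938 per
  reference gene — presence of an orthogroup anywhere in an assembly is a
  different quantity from retention inside syntenic windows and is planted
  separately.

Ground-truth fate categories are produced by applying the fate cascade to
the planted labels; the cascade itself is verified against an independent
exhaustive truth table, so the round-trip test isolates DE-calling noise
from classifier correctness.

What the generator does *not* emulate: sequence evolution (no FASTA, no
alignment artefacts), physical gene-length and spacing variation (uniform
2 kb genes every 20 kb on artificial chromosomes), correlated fractionation
beyond the seed run (real fractionation removes runs of adjacent genes),
count-level sampling noise in expression (TPM is log-normal, not a
count model), incomplete or erroneous collinearity anchors, and
assembly/annotation error. Passing recovery tests therefore demonstrates
correctness of the analysis logic under the stated generative assumptions,
not robustness to real-data artefacts.

## Problem sizes and determinism

Default study-scale runs use 122 windows × 100 reference genes (~12,000
retained genes, ~3,400 pairs, ~95,000 TEs); unit and integration tests use
12–30-window bundles, which keeps planted-effect recovery inside useful
tolerances while the whole suite stays fast. All randomness flows from a
single `numpy` Generator seeded from the config; identical seed and config
give byte-identical written bundles, and the acceptance script derives all
of its randomness from its `--seed` argument.

## Known limitations

- Subgenome assignment needs progenitor-side anchor taxa in the trees; trees
  with both copies sister to each other are uninformative and skipped.
- The window scanner assumes a dense anchor table (one row per reference
  gene); sparse tables where `ref_index` jumps would miscount capacity.
- The χ² bias partition at 100-gene windows has limited power for retention
  contrasts of the planted magnitude; counts of significant windows are
  conservative.
- The Welch-t DE rule is underpowered below ~3 replicates or above ~0.3 log₂
  replicate noise; the counts-based exact mode is a Poisson approximation
  that ignores overdispersion.
- The truncated-EM M-step is a moment-matched approximation, not an exact
  maximiser; for peaks several σ above zero the difference is negligible.
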