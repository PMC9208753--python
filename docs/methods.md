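# Methods

This note records the models, parameter choices, and numerical decisions
behind `paraspec`, and what its synthetic-data tests do and do not show
about real data.

## Sequence evolution and likelihood

Substitution follows a time-reversible amino-acid model: exchangeabilities
`s_ij` (symmetric, non-negative) and equilibrium frequencies `π` define
the generator `q_ij = s_ij π_j` (i ≠ j), diagonal set so rows sum to
zero, scaled so the expected rate at equilibrium is exactly 1 — branch
lengths are therefore substitutions per site.  Two matrices ship as
plain-text data files: LG (the Le & Gascuel 2008 empirical matrix, the
standard general-purpose choice for globular proteins) and Poisson
(equal rates, uniform frequencies), the natural null for model
comparison.  Both are fixed constants and contribute no free parameters.

Rate heterogeneity across sites uses the discrete-gamma approximation:
`k` equal-probability categories of a mean-1 gamma distribution with
shape `α`, each category carrying the conditional mean of its slice.
Defaults are `k = 4` (the community standard; more categories change
likelihoods marginally at real alignment sizes) and `α` either supplied
or estimated by bounded one-dimensional maximum likelihood (Brent on
log α in [0.02, 100]) during model selection, where it counts as one
free parameter.  AIC is `2k − 2 lnL`; ties go to the smaller model.

The site likelihood is computed by Felsenstein pruning over the
category mixture.  Transition matrices come from the symmetric
similarity transform `diag(√π) Q diag(1/√π)`, whose eigendecomposition
is real; tiny negative entries from rounding are clipped and rows
renormalized (deviations are ~1e-16).  Identical columns are collapsed
to weighted site patterns before any computation — an exact
transformation, asserted against per-column evaluation in the tests.
Partial likelihoods are rescaled at every internal node with the log
factors carried separately, so deep trees cannot underflow.  Gaps and
`X` are missing data: a leaf contributes a partial-likelihood vector of
ones, never a 21st state.  Branch lengths are taken as given; there is
no topology search or branch-length optimization (trees are inputs,
produced upstream by dedicated inference tools).

Rooting on an outgroup places the new root at the midpoint of the branch
whose bipartition separates the outgroup from the rest (an error names
the offending bipartition if no such branch exists).  The midpoint is
arbitrary for likelihood purposes — reversibility makes the likelihood
and all node posteriors independent of root placement, which the tests
verify to 1e-8 — it simply avoids inventing asymmetry the data cannot
see.

## Ancestral reconstruction

Reconstruction is marginal (empirical-Bayes): for one internal node and
site, the posterior over the 20 residues marginalizes all other
ancestral states and the rate category, with the category weighted by
its posterior given the whole site pattern.  One postorder pass
(likelihood of each subtree) and one preorder pass (likelihood of
everything outside the subtree) give every node's posteriors without
re-rooting; both passes are checked against clamp-and-renormalize
exhaustive enumeration on quartets to 1e-9.  Joint reconstruction and
ancestral-gap inference are deliberately out of scope — the downstream
analyses consume per-site posteriors.

The MAP ancestor takes the best residue per site; its confidence summary
is the mean of the per-site maxima.  Exact ties (possible on symmetric
models) are broken toward the alphabetically smaller residue and
flagged.  A site is *ambiguously reconstructed* when at least two
residues have posterior strictly greater than τ = 0.2; the AltAll
ancestor substitutes the second most likely residue at exactly those
sites.  Since two residues above 0.2 is impossible when the maximum
exceeds 0.8, high-confidence ancestors have AltAll ≡ MAP, which the
tests assert.  Strict inequality at τ follows the conventional "> 0.2"
definition; the difference matters only at exact boundary values.

On simulated 16-leaf balanced trees (branch length 0.05, LG+gamma,
300 sites, 20 replicates) root MAP accuracy averages ≈ 0.95, and
binning sites by their maximum posterior shows empirical accuracy
within ±0.08 of the bin's mean posterior — the posteriors are honest.
This holds under the generating model; on real data, model violation
makes posteriors optimistic, which is exactly why AltAll robustness
checks matter.

## Cognate-pair matching

HK–RR operons make genomic adjacency the pairing signal: two genes pair
iff they sit at consecutive gene-order positions on the same contig,
have opposite roles, and neither has a second adjacent candidate.  Any
gene with ≥ 2 adjacent opposite-role candidates is ambiguous; it *and
all its candidates* are dropped ("cluster"), a deliberately conservative
reading of cluster removal.  Genes with no adjacent partner drop as
"orphans".  Strand is recorded but not filtered on (divergently
transcribed adjacent pairs are kept; a future option could exclude
them).  Matched pairs merge into `<hk>__<rr>` records, HK columns first,
with a column-provenance map that makes the merge exactly invertible.
Inputs are assumed to be catalytic-domain alignments; removing sensory
domains is upstream of this package (a column-slicing utility is
provided, domain-boundary detection is not).

## Paralog profiling

Clade residue frequencies are computed over non-gap characters only.  A
position is called paralog-specific when a single residue, or a declared
chemical class (defaults: acidic {D,E}, basic {K,R}), reaches ≥ 0.9 in
one clade while staying ≤ 0.1 in the other.  The 0.9/0.1 thresholds
mirror the ">90 % / none-or-<10 %" language used when such positions are
described in the literature; comparisons are inclusive at the threshold
and boundary hits are flagged.  Alignment trimming removes columns with
non-gap fraction strictly below 0.5, then columns whose majority non-gap
residue falls strictly below 0.25 of the non-gap count; trimming is
idempotent.  Mutation bookkeeping (`R27Q` etc.) resolves positions
through a reference-numbering map and refuses to apply a substitution
whose stated wild type disagrees with the sequence — the guard that
catches numbering drift between alignments.

## Phosphotransfer kinetics

The simulator integrates mass-action transfer with bifunctional-HK
phosphatase activity:

    d[HK~P]/dt = −k_t [HK~P][RR]
    d[RR~P]/dt = +k_t [HK~P][RR] − k_p [HK][RR~P]

with `[HK] = hk_total − [HK~P]`, `[RR] = rr_total − [RR~P]`, starting
from fully phosphorylated kinase.  Defaults: 1 μM HK, 4 μM RR (the 1:4
assay ratio), `k_p = k_t/10` — an order-of-magnitude guess, flagged as
such, since quantitative phosphatase rates are not available; the form
reproduces the qualitative rise-then-fall of phospho-RR.
Autophosphorylation during the chase is omitted (phospho-HK is stable
over the assay window in the absence of regulator).  Integration is
adaptive Runge-Kutta at 1e-8 tolerance, cross-checked against a
fixed-step RK4 oracle to 1e-6.  Measurement noise is multiplicative
lognormal (σ default 0.05) — densitometry noise scales with band
intensity — applied before normalization to t = 0.

Rate estimation offers the field's two-point window estimator
(fractional phospho-HK loss by 30 s for cognate pairs, 5 min otherwise;
the nearest observation within ±20 % of the window is used and divided
by its actual time) and a log-linear estimator (slope of ln intensity
over points ≥ 0.1), which is unbiased for exponential decay and is the
recommended default on simulated data.  Negative rates from noise are
reported with a warning, never clamped.  Fold-preferences are ratios of
two such rates sharing a protein; because both reactions share
`[HK~P]₀` and `[RR]₀`, the rate ratio estimates the k_cat/K_M ratio in
the sub-saturating regime.  k_cat and K_M are never reported separately
— only the ratio is identifiable from these data.

One structural point governs quartet simulations: for any four rates
a = k(HK1,RR1), b = k(HK1,RR2), c = k(HK2,RR1), d = k(HK2,RR2), the
identity (a/b)(d/c) ≡ (a/c)(d/b) couples the four fold-preferences —
the HK folds' product equals the RR folds' product.  Fold sets measured
from *separate* experiments need not satisfy it (each carries its own
measurement error), so the package's demonstration quartet keeps the two
headline folds exact (28 for the post-duplication kinase, 4.5 for the
regulator) with the preference-free kinase fold at 1, which pins the
second regulator's fold at 28/4.5 ≈ 6.2; the per-experiment
fold-reproduction analysis in `scripts/acceptance.py` instead simulates
each fold's experiment pair independently, matching how such numbers
are measured in practice.

## Synthetic study conditions

The generators default to the regimes the analyses are validated in:

* *oracle checks* — 4-leaf random trees (mean branch 0.35), random
  reversible models with and without 2-category gamma, 5 sites: small
  enough for exhaustive enumeration over all 20³ internal assignments;
* *ancestral recovery* — 16-leaf balanced trees, branch length 0.05,
  LG+gamma(α = 1, k = 4), 300 sites, 20 replicates;
* *paralog profiling* — two 48-leaf clades (within-clade mean branch
  0.1, i.e. substantial within-paralog diversity) joined by 0.25 stems
  (an ancient duplication), 204 columns of which 4 carry planted
  diagnostic residue sets, 10 replicates.  Clade sizes approximate, at
  desk scale, the thousands-strong ortholog sets such profiling is run
  on in practice; planted recall is 100 % and the neutral-column
  false-positive rate ≈ 4 % — fixation by drift along the stem, the
  scan's irreducible background;
* *kinetics* — transfer constants 1e-4–6e-3 μM⁻¹s⁻¹, sampling grids
  spanning one half-life of each reaction plus the 30 s/300 s window
  points, 20 noisy replicates summarized by the median.
* *model selection* — 16-leaf trees, 1000 sites under LG+gamma,
  LG+gamma (α estimated) vs Poisson, 10 replicates.

What passing these tests shows: the estimators are exact or consistent
under their own assumptions, with calibrated uncertainty.  What they do
not show: robustness to alignment error, non-reversible or
heterotachous evolution, indels (simulated alignments are gap-free),
saturating kinetics, or gel-quantification artifacts — real-data
effects the synthetic generators intentionally do not model.

## Known limitations

* No tree inference, branch-length optimization, or support values;
  trees and alignments are inputs.
* No joint-ML ancestors, posterior sampling, or ancestral indels.
* Specificity positions are called descriptively (frequency thresholds),
  with no test statistic attached; covariation inference is out of
  scope and covarying-position lists are treated as inputs.
* The kinetic model is minimal mass-action; saturation (separate k_cat,
  K_M), competition assays, and autophosphorylation are not modeled.
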