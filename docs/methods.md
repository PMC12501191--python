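# Methods

## Phylogenetic model and reconstruction

Likelihoods use a reversible amino-acid substitution model defined by a
symmetric exchangeability matrix `S` and equilibrium frequencies `π`:
`Q_ij = S_ij π_j` for i ≠ j, diagonal set so rows sum to zero, and the
whole matrix rescaled so the expected equilibrium rate is 1 — branch
lengths are therefore expected substitutions per site. The bundled
empirical model is JTT (Jones–Taylor–Thornton 1992 counts and
frequencies); a Poisson (equal-exchangeability, uniform-frequency) model
is included for testing and teaching. Model-intrinsic frequencies are the
default; `SubstitutionModel.with_frequencies` plus
`observed_frequencies()` provides the +F variant. Transition matrices come
from the eigendecomposition of the symmetrised rate matrix, which is exact
for reversible models and fast enough to recompute per branch.

Among-site rate variation uses K equal-probability discrete gamma
categories (default K = 4) with category-mean rates (conditional means of
the Gamma(α, α) distribution between its K-quantiles), so rates average
exactly 1 and K = 1 reduces identically to the homogeneous model. The
likelihood averages categories with equal prior weight.

Marginal ("empirical Bayes") posteriors at an internal node combine
inside partial likelihoods (Felsenstein pruning, post-order) with outside
partial likelihoods (pre-order, root prior included); rate categories are
integrated with weights proportional to each category's per-site
likelihood. Underflow is handled by per-node, per-site rescaling with the
log scale factor carried separately, so reported log-likelihoods are exact.

Decisions where the design was open:

* **Branch lengths and α are inputs, never re-optimised.** Recovery
  experiments use the true simulated values; real analyses should supply a
  tree with ML branch lengths from a standard tree-inference tool.
* **Gaps and ambiguity codes** (`-.?X B Z J U O *`) are missing data: a
  partial-likelihood vector of ones.
* **Trees must be rooted and binary**; polytomies are rejected rather than
  silently resolved, because marginal posteriors at an arbitrarily
  resolved node would be an artifact of the resolution.
* **Argmax ties** in the emitted ML sequence break alphabetically (the
  state order is alphabetical, so NumPy's first-index rule realises this
  deterministically).

A note on recovery accuracy: with fixed model parameters, marginal
reconstruction is independent across sites, so expected per-site accuracy
does not grow with alignment length — longer alignments only tighten the
accuracy *estimate*. What should (and does) hold is calibration: the mean
posterior of the emitted states tracks empirical accuracy to within a few
hundredths at L = 300.

## Variant construction

Coordinates are 1-based and inclusive throughout; mapping between
alignment columns and reference numbering (e.g. positions numbered along a
full-length reference enzyme, such as residue 723) is explicit via
`ReferenceNumbering`, never positional guessing. AltAll substitutes the
second-best residue at exactly the sites whose second-best posterior
strictly exceeds the threshold (default 0.2); a site mask restricted to
the active-site regions gives the AltAlpha variant. Point edits verify the
expected ancestral residue and fail loudly (`StaleVariantSpecError`) on
mismatch — a spec written against one reconstruction must not silently
apply to another. Chimeras copy donor residues within named, disjoint
regions; swaps compose and are idempotent. Hamming distances exclude any
column where either sequence carries a gap (the conservative count — a gap
against a residue is never a substitution), and accept a site mask (e.g.
the alpha domain).

## Product profiles

Compositions are trace-internal: each replicate's analyte areas divided by
their own sum, so they are invariant to overall signal scale. The internal
standard serves only the detection threshold — a replicate whose total
analyte area is below 0.1% (configurable) of its internal-standard area is
inactive. Profiles are the renormalised arithmetic mean of active
replicate compositions with per-product sample SDs (n−1); fewer active
replicates than `n_min` (default 3) sets a warning-level under-replicated
flag rather than failing, and zero active replicates yields an inactive
profile. "Logged" total activity is log10 by default (the common
chromatography convention; base configurable), with zero totals reported
as below-detection rather than −∞.

## Functional space

Bray–Curtis is computed over the name-union, zero-filled vocabulary of the
two profiles; on unit-sum compositions it equals half the L1 distance. Two
all-zero vectors raise an error — inactive enzymes are excluded upstream
(distance matrices drop them with a logged notice and require ≥ 3 active
profiles). Functional distance normalises by the ancestor's dissimilarity
from a pure (100%) focal-product reference, so 1 means "as different from
the ancestor as a pure isopimaradiene producer".

NMDS minimises Kruskal stress-1 with the primary (weak-tie) treatment of
tied dissimilarities: disparities come from pool-adjacent-violators
regression of configuration distances on stably-sorted dissimilarity
ranks, and configurations update by the Guttman transform. Only
stress-decreasing steps are accepted (the stress trace is non-increasing
by construction); a step that fails to improve means a local optimum and
counts as convergence, while exhausting `max_iter` (default 500, tolerance
1e-7) returns the best-so-far flagged unconverged. Starts: one classical
(Torgerson) scaling configuration plus `n_starts − 1` (default 19) random
Gaussian configurations, all drawn from one `SeedSequence`, so results are
bit-reproducible given (seed, n_starts, tol). Output dimensions default to
3; coordinates are centred, and axis units are arbitrary (stress is
invariant to rotation, translation and uniform scaling, which the tests
verify directly).

## Epistasis statistics

The field describes background-dependent effects qualitatively; the
divergence score here is this package's formalisation. For one mutation
measured in two backgrounds with effect vectors Δ₁, Δ₂ (each mutant −
background, summing to 0), divergence = `0.5 Σ|Δ₁ − Δ₂|` over the union
vocabulary: bounded in [0, 2], zero iff the effects are identical, and a
pseudometric. Loss-of-function mutants carry no Δ; pairing them is
*incomparable* (an explicit marker in the divergence table, never a silent
0), and a rescue check records when a companion mutation restores
activity. Trajectory fold changes are ratios of consecutive renormalised
mean focal fractions (not per-replicate ratios); an interval starting at
exactly 0 is "undefined (from zero)" rather than infinite.

## Synthetic study design

The generator is rule-based, not mechanistic: genotype→composition rules
reproduce the qualitative determinant-site structure seen in real diterpene
synthases — a 723-class specificity switch, a 724 substitution giving
mixed pimaranes, a conditionally lethal 833 substitution rescued by 724 —
with base compositions as round-number stand-ins (e.g. 0.9/0.1 for an
isopimaradiene-dominant profile). Background classes are keyed to residues
at two "context" sites inside the alpha domain; the 723 switch yields a
focal (isopimaradiene) fraction of 0.15/0.10 (Thr/Ser) in the basal class,
0.30/0.18 in the intermediate class (planted 2.0- and 1.8-fold gains at
the class switch) and 0.90 in the derived class. An additive control
mutation (site 700) shifts 0.15 of composition mass identically in every
class, giving a true divergence of 0 against which the planted
background-dependent mutation (true divergence 0.9) is ranked.

Default study conditions, chosen once: six path ancestors over L = 850
residues (so literature-style numbering like 723/724/833 is directly
valid); alpha-domain mask 550–850; consecutive masked Hamming intervals
(40, 40, 33, 10, 20) — cumulative 113 substitutions before the first class
switch, then 10- and 20-substitution intervals; each background gets both
723 switches, the 724/833 singles and double, and the control, and the
last backbone pair gets X/Y/Z region-swap chimeras; three replicates per
enzyme with Dirichlet concentration κ = 200 (per-product replicate SD
≈ 0.02–0.035), lognormal total-area σ = 0.3 around 10⁵ area units against
a 10⁶ internal standard, detection threshold 0.1%.

Assay noise is Dirichlet over the support of the true composition (true
zeros stay exactly zero) — the standard compositional noise model when
only means ± SD are known. Every generator is a pure function of
(config, seed); bundles are byte-identical given the seed.

What the generator does *not* emulate: alignment gaps and indel history,
among-site composition of real domains, correlated (non-Dirichlet) assay
errors, retention-time or spectral artifacts, and any structural mechanism
behind the rules. Passing the planted-recovery tests therefore shows the
statistics detect the encoded dependence structure under compositional
noise, not that real assay pipelines are error-free.

## Problem sizes and tolerances

Oracle equivalence is checked on 4-tip trees against exhaustive 20³
enumeration at relative tolerance 1e-9. Recovery experiments use 16 tips,
L = 300, branch lengths 0.05–0.2, α = 1, 10 replicates (accuracy ≥ 0.85,
calibration gap ≤ 0.05). The epistasis ranking experiment uses 200
replicates at κ = 200 with 3 assays per enzyme. `scripts/acceptance.py`
re-runs all of these from scratch from a single seed.
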