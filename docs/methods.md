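# Methods

## Model and procedure

The pipeline treats sexual size dimorphism of a wing muscle as a discrete
character measured with error. Three layers:

1. **Measurement layer.** Each hemithorax is one independent record (left
   and right hemithoraces of one fly are not merged; the sampling unit in
   this kind of dataset is the hemithorax). Normalized volume of an hg
   muscle = raw volume / (hg1+hg2+hg3+hg4+b1+d-Tp+v-Tp) of the same
   hemithorax; the quantity is dimensionless and invariant to any common
   rescaling of a specimen's volumes, which is the point — overall body
   size differs by sex and species.

2. **Classification layer.** Cohen's d (pooled, Bessel-corrected SD;
   male − female sign convention) with an inclusive threshold at |d| = 1.5.
   The threshold is a property of the analysis design, not estimated. No
   Hedges small-sample correction by default — the classifier is defined in
   terms of Cohen's d; `hedges_g` is available for sensitivity analyses.
   No multiple-testing correction is applied (none is part of the design);
   the Student's t test is descriptive, not a gatekeeper. Cells with fewer
   than `min_n` (default 3) specimens in either sex, a single sex, or a
   degenerate d (zero pooled SD with unequal means) are flagged and the
   species is dropped from that muscle's reconstruction.

3. **Phylogenetic layer.** The character evolves by an Mk CTMC. Default is
   the equal-rates (ER) structure with a uniform root prior (for ER the
   uniform distribution is also stationary); SYM and ARD are available.
   hg1 is reconstructed on the binary {monomorphic, dimorphic} collapse
   (its dimorphisms are uniformly male-enlarged, and a two-state character
   is better identified from 19 tips); hg2–hg4 use the three-state
   character {monomorphic, male_enlarged, female_enlarged}.

### Likelihood and reconstruction

Tip partials are indicator vectors; the post-order (pruning) pass computes
conditional partial likelihoods with per-node max-rescaling accumulated in
log space, so 200-tip trees and tiny rates do not underflow. ER transition
probabilities use the closed form P_offdiag(t) = (1 − e^(−kqt))/k; other
structures use the scipy matrix exponential. Branch lengths below 1e-8 are
floored inside the engine only (the stored tree is untouched) to keep P(t)
nonsingular on zero-length terminals.

Marginal posteriors are exact: a pre-order pass propagates each node's
"upward" message — root prior times the messages of all subtrees *except*
the one below the node — and the posterior is the normalized elementwise
product of upward message and downward partial. This equals rerooting the
tree at each node and reading the root posterior, and is tested against
brute-force enumeration of all internal-node assignments. A `conditional`
mode (pre-order pass reusing the parent's finished posterior) is provided
for comparison with ancestral-character-estimation routines that report
conditional-scaled values rather than exact marginals; it is approximate
and never the default.

Rate estimation: bounded scalar minimization on log q over [1e-8, 1e3]
(ER), L-BFGS-B on log-rates (SYM/ARD). An all-one-state tip configuration
has its MLE at the q → 0 boundary; the fit returns the lower bound with
`at_lower_bound=True` rather than failing.

### Transition counting

MAP states per node; one event per edge with differing endpoint states;
nested same-direction changes on ancestor and descendant edges count
separately (independence = distinct edges). MAP ties within 1e-9 are broken
toward the parent's state, minimizing spurious events, and the affected
events are flagged ambiguous. Binary-mode gains cannot be attributed to a
sex and are classed `gain` rather than `gain_male`/`gain_female`; pooled
"gains" sums all three gain classes. The Sankoff parsimony score (unit
costs, exact under polytomies) is computed from the tips alone as an
independent lower bound on any consistent event tally and reported next to
it; MAP and parsimony disagreements are visible as `total >
parsimony_score`.

## Synthetic data generator

The generator emulates a 19-species comparative design: a seeded Yule tree
(17-species ingroup grown at birth rate 1, plus two long-branch outgroup
tips), per-muscle character histories simulated as exact CTMC paths (every
jump recorded, so reconstruction and tallies can be scored against truth),
and per-specimen volumes

    raw(m) = body_scale(species, sex) × fraction(m) × lognormal noise.

Defaults, chosen once as the emulated study conditions: 10 hemithoraces
per sex per species; lognormal CV 0.15; baseline fractions
hg1..hg4 = 0.10/0.06/0.05/0.04, b1 = 0.30, d-Tp = 0.25, v-Tp = 0.20
(hg muscles are the small ones); generative |d| = 2.5 for dimorphic cells;
females 1.15× the male body scale with a species-level lognormal factor
(log-SD 0.3); Mk rate q = 0.1 per unit branch length, which gives roughly
two to three expected changes per muscle on a 19-species tree — the regime
of a character that transitions several times in a genus, with hg4 held
monomorphic everywhere as the conserved-muscle control. Fixture histories
start from a monomorphic root.

The enlarged sex's mean fraction of a dimorphic muscle is multiplied by
(1 + δ), with δ calibrated by root-finding on a large common-random-numbers
Monte-Carlo estimate of the expected d of the *normalized* volume —
normalization makes the seven fractions interdependent, so no closed form
is attempted. The calibration is exact in expectation (realized d averages
within ~0.5% of target at n = 1000 per sex).

What the generator does **not** emulate: segmentation/measurement error of
the imaging step, left–right correlation within flies, unequal per-sex
sample sizes, and cross-muscle interactions — when two muscles of one
species are simultaneously dimorphic, enlarging one muscle's fraction
slightly shifts the other's normalized values, so realized effect sizes
deviate from their single-muscle targets (and monomorphic muscles in such
species acquire small nonzero d). Passing tests therefore demonstrate the
statistical machinery under idealized lognormal noise, not robustness to
every feature of real morphometric data.

Two intrinsic properties of the design worth knowing: the sampling SD of
d̂ at d = 2.5 with 10–12 specimens per sex is ≈ 0.55 (so individual
species' realized d values scatter broadly around the target — this is
sampling noise, not generator bias), and d̂ carries the usual small-sample
upward bias (≈ +4% at n = 12/sex).

## Numerical choices

* Engine branch-length floor 1e-8; rate bounds [1e-8, 1e3]; scalar-fit
  tolerance 1e-10 on log q.
* Marginal/brute-force agreement asserted at 1e-10; rerooting invariance
  at 1e-9; posterior normalization at 1e-9.
* Output tables are TSV with fixed 6-decimal floats and "." separator, for
  byte-stable diffs; the run manifest records config, hash and versions.
* Degenerate inputs: discordant tips at q → 0 give log-likelihood −inf
  (reported as such); zero total muscle volume excludes the record; an
  empty effects list yields header-only output.

## Problem sizes in the validation suite

Oracle-equivalence checks enumerate all internal-node assignments on trees
of ≤ 6 leaves (200 replicates) and marginalize joints on ≤ 5 leaves (100
replicates). Rate/state recovery uses 100 replicates of 200-tip Yule trees
(ER, k = 2, q = 0.1; plus matched low-rate replicates with q·depth ≤ 0.2).
Classifier error rates use 5000 Monte-Carlo replicates at n = 10 per sex
(null) and 500 at n = 12 (power). These sizes give binomial/Monte-Carlo
errors comfortably below the asserted margins.

## Known limitations

* Marginal (not joint) reconstruction; MAP states at adjacent nodes are
  each individually optimal, and the edge tally from them can differ from
  the best joint history — hence the parsimony cross-check.
* No rate heterogeneity across branches or characters, no correlated
  evolution between muscles, no stochastic character mapping.
* The transition tally is a point estimate from MAP states; it carries no
  uncertainty statement. Nodes with near-tied posteriors are flagged, and
  alternative histories at such nodes (single early gain vs independent
  gains) should be read from the posterior table, not the tally alone.
* Single-sex species and flagged cells are silently absent from a muscle's
  tree after pruning; the load report and manifest are the place to check
  how much data each reconstruction actually used.
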