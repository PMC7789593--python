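# Methods

## Model

For each gene *g* with DE p-value *P<sub>g</sub>* and binary evidence row
*r<sub>g</sub>*, the marginal likelihood sums the hidden mediation indicator
*Z<sub>g</sub>* out analytically:

    π_g   = σ(w0 + Σ_c w_c · r_gc)
    f(P_g) = (1 − π_g) · 1 + π_g · α · P_g^(α−1)

with σ the logistic function and α ∈ (0, 1] the Beta(α, 1) shape.  Genes are
treated as independent.  The training objective is

    L(θ) = Σ_g log f(P_g) − λ · Σ_c w_c²

— the L2 penalty covers evidence weights only, never w0 or α.  For the
factorized variant w_c = w_t(c) · w_m(c) and the penalty is
λ·(Σ_t w_t² + Σ_m w_m²), the natural analog of the free-weight penalty.
The LLR compares *unpenalized* log-likelihoods: the fitted model against an
evidence-free null (w0, α only) fitted to the same genes.  Since the null is
nested in the alternative, the λ=0 LLR is non-negative up to optimizer
tolerance, and the suite asserts this.

Assumptions worth keeping in mind: evidence enters the prior of Z only
(p-values are conditionally independent of evidence given Z); the signal
component is monotone-decreasing in p (α ≤ 1), so the model reads only
*enrichment of small p-values*; a single α is shared by all driven genes.

## Optimization

Fitting maximizes L(θ) with L-BFGS-B on analytic gradients.  α is
reparameterized as σ(a) with a bounded in [−30, 30], keeping α in (0, 1)
without constrained steps; weights are unconstrained.  Initialization:
weights at 0, w0 at logit(0.1), α at 0.5; additional restarts (default 5)
perturb the start with seeded N(0, 0.5²) noise and the best penalized
objective wins.  Log-densities use log-sum-exp throughout, so p-values at
the 1e−12 floor with small α cannot overflow; gradient ratios are formed in
linear space where float64 range is ample.  Non-convergence after
`max_iter` flags the result rather than raising.  Every stochastic
operation takes an explicit seed recorded in the output.

Two numerical conventions: p-values of exactly 0 from upstream tools are
clamped to 1e−12 (p = 1 is legal under both mixture components and left
alone; note the directional transform can produce 1 − p = 0, which is then
clamped); equal ΔLLR values in TF rankings break by TF name so output is
reproducible.

## Derived scores

ΔLLR for a TF re-evaluates the log-likelihood with that TF's columns zeroed
*at the trained weights*, without refitting: the alternative (retraining
after each deletion) is supported by refitting on the zeroed matrix but is
slower and introduces optimizer noise into what is meant to be an
attribution of the trained model; the fixed-weight reading is the default.
POR is π·α·p^(α−1)/(1−π) at the fitted parameters; RPOR divides the POR by
its value with one TF's evidence removed for that gene, so genes without
that TF's evidence score exactly 1 and, for a single active column, RPOR
reduces to exp(w_c) (the Beta factor cancels).

## Evidence construction

Coordinates are 0-based half-open (BED convention) everywhere; overlap
means ≥ 1 shared base.  The gene window is [tss − d, tss + d), symmetric
around the TSS with strand used only to locate the TSS; d defaults to
50 kb with {10 kb, 50 kb, 200 kb, 1 Mb} the usual grid.  Dynamic marks:
a stage-consistent peak is a replicate-1 interval overlapping any
replicate-2 interval of the same stage (reported with replicate-1
coordinates — the simplest auditable choice); it is "down" if it overlaps
no late-stage peak of either replicate, "up" symmetrically.  ATAC dynamic
calls use the same exclusivity rule with one profile per stage.  When both
directions fire for one (gene, TF, mark), only the direction with the
larger total TFBS∩dynamic-mark overlap length (segments clipped to the
window) is kept, ties going to "up"; each conflict is logged.  Peaks are
used as provided — FDR filtering is assumed done upstream — but the
narrowPeak reader exposes an optional −log10(q) threshold.  Chromosome
names are harmonized by stripping any "chr" prefix on both sides.

The directional p-value transform replaces p with 1 − p for genes whose
fold change opposes the analysis direction (log2fc > 0 in down-analysis,
log2fc < 0 in up-analysis); log2fc = 0 is left unchanged in both modes, and
rows missing either value are dropped with a logged count.

## Evaluation

Cross-validation partitions genes (not samples).  The 80/20 scheme scores
every (d, λ) pair on each repeat's test genes and picks the pair maximizing
the mean summed up+down test LLR; the 72/18/10 scheme lets the validation
set pick (d, λ) per repeat so the recorded test LLRs compare evidence
strategies on equal footing.  Partitions depend only on (seed, repeat), so
runs over different matrices on the same genes are paired; head-to-head
strategy counts use strict inequality with ties counted for neither.  Test
LLRs evaluate the train-fitted model and train-fitted null on held-out
genes.

The permutation null shuffles each evidence column independently among
genes (preserving column marginals), refits on the full gene set, and
summarizes the observed LLR as a z-score; (d, λ) stay at the observed-data
optimum rather than being retuned per permutation.  The hypergeometric
enrichment of a predicted regulon against an experimental gene set uses the
exact tail with the analyzed gene universe (17,200 by default) as the
population; the default is the inclusive tail P(X ≥ k).  The
strictly-greater tail P(X > k) — a raw survival-function call, the
convention behind some published enrichment figures — is available via
`inclusive=False`, and it is the convention under which the reference
configuration (sets of 500 and 1,981, overlap 87, universe 17,200) yields
3E−5 at one significant figure; the inclusive tail gives 5E−5.  Enrichment
p-values are reported raw with the universe stated.  Gene signatures rank
genes by the product of RPORs over a chosen TF list (ties by gene id) and
keep the top 50/70/100.

## Synthetic data

`simulate_dataset` draws evidence bits as independent Bernoulli(density)
variables, then priors, Z, and p-values exactly per the generative model.
Defaults are the study-scale conditions: 17,200 genes, 20 TFs, the 8
histone mark-changes, density 0.05, α = 0.2, w0 = −2, true weights uniform
in [−3, 3].  Independent-Bernoulli evidence is a simplification — real
binding sites co-localize heavily — so a `correlated` option mixes in a
per-gene shared latent factor (preserving marginal density) for robustness
checks.  What passing tests on this generator demonstrate is that the
estimator recovers the model it assumes (weight correlation ≥ 0.8, sign
agreement ≥ 90% on |w| ≥ 1, α within ±0.05 at n = 50,000 across 10 seeds)
and that the evaluation statistics are calibrated under the model's null;
they do not certify behavior under mis-specification (correlated evidence
with confounded directions, p-value miscalibration from the upstream DE
tool, peak-calling artifacts).

`simulate_genomic_fixture` lays out ≤ 100 genes every 10 kb on a synthetic
chromosome with hand-placed peaks guaranteeing that each encoding edge case
occurs: a replicate-inconsistent peak (must vanish), a 1-bp cross-stage
overlap (kills a dynamic call), TFBS at the last base inside and first base
outside the half-open window, and an up/down conflict resolved by overlap
length.  Expected matrices come from a naive all-pairs interval scan kept
deliberately independent of the production interval-tree path; the suite
requires bit-exact agreement for all six strategies.

## Problem sizes and defaults

Fits use L-BFGS-B with up to 500 iterations and ftol 1e−8; a 50,000-gene,
160-column fit takes well under a second, so the recovery battery (10
seeds) and the shuffled-null calibration (20 replicates x 50 permutations
at n = 2,000, 10 columns) run in seconds.  The λ grid defaults to
{0.01, 0.1, 1, 10}; restarts default to 5 (property tests use 1–3, which
suffices for these well-conditioned synthetic likelihoods).  The
acceptance script runs every analysis at these sizes from a single
user-supplied seed, deriving independent sub-seeds per analysis.

## Known limitations

Binary evidence discards peak strength and multiplicity; the model cannot
attribute direction of phenotypic influence (it explains p-values, not
signed effects — hence separate up- and down-analyses); ΔLLR attributions
at fixed weights can understate a TF whose signal another correlated TF's
columns can absorb; the factorized model assumes every TF has one fixed
role across all mark-changes; and the independence-across-genes likelihood
ignores co-regulation of neighboring genes.
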