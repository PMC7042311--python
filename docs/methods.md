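# Methods

## Model

A growing tissue is a discrete branching process. Every division of a
surviving lineage produces two surviving daughter lineages with
probability β (a *branching* division) or one with probability 1 − β
(*non-branching*); each surviving daughter acquires X ~ Poisson(μL)
novel mutations, where μ is the per-base-pair rate and L the callable
genome length. β is an *effective* survival rate: conditioning a
division with per-daughter death probability α on the non-extinction of
the observed lineage gives β = (1−α)/(1+α), and conversely
α = (1−β)/(1+β). β = 1/3 (α = 1/2) is the homeostatic boundary; the
model targets growing tissues (β > 1/3) but evaluates, with a warning,
below it.

The observable is the set of **mutational distances** between ancestral
cells. Two ancestral genotypes A, B with common ancestor A ∩ B are
separated by y₁ = |A \ (A∩B)| and y₂ = |B \ (A∩B)| mutations. Given r
branching divisions between an ancestral cell and the common ancestor,
the distance is Poisson with a negative-binomially inflated division
count i (r branching + i−r non-branching divisions):

P(y | r) = Σ_{i≥r} C(i−1, r−1) β^r (1−β)^{i−r} Poisson(y; iμL).

The branching-division count follows from coalescent theory for a
deterministically growing population N(t) = e^{βt} (time in divisions):
the interval density p(Δt) = e^{−βΔt} exp(−e^{−βΔt}/β), integrated over
[r, r+1] and normalised over r ≥ 1. Mixing the two gives the compound
distance distribution P(y), multimodal with peaks at multiples of μL
when μL is large; peak spacing identifies μL and tail weight identifies
β, which is what makes the joint inference possible from a single time
point.

All pmfs are evaluated in log space (log-gamma, log-sum-exp) so large
distances and rates cannot overflow. The double sum is truncated at
r_max = i_max = 30 by default (configurable). The truncation is
effectively exact for β ≳ 0.6; at β = 0.4 it retains W(β) = 0.971 of the
mass and at β = 0.3 roughly 0.80. The pmf itself is reported
unnormalised (the truncated sum, as defined); the *likelihood* divides
by W(β) by default so that low-survival parameters are not penalised by
mass that the cut-off discarded (`normalize_truncation=False` restores
raw truncated scoring). W(β) does not depend on μL, because each Poisson
component carries unit mass.

## Distance construction

`build_histogram` reconstructs the genealogy of the sample profiles by
agglomerative intersection: the pair of genotypes sharing the most
mutations merges first, is replaced by its intersection, and each merge
— one per branching event — contributes the two sibling distances to the
histogram. For profiles generated on a lineage tree this reproduces the
tree's branch lengths exactly (tested against the recorded genealogy).
Distances are deliberately *not* pooled over all pairs of ancestors:
non-adjacent ancestors are separated by several coalescent intervals,
and pooling them produces a histogram with a far heavier tail than the
single-interval compound distribution the model describes (measured:
~8× the predicted mean on a well-mixed simulation). The literal
all-pairs pooling remains available as `pairs="all"` for comparison.
Pooled sibling distances from different events still share ancestry;
treating them as independent in the likelihood is an approximation.

Terminal branches — from a profile itself to its first reconstructed
ancestor — span the whole remaining lifetime of the sampled lineage
rather than one branching interval. They are excluded by default for
single-cell samples (`include_terminal` resolves automatically) and for
phylogenies the `max_branchings` restriction keeps only the earliest
events, ranked by cumulative mutations from the root (a molecular-clock
proxy for event time, since calendar times are unavailable).
`tree_distances` applies the same per-event rule to a newick phylogeny
with integer mutation-count branch lengths; polytomies are resolved as
zero-length ladders with a warning.

## Inference

The likelihood treats the n recorded distances as i.i.d. draws from
P(y): log L = Σ_y n_y log P(y). A Metropolis–Hastings random walk with
additive uniform proposals (halfwidths 0.15 on μL, 0.06 on β), flat
priors, and rejection of out-of-bounds proposals samples the joint
posterior; 5 000 steps with a 200-step burn-in by default. Point
estimates are posterior medians; intervals are central 95% quantiles.
The β prior spans [0.05, 1.0] — below the homeostatic 1/3 on purpose, so
the posterior can express uncertainty about growth — and the μL prior is
[0.01, y_max + 3√y_max + 5] by default, adapted to the observed support
(explicit bounds override).

Because P(y) is multimodal in μL with period ≈ μL, a ±0.15 random walk
started far from the mode can lock onto a harmonic (μL/2 fits every
second peak). The chain is therefore seeded by a coarse
maximum-likelihood scan: for 13 candidate β values, the moment-matched
μL (mean distance divided by the expected division count E[i|β]) and a
spread of its multiples are scored, and the best pair starts the walk
(`init="map"`; `"moment"` and `"prior"` starts are available). This
replaces the per-dataset prior-range adjustment that the original
inference scheme performs manually.

Calibration: over 50 synthetic datasets of 200 distances drawn from the
model at (μL = 1.14, β = 0.96), the 95% credibility intervals cover the
truth 94% (μL) and 96% (β) of the time (acceptance suite).

## Simulator

`simulate_tissue` runs the embedded jump chain of a Gillespie birth–
death process: each event picks a uniformly random eligible cell, which
divides. Two death semantics are provided:

- `death="explicit"` (default): each daughter independently dies with
  probability α = (1−β)/(1+β); zero-survivor divisions shrink the
  population and extinction restarts the simulation (conditioning on
  survival). This is the microscopic process the effective-β algebra
  describes.
- `death="effective"`: the division directly yields two survivors with
  probability β or one with probability 1 − β; the population never
  shrinks.

Both record the complete division history (parent links and per-birth
mutation blocks), so exact ancestral genotypes, sample-MRCA profiles and
the reduced genealogy of any sample set are recoverable
(`ground_truth_distances`, `sample_genealogy_newick`). In well-mixed
mode every live cell is eligible; in `spatial-2D` mode cells occupy a
square lattice, only cells with a free von-Neumann neighbour divide
(boundary-driven growth), and biopsies are contiguous patches placed
either randomly or by greedy farthest-point ("maximal distance")
selection. Sequencing noise follows depth ~ Poisson(Z) and variant reads
~ Binomial(depth, f) with f the carrier fraction in the biopsy (halved
under the diploid flag); clonal genotypes are called at a configurable
VAF threshold (default 0.3, on the haploid scale).

Default scales are desk-sized: 10⁴ cells per tissue and 100–200 samples,
versus ~10⁶ cells for the published validation runs. Lineage statistics
of the early tree — which carry the signal — converge well below 10⁴
cells, but the sampling fraction is necessarily ~50× denser, which
shortens deep coalescent intervals.

### What the validation does and does not show

With explicit death and well-mixed growth, the simulated sibling-distance
histograms agree with the closed-form P(y) at high survival
(chi-square p ≈ 0.2–0.7 at β ≥ 0.85) and approximately at β = 0.4;
between roughly β = 0.55 and 0.7 the simulated coalescent intervals are
~30–35% shorter than the deterministic-exponential coalescent predicts.
This is the known weakness of deterministic-growth coalescent
approximations at small population sizes (stochastic early growth,
conditioned on survival, passes through the small-N phase faster than
e^{βt}); a birth–death coalescent would be the principled refinement and
is out of scope here. Consequences for parameter recovery over a
25-point grid (μL ∈ [1, 30] × β ∈ [0.4, 1.0], 10⁴ cells, 200 samples):
rank correlations between truth and estimate are high (Spearman ρ ≈ 0.98
for μL, ≈ 0.94 for β) because the bias is monotone, but the mean
relative error is ≈ 0.08 for μL and ≈ 0.17 for β — the β estimates
compress into roughly [0.45, 0.95]. Estimates for tissues with high
survival (development-like regimes) are essentially unbiased; β
estimates in the 0.4–0.7 range should be read as upper bounds.
Boundary-driven 2-D growth at desk scale produces genealogies 2–6×
longer than the exponential-growth model assumes and is not used for
validation, only exposed for spatial sampling studies.

The generator emulates neutral growth only: no fitness differences, no
mutation-rate changes in time or space, no copy-number events (inputs
are assumed restricted to copy-number-constant regions, with an
effective genome length L as the only normalisation), and no punctuated
mutation bursts. Passing tests therefore certify the machinery under
these assumptions, not robustness to selection or rate heterogeneity in
real tumours.

## Signatures

`fit_exposures` decomposes a sample's 96-channel trinucleotide counts
against a signature matrix by non-negative least squares; signatures
with positive exposure form the candidate set. Each mutation is assigned
to the candidate making its channel at least twice as likely as every
other candidate, else to "Other"; `stratified_histograms` then builds
per-stratum distance histograms that partition the unstratified distances
exactly, enabling signature-specific rate inference. No external
signature catalogue is shipped; `toy_signature_matrix` provides a
deterministic synthetic six-signature catalogue for tests and examples,
and any 96-row TSV is accepted. Channel annotation (trinucleotide
context extraction) is upstream of this package. Per-channel opportunity
weighting is not applied.

## Numerical and design choices

- Truncation r_max = i_max = 30; log-space throughout; likelihood
  normalised by the retained mass W(β) (see above).
- Default support for the pmf: smallest y with cumulative mass
  ≥ 1 − 10⁻⁶, capped at 10 · i_max · max(1, μL).
- Ties in the agglomerative merge are broken deterministically by list
  order, so histograms are reproducible for identical inputs.
- Relative recovery errors η are means over grid points by default
  (`error_aggregate="median"` is available); means are reported because
  they penalise the low-survival bias honestly.
- Every source of randomness flows from an explicit integer seed
  (simulator, sampling, noise, MCMC); identical seeds give bit-identical
  outputs, which the CLI tests assert.
- The chi-square goodness-of-fit helper pools support bins (plus a tail
  bin) to expected counts ≥ 5.
- The sampler-vs-pmf total-variation check in the acceptance suite uses
  a 50-cell equiprobable partition: at 10⁶ draws, raw-support TV has a
  statistical floor above the 0.005 bound whenever the support spans
  thousands of values, even for a perfect sampler.

## Limitations

Constant μ and β in time and space; neutral evolution; the pooling
independence approximation; the deterministic-coalescent bias at low β
quantified above; single-chain MCMC without multi-chain convergence
diagnostics (traces are exportable); clonality calling by a fixed VAF
threshold rather than a mixture model.
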