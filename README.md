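# mutdist

Joint inference of the **per-division mutation rate** and the **per-cell
survival rate** of a growing tissue from multi-region or single-cell
sequencing taken at a single time point.

## The problem

Both normal development and tumour growth are branching processes: cells
divide, daughters sometimes die or differentiate, and every surviving
daughter inherits its parent's somatic mutations plus a handful of new
ones. Bulk mutational burden confounds the two microscopic parameters
that drive this process — the mutation rate per genome per division
(μL) and the probability β that both daughter lineages of a division
survive — because many slow-mutating divisions and few fast-mutating
ones leave the same total burden.

Multiple samples of the same tissue break the degeneracy. Each sample's
clonal mutations are the genotype of its most recent common ancestor
(MRCA) cell; intersecting two samples' profiles reconstructs a deeper
ancestral genotype, and the two set differences

    y1 = |A \ (A ∩ B)|,   y2 = |B \ (A ∩ B)|

are *mutational distances* between ancestral cells. Because divisions
are discrete, the distribution of these distances is a compound mixture
whose peak spacing reveals μL and whose tail weight reveals β:

    P(y) = Σ_{r≥1} Σ_{i≥r} P(r) C(i−1, r−1) β^r (1−β)^{i−r} e^{−iμL} (iμL)^y / y!

Here `r` is the number of branching divisions separating two ancestral
cells — distributed according to a coalescent for an exponentially
growing population, P(r) ∝ exp(−e^{−β(r+1)}/β) − exp(−e^{−βr}/β) — the
negative-binomial factor counts interleaved single-survivor divisions,
and the Poisson factor the mutations per division. A random-walk
Metropolis–Hastings sampler fits (μL, β) jointly to an observed distance
histogram; point estimates are posterior medians with central 95%
credibility intervals. The per-daughter death probability follows as
α = (1−β)/(1+β), with β = 1/3 marking homeostasis.

The package also contains the validation engine: a Gillespie-style
tissue simulator (well-mixed or 2-D lattice growth, explicit or
effective cell death) with full lineage recording, biopsy sampling,
sequencing-noise synthesis, and trinucleotide-signature stratification
for signature-specific rate inference.

## Worked example

Grow a 2 000-cell tissue at μL = 5, β = 0.9, biopsy 30 single cells,
build the distance histogram, and re-infer the parameters:

```sh
mutdist simulate --muL 5 --beta 0.9 --cells 2000 --n-samples 30 \
        --seed 3 --out-prefix demo
mutdist distances --profiles demo_profiles.tsv --no-include-terminal \
        --out demo_hist.csv
mutdist infer --histogram demo_hist.csv --seed 1 --out demo_summary.json
```

The last command logs

```
INFO mutdist: muL = 4.961 [2.898, 6.731], beta = 0.893 [0.687, 0.994]
```

i.e. from 28 ancestral distances the sampler recovers the simulated
mutation rate (truth 5, median 4.96) and survival rate (truth 0.90,
median 0.89), each with its 95% credibility interval.
`demo_summary.json` holds the same numbers plus the per-base-pair rate
μ = μL/L when a genome length `-L` is supplied.

The same path works on real data: `mutdist distances` accepts a
presence/absence TSV matrix or a multi-sample VCF of clonal calls
(profiles), or a newick phylogeny whose branch lengths are mutation
counts (`--tree`, with `--max-branchings` to restrict to the earliest
branching events of a developmental tree).

As a library:

```python
import numpy as np
from mutdist import (SimConfig, simulate_tissue, take_samples,
                     ground_truth_distances, MCMCConfig, run_mcmc,
                     summarize_posterior)

tissue = simulate_tissue(SimConfig(muL=5.0, beta=0.9, target_cells=2000, seed=3))
samples = take_samples(tissue, 30, 1, rng=np.random.default_rng(4))
hist = ground_truth_distances(tissue, samples)
print(summarize_posterior(run_mcmc(hist, MCMCConfig(seed=1))))
```

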