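# tsmc — transformation sequential Monte Carlo

`tsmc` is a Python library and command-line tool for Bayesian inference over
a *sequence* of models of growing dimension, built on transformation SMC: a
sequential Monte Carlo sampler in which a deterministic transformation
carries a weighted particle population from the posterior of one model into
the next, adaptive geometric annealing closes the remaining gap, and an
unbiased estimate of every model's marginal likelihood (evidence) falls out
of the weight updates.  It is aimed at statisticians and evolutionary
biologists who need Bayes factors across nested model sequences, or online
posterior updates as data arrive.

Two model families are built in:

* **Gaussian mixture model comparison** — posteriors over 1..T mixture
  components, linked by *birth* (prior draw + stick-breaking weight) and
  *split* (moment-matching, the Richardson–Green construction)
  transformations, with the route choice either retained (conditional) or
  summed out (marginalised, lower variance), plus a per-model
  prior-to-posterior annealing baseline (SMC2).
* **Online coalescent inference** — the genealogy of DNA sequences under a
  Kingman coalescent prior and Jukes-Cantor substitution, with the scaled
  mutation rate θ inferred jointly.  Sequences are added one at a time: a
  SNP-guided lineage proposal and a Laplace-approximated height proposal
  attach each new leaf, and the weight update marginalises the lineage over
  the inverse image of the attachment.

The sampler core is generic: targets bridge via
φ̃^(1−γ) π̃^γ, with the next γ placed where the conditional effective sample
size CESS = P (Σ w ω)²/Σ w ω² hits βP, stratified resampling when the ESS
drops below αP, and MCMC rejuvenation sweeps at every intermediate
distribution.  See `docs/methods.md` for the full model and algorithm
description.

## Worked example: how many mixture components?

Simulate 60 points from an equal mixture of N(−3, 1) and N(3, 1), then
estimate the evidence of models with 1–4 components by split-move
transformation SMC with marginalised weights:

```bash
tsmc simulate mixture --means "-3,3" --precisions "1,1" --weights "0.5,0.5" \
     --n-points 60 --seed 3 --out sim
tsmc mixture --data sim/data.csv --particles 200 --beta 0.95 \
     --max-components 4 --move split --weight-mode marginal \
     --mcmc-iters 1 --seed 11 --out run
```

`run/evidence.json` then contains (amongst the configuration echo):

```json
"log_evidence": { "1": -167.49, "2": -139.59, "3": -141.44, "4": -143.74 },
"schedule_length": { "1": 31, "2": 24, "3": 12, "4": 10 }
```

The log evidence rises by ~28 nats from one to two components — decisive
support for the generating model — then falls as the complexity penalty
overtakes the likelihood: the two-component model is selected.
`schedule_length` is the number of intermediate distributions the adaptive
scheme spent per transition (many for the hard prior-to-posterior start,
few once neighbouring posteriors are similar), and the diagnostics CSV logs
γ, ESS, CESS, resampling events and acceptance rates per step.

## Worked example: sequences arriving one at a time

```bash
tsmc simulate sequences --n-leaves 5 --n-sites 300 --theta 0.1 --seed 2 --out coal
tsmc coalescent --fasta coal/alignment.fasta --particles 100 --beta 0.9 \
     --ordering furthest --mcmc-iters 1 --seed 5 --out coalrun
```

which reports the running log evidence after each added sequence, the θ
posterior, and a majority-rule consensus genealogy:

```json
"log_evidence": { "1": -415.89, "2": -564.66, "3": -572.80,
                  "4": -639.03, "5": -661.70 },
"theta_posterior": { "mean": 0.143, "q05": 0.061, "q95": 0.241 }
```

```
(((seq1,seq2)1.000,(seq3,seq4)1.000)0.990,seq5);
```

Here the generating θ = 0.1 sits inside the 90% interval and the consensus
(clade supports as internal labels) recovers the generating topology.
Posterior tree samples, per-step diagnostics and the consensus Newick are
written alongside.

## Library use

Everything the CLI does is a thin wrapper over the library:

```python
import numpy as np
from tsmc import AnnealConfig
from tsmc.mixture import (MixtureDataset, MixturePriorSpec, tsmc_mixture_evidences)

data = MixtureDataset.from_observations(np.loadtxt("y.csv"))
priors = MixturePriorSpec.from_data(data, max_components=8)
result = tsmc_mixture_evidences(
    data, priors, AnnealConfig(cess_fraction=0.99), np.random.default_rng(1),
    move="split", mode="marginal", n_particles=500,
)
print(result.log_evidences)
```

`tsmc.smc_core` exposes the generic machinery (`ParticleSystem`,
`ModelBridge`, `run_bridge`, `ess`, `cess`, `adapt_gamma`, …) for building
bridges between arbitrary model sequences.

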