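# consensusica

Consensus independent component analysis (ICA) for bulk transcriptome and
miRNome data: stable metagene extraction, component signatures,
survival-weighted risk scoring, cross-omics component linking, and
projection of new samples onto a discovery cohort.

## The problem

A bulk expression profile is a mixture: tumour cells, immune infiltrate,
stroma, and technical artifacts all contribute to every measured value.
Modelling a feature-by-sample matrix *E* (n features × m samples) as a
linear mixture of k statistically independent, non-Gaussian sources

```
E = S · M
```

lets ICA separate those signals blindly: the columns of *S* (n × k) are
**metagenes** — each feature's contribution to one component — and the rows
of *M* (k × m) are the component's **weights** across samples.  Because
single FastICA runs suffer from sign/order ambiguity and run-to-run
irreproducibility, the decomposition is repeated *nt* times on resampled
data (one random sample excluded per run), runs are aligned by metagene
correlation, and the aligned metagenes are averaged.  Each component gets a
**stability R²** — the mean squared correlation of its metagene between
pairs of runs — so unreliable components are visible rather than silently
wrong.

On top of the decomposition the package provides:

- **Top-contributing features** per component: z = (s − median) / (1.4826·MAD)
  against a normal background, BH-adjusted, reported at adj.p < 0.01 split
  into positive and negative lists; components are re-oriented so the
  dominant biology is positive.
- **Risk score** per sample: RS = Σᵢ Hᵢ·R²ᵢ·M*ᵢ over components whose
  univariable Cox screen passes BH-adjusted log-rank p < 0.05, where Hᵢ is
  the log-hazard ratio and M* the weight standardised with the *discovery*
  mean/sd (frozen, so the score transfers to validation cohorts).
- **Cross-omics linking**: mRNA and miRNA components are connected when the
  squared correlation of their weight rows exceeds r² > 0.25; connected
  groups form multi-omics clusters.
- **Ranking score**: a new sample's weight expressed as its quantile
  position in the discovery cohort, clamped to [0, 1].
- **Preprocessing** for heterogeneous inputs: soft count filtering
  (> threshold in ≥ 1 sample), log2 transform, qPCR Ct inversion (36 − Ct
  with NA/Ct > 36 at the detection limit), linear harmonisation of
  microarray data onto an RNA-seq reference, and batch-labelled cohort
  concatenation.
- A **synthetic-data module** generating mixtures with known sources,
  batch offsets, survival and labels, so every stage is testable without
  external cohorts.

## Worked example

```python
import numpy as np
from consensusica import (ConsensusICA, SyntheticScenario, simulate_mixture,
                          simulate_survival, ComponentCoxScreen)

scn = SyntheticScenario(n_features=2000, n_samples=100, k_true=5,
                        noise_sd=0.1, seed=11)
E, S_true, M_true, _ = simulate_mixture(scn)

res = ConsensusICA(E, n_components=5, n_runs=20).fit(seed=42)
print(res.summary())
```

```
Consensus ICA decomposition
============================================================
features: 2000   samples: 100
components (k): 5   runs (nt): 20   seed: 42
converged runs: 20/20
------------------------------------------------------------
component     stability R2
IC1                 1.0000
IC2                 1.0000
IC3                 1.0000
IC4                 1.0000
IC5                 1.0000
------------------------------------------------------------
mean stability: 1.0000   components with R2 > 0.5: 5
```

Every component is perfectly reproducible across the 20 resampled runs
(stability 1.0), as expected when k matches the true source count and noise
is low.  Linking weights to survival:

```python
surv = simulate_survival(M_true, 2, beta=1.0, censor_frac=0.3, seed=11)
screen = ComponentCoxScreen(res, surv).fit()
print(screen.summary())
```

```
Per-component Cox survival screen
============================================================
component          LHR           p       adj_p
IC1            -0.1770   1.369e-01   3.422e-01
IC2             0.0109   9.239e-01   9.820e-01
IC3            -1.0646   1.744e-12   8.719e-12
IC4             0.0029   9.820e-01   9.820e-01
IC5             0.0631   5.927e-01   9.820e-01
------------------------------------------------------------
significant at adj_p < 0.05: 1/5
```

Exactly one component is flagged (adj.p ≈ 9e-12) — the decomposition's IC3
is the matched estimate of the generating source whose weights drove the
simulated hazard with |β| = 1, and its per-standard-deviation log-hazard
ratio is recovered near ±1 (the sign is ICA's arbitrary orientation; the
risk score is invariant to it).  `screen.risk_score()` then freezes the
Eq.-style model for scoring validation cohorts.

A command-line interface mirrors the library
(`consensusica simulate|decompose|annotate|survival|score|link|project|report|pipeline`).

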