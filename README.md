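# flare-cyto

Hierarchical Bayesian mixture modelling for **rare-event detection in
multi-sample flow cytometry**.

Modern cytometry experiments measure 10⁵–10⁶ cells per sample across many
markers, and the populations of greatest biological interest — stem cells,
circulating tumor cells, regulatory T cells — can be a fraction of a
percent of events.  Finding them by manual gating is slow and subjective;
clustering each sample separately is unreliable, because a handful of
events is easily absorbed into a neighbouring large population, and the
clusters found in different samples then still have to be matched to each
other.

`flare` fits **one Gaussian mixture jointly across all samples**.  Sample
m's component k has mean μ_k^(m) and precision Λ_k^(m), drawn around shared
*prototype* parameters:

    x_n^(m)  ~  Σ_k π_k^(m) · N(μ_k^(m), (Λ_k^(m))⁻¹)
    μ_k^(m)  ~  N(η_k, (β₀ I)⁻¹)            η_k ~ N(ξ₀, (ε₀ I)⁻¹)
    Λ_k^(m)  ~  Wishart(mean Ω_k, dof σ₀)   Ω_k ~ InvWishart(Φ₀, ν₀)
    π^(m)    ~  Dirichlet(α₀)

Because index k refers to the same prototype in every sample, populations
are matched across samples by construction, a component may be present in
only a subset of samples (π_k^(m) → 0 elsewhere), and a rare population's
few events per sample pool their evidence through the prototype.  Inference
is closed-form coordinate-ascent variational Bayes with a monotone evidence
lower bound; a deliberately over-provisioned K shrinks as unused components
empty out.  On top of the fit sit a region-of-interest **zoom** (refit only
the events inside a box or a Mahalanobis ball around a fitted prototype, to
resolve subpopulations), a **fold-change screen** between conditions, and a
greedy **minimax partition planner** with a partitioned fit that is
numerically equivalent to the serial one.

See `docs/methods.md` for the full model, update equations, defaults, and
limitations.

## Worked example

Three samples from three shared populations, where the third population is
absent from the last sample; the fit starts with K = 6 components
(`examples/01_fit_multisample.py`):

```python
import numpy as np
from flare import Hyperparameters, SimulationSpec, fit, generate, summarize

spec = SimulationSpec(
    M=3, D=4, K_true=3,
    events_per_sample=[3000, 3000, 3000],
    weights=np.array([[0.5, 0.3, 0.2], [0.6, 0.2, 0.2], [0.5, 0.5, 0.0]]),
    prototype_means=np.array([[0, 0, 0, 0], [4, 4, 0, 0], [0, 4, 4, 0]], float),
    prototype_covs=np.stack([np.eye(4)] * 3),
    seed=7,
)
data, truth = generate(spec)
result = fit(data, Hyperparameters(K=6), seed=0, n_restarts=2)
summary = summarize(result, data)
```

which prints:

```
converged=True after 427 sweeps; 3 of K=6 components occupied

component  proportions per sample        present in
        0   0.2984   0.1909   0.4945   ['sample1', 'sample2', 'sample3']
        1   0.0000   0.0000   0.0000   []
        2   0.2032   0.1994   0.0000   ['sample1', 'sample2']
        3   0.0000   0.0000   0.0000   []
        4   0.0000   0.0000   0.0000   []
        5   0.4983   0.6097   0.5055   ['sample1', 'sample2', 'sample3']
```

Three components survive, their per-sample proportions track the generating
weights (0.5/0.3/0.2 etc.), and component 2 is correctly called absent from
sample3 — the same component index means the same population in every
sample, with no post-hoc matching step.

The two-step rare-event workflow (`examples/03_zoom_workflow.py`) fits five
training samples, anchors a region at the prototype of a 1% parent
population, and refits the events inside that region of a million-event
test sample:

```
step 1: component 5 sits 0.087 from the true 1% parent population mean
step 2: region captures 9131 of 1000000 test events (0.91%)
zoom refit: component 18 at distance 0.025 from the true subpopulation mean,
frequency 0.0485% of the test sample
planted frequency was 0.0450%; relative error 7.7%
```

— a 0.045% subpopulation recovered from 10⁶ events with its frequency and
mean signature, which is the intended use of the package.

The other examples cover joint-versus-independent rare detection
(`02`), the fold-change screen between conditions (`04`), and partition
planning with the serial-equivalence check (`05`).

## Command line

The same workflow is scriptable via the `flare` command:
`flare simulate`, `flare fit`, `flare zoom`, `flare screen`, `flare plan`.
Inputs are FCS 3.0/3.1 or headered CSV/TSV; an arcsinh transform with a
configurable cofactor is available at read time.  Every run writes a JSON
log of its seed and configuration, so any result is reproducible from the
log alone.  `flare plan --sizes 100,300 --workers 4` prints the assignment
`1,3` with balance `1.0`.

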