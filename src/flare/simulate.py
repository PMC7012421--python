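"""Synthetic multi-sample cytometry data drawn from the model's own generative
process: shared prototype clusters, small per-sample mean perturbations,
per-sample mixture weights (zeros allowed, expressing absent populations) and
optional rare components present in only a subset of samples.

Data are generated on the transformed scale the model assumes (roughly
standardized intensities); no fluorescence-scale artifacts such as spillover
or compensation residuals are emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import EventMatrix

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "InfeasibleSpecError",
    "generate",
    "fig3_scenario",
    "zoom_scenario",
]


class InfeasibleSpecError(ValueError):
    """A present component's expected count is below one event."""


@dataclass
class SimulationSpec:
    """Parameters of one synthetic multi-sample dataset.

    ``weights`` has one row per sample over the true components; a zero entry
    means the component is absent from that sample.  ``rare_spec`` entries
    ``(component, frequency, present_in_samples)`` rewrite the corresponding
    weight columns: the component gets ``frequency`` in the listed samples and
    zero elsewhere, with the remaining weights rescaled to sum to one.
    ``sample_jitter_sd`` is the standard deviation of the per-sample
    perturbation added to each prototype mean; the default matches the
    model's own prior scale ``1/sqrt(beta0)`` with ``beta0 = 500``.
    """

    M: int
    D: int
    K_true: int
    events_per_sample: list[int]
    weights: np.ndarray
    prototype_means: np.ndarray
    prototype_covs: np.ndarray
    sample_jitter_sd: float = 500.0 ** -0.5
    cov_jitter_sd: float = 0.0
    rare_spec: list[tuple[int, float, list[int]]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.prototype_means = np.asarray(self.prototype_means, dtype=np.float64)
        self.prototype_covs = np.asarray(self.prototype_covs, dtype=np.float64)
        if self.weights.shape != (self.M, self.K_true):
            raise ValueError("weights must have shape (M, K_true)")
        if self.prototype_means.shape != (self.K_true, self.D):
            raise ValueError("prototype_means must have shape (K_true, D)")
        if self.prototype_covs.shape != (self.K_true, self.D, self.D):
            raise ValueError("prototype_covs must have shape (K_true, D, D)")
        if len(self.events_per_sample) != self.M:
            raise ValueError("events_per_sample must have length M")
        for k, freq, present in self.rare_spec:
            if not 0.0 < freq <= 0.05:
                raise ValueError("rare frequencies must lie in (0, 0.05]")
            col = np.zeros(self.M)
            col[list(present)] = freq
            others = [j for j in range(self.K_true) if j != k]
            rest = self.weights[:, others]
            rest_sum = rest.sum(axis=1)
            if np.any(rest_sum <= 0):
                raise ValueError("rare_spec leaves a sample with no other mass")
            self.weights[:, others] = rest * ((1.0 - col) / rest_sum)[:, None]
            self.weights[:, k] = col
        sums = self.weights.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("each sample's nonzero weights must sum to 1")
        eig = np.linalg.eigvalsh(0.5 * (self.prototype_covs
                                        + np.swapaxes(self.prototype_covs, -1, -2)))
        if np.any(eig[..., 0] <= 0):
            raise ValueError("prototype_covs must all be positive definite")
        for m in range(self.M):
            for k in range(self.K_true):
                w = self.weights[m, k]
                if 0 < w and w * self.events_per_sample[m] < 1.0:
                    raise InfeasibleSpecError(
                        f"component {k} present in sample {m} with expected count "
                        f"{w * self.events_per_sample[m]:.3g} < 1 event"
                    )


@dataclass
class GroundTruth:
    """True generating quantities aligned with the generated samples."""

    labels: list[np.ndarray]        # per sample, length N_m, values in [0, K_true)
    sample_means: np.ndarray        # (M, K_true, D) jittered per-sample means
    sample_covs: np.ndarray         # (M, K_true, D, D)
    presence: np.ndarray            # (K_true, M) boolean
    weights: np.ndarray             # (M, K_true)
    prototype_means: np.ndarray     # (K_true, D)


def generate(spec: SimulationSpec) -> tuple[list[EventMatrix], GroundTruth]:
    """Draw the multi-sample dataset described by ``spec``.

    Component counts are multinomial in the sample weights; per-sample means
    are the prototypes plus isotropic Gaussian jitter; events are Gaussian.
    Fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    markers = [f"marker{d + 1}" for d in range(spec.D)]
    samples: list[EventMatrix] = []
    labels: list[np.ndarray] = []
    sample_means = np.empty((spec.M, spec.K_true, spec.D))
    sample_covs = np.empty((spec.M, spec.K_true, spec.D, spec.D))

    for m in range(spec.M):
        mu = spec.prototype_means + spec.sample_jitter_sd * rng.standard_normal(
            (spec.K_true, spec.D)
        )
        covs = spec.prototype_covs.copy()
        if spec.cov_jitter_sd > 0:
            # log-scale perturbation keeps covariances positive definite
            scale = np.exp(spec.cov_jitter_sd * rng.standard_normal(spec.K_true))
            covs = covs * scale[:, None, None]
        sample_means[m] = mu
        sample_covs[m] = covs

        counts = rng.multinomial(spec.events_per_sample[m], spec.weights[m])
        parts, labs = [], []
        for k in range(spec.K_true):
            if counts[k] == 0:
                continue
            parts.append(rng.multivariate_normal(mu[k], covs[k], size=counts[k]))
            labs.append(np.full(counts[k], k, dtype=int))
        X = np.concatenate(parts, axis=0)
        y = np.concatenate(labs)
        perm = rng.permutation(X.shape[0])
        samples.append(EventMatrix(f"sample{m + 1}", X[perm], markers))
        labels.append(y[perm])

    truth = GroundTruth(
        labels=labels,
        sample_means=sample_means,
        sample_covs=sample_covs,
        presence=(spec.weights > 0).T,
        weights=spec.weights.copy(),
        prototype_means=spec.prototype_means.copy(),
    )
    return samples, truth


def fig3_scenario(seed: int = 0, events_per_sample: int = 4000):
    """Two 2-D samples with a rare cluster that separate per-sample fits miss.

    Both samples share two large overlapping populations and one tight rare
    population (1% of events).  Fitting each sample on its own, the rare
    cluster's handful of events is easily absorbed by the neighbouring large
    population; the joint fit pools its evidence across both samples.  This
    is the standing benchmark for the joint-versus-independent comparison.
    """
    spec = SimulationSpec(
        M=2,
        D=2,
        K_true=3,
        events_per_sample=[events_per_sample, events_per_sample],
        weights=np.array([[0.55, 0.44, 0.01], [0.69, 0.30, 0.01]]),
        prototype_means=np.array([[0.0, 0.0], [2.2, 0.0], [-1.6, 2.4]]),
        prototype_covs=np.stack([np.eye(2), np.eye(2), 0.09 * np.eye(2)]),
        seed=seed,
    )
    return generate(spec)


def zoom_scenario(seed: int = 0, n_train: int = 20_000, n_test: int = 1_000_000):
    """Two-step rare-event scenario: training samples locate a 1% parent
    population; a much larger test sample hides a 0.045% subpopulation inside
    the parent's region of marker space.

    Returns ``(train_samples, train_truth, test_sample, test_truth)``.  The
    subpopulation exists only in the test sample; the workflow is expected to
    find the parent in step one and resolve the subpopulation by zooming into
    the parent's neighbourhood in step two.
    """
    D = 6
    base_means = np.array([
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [3.0, 3.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 3.0, 3.0, 0.0, 3.0, 0.0],
        [3.0, 0.0, 0.0, 3.0, 0.0, 3.0],
        [-3.0, 3.0, 0.0, 3.0, 3.0, 3.0],   # parent (1%)
    ])
    base_covs = np.stack([np.eye(D)] * 4 + [0.25 * np.eye(D)])
    big = (1.0 - 0.01) / 4.0
    train_weights = np.tile(np.array([big, big, big, big, 0.01]), (5, 1))
    train_spec = SimulationSpec(
        M=5, D=D, K_true=5,
        events_per_sample=[n_train] * 5,
        weights=train_weights,
        prototype_means=base_means,
        prototype_covs=base_covs,
        seed=seed,
    )
    train_samples, train_truth = generate(train_spec)

    # test sample: same populations plus the rare subpopulation offset inside
    # the parent region (parent SD = 0.5; offset 2 parent-SD so the parent's
    # own density at the subpopulation is negligible; subpopulation SD 0.15)
    sub_mean = base_means[4] + np.array([0.58, -0.58, 0.0, 0.58, 0.0, 0.0])
    test_means = np.vstack([base_means, sub_mean])
    test_covs = np.concatenate([base_covs, (0.15 ** 2 * np.eye(D))[None]], axis=0)
    sub_freq = 0.00045
    parent_freq = 0.01 - sub_freq
    test_weights = np.array([[big, big, big, big, parent_freq, sub_freq]])
    test_spec = SimulationSpec(
        M=1, D=D, K_true=6,
        events_per_sample=[n_test],
        weights=test_weights,
        prototype_means=test_means,
        prototype_covs=test_covs,
        seed=seed + 1_000_003,
    )
    test_samples, test_truth = generate(test_spec)
    return train_samples, train_truth, test_samples[0], test_truth
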