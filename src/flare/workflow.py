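"""The two-step rare-event workflow: population summaries, region-of-interest
"zoom" refits, and fold-change screening between conditions.

Step one fits the joint model over all samples and summarizes every
population's per-sample mean signature and proportion.  Step two extracts
the events inside a region of interest — an axis-aligned box in marker space
or a Mahalanobis ball around a fitted prototype — and runs a fresh, finer
fit on just those events to resolve subpopulations the coarse fit lumps
together.  The fold-change screen compares per-component proportions between
two conditions of one joint fit, mirroring how expanded populations are
flagged during disease progression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .inference import FitResult, fit as _fit
from .model import EventMatrix, Hyperparameters

__all__ = [
    "PopulationSummary",
    "RegionOfInterest",
    "EmptyRegionError",
    "IncompatibleSummariesError",
    "summarize",
    "zoom",
    "fold_change_screen",
]

#: default component count of a zoom refit; the subregion holds far fewer
#: populations than the full marker space
ZOOM_K = 20

#: default Mahalanobis radius of a component-anchored region (covers ~97% of
#: a Gaussian component's mass in low dimension)
ZOOM_RADIUS = 3.0


class EmptyRegionError(ValueError):
    """The region of interest selects no (or too few) events everywhere."""


class IncompatibleSummariesError(ValueError):
    """Summaries do not come from the same joint fit."""


@dataclass
class RegionOfInterest:
    """A subset of marker space, in one of two forms.

    Axis-aligned: ``bounds`` maps marker names to ``(low, high)`` intervals
    (either end may be ``None`` for open-ended); at least one marker must be
    constrained.  Component-anchored: a prototype mean plus a precision shape
    taken from a previous fit, selecting events within ``radius`` Mahalanobis
    units of the prototype.
    """

    bounds: dict[str, tuple[float | None, float | None]] | None = None
    center: np.ndarray | None = None
    precision: np.ndarray | None = None
    radius: float = ZOOM_RADIUS
    component: int | None = None

    def __post_init__(self) -> None:
        axis = self.bounds is not None
        anchored = self.center is not None
        if axis == anchored:
            raise ValueError("specify exactly one of bounds or a component anchor")
        if axis and len(self.bounds) == 0:
            raise ValueError("at least one marker must be constrained")
        if anchored:
            if self.radius <= 0:
                raise ValueError("radius must be positive")
            self.center = np.asarray(self.center, dtype=np.float64)
            self.precision = np.asarray(self.precision, dtype=np.float64)

    @classmethod
    def box(cls, **bounds: tuple[float | None, float | None]) -> "RegionOfInterest":
        return cls(bounds=dict(bounds))

    @classmethod
    def around_component(
        cls, result: FitResult, component: int, radius: float = ZOOM_RADIUS
    ) -> "RegionOfInterest":
        """Anchor the region at a fitted prototype, using the prototype shape
        posterior ``Phi_k / nu`` (the expected average precision) as metric."""
        state = result.state
        return cls(
            center=state.xi[component],
            precision=state.Phi[component] / state.nu,
            radius=radius,
            component=int(component),
        )

    def mask(self, sample: EventMatrix) -> np.ndarray:
        """Boolean membership of each event of ``sample`` in the region."""
        X = sample.data
        if self.bounds is not None:
            keep = np.ones(X.shape[0], dtype=bool)
            for marker, (lo, hi) in self.bounds.items():
                if marker not in sample.marker_names:
                    raise KeyError(
                        f"marker {marker!r} not in sample {sample.sample_id!r}"
                    )
                col = X[:, sample.marker_names.index(marker)]
                if lo is not None:
                    keep &= col >= lo
                if hi is not None:
                    keep &= col <= hi
            return keep
        diff = X - self.center
        d2 = np.einsum("nd,de,ne->n", diff, self.precision, diff)
        return d2 <= self.radius ** 2


@dataclass
class PopulationSummary:
    """Per-component, per-sample population signatures of a fit.

    ``proportion[k, m]`` is the soft occupancy ``N_k^(m) / N_m``;
    ``mean_intensity[k, m]`` is the posterior per-sample mean;
    ``marker_percentile_rank[k, d]`` ranks the prototype mean of marker d
    among all components on a 0–100 scale (0 = lowest; a single component
    ranks 0 by convention) — the matrix behind the signature heatmap.
    """

    proportion: np.ndarray             # (K, M)
    mean_intensity: np.ndarray         # (K, M, D)
    present: np.ndarray                # (K, M) boolean
    prototype_mean: np.ndarray         # (K, D)
    marker_percentile_rank: np.ndarray  # (K, D)
    sample_ids: list[str]
    marker_names: list[str]
    n_events: np.ndarray               # (M,)

    @property
    def n_components(self) -> int:
        return self.proportion.shape[0]

    def overall_proportion(self) -> np.ndarray:
        """Event-weighted proportion of each component across the summary's
        samples (total soft count over total events)."""
        counts = self.proportion * self.n_events[None, :]
        return counts.sum(axis=1) / self.n_events.sum()

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (component, sample)."""
        rows = []
        for k in range(self.n_components):
            for m, sid in enumerate(self.sample_ids):
                row = {
                    "component": k,
                    "sample": sid,
                    "proportion": self.proportion[k, m],
                    "present": bool(self.present[k, m]),
                }
                for d, name in enumerate(self.marker_names):
                    row[f"mean_{name}"] = self.mean_intensity[k, m, d]
                rows.append(row)
        return pd.DataFrame(rows)

    def heatmap_matrix(self) -> pd.DataFrame:
        """Components x markers percentile-rank matrix for heatmap rendering."""
        return pd.DataFrame(
            self.marker_percentile_rank,
            index=[f"component{k}" for k in range(self.n_components)],
            columns=self.marker_names,
        )


def summarize(
    result: FitResult,
    data: list[EventMatrix] | None = None,
    sample_indices: list[int] | None = None,
) -> PopulationSummary:
    """Build the population summary of a fit (optionally restricted to a
    subset of samples, e.g. one experimental condition).

    Deterministic given the fit; ``data`` is accepted for interface symmetry
    and consistency checks but the summary derives entirely from the state.
    """
    state = result.state
    K = state.n_components
    if data is not None and len(data) != state.n_samples:
        raise ValueError("data does not match the fitted state")
    idx = list(range(state.n_samples)) if sample_indices is None else list(sample_indices)
    n_events = np.array([state.r[m].shape[0] for m in idx], dtype=np.float64)

    proportion = np.stack([state.Nk[m] / state.r[m].shape[0] for m in idx], axis=1)
    mean_intensity = np.stack([state.omega[m] for m in idx], axis=1)
    present = result.presence[:, idx]

    if K > 1:
        ranks = np.empty_like(state.xi)
        for d in range(state.xi.shape[1]):
            ranks[:, d] = (rankdata(state.xi[:, d], method="average") - 1.0) / (K - 1) * 100.0
    else:
        ranks = np.zeros_like(state.xi)

    return PopulationSummary(
        proportion=proportion,
        mean_intensity=mean_intensity,
        present=present,
        prototype_mean=state.xi.copy(),
        marker_percentile_rank=ranks,
        sample_ids=[result.sample_ids[m] for m in idx],
        marker_names=list(result.marker_names),
        n_events=n_events,
    )


def zoom(
    data: list[EventMatrix],
    roi: RegionOfInterest,
    hp: Hyperparameters | None = None,
    seed: int = 0,
    *,
    min_events: int = 50,
    **fit_kwargs,
) -> FitResult:
    """Refit the model on only the events inside the region of interest.

    Samples left with zero events in the region are dropped from the refit;
    if no sample retains at least ``min_events`` events the region is
    considered empty.  The refit starts from scratch with a smaller default
    component count (``K = 20``) suited to a subregion.
    """
    if hp is None:
        hp = Hyperparameters(K=ZOOM_K)
    sub = []
    for sample in data:
        keep = roi.mask(sample)
        if keep.sum() == 0:
            continue
        sub.append(EventMatrix(sample.sample_id, sample.data[keep], sample.marker_names))
    if not sub or max(s.n_events for s in sub) < min_events:
        raise EmptyRegionError(
            f"region selects fewer than {min_events} events in every sample"
        )
    return _fit(sub, hp, seed=seed, **fit_kwargs)


def fold_change_screen(
    summary_case: PopulationSummary,
    summary_ref: PopulationSummary,
    min_ratio: float = 2.0,
    floor: float | None = None,
) -> list[int]:
    """Components whose proportion grew by more than ``min_ratio`` fold.

    Both summaries must come from one joint fit spanning both conditions, so
    component indices align.  Reference proportions of zero (component absent
    from the reference condition) are floored at half an event,
    ``0.5 / N_ref``, a standard continuity correction.  The default
    ``min_ratio = 2`` reads "more than 1-fold change" as a doubling; pass
    ``min_ratio = 1`` for "any increase".
    """
    if summary_case.n_components != summary_ref.n_components:
        raise IncompatibleSummariesError(
            "summaries have different component counts; they must come from "
            "one joint fit"
        )
    if summary_case.marker_names != summary_ref.marker_names:
        raise IncompatibleSummariesError("summaries disagree on markers")
    p_case = summary_case.overall_proportion()
    p_ref = summary_ref.overall_proportion()
    if floor is None:
        floor = 0.5 / summary_ref.n_events.sum()
    ratio = p_case / np.maximum(p_ref, floor)
    return [int(k) for k in np.flatnonzero((ratio > min_ratio) & (p_case > 0))]
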