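"""Data-partition planning and the partitioned (parallel) fit contract.

A deployment across worker nodes stores each sample's events on a dedicated
subset of workers (a worker never mixes samples).  The planner assigns
worker counts to samples by a greedy minimax rule — give every sample one
worker, then repeatedly give another worker to the sample with the highest
per-worker load — and reports the partition efficiency

    balance = load_opt / load_max,
    load_opt = ceil(N / W),   load_max = max_m ceil(N_m / W_m),

which is 1 exactly when the plan achieves the ideal even split.

The partitioned fit here executes in-process with the same communication
pattern a message-passing deployment would use: event-level computations run
block-wise per worker slot, per-sample reductions combine partial sums in a
fixed order, cross-sample reductions combine one contribution per sample.
Its contract is numerical equivalence with the serial fit, not wall-clock
speedup.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .inference import FitResult, fit as _fit
from .model import EventMatrix, Hyperparameters

__all__ = [
    "PartitionPlan",
    "InsufficientWorkersError",
    "OracleScopeError",
    "InvalidPlanError",
    "balance_nodes",
    "plan_optimality_check",
    "parallel_fit",
]


class InsufficientWorkersError(ValueError):
    """Fewer worker slots than samples; a valid plan needs W >= M."""


class OracleScopeError(ValueError):
    """Instance too large for the exhaustive optimality oracle."""


class InvalidPlanError(ValueError):
    """Plan is inconsistent with the data it is applied to."""


@dataclass(frozen=True)
class PartitionPlan:
    """Assignment of W worker slots to M samples."""

    sample_sizes: tuple[int, ...]
    assignment: tuple[int, ...]   # workers per sample, sums to W

    @property
    def W(self) -> int:
        return sum(self.assignment)

    @property
    def per_worker_load(self) -> np.ndarray:
        """Events per worker for each sample, N_m / W_m (real-valued)."""
        return np.asarray(self.sample_sizes) / np.asarray(self.assignment)

    @property
    def load_opt(self) -> int:
        N = sum(self.sample_sizes)
        return math.ceil(N / self.W)

    @property
    def load_max(self) -> int:
        return max(
            math.ceil(n / w) for n, w in zip(self.sample_sizes, self.assignment)
        )

    @property
    def balance(self) -> float:
        return self.load_opt / self.load_max

    def printed_form_quantities(self) -> dict:
        """The partition-efficiency quantities exactly as originally printed
        (``load_opt = ceil(W/N)``; ``load_max = argmax_m W_m``), kept for
        audit only: they contradict the surrounding prose and can exceed 1.
        """
        W = self.W
        N = sum(self.sample_sizes)
        load_opt = math.ceil(W / N)
        load_max = int(np.argmax(self.assignment))
        return {
            "load_opt": load_opt,
            "load_max": load_max,
            "balance": load_opt / load_max if load_max else math.inf,
        }

    def to_dict(self) -> dict:
        return {
            "W": self.W,
            "sample_sizes": list(self.sample_sizes),
            "assignment": list(self.assignment),
            "per_worker_load": [float(x) for x in self.per_worker_load],
            "balance": self.balance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PartitionPlan":
        return cls(tuple(d["sample_sizes"]), tuple(d["assignment"]))


def balance_nodes(sample_sizes: list[int], W: int) -> PartitionPlan:
    """Greedy minimax load balancing.

    Every sample gets one worker; each remaining worker goes to the sample
    with the highest current per-worker load, ties broken by lowest sample
    index.
    """
    M = len(sample_sizes)
    if M == 0 or any(n < 1 for n in sample_sizes):
        raise ValueError("sample sizes must all be >= 1")
    if W < M:
        raise InsufficientWorkersError(
            f"{W} workers cannot cover {M} samples (need W >= M)"
        )
    workers = [1] * M
    for _ in range(W - M):
        loads = [n / w for n, w in zip(sample_sizes, workers)]
        workers[int(np.argmax(loads))] += 1
    return PartitionPlan(tuple(int(n) for n in sample_sizes), tuple(workers))


def plan_optimality_check(sample_sizes: list[int], W: int) -> bool:
    """Exhaustively verify that the greedy plan attains the minimax load.

    Enumerates every assignment of W workers to the samples (each >= 1) and
    compares the greedy plan's maximum per-worker load with the true
    optimum.  Only small instances are in scope.
    """
    M = len(sample_sizes)
    if W > 10 or M > 5:
        raise OracleScopeError("oracle limited to W <= 10 and M <= 5")
    greedy = balance_nodes(sample_sizes, W)
    best = min(
        max(math.ceil(n / w) for n, w in zip(sample_sizes, assign))
        for assign in _compositions(W, M)
    )
    return greedy.load_max == best


def _compositions(W: int, M: int):
    """All tuples of M positive integers summing to W."""
    for cuts in itertools.combinations(range(1, W), M - 1):
        parts = []
        prev = 0
        for c in cuts:
            parts.append(c - prev)
            prev = c
        parts.append(W - prev)
        yield tuple(parts)


def make_chunks(plan: PartitionPlan) -> list[list[tuple[int, int]]]:
    """Per-sample contiguous event slices, one per worker slot (nearly equal
    sizes, earlier slots take the remainder)."""
    chunks = []
    for n, w in zip(plan.sample_sizes, plan.assignment):
        base, rem = divmod(n, w)
        spans, start = [], 0
        for i in range(w):
            size = base + (1 if i < rem else 0)
            spans.append((start, start + size))
            start += size
        chunks.append(spans)
    return chunks


def parallel_fit(
    data: list[EventMatrix],
    hp: Hyperparameters | None,
    plan: PartitionPlan,
    seed: int = 0,
    n_threads: int = 1,
    **fit_kwargs,
) -> FitResult:
    """Run the fit with event blocks partitioned according to ``plan``.

    Numerically equivalent to the serial fit: with one worker per sample the
    execution path is identical; with more workers the only differences are
    floating-point reassociations of the partial-sum reductions.
    """
    if len(plan.sample_sizes) != len(data) or any(
        n != s.n_events for n, s in zip(plan.sample_sizes, data)
    ):
        raise InvalidPlanError("plan sample sizes do not match the data")
    chunks = make_chunks(plan)
    return _fit(data, hp, seed=seed, chunks=chunks, n_threads=n_threads, **fit_kwargs)
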