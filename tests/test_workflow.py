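"""Population summaries, region-of-interest zoom, and the fold-change screen."""

import numpy as np
import pytest

from flare import simulate
from flare.inference import fit
from flare.model import EventMatrix, Hyperparameters
from flare.workflow import (
    EmptyRegionError,
    IncompatibleSummariesError,
    PopulationSummary,
    RegionOfInterest,
    fold_change_screen,
    summarize,
    zoom,
)


def make_summary(proportions, n_events, markers=("a",)):
    """Hand-built summary for screen arithmetic tests: proportions is (K, M)."""
    p = np.asarray(proportions, float)
    K, M = p.shape
    D = len(markers)
    return PopulationSummary(
        proportion=p,
        mean_intensity=np.zeros((K, M, D)),
        present=p > 0,
        prototype_mean=np.zeros((K, D)),
        marker_percentile_rank=np.zeros((K, D)),
        sample_ids=[f"s{m}" for m in range(M)],
        marker_names=list(markers),
        n_events=np.asarray(n_events, float),
    )


class TestSummarize:
    def test_single_component(self):
        data = [EventMatrix("s", np.random.default_rng(0).normal(size=(100, 2)), ["a", "b"])]
        res = fit(data, Hyperparameters(K=1), seed=0, max_sweeps=10)
        summ = summarize(res, data)
        assert summ.proportion[0, 0] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_array_equal(summ.marker_percentile_rank, 0.0)

    def test_proportions_sum_to_one_and_ranks_bounded(self, small_fit):
        res, data, _ = small_fit
        summ = summarize(res, data)
        np.testing.assert_allclose(summ.proportion.sum(axis=0), 1.0, atol=1e-8)
        assert summ.marker_percentile_rank.min() >= 0.0
        assert summ.marker_percentile_rank.max() <= 100.0

    def test_recount_oracle(self, small_fit):
        """With confident assignments, soft proportions track hard-label
        counts within 1%."""
        res, data, _ = small_fit
        summ = summarize(res, data)
        for m, sample in enumerate(data):
            if res.state.r[m].max(axis=1).min() < 0.99:
                continue
            counts = np.bincount(
                res.hard_labels[m], minlength=res.state.n_components
            ) / sample.n_events
            np.testing.assert_allclose(summ.proportion[:, m], counts, atol=0.01)

    def test_deterministic(self, small_fit):
        res, data, _ = small_fit
        a, b = summarize(res, data), summarize(res, data)
        np.testing.assert_array_equal(a.proportion, b.proportion)
        np.testing.assert_array_equal(a.marker_percentile_rank, b.marker_percentile_rank)

    def test_export_table_shape(self, small_fit):
        res, data, _ = small_fit
        summ = summarize(res, data)
        df = summ.to_frame()
        assert len(df) == summ.n_components * len(summ.sample_ids)
        assert {"component", "sample", "proportion", "present"} <= set(df.columns)
        hm = summ.heatmap_matrix()
        assert hm.shape == (summ.n_components, len(summ.marker_names))


class TestRegionOfInterest:
    def test_requires_exactly_one_form(self):
        with pytest.raises(ValueError):
            RegionOfInterest()
        with pytest.raises(ValueError):
            RegionOfInterest(bounds={"a": (0, 1)}, center=np.zeros(2),
                             precision=np.eye(2))
        with pytest.raises(ValueError):
            RegionOfInterest(bounds={})
        with pytest.raises(ValueError):
            RegionOfInterest(center=np.zeros(2), precision=np.eye(2), radius=0.0)

    def test_axis_aligned_membership(self):
        s = EventMatrix("s", np.array([[0.0, 5.0], [2.0, 5.0], [0.0, -5.0]]), ["a", "b"])
        roi = RegionOfInterest.box(a=(-1.0, 1.0))
        np.testing.assert_array_equal(roi.mask(s), [True, False, True])
        roi2 = RegionOfInterest.box(a=(-1.0, 1.0), b=(0.0, None))
        np.testing.assert_array_equal(roi2.mask(s), [True, False, False])

    def test_mahalanobis_membership(self):
        s = EventMatrix("s", np.array([[0.0, 0.0], [2.9, 0.0], [3.1, 0.0]]), ["a", "b"])
        roi = RegionOfInterest(center=np.zeros(2), precision=np.eye(2), radius=3.0)
        np.testing.assert_array_equal(roi.mask(s), [True, True, False])


class TestZoom:
    def test_full_space_roi_equals_direct_fit(self, three_cluster_data):
        data, _ = three_cluster_data
        roi = RegionOfInterest.box(marker1=(None, None))
        hp = Hyperparameters(K=3)
        a = zoom(data, roi, hp, seed=4, max_sweeps=30)
        b = fit(data, hp, seed=4, max_sweeps=30)
        assert a.elbo_trace == b.elbo_trace
        for name in ("alpha", "Nk", "omega", "Psi", "xi", "Phi"):
            np.testing.assert_array_equal(
                getattr(a.state, name), getattr(b.state, name)
            )
        for x, y in zip(a.state.r, b.state.r):
            np.testing.assert_array_equal(x, y)

    def test_region_excluding_one_sample(self):
        rng = np.random.default_rng(0)
        s1 = EventMatrix("s1", rng.normal(0.0, 1.0, size=(300, 2)), ["a", "b"])
        s2 = EventMatrix("s2", rng.normal(10.0, 1.0, size=(300, 2)), ["a", "b"])
        roi = RegionOfInterest.box(a=(-4.0, 4.0))
        res = zoom([s1, s2], roi, Hyperparameters(K=2), seed=0, max_sweeps=20)
        assert res.sample_ids == ["s1"]
        assert res.presence.shape[1] == 1

    def test_empty_region_raises(self):
        s = EventMatrix("s", np.zeros((50, 2)), ["a", "b"])
        roi = RegionOfInterest.box(a=(5.0, 6.0))
        with pytest.raises(EmptyRegionError):
            zoom([s], roi, Hyperparameters(K=2), seed=0)


class TestFoldChangeScreen:
    def test_sixfold_expansion_selected(self):
        case = make_summary([[0.06], [0.94]], [10_000])
        ref = make_summary([[0.01], [0.99]], [10_000])
        assert fold_change_screen(case, ref, min_ratio=2.0) == [0]

    def test_identical_summaries_select_nothing(self):
        s = make_summary([[0.3], [0.7]], [5_000])
        assert fold_change_screen(s, s, min_ratio=1.0000001) == []

    def test_absent_reference_uses_floor(self):
        case = make_summary([[1e-3], [1.0 - 1e-3]], [1_000_000])
        ref = make_summary([[0.0], [1.0]], [500_000])
        # floor 1e-6 -> ratio 1000
        hits = fold_change_screen(case, ref, min_ratio=2.0, floor=1e-6)
        assert hits == [0]
        # default floor is half an event over the reference total
        hits_default = fold_change_screen(case, ref, min_ratio=2.0)
        assert hits_default == [0]

    def test_direction_antisymmetry(self):
        case = make_summary([[0.30], [0.10], [0.60]], [10_000])
        ref = make_summary([[0.10], [0.30], [0.60]], [10_000])
        fwd = set(fold_change_screen(case, ref, min_ratio=2.0))
        rev = set(fold_change_screen(ref, case, min_ratio=2.0))
        assert fwd and rev and not (fwd & rev)

    def test_mismatched_components_rejected(self):
        a = make_summary([[1.0]], [100])
        b = make_summary([[0.5], [0.5]], [100])
        with pytest.raises(IncompatibleSummariesError):
            fold_change_screen(a, b)

    def test_condition_split_of_joint_fit(self, small_fit):
        """Summaries restricted to sample subsets share component indices and
        screen cleanly."""
        res, data, _ = small_fit
        s_case = summarize(res, data, sample_indices=[0])
        s_ref = summarize(res, data, sample_indices=[1, 2])
        hits = fold_change_screen(s_case, s_ref, min_ratio=2.0)
        assert all(0 <= k < res.state.n_components for k in hits)
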