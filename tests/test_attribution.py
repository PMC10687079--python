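"""Integrated-gradients axioms, group aggregation, standardisation and the
top-fraction heatmap filter."""

import numpy as np
import pytest

from connharm import attribution as attr
from connharm.autograd import Tensor
from connharm.data import ConnectivityDataset
from connharm.fc import lower_triangle_indices


def _linear_fn(w):
    wt = Tensor(np.asarray(w, float)[:, None])

    def fn(xt):
        return xt @ wt

    return fn


class TestBaseline:
    def _ds(self, features, diagnosis):
        n = len(diagnosis)
        return ConnectivityDataset(
            features=np.asarray(features, float),
            subject_id=np.array([f"s{i}" for i in range(n)]),
            site=np.array(["a"] * n), diagnosis=np.asarray(diagnosis),
            age=np.full(n, 30.0), gender=np.array(["F"] * n))

    def test_single_control_is_its_own_baseline(self):
        ds = self._ds([[1.0, 2.0]], [0])
        assert np.array_equal(attr.compute_baseline(ds), [1.0, 2.0])

    def test_mean_over_controls_only(self):
        ds = self._ds([[0.0, 0.0], [2.0, 2.0], [99.0, 99.0]], [0, 0, 1])
        assert np.array_equal(attr.compute_baseline(ds), [1.0, 1.0])

    def test_no_controls_rejected(self):
        with pytest.raises(ValueError, match="controls"):
            attr.compute_baseline(self._ds([[1.0, 1.0]], [1]))


class TestIntegratedGradients:
    def test_zero_at_baseline(self):
        fn = _linear_fn([2.0, 3.0])
        out = attr.integrated_gradients(fn, np.array([1.0, 1.0]),
                                        np.array([1.0, 1.0]), steps=10)
        assert np.array_equal(out, [0.0, 0.0])

    @pytest.mark.parametrize("steps", [1, 7, 100])
    def test_linear_model_closed_form(self, steps):
        # IG of a linear map is (x - baseline) ⊙ w for any step count
        fn = _linear_fn([2.0, 3.0])
        out = attr.integrated_gradients(fn, np.array([1.0, 1.0]),
                                        np.zeros(2), steps=steps)
        assert np.allclose(out, [2.0, 3.0], atol=1e-12)

    def test_completeness_on_trained_model(self, trained_small):
        syn, train_idx, test_idx, trained = trained_small
        ds = syn.dataset
        baseline = attr.compute_baseline(ds.subset(train_idx))
        test = ds.subset(test_idx)
        cov = trained.design.covariate_matrix(test)
        site = trained.design.site_index(test)
        fn = attr.subject_logit_fn(trained, cov[0], int(site[0]))
        scores = attr.integrated_gradients(fn, test.features[0], baseline, steps=200)
        f_x = fn(Tensor(test.features[0][None, :])).item()
        f_b = fn(Tensor(baseline[None, :])).item()
        assert abs(scores.sum() - (f_x - f_b)) < 1e-3

    def test_converged_by_one_hundred_steps(self, trained_small):
        syn, train_idx, test_idx, trained = trained_small
        ds = syn.dataset
        baseline = attr.compute_baseline(ds.subset(train_idx))
        test = ds.subset(test_idx)
        cov = trained.design.covariate_matrix(test)
        site = trained.design.site_index(test)
        fn = attr.subject_logit_fn(trained, cov[0], int(site[0]))
        r100 = attr.integrated_gradients(fn, test.features[0], baseline, steps=100)
        r200 = attr.integrated_gradients(fn, test.features[0], baseline, steps=200)
        rel = np.linalg.norm(r200 - r100) / np.linalg.norm(r200)
        assert rel < 0.01

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            attr.integrated_gradients(_linear_fn([1.0]), np.zeros(2), np.zeros(3))


class TestGroupAggregation:
    def test_absolute_value_and_sz_only(self):
        scores = np.array([[-1.0, 2.0], [100.0, 100.0]])
        out = attr.group_attribution(scores, np.array([1, 0]))
        assert np.array_equal(out, [1.0, 2.0])

    def test_mean_over_patients(self):
        scores = np.array([[1.0, 0.0], [3.0, 0.0]])
        assert np.array_equal(attr.group_attribution(scores, np.ones(2, int)),
                              [2.0, 0.0])

    def test_no_patients_rejected(self):
        with pytest.raises(ValueError, match="SZ"):
            attr.group_attribution(np.ones((2, 3)), np.zeros(2, int))

    def test_standardise_properties(self):
        rng = np.random.default_rng(0)
        groups = [rng.uniform(size=50) for _ in range(5)]
        agg = attr.aggregate_standardise(groups)
        assert agg.mean() == pytest.approx(0.0, abs=1e-10)
        assert agg.std() == pytest.approx(1.0, abs=1e-10)
        perm = attr.aggregate_standardise([groups[i] for i in [3, 1, 4, 0, 2]])
        assert np.allclose(agg, perm)
        single = attr.aggregate_standardise([groups[0]])
        z = (groups[0] - groups[0].mean()) / groups[0].std()
        assert np.allclose(single, z)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            attr.aggregate_standardise([np.ones(10)])


class TestTopFractionFilter:
    def test_exactly_one_survivor_per_hundred(self):
        rng = np.random.default_rng(1)
        r = 15   # V = 105 lower-triangle entries
        m = rng.uniform(size=(r, r))
        out = attr.top_fraction_filter(m, 0.01)
        assert np.count_nonzero(out) == 1
        assert np.all(np.triu(out) == 0)

    def test_347_survivors_for_264_rois(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(264, 264))
        out = attr.top_fraction_filter(m, 0.01)
        assert np.count_nonzero(out) == 347   # floor(0.01 · 34716)

    def test_matches_sorting_oracle(self):
        rng = np.random.default_rng(3)
        r = 30
        m = rng.normal(size=(r, r))
        out = attr.top_fraction_filter(m, 0.1)
        rows, cols = lower_triangle_indices(r)
        vec = m[rows, cols]
        k = int(np.floor(0.1 * vec.size))
        kept = set(np.argsort(-vec, kind="stable")[:k])
        got = {i for i in range(vec.size) if out[rows[i], cols[i]] != 0}
        assert got == kept

    def test_tie_at_threshold_keeps_lower_feature_index(self):
        m = np.zeros((3, 3))
        rows, cols = lower_triangle_indices(3)
        m[rows, cols] = [5.0, 5.0, 1.0]   # features 0 and 1 tie
        out = attr.top_fraction_filter(m, 1 / 3)
        assert out[rows[0], cols[0]] == 5.0
        assert out[rows[1], cols[1]] == 0.0

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            attr.top_fraction_filter(np.ones((4, 4)), 0.01)
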