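"""Location-scale harmonisation: removal/restoration algebra and the
least-squares fitter's parameter recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connharm.data import DesignInfo
from connharm.harmonise import (HarmonisationParameters, combat_fit,
                                identity_parameters, remove_site_effects,
                                restore_site_effects)
from connharm.synthetic import SyntheticSpec, generate_multisite_dataset


def _params(alpha, beta, gamma, delta, sigma=None):
    alpha = np.atleast_1d(np.asarray(alpha, float))
    v = alpha.size
    return HarmonisationParameters(
        alpha=alpha, beta=np.atleast_2d(beta),
        gamma=np.atleast_2d(gamma), delta=np.atleast_2d(delta),
        sigma=np.ones(v) if sigma is None else sigma,
        site_vocab=[f"s{i}" for i in range(np.atleast_2d(gamma).shape[0])],
        covariate_names=["c0"])


class TestRemoveRestore:
    def test_identity_parameters_pass_through(self):
        p = identity_parameters(4, ["a", "b"], n_covariates=2)
        x = np.array([1.0, -2.0, 3.0, 0.5])
        out = remove_site_effects(x, np.zeros(2), 0, p)
        assert np.array_equal(out, x)
        assert np.array_equal(restore_site_effects(x, np.zeros(2), 1, p), x)

    def test_hand_worked_example(self):
        # x=5, alpha=1, Mbeta=1, gamma=2, delta=2 -> eps=0.5, x_res=1.5
        p = _params([1.0], [[1.0]], [[2.0]], [[2.0]])
        x_res = remove_site_effects(np.array([5.0]), np.array([1.0]), 0, p)
        assert x_res[0] == pytest.approx(1.5)
        x_back = restore_site_effects(x_res, np.array([1.0]), 0, p)
        assert x_back[0] == pytest.approx(5.0)

    def test_known_residual_recovered_exactly(self):
        rng = np.random.default_rng(2)
        v = 7
        p = _params(rng.normal(size=v), rng.normal(size=(1, v)),
                    rng.normal(size=(1, v)), rng.uniform(0.5, 2, size=(1, v)))
        eps = rng.normal(size=v)
        m = rng.normal(size=1)
        x = p.alpha + m @ p.beta + p.gamma[0] + p.delta[0] * eps
        x_res = remove_site_effects(x, m, 0, p)
        assert np.allclose(x_res - p.alpha, eps)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_is_machine_exact(self, seed):
        rng = np.random.default_rng(seed)
        v, c, n_sites = 5, 3, 3
        p = _params(rng.normal(size=v), rng.normal(size=(c, v)),
                    rng.normal(size=(n_sites, v)),
                    rng.uniform(0.1, 3.0, size=(n_sites, v)))
        x = rng.normal(size=(4, v)) * 5
        cov = rng.normal(size=(4, c))
        site = rng.integers(0, n_sites, size=4)
        for add_back in (False, True):
            x_res = remove_site_effects(x, cov, site, p, add_back)
            back = restore_site_effects(x_res, cov, site, p, add_back)
            assert np.allclose(back, x, atol=1e-10)

    def test_unknown_site_and_floor_violations_rejected(self):
        p = _params([0.0], [[0.0]], [[0.0]], [[1.0]])
        with pytest.raises(ValueError, match="site"):
            remove_site_effects(np.zeros(1), np.zeros(1), 5, p)
        tiny = _params([0.0], [[0.0]], [[0.0]], [[1e-8]])
        with pytest.raises(ValueError, match="floor"):
            remove_site_effects(np.zeros(1), np.zeros(1), 0, tiny)


class TestCombatFit:
    def test_two_identical_halves_give_null_site_effects(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(80, 20))
        from connharm.data import ConnectivityDataset
        ds = ConnectivityDataset(
            features=np.vstack([x, x]),
            subject_id=np.array([f"s{i}" for i in range(160)]),
            site=np.array(["a"] * 80 + ["b"] * 80),
            diagnosis=np.zeros(160, int),
            age=np.tile(rng.uniform(20, 60, 80), 2),
            gender=np.tile(rng.choice(["F", "M"], 80), 2))
        p = combat_fit(ds)
        assert np.allclose(p.gamma, 0.0, atol=1e-10)
        assert np.allclose(p.delta, 1.0, atol=1e-10)

    def test_recovers_known_site_effects_within_ten_percent(self):
        spec = SyntheticSpec(n_features=200, n_per_site_per_class=100,
                             gamma=np.array([2.0, -2.0]),
                             delta=np.array([2.0, 0.5]), seed=42)
        syn = generate_multisite_dataset(spec)
        p = combat_fit(syn.dataset)
        null = np.setdiff1d(np.arange(200), syn.class_support)
        gamma_rel = np.abs(p.gamma[:, null] - syn.params.gamma[:, null]) / 2.0
        delta_rel = np.abs(p.delta[:, null] / syn.params.delta[:, null] - 1.0)
        assert gamma_rel.mean() < 0.10
        assert delta_rel.mean() < 0.10
        assert np.abs(p.gamma[:, null].mean(axis=1) - [2.0, -2.0]).max() < 0.2
        assert np.abs(p.delta[:, null].mean(axis=1) - [2.0, 0.5]).max() < 0.1

    def test_gamma_recovery_correlation_exceeds_point_nine(self):
        spec = SyntheticSpec(n_features=200, n_per_site_per_class=100, seed=7)
        syn = generate_multisite_dataset(spec)
        p = combat_fit(syn.dataset)
        truth = syn.params.gamma - syn.params.gamma.mean(axis=0)  # identified part
        for i in range(2):
            assert np.corrcoef(p.gamma[i], truth[i])[0, 1] > 0.9

    def test_harmonised_site_means_agree(self):
        spec = SyntheticSpec(n_features=50, n_per_site_per_class=100, seed=11)
        syn = generate_multisite_dataset(spec)
        ds = syn.dataset
        design = DesignInfo.fit(ds)
        p = combat_fit(ds, design)
        h = remove_site_effects(ds.features, design.covariate_matrix(ds),
                                design.site_index(ds), p)
        means = [h[ds.site == s].mean(axis=0) for s in ds.sites]
        se = ds.features.std(axis=0) / np.sqrt(200)
        assert np.all(np.abs(means[0] - means[1]) < 2 * se)

    def test_small_site_rejected(self):
        spec = SyntheticSpec(n_features=10, n_per_site_per_class=1, seed=0)
        syn = generate_multisite_dataset(spec)
        with pytest.raises(ValueError, match="fewer than 3"):
            combat_fit(syn.dataset)

    def test_serialisation_round_trip(self, tmp_path):
        spec = SyntheticSpec(n_features=12, n_per_site_per_class=10, seed=5)
        p = combat_fit(generate_multisite_dataset(spec).dataset)
        path = tmp_path / "params.json"
        p.save(path)
        q = HarmonisationParameters.load(path)
        for attr in ("alpha", "beta", "gamma", "delta", "sigma"):
            assert np.allclose(getattr(p, attr), getattr(q, attr))
        assert q.site_vocab == p.site_vocab
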