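"""Architecture contracts: encoder/decoder/classifier shapes, variant
dispatch, determinism, and parameter-count parity of the DNN baseline."""

import numpy as np
import pytest

from connharm.autograd import Tensor
from connharm.model import EDCConfig, EDCModel, default_loss_weights


def _cfg(**kw):
    base = dict(input_dim=50, variant="edc_sl", n_covariates=2, n_sites=2)
    base.update(kw)
    return EDCConfig(**base)


class TestEncodeDecodeClassify:
    def test_shapes_and_sigma_positivity(self):
        m = EDCModel(_cfg(), seed=0)
        m.eval()
        state = m.encode(np.random.default_rng(0).normal(size=(3, 50)))
        assert state.z_mu.data.shape == (3, 16)
        assert state.z_sigma.data.shape == (3, 16)
        assert np.all(state.z_sigma.data > 0)

    def test_zero_weights_give_standard_normal_latent(self):
        m = EDCModel(_cfg(), seed=0)
        for stack in (m.enc_mu, m.enc_sigma):
            for lin in stack:
                lin.w.data[:] = 0
                lin.b.data[:] = 0
        state = m.encode(np.ones((2, 50)))
        assert np.allclose(state.z_mu.data, 0.0)
        assert np.allclose(state.z_sigma.data, 1.0)   # exp(0)

    def test_latent_sampling_reparameterisation(self):
        m = EDCModel(_cfg(), seed=0)
        state = m.encode(np.zeros((1, 50)))
        state.z_sigma = Tensor(np.zeros((1, 16)) + 1e-300)
        m.train()
        z = m.sample_latent(state, np.random.default_rng(0))
        assert np.allclose(z.data, state.z_mu.data)   # sigma -> 0 limit
        # identical rng seed -> identical draw
        s2 = m.encode(np.zeros((1, 50)))
        z1 = m.sample_latent(s2, np.random.default_rng(7)).data.copy()
        s3 = m.encode(np.zeros((1, 50)))
        z2 = m.sample_latent(s3, np.random.default_rng(7)).data
        assert np.array_equal(z1, z2)

    def test_sample_mean_matches_clt_bound(self):
        m = EDCModel(_cfg(), seed=0)
        m.train()
        rng = np.random.default_rng(123)
        state = m.encode(np.zeros((1, 50)))
        state.z_mu = Tensor(np.zeros((1, 1)))
        state.z_sigma = Tensor(np.ones((1, 1)))
        draws = [m.sample_latent(state, rng).item() for _ in range(10_000)]
        assert abs(np.mean(draws)) < 3 / np.sqrt(10_000)

    def test_classifier_softmax_closed_forms(self):
        m = EDCModel(_cfg(), seed=0)
        assert np.allclose(m.softmax(Tensor(np.zeros((1, 2)))), [[0.5, 0.5]])
        probs = m.softmax(Tensor(np.array([[np.log(3.0), 0.0]])))
        assert np.allclose(probs, [[0.75, 0.25]])
        rng = np.random.default_rng(0)
        p = m.softmax(Tensor(rng.normal(size=(4, 2)) * 10))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_classifier_invariant_to_constant_logit_shift(self):
        m = EDCModel(_cfg(), seed=0)
        logits = np.random.default_rng(1).normal(size=(3, 2))
        assert np.allclose(m.softmax(Tensor(logits)), m.softmax(Tensor(logits + 5.0)))

    def test_dimension_mismatch_rejected(self):
        m = EDCModel(_cfg(), seed=0)
        with pytest.raises(ValueError, match="features"):
            m.encode(np.zeros((1, 49)))
        with pytest.raises(ValueError, match="latent"):
            m.decode(Tensor(np.zeros((1, 3))))


class TestForward:
    def test_eval_forward_is_deterministic(self):
        m = EDCModel(_cfg(variant="shred_iii"), seed=0)
        m.eval()
        x = np.random.default_rng(0).normal(size=(4, 50))
        cov = np.zeros((4, 2))
        site = np.array([0, 1, 0, 1])
        r1 = m.forward(x, cov, site)
        r2 = m.forward(x, cov, site)
        assert np.array_equal(r1.probs, r2.probs)
        assert np.array_equal(r1.x_hat.data, r2.x_hat.data)

    def test_identity_harmonisation_reduces_to_edc(self):
        shred = EDCModel(_cfg(variant="shred_iii"), seed=5)
        edc = EDCModel(_cfg(variant="edc_sl"), seed=5)
        # same EDC weights; harmonisation weights are zero-initialised (identity)
        for a, b in zip(shred.enc_mu + shred.enc_sigma + shred.dec + [shred.classifier],
                        edc.enc_mu + edc.enc_sigma + edc.dec + [edc.classifier]):
            b.w.data = a.w.data.copy()
            b.b.data = a.b.data.copy()
        shred.eval()
        edc.eval()
        x = np.random.default_rng(2).normal(size=(3, 50))
        rs = shred.forward(x, np.zeros((3, 2)), np.array([0, 1, 1]))
        re = edc.forward(x)
        assert np.allclose(rs.probs, re.probs)
        assert np.allclose(rs.x_hat.data, re.x_hat.data)

    def test_dnn_outputs_valid_probabilities(self):
        m = EDCModel(_cfg(variant="dnn", input_dim=30), seed=0)
        m.eval()
        r = m.forward(np.random.default_rng(0).normal(size=(5, 30)))
        assert np.all(r.probs >= 0)
        assert np.allclose(r.probs.sum(axis=1), 1.0)
        assert r.latent is None

    def test_harmonised_variant_requires_design(self):
        m = EDCModel(_cfg(variant="shred_iii"), seed=0)
        with pytest.raises(ValueError, match="covariates"):
            m.forward(np.zeros((1, 50)))


class TestConfig:
    def test_parameter_count_parity_at_v1000(self):
        # the DNN baseline's hidden sizes were chosen for parameter parity
        dnn = EDCModel(EDCConfig(input_dim=1000, variant="dnn"), seed=0)
        edc = EDCModel(EDCConfig(input_dim=1000, variant="edc_sl"), seed=0)
        ratio = dnn.n_parameters() / edc.n_parameters()
        assert abs(1 - ratio) < 0.2

    def test_variant_defaults(self):
        assert default_loss_weights("shred_iii") == (1e-5, 1e-3, 1e-4)
        assert default_loss_weights("shred") == (1e-4, 1e-3, 1.0)
        assert default_loss_weights("edc_sl") == (1e-4, 1e-3, 0.0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            EDCConfig(input_dim=50, variant="nope")
        with pytest.raises(ValueError, match="dropout"):
            EDCConfig(input_dim=50, dropout=1.0)
        with pytest.raises(ValueError, match="latent_dim"):
            EDCConfig(input_dim=20)   # V must exceed encoder width
        with pytest.raises(ValueError, match="site"):
            EDCConfig(input_dim=50, variant="shred_iii", n_sites=0)

    def test_save_load_round_trip(self, tmp_path):
        m = EDCModel(_cfg(variant="shred_iii"), seed=3)
        path = tmp_path / "model.json"
        m.save(path)
        m2 = EDCModel.load(path)
        m.eval()
        m2.eval()
        x = np.random.default_rng(1).normal(size=(2, 50))
        cov, site = np.zeros((2, 2)), np.array([0, 1])
        assert np.allclose(m.forward(x, cov, site).probs,
                           m2.forward(x, cov, site).probs)
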