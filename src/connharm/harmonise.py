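"""Location-scale harmonisation of multi-site connectivity features.

The observed feature v of subject j scanned at site i is modelled as

    x_ijv = alpha_v + (M_j beta)_v + gamma_iv + delta_iv * eps_ijv

where alpha is the grand-mean profile, M_j the covariate design row (z-scored
age, one-hot gender), gamma/delta additive and multiplicative site effects and
eps the subject residual with feature-wise s.d. sigma_v.  Harmonisation
removes site effects (and optionally the covariate contribution) by solving
for eps and re-centring on alpha:

    eps = (x - alpha - M beta - gamma_i) / delta_i
    x_res = alpha + eps                (covariates removed)
    x_res = alpha + M beta + eps       (covariates retained)

Restoration inverts the map so a reconstruction of x_res can be carried back
to the original scale.  :func:`combat_fit` provides least-squares estimates of
the parameters for the two-stage variant; the scale indeterminacy between
delta and sigma is resolved by pinning the geometric mean of the per-site
residual scales to one (equivalently sigma is the geometric-mean pooled
residual s.d.), consistent with a log-symmetric prior on delta.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .data import ConnectivityDataset, DesignInfo

DELTA_FLOOR = 1e-6


@dataclass
class HarmonisationParameters:
    """Fitted (or ground-truth) parameters of the site-effect model."""

    alpha: np.ndarray           # (V,)
    beta: np.ndarray            # (C, V) covariate coefficient map
    gamma: np.ndarray           # (I, V) additive site effects
    delta: np.ndarray           # (I, V) multiplicative site effects, > 0
    sigma: np.ndarray           # (V,) residual s.d., > 0
    site_vocab: list[str]
    covariate_names: list[str]

    def __post_init__(self):
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        self.delta = np.atleast_2d(np.asarray(self.delta, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        i, v = self.gamma.shape
        if self.delta.shape != (i, v):
            raise ValueError("gamma and delta must have matching shapes")
        if len(self.site_vocab) != i:
            raise ValueError("site_vocab length must equal gamma/delta rows")
        if np.any(self.delta <= 0):
            raise ValueError("delta must be strictly positive")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")

    @property
    def n_features(self) -> int:
        return self.alpha.size

    def site_row(self, site: str) -> int:
        try:
            return self.site_vocab.index(site)
        except ValueError:
            raise ValueError(f"unknown site {site!r}; known: {self.site_vocab}")

    # -- serialisation (versioned plain-text schema) --------------------------
    def save(self, path) -> None:
        payload = {"schema": "connharm.harmonisation/1",
                   **{k: (v.tolist() if isinstance(v, np.ndarray) else v)
                      for k, v in asdict(self).items()}}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "HarmonisationParameters":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.pop("schema", None) != "connharm.harmonisation/1":
            raise ValueError("unrecognised harmonisation parameter schema")
        return cls(**payload)


def _check(params: HarmonisationParameters, site_idx: np.ndarray) -> None:
    if np.any(site_idx < 0) or np.any(site_idx >= len(params.site_vocab)):
        raise ValueError("site index outside known site vocabulary")
    if np.any(params.delta[site_idx] < DELTA_FLOOR):
        raise ValueError(f"delta below positivity floor {DELTA_FLOOR}")


def remove_site_effects(x: np.ndarray, covariates: np.ndarray, site_idx,
                        params: HarmonisationParameters,
                        add_covariates_back: bool = False) -> np.ndarray:
    """Map observed features to the harmonised scale x_res.

    `x` may be one subject (V,) or a batch (N, V); `covariates` the matching
    design row(s); `site_idx` integer row(s) into the site vocabulary.
    ``add_covariates_back=True`` retains the covariate contribution in the
    output (the behaviour of the original end-to-end variant); the default
    removes both site effects and covariates.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xb = np.atleast_2d(x)
    mb = np.atleast_2d(np.asarray(covariates, dtype=float)) @ params.beta
    idx = np.atleast_1d(np.asarray(site_idx, dtype=np.intp))
    _check(params, idx)
    eps = (xb - params.alpha - mb - params.gamma[idx]) / params.delta[idx]
    x_res = params.alpha + eps + (mb if add_covariates_back else 0.0)
    return x_res[0] if single else x_res


def restore_site_effects(x_res_hat: np.ndarray, covariates: np.ndarray, site_idx,
                         params: HarmonisationParameters,
                         add_covariates_back: bool = False) -> np.ndarray:
    """Inverse of :func:`remove_site_effects` on a reconstruction."""
    x = np.asarray(x_res_hat, dtype=float)
    single = x.ndim == 1
    xb = np.atleast_2d(x)
    mb = np.atleast_2d(np.asarray(covariates, dtype=float)) @ params.beta
    idx = np.atleast_1d(np.asarray(site_idx, dtype=np.intp))
    _check(params, idx)
    eps_hat = xb - params.alpha - (mb if add_covariates_back else 0.0)
    x_hat = params.alpha + mb + params.gamma[idx] + params.delta[idx] * eps_hat
    return x_hat[0] if single else x_hat


def combat_fit(dataset: ConnectivityDataset,
               design: DesignInfo | None = None) -> HarmonisationParameters:
    """Least-squares estimates of the location-scale site-effect model.

    Features are regressed on per-site intercepts plus the covariates (age
    z-scored, gender with one reference level dropped for full rank — the
    standard batch-adjustment design).  alpha is then the subject-weighted
    mean of the site intercepts (the covariate-adjusted grand mean), gamma_i
    the site intercept relative to alpha, and delta_i the within-site
    residual s.d. divided by sigma, the geometric mean of the per-site
    residual s.d.s.  The geometric-mean pinning makes (gamma, delta)
    identifiable: only gamma relative to its (weighted) site mean and delta
    relative to a common scale are estimable from data.
    """
    if design is None:
        design = DesignInfo.fit(dataset)
    sites = design.site_vocab
    if len(sites) < 2:
        raise ValueError("combat_fit requires at least 2 sites")
    site_idx = design.site_index(dataset)
    n_per_site = np.array([np.sum(site_idx == i) for i in range(len(sites))])
    for i, s in enumerate(sites):
        if n_per_site[i] < 3:
            raise ValueError(f"site {s!r} has fewer than 3 subjects")
    x = dataset.features
    var = x.var(axis=0)
    bad = np.flatnonzero(var == 0)
    if bad.size:
        raise ValueError(f"zero-variance feature at index {bad[0]}")

    n_sites, v = len(sites), x.shape[1]
    S = design.site_onehot(dataset)
    M = design.covariate_matrix(dataset)       # [age_z, gender one-hot...]
    M_red = M[:, [0] + list(range(2, M.shape[1]))]  # drop first gender level
    D = np.column_stack([S, M_red])
    coef, *_ = np.linalg.lstsq(D, x, rcond=None)
    resid = x - D @ coef

    intercepts = coef[:n_sites]                # per-site covariate-adjusted means
    weights = n_per_site / n_per_site.sum()
    alpha = weights @ intercepts
    gamma = intercepts - alpha
    # re-express beta on the full one-hot covariate layout (reference level 0)
    beta = np.zeros((design.n_covariates, v))
    beta[0] = coef[n_sites]
    beta[2:] = coef[n_sites + 1:]

    site_sd = np.zeros((n_sites, v))
    for i in range(n_sites):
        site_sd[i] = resid[site_idx == i].std(axis=0, ddof=1)
    if np.any(site_sd <= 0):
        j = int(np.argwhere(site_sd <= 0)[0, 1])
        raise ValueError(f"zero within-site variance at feature index {j}")
    sigma = np.exp(np.log(site_sd).mean(axis=0))   # geometric-mean pooling
    delta = site_sd / sigma
    return HarmonisationParameters(alpha=alpha, beta=beta, gamma=gamma,
                                   delta=delta, sigma=sigma,
                                   site_vocab=list(sites),
                                   covariate_names=["age_z"] + [f"gender_{g}" for g in design.gender_vocab])


def identity_parameters(n_features: int, site_vocab: list[str],
                        covariate_names: list[str] | None = None,
                        n_covariates: int | None = None) -> HarmonisationParameters:
    """Parameters that make remove/restore the identity map (testing aid)."""
    if covariate_names is None:
        covariate_names = [f"c{i}" for i in range(n_covariates or 0)]
    c = len(covariate_names)
    i = len(site_vocab)
    return HarmonisationParameters(
        alpha=np.zeros(n_features), beta=np.zeros((c, n_features)),
        gamma=np.zeros((i, n_features)), delta=np.ones((i, n_features)),
        sigma=np.ones(n_features), site_vocab=list(site_vocab),
        covariate_names=covariate_names)
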