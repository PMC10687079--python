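"""Synthetic multi-site connectivity data with known ground truth.

Subjects are drawn from the same location-scale generative model the
harmonisation stage assumes,

    x_ijv = alpha_v + (M_j beta)_v + gamma_iv + delta_iv * eps_ijv,
    eps_ijv ~ N(0, sigma_v^2),

with a sparse diagnosis effect added to the features in a designated support
set for SZ subjects (negative by default: patients show lower connectivity).
Site location effects are drawn once per site and feature from N(0, site_gamma_sd²)
and site scale effects from LogNormal(0, site_log_delta_sd) — the
exchangeability assumptions of the canonical location-scale harmonisation
model — so the least-squares fitter's conventions (site-mean-centred gamma,
geometric-mean-one delta) match the generator in expectation.

A second generator draws ROI time series from a block-structured covariance,
as a fixture for the FC-construction stage.  The module also carries the
study-shaped cohort table (four sites, NC/SZ, gender and age margins) used to
build manifests with the real study's shape without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import ConnectivityDataset, NC, SZ, UNLABELLED
from .fc import RoiTimeSeries
from .harmonise import HarmonisationParameters

# Demographic margins of the four-site schizophrenia cohort: per site,
# (n_NC, n_SZ), (n_F, n_M), (age_min, age_max).  Totals: 417 subjects,
# 249 NC / 168 SZ.
STUDY_COHORT = {
    "COBRE": {"nc_sz": (75, 60), "f_m": (34, 101), "age_range": (18, 66)},
    "IMH": {"nc_sz": (18, 20), "f_m": (18, 20), "age_range": (23, 58)},
    "NMorphCH": {"nc_sz": (35, 38), "f_m": (29, 44), "age_range": (19, 46)},
    "UCLA": {"nc_sz": (121, 50), "f_m": (68, 103), "age_range": (21, 50)},
}


@dataclass
class SyntheticSpec:
    """Ground-truth parameters of the multi-site simulator.

    Defaults define the reduced-scale study conditions used throughout the
    test-bed: two sites, 200 subjects per site and class, 500 features, a
    −2·sigma diagnosis shift on a 10-feature support.
    """

    n_per_site_per_class: int | tuple = 200
    n_sites: int = 2
    n_features: int = 500
    alpha_loc: float = 0.2            # grand-mean level of (Fisher-z-like) features
    alpha_scale: float = 0.25
    beta_age_sd: float = 0.05         # per-feature coefficient of z-scored age
    beta_gender_sd: float = 0.05      # per-feature male-offset coefficient
    site_gamma_sd: float = 1.0        # s.d. of additive site effects
    site_log_delta_sd: float = 0.25   # s.d. of log multiplicative site effects
    sigma: float = 0.2                # residual (subject) s.d., all features
    class_effect_size: float = -2.0   # in units of sigma, applied to SZ
    class_effect_n_features: int = 10
    site_specific_effect_size: float = 0.0   # extra SZ shift confined to one site
    site_specific_n_features: int = 0
    site_specific_site: int = 0       # index of the site carrying that effect
    site_specific_delta_boost: float = 1.0   # scale inflation on those features
    age_range: tuple = (18, 65)
    labelled_site: str | None = None  # None: all subjects labelled
    gamma: np.ndarray | None = None   # explicit (I,) or (I, V) site locations
    delta: np.ndarray | None = None   # explicit (I,) or (I, V) site scales
    seed: int = 0

    def site_sizes(self) -> list[int]:
        if np.isscalar(self.n_per_site_per_class):
            return [int(self.n_per_site_per_class)] * self.n_sites
        sizes = list(self.n_per_site_per_class)
        if len(sizes) != self.n_sites:
            raise ValueError("n_per_site_per_class tuple must have n_sites entries")
        return [int(s) for s in sizes]


@dataclass
class SyntheticDataset:
    """Generated dataset plus everything needed to score recovery."""

    dataset: ConnectivityDataset
    spec: SyntheticSpec
    params: HarmonisationParameters      # realised generative parameters
    class_effect: np.ndarray             # (V,) diagnosis shift added to SZ
    class_support: np.ndarray            # indices of nonzero class effect
    site_specific_support: np.ndarray    # indices of the site-confined effect
    epsilon: np.ndarray                  # (N, V) residual draws


def _expand_site_param(values, n_sites: int, n_features: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = np.repeat(arr[:, None], n_features, axis=1)
    if arr.shape != (n_sites, n_features):
        raise ValueError("site parameter must be (I,) or (I, V)")
    return arr


def generate_multisite_dataset(spec: SyntheticSpec,
                               rng: np.random.Generator | None = None) -> SyntheticDataset:
    """Draw a multi-site dataset from the location-scale model.

    Deterministic given ``spec.seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    v, n_sites = spec.n_features, spec.n_sites
    sizes = spec.site_sizes()

    alpha = rng.normal(spec.alpha_loc, spec.alpha_scale, size=v)
    beta = np.vstack([rng.normal(0.0, spec.beta_age_sd, size=v),
                      rng.normal(0.0, spec.beta_gender_sd, size=v)])
    gamma = (_expand_site_param(spec.gamma, n_sites, v) if spec.gamma is not None
             else rng.normal(0.0, spec.site_gamma_sd, size=(n_sites, v)))
    delta = (_expand_site_param(spec.delta, n_sites, v) if spec.delta is not None
             else np.exp(rng.normal(0.0, spec.site_log_delta_sd, size=(n_sites, v))))
    if np.any(delta <= 0):
        raise ValueError("site scale effects must be strictly positive")
    sigma = np.full(v, float(spec.sigma))

    all_idx = rng.permutation(v)
    k = spec.class_effect_n_features
    support = np.sort(all_idx[:k])
    class_effect = np.zeros(v)
    class_effect[support] = spec.class_effect_size * spec.sigma

    ss_support = np.sort(all_idx[k:k + spec.site_specific_n_features])
    if ss_support.size:
        delta = delta.copy()
        delta[spec.site_specific_site, ss_support] *= spec.site_specific_delta_boost

    rows_x, subj, site_col, diag, ages, genders, eps_rows = [], [], [], [], [], [], []
    site_names = [f"site{i + 1}" for i in range(n_sites)]
    counter = 0
    for i, name in enumerate(site_names):
        n_i = 2 * sizes[i]
        age = rng.uniform(*spec.age_range, size=n_i)
        male = rng.random(n_i) < 0.5
        y = np.repeat([NC, SZ], sizes[i])
        age_z = (age - np.mean(spec.age_range)) / (np.ptp(spec.age_range) / np.sqrt(12))
        M = np.column_stack([age_z, male.astype(float)])
        eps = rng.normal(0.0, 1.0, size=(n_i, v)) * sigma
        x = alpha + M @ beta + gamma[i] + delta[i] * eps
        x = x + np.outer(y == SZ, class_effect)
        if ss_support.size and i == spec.site_specific_site:
            shift = np.zeros(v)
            shift[ss_support] = spec.site_specific_effect_size * spec.sigma
            x = x + np.outer(y == SZ, shift)
        rows_x.append(x)
        eps_rows.append(eps)
        subj += [f"{name}_s{counter + j:04d}" for j in range(n_i)]
        counter += n_i
        site_col += [name] * n_i
        diag.append(y)
        ages.append(age)
        genders += ["M" if m else "F" for m in male]

    diagnosis = np.concatenate(diag)
    site_arr = np.array(site_col)
    if spec.labelled_site is not None:
        if spec.labelled_site not in site_names:
            raise ValueError(f"labelled_site {spec.labelled_site!r} not generated")
        diagnosis = np.where(site_arr == spec.labelled_site, diagnosis, UNLABELLED)

    dataset = ConnectivityDataset(
        features=np.vstack(rows_x), subject_id=np.array(subj), site=site_arr,
        diagnosis=diagnosis, age=np.concatenate(ages), gender=np.array(genders))
    params = HarmonisationParameters(
        alpha=alpha, beta=beta, gamma=gamma, delta=delta, sigma=sigma,
        site_vocab=site_names, covariate_names=["age_z", "gender_M"])
    return SyntheticDataset(dataset=dataset, spec=spec, params=params,
                            class_effect=class_effect, class_support=support,
                            site_specific_support=ss_support,
                            epsilon=np.vstack(eps_rows))


def site_specific_scenario(base: SyntheticSpec | None = None) -> SyntheticSpec:
    """Study condition for the site-confined salient-feature comparison.

    The first site is three times larger than the second, carries an extra SZ
    shift on 10 dedicated features, and those features ride on a threefold
    site-scale inflation — a salient feature that exists only in the dominant
    site's data and is amplified by that site's variance.
    """
    base = base or SyntheticSpec()
    return replace(base, n_per_site_per_class=(300, 100),
                   site_specific_effect_size=-3.0, site_specific_n_features=10,
                   site_specific_site=0, site_specific_delta_boost=3.0)


def generate_roi_timeseries(n_rois: int, n_timepoints: int, n_subjects: int = 1,
                            block_size: int | None = None, within_r: float = 0.5,
                            rng: np.random.Generator | None = None,
                            seed: int = 0) -> list[RoiTimeSeries]:
    """Gaussian ROI time series with block (community) covariance structure.

    ROIs are grouped into consecutive blocks of `block_size` (one block if
    None); within-block pairs have correlation `within_r`, across-block pairs
    zero.  Empirical FC converges to this target as the series lengthens.
    """
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    if rng is None:
        rng = np.random.default_rng(seed)
    cov = np.eye(n_rois)
    bs = block_size or n_rois
    for start in range(0, n_rois, bs):
        sl = slice(start, min(start + bs, n_rois))
        block = np.full((sl.stop - sl.start,) * 2, within_r)
        np.fill_diagonal(block, 1.0)
        cov[sl, sl] = block
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError("target covariance is not positive definite")
    roi_ids = [f"roi{r + 1}" for r in range(n_rois)]
    out = []
    for s in range(n_subjects):
        z = rng.standard_normal((n_timepoints, n_rois))
        out.append(RoiTimeSeries(subject_id=f"sub{s + 1:03d}",
                                 values=z @ chol.T, roi_ids=roi_ids))
    return out


def study_manifest(n_features: int = 0, seed: int = 0) -> ConnectivityDataset:
    """Manifest with the four-site cohort's exact demographic margins.

    Site, diagnosis and gender counts and per-site age ranges reproduce the
    study's demographic table; ages are drawn uniformly within each site's
    range.  Feature columns (if requested) are standard-normal placeholders —
    this helper exists to exercise manifest-shaped bookkeeping, not the model.
    """
    rng = np.random.default_rng(seed)
    subj, site_col, diag, ages, genders = [], [], [], [], []
    for name, info in STUDY_COHORT.items():
        n_nc, n_sz = info["nc_sz"]
        n_f, n_m = info["f_m"]
        n = n_nc + n_sz
        assert n_f + n_m == n
        subj += [f"{name}_{j:03d}" for j in range(n)]
        site_col += [name] * n
        diag += [NC] * n_nc + [SZ] * n_sz
        ages.append(rng.uniform(*info["age_range"], size=n))
        sex = np.array(["F"] * n_f + ["M"] * n_m)
        genders += rng.permutation(sex).tolist()
    n_total = len(subj)
    feats = rng.standard_normal((n_total, n_features)) if n_features else np.zeros((n_total, 0))
    return ConnectivityDataset(
        features=feats, subject_id=np.array(subj), site=np.array(site_col),
        diagnosis=np.array(diag), age=np.concatenate(ages), gender=np.array(genders))
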