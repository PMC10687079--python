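"""End-to-end optimisation and the repeated stratified cross-validation protocol.

Training minimises the joint loss with Adam (learning rate 0.002, weight
decay 0.001) under global-norm gradient clipping — without clipping the VAE
loss can blow up on small high-dimensional data.  Semi-supervised batching
draws a labelled batch and, when an unlabelled pool exists, an equally sized
unlabelled batch each step; the cross-entropy term sees only the labelled
rows while the VAE terms see both.

Everything fitted from data — covariate scaling, the per-feature residual
scale sigma_v, and the least-squares harmonisation of the two-stage variant —
is computed on the training split only, so cross-validation folds never leak
test information.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .autograd import Adam, Tensor, clip_global_norm, no_grad
from .data import ConnectivityDataset, DesignInfo, UNLABELLED
from .harmonise import HarmonisationParameters, combat_fit, remove_site_effects
from .losses import (cross_entropy_from_logits, joint_loss, kl_loss,
                     likelihood_loss, reconstruction_loss)
from .model import EDCConfig, EDCModel


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 0.002
    weight_decay: float = 0.001
    grad_clip_norm: float = 1.0
    seed: int = 0
    folds: int = 5
    seeds: int = 10
    labelled_site: str | None = None
    ll_on_original_scale: bool = True   # L_L compares x vs restored x̂ (not x_res)

    def __post_init__(self):
        if self.folds < 2 or self.seeds < 1:
            raise ValueError("need folds >= 2 and seeds >= 1")
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch size and learning rate must be positive")


@dataclass
class TrainedModel:
    """A fitted model plus the training-split statistics it depends on."""

    model: EDCModel
    design: DesignInfo
    sigma: np.ndarray                      # fixed per-feature residual s.d.
    variant: str
    combat_params: HarmonisationParameters | None = None   # two-stage variant only
    loss_history: pd.DataFrame | None = None

    def _prepare(self, dataset: ConnectivityDataset):
        x = dataset.features
        cov = self.design.covariate_matrix(dataset)
        site = self.design.site_index(dataset)
        if self.combat_params is not None:
            x = remove_site_effects(x, cov, site, self.combat_params,
                                    add_covariates_back=True)
        return x, cov, site

    def predict(self, dataset: ConnectivityDataset) -> np.ndarray:
        x, cov, site = self._prepare(dataset)
        return self.model.predict(x, cov, site)

    def predict_proba(self, dataset: ConnectivityDataset) -> np.ndarray:
        x, cov, site = self._prepare(dataset)
        self.model.eval()
        with no_grad():
            return self.model.forward(x, cov, site).probs


def _loss_terms_for(variant: str):
    use_ce = True
    use_vae = variant in ("edc_sl", "edc_ssl", "shred", "shred_ii", "shred_iii")
    use_recon = variant in ("dnn_dh", "shred", "shred_iii")
    return use_ce, use_vae, use_recon


def train_model(dataset: ConnectivityDataset, config: TrainConfig,
                variant: str = "shred_iii",
                model_config: EDCConfig | None = None) -> TrainedModel:
    """Fit one model on `dataset` (the training split) deterministically.

    The RNG driving initialisation, batching, dropout and latent sampling is
    derived from ``config.seed`` alone, so identical calls give identical
    weights.
    """
    labelled = np.flatnonzero(dataset.diagnosis != UNLABELLED)
    if labelled.size == 0:
        raise ValueError("training requires labelled subjects")
    classes = np.unique(dataset.diagnosis[labelled])
    if classes.size < 2:
        raise ValueError("labelled subjects cover a single class")

    design = DesignInfo.fit(dataset)
    sigma = dataset.features.std(axis=0)
    if np.any(sigma <= 0):
        raise ValueError(f"zero-variance feature at index {int(np.argmin(sigma))}")

    combat_params = None
    x_all = dataset.features
    if variant == "shred_ii":
        combat_params = combat_fit(dataset, design)
        x_all = remove_site_effects(x_all, design.covariate_matrix(dataset),
                                    design.site_index(dataset), combat_params,
                                    add_covariates_back=True)

    if model_config is None:
        model_config = EDCConfig(input_dim=dataset.n_features, variant=variant,
                                 n_covariates=design.n_covariates,
                                 n_sites=design.n_sites,
                                 learning_rate=config.learning_rate,
                                 weight_decay=config.weight_decay,
                                 grad_clip_norm=config.grad_clip_norm)
    elif model_config.variant != variant:
        raise ValueError("model_config.variant disagrees with requested variant")

    rng = np.random.default_rng(config.seed)
    model = EDCModel(model_config, seed=int(rng.integers(2**31)))
    opt = Adam(model.params, lr=model_config.learning_rate,
               weight_decay=model_config.weight_decay)

    cov_all = design.covariate_matrix(dataset)
    site_all = design.site_index(dataset)
    unlabelled = np.flatnonzero(dataset.diagnosis == UNLABELLED)
    use_ce, use_vae, use_recon = _loss_terms_for(variant)
    use_unlab = use_vae and variant in ("edc_ssl", "shred", "shred_ii", "shred_iii")

    history = []
    model.train()
    for epoch in range(config.epochs):
        order = rng.permutation(labelled)
        unlab_order = rng.permutation(unlabelled) if use_unlab and unlabelled.size else np.array([], int)
        u_ptr = 0
        epoch_rows = []
        for start in range(0, order.size, config.batch_size):
            lab_idx = order[start:start + config.batch_size]
            if use_unlab and unlab_order.size:
                take = lab_idx.size
                if u_ptr + take > unlab_order.size:
                    unlab_order = rng.permutation(unlabelled)
                    u_ptr = 0
                un_idx = unlab_order[u_ptr:u_ptr + take]
                u_ptr += take
            else:
                un_idx = np.array([], int)
            batch = np.concatenate([lab_idx, un_idx])

            res = model.forward(x_all[batch], cov_all[batch], site_all[batch], rng)
            n_lab = lab_idx.size
            lab_logits = res.logits.take_rows(np.arange(n_lab))
            l_c = cross_entropy_from_logits(lab_logits, dataset.diagnosis[lab_idx]) if use_ce else None

            l_l = l_d = l_r = None
            if use_vae:
                if config.ll_on_original_scale:
                    l_l = likelihood_loss(x_all[batch], res.x_hat, sigma)
                else:
                    l_l = likelihood_loss(res.x_res, res.x_res_hat, sigma)
                l_d = kl_loss(res.latent.z_mu, res.latent.z_sigma)
            if use_recon:
                harm = model.harmonisation
                _, g_rows, d_rows = harm.site_terms(cov_all[batch], site_all[batch])
                l_r = reconstruction_loss(x_all[batch], harm.alpha, g_rows, d_rows, sigma)

            total, breakdown = joint_loss(l_c, l_l, l_d, l_r,
                                          gamma1=model_config.gamma1,
                                          gamma2=model_config.gamma2,
                                          gamma3=model_config.gamma3)
            if not np.isfinite(breakdown.total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {breakdown.as_row()}")
            opt.zero_grad()
            total.backward()
            clip_global_norm(model.params, model_config.grad_clip_norm)
            opt.step()
            epoch_rows.append(breakdown.as_row())
        frame = pd.DataFrame(epoch_rows)
        mean = frame.mean(numeric_only=True).to_dict()
        mean["epoch"] = epoch
        history.append(mean)
    model.eval()
    return TrainedModel(model=model, design=design, sigma=sigma, variant=variant,
                        combat_params=combat_params,
                        loss_history=pd.DataFrame(history))


@dataclass
class CVRecord:
    seed_index: int
    fold: int
    trained: TrainedModel
    train_idx: np.ndarray
    test_idx: np.ndarray
    accuracy: float
    sensitivity: float | None
    specificity: float | None


@dataclass
class CVResult:
    records: list[CVRecord]
    folds: int
    seeds: int

    @property
    def n_models(self) -> int:
        return len(self.records)

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "seed": r.seed_index, "fold": r.fold, "accuracy": r.accuracy,
            "sensitivity": r.sensitivity, "specificity": r.specificity,
        } for r in self.records])

    def summary(self) -> dict:
        df = self.metrics_frame()
        return {m: (float(df[m].mean()), float(df[m].std(ddof=1)) if len(df) > 1 else 0.0)
                for m in ("accuracy", "sensitivity", "specificity")}


def _stratified_folds(strata: np.ndarray, idx: np.ndarray, folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Partition `idx` into `folds` test sets, stratified by `strata` values."""
    assignments = [[] for _ in range(folds)]
    for key in np.unique(strata):
        members = idx[strata == key]
        if members.size < folds:
            raise ValueError(f"stratum {key!r} has {members.size} subjects, "
                             f"fewer than {folds} folds")
        members = rng.permutation(members)
        for f, chunk in enumerate(np.array_split(members, folds)):
            assignments[f].append(chunk)
    return [np.sort(np.concatenate(ch)) for ch in assignments]


def cross_validate(dataset: ConnectivityDataset, config: TrainConfig,
                   variant: str = "shred_iii",
                   model_config: EDCConfig | None = None) -> CVResult:
    """Stratified k-fold CV repeated over independent seeds.

    Folds partition the *labelled* subjects (stratified jointly by diagnosis
    and site); unlabelled subjects join every training split but are never
    tested.  With the protocol defaults (5 folds × 10 seeds) this trains 50
    models.
    """
    from .evaluation import classification_metrics

    labelled = np.flatnonzero(dataset.diagnosis != UNLABELLED)
    if config.labelled_site is not None:
        labelled = labelled[dataset.site[labelled] == config.labelled_site]
    if labelled.size == 0:
        raise ValueError("no labelled subjects to cross-validate on")
    strata = np.char.add(dataset.diagnosis[labelled].astype(str),
                         dataset.site[labelled].astype(str))
    unlabelled = np.setdiff1d(np.arange(dataset.n_subjects), labelled)

    records = []
    for s in range(config.seeds):
        fold_rng = np.random.default_rng([config.seed, s])
        test_folds = _stratified_folds(strata, labelled, config.folds, fold_rng)
        for f, test_idx in enumerate(test_folds):
            train_idx = np.concatenate([np.setdiff1d(labelled, test_idx), unlabelled])
            train_idx = np.sort(train_idx)
            train_seed = int((config.seed * 1000003 + s * 131 + f) % (2**31))
            sub_cfg = replace(config, seed=train_seed)
            trained = train_model(dataset.subset(train_idx), sub_cfg, variant,
                                  model_config)
            test = dataset.subset(test_idx)
            pred = trained.predict(test)
            m = classification_metrics(test.diagnosis, pred)
            records.append(CVRecord(seed_index=s, fold=f, trained=trained,
                                    train_idx=train_idx, test_idx=test_idx,
                                    accuracy=m.accuracy,
                                    sensitivity=m.sensitivity,
                                    specificity=m.specificity))
    return CVResult(records=records, folds=config.folds, seeds=config.seeds)
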