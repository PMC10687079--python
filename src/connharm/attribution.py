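"""Integrated-gradients saliency and group-level biomarker aggregation.

Attribution follows the path-integral definition

    R_v(x_j | F) = (x_jv − x̄_v) · ∫₀¹ ∂F(x̄ + a (x_j − x̄)) / ∂x_v da,

approximated by a midpoint Riemann sum over `steps` points, where F is the
pre-softmax logit of the SZ class evaluated deterministically (z = z_mu, no
dropout) and the baseline x̄ is the mean feature vector of the training-split
normal controls.  Completeness (Σ_v R_v = F(x) − F(x̄)) holds in the limit of
many steps and is tested as an axiom.

Group scores average the absolute per-subject attributions over the SZ test
subjects; across models the group scores are averaged and then z-scored
across features.  Heatmaps keep the strict lower triangle of the score
matrix, with only the top fraction of features retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autograd import Tensor
from .data import ConnectivityDataset, NC, SZ
from .fc import feature_legend, lower_triangle_indices, matricize_lower_triangle, n_features
from .training import TrainedModel


def compute_baseline(train_split: ConnectivityDataset) -> np.ndarray:
    """Mean feature vector over the normal controls of the training split."""
    nc_rows = train_split.features[train_split.diagnosis == NC]
    if nc_rows.shape[0] == 0:
        raise ValueError("no normal controls in the training split")
    return nc_rows.mean(axis=0)


def subject_logit_fn(trained: TrainedModel, covariates: np.ndarray,
                     site_index: int, class_index: int = SZ):
    """Differentiable map x ↦ pre-softmax logit of `class_index` for one subject.

    Returns a function of a (B, V) Tensor, where every row shares the
    subject's covariates and site; B lets the integration path be evaluated
    in one batch.  For the two-stage variant the fixed least-squares
    harmonisation is applied inside the function (as constant Tensor
    arithmetic) so gradients still reach the original input scale.
    """
    model = trained.model
    model.eval()
    cov = np.atleast_1d(np.asarray(covariates, dtype=float))
    selector = Tensor(np.eye(model.config.n_classes)[:, [class_index]])  # (n_classes, 1)

    def fn(xt: Tensor) -> Tensor:
        b = xt.data.shape[0]
        if trained.combat_params is not None:
            p = trained.combat_params
            mb = cov @ p.beta
            g, d = p.gamma[site_index], p.delta[site_index]
            xt = (xt - p.alpha - mb - g) / d + (p.alpha + mb)
        cov_b = np.tile(cov, (b, 1))
        site_b = np.full(b, site_index, dtype=np.intp)
        res = model.forward(xt, cov_b, site_b)
        return res.logits @ selector

    return fn


def integrated_gradients(fn, x: np.ndarray, baseline: np.ndarray,
                         steps: int = 100) -> np.ndarray:
    """Midpoint-rule integrated gradients of scalar map `fn` for one input."""
    x = np.asarray(x, dtype=float).ravel()
    baseline = np.asarray(baseline, dtype=float).ravel()
    if x.shape != baseline.shape:
        raise ValueError("input and baseline shapes differ")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    a = (np.arange(1, steps + 1) - 0.5) / steps
    points = baseline + a[:, None] * (x - baseline)
    xt = Tensor(points, requires_grad=True)
    out = fn(xt).sum()
    out.backward()
    avg_grad = xt.grad.mean(axis=0)
    return (x - baseline) * avg_grad


def attribute_subjects(trained: TrainedModel, subjects: ConnectivityDataset,
                       baseline: np.ndarray, steps: int = 100) -> np.ndarray:
    """Per-subject attribution matrix (M, V) for every row of `subjects`."""
    cov = trained.design.covariate_matrix(subjects)
    site = trained.design.site_index(subjects)
    scores = np.empty_like(subjects.features)
    for j in range(subjects.n_subjects):
        fn = subject_logit_fn(trained, cov[j], int(site[j]))
        scores[j] = integrated_gradients(fn, subjects.features[j], baseline, steps)
    return scores


def group_attribution(per_subject: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Mean absolute attribution over the SZ (y = 1) subjects."""
    labels = np.asarray(labels)
    sz = np.flatnonzero(labels == SZ)
    if sz.size == 0:
        raise ValueError("no SZ subjects in the test set")
    return np.abs(np.atleast_2d(per_subject)[sz]).mean(axis=0)


def aggregate_standardise(group_scores: list | np.ndarray,
                          per_model_first: bool = False) -> np.ndarray:
    """Average group scores over models, then z-score across features.

    ``per_model_first=True`` z-scores each model's score vector before
    averaging (and re-standardises the mean).
    """
    arr = np.atleast_2d(np.asarray(group_scores, dtype=float))
    if arr.shape[0] == 0:
        raise ValueError("need scores from at least one model")

    def _z(v):
        sd = v.std()
        if sd == 0:
            raise ValueError("zero variance across features; cannot standardise")
        return (v - v.mean()) / sd

    if per_model_first:
        arr = np.vstack([_z(row) for row in arr])
    return _z(arr.mean(axis=0))


def top_fraction_filter(matrix: np.ndarray, fraction: float = 0.01) -> np.ndarray:
    """Keep the top `fraction` of lower-triangle scores; zero the rest.

    The upper triangle and diagonal are zeroed.  k = floor(fraction · V)
    survivors are kept; ties at the threshold resolve toward the lower
    feature index (stable sort), so the survivor set is deterministic.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    m = np.asarray(matrix, dtype=float)
    r = m.shape[0]
    rows, cols = lower_triangle_indices(r)
    vec = m[rows, cols]
    k = int(np.floor(fraction * vec.size))
    if k == 0:
        raise ValueError(f"fraction {fraction} keeps zero of {vec.size} features")
    order = np.argsort(-vec, kind="stable")
    out_vec = np.zeros_like(vec)
    keep = order[:k]
    out_vec[keep] = vec[keep]
    return matricize_lower_triangle(out_vec, r, symmetric=False)


def saliency_table(aggregate: np.ndarray, roi_ids: list[str],
                   labels: dict | None = None) -> pd.DataFrame:
    """Length-V score table with the ROI-pair legend (and optional labels)."""
    aggregate = np.asarray(aggregate, dtype=float)
    legend = feature_legend(roi_ids)
    if len(legend) != aggregate.size:
        raise ValueError("score vector length does not match the ROI count")
    legend["score"] = aggregate
    if labels is not None:
        legend["label_i"] = [labels.get(r, "") for r in legend["roi_i"]]
        legend["label_j"] = [labels.get(r, "") for r in legend["roi_j"]]
    return legend.sort_values("score", ascending=False).reset_index(drop=True)


@dataclass
class AttributionResult:
    """Bundled attribution outputs for one model (or an aggregate)."""

    per_subject: np.ndarray          # (M, V)
    group: np.ndarray                # (V,) nonnegative
    aggregate: np.ndarray | None     # (V,) standardised across features

    def matrix_form(self, n_rois: int | None = None) -> np.ndarray:
        vec = self.aggregate if self.aggregate is not None else self.group
        return matricize_lower_triangle(vec, n_rois, symmetric=False)
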