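"""Classification metrics, distributional diagnostics and association tests.

* :func:`classification_metrics` — accuracy, sensitivity (true SZ rate) and
  specificity (true NC rate) from the confusion table; ratios with an empty
  class are reported as missing rather than zero.
* :func:`welch_t_test` — two-sample t-test with unequal variances, used for
  between-model comparisons of cross-validated accuracies.
* :func:`hellinger_distance` — bounded [0, 1] divergence between two samples'
  kernel density estimates on a shared grid, quantifying between-site
  distribution shift before and after harmonisation.
* :func:`symptom_association` — Spearman correlations between selected
  connectivity features and symptom-scale scores, corrected with the
  Benjamini–Yekutieli FDR procedure (valid under arbitrary dependence).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class MetricSet:
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    tp: int
    fp: int
    tn: int
    fn: int


def classification_metrics(y_true, y_pred) -> MetricSet:
    """Confusion-table metrics with SZ coded 1 and NC coded 0."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} contains labels outside {{0, 1}}")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    return MetricSet(accuracy=(tp + tn) / y_true.size, sensitivity=sens,
                     specificity=spec, tp=tp, fp=fp, tn=tn, fn=fn)


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(a.size, b.size) < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("both samples are degenerate with different means")
    res = stats.ttest_ind(a, b, equal_var=False)
    se2 = va / a.size + vb / b.size
    df = se2**2 / ((va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def hellinger_distance(a, b, grid_size: int = 512) -> float:
    """Hellinger distance between the Gaussian-KDE densities of two samples.

    A single bandwidth — Silverman's rule on the pooled sample — is shared by
    both densities, and the grid spans the pooled range padded by three
    bandwidths, so the distance reflects the samples and not estimator
    choices.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if min(a.size, b.size) < 10:
        raise ValueError("each sample needs at least 10 points")
    pooled = np.concatenate([a, b])
    sd = pooled.std(ddof=1)
    iqr = np.subtract(*np.percentile(pooled, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread == 0:
        return 0.0 if np.allclose(a.mean(), b.mean()) else 1.0
    h = 0.9 * spread * pooled.size ** (-1 / 5)
    grid = np.linspace(pooled.min() - 3 * h, pooled.max() + 3 * h, grid_size)
    dx = grid[1] - grid[0]

    def kde(sample):
        z = (grid[:, None] - sample[None, :]) / h
        return np.exp(-0.5 * z**2).sum(axis=1) / (sample.size * h * np.sqrt(2 * np.pi))

    p, q = kde(a), kde(b)
    h2 = 0.5 * np.sum((np.sqrt(p) - np.sqrt(q)) ** 2) * dx
    return float(np.clip(np.sqrt(h2), 0.0, 1.0))


def _spearman_exact_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided permutation p for the Spearman rho of tiny samples."""
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    ra_c = ra - ra.mean()
    rb_c = rb - rb.mean()
    denom = np.sqrt((ra_c**2).sum() * (rb_c**2).sum())
    rho_obs = float(ra_c @ rb_c / denom)
    n = a.size
    count = total = 0
    chunk = []
    for perm in itertools.permutations(rb_c):
        chunk.append(perm)
        if len(chunk) == 100_000:
            rhos = np.asarray(chunk) @ ra_c / denom
            count += int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12))
            total += len(chunk)
            chunk = []
    if chunk:
        rhos = np.asarray(chunk) @ ra_c / denom
        count += int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12))
        total += len(chunk)
    return rho_obs, count / total


def spearman_correlation(a, b) -> tuple[float, float]:
    """Spearman rho and two-sided p (exact permutation for n <= 10)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 5:
        raise ValueError("need at least 5 complete pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant column: correlation undefined")
    if a.size <= 10:
        return _spearman_exact_p(a, b)
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def benjamini_yekutieli(pvalues, q: float = 0.05) -> np.ndarray:
    """BY step-up rejections at FDR level q (arbitrary dependence)."""
    pvalues = np.asarray(pvalues, dtype=float)
    reject, *_ = multipletests(pvalues, alpha=q, method="fdr_by")
    return reject


def symptom_association(fc_values, scores, q: float = 0.05,
                        feature_names=None, scale_names=None) -> pd.DataFrame:
    """Spearman association of selected FC features with symptom scales.

    `fc_values` is subjects × features, `scores` subjects × scales (NaNs
    allowed; pairs are complete-case).  Constant columns are skipped with a
    notice in the table; BY correction is applied across all computed tests.
    """
    fc = np.atleast_2d(np.asarray(fc_values, dtype=float))
    sc = np.atleast_2d(np.asarray(scores, dtype=float))
    if sc.shape[0] != fc.shape[0]:
        raise ValueError("fc_values and scores must have matching subject rows")
    feature_names = list(feature_names or [f"feature_{k}" for k in range(fc.shape[1])])
    scale_names = list(scale_names or [f"scale_{k}" for k in range(sc.shape[1])])

    rows = []
    for k, fname in enumerate(feature_names):
        for m, sname in enumerate(scale_names):
            ok = np.isfinite(fc[:, k]) & np.isfinite(sc[:, m])
            row = {"feature": fname, "scale": sname, "n": int(ok.sum()),
                   "rho": np.nan, "p": np.nan, "note": ""}
            try:
                rho, p = spearman_correlation(fc[ok, k], sc[ok, m])
                row.update(rho=rho, p=p)
            except ValueError as exc:
                row["note"] = str(exc)
            rows.append(row)
    table = pd.DataFrame(rows)
    tested = table["p"].notna()
    table["significant"] = False
    if tested.any():
        table.loc[tested, "significant"] = benjamini_yekutieli(
            table.loc[tested, "p"].to_numpy(), q=q)
    return table
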