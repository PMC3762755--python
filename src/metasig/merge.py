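"""Empirical-Bayes location/scale batch adjustment and cross-study ratios.

Cross-study merging follows the parametric empirical-Bayes adjustment of
microarray batch effects: per gene g and batch i the model is

    X_ijg = alpha_g + gamma_ig + delta_ig * eps_ijg,   eps ~ N(0, sigma_g^2)

Batch locations gamma_ig are shrunk toward a normal prior N(gamma_bar_i,
tau_i^2) and batch scales delta_ig^2 toward an inverse-gamma prior, both
with hyperparameters moment-matched across genes within the batch.  The
conditional posterior point estimates (gamma*, delta*) are iterated to
convergence and removed, leaving all batches on a common location/scale.

The ratio table then reports, per gene and study, the mean log2(HM/CT)
difference — the cross-study concordance view of the signature.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .matrix import ExpressionMatrix
from .signature import Signature

__all__ = ["EmpiricalBayesMerger", "eb_adjust", "ratio_table"]


def _moment_match_invgamma(delta_hat: np.ndarray) -> tuple[float, float]:
    """Inverse-gamma hyperparameters (a, b) matching mean/variance of delta^2."""
    m = float(np.mean(delta_hat))
    s2 = float(np.var(delta_hat))
    if s2 == 0:
        return np.inf, np.inf
    a = (2 * s2 + m ** 2) / s2
    b = (m * s2 + m ** 3) / s2
    return a, b


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(ssq, n, a, b):
    return (0.5 * ssq + b) / (n / 2.0 + a - 1.0)


def _it_sol(Z: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
            g_bar: float, t2: float, a: float, b: float,
            conv: float = 1e-6, max_iter: int = 200
            ) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the coupled posterior estimates for one batch (all genes)."""
    n = np.sum(~np.isnan(Z), axis=1).astype(float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        ssq = np.nansum((Z - g_new[:, None]) ** 2, axis=1)
        d_new = _postvar(ssq, n, a, b)
        change = max(np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                     np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)))
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


class EmpiricalBayesMerger(BaseEstimator, TransformerMixin):
    """Parametric empirical-Bayes batch-effect remover (transformer).

    ``fit_transform(X, y)`` takes a samples x genes frame ``X`` and batch
    labels ``y`` and returns the adjusted frame.  No covariates are
    protected; priors are parametric (normal / inverse-gamma) only.

    Attributes (after ``fit``)
    --------------------------
    grand_mean_ : per-gene pooled location alpha_g
    pooled_var_ : per-gene pooled variance sigma_g^2
    gamma_star_, delta_star_ : per batch x gene shrunken location and scale
    """

    def __init__(self, conv: float = 1e-6, max_iter: int = 200):
        self.conv = conv
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, y=None) -> "EmpiricalBayesMerger":
        self.fit_transform(X, y)
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        X = pd.DataFrame(X)
        if y is None:
            raise ValueError("batch labels are required")
        batches = pd.Series(list(y), index=X.index)
        levels = list(pd.unique(batches))
        if len(levels) < 2:
            raise ValueError("need at least 2 batches")
        counts = batches.value_counts()
        if (counts < 2).any():
            small = list(counts.index[counts < 2])
            raise ValueError(f"singleton batch(es): {small}")

        V = X.to_numpy(dtype=float).T        # genes x samples
        n_genes, n_samples = V.shape
        groups = {b: np.flatnonzero((batches == b).to_numpy()) for b in levels}

        # per-batch gene means; pooled location is the size-weighted average
        batch_mean = np.column_stack([
            np.nanmean(V[:, idx], axis=1) for b, idx in groups.items()])
        sizes = np.array([len(groups[b]) for b in levels], dtype=float)
        alpha = batch_mean @ (sizes / n_samples)
        mean_per_sample = np.empty_like(V)
        for k, b in enumerate(levels):
            mean_per_sample[:, groups[b]] = batch_mean[:, [k]]
        sigma2 = np.nanmean((V - mean_per_sample) ** 2, axis=1)
        sigma2 = np.maximum(sigma2, 1e-12)
        sigma = np.sqrt(sigma2)

        Z = (V - alpha[:, None]) / sigma[:, None]

        gamma_star = np.zeros((len(levels), n_genes))
        delta_star = np.ones((len(levels), n_genes))
        for k, b in enumerate(levels):
            idx = groups[b]
            Zb = Z[:, idx]
            g_hat = np.nanmean(Zb, axis=1)
            d_hat = np.nanvar(Zb, axis=1, ddof=1)
            d_hat = np.maximum(d_hat, 1e-12)
            g_bar, t2 = float(np.mean(g_hat)), float(np.var(g_hat))
            a, bb = _moment_match_invgamma(d_hat)
            if not np.isfinite(a):
                gamma_star[k], delta_star[k] = g_hat, d_hat
            else:
                gamma_star[k], delta_star[k] = _it_sol(
                    Zb, g_hat, d_hat, g_bar, max(t2, 1e-12), a, bb,
                    conv=self.conv, max_iter=self.max_iter)

        adj = Z.copy()
        for k, b in enumerate(levels):
            idx = groups[b]
            adj[:, idx] = (Z[:, idx] - gamma_star[k][:, None]) \
                / np.sqrt(delta_star[k])[:, None]
        adj = adj * sigma[:, None] + alpha[:, None]

        self.batches_ = levels
        self.grand_mean_ = pd.Series(alpha, index=X.columns)
        self.pooled_var_ = pd.Series(sigma2, index=X.columns)
        self.gamma_star_ = pd.DataFrame(gamma_star, index=levels, columns=X.columns)
        self.delta_star_ = pd.DataFrame(delta_star, index=levels, columns=X.columns)
        self.adjusted_ = pd.DataFrame(adj.T, index=X.index, columns=X.columns)
        return self.adjusted_

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return the adjusted training data (the merge is transductive)."""
        if not hasattr(self, "adjusted_"):
            raise ValueError("fit the merger first")
        return self.adjusted_.loc[pd.DataFrame(X).index]


def eb_adjust(matrices: list[ExpressionMatrix],
              conv: float = 1e-6, max_iter: int = 200) -> ExpressionMatrix:
    """Merge studies on their common features and remove batch effects.

    Each input matrix is one study (its ``study_id`` annotations name the
    batch).  The merged matrix lives on the intersection of the feature
    sets; studies with fewer than two samples are rejected.
    """
    if len(matrices) < 2:
        # a single matrix may still contain >=2 embedded study_ids
        if len(matrices) == 1 and matrices[0].annotations["study_id"].nunique() >= 2:
            pass
        else:
            raise ValueError("need at least 2 studies")
    common = set(matrices[0].probe_ids)
    for m in matrices[1:]:
        common &= set(m.probe_ids)
    if not common:
        raise ValueError("studies share no features")
    features = [p for p in matrices[0].probe_ids if p in common]

    frames, anns, batch = [], [], []
    for m in matrices:
        sub = m.subset_probes(features)
        frames.append(sub.values)
        anns.append(sub.annotations.reset_index(drop=True))
        batch.extend(sub.annotations["study_id"])
    values = pd.concat(frames, axis=1)
    ann = pd.concat(anns, ignore_index=True)
    if ann["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids across studies")

    merger = EmpiricalBayesMerger(conv=conv, max_iter=max_iter)
    adjusted = merger.fit_transform(values.T, batch)
    return ExpressionMatrix(adjusted.T, ann, log_scale=matrices[0].log_scale)


def ratio_table(merged: ExpressionMatrix, sig: Signature | None = None,
                reference_study: str | None = None) -> pd.DataFrame:
    """Per gene x study mean log2(HM/CT), ordered by the reference study.

    Studies lacking either tissue are omitted with a warning.  Genes are
    ordered from the most down- to the most up-regulated in HM according
    to the reference study (default: first listed).
    """
    ann = merged.annotations
    features = merged.probe_ids if sig is None else \
        [f for f in sig.feature_ids if f in merged.values.index]
    vals = merged.values.loc[features]

    cols = {}
    for study in pd.unique(ann["study_id"]):
        sub = ann[ann["study_id"] == study]
        hm = list(sub.index[sub["tissue_code"] == "HM"])
        ct = list(sub.index[sub["tissue_code"] == "CT"])
        if not hm or not ct:
            warnings.warn(f"study {study!r} lacks HM or CT samples; omitted")
            continue
        cols[study] = vals[hm].mean(axis=1) - vals[ct].mean(axis=1)
    if not cols:
        raise ValueError("no study has both HM and CT samples")
    table = pd.DataFrame(cols)
    if reference_study is None:
        reference_study = table.columns[0]
    return table.sort_values(reference_study)
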