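"""Paired SAM: moderated paired t-like statistic with sign-flip permutation FDR.

Two-class paired SAM is realized as the one-sample SAM on per-patient
differences: for probe i with paired differences x_i1..x_in,

    d_i = mean(x_i) / (se(x_i) + s0)

with se the standard error of the differences and s0 a small "fudge factor"
stabilizing low-variance probes.  The null distribution comes from random
sign flips of the pair columns (a patient's CT/HM labels are exchangeable
under the null); when 2^n_pairs <= n_permutations the full set of 2^n flips
is enumerated and the result is exact and seed-independent.

The q-value of a probe follows the SAM convention: the median, over
permutations, of the number of null |d*| values exceeding the probe's |d|,
divided by the observed count at that cut, monotonized so that threshold
sets are nested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import ExpressionMatrix, PairedDesign, paired_differences

__all__ = [
    "PairedSAM", "SamResult", "sam_statistic", "estimate_s0",
    "permutation_fdr", "select_probes", "paired_differences",
]

_PERM_BLOCK = 1024  # permutations processed per chunk to bound memory


@dataclass
class SamResult:
    """Per-probe paired-SAM output."""

    table: pd.DataFrame    # columns: mean_diff, se, d, q, n_complete
    s0: float
    n_permutations: int
    exhaustive: bool

    @property
    def d(self) -> pd.Series:
        return self.table["d"]

    @property
    def q(self) -> pd.Series:
        return self.table["q"]

    def n_called(self, fdr_threshold: float) -> int:
        return int((self.table["q"] < fdr_threshold).sum())


def _mean_se(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise mean, standard error and complete-pair count, NaN-aware."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n = np.sum(~np.isnan(diffs), axis=1)
        mean = np.nanmean(diffs, axis=1)
        sd = np.nanstd(diffs, axis=1, ddof=1)
    se = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return mean, se, n


def sam_statistic(diffs: pd.DataFrame | np.ndarray, s0: float) -> pd.Series:
    """d_i = mean_i / (se_i + s0) on a probes x pairs difference matrix.

    Probes with fewer than two complete pairs get NaN and are excluded
    downstream.  With s0 = 0 a zero-variance probe yields +/-inf.
    """
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    arr = np.asarray(diffs, dtype=float)
    mean, se, n = _mean_se(arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = mean / (se + s0)
    d = np.where(n >= 2, d, np.nan)
    index = diffs.index if isinstance(diffs, pd.DataFrame) else pd.RangeIndex(len(d))
    return pd.Series(d, index=index, name="d")


def estimate_s0(diffs: pd.DataFrame | np.ndarray, n_bins: int = 100) -> float:
    """Choose the fudge factor by the samr heuristic.

    Candidates are the percentiles (0, 5, ..., 100) of the se distribution.
    For each candidate, probes are split into equal-count se bins and the
    median absolute deviation of d within each bin is computed; the candidate
    minimizing the coefficient of variation of these MADs wins.  This keeps
    the spread of d flat across the se range, so no variance stratum
    dominates the significant list.
    """
    arr = np.asarray(diffs, dtype=float)
    mean, se, n = _mean_se(arr)
    ok = (n >= 2) & np.isfinite(se)
    mean, se = mean[ok], se[ok]
    if se.size == 0 or np.all(se == 0):
        warnings.warn("all standard errors are zero; s0 set to 0")
        return 0.0
    candidates = np.percentile(se, np.arange(0, 101, 5))
    # keep >= ~25 probes per bin so the within-bin MAD is stable
    n_bins = min(n_bins, max(2, se.size // 25))
    # equal-count bins by se rank
    order = np.argsort(se, kind="stable")
    bin_of = np.empty(se.size, dtype=int)
    bin_of[order] = np.minimum((np.arange(se.size) * n_bins) // se.size, n_bins - 1)

    best_s0, best_cv = float(candidates[0]), np.inf
    for s0 in candidates:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = mean / (se + s0)
        mads = np.array([
            np.median(np.abs(d[bin_of == b] - np.median(d[bin_of == b])))
            for b in range(n_bins) if np.any(bin_of == b)
        ])
        mads = mads[np.isfinite(mads)]
        if mads.size == 0 or np.mean(mads) == 0:
            continue
        cv = np.std(mads) / np.mean(mads)
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _sign_flips(n_pairs: int, n_permutations: int, seed: int | None
                ) -> tuple[np.ndarray, bool]:
    """Sign-flip matrix (n_flips x n_pairs) of +/-1; exhaustive when feasible."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if 2 ** n_pairs <= n_permutations:
        bits = np.arange(2 ** n_pairs, dtype=np.int64)
        eps = ((bits[:, None] >> np.arange(n_pairs)) & 1) * 2 - 1
        return eps.astype(np.float64), True
    rng = np.random.default_rng(seed)
    eps = rng.choice([-1.0, 1.0], size=(n_permutations, n_pairs))
    return eps, False


def permutation_fdr(diffs: pd.DataFrame,
                    s0: float | str = "auto",
                    n_permutations: int = 10_000,
                    seed: int | None = 0) -> SamResult:
    """Full paired-SAM analysis of a probes x pairs difference matrix.

    Probes with missing pairs are handled by restricting each probe to its
    complete pairs for the observed statistic; the permutation null is built
    on probes with no missing values (flips of incomplete probes use the
    same flip vector restricted to their complete entries).
    """
    arr = diffs.to_numpy(dtype=float)
    n_probes, n_pairs = arr.shape
    if n_pairs < 2:
        raise ValueError("paired SAM needs at least 2 pairs")

    if s0 == "auto":
        s0 = estimate_s0(diffs)
    s0 = float(s0)

    mean, se, n_complete = _mean_se(arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_obs = np.where(n_complete >= 2, mean / (se + s0), np.nan)

    defined = np.isfinite(d_obs)
    abs_obs = np.abs(d_obs[defined])
    order = np.argsort(abs_obs)          # ascending
    sorted_abs = abs_obs[order]
    m_def = sorted_abs.size
    # observed count at each probe's own cut |d| (ties counted inclusively)
    obs_count = m_def - np.searchsorted(sorted_abs, abs_obs, side="left")

    eps, exhaustive = _sign_flips(n_pairs, n_permutations, seed)
    n_flips = eps.shape[0]

    # NaN-free fast path: flipping signs leaves the per-probe mean square
    # unchanged, so only the flipped mean is needed per permutation.
    work = np.nan_to_num(arr[defined], nan=0.0)
    n_i = n_complete[defined].astype(float)
    sumsq = np.sum(work ** 2, axis=1)

    null_counts = np.empty((m_def, n_flips), dtype=np.int32)
    for start in range(0, n_flips, _PERM_BLOCK):
        block = eps[start:start + _PERM_BLOCK]           # b x n_pairs
        mean_b = (block @ work.T) / n_i[None, :]          # b x probes
        var_b = (sumsq[None, :] - n_i[None, :] * mean_b ** 2) / (n_i[None, :] - 1)
        var_b = np.maximum(var_b, 0.0)
        se_b = np.sqrt(var_b) / np.sqrt(n_i)[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            d_b = np.abs(mean_b / (se_b + s0))
        d_b = np.nan_to_num(d_b, nan=0.0, posinf=np.inf)
        d_b.sort(axis=1)
        for j in range(d_b.shape[0]):
            null_counts[:, start + j] = m_def - np.searchsorted(
                d_b[j], abs_obs, side="left")

    med_null = np.median(null_counts, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        q_raw = np.minimum(med_null / obs_count, 1.0)

    # monotonize: each probe's q is the best (smallest) raw estimate among
    # all cuts at or below its own |d|, so threshold sets are nested
    desc = np.argsort(-abs_obs, kind="stable")
    q_sorted = np.minimum.accumulate(q_raw[desc][::-1])[::-1]
    q_def = np.empty(m_def)
    q_def[desc] = q_sorted

    q = np.full(n_probes, np.nan)
    q[defined] = q_def

    table = pd.DataFrame({
        "mean_diff": mean, "se": se, "d": d_obs, "q": q,
        "n_complete": n_complete,
    }, index=diffs.index)
    return SamResult(table=table, s0=s0, n_permutations=n_flips,
                     exhaustive=exhaustive)


def select_probes(res: SamResult, fdr_threshold: float) -> list[str]:
    """Probes with q < threshold, ordered by |d| descending."""
    t = res.table.dropna(subset=["d", "q"])
    hits = t[t["q"] < fdr_threshold]
    return list(hits.reindex(hits["d"].abs().sort_values(ascending=False).index).index)


class PairedSAM(BaseEstimator):
    """Paired-SAM probe selector with a scikit-learn-style interface.

    Parameters
    ----------
    fdr_threshold : float, default 0.001
        q-value cut below which a probe is called differential.
    n_permutations : int, default 10000
        Sign-flip permutations; exhaustive enumeration replaces sampling
        whenever 2**n_pairs <= n_permutations.
    s0 : float or "auto"
        Fudge factor; "auto" uses the samr-style CV-minimizing heuristic.
    seed : int
        Seed for the permutation sampler (unused in exhaustive mode).

    Attributes (after ``fit``)
    --------------------------
    result_ : SamResult
    s0_ : float
    selected_probes_ : list of probe ids ordered by |d| descending
    support_ : boolean array over input probes
    """

    def __init__(self, fdr_threshold: float = 0.001,
                 n_permutations: int = 10_000,
                 s0: float | str = "auto", seed: int = 0):
        self.fdr_threshold = fdr_threshold
        self.n_permutations = n_permutations
        self.s0 = s0
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None) -> "PairedSAM":
        """Fit on a probes x pairs difference matrix."""
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must lie in (0, 1)")
        X = pd.DataFrame(X)
        self.result_ = permutation_fdr(X, s0=self.s0,
                                       n_permutations=self.n_permutations,
                                       seed=self.seed)
        self.s0_ = self.result_.s0
        self.selected_probes_ = select_probes(self.result_, self.fdr_threshold)
        sel = set(self.selected_probes_)
        self.support_ = np.array([p in sel for p in X.index])
        return self

    def fit_matrix(self, m: ExpressionMatrix, design: PairedDesign) -> "PairedSAM":
        """Convenience: build paired differences from a matrix and fit."""
        return self.fit(paired_differences(m, design))

    def get_support(self) -> np.ndarray:
        return self.support_
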