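"""Contamination-aware geometric filtering of candidate probes.

A hepatic metastasis (HM) sample is pathologically guaranteed to contain at
least 50% cancer cells, but up to half of its RNA can come from admixed
normal liver (HN).  If a probe has identical expression in the primary
tumor and the pure metastasis (pHM = pCT) but a different level in liver,
mixing at fraction lambda produces a *measured* ratio

    pHMm = (1 - lambda) * pHM + lambda * pHN.

In the log2 plane with x = log2(pCT/pHN) and y = log2(pCT/pHMm), such a
contamination-only probe lies on the curve

    f_lambda(x) = x - log2((1 - lambda) * 2**x + lambda),

which sweeps from the x-axis (lambda = 0) to a curve running from the
diagonal + 1 (x -> -inf) to the horizontal line y = 1 (x -> +inf) at
lambda = 0.5.  Any dot between the x-axis and f_{lambda_max} is explainable
by contamination alone and is discarded, together with dots showing under a
2-fold CT/HM change (|y| < 1) or sitting near the diagonal HM = HN
(|y - x| < 1).  Surviving dots fall in quadrant b (up in HM vs both CT and
HN; y < 0, y < x) or d (down in HM vs both; y > 0, y > x).  Because the
true liver baseline of each probe is unknown, the x coordinate is bracketed
by the minimum and maximum CT/HN ratio across reference tumor/normal-liver
pairs, and a dot only counts if it survives in the same quadrant under both
envelope bounds.  A probe enters the signature when at least ``min_votes``
of its pairs (8 of 13 by default) vote for a single quadrant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import ExpressionMatrix, PairedDesign, paired_differences
from .signature import Signature, SignatureEntry

__all__ = [
    "contamination_boundary", "reference_envelope", "ratio_points",
    "classify_point", "vote", "ContaminationFilter", "apply_filter",
    "KEPT_B", "KEPT_D", "SURVIVED_A", "SURVIVED_C",
    "REMOVED_LOW_FC", "REMOVED_NEAR_DIAGONAL", "REMOVED_CONTAMINATION",
    "UNFILTERABLE",
]

# per-dot verdicts
KEPT_B = "kept_b"
KEPT_D = "kept_d"
SURVIVED_A = "survived_a"   # possible in principle; provably empty at defaults
SURVIVED_C = "survived_c"
REMOVED_LOW_FC = "removed_low_fc"
REMOVED_NEAR_DIAGONAL = "removed_near_diagonal"
REMOVED_CONTAMINATION = "removed_contamination"
UNFILTERABLE = "unfilterable"  # probe absent from the reference matrix

_QUADRANT_OF = {KEPT_B: "b", KEPT_D: "d", SURVIVED_A: "a", SURVIVED_C: "c"}


def contamination_boundary(x, lam: float):
    """y produced by contamination alone: f_lambda(x) = x - log2((1-lam)2^x + lam).

    f_0 is identically zero; f_0.5 runs from the diagonal + 1 at x -> -inf
    to the horizontal y = 1 at x -> +inf.  Vectorized over x.
    """
    if not 0 <= lam < 1:
        raise ValueError("lambda must lie in [0, 1)")
    x = np.asarray(x, dtype=float)
    if lam == 0:
        out = np.zeros_like(x)
    else:
        # log2((1-lam)*2^x + lam) via logaddexp2 for numerical stability
        with np.errstate(invalid="ignore"):
            out = x - np.logaddexp2(np.log2(1 - lam) + x, np.log2(lam))
    return out if out.ndim else float(out)


def reference_envelope(ref_matrix: ExpressionMatrix,
                       ref_design: PairedDesign) -> pd.DataFrame:
    """Per-probe min and max of log2(pCT/pHN) across reference pairs.

    Returns a DataFrame indexed by probe with columns ``x_min`` and
    ``x_max``.  Probes with no complete reference pair get NaN bounds and
    are later marked unfilterable.
    """
    # design roles are CT/HN; paired_differences gives B - A = HN - CT,
    # so x = log2(CT/HN) is the negation.
    x = -paired_differences(ref_matrix, ref_design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        env = pd.DataFrame({"x_min": x.min(axis=1), "x_max": x.max(axis=1)})
    return env


def ratio_points(m: ExpressionMatrix, design: PairedDesign,
                 envelope: pd.DataFrame, which: str) -> pd.DataFrame:
    """One (x, y) dot per probe x pair, in long form.

    y = log2(pCT/pHMm) comes from the pair's own samples; x is the chosen
    envelope bound, constant per probe, so a probe's dots align vertically.
    """
    if which not in ("min", "max"):
        raise ValueError("which must be 'min' or 'max'")
    y = -paired_differences(m, design)          # log2(CT) - log2(HM)
    x = envelope["x_min" if which == "min" else "x_max"].reindex(y.index)
    long = y.stack(future_stack=True).rename("y").reset_index()
    long.columns = ["probe", "pair", "y"]
    long["x"] = x.loc[long["probe"]].to_numpy()
    long["envelope"] = which
    return long[["probe", "pair", "envelope", "x", "y"]]


@dataclass
class FilterParams:
    """Geometric thresholds of the contamination filter (log2 units)."""

    lambda_max: float = 0.5
    min_abs_y: float = 1.0        # >= 2-fold CT/HM change
    min_diag_dist: float = 1.0    # >= 2-fold HM/HN change
    min_votes: int | None = None  # default: ceil(8/13 * n_pairs)
    n_pairs: int = 13

    def __post_init__(self) -> None:
        if not 0 <= self.lambda_max < 1:
            raise ValueError("lambda_max must lie in [0, 1)")
        if self.min_abs_y < 0 or self.min_diag_dist < 0:
            raise ValueError("thresholds must be >= 0")
        if self.min_votes is None:
            self.min_votes = int(np.ceil(8 / 13 * self.n_pairs))
        if self.min_votes > self.n_pairs:
            warnings.warn(
                f"min_votes={self.min_votes} exceeds n_pairs={self.n_pairs}; "
                "every probe will be removed")


def classify_point(x, y, params: FilterParams):
    """Per-dot verdict; vectorized over equally shaped x, y arrays.

    Removal rules, in order of precedence:

    1. |y| < min_abs_y            -> removed_low_fc
    2. |y - x| < min_diag_dist    -> removed_near_diagonal
    3. y within the closed band between 0 and f_{lambda_max}(x)
                                  -> removed_contamination
    Survivors are assigned a quadrant; dots exactly on the axis or the
    diagonal are already removed by rules 1-2 (ties break toward removal).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scalar = x.ndim == 0
    x, y = np.atleast_1d(x), np.atleast_1d(y)

    f = np.atleast_1d(contamination_boundary(x, params.lambda_max))
    band_lo = np.minimum(0.0, f)
    band_hi = np.maximum(0.0, f)

    verdict = np.empty(x.shape, dtype=object)
    low_fc = np.abs(y) < params.min_abs_y
    near_diag = np.abs(y - x) < params.min_diag_dist
    in_band = (y >= band_lo) & (y <= band_hi)   # closed band

    quad = np.where(y < 0, np.where(y < x, KEPT_B, SURVIVED_A),
                    np.where(y > x, KEPT_D, SURVIVED_C))
    verdict[:] = quad
    verdict[in_band] = REMOVED_CONTAMINATION
    verdict[near_diag] = REMOVED_NEAR_DIAGONAL
    verdict[low_fc] = REMOVED_LOW_FC
    nan_mask = ~(np.isfinite(x) & np.isfinite(y))
    verdict[nan_mask] = UNFILTERABLE
    if scalar:
        return verdict.item()
    return verdict


def vote(verdicts_min: pd.DataFrame, verdicts_max: pd.DataFrame,
         params: FilterParams) -> pd.DataFrame:
    """Probe-level decision from per-pair verdicts under both envelopes.

    A pair contributes a vote to a quadrant only when it survives with the
    *same* quadrant under both the min and max envelope.  A probe is kept
    when one quadrant in {b, d} collects at least ``min_votes`` votes;
    quadrant b means up in HM, d means down in HM.

    Returns a DataFrame indexed by probe with vote counts per quadrant,
    ``final_kept`` and ``direction``.
    """
    probes = verdicts_min.index
    vmin = verdicts_min.to_numpy(dtype=object)
    vmax = verdicts_max.to_numpy(dtype=object)
    rows = []
    for i, probe in enumerate(probes):
        counts = {"a": 0, "b": 0, "c": 0, "d": 0}
        for a, b in zip(vmin[i], vmax[i]):
            qa, qb = _QUADRANT_OF.get(a), _QUADRANT_OF.get(b)
            if qa is not None and qa == qb:
                counts[qa] += 1
        best_q = max(("b", "d"), key=lambda q: counts[q])
        kept = counts[best_q] >= params.min_votes
        rows.append({
            "probe": probe,
            "votes_a": counts["a"], "votes_b": counts["b"],
            "votes_c": counts["c"], "votes_d": counts["d"],
            "final_kept": bool(kept),
            "direction": ({"b": "up_in_HM", "d": "down_in_HM"}[best_q]
                          if kept else None),
        })
    return pd.DataFrame(rows).set_index("probe")


class ContaminationFilter(BaseEstimator):
    """Selector removing probes explainable by normal-liver contamination.

    Parameters mirror :class:`FilterParams`; ``min_votes=None`` scales the
    8-of-13 voting rule to the number of pairs.

    Attributes (after ``fit``)
    --------------------------
    envelope_ : DataFrame with per-probe x_min/x_max reference bounds
    points_ : long DataFrame of every dot with its verdict
    decisions_ : per-probe vote counts, final_kept and direction
    signature_ : Signature of kept probes, SAM candidate order preserved
    """

    def __init__(self, lambda_max: float = 0.5, min_abs_y: float = 1.0,
                 min_diag_dist: float = 1.0, min_votes: int | None = None):
        self.lambda_max = lambda_max
        self.min_abs_y = min_abs_y
        self.min_diag_dist = min_diag_dist
        self.min_votes = min_votes

    def fit(self, tumor: ExpressionMatrix, design: PairedDesign,
            ref: ExpressionMatrix, ref_design: PairedDesign,
            candidates: list[str] | None = None) -> "ContaminationFilter":
        if candidates is None:
            candidates = tumor.probe_ids
        params = FilterParams(lambda_max=self.lambda_max,
                              min_abs_y=self.min_abs_y,
                              min_diag_dist=self.min_diag_dist,
                              min_votes=self.min_votes,
                              n_pairs=len(design))
        self.params_ = params
        if not candidates:
            self.envelope_ = pd.DataFrame(columns=["x_min", "x_max"])
            self.points_ = pd.DataFrame(
                columns=["probe", "pair", "envelope", "x", "y", "verdict"])
            self.decisions_ = pd.DataFrame(
                columns=["votes_a", "votes_b", "votes_c", "votes_d",
                         "final_kept", "direction"])
            self.signature_ = Signature(entries=(), feature_space="probe")
            return self

        sub = tumor.subset_probes(candidates)
        in_ref = [p for p in candidates if p in ref.values.index]
        env = reference_envelope(ref.subset_probes(in_ref), ref_design) \
            .reindex(candidates)
        self.envelope_ = env

        frames, verdict_wide = [], {}
        for which in ("min", "max"):
            pts = ratio_points(sub, design, env, which)
            pts["verdict"] = classify_point(pts["x"].to_numpy(),
                                            pts["y"].to_numpy(), params)
            frames.append(pts)
            verdict_wide[which] = pts.pivot(index="probe", columns="pair",
                                            values="verdict").reindex(candidates)
        self.points_ = pd.concat(frames, ignore_index=True)
        self.decisions_ = vote(verdict_wide["min"], verdict_wide["max"], params)

        kept = self.decisions_[self.decisions_["final_kept"]]
        entries = tuple(
            SignatureEntry(feature_id=p,
                           direction=kept.at[p, "direction"],
                           source_probes=(p,))
            for p in candidates if p in kept.index)
        self.signature_ = Signature(entries=entries, feature_space="probe")
        return self

    def get_support(self) -> np.ndarray:
        kept = set(e.feature_id for e in self.signature_.entries)
        return np.array([p in kept for p in self.decisions_.index])


def apply_filter(candidates: list[str],
                 tumor: ExpressionMatrix, design: PairedDesign,
                 ref: ExpressionMatrix, ref_design: PairedDesign,
                 params: FilterParams | None = None) -> Signature:
    """Functional wrapper: envelope -> dots -> classify -> vote -> Signature."""
    kw = {}
    if params is not None:
        kw = dict(lambda_max=params.lambda_max, min_abs_y=params.min_abs_y,
                  min_diag_dist=params.min_diag_dist,
                  min_votes=params.min_votes)
    flt = ContaminationFilter(**kw).fit(tumor, design, ref, ref_design,
                                        candidates)
    return flt.signature_
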