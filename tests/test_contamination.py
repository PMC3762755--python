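import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metasig import (
    CohortSpec, ContaminationFilter, FilterParams, build_pairs,
    classify_point, contamination_boundary, generate_cohort,
    generate_reference_pairs, ratio_points, reference_envelope, vote,
)
from metasig.contamination import (
    KEPT_B, KEPT_D, REMOVED_CONTAMINATION, REMOVED_LOW_FC,
    REMOVED_NEAR_DIAGONAL, SURVIVED_C,
)
from conftest import make_matrix


# ------------------------------------------------------------ boundary

def test_boundary_zero_lambda_is_x_axis():
    x = np.linspace(-10, 10, 101)
    assert np.allclose(contamination_boundary(x, 0.0), 0.0)


def test_boundary_half_lambda_values():
    assert contamination_boundary(3.0, 0.5) == pytest.approx(
        3 - np.log2(4.5), abs=1e-9)
    assert contamination_boundary(-3.0, 0.5) == pytest.approx(
        -np.log2(4.5), abs=1e-9)  # = -2.1699


def test_boundary_half_lambda_asymptotes():
    # y -> 1 as x -> +inf; y -> x + 1 as x -> -inf
    assert contamination_boundary(20.0, 0.5) == pytest.approx(1.0, abs=1e-3)
    assert contamination_boundary(-20.0, 0.5) - (-20.0) == pytest.approx(
        1.0, abs=1e-3)


def test_boundary_invalid_lambda():
    with pytest.raises(ValueError):
        contamination_boundary(0.0, 1.0)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.floats(min_value=-15, max_value=15),
       st.floats(min_value=0, max_value=0.9),
       st.floats(min_value=0, max_value=0.9))
def test_boundary_monotone_in_lambda_and_x(x, lam1, lam2):
    lo, hi = sorted((lam1, lam2))
    f_lo = contamination_boundary(x, lo)
    f_hi = contamination_boundary(x, hi)
    assert abs(f_hi) >= abs(f_lo) - 1e-12           # |f| grows with lambda
    assert contamination_boundary(0.0, hi) == pytest.approx(0.0, abs=1e-12)
    # monotone non-decreasing in x
    assert (contamination_boundary(x + 0.5, hi)
            >= contamination_boundary(x, hi) - 1e-12)


# ------------------------------------------------------------ envelope

def test_envelope_single_pair_degenerate():
    m = make_matrix(np.array([[5.0, 3.0]]), ["CT", "HN"], ["a", "a"])
    env = reference_envelope(m, build_pairs(m, "CT", "HN"))
    assert env.at["p0", "x_min"] == env.at["p0", "x_max"] == 2.0


def test_envelope_matches_loop_oracle():
    rng = np.random.default_rng(3)
    n_pairs = 5
    vals = rng.normal(8, 1, (20, 2 * n_pairs))
    codes = ["CT"] * n_pairs + ["HN"] * n_pairs
    patients = [f"r{i}" for i in range(n_pairs)] * 2
    m = make_matrix(vals, codes, patients)
    design = build_pairs(m, "CT", "HN")
    env = reference_envelope(m, design)
    for i, probe in enumerate(m.probe_ids):
        xs = [m.values.at[probe, a] - m.values.at[probe, b]
              for _, a, b in design.pairs]
        assert env.at[probe, "x_min"] == pytest.approx(min(xs), abs=1e-12)
        assert env.at[probe, "x_max"] == pytest.approx(max(xs), abs=1e-12)


def test_envelope_noise_free_decoy():
    spec = CohortSpec(n_probes=10, n_planted_de=0, n_liver_decoys=10,
                      n_tumor_de=0, decoy_liver_log2fc_range=(3.0, 3.0),
                      noise_sd=0.0, seed=2)
    ref, design = generate_reference_pairs(spec)
    env = reference_envelope(ref, design)
    assert np.allclose(env["x_min"], -3.0, atol=1e-9)
    assert np.allclose(env["x_max"], -3.0, atol=1e-9)


def test_ratio_points_counts_and_vertical_alignment(small_cohort,
                                                    ct_hm_design):
    _, matrix, _ = small_cohort
    probes = matrix.probe_ids[:5]
    env = pd.DataFrame({"x_min": 0.5, "x_max": 1.5}, index=probes)
    pts = ratio_points(matrix.subset_probes(probes), ct_hm_design, env, "min")
    assert len(pts) == 5 * len(ct_hm_design)
    # per probe the x coordinate is constant (vertical line of dots)
    assert (pts.groupby("probe")["x"].nunique() == 1).all()
    assert np.allclose(pts["x"].unique(), 0.5)


# ------------------------------------------------------------ classification

@pytest.mark.parametrize("x,y,expected", [
    (-4.0, -2.5, REMOVED_CONTAMINATION),   # f_0.5(-4) ~ -3.087; 0 > y > f
    (0.0, 0.5, REMOVED_LOW_FC),
    (-3.0, 2.0, KEPT_D),                   # y>=1, y-x=5>=1, above the band
    (3.0, 1.2, SURVIVED_C),                # above f_0.5(3)~0.830, below diag
    (0.0, -1.5, KEPT_B),
    (2.0, 1.4, REMOVED_NEAR_DIAGONAL),
    # near the lambda=0.5 curve at x=-4 the curve itself sits within one
    # log2 unit of the diagonal, so the diagonal rule takes precedence
    (-4.0, -3.087, REMOVED_NEAR_DIAGONAL),
    (5.0, 1.0, SURVIVED_C),                 # just above the y=1 tail
])
def test_classify_point_cases(x, y, expected):
    assert classify_point(x, y, FilterParams()) == expected


def test_quadrant_a_vacuity_on_grid():
    # no surviving point with y < 0 and y > x at default thresholds
    xs = np.arange(-10, 10, 0.05)
    ys = np.arange(-10, 10, 0.05)
    X, Y = np.meshgrid(xs, ys)
    v = classify_point(X.ravel(), Y.ravel(), FilterParams())
    survivors = np.isin(v, [KEPT_B, KEPT_D, "survived_a", SURVIVED_C])
    in_a = (Y.ravel() < 0) & (Y.ravel() > X.ravel())
    assert not np.any(survivors & in_a)


def test_contamination_completeness_noise_free():
    # pHM = pCT dots at the true x are always inside the closed band
    rng = np.random.default_rng(0)
    lam = rng.uniform(0, 0.5, 500)
    fold = rng.uniform(1, 6, 500)          # log2 liver fold 2..64
    x = -fold
    y = x - np.log2((1 - lam) * 2.0 ** x + lam)  # measured dot, pHM = pCT
    v = classify_point(x, y, FilterParams())
    assert set(np.unique(v)) <= {REMOVED_CONTAMINATION, REMOVED_LOW_FC,
                                 REMOVED_NEAR_DIAGONAL}


# ------------------------------------------------------------ voting

def _verdict_frame(verdicts):
    return pd.DataFrame([verdicts], index=["probe"],
                        columns=[f"P{i}" for i in range(len(verdicts))])


def test_vote_unanimous_kept():
    v = _verdict_frame([KEPT_D] * 13)
    out = vote(v, v, FilterParams())
    assert bool(out.at["probe", "final_kept"])
    assert out.at["probe", "direction"] == "down_in_HM"


def test_vote_seven_of_thirteen_not_kept():
    v = _verdict_frame([KEPT_B] * 7 + [REMOVED_LOW_FC] * 6)
    out = vote(v, v, FilterParams())
    assert not out.at["probe", "final_kept"]
    assert out.at["probe", "votes_b"] == 7


def test_vote_requires_same_quadrant_under_both_envelopes():
    vmin = _verdict_frame([KEPT_B] * 13)
    vmax = _verdict_frame([REMOVED_CONTAMINATION] * 13)
    out = vote(vmin, vmax, FilterParams())
    assert out.at["probe", "votes_b"] == 0
    assert not out.at["probe", "final_kept"]


def test_vote_pair_order_invariant():
    verd = [KEPT_B] * 9 + [REMOVED_LOW_FC] * 4
    rng = np.random.default_rng(1)
    perm = rng.permutation(13)
    v1 = _verdict_frame(verd)
    v2 = _verdict_frame([verd[i] for i in perm])
    out1 = vote(v1, v1, FilterParams())
    out2 = vote(v2, v2, FilterParams())
    assert out1.at["probe", "votes_b"] == out2.at["probe", "votes_b"]
    assert (out1.at["probe", "final_kept"] == out2.at["probe", "final_kept"])


def test_min_votes_scales_with_pairs():
    assert FilterParams(n_pairs=13).min_votes == 8
    assert FilterParams(n_pairs=26).min_votes == 16
    assert FilterParams(n_pairs=6).min_votes == 4


# ------------------------------------------------------------ end to end

def test_noise_free_recovery_exact_without_contamination(small_cohort):
    _, matrix, truth = small_cohort     # noise 0, lambda 0
    spec = CohortSpec(n_probes=200, n_planted_de=20, n_liver_decoys=20,
                      n_tumor_de=20, noise_sd=0.0, lambda_range=(0.0, 0.0),
                      seed=11)
    ref, ref_design = generate_reference_pairs(spec)
    design = build_pairs(matrix, "CT", "HM")
    planted = set(truth.probes_of("planted_up") + truth.probes_of("planted_down"))
    decoys = set(truth.probes_of("liver_decoy"))
    flt = ContaminationFilter().fit(matrix, design, ref, ref_design,
                                    sorted(planted | decoys))
    kept = set(flt.signature_.feature_ids)
    assert kept == planted
    # directions match planted sign (positive fc = up in HM = quadrant b)
    for probe in kept:
        want = "up_in_HM" if truth.planted_log2fc[probe] > 0 else "down_in_HM"
        assert flt.signature_.direction_of(probe) == want


def test_null_candidates_give_empty_signature(small_cohort):
    _, matrix, truth = small_cohort
    spec = CohortSpec(n_probes=200, n_planted_de=20, n_liver_decoys=20,
                      n_tumor_de=20, noise_sd=0.0, lambda_range=(0.0, 0.0),
                      seed=11)
    ref, ref_design = generate_reference_pairs(spec)
    design = build_pairs(matrix, "CT", "HM")
    flt = ContaminationFilter().fit(matrix, design, ref, ref_design,
                                    truth.probes_of("null")[:50])
    assert len(flt.signature_) == 0


def test_empty_candidate_list(small_cohort):
    _, matrix, _ = small_cohort
    spec = CohortSpec(n_probes=200, n_planted_de=20, n_liver_decoys=20,
                      n_tumor_de=20, noise_sd=0.0, seed=11)
    ref, ref_design = generate_reference_pairs(spec)
    design = build_pairs(matrix, "CT", "HM")
    flt = ContaminationFilter().fit(matrix, design, ref, ref_design, [])
    assert len(flt.signature_) == 0


def test_unfilterable_probe_excluded(small_cohort):
    _, matrix, truth = small_cohort
    spec = CohortSpec(n_probes=200, n_planted_de=20, n_liver_decoys=20,
                      n_tumor_de=20, noise_sd=0.0, lambda_range=(0.0, 0.0),
                      seed=11)
    ref, ref_design = generate_reference_pairs(spec)
    ref_dropped = ref.subset_probes(ref.probe_ids[1:])  # drop first probe
    design = build_pairs(matrix, "CT", "HM")
    target = matrix.probe_ids[0]
    flt = ContaminationFilter().fit(matrix, design, ref_dropped, ref_design,
                                    [target])
    assert target not in flt.signature_.feature_ids
    assert (flt.points_["verdict"] == "unfilterable").all()


def test_shrinking_lambda_enlarges_kept_set(noisy_cohort):
    spec, matrix, truth = noisy_cohort
    ref, ref_design = generate_reference_pairs(spec)
    design = build_pairs(matrix, "CT", "HM")
    cand = sorted(truth.probes_of("planted_up")
                  + truth.probes_of("planted_down")
                  + truth.probes_of("liver_decoy"))
    kept = {}
    for lam in (0.5, 0.25, 0.0):
        flt = ContaminationFilter(lambda_max=lam).fit(
            matrix, design, ref, ref_design, cand)
        kept[lam] = set(flt.signature_.feature_ids)
    assert kept[0.5] <= kept[0.25] <= kept[0.0]
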