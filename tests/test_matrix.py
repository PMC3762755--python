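import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metasig import (
    CohortSpec, MatrixError, build_pairs, generate_cohort, log2_transform,
    paired_differences, presence_calls_from_threshold, presence_filter,
    read_matrix, write_matrix,
)
from conftest import make_matrix


# ---------------------------------------------------------------- I/O

def test_tsv_round_trip(tmp_path):
    m = make_matrix(np.arange(12, dtype=float).reshape(3, 4),
                    ["CT", "HM", "CN", "HN"])
    write_matrix(m, tmp_path / "m.tsv", tmp_path / "a.tsv")
    back = read_matrix(tmp_path / "m.tsv", tmp_path / "a.tsv")
    assert back.shape == (3, 4)
    assert np.allclose(back.values.to_numpy(), m.values.to_numpy(), atol=1e-12)
    assert list(back.tissue_codes()) == ["CT", "HM", "CN", "HN"]


def test_synthetic_cohort_round_trip(tmp_path):
    spec = CohortSpec(n_probes=50, n_planted_de=5, n_liver_decoys=5,
                      n_tumor_de=5, seed=2)
    m, _ = generate_cohort(spec)
    write_matrix(m, tmp_path / "m.tsv", tmp_path / "a.tsv")
    back = read_matrix(tmp_path / "m.tsv", tmp_path / "a.tsv")
    assert np.abs(back.values.to_numpy() - m.values.to_numpy()).max() < 1e-12


def test_missing_values_preserved(tmp_path):
    vals = np.array([[1.0, np.nan], [2.0, 3.0]])
    m = make_matrix(vals, ["CT", "HM"], ["a", "a"])
    write_matrix(m, tmp_path / "m.tsv", tmp_path / "a.tsv")
    back = read_matrix(tmp_path / "m.tsv", tmp_path / "a.tsv")
    assert np.isnan(back.values.iloc[0, 1])


def test_duplicate_probe_id_rejected():
    vals = pd.DataFrame(np.ones((2, 2)), index=["p1", "p1"], columns=["a", "b"])
    ann = pd.DataFrame({"sample_id": ["a", "b"], "tissue_code": ["CT", "HM"],
                        "patient_id": ["x", "x"], "study_id": ["s", "s"]})
    with pytest.raises(MatrixError, match="p1"):
        from metasig import ExpressionMatrix
        ExpressionMatrix(vals, ann)


def test_unknown_tissue_code_names_sample():
    with pytest.raises(MatrixError, match="XX"):
        make_matrix(np.ones((2, 2)), ["CT", "XX"])


def test_geo_series_matrix_dialect(tmp_path):
    text = (
        "!Series_title\t\"demo\"\n"
        "!Sample_geo_accession\t\"GSM1\"\t\"GSM2\"\n"
        "!series_matrix_table_begin\n"
        "\"ID_REF\"\t\"GSM1\"\t\"GSM2\"\n"
        "\"p1\"\t1.5\t2.5\n"
        "\"p2\"\t3.5\tnull\n"
        "!series_matrix_table_end\n")
    path = tmp_path / "series.txt"
    path.write_text(text)
    ann = pd.DataFrame({"sample_id": ["GSM1", "GSM2"],
                        "tissue_code": ["CT", "HM"],
                        "patient_id": ["a", "a"], "study_id": ["s", "s"]})
    m = read_matrix(path, ann, dialect="geo_series_matrix")
    assert m.shape == (2, 2)
    assert m.values.loc["p1", "GSM1"] == 1.5
    assert np.isnan(m.values.loc["p2", "GSM2"])


# ---------------------------------------------------------------- presence

def test_presence_boundary_inclusive():
    # present in exactly half the samples passes min_fraction 0.5
    m = make_matrix(np.ones((1, 26)), ["CT"] * 26, [f"p{i}" for i in range(26)])
    calls = np.zeros((1, 26), dtype=bool)
    calls[0, :13] = True
    assert presence_filter(m, calls, 0.5).shape[0] == 1
    calls[0, 12] = False  # 12/26 < 0.5
    assert presence_filter(m, calls, 0.5).shape[0] == 0


def test_presence_never_present_removed():
    m = make_matrix(np.ones((2, 4)), ["CT"] * 4, list("abcd"))
    calls = np.array([[True] * 4, [False] * 4])
    for frac in (0.01, 0.5, 1.0):
        assert presence_filter(m, calls, frac).probe_ids == ["p0"]


def test_presence_matches_loop_oracle():
    rng = np.random.default_rng(5)
    m = make_matrix(rng.normal(size=(100, 20)), ["CT"] * 20,
                    [f"p{i}" for i in range(20)])
    calls = rng.random((100, 20)) > 0.4
    got = presence_filter(m, calls, 0.6).probe_ids
    expected = [m.probe_ids[i] for i in range(100)
                if sum(calls[i]) / 20 >= 0.6]
    assert got == expected


def test_presence_idempotent_and_subset():
    rng = np.random.default_rng(6)
    m = make_matrix(rng.normal(size=(30, 8)), ["CT"] * 8, list("abcdefgh"))
    calls = pd.DataFrame(rng.random((30, 8)) > 0.5, index=m.probe_ids,
                         columns=m.sample_ids)
    once = presence_filter(m, calls, 0.5)
    again = presence_filter(once, calls.loc[once.probe_ids], 0.5)
    assert again.probe_ids == once.probe_ids
    assert set(once.probe_ids) <= set(m.probe_ids)


def test_presence_bad_fraction():
    m = make_matrix(np.ones((1, 2)), ["CT", "HM"], ["a", "a"])
    for bad in (0.0, 1.5, -0.1):
        with pytest.raises(MatrixError):
            presence_filter(m, np.ones((1, 2), dtype=bool), bad)


def test_threshold_calls_default_quartile():
    vals = np.arange(1.0, 101.0).reshape(10, 10)
    m = make_matrix(vals, ["CT"] * 10, [f"p{i}" for i in range(10)])
    calls = presence_calls_from_threshold(m)
    assert calls.to_numpy().mean() == pytest.approx(0.75, abs=0.02)


# ---------------------------------------------------------------- log2

def test_log2_powers_of_two():
    m = make_matrix(np.array([[1.0, 2.0], [4.0, 8.0]]), ["CT", "HM"],
                    ["a", "a"], log_scale=False)
    out = log2_transform(m, floor=1.0)
    assert np.allclose(out.values.to_numpy(), [[0, 1], [2, 3]])
    assert out.log_scale


def test_log2_floor_and_double_transform_guard():
    m = make_matrix(np.array([[0.25]]), ["CT"], ["a"], log_scale=False)
    out = log2_transform(m, floor=1.0)
    assert out.values.iloc[0, 0] == 0.0
    with pytest.raises(MatrixError, match="already"):
        log2_transform(out)


def test_log2_negative_rejected():
    m = make_matrix(np.array([[-1.0]]), ["CT"], ["a"], log_scale=False)
    with pytest.raises(MatrixError):
        log2_transform(m)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.lists(st.floats(min_value=1.001, max_value=1e6), min_size=1,
                max_size=20))
def test_log2_round_trip_above_floor(values):
    arr = np.array(values)[:, None]
    m = make_matrix(arr, ["CT"], ["a"], log_scale=False)
    out = log2_transform(m, floor=1.0)
    assert np.allclose(2.0 ** out.values.to_numpy(), arr, rtol=1e-9)


# ---------------------------------------------------------------- pairing

def test_build_pairs_counts(paired_matrix):
    design = build_pairs(paired_matrix, "CT", "HM")
    assert len(design) == 3
    assert design.patients == ["a", "b", "c"]  # patient d lacks HM


def test_build_pairs_empty():
    m = make_matrix(np.ones((1, 2)), ["CN", "CN"], ["a", "b"])
    assert len(build_pairs(m, "CT", "HM")) == 0


def test_build_pairs_permutation_invariant(paired_matrix):
    design = build_pairs(paired_matrix, "CT", "HM")
    shuffled_cols = list(paired_matrix.values.columns)[::-1]
    shuffled = paired_matrix.subset_samples(shuffled_cols)
    assert build_pairs(shuffled, "CT", "HM").pairs == design.pairs


def test_build_pairs_ambiguous_role():
    m = make_matrix(np.ones((1, 3)), ["CT", "CT", "HM"], ["a", "a", "a"])
    with pytest.raises(MatrixError, match="ambiguous"):
        build_pairs(m, "CT", "HM")


def test_paired_differences_matches_loop(paired_matrix):
    design = build_pairs(paired_matrix, "CT", "HM")
    diffs = paired_differences(paired_matrix, design)
    for j, (patient, a, b) in enumerate(design.pairs):
        for i, probe in enumerate(paired_matrix.probe_ids):
            expected = (paired_matrix.values.at[probe, b]
                        - paired_matrix.values.at[probe, a])
            assert diffs.iloc[i, j] == pytest.approx(expected, abs=1e-12)


def test_paired_differences_absent_sample(paired_matrix):
    from metasig import PairedDesign
    bad = PairedDesign((("z", "nope_1", "nope_2"),), "CT", "HM")
    with pytest.raises(MatrixError, match="absent"):
        paired_differences(paired_matrix, bad)
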