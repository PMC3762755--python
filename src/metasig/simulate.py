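"""Synthetic paired cohorts with planted truth.

Emulates the data geometry of a paired colorectal liver-metastasis study:
patients contribute a primary-tumor (CT) / hepatic-metastasis (HM) pair, a
separate reference cohort contributes primary-tumor / normal-liver (CT/HN)
pairs, and every HM sample is an RNA mixture of pure metastasis and normal
liver at a per-sample contamination fraction lambda.

Planted probe classes:

* ``planted_up`` / ``planted_down`` — true metastasis genes whose pure HM
  expression differs from CT by a planted log2 fold change.
* ``liver_decoy`` — genes with pHM = pCT but strong liver expression
  (pHN != pCT); contamination makes them look differential, which is
  exactly the false-positive mode the contamination filter removes.
* ``tumor_gene`` — CN vs CT effects shared by CT and HM, giving the
  three-class CN/CT/HM structure used by clustering validation.
* ``null`` — everything else.

Contamination mixes RNA mass, so mixing is done in *linear* intensity
space: I_HMm = (1-lambda) * I_HM,pure + lambda * I_HN, after which
log-normal noise is applied in log2 space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, PairedDesign

_STREAMS = ("baseline", "effects", "lambda", "noise", "ref_noise", "batch")


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a synthetic paired cohort.

    Defaults mirror the study geometry the package targets: 13 CT/HM
    pairs, 6 CT/HN reference pairs, contamination lambda ~ U(0, 0.5)
    (metastases are pathology-screened to >= 50% cancer cells), and
    log-normal noise of 0.4 log2 units.
    """

    n_pairs: int = 13
    n_ref_pairs: int = 6
    n_probes: int = 10_000
    n_planted_de: int = 150
    planted_log2fc_range: tuple[float, float] = (1.5, 3.0)
    n_liver_decoys: int = 300
    decoy_liver_log2fc_range: tuple[float, float] = (1.0, 6.0)
    lambda_range: tuple[float, float] = (0.0, 0.5)
    noise_sd: float = 0.4
    n_studies: int = 1
    batch_shift_sd: float = 0.0
    batch_scale_sd: float = 0.0
    seed: int = 0
    # three-class structure (CN vs CT effects) for clustering validation
    n_tumor_de: int = 150
    tumor_log2fc_range: tuple[float, float] = (1.5, 3.0)
    n_cn: int = 13
    n_hn: int = 0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5

    def validate(self) -> None:
        counts = dict(n_pairs=self.n_pairs, n_ref_pairs=self.n_ref_pairs,
                      n_probes=self.n_probes, n_planted_de=self.n_planted_de,
                      n_liver_decoys=self.n_liver_decoys,
                      n_tumor_de=self.n_tumor_de, n_cn=self.n_cn, n_hn=self.n_hn)
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_planted_de + self.n_liver_decoys + self.n_tumor_de > self.n_probes:
            raise ValueError("planted + decoy + tumor probes exceed n_probes")
        lo, hi = self.lambda_range
        if not (0 <= lo <= hi < 1):
            raise ValueError(f"lambda_range must lie within [0, 1), got {self.lambda_range}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class CohortTruth:
    """Ground truth for a generated cohort."""

    probe_class: pd.Series            # probe -> class label
    lambda_by_sample: dict[str, float]  # HM sample -> contamination fraction
    batch_by_sample: dict[str, str] = field(default_factory=dict)
    planted_log2fc: pd.Series | None = None   # planted probes, signed (HM - CT)
    decoy_liver_log2fc: pd.Series | None = None  # decoys, log2(pHN/pCT)

    def probes_of(self, cls: str) -> list[str]:
        return list(self.probe_class.index[self.probe_class == cls])


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    """Independent substreams derived from one global seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


@dataclass
class _Profiles:
    """Shared noise-free log2 tissue profiles for one generated universe."""

    probes: list[str]
    baseline: np.ndarray      # CN / null log2 baseline
    ct: np.ndarray            # primary tumor profile (baseline + tumor effects)
    hm_pure: np.ndarray       # pure metastasis (ct + planted effects)
    hn: np.ndarray            # normal liver (baseline + decoy liver effects)
    truth: CohortTruth


def _build_profiles(spec: CohortSpec) -> _Profiles:
    spec.validate()
    rng = _rngs(spec.seed)
    n = spec.n_probes
    probes = [f"probe_{i:05d}" for i in range(n)]

    baseline = rng["baseline"].normal(spec.baseline_mean, spec.baseline_sd, n)

    classes = np.array(["null"] * n, dtype=object)
    idx = np.arange(n)
    n_up = spec.n_planted_de // 2
    planted_idx = idx[: spec.n_planted_de]
    decoy_idx = idx[spec.n_planted_de: spec.n_planted_de + spec.n_liver_decoys]
    tumor_idx = idx[spec.n_planted_de + spec.n_liver_decoys:
                    spec.n_planted_de + spec.n_liver_decoys + spec.n_tumor_de]
    classes[planted_idx[:n_up]] = "planted_up"
    classes[planted_idx[n_up:]] = "planted_down"
    classes[decoy_idx] = "liver_decoy"
    classes[tumor_idx] = "tumor_gene"

    eff = rng["effects"]
    lo, hi = spec.planted_log2fc_range
    planted_fc = np.zeros(n)
    mag = eff.uniform(lo, hi, spec.n_planted_de)
    sign = np.where(np.arange(spec.n_planted_de) < n_up, 1.0, -1.0)
    planted_fc[planted_idx] = sign * mag

    dlo, dhi = spec.decoy_liver_log2fc_range
    decoy_fc = np.zeros(n)
    decoy_fc[decoy_idx] = eff.uniform(dlo, dhi, spec.n_liver_decoys)

    tlo, thi = spec.tumor_log2fc_range
    tumor_fc = np.zeros(n)
    tmag = eff.uniform(tlo, thi, spec.n_tumor_de)
    tsign = eff.choice([-1.0, 1.0], spec.n_tumor_de)
    tumor_fc[tumor_idx] = tmag * tsign

    ct = baseline + tumor_fc
    hm_pure = ct + planted_fc        # planted +fc => HM above CT
    hn = baseline + decoy_fc         # liver decoys expressed in normal liver

    truth = CohortTruth(
        probe_class=pd.Series(classes, index=probes, name="probe_class"),
        lambda_by_sample={},
        planted_log2fc=pd.Series(planted_fc[planted_idx],
                                 index=[probes[i] for i in planted_idx]),
        decoy_liver_log2fc=pd.Series(decoy_fc[decoy_idx],
                                     index=[probes[i] for i in decoy_idx]),
    )
    return _Profiles(probes, baseline, ct, hm_pure, hn, truth)


def _noisy(profile_log2: np.ndarray, n_cols: int, sd: float,
           rng: np.random.Generator) -> np.ndarray:
    cols = np.tile(profile_log2[:, None], (1, n_cols))
    if sd > 0:
        cols = cols + rng.normal(0.0, sd, cols.shape)
    return cols


def generate_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, CohortTruth]:
    """Generate the paired CT/HM cohort (plus CN and optional HN samples).

    Every HM sample s receives its own contamination fraction lambda_s drawn
    uniformly from ``spec.lambda_range``; the observed HM intensities are the
    linear-space mixture (1-lambda_s) * HM_pure + lambda_s * HN, after which
    noise is added in log2 space.  Deterministic under ``spec.seed``.
    """
    prof = _build_profiles(spec)
    rng = _rngs(spec.seed)
    noise = rng["noise"]

    lam_lo, lam_hi = spec.lambda_range
    lam = rng["lambda"].uniform(lam_lo, lam_hi, spec.n_pairs)

    # linear-space mixing, per HM sample
    hm_lin = (1.0 - lam)[None, :] * np.power(2.0, prof.hm_pure)[:, None] \
        + lam[None, :] * np.power(2.0, prof.hn)[:, None]
    hm_log = np.log2(hm_lin)

    blocks, columns, ann_rows = [], [], []

    def add_block(vals: np.ndarray, code: str, ids: list[str],
                  patients: list[str]) -> None:
        blocks.append(vals)
        columns.extend(ids)
        ann_rows.extend(
            {"sample_id": s, "tissue_code": code, "patient_id": p,
             "study_id": "study0"}
            for s, p in zip(ids, patients))

    pair_patients = [f"P{i:03d}" for i in range(spec.n_pairs)]
    add_block(_noisy(prof.ct, spec.n_pairs, spec.noise_sd, noise), "CT",
              [f"CT_{p}" for p in pair_patients], pair_patients)
    hm_ids = [f"HM_{p}" for p in pair_patients]
    hm_vals = hm_log + (noise.normal(0, spec.noise_sd, hm_log.shape)
                        if spec.noise_sd > 0 else 0.0)
    add_block(hm_vals, "HM", hm_ids, pair_patients)

    cn_patients = [f"P{i:03d}" for i in range(spec.n_cn)]
    if spec.n_cn:
        add_block(_noisy(prof.baseline, spec.n_cn, spec.noise_sd, noise), "CN",
                  [f"CN_{p}" for p in cn_patients], cn_patients)
    if spec.n_hn:
        hn_patients = [f"Q{i:03d}" for i in range(spec.n_hn)]
        add_block(_noisy(prof.hn, spec.n_hn, spec.noise_sd, noise), "HN",
                  [f"HN_{p}" for p in hn_patients], hn_patients)

    values = pd.DataFrame(np.hstack(blocks), index=prof.probes, columns=columns)
    matrix = ExpressionMatrix(values, pd.DataFrame(ann_rows), log_scale=True)
    truth = prof.truth
    truth.lambda_by_sample = dict(zip(hm_ids, lam))
    truth.batch_by_sample = {s: "study0" for s in columns}
    return matrix, truth


def generate_reference_pairs(spec: CohortSpec) -> tuple[ExpressionMatrix, PairedDesign]:
    """Generate the CT/HN reference cohort sharing the main cohort's profiles.

    Reference patients are disjoint from the paired cohort but share the same
    probe-level colon/liver profiles, with independent noise.  These pairs
    supply the per-probe CT/HN ratio envelope used by the contamination filter.
    """
    if spec.n_ref_pairs < 1:
        raise ValueError("n_ref_pairs must be >= 1: the reference envelope "
                         "is undefined without reference pairs")
    prof = _build_profiles(spec)
    rng = _rngs(spec.seed)
    noise = rng["ref_noise"]

    patients = [f"R{i:03d}" for i in range(spec.n_ref_pairs)]
    ct_ids = [f"CT_{p}" for p in patients]
    hn_ids = [f"HN_{p}" for p in patients]
    ct_vals = _noisy(prof.ct, spec.n_ref_pairs, spec.noise_sd, noise)
    hn_vals = _noisy(prof.hn, spec.n_ref_pairs, spec.noise_sd, noise)

    values = pd.DataFrame(np.hstack([ct_vals, hn_vals]), index=prof.probes,
                          columns=ct_ids + hn_ids)
    ann = pd.DataFrame(
        [{"sample_id": s, "tissue_code": "CT", "patient_id": p,
          "study_id": "ref"} for s, p in zip(ct_ids, patients)]
        + [{"sample_id": s, "tissue_code": "HN", "patient_id": p,
            "study_id": "ref"} for s, p in zip(hn_ids, patients)])
    matrix = ExpressionMatrix(values, ann, log_scale=True)
    design = PairedDesign(tuple(zip(patients, ct_ids, hn_ids)), "CT", "HN")
    return matrix, design


def inject_batches(m: ExpressionMatrix, spec: CohortSpec
                   ) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Partition samples into studies and apply per-study location/scale shifts.

    Each study s gets a per-probe additive shift ~ N(0, batch_shift_sd) and a
    multiplicative scale exp(N(0, batch_scale_sd)) applied to probe-centered
    values, both in log2 space.  Returns the shifted matrix and the
    sample -> study assignment.
    """
    if spec.n_studies < 2:
        raise ValueError("inject_batches needs n_studies >= 2")
    rng = _rngs(spec.seed)["batch"]
    samples = m.sample_ids
    assignment = {s: f"study{i % spec.n_studies}" for i, s in enumerate(samples)}

    vals = m.values.to_numpy().copy()
    center = np.nanmean(vals, axis=1, keepdims=True)
    for j in range(spec.n_studies):
        cols = [i for i, s in enumerate(samples) if assignment[s] == f"study{j}"]
        shift = (rng.normal(0, spec.batch_shift_sd, (vals.shape[0], 1))
                 if spec.batch_shift_sd > 0 else np.zeros((vals.shape[0], 1)))
        scale = (np.exp(rng.normal(0, spec.batch_scale_sd, (vals.shape[0], 1)))
                 if spec.batch_scale_sd > 0 else np.ones((vals.shape[0], 1)))
        vals[:, cols] = center + (vals[:, cols] - center) * scale + shift

    ann = m.annotations.copy()
    ann["study_id"] = [assignment[s] for s in ann["sample_id"]]
    out = ExpressionMatrix(pd.DataFrame(vals, index=m.values.index,
                                        columns=m.values.columns),
                           ann.reset_index(drop=True), log_scale=m.log_scale,
                           tissue_alphabet=m.tissue_alphabet)
    return out, assignment
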