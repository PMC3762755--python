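"""Expression matrices, sample annotations and patient-paired designs.

The pipeline's universal currency is a probes x samples matrix of log2
intensities together with per-sample annotations.  Samples carry a
two-letter tissue code: the first letter is the organ (C colon, H hepatic,
L lung, P peritoneum), the second the state (N normal, P polyp, T primary
tumor, M metastasis).  Paired statistics operate on patient-matched sample
pairs (e.g. primary tumor CT vs hepatic metastasis HM).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ORGAN_LETTERS = frozenset("CHLP")
STATE_LETTERS = frozenset("NPTM")

#: closed but extensible alphabet of tissue codes
DEFAULT_TISSUE_CODES = frozenset(
    o + s for o in ORGAN_LETTERS for s in STATE_LETTERS
)

ANNOTATION_COLUMNS = ("sample_id", "tissue_code", "patient_id", "study_id")


class MatrixError(ValueError):
    """Raised when a matrix or annotation fails validation."""


def validate_tissue_codes(codes: Iterable[str],
                          alphabet: frozenset[str] = DEFAULT_TISSUE_CODES,
                          sample_ids: Sequence[str] | None = None) -> None:
    for i, code in enumerate(codes):
        if code not in alphabet:
            who = f" (sample {sample_ids[i]!r})" if sample_ids is not None else ""
            raise MatrixError(f"unknown tissue code {code!r}{who}")


@dataclass
class ExpressionMatrix:
    """Probes x samples expression values with sample annotations.

    Parameters
    ----------
    values : DataFrame
        Probe-indexed rows, sample-id columns.  NaN marks missing.
    annotations : DataFrame
        One row per sample with columns ``sample_id``, ``tissue_code``,
        ``patient_id``, ``study_id``; indexed by sample_id after validation.
    log_scale : bool
        Whether ``values`` are log2 intensities (True) or linear (False).
        Guards against double log-transformation.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    log_scale: bool = True
    tissue_alphabet: frozenset[str] = field(default=DEFAULT_TISSUE_CODES)

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        ann = pd.DataFrame(self.annotations).copy()
        missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
        if missing:
            raise MatrixError(f"annotation table lacks columns {missing}")
        ann = ann.astype({c: str for c in ANNOTATION_COLUMNS})
        if ann["sample_id"].duplicated().any():
            dup = ann.loc[ann["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise MatrixError(f"duplicated sample id {dup!r}")
        ann = ann.set_index("sample_id", drop=False)
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise MatrixError(f"duplicated probe id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise MatrixError(f"duplicated sample id {dup!r} in matrix header")
        if set(self.values.columns) != set(ann.index):
            raise MatrixError("matrix columns and annotation sample ids differ")
        # align annotation rows to the matrix column order
        self.annotations = ann.loc[list(self.values.columns)]
        validate_tissue_codes(self.annotations["tissue_code"],
                              self.tissue_alphabet,
                              list(self.annotations["sample_id"]))

    # ---- convenience ---------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def tissue_codes(self) -> pd.Series:
        return self.annotations["tissue_code"]

    def samples_with_code(self, code: str) -> list[str]:
        return list(self.annotations.index[self.annotations["tissue_code"] == code])

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        missing = [p for p in probes if p not in self.values.index]
        if missing:
            raise MatrixError(f"probes absent from matrix: {missing[:5]}")
        return replace(self, values=self.values.loc[list(probes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise MatrixError(f"samples absent from matrix: {missing[:5]}")
        return replace(
            self,
            values=self.values[list(samples)],
            annotations=self.annotations.loc[list(samples)].reset_index(drop=True),
        )


@dataclass(frozen=True)
class PairedDesign:
    """Ordered patient-matched sample pairs for paired statistics.

    ``pairs`` holds ``(patient_id, sample_id_A, sample_id_B)`` with sample A
    of tissue ``role_A`` and sample B of tissue ``role_B`` (e.g. CT/HM).
    """

    pairs: tuple[tuple[str, str, str], ...]
    role_A: str
    role_B: str

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def patients(self) -> list[str]:
        return [p for p, _, _ in self.pairs]

    @property
    def samples_A(self) -> list[str]:
        return [a for _, a, _ in self.pairs]

    @property
    def samples_B(self) -> list[str]:
        return [b for _, _, b in self.pairs]

    def validate_against(self, m: ExpressionMatrix) -> None:
        for patient, a, b in self.pairs:
            for sid, role in ((a, self.role_A), (b, self.role_B)):
                if sid not in m.annotations.index:
                    raise MatrixError(
                        f"design references absent sample {sid!r} (patient {patient})")
                code = m.annotations.at[sid, "tissue_code"]
                if code != role:
                    raise MatrixError(
                        f"sample {sid!r} has tissue {code}, expected {role}")


def build_pairs(m: ExpressionMatrix, role_A: str, role_B: str) -> PairedDesign:
    """Pair each patient's ``role_A`` sample with its ``role_B`` sample.

    Patients lacking either role are omitted; a patient with two samples of
    the same requested role is ambiguous and raises.  Output is ordered by
    patient id, so it is invariant to the matrix's row/column order.
    """
    ann = m.annotations
    pairs: list[tuple[str, str, str]] = []
    for patient in sorted(ann["patient_id"].unique()):
        rows = ann[ann["patient_id"] == patient]
        picks = []
        for role in (role_A, role_B):
            hits = sorted(rows.index[rows["tissue_code"] == role])
            if len(hits) > 1:
                raise MatrixError(
                    f"patient {patient!r} has {len(hits)} samples with role "
                    f"{role}: ambiguous pairing")
            picks.append(hits[0] if hits else None)
        if picks[0] is not None and picks[1] is not None:
            pairs.append((patient, picks[0], picks[1]))
    return PairedDesign(tuple(pairs), role_A, role_B)


# ---------------------------------------------------------------------------
# transforms and filters
# ---------------------------------------------------------------------------

def log2_transform(m: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """Replace each linear-scale value v by log2(max(v, floor)).

    Flooring keeps downstream ratios finite.  Transforming a matrix already
    flagged as log-scale, or one containing negative values, is an error.
    """
    if m.log_scale:
        raise MatrixError("matrix is already log2-transformed")
    if floor <= 0:
        raise MatrixError("floor must be positive")
    vals = m.values
    if (vals < 0).any().any():
        raise MatrixError("negative values cannot be log2-transformed")
    out = np.log2(vals.clip(lower=floor))
    return replace(m, values=out, log_scale=True)


def presence_filter(m: ExpressionMatrix,
                    present: pd.DataFrame | np.ndarray,
                    min_fraction: float) -> ExpressionMatrix:
    """Keep probes called present in at least ``min_fraction`` of samples.

    The boundary is inclusive: a probe present in exactly half the samples
    passes ``min_fraction=0.5``.  The sample set is unchanged.
    """
    if not (0 < min_fraction <= 1):
        raise MatrixError("min_fraction must lie in (0, 1]")
    pres = np.asarray(present, dtype=bool)
    if pres.shape != m.values.shape:
        raise MatrixError(
            f"presence matrix shape {pres.shape} != matrix shape {m.values.shape}")
    frac = pres.mean(axis=1)
    keep = [p for p, f in zip(m.probe_ids, frac) if f >= min_fraction]
    return m.subset_probes(keep)


def presence_calls_from_threshold(m: ExpressionMatrix,
                                  threshold: float | None = None) -> pd.DataFrame:
    """Derive detection calls by thresholding intensities.

    When platform present/absent calls are unavailable, "present" is defined
    as value > threshold on the matrix's own scale; the default threshold is
    the study-wide 25th percentile of all values.
    """
    vals = m.values
    if threshold is None:
        threshold = float(np.nanpercentile(vals.to_numpy(), 25))
    return (vals > threshold) & vals.notna()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path,
                     tissue_alphabet: frozenset[str] = DEFAULT_TISSUE_CODES,
                     ) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise MatrixError(f"annotation file lacks columns {missing}")
    return ann


def read_matrix(path: str | Path,
                annotations: str | Path | pd.DataFrame | None = None,
                dialect: str = "tsv",
                log_scale: bool = True,
                tissue_alphabet: frozenset[str] = DEFAULT_TISSUE_CODES,
                ) -> ExpressionMatrix:
    """Read an expression matrix from TSV or a GEO series-matrix file.

    TSV dialect: first column probe id, header row sample ids, "NA" missing.
    GEO dialect: sample ids from the ``!Sample_geo_accession`` line, the
    expression block between the series_matrix_table markers; annotations
    must still be supplied separately (tissue codes are study-specific).
    """
    path = Path(path)
    if not path.exists():
        raise MatrixError(f"no such file: {path}")
    if dialect == "tsv":
        values = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    elif dialect == "geo_series_matrix":
        values = _read_geo_series_matrix(path)
    else:
        raise MatrixError(f"unknown dialect {dialect!r}")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    if annotations is None:
        raise MatrixError("an annotation table is required")
    if not isinstance(annotations, pd.DataFrame):
        annotations = read_annotations(annotations, tissue_alphabet)
    return ExpressionMatrix(values, annotations, log_scale=log_scale,
                            tissue_alphabet=tissue_alphabet)


def _read_geo_series_matrix(path: Path) -> pd.DataFrame:
    header: list[str] | None = None
    rows: list[list[str]] = []
    in_table = False
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if not in_table:
                continue
            fields = [f.strip().strip('"') for f in line.split("\t")]
            if header is None:
                header = fields
            else:
                rows.append(fields)
    if header is None:
        raise MatrixError(f"{path}: no series_matrix_table block found")
    df = pd.DataFrame(rows, columns=header).set_index(header[0])
    return df.apply(pd.to_numeric, errors="coerce")


def write_matrix(m: ExpressionMatrix, matrix_path: str | Path,
                 annotation_path: str | Path | None = None) -> None:
    out = m.values.copy()
    out.index.name = "probe_id"
    out.to_csv(matrix_path, sep="\t", na_rep="NA")
    if annotation_path is not None:
        m.annotations.reset_index(drop=True).to_csv(
            annotation_path, sep="\t", index=False)


def paired_differences(m: ExpressionMatrix, design: PairedDesign) -> pd.DataFrame:
    """Per probe x pair difference: value in sample B minus sample A.

    For a CT/HM design this is log2(HM) - log2(CT), the paired log-ratio
    used by the paired SAM statistic.  Missing values propagate.
    """
    design.validate_against(m)
    a = m.values[list(design.samples_A)].to_numpy()
    b = m.values[list(design.samples_B)].to_numpy()
    return pd.DataFrame(b - a, index=m.values.index, columns=design.patients)
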