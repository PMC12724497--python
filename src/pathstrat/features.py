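"""Subject x feature table ingestion, QC filtering, standardization and views.

The wide metrics CSV has one row per subject and one column per
ROI-modality-hemisphere feature, named ``<roi>_<MOD>_<HEMI>`` with
``MOD in {VOL, FA, MD, SBR}`` and ``HEMI in {L, R, B, ASYM}``. Clinical score
columns use reserved names (``NP3TOT``, ``NPTOT``, ``MCATOT``, ``QUIP_SUM``)
and the intracranial-volume column is named ``ICV``. Columns ending in
``-std`` (per-ROI dispersion summaries) and non-numeric metadata are dropped
at load time; rows with non-finite values or a fully zeroed modality are
removed. Every dropped row/column is recorded in a QC ledger.

Feature views are nested: V1 (clinical only) < V2 (+ volumes and DaT-SBR)
< V3 (+ uncorrected diffusion) and V2 < V4 (+ free-water-corrected
diffusion). View membership is carried on each descriptor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODALITIES = ("VOL", "FA", "MD", "SBR", "CLIN")
HEMISPHERES = ("L", "R", "B", "ASYM")
VIEWS = ("V1", "V2", "V3", "V4")

#: reserved clinical feature columns (the V1 view)
CLINICAL_FEATURES = ("NP3TOT", "NPTOT", "MCATOT", "QUIP_SUM")
ICV_COLUMN = "ICV"
SUBJECT_ID = "subject_id"

ALL_VIEWS = frozenset(VIEWS)


class FormatError(ValueError):
    """Input table violates the expected layout."""


class EmptyDataError(ValueError):
    """No rows (or no features) survive quality control."""


class InsufficientDataError(ValueError):
    """Too few subjects for the requested operation."""


@dataclass(frozen=True)
class FeatureDescriptor:
    """Metadata for one column of the feature matrix."""

    name: str
    roi: str
    modality: str
    hemisphere: str
    views: frozenset = frozenset()

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.modality == "CLIN" and "V1" not in self.views:
            raise ValueError("clinical features must belong to view V1")


def parse_feature_name(name: str, view_map: dict | None = None) -> FeatureDescriptor | None:
    """Parse a column name into a descriptor, or None if unparseable.

    ``view_map`` optionally assigns curated view tags by column name; without
    it, views follow the modality defaults (CLIN -> all views, VOL/SBR -> V2+,
    FA/MD -> V3 and V4).
    """
    if name in CLINICAL_FEATURES:
        return FeatureDescriptor(name, roi="clinical", modality="CLIN",
                                 hemisphere="B", views=ALL_VIEWS)
    if name == ICV_COLUMN:
        return FeatureDescriptor(name, roi="intracranial", modality="VOL",
                                 hemisphere="B", views=frozenset())
    parts = name.rsplit("_", 2)
    if len(parts) != 3:
        return None
    roi, mod, hemi = parts
    if mod not in ("VOL", "FA", "MD", "SBR") or hemi not in HEMISPHERES or not roi:
        return None
    if view_map is not None:
        views = frozenset(view_map.get(name, ()))
    elif mod in ("VOL", "SBR"):
        views = frozenset({"V2", "V3", "V4"})
    else:
        views = frozenset({"V3", "V4"})
    return FeatureDescriptor(name, roi=roi, modality=mod, hemisphere=hemi, views=views)


@dataclass
class FeatureMatrix:
    """An N x D feature matrix with per-column descriptors.

    ``standardized`` is True once every column has been globally z-scored.
    ``qc_ledger`` accumulates one record per dropped row or column.
    """

    subject_ids: list
    values: np.ndarray
    descriptors: list
    standardized: bool = False
    qc_ledger: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["kind", "id", "reason"]))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, d = self.values.shape
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length mismatch")
        if len(self.descriptors) != d:
            raise ValueError("descriptors length mismatch")
        if len(set(self.subject_ids)) != n:
            raise FormatError("subject ids must be unique")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> list:
        return [d.name for d in self.descriptors]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, SUBJECT_ID, self.subject_ids)
        return df

    def log_qc(self, kind: str, ident, reason: str) -> None:
        rec = pd.DataFrame([{"kind": kind, "id": ident, "reason": reason}])
        self.qc_ledger = pd.concat([self.qc_ledger, rec], ignore_index=True)


DIAGNOSES = ("PD", "HC", "SWEDD")

CLINICAL_COLUMNS = (
    SUBJECT_ID, "diagnosis", "age", "sex", "education", "disease_duration",
    "medication_status", "field_strength", "updrs3", "moca", "quip_sum",
)


@dataclass
class ClinicalTable:
    """Per-subject outcomes and covariates, linked to imaging post hoc."""

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"clinical table missing columns: {missing}")
        bad = set(self.data["diagnosis"].dropna()) - set(DIAGNOSES)
        if bad:
            raise FormatError(f"unknown diagnosis values: {sorted(bad)}")
        self.data = self.data.reset_index(drop=True)

    @property
    def subject_ids(self) -> list:
        return list(self.data[SUBJECT_ID])

    def aligned_to(self, fm: FeatureMatrix) -> "ClinicalTable":
        """Return rows reordered to match ``fm.subject_ids`` exactly."""
        idx = self.data.set_index(SUBJECT_ID)
        missing = [s for s in fm.subject_ids if s not in idx.index]
        if missing:
            raise FormatError(f"clinical table missing subjects: {missing[:5]}")
        return ClinicalTable(idx.loc[fm.subject_ids].reset_index())


# ---------------------------------------------------------------------------
# loading and QC


def load_feature_table(csv_path, clinical_path, view_map: dict | None = None):
    """Read the wide metrics CSV and clinical CSV and apply column/row QC.

    Returns ``(FeatureMatrix_raw, ClinicalTable)``; the matrix carries its QC
    ledger. Columns that are non-numeric, end in ``-std`` or have unparseable
    names are dropped; rows with NaN/inf anywhere, or with every value of some
    modality exactly zero, are removed.
    """
    raw = pd.read_csv(csv_path)
    clin = ClinicalTable(pd.read_csv(clinical_path))
    return _qc_frame(raw, view_map=view_map), clin


def _qc_frame(raw: pd.DataFrame, view_map: dict | None = None) -> FeatureMatrix:
    if SUBJECT_ID not in raw.columns:
        raise FormatError(f"feature CSV must contain a {SUBJECT_ID!r} column")
    ledger = []
    keep: list[FeatureDescriptor] = []
    for col in raw.columns:
        if col == SUBJECT_ID:
            continue
        if col.endswith("-std"):
            ledger.append(("column", col, "std_suffix"))
            continue
        series = pd.to_numeric(raw[col], errors="coerce")
        if series.isna().all() or (raw[col].dtype == object and series.isna().any()):
            ledger.append(("column", col, "non_numeric"))
            continue
        desc = parse_feature_name(col, view_map=view_map)
        if desc is None:
            ledger.append(("column", col, "unparseable_name"))
            continue
        keep.append(desc)
    if not keep:
        raise EmptyDataError("no feature columns survive column QC")

    values = raw[[d.name for d in keep]].apply(pd.to_numeric).to_numpy(dtype=float)
    ids = list(raw[SUBJECT_ID].astype(str))

    row_ok = np.ones(len(ids), dtype=bool)
    reasons = {}
    finite = np.isfinite(values).all(axis=1)
    for i in np.nonzero(~finite)[0]:
        row_ok[i] = False
        reasons[i] = "nonfinite"
    modalities = np.array([d.modality for d in keep])
    for mod in sorted(set(modalities) - {"CLIN"}):
        cols = modalities == mod
        with np.errstate(invalid="ignore"):
            allzero = (values[:, cols] == 0).all(axis=1)
        for i in np.nonzero(allzero & row_ok)[0]:
            row_ok[i] = False
            reasons[i] = f"all_zero_{mod}"
    for i in sorted(reasons):
        ledger.append(("row", ids[i], reasons[i]))
    if not row_ok.any():
        raise EmptyDataError("no rows survive row QC")

    fm = FeatureMatrix(
        subject_ids=[s for s, ok in zip(ids, row_ok) if ok],
        values=values[row_ok],
        descriptors=keep,
    )
    if ledger:
        fm.qc_ledger = pd.DataFrame(ledger, columns=["kind", "id", "reason"])
    return fm


def zscore_columns(fm: FeatureMatrix) -> FeatureMatrix:
    """Globally z-score each column (sample SD, ddof=1).

    Zero-variance columns cannot be standardized; they are excluded and
    logged in the ledger rather than propagated as zeros.
    """
    if fm.n_subjects < 2:
        raise InsufficientDataError("z-scoring requires at least 2 subjects")
    mu = fm.values.mean(axis=0)
    sd = fm.values.std(axis=0, ddof=1)
    keep = sd > 0
    out = FeatureMatrix(
        subject_ids=list(fm.subject_ids),
        values=(fm.values[:, keep] - mu[keep]) / sd[keep],
        descriptors=[d for d, k in zip(fm.descriptors, keep) if k],
        standardized=True,
        qc_ledger=fm.qc_ledger.copy(),
    )
    for d, k in zip(fm.descriptors, keep):
        if not k:
            out.log_qc("column", d.name, "zero_variance")
    return out


def asymmetry_index(right, left):
    """Asymmetry index ``(R - L) / (R + L)`` for nonnegative measurements.

    A zero denominator yields a missing value (NaN) rather than an error;
    downstream row QC then applies.
    """
    right = np.asarray(right, dtype=float)
    left = np.asarray(left, dtype=float)
    denom = right + left
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom == 0, np.nan, (right - left) / denom)
    if np.any(denom == 0):
        warnings.warn("asymmetry index undefined for R + L = 0; emitted NaN")
    return out if out.ndim else float(out)


def select_view(fm: FeatureMatrix, view: str) -> FeatureMatrix:
    """Restrict to the features tagged with the requested nested view."""
    if view not in VIEWS:
        raise ValueError(f"unknown view {view!r}; expected one of {VIEWS}")
    keep = [i for i, d in enumerate(fm.descriptors) if view in d.views]
    return FeatureMatrix(
        subject_ids=list(fm.subject_ids),
        values=fm.values[:, keep],
        descriptors=[fm.descriptors[i] for i in keep],
        standardized=fm.standardized,
        qc_ledger=fm.qc_ledger.copy(),
    )


def strip_clinical(fm: FeatureMatrix) -> FeatureMatrix:
    """Drop CLIN-modality columns (clustering is imaging-only by default)."""
    keep = [i for i, d in enumerate(fm.descriptors) if d.modality != "CLIN"]
    return FeatureMatrix(
        subject_ids=list(fm.subject_ids),
        values=fm.values[:, keep],
        descriptors=[fm.descriptors[i] for i in keep],
        standardized=fm.standardized,
        qc_ledger=fm.qc_ledger.copy(),
    )


def row_col_normalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Per-column z then per-row centering/scaling, used inside training only.

    Population SD (ddof=0) is used here so that a matrix already satisfying
    both normalizations is an exact fixed point; the global z-transform in
    :func:`zscore_columns` keeps the sample-SD convention. Constant rows are
    centered but not scaled, and logged.
    """
    x = fm.values.copy()
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    x = (x - mu) / sd
    rmu = x.mean(axis=1, keepdims=True)
    rsd = x.std(axis=1, ddof=0, keepdims=True)
    const = rsd[:, 0] == 0
    rsd[const, 0] = 1.0
    x = (x - rmu) / rsd
    out = FeatureMatrix(
        subject_ids=list(fm.subject_ids),
        values=x,
        descriptors=list(fm.descriptors),
        standardized=True,
        qc_ledger=fm.qc_ledger.copy(),
    )
    for sid, c in zip(fm.subject_ids, const):
        if c:
            out.log_qc("row", sid, "constant_row_scaling_skipped")
    return out
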