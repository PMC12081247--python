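"""Core in-memory containers shared by every pipeline stage.

The pipeline consumes a patients x features table of real-valued radiomic
features (column names carry a ``PET_``/``CT_`` modality prefix, or a
``wavelet-``-style name under one of those prefixes), a clinical covariate
table, and right-censored overall-survival outcomes.  All three are thin,
validated wrappers around :class:`pandas.DataFrame` / :class:`numpy.ndarray`
so that downstream stages can rely on alignment and completeness without
re-checking it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix", "SurvivalData", "ClinicalTable", "CLINICAL_COLUMNS"]

_MODALITIES = ("PET", "CT")

#: Canonical clinical column order (one row per patient).
CLINICAL_COLUMNS = [
    "age",
    "bmi",
    "t_stage",
    "suv_max",
    "suv_mean",
    "suv_peak",
    "wbc",
    "nc",
    "lc",
    "plt",
    "nlr",
    "lymph_node_positive",
]


def modality_from_name(name: str) -> str:
    """Infer the imaging modality of a feature from its name prefix."""
    for tag in _MODALITIES:
        if name.startswith(tag + "_"):
            return tag
    raise ValueError(
        f"feature {name!r} has no recognised modality prefix "
        f"(expected one of {[t + '_' for t in _MODALITIES]})"
    )


@dataclass
class FeatureMatrix:
    """A patients x features real matrix with modality-tagged columns.

    Parameters
    ----------
    values
        ``(n_patients, n_features)`` float array; no missing values allowed.
    patient_ids
        Unique string identifiers, one per row.
    feature_names
        Unique column names; each must start with ``"PET_"`` or ``"CT_"``.
    """

    values: np.ndarray
    patient_ids: list[str]
    feature_names: list[str]
    modality: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.patient_ids = [str(p) for p in self.patient_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, f = self.values.shape
        if len(self.patient_ids) != n:
            raise ValueError("patient_ids length does not match row count")
        if len(self.feature_names) != f:
            raise ValueError("feature_names length does not match column count")
        if len(set(self.patient_ids)) != n:
            raise ValueError("duplicate patient ids")
        if len(set(self.feature_names)) != f:
            raise ValueError("duplicate feature names")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            cells = [
                f"(patient {self.patient_ids[i]}, feature {self.feature_names[j]})"
                for i, j in bad[:10]
            ]
            raise ValueError(f"non-finite entries at {', '.join(cells)}")
        if self.modality is None:
            self.modality = [modality_from_name(f) for f in self.feature_names]
        elif len(self.modality) != f:
            raise ValueError("modality length does not match column count")

    # -- basic geometry -------------------------------------------------
    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    # -- conversions ----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "patient_id", self.patient_ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureMatrix":
        if "patient_id" not in df.columns:
            raise ValueError("expected a 'patient_id' column")
        pids = df["patient_id"].astype(str).tolist()
        vals = df.drop(columns="patient_id")
        non_numeric = [c for c in vals.columns if not np.issubdtype(vals[c].dtype, np.number)]
        if non_numeric:
            raise ValueError(f"non-numeric feature columns: {non_numeric}")
        if vals.isna().any().any():
            missing = [
                f"(row {pids[i]}, column {vals.columns[j]})"
                for i, j in zip(*np.where(vals.isna().to_numpy()))
            ][:10]
            raise ValueError(f"missing values at {', '.join(missing)}")
        return cls(vals.to_numpy(float), pids, list(vals.columns))

    # -- subsetting -----------------------------------------------------
    def select_features(self, names: list[str]) -> "FeatureMatrix":
        """Column subset preserving the requested order."""
        idx = {f: j for j, f in enumerate(self.feature_names)}
        cols = [idx[n] for n in names]
        return FeatureMatrix(
            self.values[:, cols],
            list(self.patient_ids),
            list(names),
            [self.modality[j] for j in cols],
        )

    def select_patients(self, rows: np.ndarray) -> "FeatureMatrix":
        rows = np.asarray(rows)
        return FeatureMatrix(
            self.values[rows],
            [self.patient_ids[i] for i in rows],
            list(self.feature_names),
            list(self.modality),
        )


@dataclass
class SurvivalData:
    """Right-censored survival outcomes: time in months, event 1 = death."""

    time_months: np.ndarray
    event: np.ndarray
    patient_ids: list[str]

    def __post_init__(self) -> None:
        self.time_months = np.asarray(self.time_months, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.patient_ids = [str(p) for p in self.patient_ids]
        if self.time_months.shape != self.event.shape:
            raise ValueError("time and event lengths differ")
        if len(self.patient_ids) != len(self.time_months):
            raise ValueError("patient_ids length mismatch")
        if np.any(self.time_months <= 0):
            raise ValueError("survival times must be positive")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicator must be 0 or 1")

    def __len__(self) -> int:
        return len(self.time_months)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, rows: np.ndarray) -> "SurvivalData":
        rows = np.asarray(rows)
        return SurvivalData(
            self.time_months[rows],
            self.event[rows],
            [self.patient_ids[i] for i in rows],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "time_months": self.time_months,
                "event": self.event,
            }
        )

    def to_structured(self) -> np.ndarray:
        """scikit-survival structured array view (event flag, time)."""
        return np.array(
            list(zip(self.event.astype(bool), self.time_months)),
            dtype=[("event", "?"), ("time", "<f8")],
        )


@dataclass
class ClinicalTable:
    """Per-patient clinical covariates.

    Enforces the identity NLR = NC / LC on every row and positivity of the
    blood counts; T stage is the ordinal 2/3/4 coding used clinically.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ["patient_id", *CLINICAL_COLUMNS] if c not in df.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        if df[CLINICAL_COLUMNS].isna().any().any():
            raise ValueError("clinical table contains missing values")
        if (df["lc"] <= 0).any():
            raise ValueError("lymphocyte counts must be positive")
        for c in ("wbc", "nc", "plt"):
            if (df[c] <= 0).any():
                raise ValueError(f"{c} counts must be positive")
        if not np.allclose(df["nlr"], df["nc"] / df["lc"], rtol=0, atol=1e-12):
            raise ValueError("nlr column violates NLR = NC / LC")
        if not df["t_stage"].isin([2, 3, 4]).all():
            raise ValueError("t_stage must be 2, 3 or 4")
        self.data = df.reset_index(drop=True)

    @property
    def patient_ids(self) -> list[str]:
        return self.data["patient_id"].astype(str).tolist()

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, rows: np.ndarray) -> "ClinicalTable":
        return ClinicalTable(self.data.iloc[np.asarray(rows)].reset_index(drop=True))
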