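"""Shared ingestion, validation and configuration.

All tables are CSV with a header row and a leading ``patient_id`` column.
Patient order is canonicalized by sorted id at ingest, so downstream fold
assignment never depends on input row order.  Survival times are months as
reals; the NLR column is cross-checked against NC / LC on read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import GeneratorConfig
from .containers import CLINICAL_COLUMNS, ClinicalTable, FeatureMatrix, SurvivalData
from .evaluate import EvaluationConfig

__all__ = [
    "read_feature_table",
    "read_clinical_survival",
    "PipelineConfig",
    "load_pipeline_config",
    "content_hash",
]


def read_feature_table(path: str | Path) -> FeatureMatrix:
    """Load and validate a patients x features CSV (modality from name prefix)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "patient_id":
        raise ValueError("first column must be 'patient_id'")
    df = df.sort_values("patient_id", kind="stable").reset_index(drop=True)
    return FeatureMatrix.from_dataframe(df)


def read_clinical_survival(
    clinical_path: str | Path,
    survival_path: str | Path,
    patient_ids: list[str] | None = None,
) -> tuple[ClinicalTable, SurvivalData]:
    """Load the clinical and survival tables, aligned to ``patient_ids``.

    The NLR column is recomputed from NC / LC; a discrepancy above 1e-6
    raises a warning and the recomputed value is kept.
    """
    clin = pd.read_csv(clinical_path, float_precision="round_trip")
    surv = pd.read_csv(survival_path, float_precision="round_trip")
    for name, df, req in (
        ("clinical", clin, ["patient_id", *CLINICAL_COLUMNS]),
        ("survival", surv, ["patient_id", "time_months", "event"]),
    ):
        missing = [c for c in req if c not in df.columns]
        if missing:
            raise ValueError(f"{name} table missing columns: {missing}")
    clin["patient_id"] = clin["patient_id"].astype(str)
    surv["patient_id"] = surv["patient_id"].astype(str)
    if patient_ids is not None:
        for name, df in (("clinical", clin), ("survival", surv)):
            missing = set(patient_ids) - set(df["patient_id"])
            if missing:
                raise ValueError(f"{name} table missing patients: {sorted(missing)[:5]}")
        clin = clin.set_index("patient_id").loc[patient_ids].reset_index()
        surv = surv.set_index("patient_id").loc[patient_ids].reset_index()
    else:
        clin = clin.sort_values("patient_id", kind="stable").reset_index(drop=True)
        surv = surv.sort_values("patient_id", kind="stable").reset_index(drop=True)
    if list(clin["patient_id"]) != list(surv["patient_id"]):
        raise ValueError("clinical and survival tables list different patients")

    recomputed = clin["nc"] / clin["lc"]
    if (np.abs(clin["nlr"] - recomputed) > 1e-6).any():
        warnings.warn("provided NLR column inconsistent with NC/LC; recomputed")
        clin = clin.assign(nlr=recomputed)

    survival = SurvivalData(
        surv["time_months"].to_numpy(float),
        surv["event"].to_numpy(),
        surv["patient_id"].tolist(),
    )
    return ClinicalTable(clin), survival


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one flat, serializable record."""

    icc_threshold: float = 0.75
    r_threshold_pet: float = 0.76
    r_threshold_ct: float = 0.40
    k_s: int = 3
    k_f: int = 9
    kf_grid: tuple[int, ...] = tuple(range(2, 11))
    cv_folds: int = 3
    cv_reps: int = 100
    lasso_inner_folds: int = 3
    nested_outer_folds: int = 5
    rsf_trees: int = 500
    rsf_min_leaf: int = 5
    train_fraction: float = 0.7
    auc_horizon_months: float = 36.0
    trifactor_restarts: int = 10
    trifactor_max_iter: int = 500
    trifactor_tol: float = 1e-6
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def to_yaml(self, path: str | Path) -> None:
        rec = dataclasses.asdict(self)
        rec["kf_grid"] = list(self.kf_grid)
        gen = rec.pop("generator")
        for k, v in gen.items():
            rec[f"generator.{k}"] = list(v) if isinstance(v, tuple) else v
        Path(path).write_text(yaml.safe_dump(rec, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        rec = yaml.safe_load(Path(path).read_text()) or {}
        gen_kwargs, own_kwargs = {}, {}
        gen_fields = {f.name for f in dataclasses.fields(GeneratorConfig)}
        own_fields = {f.name for f in dataclasses.fields(cls)} - {"generator"}
        for key, val in rec.items():
            if key.startswith("generator."):
                name = key.split(".", 1)[1]
                if name not in gen_fields:
                    raise ValueError(f"unknown generator key {name!r}")
                gen_kwargs[name] = tuple(val) if isinstance(val, list) else val
            elif key in own_fields:
                own_kwargs[key] = tuple(val) if isinstance(val, list) else val
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(generator=GeneratorConfig(**gen_kwargs), **own_kwargs)

    def evaluation_config(self, **overrides) -> EvaluationConfig:
        base = dict(
            generator=self.generator,
            icc_threshold=self.icc_threshold,
            r_threshold_pet=self.r_threshold_pet,
            r_threshold_ct=self.r_threshold_ct,
            k_s=self.k_s,
            k_f=self.k_f,
            kf_grid=self.kf_grid,
            cv_folds=self.cv_folds,
            train_fraction=self.train_fraction,
            auc_horizon_months=self.auc_horizon_months,
            seed=self.seed,
        )
        base.update(overrides)
        return EvaluationConfig(**base)


def load_pipeline_config(path: str | Path | None, seed: int | None = None) -> PipelineConfig:
    cfg = PipelineConfig.from_yaml(path) if path else PipelineConfig()
    if seed is not None:
        gen = dataclasses.replace(cfg.generator, seed=seed)
        cfg = dataclasses.replace(cfg, seed=seed, generator=gen)
    return cfg


def content_hash(*paths: str | Path) -> str:
    """Stable SHA-256 over file contents, for provenance records."""
    h = hashlib.sha256()
    for p in sorted(map(str, paths)):
        h.update(p.encode())
        h.update(Path(p).read_bytes())
    return h.hexdigest()
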