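"""End-to-end glue: per-patient region building and feature-table assembly."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import DegenerateROIError, PatientRecord, resample_to_grid
from .dose import extract_dose_catalog
from .radiomics import ExtractionSettings, extract_radiomics_catalog
from .regions import build_region_set

logger = logging.getLogger("fwlomics")

REGION_KEYS = ("WL", "highFWL", "lowFWL")


def extract_patient_features(
    p: PatientRecord,
    threshold: float = 0.3,
    settings: ExtractionSettings | None = None,
    regions_subset: tuple[str, ...] = REGION_KEYS,
) -> dict[tuple[str, str], dict[str, float]]:
    """All (region, modality) feature vectors for one patient.

    Returns {(region, 'R'|'D'): {feature name: value}} with names prefixed
    '<region>:<modality>:'.  Dose and perfusion are resampled to the CT
    grid first (identity when already aligned).
    """
    settings = settings or ExtractionSettings()
    dose = resample_to_grid(p.dose, p.ct, "trilinear")
    perf = resample_to_grid(p.perfusion, p.ct, "trilinear")
    regions = build_region_set(perf, p.lung, p.gtv, threshold)
    masks = {"WL": regions.wl, "highFWL": regions.high, "lowFWL": regions.low}
    out: dict[tuple[str, str], dict[str, float]] = {}
    for key in regions_subset:
        roi = masks[key]
        roi.require_nonempty(f"{key} region for patient {p.id}")
        r = extract_radiomics_catalog(p.ct, roi, settings)
        d = extract_dose_catalog(dose, roi, p.prescription)
        out[(key, "R")] = {f"{key}:R:{k}": v for k, v in r.items()}
        out[(key, "D")] = {f"{key}:D:{k}": v for k, v in d.items()}
    return out


def cohort_feature_tables(
    records: list[PatientRecord],
    threshold: float = 0.3,
    settings: ExtractionSettings | None = None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Patients x features tables per (region, modality)."""
    rows: dict[tuple[str, str], list[dict]] = {}
    ids = []
    for p in records:
        feats = extract_patient_features(p, threshold, settings)
        ids.append(p.id)
        for key, vec in feats.items():
            rows.setdefault(key, []).append(vec)
    tables = {
        key: pd.DataFrame(vals, index=pd.Index(ids, name="patient_id"))
        for key, vals in rows.items()
    }
    for key, t in tables.items():
        logger.info("feature table %s: %d patients x %d features", key, *t.shape)
    return tables


def cohort_labels(records: list[PatientRecord]) -> pd.Series:
    return pd.Series(
        [p.rp for p in records],
        index=pd.Index([p.id for p in records], name="patient_id"),
        name="rp",
    )


def cohort_manifest(records: list[PatientRecord]) -> pd.DataFrame:
    rows = [
        {"patient_id": p.id, "prescription": p.prescription, "rp": p.rp, **p.covariates}
        for p in records
    ]
    return pd.DataFrame(rows).set_index("patient_id")
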