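"""Cohort container and CSV I/O.

A cohort couples a wide concentration matrix (rows = subject x visit samples,
columns = panel metabolites, values in uM) with a clinical table (one row per
subject x visit).  On disk both live as comma-separated UTF-8 CSV with a
header row; samples are keyed ``subject_id:visit`` and missing values use the
token ``NA``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import MetabolitePanel

__all__ = ["ClinicalRecord", "CohortDataset", "read_cohort", "write_cohort"]

ARMS = ("O", "P")
VISITS = ("V1", "V12")
CLINICAL_COLUMNS = [
    "arm", "alsfrs_r", "svc", "mmt", "bmi", "gender", "onset_site",
    "age_onset", "died_before_v12",
]
#: clinical progression variables usable as model responses
CLINICAL_VARIABLES = {"ALSFRS-r": "alsfrs_r", "SVC": "svc", "MMT": "mmt", "BMI": "bmi"}
NA_TOKEN = "NA"


@dataclass(frozen=True)
class ClinicalRecord:
    """Clinical observation for one subject at one visit."""

    subject_id: str
    arm: str
    visit: str
    alsfrs_r: int
    svc: float
    mmt: float
    bmi: float
    gender: str
    onset_site: str
    age_onset: float
    died_before_v12: bool = False

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"{self.subject_id}: arm must be one of {ARMS}")
        if self.visit not in VISITS:
            raise ValueError(f"{self.subject_id}: visit must be one of {VISITS}")
        if not 0 <= self.alsfrs_r <= 48:
            raise ValueError(f"{self.subject_id}: ALSFRS-r out of range [0, 48]")
        if self.svc < 0 or self.mmt < 0:
            raise ValueError(f"{self.subject_id}: SVC and MMT must be >= 0")
        if self.bmi <= 0:
            raise ValueError(f"{self.subject_id}: BMI must be > 0")
        if self.gender not in ("M", "F"):
            raise ValueError(f"{self.subject_id}: gender must be M or F")
        if self.onset_site not in ("bulbar", "spinal"):
            raise ValueError(f"{self.subject_id}: onset_site must be bulbar or spinal")


@dataclass
class CohortDataset:
    """Aligned concentration matrix and clinical table for a two-visit cohort.

    Both frames are indexed by a (subject_id, visit) MultiIndex and share the
    same row order.  ``concentrations`` holds linear uM values; zeros and NaN
    mark sub-detection-limit measurements prior to imputation.
    """

    panel: MetabolitePanel
    concentrations: pd.DataFrame
    clinical: pd.DataFrame
    imputed: bool = False
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        conc, clin = self.concentrations, self.clinical
        if not conc.index.equals(clin.index):
            raise ValueError("concentration and clinical rows are not aligned")
        if conc.index.has_duplicates:
            raise ValueError("duplicate (subject, visit) samples")
        allowed = set(self.panel.feature_names)
        unknown = [c for c in conc.columns if c not in allowed]
        if unknown:
            raise ValueError(f"columns not defined by the panel: {unknown[:5]}")
        vals = conc.to_numpy(dtype=float)
        if self.log_transformed:
            if not np.all(np.isfinite(vals)):
                raise ValueError("non-finite values in log-transformed matrix")
        else:
            finite = vals[np.isfinite(vals)]
            if (finite < 0).any():
                raise ValueError("negative concentrations")
            if self.imputed and ((vals <= 0).any() or not np.all(np.isfinite(vals))):
                raise ValueError("imputed matrix must be strictly positive and finite")
        # every subject has a V1 row; V12 may be absent only for deaths
        subjects = clin.index.get_level_values("subject_id")
        visits = clin.index.get_level_values("visit")
        by_subject = pd.Series(visits, index=subjects).groupby(level=0).agg(set)
        for sid, vset in by_subject.items():
            if "V1" not in vset:
                raise ValueError(f"subject {sid} lacks a V1 record")
            if "V12" not in vset:
                died = clin.loc[(sid, "V1"), "died_before_v12"]
                if not bool(died):
                    raise ValueError(
                        f"subject {sid} lacks a V12 record but is not flagged deceased"
                    )

    # -- convenience accessors -------------------------------------------------
    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.clinical.index.get_level_values("subject_id")))

    def arm_of(self) -> pd.Series:
        """Arm label per subject."""
        v1 = self.clinical.xs("V1", level="visit")
        return v1["arm"]

    def n_by_arm(self) -> dict[str, int]:
        return self.arm_of().value_counts().to_dict()

    def visit_view(self, visit: str) -> pd.DataFrame:
        """Concentration rows for one visit, indexed by subject."""
        return self.concentrations.xs(visit, level="visit")

    def subset_arm(self, arm: str) -> "CohortDataset":
        keep = self.clinical["arm"] == arm
        return CohortDataset(
            self.panel,
            self.concentrations.loc[keep.to_numpy()],
            self.clinical.loc[keep.to_numpy()],
            imputed=self.imputed,
            log_transformed=self.log_transformed,
        )

    def records(self) -> list[ClinicalRecord]:
        out = []
        for (sid, visit), row in self.clinical.iterrows():
            out.append(ClinicalRecord(
                subject_id=str(sid), arm=str(row["arm"]), visit=str(visit),
                alsfrs_r=int(row["alsfrs_r"]), svc=float(row["svc"]),
                mmt=float(row["mmt"]), bmi=float(row["bmi"]),
                gender=str(row["gender"]), onset_site=str(row["onset_site"]),
                age_onset=float(row["age_onset"]),
                died_before_v12=bool(row["died_before_v12"]),
            ))
        return out


def _make_index(keys: pd.Series) -> pd.MultiIndex:
    parts = keys.astype(str).str.split(":", n=1, expand=True)
    if parts.shape[1] != 2 or parts.isna().any().any():
        bad = keys[parts.isna().any(axis=1)] if parts.shape[1] == 2 else keys
        raise ValueError(f"malformed sample key (expected subject:visit): {list(bad[:3])}")
    return pd.MultiIndex.from_arrays(
        [parts[0], parts[1]], names=["subject_id", "visit"]
    )


def read_cohort(conc_path, clinical_path, panel: MetabolitePanel) -> CohortDataset:
    """Load a cohort from ``concentrations.csv`` and ``clinical.csv``.

    Concentration columns absent from the panel are dropped with a single
    warning stating how many were ignored.  Non-numeric concentration cells
    and clinical-table gaps raise with the offending row/column named.
    """
    conc = pd.read_csv(conc_path, na_values=[NA_TOKEN], keep_default_na=False)
    if conc.columns[0] != "sample_id":
        raise ValueError("concentration file must start with a sample_id column")
    idx = _make_index(conc["sample_id"])
    conc = conc.drop(columns="sample_id")

    allowed = set(panel.feature_names)
    unknown = [c for c in conc.columns if c not in allowed]
    if unknown:
        warnings.warn(
            f"dropped {len(unknown)} concentration column(s) not in the panel: "
            f"{unknown[:5]}{'...' if len(unknown) > 5 else ''}",
            stacklevel=2,
        )
        conc = conc.drop(columns=unknown)
    for col in conc.columns:
        coerced = pd.to_numeric(conc[col], errors="coerce")
        bad = coerced.isna() & conc[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric concentration at row {row} ({idx[row][0]}:{idx[row][1]}),"
                f" column {col!r}: {conc[col].iloc[row]!r}"
            )
        conc[col] = coerced
    conc.index = idx

    clin = pd.read_csv(clinical_path, na_values=[NA_TOKEN], keep_default_na=False)
    required = {"subject_id", "visit", *CLINICAL_COLUMNS}
    missing_cols = required - set(clin.columns)
    if missing_cols:
        raise ValueError(f"clinical table lacks columns: {sorted(missing_cols)}")
    clin.index = pd.MultiIndex.from_arrays(
        [clin["subject_id"].astype(str), clin["visit"].astype(str)],
        names=["subject_id", "visit"],
    )
    clin = clin.drop(columns=["subject_id", "visit"])
    clin["died_before_v12"] = clin["died_before_v12"].astype(bool)
    clin["alsfrs_r"] = clin["alsfrs_r"].astype(int)

    missing = conc.index.difference(clin.index)
    if len(missing) > 0:
        sid, visit = missing[0]
        raise ValueError(f"sample {sid}:{visit} has no clinical record")
    clin = clin.loc[conc.index]
    return CohortDataset(panel, conc, clin)


def write_cohort(dataset: CohortDataset, out_dir) -> dict[str, Path]:
    """Write ``concentrations.csv`` and ``clinical.csv``; returns the paths.

    Full float precision is preserved so that a read/write round trip is exact
    to 1e-12 relative tolerance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conc_path = out / "concentrations.csv"
    clin_path = out / "clinical.csv"

    conc = dataset.concentrations.copy()
    keys = [f"{s}:{v}" for s, v in conc.index]
    conc.insert(0, "sample_id", keys)
    conc.to_csv(conc_path, index=False, na_rep=NA_TOKEN)

    clin = dataset.clinical.reset_index()
    clin.to_csv(clin_path, index=False, na_rep=NA_TOKEN)
    return {"concentrations": conc_path, "clinical": clin_path}
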