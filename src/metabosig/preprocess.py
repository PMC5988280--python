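"""From cohort to model-ready feature tables.

The modelling levels mirror the analysis design: metabolome at V1, at V12,
and per-feature percent change from V1 to V12.  Concentrations are
half-minimum imputed, ratio columns are computed on linear concentrations,
log (natural) transform is applied for the visit-level views, and columns are
autoscaled (unit variance) by default.

Clinical progression responses use the percent *loss* convention:
positive values mean worsening (decline of ALSFRS-r, SVC, MMT or BMI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CLINICAL_VARIABLES, CohortDataset
from .panel import RatioDef

__all__ = [
    "FeatureTable",
    "impute_floor",
    "log_transform",
    "add_ratios",
    "percent_change",
    "clinical_pct_change",
    "build_table",
]

LEVELS = ("V1", "V12", "delta_pct")
log = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """Scaled feature matrix with an attached response vector.

    ``y`` is either an object array of class labels (``y_kind == "class"``)
    or a float array (``y_kind == "continuous"``).  ``column_means`` and
    ``column_sds`` invert the autoscaling.
    """

    X: np.ndarray
    features: list[str]
    y: np.ndarray
    level: str
    sample_ids: list[str]
    response_name: str
    y_kind: str
    scaling: str = "unit_variance"
    column_means: np.ndarray = field(default=None)  # type: ignore[assignment]
    column_sds: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.y) != self.X.shape[0]:
            raise ValueError("y length does not match number of rows")
        if len(self.features) != self.X.shape[1]:
            raise ValueError("feature names do not match number of columns")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> list:
        if self.y_kind != "class":
            raise ValueError("continuous response has no classes")
        return sorted(set(self.y))

    def y_numeric(self) -> np.ndarray:
        """Response as floats; class labels are coded 0/1 in sorted label order."""
        if self.y_kind == "class":
            classes = self.classes
            if len(classes) != 2:
                raise ValueError(f"need exactly 2 classes, got {classes}")
            return np.array([classes.index(v) for v in self.y], dtype=float)
        return np.asarray(self.y, dtype=float)

    def select(self, features: list[str]) -> "FeatureTable":
        """Column subset preserving scaling statistics and response."""
        idx = [self.features.index(f) for f in features]
        return FeatureTable(
            X=self.X[:, idx],
            features=list(features),
            y=self.y.copy(),
            level=self.level,
            sample_ids=list(self.sample_ids),
            response_name=self.response_name,
            y_kind=self.y_kind,
            scaling=self.scaling,
            column_means=None if self.column_means is None else self.column_means[idx],
            column_sds=None if self.column_sds is None else self.column_sds[idx],
        )


def impute_floor(dataset: CohortDataset) -> CohortDataset:
    """Replace zeros/missing by half the minimum positive value per column."""
    if dataset.log_transformed:
        raise ValueError("impute before log transform")
    conc = dataset.concentrations.copy()
    for col in conc.columns:
        vals = conc[col].to_numpy(dtype=float)
        bad = ~np.isfinite(vals) | (vals <= 0)
        if bad.all():
            raise ValueError(f"metabolite {col!r} has no positive measurement")
        if bad.any():
            vals[bad] = vals[~bad].min() / 2.0
            conc[col] = vals
    return CohortDataset(
        dataset.panel, conc, dataset.clinical.copy(), imputed=True
    )


def log_transform(dataset: CohortDataset) -> CohortDataset:
    """Natural log, elementwise; requires strictly positive values."""
    vals = dataset.concentrations.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or (vals <= 0).any():
        raise ValueError("log transform requires strictly positive finite values")
    return CohortDataset(
        dataset.panel,
        np.log(dataset.concentrations),
        dataset.clinical.copy(),
        imputed=dataset.imputed,
        log_transformed=True,
    )


def add_ratios(dataset: CohortDataset, ratios: list[RatioDef] | None = None) -> CohortDataset:
    """Append ratio columns, computed on linear (imputed) concentrations."""
    if dataset.log_transformed:
        raise ValueError("ratios are computed on linear concentrations before log")
    if not dataset.imputed:
        raise ValueError("impute before computing ratios (zero denominators)")
    ratios = dataset.panel.ratios if ratios is None else ratios
    conc = dataset.concentrations.copy()
    for r in ratios:
        for operand in (r.numerator, r.denominator):
            if operand not in conc.columns:
                raise ValueError(f"ratio {r.name}: operand {operand!r} absent")
        conc[r.name] = conc[r.numerator] / conc[r.denominator]
    return CohortDataset(
        dataset.panel, conc, dataset.clinical.copy(), imputed=True
    )


def percent_change(v1_row, v12_row) -> np.ndarray:
    """Per-feature percent change 100 * (V12 - V1) / V1 on linear values."""
    v1 = np.asarray(v1_row, dtype=float)
    v12 = np.asarray(v12_row, dtype=float)
    return 100.0 * (v12 - v1) / v1


def clinical_pct_change(dataset: CohortDataset, variable: str) -> pd.Series:
    """Percent loss of a clinical variable from V1 to V12 (positive = worsening).

    Subjects without a V12 visit are excluded (and logged).
    """
    col = CLINICAL_VARIABLES.get(variable, variable)
    clin = dataset.clinical
    v1 = clin.xs("V1", level="visit")[col].astype(float)
    v12 = clin.xs("V12", level="visit")[col].astype(float)
    paired = v1.index.intersection(v12.index)
    dropped = v1.index.difference(v12.index)
    if len(dropped):
        log.info("excluding %d subject(s) without V12 from %s change: %s",
                 len(dropped), variable, list(dropped))
    return 100.0 * (v1.loc[paired] - v12.loc[paired]) / v1.loc[paired]


def _dichotomize(values: pd.Series, rule: str) -> pd.Series:
    """Map a continuous progression value to fast/slow classes."""
    if rule == "median":
        cut = values.median()
        return pd.Series(np.where(values >= cut, "fast", "slow"), index=values.index)
    if rule == "tertile":
        lo, hi = values.quantile([1 / 3, 2 / 3])
        out = pd.Series("mid", index=values.index)
        out[values <= lo] = "slow"
        out[values >= hi] = "fast"
        return out[out != "mid"]
    if rule.startswith("threshold:"):
        thr = float(rule.split(":", 1)[1])
        return pd.Series(np.where(values >= thr, "fast", "slow"), index=values.index)
    raise ValueError(f"unknown dichotomization rule {rule!r}")


def build_table(
    dataset: CohortDataset,
    level: str,
    response: str | tuple[str, str] = "arm",
    scaling: str = "unit_variance",
    dichotomize: str = "median",
    with_ratios: bool = True,
) -> FeatureTable:
    """Assemble the feature table for one modelling level.

    ``response`` is ``"arm"`` for treatment-group discrimination or a tuple
    ``(clinical_variable, kind)`` with kind ``"continuous"`` (percent loss) or
    ``"class"`` (dichotomised progression).  Classification tables require at
    least 3 samples per class.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    ds = impute_floor(dataset) if not dataset.imputed else dataset
    if with_ratios and dataset.panel.ratios:
        ds = add_ratios(ds)
    features = list(ds.concentrations.columns)

    if level in ("V1", "V12"):
        logged = log_transform(ds)
        block = logged.visit_view(level)
    else:
        v1 = ds.visit_view("V1")
        v12 = ds.visit_view("V12")
        paired = v1.index.intersection(v12.index)
        if len(paired) < len(v1):
            log.info("delta level: excluding %d subject(s) without V12",
                     len(v1) - len(paired))
        block = pd.DataFrame(
            percent_change(v1.loc[paired].to_numpy(), v12.loc[paired].to_numpy()),
            index=paired, columns=features,
        )

    arm = ds.arm_of()
    if response == "arm":
        y = arm.loc[block.index].to_numpy(dtype=object)
        y_kind, response_name = "class", "arm"
    else:
        var, kind = response
        if var not in CLINICAL_VARIABLES:
            raise ValueError(f"unknown clinical variable {var!r}")
        change = clinical_pct_change(ds, var)
        keep = block.index.intersection(change.index)
        block = block.loc[keep]
        change = change.loc[keep]
        if kind == "continuous":
            y = change.to_numpy(dtype=float)
            y_kind, response_name = "continuous", f"{var} % loss"
        elif kind == "class":
            cls = _dichotomize(change, dichotomize)
            block = block.loc[cls.index]
            y = cls.to_numpy(dtype=object)
            y_kind, response_name = "class", f"{var} progression class"
        else:
            raise ValueError(f"response kind must be continuous or class, got {kind!r}")

    if y_kind == "class":
        counts = pd.Series(y).value_counts()
        if len(counts) < 2 or counts.min() < 3:
            raise ValueError(
                f"need >= 3 samples per class, got {counts.to_dict()}"
            )

    X = block.to_numpy(dtype=float)
    means = sds = None
    if scaling == "unit_variance":
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        if (sds == 0).any():
            zero = [features[i] for i in np.flatnonzero(sds == 0)]
            raise ValueError(f"constant feature column(s): {zero[:5]}")
        X = (X - means) / sds
    elif scaling != "none":
        raise ValueError(f"unknown scaling {scaling!r}")

    return FeatureTable(
        X=X, features=features, y=y, level=level,
        sample_ids=[str(s) for s in block.index],
        response_name=response_name, y_kind=y_kind, scaling=scaling,
        column_means=means, column_sds=sds,
    )
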