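"""Study orchestration: discrimination, association, prediction, validation.

The three analysis objectives are:

1. treatment-group discrimination from the metabolome at V1, V12 and the
   V1-to-V12 percent change (OPLS-DA with low-VIP variable exclusion);
2. association between the percent-change metabolome and the concurrent
   percent change in each clinical progression variable, per arm (PLS);
3. prediction of dichotomised clinical progression from the V1 metabolome
   (OPLS-DA quality check, tiered signature selection, and an independent
   bootstrap validation on random train/test splits with a random forest).

Clinical changes use the percent-loss convention: positive = worsening.
Reports are plain dicts ready for JSON serialisation; Venn overlaps of
top-15 discriminant lists are emitted as region tables, not drawings.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import __version__
from .cohort import CLINICAL_VARIABLES, CohortDataset
from .preprocess import FeatureTable, build_table
from .pls import (
    ExclusionResult, evaluate_model, optimize_by_exclusion, top_discriminants,
)
from .signature import (
    SelectorConfig, TierResult, confusion_metrics, select_signature,
)

__all__ = [
    "StudyConfig", "BootstrapPerformance", "VennSummary",
    "run_group_discrimination", "run_progression_association",
    "run_progression_prediction", "bootstrap_validate", "venn_summary",
    "run_full_study",
]

LEVELS = ("V1", "V12", "delta_pct")
ARMS_EXTENDED = ("O", "P", "pooled")


@dataclass
class StudyConfig:
    """Knobs of the full analysis; defaults reproduce the standard workflow."""

    folds: int = 7
    fold_seed: int = 0
    q2_rule: str = "additive"
    patience: int = 5
    dichotomize: str = "median"
    n_splits: int = 1000
    test_fraction: float = 1 / 3
    rf_estimators: int = 100
    top_k: int = 15
    seed: int = 0
    selector: SelectorConfig = field(default_factory=SelectorConfig)


@dataclass
class BootstrapPerformance:
    """Per-split and median test-set performance over random splits."""

    n_splits: int
    seed: int
    model: str
    per_split: dict[str, np.ndarray]
    confusions: np.ndarray            # n_splits x (tp, fn, tn, fp)
    medians: dict[str, float]
    n_undefined: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_splits": self.n_splits, "seed": self.seed, "model": self.model,
            "medians": self.medians, "n_undefined": self.n_undefined,
        }


@dataclass
class VennSummary:
    """Exact region decomposition of 2-4 named feature sets."""

    set_names: list[str]
    regions: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {"sets": self.set_names, "regions": self.regions}


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _model_report(fit, quality, table: FeatureTable, top_k: int,
                  excluded: list[str] | None = None) -> dict:
    top = top_discriminants(fit, min(top_k, len(fit.features)))
    return {
        "level": table.level,
        "response": table.response_name,
        "direction_convention": "positive clinical change = worsening (% loss)",
        "n_samples": table.n_samples,
        "n_features": len(fit.features),
        "n_pred": fit.n_pred,
        "n_orth": fit.n_orth,
        "r2x_cum": round(quality.r2x_cum, 6),
        "r2y_cum": round(quality.r2y_cum, 6),
        "q2_cum": round(quality.q2_cum, 6),
        "cv_anova_F": round(quality.cv_anova_F, 6),
        "cv_anova_p": float(quality.cv_anova_p),
        "status": quality.status,
        "top15": top,
        "vip": {f: round(float(v), 6) for f, v in zip(fit.features, fit.vip)},
        "pcorr": {f: round(float(v), 6) for f, v in zip(fit.features, fit.pcorr)},
        "excluded": excluded or [],
    }


def run_group_discrimination(
    dataset: CohortDataset, level: str, config: StudyConfig | None = None
) -> dict:
    """OPLS-DA arm discrimination at one level, with variable exclusion."""
    cfg = config or StudyConfig()
    table = build_table(dataset, level, response="arm", dichotomize=cfg.dichotomize)
    res: ExclusionResult = optimize_by_exclusion(
        table, model="auto", patience=cfg.patience,
        folds=cfg.folds, fold_seed=cfg.fold_seed, q2_rule=cfg.q2_rule,
    )
    sub = table.select(res.features)
    return _model_report(res.fit, res.quality, sub, cfg.top_k, res.excluded)


def run_progression_association(
    dataset: CohortDataset, arm: str, clinical_var: str,
    config: StudyConfig | None = None,
) -> dict:
    """PLS of the percent-change metabolome against a clinical percent change."""
    cfg = config or StudyConfig()
    if clinical_var == "all":
        return {
            var: run_progression_association(dataset, arm, var, cfg)
            for var in CLINICAL_VARIABLES
        }
    ds = dataset if arm == "pooled" else dataset.subset_arm(arm)
    table = build_table(ds, "delta_pct", response=(clinical_var, "continuous"))
    fit, quality, _ = evaluate_model(
        table, model="pls", folds=cfg.folds, fold_seed=cfg.fold_seed,
        q2_rule=cfg.q2_rule,
    )
    report = _model_report(fit, quality, table, cfg.top_k)
    report["arm"] = arm
    return report


def run_progression_prediction(
    dataset: CohortDataset, arm: str, clinical_var: str,
    config: StudyConfig | None = None,
) -> dict:
    """Predict dichotomised progression from the V1 metabolome.

    Runs the OPLS-DA quality assessment, the tiered signature selector, and
    the independent bootstrap validation on the signature (tiers S and A
    pooled over classifiers; top-15 by VIP when the signature is empty).
    """
    cfg = config or StudyConfig()
    ds = dataset if arm == "pooled" else dataset.subset_arm(arm)
    table = build_table(
        ds, "V1", response=(clinical_var, "class"), dichotomize=cfg.dichotomize
    )
    fit, quality, _ = evaluate_model(
        table, model="auto", folds=cfg.folds, fold_seed=cfg.fold_seed,
        q2_rule=cfg.q2_rule,
    )
    report = _model_report(fit, quality, table, cfg.top_k)
    report["arm"] = arm

    tiers: TierResult = select_signature(table, cfg.selector)
    signature = sorted(tiers.union(("S", "A")))
    fallback = not signature
    features = signature or report["top15"]
    perf = bootstrap_validate(
        table, features, n_splits=cfg.n_splits, seed=cfg.seed,
        test_fraction=cfg.test_fraction, rf_estimators=cfg.rf_estimators,
    )
    return {
        "model": report,
        "tiers": tiers.tiers,
        "rounds_run": tiers.rounds_run,
        "signature": features,
        "signature_source": "top15_fallback" if fallback else "tiers_S_A",
        "bootstrap": perf.to_dict(),
        "_bootstrap_full": perf,
        "_tier_result": tiers,
    }


def _stratified_split(y01: np.ndarray, test_fraction: float, rng):
    te = []
    for c in (0, 1):
        idx = rng.permutation(np.flatnonzero(y01 == c))
        k = max(1, round(test_fraction * len(idx)))
        te.append(idx[:k])
    te = np.sort(np.concatenate(te))
    tr = np.setdiff1d(np.arange(len(y01)), te)
    return tr, te


def bootstrap_validate(
    table: FeatureTable,
    features: list[str],
    n_splits: int = 1000,
    seed: int = 0,
    test_fraction: float = 1 / 3,
    rf_estimators: int = 100,
    pos_label=None,
) -> BootstrapPerformance:
    """Random-forest validation over random stratified train/test splits.

    For each split a forest is fitted on the training samples restricted to
    ``features`` and the test-set confusion matrix is recorded; medians are
    taken per metric over the splits where it is defined.
    """
    if not features:
        raise ValueError("feature list is empty")
    sub = table.select(features)
    X = np.asarray(sub.X, dtype=float)
    classes = sorted(set(np.asarray(sub.y).tolist()))
    if len(classes) != 2:
        raise ValueError(f"need 2 classes, got {classes}")
    y01 = np.array([classes.index(v) for v in sub.y])
    counts = np.bincount(y01, minlength=2)
    if counts.min() < 3:
        raise ValueError("each class needs at least 3 members")
    pos = classes.index(pos_label) if pos_label is not None else 0

    rng = np.random.default_rng(seed)
    names = ("sensitivity", "specificity", "ppv", "npv")
    per_split = {k: np.empty(n_splits) for k in names}
    confusions = np.empty((n_splits, 4), dtype=int)
    for s in range(n_splits):
        tr, te = _stratified_split(y01, test_fraction, rng)
        clf = RandomForestClassifier(
            n_estimators=rf_estimators,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        ).fit(X[tr], y01[tr])
        pred = clf.predict(X[te])
        yte = y01[te]
        tp = int(((pred == pos) & (yte == pos)).sum())
        fn = int(((pred != pos) & (yte == pos)).sum())
        tn = int(((pred != pos) & (yte != pos)).sum())
        fp = int(((pred == pos) & (yte != pos)).sum())
        confusions[s] = (tp, fn, tn, fp)
        for k, v in confusion_metrics(tp, fn, tn, fp).items():
            per_split[k][s] = v
    medians, n_undef = {}, {}
    for k in names:
        arr = per_split[k]
        defined = arr[~np.isnan(arr)]
        medians[k] = float(np.median(defined)) if len(defined) else float("nan")
        n_undef[k] = int(np.isnan(arr).sum())
    return BootstrapPerformance(
        n_splits=n_splits, seed=seed, model="random_forest",
        per_split=per_split, confusions=confusions,
        medians=medians, n_undefined=n_undef,
    )


def venn_summary(named_sets: dict[str, list]) -> VennSummary:
    """Exact Venn region decomposition of 2-4 named sets (as a table)."""
    names = list(named_sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("venn_summary takes 2 to 4 sets")
    sets = {n: set(v) for n, v in named_sets.items()}
    for n, s in sets.items():
        if len(s) > 15:
            raise ValueError(f"set {n!r} has more than 15 members")
    regions: dict[str, list[str]] = {}
    for r in range(1, len(names) + 1):
        for included in itertools.combinations(names, r):
            inc = set.intersection(*(sets[n] for n in included))
            exc = set().union(*(sets[n] for n in names if n not in included), set())
            regions["&".join(included)] = sorted(inc - exc)
    return VennSummary(set_names=names, regions=regions)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not serialisable: {type(o)}")


def run_full_study(
    dataset: CohortDataset,
    config: StudyConfig | None = None,
    out_dir=None,
) -> dict:
    """All three objectives end to end; individual model failures are
    recorded in the bundle rather than aborting the run."""
    cfg = config or StudyConfig()
    bundle: dict = {"discrimination": {}, "association": {}, "prediction": {},
                    "venn": {}, "errors": []}

    def _attempt(key_path, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - recorded, not silenced
            bundle["errors"].append({"model": key_path, "error": str(exc)})
            return None

    for level in LEVELS:
        rep = _attempt(f"discrimination/{level}",
                       lambda lv=level: run_group_discrimination(dataset, lv, cfg))
        if rep is not None:
            bundle["discrimination"][level] = rep
    disc_tops = {
        lv: rep["top15"] for lv, rep in bundle["discrimination"].items()
    }
    if len(disc_tops) >= 2:
        bundle["venn"]["discrimination"] = venn_summary(disc_tops).to_dict()

    for arm in ("O", "P"):
        for var in CLINICAL_VARIABLES:
            rep = _attempt(
                f"association/{arm}/{var}",
                lambda a=arm, v=var: run_progression_association(dataset, a, v, cfg),
            )
            if rep is not None:
                bundle["association"][f"{arm}/{var}"] = rep
        tops = {
            var: bundle["association"][f"{arm}/{var}"]["top15"]
            for var in CLINICAL_VARIABLES
            if f"{arm}/{var}" in bundle["association"]
        }
        if len(tops) >= 2:
            bundle["venn"][f"association_{arm}"] = venn_summary(tops).to_dict()

    for arm in ARMS_EXTENDED:
        for var in CLINICAL_VARIABLES:
            rep = _attempt(
                f"prediction/{arm}/{var}",
                lambda a=arm, v=var: run_progression_prediction(dataset, a, v, cfg),
            )
            if rep is not None:
                rep = {k: v for k, v in rep.items() if not k.startswith("_")}
                bundle["prediction"][f"{arm}/{var}"] = rep

    cfg_dict = asdict(cfg)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=_json_default)
    bundle["manifest"] = {
        "package": "metabosig",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_models": (len(bundle["discrimination"]) + len(bundle["association"])
                     + len(bundle["prediction"])),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "reports.json").write_text(
            json.dumps(bundle, indent=2, default=_json_default, allow_nan=True)
        )
        rows = []
        for section in ("discrimination", "association"):
            for key, rep in bundle[section].items():
                rows.append({"model": f"{section}/{key}", "status": rep["status"],
                             "top15": ";".join(rep["top15"])})
        for key, rep in bundle["prediction"].items():
            rows.append({"model": f"prediction/{key}",
                         "status": rep["model"]["status"],
                         "top15": ";".join(rep["model"]["top15"])})
        pd.DataFrame(rows).to_csv(out / "top15.csv", index=False)
        tier_rows = []
        for key, rep in bundle["prediction"].items():
            for clf, fmap in rep["tiers"].items():
                for feat, tier in fmap.items():
                    if tier != "none":
                        tier_rows.append({"model": key, "classifier": clf,
                                          "feature": feat, "tier": tier})
        pd.DataFrame(tier_rows).to_csv(out / "tiers.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps(bundle["manifest"], indent=2, default=_json_default)
        )
    return bundle
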