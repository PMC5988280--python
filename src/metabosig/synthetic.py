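"""Synthetic two-arm, two-visit metabolomics cohorts with known ground truth.

The generator emulates the structure of a placebo-controlled trial cohort:
38 treated (arm O) and 36 placebo (arm P) subjects, each sampled at one month
(V1) and twelve months (V12), profiled on the default 188-metabolite panel.

Concentrations follow a log-normal model around class-typical plasma medians
(amino acids tens of uM, sphingomyelins/phosphatidylcholines single- to
double-digit uM, hexose ~5 mM).  Treatment is encoded as a log-scale shift of
designated metabolites in arm O, present at both visits.  A latent per-subject
progression rate drives both the twelve-month clinical declines (ALSFRS-r,
SVC, MMT, BMI) and V12 log-shifts of designated sphingomyelin progression
markers, so that downstream models have a recoverable signal with a recorded
ground truth.  Values below a per-metabolite detection floor are reported as
0 at approximately ``missing_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortDataset
from .panel import MetabolitePanel, default_panel

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "clinical_baselines",
    "generate_cohort",
    "metabolite_medians",
]

# Baseline clinical distributions per arm: variable -> {arm: (mean, sd)}.
# These are the one-month (V1) characteristics of the emulated trial cohort.
_BASELINES = {
    "ALSFRS-r": {"O": (39.5, 5.2), "P": (38.5, 6.1)},
    "SVC": {"O": (93.6, 13.9), "P": (94.4, 14.6)},
    "MMT": {"O": (130.4, 15.9), "P": (126.5, 22.4)},
    "BMI": {"O": (25.8, 3.2), "P": (24.3, 4.0)},
    "age_onset": {"O": (53.6, 11.5), "P": (50.2, 11.7)},
}
# Twelve-month percent declines (positive = worsening), pooled across arms;
# trial-typical magnitudes for a one-year observation window.
_DECLINES = {
    "ALSFRS-r": (21.0, 15.0),
    "SVC": (20.0, 25.0),
    "MMT": (21.0, 18.0),
    "BMI": (2.2, 6.7),
}
#: correlation between the shared latent progression rate and each clinical decline
_LATENT_RHO = 0.8
_MALE_FRACTION = {"O": 0.684, "P": 0.694}
_BULBAR_FRACTION = {"O": 0.13, "P": 0.19}

# Class-typical plasma medians (uM) and log-scale within-class spread.
_CLASS_MEDIANS = {
    "acylcarnitine": 0.25,
    "amino_acid": 80.0,
    "biogenic_amine": 1.0,
    "hexose": 5000.0,
    "lysoPC": 30.0,
    "PC_aa": 20.0,
    "PC_ae": 2.5,
    "SM": 60.0,
    "SM_OH": 8.0,
}
_CLASS_SPREAD = 0.9
_MEDIAN_SEED = 20180605  # fixed: medians are part of the panel definition, not the draw


def clinical_baselines() -> dict[str, dict[str, tuple[float, float]]]:
    """Baseline (mean, sd) per clinical variable and arm used by the generator."""
    return {var: dict(arms) for var, arms in _BASELINES.items()}


def metabolite_medians(panel: MetabolitePanel) -> pd.Series:
    """Deterministic class-typical median concentration (uM) per metabolite."""
    rng = np.random.default_rng(_MEDIAN_SEED)
    med = {}
    for m in panel.metabolites:
        base = _CLASS_MEDIANS[m.chem_class]
        if m.chem_class == "hexose":
            med[m.name] = base
        else:
            med[m.name] = base * float(np.exp(_CLASS_SPREAD * rng.standard_normal()))
    return pd.Series(med)


@dataclass
class SyntheticSpec:
    """Parameters of the generated cohort.

    Effect sizes are in units of the log-scale noise SD; ``arm_effect`` shifts
    are applied to arm O at both visits, ``progression_markers`` couple the
    V12 shift of a metabolite to the latent progression rate.
    """

    n_O: int = 38
    n_P: int = 36
    seed: int = 0
    arm_effect: dict[str, float] = field(default_factory=lambda: {
        "Gly": -0.8, "Kynurenine": +0.8, "Cit": -0.5, "Arg": +0.5,
    })
    progression_markers: dict[str, float] = field(default_factory=lambda: {
        "SM C24:1": 0.7, "SM OH C22:2": 0.7, "SM C16:1": 0.5,
    })
    noise_sd: float = 0.35
    decline_mean: float = 20.0
    decline_sd: float = 15.0
    missing_rate: float = 0.01
    censor_deaths: bool = False

    def __post_init__(self) -> None:
        if self.n_O < 4 or self.n_P < 4:
            raise ValueError("need at least 4 subjects per arm")
        if not 0 <= self.missing_rate < 0.2:
            raise ValueError("missing_rate must be in [0, 0.2)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """What the generator planted: discriminant sets and the latent rates."""

    arm_discriminants: set[str]
    progression_discriminants: set[str]
    latent_progression: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "arm_discriminants": sorted(self.arm_discriminants),
            "progression_discriminants": sorted(self.progression_discriminants),
            "latent_progression": self.latent_progression,
        }


def _draw_baseline(rng, mean, sd, n, lo=None, hi=None):
    x = mean + sd * rng.standard_normal(n)
    if lo is not None or hi is not None:
        x = np.clip(x, lo, hi)
    return x


def generate_cohort(
    spec: SyntheticSpec, panel: MetabolitePanel | None = None
) -> tuple[CohortDataset, GroundTruth]:
    """Generate a cohort; identical spec (incl. seed) gives an identical dataset."""
    panel = panel or default_panel()
    names = panel.names
    unknown = (set(spec.arm_effect) | set(spec.progression_markers)) - set(names)
    if unknown:
        raise ValueError(f"effect metabolites not in panel: {sorted(unknown)}")

    rng = np.random.default_rng(spec.seed)
    medians = metabolite_medians(panel).loc[names]
    log_med = np.log(medians.to_numpy())
    p = len(names)

    subjects = [f"O{i + 1:02d}" for i in range(spec.n_O)] + [
        f"P{i + 1:02d}" for i in range(spec.n_P)
    ]
    arms = ["O"] * spec.n_O + ["P"] * spec.n_P
    n = len(subjects)

    # latent progression rate (percent decline scale) via standard-normal z
    z = rng.standard_normal(n)
    latent = spec.decline_mean + spec.decline_sd * z

    arm_shift = np.zeros(p)
    for met, eff in spec.arm_effect.items():
        arm_shift[names.index(met)] = eff * spec.noise_sd
    coupling = np.zeros(p)
    for met, c in spec.progression_markers.items():
        coupling[names.index(met)] = c * spec.noise_sd

    # between-subject and within-subject (visit) variance split of noise_sd^2
    sd_between = spec.noise_sd * np.sqrt(0.7)
    sd_within = spec.noise_sd * np.sqrt(0.3)
    subj_dev = sd_between * rng.standard_normal((n, p))
    e_v1 = sd_within * rng.standard_normal((n, p))
    e_v12 = sd_within * rng.standard_normal((n, p))

    is_o = (np.array(arms) == "O").astype(float)[:, None]
    # progression markers enter twice: a subject-level baseline component
    # (fast progressors differ already at V1, making early prediction
    # possible) and an additional V12 shift (the marker tracks progression,
    # driving the percent-change association)
    base = log_med[None, :] + subj_dev + is_o * arm_shift[None, :] \
        + np.outer(z, coupling)
    log_v1 = base + e_v1
    log_v12 = base + e_v12 + np.outer(z, coupling)
    conc_v1 = np.exp(log_v1)
    conc_v12 = np.exp(log_v12)

    if spec.missing_rate > 0:
        floor = medians.to_numpy() * np.exp(
            spec.noise_sd * stats.norm.ppf(spec.missing_rate)
        )
        conc_v1 = np.where(conc_v1 < floor[None, :], 0.0, conc_v1)
        conc_v12 = np.where(conc_v12 < floor[None, :], 0.0, conc_v12)

    # clinical tables -------------------------------------------------------
    arm_arr = np.array(arms)
    v1_clin = {}
    for var in ("ALSFRS-r", "SVC", "MMT", "BMI"):
        vals = np.empty(n)
        for arm in ("O", "P"):
            mask = arm_arr == arm
            mean, sd = _BASELINES[var][arm]
            vals[mask] = _draw_baseline(rng, mean, sd, int(mask.sum()))
        v1_clin[var] = vals
    v1_clin["ALSFRS-r"] = np.clip(np.rint(v1_clin["ALSFRS-r"]), 0, 48)
    v1_clin["SVC"] = np.clip(v1_clin["SVC"], 20.0, None)
    v1_clin["MMT"] = np.clip(v1_clin["MMT"], 20.0, None)
    v1_clin["BMI"] = np.clip(v1_clin["BMI"], 14.0, None)

    age = np.empty(n)
    gender = np.empty(n, dtype=object)
    onset = np.empty(n, dtype=object)
    for arm in ("O", "P"):
        mask = arm_arr == arm
        k = int(mask.sum())
        mean, sd = _BASELINES["age_onset"][arm]
        age[mask] = np.clip(mean + sd * rng.standard_normal(k), 18.0, 90.0)
        gender[mask] = np.where(rng.random(k) < _MALE_FRACTION[arm], "M", "F")
        onset[mask] = np.where(rng.random(k) < _BULBAR_FRACTION[arm], "bulbar", "spinal")

    # percent declines, correlated with the latent rate; positive = worsening
    pct = {}
    for var, (m_v, s_v) in _DECLINES.items():
        eps = rng.standard_normal(n)
        pct[var] = m_v + s_v * (
            _LATENT_RHO * z + np.sqrt(1.0 - _LATENT_RHO**2) * eps
        )

    v12_clin = {
        "ALSFRS-r": np.clip(
            np.rint(v1_clin["ALSFRS-r"] * (1 - pct["ALSFRS-r"] / 100.0)), 0, 48
        ),
        "SVC": np.clip(v1_clin["SVC"] * (1 - pct["SVC"] / 100.0), 5.0, None),
        "MMT": np.clip(v1_clin["MMT"] * (1 - pct["MMT"] / 100.0), 5.0, None),
        "BMI": np.clip(v1_clin["BMI"] * (1 - pct["BMI"] / 100.0), 12.0, None),
    }

    died = np.zeros(n, dtype=bool)
    if spec.censor_deaths:
        svc_pct = pct["SVC"]
        cut = np.quantile(svc_pct, 0.9)
        died = svc_pct >= cut

    def _clin_frame(visit, clin_vals):
        return pd.DataFrame({
            "arm": arm_arr,
            "alsfrs_r": clin_vals["ALSFRS-r"].astype(int),
            "svc": clin_vals["SVC"],
            "mmt": clin_vals["MMT"],
            "bmi": clin_vals["BMI"],
            "gender": gender,
            "onset_site": onset,
            "age_onset": age,
            "died_before_v12": died,
        }, index=pd.MultiIndex.from_arrays(
            [subjects, [visit] * n], names=["subject_id", "visit"]
        ))

    conc_rows, clin_rows = [], []
    for i, sid in enumerate(subjects):
        conc_rows.append((sid, "V1", conc_v1[i]))
        if not died[i]:
            conc_rows.append((sid, "V12", conc_v12[i]))
    conc_index = pd.MultiIndex.from_arrays(
        [[r[0] for r in conc_rows], [r[1] for r in conc_rows]],
        names=["subject_id", "visit"],
    )
    conc = pd.DataFrame(
        np.vstack([r[2] for r in conc_rows]), index=conc_index, columns=names
    )
    clin_v1 = _clin_frame("V1", v1_clin)
    clin_v12 = _clin_frame("V12", v12_clin).loc[[s for i, s in enumerate(subjects) if not died[i]]]
    clin = pd.concat([clin_v1, clin_v12]).loc[conc_index]

    dataset = CohortDataset(panel, conc, clin)
    truth = GroundTruth(
        arm_discriminants=set(spec.arm_effect),
        progression_discriminants=set(spec.progression_markers),
        latent_progression={s: float(v) for s, v in zip(subjects, latent)},
    )
    return dataset, truth
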