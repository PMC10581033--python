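"""Parameter containers, validation, and (de)serialization.

Every tunable quantity of the simulator lives in one of the frozen
dataclasses below.  Each class knows how to validate itself
(:meth:`validate`, raising :class:`ConfigError`) and how to round-trip
through plain dictionaries (``to_dict`` / ``from_dict``) so that a whole
bundle can be written to YAML/CSV and read back bit-identically.

Units are years for ages and durations, millimetres for lesion sizes,
and a single currency-year (2022 USD in the shipped defaults) for costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

LOCATIONS = ("rectum", "distal_colon", "proximal_colon")
SITES = ("colon", "rectum")  # survival granularity
STAGES = (1, 2, 3, 4)
MODALITIES = ("colonoscopy", "mt_sdna", "fit")
ARMS = MODALITIES + ("unscreened",)
STOOL_MODALITIES = ("mt_sdna", "fit")
SIZE_CATEGORIES = ("adenoma_le5mm", "adenoma_6_9mm", "adenoma_ge10mm", "crc")
COMPLICATION_TYPES = ("bleeding", "perforation", "other")
PHASES = ("initial", "continuous", "terminal")


class ConfigError(ValueError):
    """Raised when a parameter set fails schema or invariant validation."""


def site_of(location: str) -> str:
    """Collapse the three lesion locations to the colon/rectum survival site."""
    if location == "rectum":
        return "rectum"
    if location in ("distal_colon", "proximal_colon"):
        return "colon"
    raise ConfigError(f"unknown lesion location {location!r}")


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


def _finite(x) -> bool:
    return bool(np.all(np.isfinite(x)))


@dataclass(frozen=True)
class LifeTable:
    """Annual probabilities of death from causes other than colorectal cancer.

    ``ages`` are consecutive integers; the final age must carry probability 1
    for both sexes so every simulated life terminates.
    """

    ages: tuple[int, ...]
    q_female: tuple[float, ...]
    q_male: tuple[float, ...]

    def validate(self) -> None:
        ages = np.asarray(self.ages)
        _check(len(ages) > 0, "life table is empty")
        _check(np.all(np.diff(ages) == 1), "life table has a gap in ages")
        for name, q in (("female", self.q_female), ("male", self.q_male)):
            qa = np.asarray(q, dtype=float)
            _check(len(qa) == len(ages), f"life table {name} column length mismatch")
            _check(_finite(qa) and np.all((qa >= 0) & (qa <= 1)),
                   f"life table {name} probabilities outside [0,1]")
            _check(qa[-1] == 1.0, f"life table {name} final age must have q=1")

    def q(self, sex: str) -> np.ndarray:
        return np.asarray(self.q_male if sex == "male" else self.q_female, dtype=float)

    # -- closed-form moments (used by callers and tests alike) -------------
    def expected_death_age(self, sex: str, start_age: int = 0) -> float:
        """E[death age | alive at start_age] under mid-year placement of deaths."""
        ages = np.asarray(self.ages)
        mask = ages >= start_age
        q = self.q(sex)[mask]
        a = ages[mask]
        surv = np.concatenate([[1.0], np.cumprod(1.0 - q)])[:-1]
        pdeath = surv * q
        pdeath = pdeath / pdeath.sum()  # guard: q[-1]==1 makes the sum 1 already
        return float(np.sum(pdeath * (a + 0.5)))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex, col in (("female", self.q_female), ("male", self.q_male)):
            for a, q in zip(self.ages, col):
                rows.append({"age": a, "sex": sex, "annual_death_probability": q})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        need = {"age", "sex", "annual_death_probability"}
        _check(need.issubset(df.columns), f"life table CSV must have columns {sorted(need)}")
        out = {}
        for sex, grp in df.groupby("sex"):
            grp = grp.sort_values("age")
            out[sex] = (tuple(int(a) for a in grp["age"]),
                        tuple(float(q) for q in grp["annual_death_probability"]))
        _check(set(out) == {"female", "male"}, "life table needs both sexes")
        _check(out["female"][0] == out["male"][0], "sexes cover different ages")
        lt = cls(ages=out["female"][0], q_female=out["female"][1], q_male=out["male"][1])
        lt.validate()
        return lt


@dataclass(frozen=True)
class NaturalHistoryParams:
    """Parameters of the adenoma–carcinoma natural-history model.

    Adenoma onset is a non-homogeneous Poisson process with log-intensity
    ``baseline_log_onset_rate + sex_effect_male·[male] + age_effect(age)``
    multiplied by a person-level log-normal frailty.  ``age_band_edges``
    are the breakpoints of the piecewise-constant age effect; band *i*
    covers ``[edge_i, edge_{i+1})`` with the last band open-ended.
    """

    baseline_log_onset_rate: float
    sex_effect_male: float
    age_band_edges: tuple[float, ...]
    age_band_effects: tuple[float, ...]
    frailty_sd: float
    location_probs: Mapping[str, float]
    # time from onset (1 mm) to 10 mm: Frechet (inverse-Weibull) per location
    growth_frechet: Mapping[str, Mapping[str, float]]  # {loc: {shape, scale}}
    initial_diameter_mm: float
    max_diameter_mm: float
    # annual adenoma -> preclinical-cancer transition probability (logistic)
    transition_intercept: float
    transition_per_mm: float
    transition_per_year_age: float
    transition_male: float
    # preclinical sojourn: log-normal per site
    sojourn_lognormal: Mapping[str, Mapping[str, float]]  # {site: {mu, sigma}}
    # stage (I-IV) at symptomatic presentation
    stage_probs: tuple[float, float, float, float]
    # CRC survival: Weibull, shared shape, per-stage scale with AFT modifiers
    survival_shape: float
    survival_scale_by_stage: tuple[float, float, float, float]
    survival_scale_male: float
    survival_scale_rectum: float
    survival_age_coef: float  # scale *= exp(-coef*(age_dx - 65))
    max_age: float = 110.0

    def validate(self) -> None:
        _check(_finite([self.baseline_log_onset_rate, self.sex_effect_male,
                        self.frailty_sd]), "non-finite onset parameters")
        _check(self.frailty_sd >= 0, "frailty_sd must be non-negative")
        _check(len(self.age_band_effects) == len(self.age_band_edges),
               "need one age effect per age band edge")
        _check(tuple(self.age_band_edges) == tuple(sorted(self.age_band_edges)),
               "age band edges must be sorted")
        _check(set(self.location_probs) == set(LOCATIONS),
               f"location_probs must cover {LOCATIONS}")
        lp = np.array([self.location_probs[l] for l in LOCATIONS], dtype=float)
        _check(np.all(lp >= 0) and abs(lp.sum() - 1) < 1e-9,
               "location probabilities must be non-negative and sum to 1")
        for loc in LOCATIONS:
            g = self.growth_frechet[loc]
            _check(g["shape"] > 0 and g["scale"] > 0,
                   f"growth parameters for {loc} must be positive")
        _check(0 < self.initial_diameter_mm < 10 < self.max_diameter_mm,
               "diameters must satisfy 0 < initial < 10 < max")
        for s in SITES:
            sj = self.sojourn_lognormal[s]
            _check(sj["sigma"] >= 0 and _finite([sj["mu"], sj["sigma"]]),
                   f"sojourn parameters for {s} invalid")
        sp = np.asarray(self.stage_probs, dtype=float)
        _check(len(sp) == 4 and np.all(sp >= 0) and abs(sp.sum() - 1) < 1e-9,
               "stage probabilities must be a length-4 simplex")
        _check(self.survival_shape > 0, "survival shape must be positive")
        _check(all(s > 0 for s in self.survival_scale_by_stage),
               "survival scales must be positive")
        _check(self.survival_scale_male > 0 and self.survival_scale_rectum > 0,
               "survival scale multipliers must be positive")
        _check(self.max_age > 0, "max_age must be positive")

    def onset_log_rate(self, age: float, sex: str) -> float:
        idx = int(np.searchsorted(self.age_band_edges, age, side="right")) - 1
        eff = self.age_band_effects[idx] if idx >= 0 else -np.inf
        return (self.baseline_log_onset_rate
                + (self.sex_effect_male if sex == "male" else 0.0) + eff)

    def transition_annual_prob(self, size_mm: float, age: float, sex: str) -> float:
        from scipy.special import expit
        z = (self.transition_intercept + self.transition_per_mm * size_mm
             + self.transition_per_year_age * (age - 65.0)
             + (self.transition_male if sex == "male" else 0.0))
        return float(expit(z))

    def survival_scale(self, stage: int, site: str, sex: str, age_dx: float) -> float:
        scale = self.survival_scale_by_stage[stage - 1]
        if sex == "male":
            scale *= self.survival_scale_male
        if site == "rectum":
            scale *= self.survival_scale_rectum
        scale *= float(np.exp(-self.survival_age_coef * (age_dx - 65.0)))
        return scale


@dataclass(frozen=True)
class ScreeningStrategy:
    """Periodic screening schedule: ``modality`` every ``interval`` years."""

    modality: str  # colonoscopy | mt_sdna | fit | none
    interval: float
    start_age: float
    stop_age: float

    def validate(self) -> None:
        _check(self.modality in MODALITIES + ("none",),
               f"unknown modality {self.modality!r}")
        _check(self.interval > 0, "screening interval must be positive")
        _check(self.start_age <= self.stop_age, "start_age must be <= stop_age")


@dataclass(frozen=True)
class TestPerformance:
    """Per-application sensitivity/specificity of one screening test.

    Sensitivity is indexed by the most advanced lesion category present;
    ``reach`` is the probability that a colonoscope visualises a given
    lesion's segment (1.0 for stool tests, which sample the whole colon).
    """

    __test__ = False  # the name looks like a test class to pytest; it is not

    sensitivity: Mapping[str, float]  # keys = SIZE_CATEGORIES
    specificity: float
    reach: float = 1.0

    def validate(self) -> None:
        _check(set(self.sensitivity) == set(SIZE_CATEGORIES),
               f"sensitivity must cover {SIZE_CATEGORIES}")
        for k, v in self.sensitivity.items():
            _check(0 <= v <= 1, f"sensitivity[{k}] outside [0,1]")
        _check(0 <= self.specificity <= 1, "specificity outside [0,1]")
        _check(0 <= self.reach <= 1, "reach outside [0,1]")

    def size_category(self, size_mm: float) -> str:
        if size_mm < 5.5:
            return "adenoma_le5mm"
        if size_mm < 9.5:
            return "adenoma_6_9mm"
        return "adenoma_ge10mm"


@dataclass(frozen=True)
class AdherenceModel:
    """Adherence to initial screening rounds and to follow-up colonoscopy."""

    initial_adherence: float = 1.0
    followup_colonoscopy_adherence: Mapping[str, float] = field(
        default_factory=lambda: {"mt_sdna": 1.0, "fit": 1.0})

    def validate(self) -> None:
        _check(0 <= self.initial_adherence <= 1, "initial adherence outside [0,1]")
        for m, v in self.followup_colonoscopy_adherence.items():
            _check(m in STOOL_MODALITIES, f"follow-up adherence for non-stool modality {m!r}")
            _check(0 <= v <= 1, f"follow-up adherence[{m}] outside [0,1]")


@dataclass(frozen=True)
class ComplicationModel:
    """Colonoscopy complication probabilities, conditional on polypectomy."""

    prob_without_polypectomy: Mapping[str, float]
    prob_with_polypectomy: Mapping[str, float]
    fatality: Mapping[str, float]

    def validate(self) -> None:
        for name, m in (("without", self.prob_without_polypectomy),
                        ("with", self.prob_with_polypectomy)):
            _check(set(m) == set(COMPLICATION_TYPES),
                   f"complication probs ({name} polypectomy) must cover {COMPLICATION_TYPES}")
            total = sum(m.values())
            _check(all(0 <= v <= 1 for v in m.values()) and total <= 1,
                   f"complication probs ({name}) invalid")
        _check(set(self.fatality) == set(COMPLICATION_TYPES)
               and all(0 <= v <= 1 for v in self.fatality.values()),
               "complication fatality probabilities invalid")

    def without_fatalities(self) -> "ComplicationModel":
        return ComplicationModel(self.prob_without_polypectomy,
                                 self.prob_with_polypectomy,
                                 {k: 0.0 for k in self.fatality})


@dataclass(frozen=True)
class SurveillancePolicy:
    """Post-colonoscopy interval to the next colonoscopy, by findings.

    Categories: ``none`` (no adenoma found), ``low_risk`` (1-2 small
    adenomas), ``high_risk`` (>=3 adenomas or any >=10 mm).  After any
    completed colonoscopy the person follows these intervals; routine
    stool testing does not resume.
    """

    interval_by_findings: Mapping[str, float] = field(
        default_factory=lambda: {"none": 10.0, "low_risk": 5.0, "high_risk": 3.0})
    stop_age: float = 85.0
    enabled: bool = True

    def validate(self) -> None:
        _check(set(self.interval_by_findings) == {"none", "low_risk", "high_risk"},
               "surveillance intervals must cover none/low_risk/high_risk")
        _check(all(v > 0 for v in self.interval_by_findings.values()),
               "surveillance intervals must be positive")


@dataclass(frozen=True)
class CostInputs:
    """Unit costs in one currency-year (defaults: 2022 USD, Medicare-style)."""

    stool_test_cost: Mapping[str, float]  # per stool modality
    colonoscopy_cost: float
    colonoscopy_with_polypectomy_cost: float
    complication_cost: Mapping[str, float]
    crc_care_cost: Mapping[int, Mapping[str, float]]  # stage -> phase -> USD
    currency_year: int = 2022

    def validate(self) -> None:
        for m, v in self.stool_test_cost.items():
            _check(m in STOOL_MODALITIES and v >= 0, f"bad stool test cost for {m!r}")
        _check(self.colonoscopy_cost >= 0
               and self.colonoscopy_with_polypectomy_cost >= 0,
               "colonoscopy costs must be non-negative")
        _check(set(self.complication_cost) == set(COMPLICATION_TYPES)
               and all(v >= 0 for v in self.complication_cost.values()),
               "complication costs invalid")
        _check(set(self.crc_care_cost) == set(STAGES), "CRC care costs must cover stages I-IV")
        for st in STAGES:
            m = self.crc_care_cost[st]
            _check(set(m) == set(PHASES) and all(v >= 0 for v in m.values()),
                   f"CRC care costs for stage {st} invalid")

    def scaled(self, factor: float) -> "CostInputs":
        return CostInputs(
            stool_test_cost={k: v * factor for k, v in self.stool_test_cost.items()},
            colonoscopy_cost=self.colonoscopy_cost * factor,
            colonoscopy_with_polypectomy_cost=self.colonoscopy_with_polypectomy_cost * factor,
            complication_cost={k: v * factor for k, v in self.complication_cost.items()},
            crc_care_cost={s: {p: v * factor for p, v in m.items()}
                           for s, m in self.crc_care_cost.items()},
            currency_year=self.currency_year)


@dataclass(frozen=True)
class UtilityInputs:
    """Health-state utilities: age-band baseline minus care-phase disutility."""

    utility_band_edges: tuple[float, ...]  # band i covers [edge_i, edge_{i+1})
    utility_by_band: tuple[float, ...]
    disutility: Mapping[int, Mapping[str, float]]  # stage -> phase -> decrement
    screening_disutility: float = 0.0

    def validate(self) -> None:
        _check(len(self.utility_by_band) == len(self.utility_band_edges),
               "need one utility per age band")
        _check(all(0 <= u <= 1 for u in self.utility_by_band), "utilities outside [0,1]")
        _check(set(self.disutility) == set(STAGES), "disutility must cover stages I-IV")
        for st in STAGES:
            m = self.disutility[st]
            _check(set(m) == set(PHASES) and all(v >= 0 for v in m.values()),
                   f"disutility for stage {st} invalid")
        _check(self.screening_disutility >= 0, "screening disutility must be >= 0")

    def baseline(self, age: float) -> float:
        idx = int(np.searchsorted(self.utility_band_edges, age, side="right")) - 1
        return self.utility_by_band[max(idx, 0)]


@dataclass(frozen=True)
class DiscountingPolicy:
    """Annual discount rates; everything is discounted to ``reference_age``."""

    annual_rate_costs: float = 0.03
    annual_rate_qalys: float = 0.03
    reference_age: float = 65.0

    def validate(self) -> None:
        _check(self.annual_rate_costs >= 0 and self.annual_rate_qalys >= 0,
               "discount rates must be non-negative")

    def cost_factor(self, age: float) -> float:
        return (1.0 + self.annual_rate_costs) ** (-(age - self.reference_age))

    def qaly_factor(self, age: float) -> float:
        return (1.0 + self.annual_rate_qalys) ** (-(age - self.reference_age))


@dataclass(frozen=True)
class ModalityMix:
    """Population weights over colonoscopy / mt-sDNA / FIT / unscreened."""

    weights: Mapping[str, float]

    def validate(self) -> None:
        _check(set(self.weights) == set(ARMS), f"mix must cover {ARMS}")
        w = np.array([self.weights[a] for a in ARMS], dtype=float)
        _check(np.all(w >= -1e-15), "mix weights must be non-negative")
        _check(abs(w.sum() - 1.0) <= 1e-12, "mix weights must sum to 1")

    def __getitem__(self, arm: str) -> float:
        return float(self.weights[arm])


# ---------------------------------------------------------------------------
# dict round-tripping for YAML serialization
# ---------------------------------------------------------------------------

def _plain(obj):
    if isinstance(obj, Mapping):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def to_dict(obj) -> dict:
    return {f.name: _plain(getattr(obj, f.name)) for f in fields(obj)}


_TUPLE_FIELDS = {
    "age_band_edges", "age_band_effects", "stage_probs",
    "survival_scale_by_stage", "utility_band_edges", "utility_by_band",
    "ages", "q_female", "q_male",
}
_INT_KEY_FIELDS = {"crc_care_cost", "disutility"}


def from_dict(cls, d: Mapping):
    """Rebuild a parameter dataclass from a plain dict (e.g. parsed YAML)."""
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    _check(not unknown, f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for k, v in d.items():
        if k in _TUPLE_FIELDS and isinstance(v, Sequence):
            v = tuple(v)
        if k in _INT_KEY_FIELDS and isinstance(v, Mapping):
            v = {int(s): dict(m) for s, m in v.items()}
        kwargs[k] = v
    obj = cls(**kwargs)
    obj.validate()
    return obj
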