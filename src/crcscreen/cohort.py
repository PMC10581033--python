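"""Synthetic fixtures and cohort generation.

Everything the pipeline needs is built here without downloads: a default
natural-history parameter set, a synthetic life table, stool-test and
colonoscopy performance fixtures, cost/utility schedules, the base-case
modality mix and follow-up adherence, and seeded cohort draws.

Base-case utilization weights (45.3% colonoscopy, 10.7% mt-sDNA, 13.7%
FIT, 30.3% unscreened) and follow-up colonoscopy adherence (71.5% after
a positive mt-sDNA, 46.7% after a positive FIT) are real-world figures
for a U.S. Medicare-age population.  All other defaults are documented,
order-of-magnitude-plausible values: reproducing any published model's
headline numbers requires supplying that model's calibrated parameter
files through the same configuration interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
import yaml

from . import params as P
from .natural_history import (Person, generate_latent_history, person_rng,
                              resolve_unscreened)

__all__ = ["FixtureBundle", "CalibrationTargets", "default_life_table",
           "default_bundle", "write_bundle", "read_bundle",
           "generate_cohort", "iter_cohort", "smoke_calibration",
           "targets_from_sim"]

ENTRY_AGE = 65
_MAX_REJECT_ATTEMPTS = 200


@dataclass(frozen=True)
class FixtureBundle:
    """All inputs consumed by the simulation pipeline."""

    nh_params: P.NaturalHistoryParams
    life_table: P.LifeTable
    performance: dict  # modality -> TestPerformance (incl. 'colonoscopy')
    adherence: P.AdherenceModel
    complications: P.ComplicationModel
    surveillance: P.SurveillancePolicy
    strategies: dict  # modality -> ScreeningStrategy
    costs: P.CostInputs
    utilities: P.UtilityInputs
    discounting: P.DiscountingPolicy
    base_mix: P.ModalityMix
    shift_split_mt_sdna: float = 0.44
    entry_age: int = ENTRY_AGE

    def validate(self) -> None:
        self.nh_params.validate()
        self.life_table.validate()
        for m in ("colonoscopy", "mt_sdna", "fit"):
            self.performance[m].validate()
        self.adherence.validate()
        self.complications.validate()
        self.surveillance.validate()
        for s in self.strategies.values():
            s.validate()
        self.costs.validate()
        self.utilities.validate()
        self.discounting.validate()
        self.base_mix.validate()


@dataclass(frozen=True)
class CalibrationTargets:
    """Smoke-test targets for the unscreened natural history."""

    ages: tuple[float, ...]
    adenoma_prevalence: tuple[float, ...]
    crc_cumulative_incidence: tuple[float, ...]
    n_source: int  # simulated sample size behind the targets


def default_life_table(max_age: int = 110) -> P.LifeTable:
    """Synthetic all-cause-minus-CRC life table (Gompertz-Makeham).

    Calibrated loosely to U.S.-like longevity: remaining life expectancy
    at 65 of roughly 19-21 years, women outliving men.  Replaceable via
    the bundle's CSV interface.
    """
    ages = np.arange(max_age + 1)
    base = 4e-4 + 1.8e-5 * np.exp(0.098 * ages)
    q_f = np.minimum(base * 0.85, 1.0)
    q_m = np.minimum(base * 1.30, 1.0)
    q_f[-1] = q_m[-1] = 1.0
    lt = P.LifeTable(ages=tuple(int(a) for a in ages),
                     q_female=tuple(float(x) for x in q_f),
                     q_male=tuple(float(x) for x in q_m))
    lt.validate()
    return lt


def default_nh_params() -> P.NaturalHistoryParams:
    """Default natural-history parameters (documented plausible values).

    Chosen so that by age 65 roughly a third of the cohort has had at
    least one adenoma and lifetime colorectal-cancer risk lands in the
    low single-digit percent range — the right order of magnitude for an
    average-risk population, without claiming any published calibration.
    """
    nh = P.NaturalHistoryParams(
        baseline_log_onset_rate=-6.0,
        sex_effect_male=0.35,
        age_band_edges=(0.0, 30.0, 40.0, 50.0, 60.0, 70.0, 85.0),
        age_band_effects=(-30.0, 0.0, 1.0, 1.6, 2.0, 2.2, 2.2),
        frailty_sd=0.6,
        location_probs={"rectum": 0.20, "distal_colon": 0.45,
                        "proximal_colon": 0.35},
        growth_frechet={"rectum": {"shape": 2.4, "scale": 24.0},
                        "distal_colon": {"shape": 2.4, "scale": 27.0},
                        "proximal_colon": {"shape": 2.4, "scale": 29.0}},
        initial_diameter_mm=1.0,
        max_diameter_mm=50.0,
        transition_intercept=-8.2,
        transition_per_mm=0.20,
        transition_per_year_age=0.02,
        transition_male=0.2,
        sojourn_lognormal={"colon": {"mu": 1.15, "sigma": 0.55},
                           "rectum": {"mu": 1.05, "sigma": 0.55}},
        stage_probs=(0.19, 0.33, 0.27, 0.21),
        survival_shape=0.9,
        survival_scale_by_stage=(45.0, 22.0, 10.0, 2.2),
        survival_scale_male=0.95,
        survival_scale_rectum=0.95,
        survival_age_coef=0.02,
    )
    nh.validate()
    return nh


def default_bundle() -> FixtureBundle:
    """Deterministic fixture bundle; see the module docstring for which
    values are real-world figures and which are documented defaults."""
    perf = {
        # screening-guideline-style stool test characteristics (defaults)
        "fit": P.TestPerformance(
            sensitivity={"adenoma_le5mm": 0.05, "adenoma_6_9mm": 0.101,
                         "adenoma_ge10mm": 0.22, "crc": 0.74},
            specificity=0.964),
        "mt_sdna": P.TestPerformance(
            sensitivity={"adenoma_le5mm": 0.17, "adenoma_6_9mm": 0.22,
                         "adenoma_ge10mm": 0.424, "crc": 0.923},
            specificity=0.866),
        "colonoscopy": P.TestPerformance(
            sensitivity={"adenoma_le5mm": 0.75, "adenoma_6_9mm": 0.85,
                         "adenoma_ge10mm": 0.95, "crc": 0.95},
            specificity=1.0, reach=0.98),
    }
    for t in perf.values():
        t.validate()
    strategies = {
        "colonoscopy": P.ScreeningStrategy("colonoscopy", 10.0, 65.0, 75.0),
        "mt_sdna": P.ScreeningStrategy("mt_sdna", 3.0, 65.0, 75.0),
        "fit": P.ScreeningStrategy("fit", 1.0, 65.0, 75.0),
        "none": P.ScreeningStrategy("none", 1.0, 65.0, 75.0),
    }
    costs = P.CostInputs(
        stool_test_cost={"mt_sdna": 509.0, "fit": 24.0},
        colonoscopy_cost=1022.0,
        colonoscopy_with_polypectomy_cost=1301.0,
        complication_cost={"bleeding": 8255.0, "perforation": 24331.0,
                           "other": 6465.0},
        crc_care_cost={
            1: {"initial": 68000.0, "continuous": 3100.0, "terminal": 72000.0},
            2: {"initial": 91000.0, "continuous": 3600.0, "terminal": 77000.0},
            3: {"initial": 116000.0, "continuous": 4700.0, "terminal": 87000.0},
            4: {"initial": 156000.0, "continuous": 17500.0, "terminal": 110000.0},
        })
    utilities = P.UtilityInputs(
        utility_band_edges=(0.0, 75.0, 85.0),
        utility_by_band=(0.84, 0.81, 0.76),
        disutility={
            1: {"initial": 0.10, "continuous": 0.04, "terminal": 0.28},
            2: {"initial": 0.14, "continuous": 0.05, "terminal": 0.28},
            3: {"initial": 0.19, "continuous": 0.08, "terminal": 0.28},
            4: {"initial": 0.29, "continuous": 0.20, "terminal": 0.28},
        })
    bundle = FixtureBundle(
        nh_params=default_nh_params(),
        life_table=default_life_table(),
        performance=perf,
        adherence=P.AdherenceModel(
            initial_adherence=1.0,
            followup_colonoscopy_adherence={"mt_sdna": 0.715, "fit": 0.467}),
        complications=P.ComplicationModel(
            prob_without_polypectomy={"bleeding": 0.0006,
                                      "perforation": 0.0004, "other": 0.0010},
            prob_with_polypectomy={"bleeding": 0.0025,
                                   "perforation": 0.0016, "other": 0.0020},
            fatality={"bleeding": 0.0, "perforation": 0.05, "other": 0.0}),
        surveillance=P.SurveillancePolicy(),
        strategies=strategies,
        costs=costs,
        utilities=utilities,
        discounting=P.DiscountingPolicy(annual_rate_costs=0.03,
                                        annual_rate_qalys=0.03,
                                        reference_age=65.0),
        base_mix=P.ModalityMix({"colonoscopy": 0.453, "mt_sdna": 0.107,
                                "fit": 0.137, "unscreened": 0.303}),
    )
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# serialization: YAML for parameters, CSV for tabular inputs
# ---------------------------------------------------------------------------

def _costs_frame(costs: P.CostInputs) -> pd.DataFrame:
    rows = [{"item": "stool_test", "stratum": m, "value": v, "units": "USD"}
            for m, v in sorted(costs.stool_test_cost.items())]
    rows += [{"item": "colonoscopy", "stratum": "no_polypectomy",
              "value": costs.colonoscopy_cost, "units": "USD"},
             {"item": "colonoscopy", "stratum": "polypectomy",
              "value": costs.colonoscopy_with_polypectomy_cost, "units": "USD"}]
    rows += [{"item": "complication", "stratum": t,
              "value": costs.complication_cost[t], "units": "USD"}
             for t in P.COMPLICATION_TYPES]
    for st in P.STAGES:
        for ph in P.PHASES:
            rows.append({"item": "crc_care", "stratum": f"stage{st}_{ph}",
                         "value": costs.crc_care_cost[st][ph],
                         "units": "USD_per_year" if ph == "continuous" else "USD"})
    return pd.DataFrame(rows)


def _costs_from_frame(df: pd.DataFrame, currency_year: int) -> P.CostInputs:
    get = lambda item, stratum: float(
        df.loc[(df["item"] == item) & (df["stratum"] == stratum), "value"].iloc[0])
    care = {st: {ph: get("crc_care", f"stage{st}_{ph}") for ph in P.PHASES}
            for st in P.STAGES}
    return P.CostInputs(
        stool_test_cost={m: get("stool_test", m) for m in P.STOOL_MODALITIES},
        colonoscopy_cost=get("colonoscopy", "no_polypectomy"),
        colonoscopy_with_polypectomy_cost=get("colonoscopy", "polypectomy"),
        complication_cost={t: get("complication", t)
                           for t in P.COMPLICATION_TYPES},
        crc_care_cost=care, currency_year=currency_year)


def _utilities_frame(u: P.UtilityInputs) -> pd.DataFrame:
    rows = [{"item": "baseline_utility", "stratum": f"age_ge_{e:g}",
             "value": v, "units": "utility"}
            for e, v in zip(u.utility_band_edges, u.utility_by_band)]
    for st in P.STAGES:
        for ph in P.PHASES:
            rows.append({"item": "disutility", "stratum": f"stage{st}_{ph}",
                         "value": u.disutility[st][ph], "units": "utility"})
    rows.append({"item": "screening_disutility", "stratum": "per_event",
                 "value": u.screening_disutility, "units": "utility"})
    return pd.DataFrame(rows)


def _utilities_from_frame(df: pd.DataFrame) -> P.UtilityInputs:
    base = df[df["item"] == "baseline_utility"]
    edges = tuple(float(s.split("_")[-1]) for s in base["stratum"])
    vals = tuple(float(v) for v in base["value"])
    dis = {st: {ph: float(df.loc[df["stratum"] == f"stage{st}_{ph}", "value"]
                          .loc[df["item"] == "disutility"].iloc[0])
                for ph in P.PHASES} for st in P.STAGES}
    sd = float(df.loc[df["item"] == "screening_disutility", "value"].iloc[0])
    return P.UtilityInputs(utility_band_edges=edges, utility_by_band=vals,
                           disutility=dis, screening_disutility=sd)


def write_bundle(bundle: FixtureBundle, directory) -> None:
    """Materialize a bundle as params.yaml + life_table/costs/utilities CSVs."""
    from pathlib import Path
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    doc = {
        "natural_history": P.to_dict(bundle.nh_params),
        "performance": {m: P.to_dict(t) for m, t in bundle.performance.items()},
        "adherence": P.to_dict(bundle.adherence),
        "complications": P.to_dict(bundle.complications),
        "surveillance": P.to_dict(bundle.surveillance),
        "strategies": {m: P.to_dict(s) for m, s in bundle.strategies.items()},
        "discounting": P.to_dict(bundle.discounting),
        "base_mix": dict(bundle.base_mix.weights),
        "shift_split_mt_sdna": bundle.shift_split_mt_sdna,
        "entry_age": bundle.entry_age,
        "currency_year": bundle.costs.currency_year,
        "note": "defaults are documented plausible values, not a published calibration",
    }
    (d / "params.yaml").write_text(yaml.safe_dump(doc, sort_keys=True))
    # %.17g round-trips IEEE doubles exactly
    bundle.life_table.to_frame().to_csv(d / "life_table.csv", index=False,
                                        float_format="%.17g")
    _costs_frame(bundle.costs).to_csv(d / "costs.csv", index=False,
                                      float_format="%.17g")
    _utilities_frame(bundle.utilities).to_csv(d / "utilities.csv", index=False,
                                              float_format="%.17g")


def read_bundle(directory) -> FixtureBundle:
    from pathlib import Path
    d = Path(directory)
    doc = yaml.safe_load((d / "params.yaml").read_text())
    read = lambda name: pd.read_csv(d / name, float_precision="round_trip")
    lt = P.LifeTable.from_frame(read("life_table.csv"))
    costs = _costs_from_frame(read("costs.csv"),
                              int(doc.get("currency_year", 2022)))
    utilities = _utilities_from_frame(read("utilities.csv"))
    bundle = FixtureBundle(
        nh_params=P.from_dict(P.NaturalHistoryParams, doc["natural_history"]),
        life_table=lt,
        performance={m: P.from_dict(P.TestPerformance, t)
                     for m, t in doc["performance"].items()},
        adherence=P.from_dict(P.AdherenceModel, doc["adherence"]),
        complications=P.from_dict(P.ComplicationModel, doc["complications"]),
        surveillance=P.from_dict(P.SurveillancePolicy, doc["surveillance"]),
        strategies={m: P.from_dict(P.ScreeningStrategy, s)
                    for m, s in doc["strategies"].items()},
        costs=costs,
        utilities=utilities,
        discounting=P.from_dict(P.DiscountingPolicy, doc["discounting"]),
        base_mix=P.ModalityMix(doc["base_mix"]),
        shift_split_mt_sdna=float(doc["shift_split_mt_sdna"]),
        entry_age=int(doc["entry_age"]),
    )
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# cohort draws
# ---------------------------------------------------------------------------

def _eligible(person: Person, entry_age: float) -> bool:
    """Alive and free of diagnosed colorectal cancer at cohort entry."""
    if person.other_cause_death_age <= entry_age:
        return False
    return not any(c.detection_age <= entry_age for c in person.cancers)


def iter_cohort(bundle: FixtureBundle, n: int, master_seed: int):
    """Yield ``(seed_triple, unscreened_person)`` for n eligible people.

    Eligibility (alive, no prior CRC diagnosis at the entry age) is
    enforced by rejection within each person's slot: attempt *a* for
    person *i* uses the stream keyed ``(i, a)``, so the accepted draw for
    person *i* never depends on the cohort size — the property that makes
    common random numbers work across runs of different sizes.
    """
    for pid in range(n):
        for attempt in range(_MAX_REJECT_ATTEMPTS):
            latent = generate_latent_history(master_seed, pid,
                                             bundle.nh_params,
                                             bundle.life_table, attempt)
            person = resolve_unscreened(latent, bundle.nh_params)
            if _eligible(person, bundle.entry_age):
                yield (master_seed, pid, attempt), person
                break
        else:  # pragma: no cover - would need a pathological life table
            raise RuntimeError(f"could not draw an eligible person in slot {pid}")


def generate_cohort(n: int, master_seed: int,
                    bundle: FixtureBundle) -> pd.DataFrame:
    """Reproducible cohort attribute table (one row per eligible person)."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rows = []
    for (ms, pid, attempt), person in iter_cohort(bundle, n, master_seed):
        rows.append({"person_id": pid, "attempt": attempt, "sex": person.sex,
                     "frailty": person.frailty,
                     "other_cause_death_age": person.other_cause_death_age})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# smoke calibration
# ---------------------------------------------------------------------------

def _curves(persons: list[Person], ages) -> tuple[np.ndarray, np.ndarray]:
    prev = np.zeros(len(ages))
    cum = np.zeros(len(ages))
    for p in persons:
        for k, a in enumerate(ages):
            if p.death_age > a:
                if any(l.onset_age <= a and
                       (l.transition_age is None or l.transition_age > a)
                       for l in p.lesions):
                    prev[k] += 1
            if any(c.detection_age <= a for c in p.cancers):
                cum[k] += 1
    n = max(len(persons), 1)
    return prev / n, cum / n


def _simulate_unscreened(bundle: FixtureBundle, n: int, seed: int) -> list[Person]:
    from .natural_history import simulate_person_unscreened
    return [simulate_person_unscreened((seed, i, 0), bundle.nh_params,
                                       bundle.life_table) for i in range(n)]


def targets_from_sim(bundle: FixtureBundle, n: int, seed: int,
                     ages=(50.0, 65.0, 75.0, 85.0)) -> CalibrationTargets:
    """Self-consistency targets: curves simulated from the bundle itself."""
    persons = _simulate_unscreened(bundle, n, seed)
    prev, cum = _curves(persons, ages)
    return CalibrationTargets(ages=tuple(ages),
                              adenoma_prevalence=tuple(prev),
                              crc_cumulative_incidence=tuple(cum),
                              n_source=n)


def smoke_calibration(bundle: FixtureBundle, targets: CalibrationTargets,
                      n: int, seed: int) -> pd.DataFrame:
    """Compare simulated prevalence/incidence curves against targets.

    Reports a z-score per (age, quantity) using the pooled binomial
    standard error of the simulated and target proportions.  Purely a
    diagnostic — no parameter is fitted.
    """
    persons = _simulate_unscreened(bundle, n, seed)
    prev, cum = _curves(persons, targets.ages)
    rows = []
    for name, sim, tgt in (("adenoma_prevalence", prev,
                            targets.adenoma_prevalence),
                           ("crc_cumulative_incidence", cum,
                            targets.crc_cumulative_incidence)):
        for a, s, t in zip(targets.ages, sim, tgt):
            se = math.sqrt(max(s * (1 - s), 1e-12) / n
                           + max(t * (1 - t), 1e-12) / targets.n_source)
            rows.append({"quantity": name, "age": a, "simulated": s,
                         "target": t, "z": (s - t) / se,
                         "flag": abs(s - t) / se > 4.0})
    return pd.DataFrame(rows)
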