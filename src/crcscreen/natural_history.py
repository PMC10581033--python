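"""Event-driven simulation of the colorectal adenoma-carcinoma sequence.

One simulated person carries a latent disease course generated in a single
pass from a dedicated random stream: adenoma onsets (non-homogeneous
Poisson process), deterministic growth curves, annual malignant-transition
draws, preclinical sojourn, stage at symptomatic presentation, and a
reserved survival quantile per cancer.  The latent course is independent
of any screening overlay, which is what makes common-random-numbers
comparisons across screening scenarios exact: a screened run embeds the
bit-identical unscreened trajectory and only *re-interprets* it (removing
lesions, detecting cancers early).

Ages are continuous years from birth; the clock never runs past
``other_cause_death_age`` drawn from the life table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import (ConfigError, LifeTable, NaturalHistoryParams, site_of,
                     LOCATIONS)

__all__ = [
    "Lesion", "PreclinicalCancer", "ClinicalCancer", "Person",
    "draw_other_cause_death", "draw_adenoma_onsets", "lesion_size_at",
    "draw_transition", "draw_sojourn_and_stage", "draw_crc_survival",
    "weibull_survival_time", "stage_at", "simulate_person_unscreened",
    "person_rng",
]


@dataclass
class Lesion:
    """One adenoma: onset, location, growth curve and latent transition."""

    onset_age: float
    location: str  # rectum | distal_colon | proximal_colon
    time_to_10mm: float  # drawn Frechet variate, years from onset
    transition_age: float | None = None  # latent; None = never transitions
    removed_age: float | None = None

    @property
    def site(self) -> str:
        return site_of(self.location)


@dataclass
class PreclinicalCancer:
    """Screen-detectable but asymptomatic cancer arising from a lesion."""

    lesion_index: int
    onset_age: float  # == origin lesion's transition_age
    sojourn_time: float
    location: str
    symptomatic_stage: int  # stage at the end of the sojourn
    survival_quantile: float  # reserved U(0,1) for survival inversion

    @property
    def clinical_age(self) -> float:
        return self.onset_age + self.sojourn_time

    @property
    def site(self) -> str:
        return site_of(self.location)


@dataclass
class ClinicalCancer:
    """A diagnosed cancer: how, when and at what stage it surfaced."""

    detection_age: float
    detection_mode: str  # symptomatic | screen_detected | followup_detected
    stage: int
    location: str  # colon | rectum
    survival_time: float  # years from detection, CRC cause-specific


@dataclass
class Person:
    """One individual's attributes and full event timeline."""

    id: int
    sex: str
    frailty: float
    other_cause_death_age: float
    lesions: list[Lesion] = field(default_factory=list)
    preclinical: list[PreclinicalCancer] = field(default_factory=list)
    cancers: list[ClinicalCancer] = field(default_factory=list)
    death_age: float = math.nan
    death_cause: str = "other"  # other | crc | complication
    # screening-era events, empty for unscreened runs
    stool_tests: list = field(default_factory=list)
    colonoscopies: list = field(default_factory=list)


def person_rng(master_seed: int, person_id: int, attempt: int = 0,
               stream: int = 0) -> np.random.Generator:
    """Disjoint, size-stable random stream for one person.

    Streams are keyed by ``(person_id, attempt, stream)`` under the master
    seed, so person *i*'s draws do not change when the cohort grows and a
    screening overlay (stream 1) never disturbs natural history (stream 0).
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(person_id, attempt, stream))
    return np.random.Generator(np.random.PCG64(ss))


# ---------------------------------------------------------------------------
# elementary draws
# ---------------------------------------------------------------------------

def draw_other_cause_death(sex: str, life_table: LifeTable,
                           rng: np.random.Generator,
                           start_age: int = 0) -> float:
    """Sample an age at death from non-CRC causes, conditional on being
    alive at ``start_age``.  The death year comes from inverting the
    cumulative survival implied by the table; placement within the year is
    uniform."""
    ages = np.asarray(life_table.ages)
    if start_age < ages[0] or start_age > ages[-1]:
        raise ConfigError(f"start_age {start_age} outside life table range")
    mask = ages >= start_age
    q = life_table.q(sex)[mask]
    a0 = int(ages[mask][0])
    u = rng.random()
    surv = 1.0
    year = a0 + len(q) - 1
    for i, qi in enumerate(q):
        nxt = surv * (1.0 - qi)
        if u > nxt:  # death during year a0+i
            year = a0 + i
            break
        surv = nxt
    return year + rng.random()


def draw_adenoma_onsets(sex: str, frailty: float,
                        params: NaturalHistoryParams, horizon: float,
                        rng: np.random.Generator) -> list[tuple[float, str]]:
    """Adenoma onset ages and locations on ``(0, horizon]``.

    The intensity is piecewise constant (the age-band effects), so the
    process is simulated exactly band by band: a Poisson count per band,
    uniform placement within the band.  Returns onsets sorted by age.
    """
    if frailty < 0:
        raise ConfigError("frailty must be non-negative")
    edges = list(params.age_band_edges) + [math.inf]
    onset_ages: list[float] = []
    for i in range(len(params.age_band_effects)):
        lo = max(0.0, edges[i])
        hi = min(horizon, edges[i + 1])
        if hi <= lo:
            continue
        log_rate = params.onset_log_rate((lo + hi) / 2.0, sex)
        rate = math.exp(log_rate) * frailty if math.isfinite(log_rate) else 0.0
        if rate <= 0:
            continue
        k = rng.poisson(rate * (hi - lo))
        if k:
            onset_ages.extend(lo + (hi - lo) * rng.random(k))
    onset_ages.sort()
    locs = list(LOCATIONS)
    probs = np.array([params.location_probs[l] for l in locs])
    out = []
    for a in onset_ages:
        loc = locs[int(rng.choice(len(locs), p=probs))]
        out.append((float(a), loc))
    return out


def lesion_size_at(lesion: Lesion, age: float,
                   params: NaturalHistoryParams) -> float:
    """Deterministic lesion diameter (mm) at ``age``.

    Exponential growth from the initial diameter, scaled so the lesion is
    exactly 10 mm at ``onset_age + time_to_10mm``; capped at the maximum
    diameter.  Monotone non-decreasing in age by construction.
    """
    if age < lesion.onset_age:
        raise ValueError("lesion size queried before onset")
    d0 = params.initial_diameter_mm
    t = age - lesion.onset_age
    size = d0 * (10.0 / d0) ** (t / lesion.time_to_10mm)
    return min(size, params.max_diameter_mm)


def draw_transition(lesion: Lesion, sex: str, params: NaturalHistoryParams,
                    horizon: float, rng: np.random.Generator) -> float | None:
    """Latent age of malignant transformation, or None before ``horizon``.

    Each whole year ``[onset+k, onset+k+1)`` carries a Bernoulli trial with
    the annual probability evaluated from the lesion's size and the
    person's age/sex at the start of the interval; a success places the
    transition uniformly inside the interval.
    """
    k = 0
    while True:
        t0 = lesion.onset_age + k
        if t0 >= horizon:
            return None
        p = params.transition_annual_prob(
            lesion_size_at(lesion, t0, params), t0, sex)
        if rng.random() < p:
            age = t0 + rng.random()
            return age if age < horizon else None
        k += 1
        if k > 100_000:  # guard against p ~ 0 with an unbounded horizon
            return None


def draw_sojourn_and_stage(location: str, params: NaturalHistoryParams,
                           rng: np.random.Generator) -> tuple[float, int]:
    """Preclinical sojourn time and stage at symptomatic presentation."""
    sj = params.sojourn_lognormal[site_of(location)]
    sojourn = float(rng.lognormal(mean=sj["mu"], sigma=sj["sigma"]))
    stage = 1 + int(rng.choice(4, p=np.asarray(params.stage_probs)))
    return sojourn, stage


def stage_at(cancer: PreclinicalCancer, age: float) -> int:
    """Stage along the sojourn: the path is non-decreasing, splits the
    sojourn into equal dwell fractions per stage, and ends at the stage
    drawn for symptomatic presentation."""
    s_final = cancer.symptomatic_stage
    t = age - cancer.onset_age
    if t < -1e-9 or t > cancer.sojourn_time + 1e-9:
        raise ValueError("stage queried outside the sojourn window")
    t = min(max(t, 0.0), cancer.sojourn_time)
    if cancer.sojourn_time == 0:
        return s_final
    frac = t / cancer.sojourn_time
    return min(s_final, 1 + int(frac * s_final))


def weibull_survival_time(u: float, stage: int, site: str, sex: str,
                          age_dx: float, params: NaturalHistoryParams) -> float:
    """Invert the Weibull cause-specific survival function at quantile u.

    S(t) = exp(-(t/scale)^shape); using the same u across strata gives
    monotone coupling (a later stage at the same quantile means a shorter
    survival), which keeps stage-shift benefits noise-free under CRN.
    """
    scale = params.survival_scale(stage, site, sex, age_dx)
    u = min(max(u, 1e-15), 1.0 - 1e-15)
    return scale * (-math.log(u)) ** (1.0 / params.survival_shape)


def draw_crc_survival(stage: int, site: str, sex: str, age_dx: float,
                      params: NaturalHistoryParams,
                      rng: np.random.Generator) -> float:
    if stage not in (1, 2, 3, 4) or site not in ("colon", "rectum"):
        raise ConfigError("missing survival covariate stratum")
    return weibull_survival_time(rng.random(), stage, site, sex, age_dx, params)


# ---------------------------------------------------------------------------
# whole-person simulation
# ---------------------------------------------------------------------------

def generate_latent_history(master_seed: int, person_id: int,
                            params: NaturalHistoryParams,
                            life_table: LifeTable,
                            attempt: int = 0) -> Person:
    """Draw the complete latent disease course for one person.

    All natural-history randomness is consumed here, in a fixed order, from
    the person's stream 0; screening overlays never touch it.
    """
    rng = person_rng(master_seed, person_id, attempt, stream=0)
    sex = "male" if rng.random() < 0.5 else "female"
    frailty = float(np.exp(rng.normal(-0.5 * params.frailty_sd ** 2,
                                      params.frailty_sd))) if params.frailty_sd > 0 else 1.0
    ocd = draw_other_cause_death(sex, life_table, rng)
    person = Person(id=person_id, sex=sex, frailty=frailty,
                    other_cause_death_age=ocd)
    onsets = draw_adenoma_onsets(sex, frailty, params, ocd, rng)
    for onset_age, loc in onsets:
        g = params.growth_frechet[loc]
        # inverse-CDF of the Frechet (inverse-Weibull) law
        u = rng.random()
        t10 = g["scale"] * (-math.log(u)) ** (-1.0 / g["shape"])
        lesion = Lesion(onset_age=onset_age, location=loc, time_to_10mm=t10)
        lesion.transition_age = draw_transition(lesion, sex, params, ocd, rng)
        idx = len(person.lesions)
        person.lesions.append(lesion)
        if lesion.transition_age is not None:
            sojourn, stage = draw_sojourn_and_stage(loc, params, rng)
            person.preclinical.append(PreclinicalCancer(
                lesion_index=idx, onset_age=lesion.transition_age,
                sojourn_time=sojourn, location=loc,
                symptomatic_stage=stage, survival_quantile=rng.random()))
    return person


def resolve_unscreened(person: Person, params: NaturalHistoryParams) -> Person:
    """Fill in death and clinical-cancer fields assuming no screening.

    The first preclinical cancer to finish its sojourn before death
    presents symptomatically and triggers stage/site/sex/age-specific
    survival; later cancers are subsumed under that care episode.
    """
    dx_age = math.inf
    first = None
    for pc in person.preclinical:
        if pc.clinical_age < dx_age:
            dx_age, first = pc.clinical_age, pc
    death = person.other_cause_death_age
    cause = "other"
    if first is not None and dx_age < person.other_cause_death_age:
        surv = weibull_survival_time(first.survival_quantile,
                                     first.symptomatic_stage, first.site,
                                     person.sex, dx_age, params)
        person.cancers.append(ClinicalCancer(
            detection_age=dx_age, detection_mode="symptomatic",
            stage=first.symptomatic_stage, location=first.site,
            survival_time=surv))
        if dx_age + surv < death:
            death, cause = dx_age + surv, "crc"
    person.death_age = death
    person.death_cause = cause
    return person


def simulate_person_unscreened(person_seed: tuple[int, int, int] | int,
                               params: NaturalHistoryParams,
                               life_table: LifeTable) -> Person:
    """Simulate one person's full unscreened life course.

    ``person_seed`` is either a bare master seed (person 0, attempt 0) or a
    ``(master_seed, person_id, attempt)`` triple.  Reproducible: the same
    seed and parameters give a bit-identical Person.
    """
    if isinstance(person_seed, int):
        master, pid, attempt = person_seed, 0, 0
    else:
        master, pid, attempt = person_seed
    person = generate_latent_history(master, pid, params, life_table, attempt)
    return resolve_unscreened(person, params)
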