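"""Screening overlay on a latent natural history.

The overlay walks a person's screening schedule chronologically, racing
scheduled exams against symptomatic presentation of any latent cancer.
Stool tests are evaluated against the person's current lesion state,
positives trigger a follow-up colonoscopy with the configured adherence,
colonoscopies remove the adenomas they detect (cancelling those lesions'
latent transitions) and may detect preclinical cancers early, and every
completed colonoscopy can generate a complication.

Randomness discipline (common random numbers): every screening decision
consumes a pre-drawn uniform indexed by its *slot* — the screening round
for routine exams, a dedicated block for surveillance exams — and by the
lesion/cancer index where relevant.  Scenarios that differ only in
adherence therefore share every other draw, and raising an adherence
parameter can only add events, never reshuffle them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .natural_history import (ClinicalCancer, Person, generate_latent_history,
                              lesion_size_at, person_rng, resolve_unscreened,
                              stage_at, weibull_survival_time)
from .params import (AdherenceModel, ComplicationModel, LifeTable,
                     NaturalHistoryParams, ScreeningStrategy,
                     SurveillancePolicy, TestPerformance, COMPLICATION_TYPES)

__all__ = [
    "StoolTestEvent", "ColonoscopyOutcome", "schedule_screens",
    "stool_positive_prob", "apply_stool_test", "resolve_positive_stool",
    "simulate_person_screened", "ScreeningContext",
]

_SURVEILLANCE_SLOTS = 16  # upper bound on surveillance exams per person


@dataclass
class StoolTestEvent:
    age: float
    modality: str
    positive: bool
    followed_up: bool | None = None  # None for negative tests


@dataclass
class ColonoscopyOutcome:
    performed_age: float
    indication: str  # screening | followup | surveillance | diagnostic
    lesions_detected: list[int] = field(default_factory=list)
    polypectomy: bool = False
    cancer_detected: ClinicalCancer | None = None
    complication: str = "none"
    complication_fatal: bool = False


def schedule_screens(strategy: ScreeningStrategy) -> list[float]:
    """Routine screening ages: start, start+interval, ... up to stop_age."""
    strategy.validate()
    if strategy.modality == "none":
        return []
    ages = []
    a = strategy.start_age
    while a <= strategy.stop_age + 1e-9:
        ages.append(round(a, 9))
        a += strategy.interval
    return ages


def stool_positive_prob(lesion_sizes_mm: list[float], has_preclinical: bool,
                        performance: TestPerformance) -> float:
    """Positivity probability given the person's current lesion state.

    A preclinical cancer dominates (CRC sensitivity); otherwise the most
    advanced adenoma size category sets the sensitivity; with nothing to
    find, positivity is the false-positive rate 1 - specificity.
    """
    if has_preclinical:
        return performance.sensitivity["crc"]
    if lesion_sizes_mm:
        cat = performance.size_category(max(lesion_sizes_mm))
        return performance.sensitivity[cat]
    return 1.0 - performance.specificity


def apply_stool_test(person: Person, age: float, performance: TestPerformance,
                     rng: np.random.Generator,
                     params: NaturalHistoryParams) -> bool:
    """Single stool test against the person's *current* (unscreened) state.

    Convenience entry point used in calibration checks; the overlay itself
    uses slot-indexed uniforms through the same positivity rule.
    """
    sizes = [lesion_size_at(l, age, params) for l in person.lesions
             if l.onset_age <= age and (l.removed_age is None or l.removed_age > age)
             and (l.transition_age is None or l.transition_age > age)]
    has_pc = any(pc.onset_age <= age < pc.clinical_age for pc in person.preclinical)
    return bool(rng.random() < stool_positive_prob(sizes, has_pc, performance))


def resolve_positive_stool(adherence: AdherenceModel, modality: str,
                           rng: np.random.Generator) -> str:
    """Bernoulli follow-up attendance after a positive stool test."""
    p = adherence.followup_colonoscopy_adherence[modality]
    return "followup_done" if rng.random() < p else "followup_missed"


# ---------------------------------------------------------------------------
# full screened-person simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreeningContext:
    """Everything a screened run needs beyond the natural history."""

    strategy: ScreeningStrategy
    adherence: AdherenceModel
    performance: dict[str, TestPerformance]  # per modality incl. 'colonoscopy'
    complications: ComplicationModel
    surveillance: SurveillancePolicy
    params: NaturalHistoryParams
    life_table: LifeTable


class _Draws:
    """Slot-indexed uniforms for one person under one schedule length.

    Shapes depend only on (schedule length, lesion count, cancer count), so
    adherence changes leave every uniform in place.
    """

    def __init__(self, master: int, pid: int, attempt: int,
                 n_rounds: int, n_lesions: int, n_cancers: int):
        rng = person_rng(master, pid, attempt, stream=1)
        slots = n_rounds + _SURVEILLANCE_SLOTS
        self.attend = rng.random(slots)
        self.stool = rng.random(max(n_rounds, 1))
        self.follow = rng.random(max(n_rounds, 1))
        self.detect = rng.random((slots, n_lesions)) if n_lesions else np.empty((slots, 0))
        self.cancer = rng.random((slots, n_cancers)) if n_cancers else np.empty((slots, 0))
        self.comp = rng.random((slots, 2))


def _findings_category(n_removed: int, any_large: bool) -> str:
    if n_removed == 0:
        return "none"
    if n_removed >= 3 or any_large:
        return "high_risk"
    return "low_risk"


def simulate_person_screened(person_seed: tuple[int, int, int] | int,
                             ctx: ScreeningContext,
                             latent: Person | None = None) -> Person:
    """Simulate one person's life course under a screening strategy.

    The latent natural history is (re)generated from the person's stream 0
    — or taken from ``latent``, which is never mutated — so the embedded
    unscreened trajectory is bit-identical to ``simulate_person_unscreened``
    for the same seed.  With ``strategy.modality == 'none'`` the result *is*
    the unscreened life course.
    """
    if isinstance(person_seed, int):
        master, pid, attempt = person_seed, 0, 0
    else:
        master, pid, attempt = person_seed
    if latent is None:
        latent = generate_latent_history(master, pid, ctx.params,
                                         ctx.life_table, attempt)

    out = Person(id=latent.id, sex=latent.sex, frailty=latent.frailty,
                 other_cause_death_age=latent.other_cause_death_age,
                 lesions=[replace(l) for l in latent.lesions],
                 preclinical=list(latent.preclinical))
    if ctx.strategy.modality == "none":
        return resolve_unscreened(out, ctx.params)

    params = ctx.params
    sched = schedule_screens(ctx.strategy)
    draws = _Draws(master, pid, attempt, len(sched),
                   len(out.lesions), len(out.preclinical))
    modality = ctx.strategy.modality
    ocd = out.other_cause_death_age

    removed: list[float | None] = [None] * len(out.lesions)
    diagnosed: ClinicalCancer | None = None
    complication_death_age = math.inf
    surv_count = 0
    round_idx = 0
    next_surveillance_age: float | None = None
    in_surveillance = False

    def cancer_active(i: int, t: float) -> bool:
        pc = out.preclinical[i]
        if not (pc.onset_age <= t < pc.clinical_age):
            return False
        r = removed[pc.lesion_index]
        return r is None or r > pc.onset_age  # removal before transition cancels it

    def adenoma_sizes(t: float) -> list[float]:
        sizes = []
        for j, l in enumerate(out.lesions):
            if l.onset_age <= t and removed[j] is None and \
                    (l.transition_age is None or l.transition_age > t):
                sizes.append(lesion_size_at(l, t, params))
        return sizes

    def next_symptomatic(after: float) -> tuple[float, int | None]:
        best, who = math.inf, None
        for i, pc in enumerate(out.preclinical):
            r = removed[pc.lesion_index]
            if r is not None and r <= pc.onset_age:
                continue
            if pc.clinical_age >= after and pc.clinical_age < best:
                best, who = pc.clinical_age, i
        return best, who

    def do_colonoscopy(age: float, indication: str, slot: int) -> ColonoscopyOutcome:
        nonlocal diagnosed, complication_death_age
        perf = ctx.performance["colonoscopy"]
        outcome = ColonoscopyOutcome(performed_age=age, indication=indication)
        any_large = False
        for j, l in enumerate(out.lesions):
            if l.onset_age <= age and removed[j] is None and \
                    (l.transition_age is None or l.transition_age > age):
                size = lesion_size_at(l, age, params)
                sens = perf.sensitivity[perf.size_category(size)] * perf.reach
                if draws.detect[slot, j] < sens:
                    removed[j] = age
                    out.lesions[j].removed_age = age
                    outcome.lesions_detected.append(j)
                    any_large = any_large or size >= 10.0
        outcome.polypectomy = bool(outcome.lesions_detected)
        # preclinical cancer detection; if several, care follows the worst stage
        best = None
        for i in range(len(out.preclinical)):
            if cancer_active(i, age):
                sens = perf.sensitivity["crc"] * perf.reach
                if draws.cancer[slot, i] < sens:
                    pc = out.preclinical[i]
                    st = stage_at(pc, age)
                    if best is None or st > best[0]:
                        best = (st, pc)
        if best is not None:
            st, pc = best
            mode = "followup_detected" if indication == "followup" else "screen_detected"
            surv = weibull_survival_time(pc.survival_quantile, st, pc.site,
                                         out.sex, age, params)
            diagnosed = ClinicalCancer(detection_age=age, detection_mode=mode,
                                       stage=st, location=pc.site,
                                       survival_time=surv)
            outcome.cancer_detected = diagnosed
        # complications
        probs = (ctx.complications.prob_with_polypectomy if outcome.polypectomy
                 else ctx.complications.prob_without_polypectomy)
        u, cum = draws.comp[slot, 0], 0.0
        for ctype in COMPLICATION_TYPES:
            cum += probs[ctype]
            if u < cum:
                outcome.complication = ctype
                if draws.comp[slot, 1] < ctx.complications.fatality[ctype]:
                    outcome.complication_fatal = True
                    complication_death_age = min(complication_death_age, age)
                break
        out.colonoscopies.append(outcome)
        # surveillance scheduling
        nonlocal next_surveillance_age, in_surveillance
        if ctx.surveillance.enabled and diagnosed is None and not outcome.complication_fatal:
            cat = _findings_category(len(outcome.lesions_detected), any_large)
            nxt = age + ctx.surveillance.interval_by_findings[cat]
            if nxt <= ctx.surveillance.stop_age and surv_count < _SURVEILLANCE_SLOTS:
                next_surveillance_age = nxt
                in_surveillance = True
        return outcome

    # ---- chronological event loop ------------------------------------
    while diagnosed is None and complication_death_age is math.inf:
        exam_age, exam_kind = math.inf, None
        if in_surveillance:
            if next_surveillance_age is not None:
                exam_age, exam_kind = next_surveillance_age, "surveillance"
        elif round_idx < len(sched):
            exam_age, exam_kind = sched[round_idx], "routine"
        sym_age, sym_idx = next_symptomatic(0.0)
        horizon = min(ocd, complication_death_age)
        if sym_age < min(exam_age, horizon):
            pc = out.preclinical[sym_idx]
            surv = weibull_survival_time(pc.survival_quantile,
                                         pc.symptomatic_stage, pc.site,
                                         out.sex, sym_age, params)
            diagnosed = ClinicalCancer(detection_age=sym_age,
                                       detection_mode="symptomatic",
                                       stage=pc.symptomatic_stage,
                                       location=pc.site, survival_time=surv)
            break
        if exam_kind is None or exam_age >= horizon:
            break
        if exam_kind == "surveillance":
            next_surveillance_age = None
            slot = len(sched) + surv_count
            surv_count += 1
            if draws.attend[slot] < ctx.adherence.initial_adherence:
                do_colonoscopy(exam_age, "surveillance", slot)
            if next_surveillance_age is None:
                break  # nothing further scheduled: organized screening ends
        else:
            slot = round_idx
            round_idx += 1
            if draws.attend[slot] >= ctx.adherence.initial_adherence:
                continue
            if modality == "colonoscopy":
                do_colonoscopy(exam_age, "screening", slot)
            else:
                sizes = adenoma_sizes(exam_age)
                has_pc = any(cancer_active(i, exam_age)
                             for i in range(len(out.preclinical)))
                p_pos = stool_positive_prob(sizes, has_pc,
                                            ctx.performance[modality])
                positive = draws.stool[slot] < p_pos
                ev = StoolTestEvent(age=exam_age, modality=modality,
                                    positive=bool(positive))
                if positive:
                    p_fu = ctx.adherence.followup_colonoscopy_adherence[modality]
                    ev.followed_up = bool(draws.follow[slot] < p_fu)
                    if ev.followed_up:
                        out.stool_tests.append(ev)
                        do_colonoscopy(exam_age, "followup", slot)
                        continue
                out.stool_tests.append(ev)

    # ---- resolve death ------------------------------------------------
    death, cause = ocd, "other"
    if diagnosed is not None:
        out.cancers.append(diagnosed)
        crc_death = diagnosed.detection_age + diagnosed.survival_time
        if crc_death < death:
            death, cause = crc_death, "crc"
    if complication_death_age < death:
        death, cause = complication_death_age, "complication"
    out.death_age = death
    out.death_cause = cause
    return out
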