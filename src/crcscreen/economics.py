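"""Discounted costs and quality-adjusted life-years from event timelines.

Costing follows phase-of-care accounting: an *initial* window of 12 months
after diagnosis, a *terminal* window of the final 12 months before a CRC
death, and a *continuous* phase (annualized cost) in between.  When
survival is shorter than 24 months the terminal window takes precedence,
counting backwards from death; initial and terminal lump sums are prorated
by the fraction of their 12-month window actually lived.

Point events (tests, colonoscopies, complications) are discounted at their
exact age.  Continuous flows (phase costs, utility) are integrated in
yearly slices aligned to the start of each window, each slice discounted
at its midpoint — the half-year convention.  Everything is discounted to
the cohort entry age (``DiscountingPolicy.reference_age``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .natural_history import Person
from .params import (ConfigError, CostInputs, DiscountingPolicy,
                     UtilityInputs, PHASES)

__all__ = ["PersonEconomics", "StrategyOutcome", "care_windows",
           "accumulate_costs", "accumulate_qalys", "person_economics",
           "summarize_arm"]


@dataclass(frozen=True)
class PersonEconomics:
    """Per-person economic summary; cost components add up exactly."""

    life_years: float  # undiscounted years lived past reference age
    qalys_discounted: float
    cost_screening: float
    cost_complications: float
    cost_crc_care: float

    @property
    def cost_total(self) -> float:
        return self.cost_screening + self.cost_complications + self.cost_crc_care


@dataclass(frozen=True)
class StrategyOutcome:
    """Arithmetic means over one arm (or one weighted population)."""

    mean_life_years: float
    mean_qalys: float
    mean_cost_screening: float
    mean_cost_complications: float
    mean_cost_crc_care: float
    n: int

    @property
    def mean_cost_total(self) -> float:
        return (self.mean_cost_screening + self.mean_cost_complications
                + self.mean_cost_crc_care)


def _discounted_flow(a0: float, a1: float, annual_rate: float,
                     ref: float) -> float:
    """∫ over [a0,a1) of the discount factor, yearly slices at midpoints."""
    if a1 <= a0:
        return 0.0
    total = 0.0
    t = a0
    while t < a1 - 1e-12:
        t_next = min(t + 1.0, a1)
        mid = 0.5 * (t + t_next)
        total += (t_next - t) * (1.0 + annual_rate) ** (-(mid - ref))
        t = t_next
    return total


def care_windows(detection_age: float, death_age: float,
                 crc_death: bool) -> dict[str, tuple[float, float]]:
    """Phase-of-care windows ``{phase: (start, end)}``; empty phases omitted.

    Terminal care applies only to CRC deaths and is anchored backwards from
    death; with <24 months of survival it wins the overlap with the
    initial window.
    """
    windows: dict[str, tuple[float, float]] = {}
    if crc_death:
        term_start = max(death_age - 1.0, detection_age)
        if death_age > term_start:
            windows["terminal"] = (term_start, death_age)
        init_end = min(detection_age + 1.0, term_start)
    else:
        init_end = min(detection_age + 1.0, death_age)
    if init_end > detection_age:
        windows["initial"] = (detection_age, init_end)
    cont_end = windows["terminal"][0] if crc_death and "terminal" in windows else death_age
    if cont_end > init_end:
        windows["continuous"] = (init_end, cont_end)
    return windows


def accumulate_costs(person: Person, costs: CostInputs,
                     disc: DiscountingPolicy) -> tuple[float, float, float]:
    """Discounted (screening, complication, CRC-care) cost components."""
    ref = disc.reference_age
    r = disc.annual_rate_costs
    c_screen = 0.0
    for ev in person.stool_tests:
        try:
            unit = costs.stool_test_cost[ev.modality]
        except KeyError:
            raise ConfigError(f"no cost configured for stool test {ev.modality!r}")
        c_screen += unit * (1.0 + r) ** (-(ev.age - ref))
    c_comp = 0.0
    for col in person.colonoscopies:
        unit = (costs.colonoscopy_with_polypectomy_cost if col.polypectomy
                else costs.colonoscopy_cost)
        f = (1.0 + r) ** (-(col.performed_age - ref))
        c_screen += unit * f
        if col.complication != "none":
            c_comp += costs.complication_cost[col.complication] * f
    c_crc = 0.0
    for ca in person.cancers:
        windows = care_windows(ca.detection_age, person.death_age,
                               person.death_cause == "crc")
        table = costs.crc_care_cost[ca.stage]
        for phase in PHASES:
            if phase not in windows:
                continue
            a0, a1 = windows[phase]
            flow = _discounted_flow(a0, a1, r, ref)
            # initial/terminal are lump sums spread over their 12-month
            # window (prorated if truncated); continuous is annualized
            c_crc += table[phase] * flow
    return c_screen, c_comp, c_crc


def accumulate_qalys(person: Person, utilities: UtilityInputs,
                     disc: DiscountingPolicy) -> float:
    """Discounted QALYs over [reference_age, death_age].

    Baseline age-band utility, minus the stage/phase disutility while a
    cancer-care window is active, floored at zero; integrated in yearly
    slices with midpoint discounting.
    """
    ref = disc.reference_age
    r = disc.annual_rate_qalys
    start, end = ref, person.death_age
    if end <= start:
        return 0.0
    cuts = {start, end}
    for e in utilities.utility_band_edges:
        if start < e < end:
            cuts.add(float(e))
    phase_of: list[tuple[float, float, float]] = []  # (a0, a1, disutility)
    for ca in person.cancers:
        windows = care_windows(ca.detection_age, person.death_age,
                               person.death_cause == "crc")
        for phase, (a0, a1) in windows.items():
            d = utilities.disutility[ca.stage][phase]
            phase_of.append((a0, a1, d))
            for e in (a0, a1):
                if start < e < end:
                    cuts.add(e)
    grid = sorted(cuts)
    total = 0.0
    for a0, a1 in zip(grid[:-1], grid[1:]):
        mid = 0.5 * (a0 + a1)
        u = utilities.baseline(mid)
        for w0, w1, d in phase_of:
            if w0 <= mid < w1:
                u -= d
        u = max(u, 0.0)
        total += u * _discounted_flow(a0, a1, r, ref)
    return total


def person_economics(person: Person, costs: CostInputs,
                     utilities: UtilityInputs,
                     disc: DiscountingPolicy) -> PersonEconomics:
    c_screen, c_comp, c_crc = accumulate_costs(person, costs, disc)
    q = accumulate_qalys(person, utilities, disc)
    return PersonEconomics(
        life_years=max(person.death_age - disc.reference_age, 0.0),
        qalys_discounted=q, cost_screening=c_screen,
        cost_complications=c_comp, cost_crc_care=c_crc)


def summarize_arm(econs: list[PersonEconomics] | "np.ndarray") -> StrategyOutcome:
    """Arithmetic per-person means over one arm."""
    if len(econs) == 0:
        raise ValueError("cannot summarize an empty arm")
    return StrategyOutcome(
        mean_life_years=float(np.mean([e.life_years for e in econs])),
        mean_qalys=float(np.mean([e.qalys_discounted for e in econs])),
        mean_cost_screening=float(np.mean([e.cost_screening for e in econs])),
        mean_cost_complications=float(np.mean([e.cost_complications for e in econs])),
        mean_cost_crc_care=float(np.mean([e.cost_crc_care for e in econs])),
        n=len(econs))
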