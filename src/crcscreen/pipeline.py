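"""End-to-end runs: cohort -> per-arm outcomes -> policy grid.

Per-strategy outcomes depend on the follow-up adherence uplift but not on
the modality mix, so a full scenario grid needs only the unscreened and
colonoscopy arms once plus one stool arm per follow-up uplift level.  All
arms for a given person reuse the same latent natural history (common
random numbers), so incremental quantities are estimated from paired
per-person differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import FixtureBundle, iter_cohort
from .economics import PersonEconomics, StrategyOutcome, person_economics, \
    summarize_arm
from .params import ModalityMix, ARMS
from .scenarios import (ScenarioSpec, apply_followup_uplift, grid_table,
                        scenario_mix, DEFAULT_ICER_THRESHOLD)
from .screening import ScreeningContext, simulate_person_screened

__all__ = ["ArmResults", "simulate_arms", "run_grid",
           "incremental_life_years", "population_series"]

_ECON_FIELDS = ("life_years", "qalys_discounted", "cost_screening",
                "cost_complications", "cost_crc_care")


@dataclass
class ArmResults:
    """Per-person economics for every simulated (arm, follow-up-uplift)."""

    n: int
    master_seed: int
    econ: dict  # (arm, fu_points) -> list[PersonEconomics]

    def key(self, arm: str, fu: float = 0.0):
        # colonoscopy and unscreened arms are insensitive to follow-up uplift
        return (arm, 0.0 if arm in ("colonoscopy", "unscreened") else float(fu))

    def series(self, arm: str, field: str, fu: float = 0.0) -> np.ndarray:
        return np.array([getattr(e, field)
                         for e in self.econ[self.key(arm, fu)]])

    def outcome(self, arm: str, fu: float = 0.0) -> StrategyOutcome:
        return summarize_arm(self.econ[self.key(arm, fu)])

    def outcomes_by_uplift(self, followup_grid) -> dict:
        return {float(fu): {arm: self.outcome(arm, fu) for arm in ARMS}
                for fu in followup_grid}


def _contexts(bundle: FixtureBundle, followup_uplifts,
              fatal_complications: bool) -> dict:
    comps = (bundle.complications if fatal_complications
             else bundle.complications.without_fatalities())
    ctxs = {}
    for arm in ("colonoscopy", "mt_sdna", "fit"):
        for fu in followup_uplifts:
            if arm == "colonoscopy" and fu != min(followup_uplifts):
                continue
            adh = apply_followup_uplift(bundle.adherence, fu)
            key = (arm, 0.0 if arm == "colonoscopy" else float(fu))
            ctxs[key] = ScreeningContext(
                strategy=bundle.strategies[arm], adherence=adh,
                performance=bundle.performance, complications=comps,
                surveillance=bundle.surveillance, params=bundle.nh_params,
                life_table=bundle.life_table)
    return ctxs


def simulate_arms(bundle: FixtureBundle, n: int, master_seed: int,
                  followup_uplifts=(0.0,),
                  fatal_complications: bool = True) -> ArmResults:
    """Simulate every arm the scenario grid needs, sharing latent histories.

    Returns per-person :class:`PersonEconomics` lists keyed by
    ``(arm, followup_uplift_points)``; the unscreened and colonoscopy arms
    are stored under uplift 0 only.
    """
    followup_uplifts = sorted({float(f) for f in followup_uplifts} | {0.0})
    ctxs = _contexts(bundle, followup_uplifts, fatal_complications)
    econ: dict = {("unscreened", 0.0): []}
    for key in ctxs:
        econ[key] = []
    cu = (bundle.costs, bundle.utilities, bundle.discounting)
    for seed_triple, unscreened in iter_cohort(bundle, n, master_seed):
        econ[("unscreened", 0.0)].append(person_economics(unscreened, *cu))
        for key, ctx in ctxs.items():
            p = simulate_person_screened(seed_triple, ctx, latent=unscreened)
            econ[key].append(person_economics(p, *cu))
    return ArmResults(n=n, master_seed=master_seed, econ=econ)


def population_series(arms: ArmResults, mix: ModalityMix, field: str,
                      fu: float = 0.0) -> np.ndarray:
    """Per-person mix-weighted value of one economics field.

    Because every arm simulates the *same* people, the population mean for
    a scenario is the mean of this paired series; differences of such
    series across scenarios carry the common-random-numbers variance
    reduction.
    """
    out = np.zeros(arms.n)
    for arm in ARMS:
        w = mix[arm]
        if w > 0:
            out += w * arms.series(arm, field, fu)
    return out


def incremental_life_years(arms: ArmResults, base_mix: ModalityMix,
                           spec: ScenarioSpec) -> np.ndarray:
    """Paired per-person incremental life-years of a scenario vs base."""
    mix = scenario_mix(base_mix, spec)
    base = population_series(arms, base_mix, "life_years", fu=0.0)
    scen = population_series(arms, mix, "life_years", fu=spec.followup_uplift)
    return scen - base


def run_grid(bundle: FixtureBundle, n: int, master_seed: int,
             screening_grid=(0, 5, 10, 15), followup_grid=(0, 5, 10, 15),
             shifts=(0,), threshold: float = DEFAULT_ICER_THRESHOLD,
             arms: ArmResults | None = None) -> pd.DataFrame:
    """Simulate (or reuse) the arms and assemble the full scenario table."""
    if arms is None:
        arms = simulate_arms(bundle, n, master_seed,
                             followup_uplifts=followup_grid)
    outcomes = arms.outcomes_by_uplift(followup_grid)
    return grid_table(outcomes, bundle.base_mix,
                      screening_grid=screening_grid,
                      followup_grid=followup_grid, shifts=shifts,
                      shift_split_mt_sdna=bundle.shift_split_mt_sdna,
                      threshold=threshold)
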