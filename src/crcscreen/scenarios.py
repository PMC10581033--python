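"""Policy scenario engine: modality mixes, behavior changes, ICERs.

The base case weight-averages per-strategy outcomes by real-world test
utilization.  Policy scenarios perturb that mix and the follow-up
adherence along three axes, composed in a fixed order:

1. *modality shift*  — move mass from colonoscopy to the stool tests,
   split between mt-sDNA and FIT by their utilization pattern;
2. *screening uplift* — move mass from unscreened to the screened
   modalities in proportion to their current weights;
3. *follow-up uplift* — add absolute percentage points to the follow-up
   colonoscopy adherence of both stool tests (capped at 1).

Per-strategy outcomes depend only on the follow-up uplift, so a whole
grid of scenarios re-uses a handful of simulated arms; every arm shares
the per-person natural-history draws (common random numbers), making the
incremental comparisons against the base case low-variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .economics import StrategyOutcome
from .params import AdherenceModel, ConfigError, ModalityMix, ARMS, \
    STOOL_MODALITIES

__all__ = [
    "ScenarioSpec", "IcerResult", "apply_modality_shift",
    "apply_screening_uplift", "apply_followup_uplift", "weighted_aggregate",
    "compute_icer", "scenario_mix", "grid_table",
]

DEFAULT_ICER_THRESHOLD = 100_000.0  # USD per QALY


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the policy grid, in absolute percentage points."""

    screening_uplift: float = 0.0
    followup_uplift: float = 0.0
    modality_shift: float = 0.0
    shift_split_mt_sdna: float = 0.44  # remainder goes to FIT

    def validate(self) -> None:
        if not (0 <= self.shift_split_mt_sdna <= 1):
            raise ConfigError("shift split must be in [0,1]")
        for v in (self.screening_uplift, self.followup_uplift,
                  self.modality_shift):
            if v < 0 or v > 100:
                raise ConfigError("uplift/shift points must be in [0,100]")


@dataclass(frozen=True)
class IcerResult:
    """Incremental cost-effectiveness of a scenario against the base case."""

    delta_cost: float
    delta_qaly: float
    icer: float  # NaN when delta_qaly == 0
    classification: str  # dominant_cost_saving | cost_effective |
    #                      not_cost_effective | dominated | neutral


def apply_modality_shift(mix: ModalityMix, shift_points: float,
                         split_mt_sdna: float = 0.44) -> ModalityMix:
    """Move ``shift_points`` absolute points from colonoscopy to stool tests."""
    s = shift_points / 100.0
    if mix["colonoscopy"] < s - 1e-12:
        raise ConfigError("modality shift exceeds the colonoscopy share")
    w = dict(mix.weights)
    w["colonoscopy"] -= s
    w["mt_sdna"] += split_mt_sdna * s
    w["fit"] += (1.0 - split_mt_sdna) * s
    out = ModalityMix(w)
    out.validate()
    return out


def apply_screening_uplift(mix: ModalityMix, uplift_points: float) -> ModalityMix:
    """Move ``uplift_points`` absolute points from unscreened to the screened
    modalities, allocated proportionally to their current weights."""
    u = uplift_points / 100.0
    if mix["unscreened"] < u - 1e-12:
        raise ConfigError("screening uplift exceeds the unscreened share")
    screened = [m for m in ARMS if m != "unscreened"]
    total = sum(mix[m] for m in screened)
    w = dict(mix.weights)
    w["unscreened"] -= u
    if total <= 0:
        raise ConfigError("no screened modality to receive the uplift")
    for m in screened:
        w[m] += u * mix[m] / total
    out = ModalityMix(w)
    out.validate()
    return out


def apply_followup_uplift(adherence: AdherenceModel,
                          uplift_points: float) -> AdherenceModel:
    """Raise follow-up colonoscopy adherence of both stool tests by
    ``uplift_points`` absolute points, capped at 1."""
    u = uplift_points / 100.0
    fu = {m: min(1.0, p + u)
          for m, p in adherence.followup_colonoscopy_adherence.items()}
    out = dc_replace(adherence, followup_colonoscopy_adherence=fu)
    out.validate()
    return out


def scenario_mix(base_mix: ModalityMix, spec: ScenarioSpec) -> ModalityMix:
    """Compose the mix operations in the fixed order shift -> uplift."""
    spec.validate()
    mix = apply_modality_shift(base_mix, spec.modality_shift,
                               spec.shift_split_mt_sdna)
    return apply_screening_uplift(mix, spec.screening_uplift)


def weighted_aggregate(outcomes: dict[str, StrategyOutcome],
                       mix: ModalityMix) -> StrategyOutcome:
    """Population outcome: mix-weighted average of per-arm outcomes."""
    mix.validate()
    for arm in ARMS:
        if mix[arm] > 0 and arm not in outcomes:
            raise ConfigError(f"missing outcomes for arm {arm!r}")
    def agg(attr: str) -> float:
        return sum(mix[a] * getattr(outcomes[a], attr)
                   for a in ARMS if mix[a] > 0)
    n = max(o.n for o in outcomes.values())
    return StrategyOutcome(
        mean_life_years=agg("mean_life_years"),
        mean_qalys=agg("mean_qalys"),
        mean_cost_screening=agg("mean_cost_screening"),
        mean_cost_complications=agg("mean_cost_complications"),
        mean_cost_crc_care=agg("mean_cost_crc_care"),
        n=n)


def compute_icer(scenario: StrategyOutcome, base: StrategyOutcome,
                 threshold: float = DEFAULT_ICER_THRESHOLD) -> IcerResult:
    """ICER of a scenario against the base case, with dominance labels.

    A scenario that costs less and yields more QALYs dominates the base
    case (its ICER is negative); one that costs more and yields fewer
    QALYs is dominated.  In the south-west quadrant (cheaper, less
    effective) the ratio is savings per QALY forgone and is acceptable
    when it meets the threshold.  The threshold boundary is inclusive.
    """
    dc = scenario.mean_cost_total - base.mean_cost_total
    dq = scenario.mean_qalys - base.mean_qalys
    if dq == 0.0:
        icer = math.nan
        cls = "neutral" if dc == 0 else (
            "dominant_cost_saving" if dc < 0 else "dominated")
        return IcerResult(dc, dq, icer, cls)
    icer = dc / dq
    if dq > 0:
        if dc < 0:
            cls = "dominant_cost_saving"
        else:
            cls = "cost_effective" if icer <= threshold else "not_cost_effective"
    else:
        if dc >= 0:
            cls = "dominated"
        else:  # cheaper but less effective: savings per QALY forgone
            cls = "cost_effective" if icer >= threshold else "not_cost_effective"
    return IcerResult(dc, dq, icer, cls)


def grid_table(arm_outcomes: dict[float, dict[str, StrategyOutcome]],
               base_mix: ModalityMix,
               screening_grid=(0, 5, 10, 15),
               followup_grid=(0, 5, 10, 15),
               shifts=(0,),
               shift_split_mt_sdna: float = 0.44,
               threshold: float = DEFAULT_ICER_THRESHOLD) -> pd.DataFrame:
    """Assemble the policy grid as a tidy table.

    ``arm_outcomes[fu][arm]`` holds the per-arm outcome simulated under a
    follow-up uplift of ``fu`` points; only the stool arms actually vary
    with ``fu``.  The base case is the (0, 0, 0) cell.
    """
    base = weighted_aggregate(arm_outcomes[0], base_mix)
    rows = []
    for shift in shifts:
        for su in screening_grid:
            for fu in followup_grid:
                spec = ScenarioSpec(screening_uplift=su, followup_uplift=fu,
                                    modality_shift=shift,
                                    shift_split_mt_sdna=shift_split_mt_sdna)
                mix = scenario_mix(base_mix, spec)
                agg = weighted_aggregate(arm_outcomes[fu], mix)
                res = compute_icer(agg, base, threshold)
                rows.append({
                    "shift": shift, "screening_uplift": su,
                    "followup_uplift": fu,
                    "lyg_per_1000_incremental":
                        (agg.mean_life_years - base.mean_life_years) * 1000.0,
                    "cost_per_person_incremental": res.delta_cost,
                    "delta_qaly": res.delta_qaly,
                    "icer": res.icer,
                    "classification": res.classification,
                    "mean_cost_total": agg.mean_cost_total,
                    "mean_life_years": agg.mean_life_years,
                })
    df = pd.DataFrame(rows)
    df.insert(0, "scenario_id",
              [f"s{r.shift:g}_u{r.screening_uplift:g}_f{r.followup_uplift:g}"
               for r in df.itertuples()])
    return df
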