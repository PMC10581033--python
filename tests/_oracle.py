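"""Brute-force discrete-time simulator used as an independent oracle.

Re-implements the unscreened natural-history *model* (same distributions
and rules) with a completely different engine: fixed 1/24-year time steps,
per-step Bernoulli draws for adenoma onset and other-cause death, and its
own random stream.  Used to cross-check the event-driven engine's
age-specific cumulative colorectal-cancer incidence.
"""

from __future__ import annotations

import math

import numpy as np

DT = 1.0 / 24.0


def _step_rates(params, sex: str, max_age: float) -> np.ndarray:
    """Onset intensity per step for integer-step midpoint ages."""
    steps = int(max_age / DT)
    ages = (np.arange(steps) + 0.5) * DT
    lam = np.empty(steps)
    for i, a in enumerate(ages):
        lr = params.onset_log_rate(a, sex)
        lam[i] = math.exp(lr) if math.isfinite(lr) else 0.0
    return lam


def _death_step_probs(life_table, sex: str) -> np.ndarray:
    q = life_table.q(sex)
    return 1.0 - (1.0 - np.minimum(q, 1.0)) ** DT  # per-step hazard


def simulate_incidence_by_age(params, life_table, n: int, seed: int,
                              by_age: float = 75.0) -> float:
    """Fraction of n people with a symptomatic CRC presentation by ``by_age``
    (censored by other-cause death), via per-step simulation."""
    rng = np.random.default_rng(seed)
    steps = int(by_age / DT)
    lam_cache = {s: _step_rates(params, s, by_age) for s in ("female", "male")}
    dq_cache = {s: _death_step_probs(life_table, s) for s in ("female", "male")}
    hits = 0
    for _ in range(n):
        sex = "male" if rng.random() < 0.5 else "female"
        frailty = (math.exp(rng.normal(-0.5 * params.frailty_sd ** 2,
                                       params.frailty_sd))
                   if params.frailty_sd > 0 else 1.0)
        # other-cause death: first step whose per-step hazard fires
        dq = dq_cache[sex]
        death_age = by_age + 1.0
        u_death = rng.random(steps)
        for k in range(steps):
            if u_death[k] < dq[int(k * DT)]:
                death_age = (k + 1) * DT
                break
        horizon = min(death_age, by_age)
        # adenoma onsets: per-step Bernoulli with intensity*dt
        p_on = np.minimum(lam_cache[sex] * frailty * DT, 1.0)
        n_steps_alive = int(horizon / DT)
        u_on = rng.random(n_steps_alive)
        onset_steps = np.nonzero(u_on < p_on[:n_steps_alive])[0]
        first_clinical = math.inf
        locs = list(params.location_probs)
        lp = np.array([params.location_probs[l] for l in locs])
        for k in onset_steps:
            onset = (k + rng.random()) * DT
            loc = locs[int(rng.choice(len(locs), p=lp))]
            g = params.growth_frechet[loc]
            t10 = g["scale"] * (-math.log(rng.random())) ** (-1.0 / g["shape"])
            # annual transition checks at onset anniversaries
            trans = None
            j = 0
            while True:
                t0 = onset + j
                if t0 >= horizon:
                    break
                size = min(params.initial_diameter_mm
                           * (10.0 / params.initial_diameter_mm) ** (j / t10),
                           params.max_diameter_mm)
                if rng.random() < params.transition_annual_prob(size, t0, sex):
                    cand = t0 + rng.random()
                    if cand < horizon:
                        trans = cand
                    break
                j += 1
            if trans is None:
                continue
            site = "rectum" if loc == "rectum" else "colon"
            sj = params.sojourn_lognormal[site]
            sojourn = rng.lognormal(sj["mu"], sj["sigma"])
            clinical = trans + sojourn
            if clinical < horizon:
                first_clinical = min(first_clinical, clinical)
        if first_clinical <= by_age:
            hits += 1
    return hits / n
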