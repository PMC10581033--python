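# Methods

`crcscreen` is a person-level, continuous-time microsimulation of
colorectal cancer (CRC) natural history with screening overlays and a
cost-effectiveness layer. This note records the model, its assumptions,
the defaults and why they were chosen, and what the synthetic setup does
and does not show about real populations.

## Natural history

Each simulated person carries a latent disease course drawn once from a
dedicated random stream.

**Adenoma onset.** A non-homogeneous Poisson process with log-intensity

    log λ(a) = β₀ + β_male·[male] + γ(a) + log Z,

where γ(a) is piecewise constant over age bands and Z is a per-person
log-normal frailty with E[Z] = 1 (`frailty_sd` is the SD of log Z,
default 0.6). The intensity is piecewise constant, so the process is
simulated exactly band by band (Poisson count, uniform placement).
Frailty multiplies onset only, not malignant transformation.

**Growth.** Lesions start at 1 mm and grow exponentially, scaled so the
diameter is exactly 10 mm at onset plus a Fréchet-distributed
time-to-10-mm (location-specific shape/scale; defaults give a median of
roughly 20–25 years, so most adenomas never become large). Diameter is
capped at 50 mm.

**Malignant transformation.** Each whole year after onset carries a
Bernoulli trial with annual probability logit⁻¹(c₀ + c_size·d +
c_age·(a−65) + c_male), evaluated at the interval start; a success
places the transition uniformly within that year. With a constant
annual probability p the waiting time is geometric plus U(0,1), mean
1/p − ½.

**Preclinical sojourn and stage.** Sojourn time is log-normal by site
(colon/rectum; default medians ≈ 3 years). The stage at symptomatic
presentation is drawn from a four-point distribution (defaults
0.19/0.33/0.27/0.21 for stages I–IV). The stage path within the sojourn
splits the sojourn into equal dwell fractions per stage, so
screen-detection earlier in the sojourn yields the same or an earlier
stage, ending exactly at the symptomatic stage.

**Survival.** CRC cause-specific survival is Weibull with a shared shape
(0.9) and per-stage scales (45/22/10/2.2 years), with accelerated-
failure-time modifiers for sex, site, and age at diagnosis. One uniform
quantile is reserved per cancer and reused when screening changes the
stage or age at detection: the same person at an earlier stage always
survives at least as long (pathwise stage dominance), which removes
coupling noise from stage-shift benefits.

**Competing mortality.** Other-cause death comes from a bundled
synthetic Gompertz–Makeham life table (annual probabilities by sex,
final age 110 absorbing), giving a remaining life expectancy at 65 of
about 19–21 years. Death age is the minimum of other-cause death,
CRC death (detection + survival draw), and a fatal colonoscopy
complication.

**Why these defaults.** The published calibrations of models in this
family are external artifacts; the defaults here were chosen once to be
epidemiologically plausible for an average-risk U.S.-like population —
lifetime unscreened CRC risk ≈ 5%, cumulative incidence between 65 and
85 among entrants ≈ 3%, CRC mortality ≈ 2% — and are not fitted to any
registry. Users who need a published calibration supply its parameter
files through the same configuration interface (`read_bundle`).

## Cohort

The cohort enters at age 65 (Medicare-age, configurable), sex ratio
50/50 at birth. Eligibility — alive and free of diagnosed CRC at entry —
is enforced by rejection sampling *within each person's seed slot*
(attempt *a* of person *i* uses stream `(i, a)`), so person *i*'s
accepted draw never depends on the cohort size. That makes common
random numbers (CRN) valid across runs of different sizes.

## Screening

Strategies: colonoscopy every 10 years, mt-sDNA every 3 years, or FIT
annually, ages 65–75. A stool test is positive with the CRC sensitivity
if a preclinical cancer is present, otherwise with the sensitivity of
the most advanced adenoma size category (≤5, 6–9, ≥10 mm), otherwise
with 1 − specificity. A positive stool test triggers a follow-up
colonoscopy with the configured adherence (base case 71.5% after
mt-sDNA, 46.7% after FIT); a missed follow-up resumes the routine stool
schedule. Colonoscopy detects each lesion independently with
size-category sensitivity × reach, removes what it detects (cancelling
that lesion's latent transformation), detects preclinical cancers with
CRC sensitivity × reach (stage read off the stage path at the exam
age), and draws a complication (bleeding/perforation/other) with
polypectomy-dependent probabilities; perforation carries a small
fatality probability by default.

After any completed colonoscopy the person follows post-polypectomy
surveillance intervals (no adenoma → 10 y, low-risk → 5 y, high-risk
→ 3 y, until age 85) and routine stool testing does not resume — the
no-findings 10-year interval reproduces routine colonoscopy screening
naturally. Symptomatic presentation at any point ends screening and
triggers stage-specific care. Within-arm initial adherence defaults to
100%: population-level uptake is carried entirely by the modality-mix
weights, because the base case weights arm outcomes by observed
real-world utilization and applying uptake at both levels would
double-count it.

**Randomness discipline.** All natural-history draws live on stream 0 of
the person's seed; all screening draws on stream 1, pre-drawn as arrays
indexed by (screening-round or surveillance slot, lesion/cancer index).
A screened run therefore embeds the bit-identical unscreened trajectory
(tested exactly), and scenarios differing only in adherence share every
other draw — raising adherence adds follow-up colonoscopies without
reshuffling anything, which makes incremental estimates low-variance
and directionally stable.

## Economics

Costs (one currency-year, defaults 2022 USD, Medicare-flavored): stool
tests and colonoscopies (with/without polypectomy) at their exam age;
complication costs; CRC care by stage and phase of care. Phases:
initial = first 12 months after diagnosis, terminal = final 12 months
before a CRC death (taking precedence backwards when survival < 24
months; non-CRC deaths have no terminal phase), continuous in between
at an annualized rate. Initial/terminal lump sums are prorated by the
fraction of their window actually lived. Point events are discounted at
their exact age; flows are integrated in yearly slices discounted at
slice midpoints (half-year convention). Everything discounts to age 65
at 3%/year for both costs and QALYs by default (configurable,
including 0%).

QALYs integrate an age-band baseline utility minus the active care
phase's stage-specific disutility, floored at 0. Life-years gained
(LYG) are reported undiscounted, per 1,000 people, against the
unscreened arm — consistent with the convention of reporting
undiscounted LYG alongside discounted QALYs in U.S. cost-effectiveness
practice.

## Scenario engine

The base case weights the four arm outcomes (colonoscopy, mt-sDNA, FIT,
unscreened) by real-world utilization (45.3/10.7/13.7/30.3%). Policy
cells compose, in fixed order: (1) modality shift — move mass from
colonoscopy to stool tests, split 44/56 between mt-sDNA and FIT;
(2) screening uplift — move mass from unscreened to screened arms
proportionally to their current weights (the allocation is a modeling
choice; alternatives are configurable); (3) follow-up uplift — add
absolute points to both stool tests' follow-up adherence, capped at 1.
Only the follow-up uplift changes arm-level outcomes, so a full 4×4×3
grid reuses ten simulated arms.

ICERs are ΔCost/ΔQALY against the base case on the same per-person
seeds. Classification: cheaper & more effective → dominant
(cost-saving; negative ICER); dearer & more effective → cost-effective
iff ICER ≤ $100,000/QALY (boundary inclusive); dearer & less effective
→ dominated; cheaper & less effective → judged on the reversed ratio
(savings per QALY forgone ≥ threshold is acceptable); ΔQ = 0 resolves
by the sign of ΔC.

## Numerical and testing choices

* Problem sizes: statistical tests run at 10⁴–10⁵ with 3-standard-error
  tolerances (chi-square and binomial checks at α = 0.001); the
  acceptance script uses 50,000 people per arm, where the Monte-Carlo
  SE of base-case LYG is a few per 1,000.
* An independent brute-force oracle (1/24-year discrete time stepping,
  separate code path and RNG) reproduces the event-driven engine's
  unscreened cumulative incidence by age 75 within Monte-Carlo error.
* Hand-priced economics cases are asserted to 1e-9; component
  additivity and the zero-discount identity are exact.
* Ties: an exam scheduled exactly at symptomatic presentation performs
  the exam first; multiple cancers detected at one exam are managed by
  the most advanced stage; float tolerance of 1e-9 at sojourn
  boundaries.

## What the synthetic setup does not show

The generator emulates the *structure* of the decision problem, not any
specific registry: absolute LYG, costs, and ICERs under the default
parameters are indicative magnitudes, not predictions. Passing tests
demonstrate internal correctness (event logic, CRN contracts,
estimator arithmetic, classification rules) and directional validity
(screening gains life-years; higher adherence gains more; stool-heavy
mixes are cheaper per gained life-year under these cost defaults) — not
agreement with any published calibrated model. Serrated-pathway
biology, adenoma regression, imperfect bowel prep, capacity
constraints, and probabilistic sensitivity analysis are out of scope.
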