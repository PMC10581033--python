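# crcscreen

Person-level microsimulation of colorectal cancer (CRC) screening and
its cost-effectiveness, aimed at policy questions of the form: *if a
coverage change nudges screening behavior — more people screened, more
follow-up colonoscopies completed after a positive stool test, or a
shift from colonoscopy to stool-based testing — what happens to
life-years, costs, and the incremental cost-effectiveness ratio (ICER)?*

The package is built for health-economics and screening-policy
modelers. It simulates the adenoma–carcinoma sequence in continuous
time, overlays screening strategies with common random numbers (CRN),
prices the resulting event timelines with phase-of-care accounting, and
evaluates a grid of behavior-change scenarios against a
utilization-weighted base case.

## Model in brief

* **Natural history.** Adenomas arise from a non-homogeneous Poisson
  process with intensity exp(β₀ + β_sex + γ(age))·Z, Z a log-normal
  frailty; grow deterministically to 10 mm at a Fréchet-distributed
  time; transform malignantly with an annual logistic probability in
  size, age, and sex; progress through a log-normal preclinical sojourn
  with a non-decreasing stage path; and trigger Weibull cause-specific
  survival by stage, site, sex, and age at diagnosis, against life-table
  other-cause mortality.
* **Screening.** Colonoscopy every 10 y, mt-sDNA every 3 y, or annual
  FIT at ages 65–75; stool positives need a follow-up colonoscopy
  (adherence 71.5% after mt-sDNA, 46.7% after FIT in the base case);
  polypectomy removes lesions and starts surveillance; colonoscopies can
  cause (rarely fatal) complications.
* **Economics.** Discounted costs (screening, complications, CRC care
  by stage × initial/continuous/terminal phase) and QALYs; LYG reported
  undiscounted per 1,000 versus no screening.
* **Scenarios.** Base-case mix 45.3% colonoscopy / 10.7% mt-sDNA /
  13.7% FIT / 30.3% unscreened; policy axes are overall-screening
  uplift, follow-up-colonoscopy uplift (each 0–15 points), and a
  colonoscopy→stool shift (0/5/10 points, split 44/56 mt-sDNA/FIT);
  ICERs classified against a $100,000/QALY threshold, with dominance
  (cheaper *and* more effective) reported as negative ICERs.

Default parameters are documented, plausible values — not a published
calibration. Every input is replaceable through the YAML/CSV bundle
interface (`crcscreen fixtures`, `read_bundle`). See `docs/methods.md`
for the full model description and its limitations.

## Worked example

```sh
crcscreen simulate --n 5000 --seed 11 --out demo
```

```
        arm    n  mean_life_years  mean_qalys  mean_cost_screening  mean_cost_complications  mean_cost_crc_care  mean_cost_total
colonoscopy 5000        19.531698   11.589035          2206.476657                88.829539          659.783506      2955.089702
    mt_sdna 5000        19.445553   11.549478          2105.942335                19.418336         2418.630603      4543.991274
        fit 5000        19.427339   11.541474           559.864400                18.744208         2613.355774      3191.964381
 unscreened 5000        19.334472   11.499309             0.000000                 0.000000         4351.546613      4351.546613
```

Each row is one arm's per-person means from age 65: screening adds
life-years versus no screening (e.g. colonoscopy 19.53 vs 19.33, i.e.
~197 LYG per 1,000 in that arm) and converts CRC-care spending into
screening spending. The scenario grid compares behavior changes against
the utilization-weighted base case:

```sh
crcscreen grid --n 5000 --seed 11 --out demo
```

```
scenario_id  shift  screening_uplift  followup_uplift  lyg_per_1000_incremental  cost_per_person_incremental          icer       classification
   s0_u0_f0      0                 0                0                  0.000000                     0.000000           NaN              neutral
   s0_u0_f5      0                 0                5                  1.077061                   -23.832539 -56522.808370 dominant_cost_saving
  s0_u0_f10      0                 0               10                  2.810786                   -42.757916 -35485.275725 dominant_cost_saving
   s0_u5_f0      0                 5                0                  8.174417                   -55.298864 -14884.412540 dominant_cost_saving
   ...
```

A 5-point follow-up-adherence increase alone yields ~1.1 incremental
LYG per 1,000 and saves ~$24 per person; every behavior-change cell is
cheaper *and* more effective than the base case (negative ICER =
dominant). `crcscreen report --results demo` renders a summary, and
`crcscreen fixtures --out dir` materializes all inputs for editing.

The library API mirrors the CLI: `default_bundle()`,
`simulate_person_unscreened`, `simulate_person_screened`,
`simulate_arms`, `run_grid`, `compute_icer`, and the parameter
dataclasses in `crcscreen.params`.

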