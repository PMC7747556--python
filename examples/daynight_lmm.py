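"""Which covariates drive daytime vs nighttime activity?

Per-day mean counts in each stratum (owner-diary nights vs the rest)
are log-transformed and modelled with a random intercept per dog; all
16 subsets of {day type, age, sex, mass} are ranked by AIC and the
models within delta-AIC 10 of the best are conditionally averaged. The
printed tables mirror the conventional mixed-model reporting layout:
standardized estimate (SE), z, p, and 95% CI per predictor.
"""

from actiflm import SimConfig, generate_cohort
from actiflm.io import CohortTable, cohort_summaries
from actiflm.lmm import fit_both_strata

cohort = generate_cohort(SimConfig(seed=8))  # 42 dogs x 14 days, default effects
table = CohortTable(
    subjects=cohort.truth[["id", "age", "sex", "mass"]],
    series={s.subject_id: s for s in cohort.series},
    diaries=cohort.diary,
)

summaries = cohort_summaries(table)
results = fit_both_strata(summaries, table.subjects)

for stratum, res in results.items():
    best = res.candidates.iloc[0]
    print(f"\n=== {stratum} model ===")
    print(f"best candidate: {best['terms']}  (AIC {best['AIC']:.1f})")
    print(res.table1_style().to_string(index=False))

print(
    "\nThe simulator injects a weekend daytime boost plus mild, window-localized"
    "\nage and sex effects. The day-type CI excludes 0 decisively in the daytime"
    "\nmodel; the localized effects dilute in a whole-day mean (the pointwise"
    "\nF-test is the tool that finds them), and no nighttime term is injected,"
    "\nso nighttime CIs all include 0."
)
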