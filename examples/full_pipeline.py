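"""One-call pipeline: simulate -> validate -> smooth -> flm -> lmm -> report.

Writes every intermediate artifact (epoch CSVs, QC report, Fourier
coefficients, F-test curves and intervals, coefficient tables) plus a
markdown report with the figures, all under ./pipeline_out.
Equivalent CLI: actiflm run-all --seed 5 --out pipeline_out
"""

from actiflm.pipeline import RunConfig, run_pipeline

config = RunConfig(
    cohort_dir="pipeline_cohort",
    out_dir="pipeline_out",
    n_permutations=200,       # 500 is the analysis default; reduced for a quick demo
    grid_step_minutes=10,
    seed=5,
    sim_overrides={"n_subjects": 12, "n_days": 7},
)
products = run_pipeline(config)

print(f"report: {products['report']}")
for entry in products["log"]:
    print(f"  stage {entry['stage']:<9} {entry['seconds']:6.1f}s")
for cov, res in products["flm"].items():
    print(f"FLM {cov}: {res.significant_mask().sum()}/{res.grid.size} grid points significant")
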