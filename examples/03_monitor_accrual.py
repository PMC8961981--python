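"""Monitor model robustness as the registry accrues data.

Emulates quarterly data cuts (each 1.3% larger than the last), refits the
relapse model at every cut, and tracks two robustness measures against the
first cut:

  * the median span of the empirical 90% coefficient intervals across 20
    random-initialization refits (small spans = data, not initialization,
    determine the coefficients), and
  * the out-of-sample C-index on a fixed held-out evaluation cohort.

Run:  python examples/03_monitor_accrual.py     (~5 minutes on one CPU)
"""

from dmtrank import (
    ModelSpec,
    default_generator_spec,
    generate_cohort,
    generate_growth_series,
    monitor_growth,
)

spec = default_generator_spec()
series = generate_growth_series(spec.replace(n_patients=300), n_cuts=5, seed=4)
eval_cohort = generate_cohort(spec.replace(n_patients=1500), seed=905)

report = monitor_growth(
    series,
    ModelSpec(outcome="relapse", catalogue=spec.catalogue),
    eval_cohort,
    n_refits=20,
    seed=0,
)

print(f"{'cut':>3} {'patients':>8} {'rows':>6} {'C out':>7} {'dC out':>8} {'med span':>9}")
for c in report.cuts:
    print(f"{c.cut:>3} {c.n_patients:>8} {c.n_rows:>6} "
          f"{c.c_index_out:>7.4f} {c.delta_out:>+8.4f} {c.median_span:>9.4f}")
print("\nA healthy accruing registry shows non-increasing spans and a"
      "\nnon-degrading out-of-sample C-index relative to the first cut.")
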