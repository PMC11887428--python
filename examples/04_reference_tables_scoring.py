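"""Score the bundled computed-vs-experimental CCS tables.

The package ships the drift-tube reference tables (stepped-field and
single-field CCS per glycan, plus the computed CCS of the assignment
workflow before and after conformational sampling) and recomputes every
statistic from the CCS columns.
"""

from glyccs.scoring import (
    error_summary,
    isomer_ordering,
    load_reference_table,
    success_rate,
    table1_percent_differences,
)

t1 = load_reference_table("table1")
pct = table1_percent_differences(t1)["pct_difference"]
print(f"stepped vs single field discrepancy: mean %D = {pct.mean():.1f} over {len(t1)} glycans")

for name, label in (("table2", "before sampling"), ("table3", "after sampling")):
    df = load_reference_table(name)
    count, frac = success_rate(df, threshold=3.0, policy="averaged")
    best, bfrac = success_rate(df, threshold=3.0, policy="best_of_methods")
    means = error_summary(df)
    print(f"{label}: {count}/{len(df)} within 3% of the averaged reference "
          f"({100 * frac:.0f}%), {100 * bfrac:.0f}% against the better method; "
          f"mean %error (single/stepped/avg) = "
          f"{means['single']['mean']}/{means['stepped']['mean']}/{means['averaged']['mean']}")

# isomer trend reporting: beta anomers larger than alpha, 1->3 larger than 1->4
ccs = {"beta_1_3": (251.0, 1.5), "alpha_1_3": (247.0, 1.5), "beta_1_4": (245.5, 1.5)}
report = isomer_ordering(ccs, [("beta_1_3", "alpha_1_3", ">"), ("beta_1_3", "beta_1_4", ">")])
print(report.to_string(index=False))
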