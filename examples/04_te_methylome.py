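"""TE-silencing classifiers on a synthetic reciprocal-F1 methylome.

Generates per-cytosine mCHG/mCHH data for the F1 establishment experiment
(wild type high, F1s intermediate, planted subsets shifted by the ldl2 or
ashh3 mutation), classifies TE genes by the four-comparison criterion, and
compares the calls with the planted truth.
"""
from epiloop import TEMethylomeConfig, generate_te_methylomes
from epiloop.methylome import classify_ashh3_regulated, classify_ldl2_regulated

tem = generate_te_methylomes(TEMethylomeConfig(n_te=400, seed=11))
meth = tem.meth_by_sample("CHG")
ids = tem.units.ids()

for name, classify, col in (
    ("LDL2-regulated", classify_ldl2_regulated, "ldl2_regulated"),
    ("ASHH3-regulated", classify_ashh3_regulated, "ashh3_regulated"),
):
    calls = classify(meth, ids, min_counts=100)
    called = {u for u, c in calls.items() if c.label != "none"}
    planted = set(tem.truth.index[tem.truth[col]])
    print(f"{name} TE genes: called {len(called)}, planted {len(planted)}, "
          f"true positives {len(called & planted)}, "
          f"false positives {len(called - planted)}")

# A TE gene is called only when all four mCHG comparisons (two reciprocal
# crosses x two replicates) cross the +-0.05 threshold and every sample has
# more than 100 CHG read calls -- the replicate-consistent criterion keeps
# binomial sampling noise from producing spurious calls.
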