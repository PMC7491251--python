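"""Relate 3C contact frequency to pairwise co-expression at 5 kbp bins.

Simulates a contact map whose frequencies decay with circular distance and
are boosted where bins share the planted coupling field, then groups all
bin pairs more than 20 kbp apart by contact frequency and compares each
group's correlation distribution with the lowest-contact group
(two-sided rank-sum, Bonferroni-adjusted).
"""

import cpedscan as cs

truth = cs.make_truth(500_000, 1, [50_000], seed=6)
bundle = cs.simulate_expression(truth, bin_width=5_000, noise_sd=0.2, seed=6)
contacts = cs.simulate_contacts(truth, bin_width=5_000, decay_exponent=1.0,
                                coupling_boost=5.0, seed=6)

assoc = cs.build_pairs(bundle.expression_matrix(), contacts, min_linear_distance=20_000)
assoc = cs.group_and_test(assoc, n_groups=8)

print(f"pairs kept (distance > 20 kbp): {len(assoc.pairs)}")
print("group  n      mean_r   ci95     p_bonferroni_vs_group1")
tests = {int(r["group"]): r["p_bonferroni"] for r in assoc.tests.to_dict("records")}
for row in assoc.group_summary.to_dict("records"):
    g = int(row["group"])
    p = tests.get(g)
    print(f"{g:5d}  {row['n']:5d}  {row['mean_r']:+.3f}  {row['ci95']:.3f}    "
          f"{'-' if p is None else f'{p:.2g}'}")
# Mean correlation rising monotonically with the contact group reproduces
# the expected signature of spatial-proximity-coupled expression; with
# coupling_boost=1 the trend disappears (pure distance-decay null).
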