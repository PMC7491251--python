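"""Ask whether regulator binding explains the co-expression.

Two synthetic regulators are planted: one whose targets sit exactly at the
coupling anchors (its targets genuinely co-express) and one with uniformly
random targets. For each, correlation coefficients are pooled within four
bin subsets: At (bins within 500 bp of a target), Between (mock sites at
circular midpoints between real sites), Random (repeated same-size draws)
and Without (all pairs not touching a target bin).
"""

import cpedscan as cs
from cpedscan.regulon import RegulatorTargets

truth = cs.make_truth(1_000_000, 1, [40_000], seed=7)
bundle = cs.simulate_expression(truth, noise_sd=0.2, seed=7)
band = cs.correlation_band(bundle.expression_matrix(), max_lag=200_000)

for name in ["RegAnchor", "RegUniform"]:
    rt = RegulatorTargets.from_positions(
        name, truth.regulators[name], bundle.grid, flank=500
    )
    sc = cs.subset_distributions(band, rt, bundle.grid, n_random=100, seed=1)
    means = {row["subset"]: row["mean"] for row in sc.summary.to_dict("records")}
    print(f"{name}: " + "  ".join(f"{k}={v:+.3f}" for k, v in means.items()))
# An anchored regulator shows mean(At) well above Random/Without (its bins
# share a latent factor); a uniform regulator's At mean is just another
# random draw. This is the genome-wide subset comparison; whether excluding
# At bins destroys the local periodicity is checked by exclusion_reprofile.
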