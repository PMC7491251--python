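"""Test the transcription-orientation (supercoiling-gradient) hypothesis.

If transcription-induced supercoiling drove the distance-periodic
co-expression, profiles aligned to transcription direction would be
asymmetric: elevated correlation downstream, depressed upstream. Bins are
assigned an orientation from the stranded annotation, counter-clockwise
bins' profiles are mirrored, and the up/downstream asymmetry is summarized.
A direction-symmetric plant (cosine coupling) shows none; a sawtooth plant
decaying downstream of each anchor shows a positive asymmetry.
"""

import cpedscan as cs

for kernel, label in [("cosine", "symmetric plant"), ("sawtooth", "directional plant")]:
    if kernel == "cosine":
        # genes centered on the coupling anchors: the genic subset is
        # direction-symmetric around the extrema of the cosine field
        operons = [(s - 1_000, s + 1_000, "+") for s in range(20_000, 200_000, 20_000)]
    else:
        # promoter at the anchor, gene body downstream: coupling decays
        # clockwise from each anchor, an explicitly directional plant
        operons = [(s, s + 1_500, "+") for s in range(0, 200_000, 20_000)]
    truth = cs.SyntheticTruth(
        genome_length=200_000,
        regions=[(0, 200_000, 20_000, 1.0)],
        operons=operons,
        structural_rna=[], regulators={}, factor_seed=13, kernel=kernel,
    )
    bundle = cs.simulate_expression(truth, noise_sd=0.2, seed=19)
    band = cs.correlation_band(bundle.expression_matrix(), max_lag=8_000)
    table = cs.assign_orientation(bundle.annotation, bundle.grid)
    mirrored = cs.mirror_profiles(band, table)
    whole = (0, truth.genome_length)
    contrast = cs.supercoiling_contrast(
        cs.average_profiles(mirrored, whole), cs.average_profiles(band, whole)
    )
    print(f"{label:18s} discarded bins: {table.discard_fraction:.0%}  "
          f"asymmetry: {contrast.asymmetry:+.4f} +/- {contrast.asymmetry_ci95:.4f}")
# Asymmetry is the mean over positive lags of r(downstream) - r(upstream) on
# the oriented profile; a value inside its CI of zero is the signature the
# analysis reports for supercoiling-independent co-expression.
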