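# cpedscan

Distance-dependent co-expression analysis for circular bacterial
chromosomes.

Bacterial genes separated by tens of kilobases on the chromosome often
change expression together, and the strength of that co-expression varies
*periodically* with the genomic distance between them — a signature of
nucleoid structure (spatially anchored DNA loops sharing local RNA
polymerase pools) rather than of classical regulation. `cpedscan` is a
library for detecting and dissecting that signature in multi-condition
RNA-seq data:

1. **Binning** — per-sample coverage (SAM/BAM or bedGraph) is counted into
   fixed 500 bp bins, normalized to fragments per million (FPM), bins
   overlapping rRNA/tRNA/tmRNA are nulled, and biological replicates are
   averaged per growth phase.
2. **CPED profiles** — for every bin, the Pearson correlation of its
   expression changes (across growth phases) with each neighbor out to
   ±200 kbp, as a function of signed circular genomic lag:
   r<sub>i</sub>(ℓ) = corr(x<sub>i</sub>, x<sub>i+ℓ</sub>).
3. **Periodicity** — profiles are averaged over 400 kbp windows sliding at
   5 kbp and the dominant wavelength in 10–70 kbp is estimated per window
   with the classical normalized Lomb–Scargle periodogram, which tolerates
   the missing lags left by masking. Peak credibility is reported as
   PNmax = −ln *p*, with *p* = 1 − (1 − e<sup>−z</sup>)<sup>M</sup> the
   Horne–Baliunas false-alarm probability of the peak power *z*
   (PNmax > 3 ⇔ *p* < 0.05). A shuffled-genome permutation null
   (bins assigned random unique positions) is built the same way.
4. **Falsification analyses** — three companion modules test the obvious
   alternative explanations: `orientation` re-expresses lags relative to
   transcription direction (supercoiling gradients would make profiles
   asymmetric), `regulon` compares correlation distributions at/between/
   without regulator targets and re-profiles regions with target bins
   excluded, and `hic` joins 5 kbp-binned expression correlations to 3C
   contact frequencies (pairs >20 kbp apart, grouped by contact, rank-sum
   tests vs the lowest-contact group with Bonferroni adjustment).

A first-class synthetic-data module (`cpedscan.synth`) generates genomes
with planted periodic coupling, operons, structural-RNA bins, regulator
target sets and contact maps, so the whole pipeline is testable without
any downloads.

## Worked example

```bash
python examples/01_simulate_and_scan.py
```

```
windows scanned:           200
median peak period:        39,118 bp (planted 40,000)
windows with PNmax > 3:    100%
median PNmax:              184.4
```

A 1 Mbp circular genome is simulated with a 40 kbp coupling wavelength
(5 growth phases × 2 replicates, log-noise SD 0.2, Poisson counts), and
the windowed scan recovers the plant in every window: 39,118 bp is the
frequency-grid point nearest 40 kbp (the grid resolves ~2 kbp at this
period), and PNmax ≈ 184 means the peak is overwhelmingly unlikely under
the no-periodicity null. The other examples exercise orientation
mirroring (`02`), regulator subsets (`03`), the contact-frequency
association (`04`) and the DNA contour geometry that motivates the
plectoneme picture (`05`).

There is also a thin CLI mirroring the stages
(`cpedscan simulate|binexpr|cped|scan|orient|regulon|hic|all`); run
`cpedscan --help`.

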