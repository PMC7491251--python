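# Methods

## The statistic

For a circular chromosome tiled into bins of width *w* (default 500 bp,
step = width; a sliding tiling is supported), each sample's fragment
counts are normalized to fragments per million and biological replicates
are averaged per condition, giving a bins × conditions matrix *X*. The
CPED profile of bin *i* is the Pearson correlation of its row with the row
at each signed circular lag ℓ,

r_i(ℓ) = corr(X_i, X_{i+ℓ/step}),  ℓ = ±step … ±max_lag (lag 0 excluded),

computed on the phase-averaged matrix (n = number of conditions, 5 in the
default design). Profiles of all unmasked bins whose start lies in a
region are averaged per lag, with a 95% CI of the mean
(1.96·sd/√n per lag). The dominant wavelength of an averaged profile is
the peak of the classical normalized Lomb–Scargle periodogram over a
period range (default 10–70 kbp), and its credibility is
PNmax = −ln p with p the Horne–Baliunas false-alarm probability
p = 1 − (1 − e^(−z))^M of the peak power z. The natural logarithm makes
PNmax > 3 equivalent to p < 0.05. A genome-wide map records
(window center, peak period, PNmax) for 400 kbp windows sliding at 5 kbp.

## Parameters that matter

| parameter | default | units | why |
| --- | --- | --- | --- |
| bin width / step | 500 / 500 | bp | fine enough to avoid gene-length bias; non-overlapping so each fragment counts once. A 1000/500 sliding tiling is configurable. |
| max_lag | 200,000 | bp | profiles span ±200 kbp; comfortably more than two periods of the longest searched wavelength |
| window / slide | 400,000 / 5,000 | bp | window must hold several periods; the slide sets map resolution |
| period range | 10,000–70,000 | bp | the band in which macrodomain-scale periodicity is searched |
| oversampling | 4 | – | frequency-grid spacing 1/(4·span); period resolution ≈ P²/(4·span), ~2 kbp at P = 40 kbp |
| n_randomizations | 400 | – | shuffled-genome replicates for the empirical null |
| flank | 500 | bp | half-width of the regulator-target window; regulators with ≤ 20 associated bins are dropped |
| min_linear_distance | 20,000 | bp | strict pair exclusion in the contact association, removing operon- and supercoiling-scale co-expression |
| contact groups | 8 (also 21) | – | equal-width intervals on log10(contact), giving unequal memberships; quantile mode available |

## Normalization and masking choices

Bins overlapping any rRNA/tRNA/tmRNA feature (≥1 bp) are nulled, and by
default they are excluded from the per-million denominator: depletion
efficiency differs between libraries, and leaving the (huge) structural-RNA
counts in the denominator would propagate that technical variation into
every other bin. The alternative (masked bins in the denominator) is a
flag. Masking happens before normalization; replicates are averaged after
normalization. Fragments are assigned to bins by midpoint (coverage-sum
mode exists for sliding tilings). Internally all coordinates are 0-based
half-open; GFF3 is converted at the boundary.

In the correlation band, any pair touching a masked bin is missing, and a
bin with a constant row is missing everywhere (Pearson undefined). The
band requires complete rows; the scalar `pearson` helper implements
complete-case filtering for irregularly missing vectors.

## Periodogram calibration

Two numerical decisions matter and both are documented here because they
are easy to get wrong:

**Positive lags only.** An averaged CPED profile is nearly symmetric in
lag — the entries at −ℓ re-measure almost exactly the bin pairs measured
at +ℓ. Feeding both sides to the periodogram would double-count evidence
and inflate every peak's significance, so the scan evaluates periodograms
on the positive-lag half (configurable; `lomb_scargle` accepts any lag
set, e.g. a full two-sided profile).

**Effective independent frequencies.** The false-alarm probability needs
the number M of effectively independent frequencies. The naive count
(frequency-grid points divided by the oversampling factor) assumes the
profile is white noise, but an averaged CPED profile is an
autocovariance-like statistic of few-condition data: its realized spectrum
fluctuates far more than white noise, and with the naive M about a quarter
of pure-noise windows exceed PNmax 3. The default M is therefore the
Horne–Baliunas empirical regression M(N) = −6.362 + 1.193·N + 0.00098·N²
in the number of profile points N, which keeps the measured false-alarm
rate at the nominal ~5% for exactly this profile class (and ~1–8% across
whole simulated noise genomes). M remains overridable
(`ScanConfig.m_indep`). The shuffled-genome permutation null is the
assumption-free check and is implemented as a first-class operation.

Other numerics: p is clipped to [1e-300, 1] before the log; exact peak-power
ties resolve to the smaller period; windows wrap circularly (a linear mode
truncates at the ends); windows with fewer than 8 usable profile points are
skipped and counted.

## What the generator emulates

`cpedscan.synth` inverts the analysis' model of the data. Each region of
the genome carries one latent "spatial factor" f(k, p) ~ N(0,1) per growth
phase p; bin b couples to its region's factor with weight w(b), and its
log-expression in sample (p, rep) is a·w(b)·f(k,p) + ε with
ε ~ N(0, noise_sd) per bin/sample (replicates share f, mirroring averaged
biological duplicates). Counts are Poisson around the exponentiated signal
scaled to a library size (default 2 × 10⁶ fragments, five phases in
duplicate); structural-RNA intervals get 100× inflated intensities so
masking failures are loud; operon members share the signal of their first
bin.

Coupling kernels, evaluated at bin centers:

- **cosine** (default): w = cos(2π·x/P). The averaged CPED profile is then
  genuinely sinusoidal with period P (maxima at multiples of P), anchor
  bins of one family correlate +1 and antiphase bins −1 in the noiseless
  limit, and the periodogram fundamental dominates. A narrow kernel
  (tried first) produces a spike train whose harmonics (P/2, P/3 …) fall
  inside the 10–70 kbp search band with comparable power, making peak
  recovery ambiguous — a property of the construction, not of the scan.
- **triangular**: narrow tent of configurable half-width around each
  anchor — periodicity carried *entirely* by a known bin set, used to
  demonstrate that excluding those bins destroys the pattern.
- **sawtooth**: weight decays clockwise from each anchor — a
  transcription-direction-asymmetric plant for the orientation analysis.

Contacts follow a circular distance-decay power law d^(−α) (α default 1)
multiplied by boost^(w_i·w_j) for same-region pairs, so spatial proximity
and co-expression are coherently coupled; boost = 1 is the pure
distance-decay null. A binary "boosted if anchored" rule would boost
anti-correlated (antiphase) pairs equally and erase the monotone
contact–correlation relation the model is supposed to embody, which is why
the boost is graded by the coupling product.

What the generator does **not** emulate: real library-size and GC biases,
overdispersed (negative binomial) counts, transcription kinetics,
replication-associated copy-number gradients, or genuine 3C matrices with
balancing artifacts. Passing tests therefore demonstrate that the pipeline
recovers the structure it is designed to detect under its own statistical
model — not that any particular real genome contains that structure.

## Design decisions in the follow-up analyses

- Orientation: "clockwise" = forward strand of the reference (flippable);
  a bin is oriented only if all overlapping genes (≥1 bp) agree; the
  discarded fraction is logged. Expression strength = mean phase-averaged
  FPM; quintiles are assigned with index-order tie-breaking so strata are
  equal ±1. The asymmetry summary is the mean over positive lags of
  r(+ℓ) − r(−ℓ) on the oriented profile; its CI combines per-lag CIs in
  quadrature and ignores inter-lag correlation (adequate for a summary
  flag, not a formal test).
- Regulon: target position = strand-aware 5' gene end (configurable to
  leftmost coordinate); mock "between" sites are circular midpoints toward
  the clockwise successor site; random subsets are drawn from unmasked
  bins, seed-deterministic and size-exact; the At-vs-others comparison is
  a two-sided rank-sum test. Exclusion re-profiling drops excluded bins'
  *profiles* (rows); their appearances as partners in other bins' profiles
  remain, which is exactly why a pattern carried only by the excluded bins
  collapses (both profile ends must be anchored).
- Contact association: pairs with missing or zero contact are dropped and
  counted (zero cannot be placed on a log-width grouping); group rank-sum
  p-values are Bonferroni-multiplied by (groups − 1) and capped at 1. Pairs
  sharing bins are not independent, so these p-values order the evidence
  rather than calibrate it exactly — the group-mean trend is the readout.
- Pipeline: one run seed expands into per-stage seeds via
  `numpy.random.SeedSequence` (each below 2³¹); every output TSV embeds the
  config hash.

## Problem sizes

The test suite and the acceptance script run on synthetic genomes of
0.1–1 Mbp (200–2,000 bins at 500 bp; 20–200 scan windows), with 20
replicate genomes per stochastic rate; the band computation is vectorized
(standardized rows + rolled dot products) and the window averaging uses
prefix sums, so a 1 Mbp genome scans in about a second. The same code
paths handle a 4.6 Mbp chromosome at the default 400 kbp/5 kbp scan
unchanged.

## Known limitations

- The analytic PNmax is calibrated for the package's own profile class;
  for unusual designs (very few conditions, tiny windows) the shuffled-
  genome null is the trustworthy reference.
- Rank-sum tests in the regulon and contact modules treat pairwise
  coefficients as exchangeable samples; with shared bins they are not
  independent, so significance there is comparative, not exact.
- `pearson` reproduces complete-case semantics, but the band requires
  row-level completeness (masking is row-level, so nothing is lost in the
  supported designs).
- Contact matrices are consumed as provided ("processed"); no ICE/KR
  balancing is performed.
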