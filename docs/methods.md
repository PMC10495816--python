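# Methods

## Scope

`mdiaquant` implements the quantification stack of a dimethyl-labeled
multiplexed-DIA (mDIA) workflow in which one isotope channel carries a
constant, high-input *reference* proteome and the remaining *target*
channels carry low-input samples (down to single cells). The package covers
report parsing and q-value filtering, dimethyl label-mass chemistry,
reference-channel precursor quantification (RefQuant), MaxLFQ protein
roll-up, experiment-level QC metrics, and a ground-truth synthetic report
generator used to verify every stage.

## Label chemistry

Dimethylation converts each primary amine of a peptide (the N-terminus and
each lysine epsilon-amine) into a dimethylamino group. The light tag adds
C2H4 (28.0313 Da monoisotopic); heavier channels replace hydrogens by
deuterium and, for the heaviest, carbons by 13C:

| channel | composition vs light   | tag mass (Da) | delta vs d0 (Da) |
|---------|------------------------|---------------|------------------|
| d0      | C2H4                   | 28.0313       | 0                |
| d2      | +2 (2H - 1H)           | 30.0439       | 2.0126           |
| d4      | +4 (2H - 1H)           | 32.0564       | 4.0251           |
| d6      | +6 (2H - 1H)           | 34.0690       | 6.0377           |
| d8      | +2 (13C-12C) +6 (2H-1H)| 36.0757       | 8.0444           |

Masses are computed from standard monoisotopic isotope masses (1H
1.0078250319, 2H 2.0141017780, 12C 12, 13C 13.0033548) and rounded to four
decimals for display only. Note the d6-to-d8 spacing is 2.0067 Da per
label, not 2.0126, because that step trades four deuteriums for two 13C.
Tryptic peptides carry one label (C-terminal Arg) or two (C-terminal Lys);
Lys-N places both labelable amines at the peptide N-terminus, so every
zero-missed-cleavage peptide carries two labels and adjacent channels of
the 5-plex scheme separate by ~4 Da at the precursor and b-ion level.
Labeling efficiency is the intensity fraction of fully labeled peptides
among all detected peptides; partially labeled species count as unlabeled.

## Filtering

Two q-value presets are shipped, both with strict `<` comparisons:

* bulk: `Global.PG.Q.Value < 0.01`, `PG.Q.Value < 0.05`,
  `Channel.Q.Value < 0.01`
* single-cell: `Lib.PG.Q.Value < 0.01`, `Q.Value < 0.01`,
  `Channel.Q.Value < 0.15`

The relaxed single-cell channel threshold reflects that channel-level
identification transfers from the dominant reference; the count-based FDR
machinery (below) is the tool for checking that a chosen threshold holds.

## RefQuant

For each precursor in each run, every shared ion between a target channel
and the reference channel contributes one ratio: fragment ions pair by
fragment index, the MS1 area adds one further ratio. Ions where either
side is missing or zero contribute nothing (a zero is an integration
failure, not a measurement). With 6-13 fragments plus MS1 this yields
typically 7-14 ratios.

The ratio distribution is right-skewed: a fraction of target-channel ions
is dominated by interference, inflating target/reference ratios away from
the true (small) value. The estimator therefore sorts ratios ascending and
retains the first `max(1, floor(0.40 * n))` of them — 2 of 7, 5 of 14 —
and takes their arithmetic mean as the precursor ratio R. The retained-set
mean is computed with exact (compensated) summation. The mean is taken on
the linear scale by default; a geometric (log-space) mean is available via
`RefQuantConfig(log_space_mean=True)`.

The target intensity is `R x scale`, where the precursor-specific scaling
factor is the median reference intensity over **all** runs — this cross-run
pooling is what lets the constant reference stabilize quantification. The
scaling source falls back through `Ms1.Area` → `Precursor.Translated` →
`Precursor.Normalised` (each requiring at least two non-missing values)
→ the per-run summed ion intensities. A precursor never observed in any
reference channel cannot be quantified and is dropped (counted and listed).
A precursor/run/channel with no shared ion yields a missing matrix entry,
never a zero.

Known bias: on weakly contaminated data the lower-quantile mean
systematically underestimates the ratio (the retained set is the lower
tail of the noise distribution). The 40% retention is calibrated for the
skewed distributions this workflow actually produces; comparisons between
two target channels, where the trim bias largely cancels, are accurate to
a few percent in the recovery tests.

## Protein roll-up and normalization

MaxLFQ: per protein, the log2 ratio between two samples is the median of
per-precursor log2 ratios over precursors observed in both; per-sample
log-abundances solve the least-squares system over all such pairs,
restricted to the largest connected component of the sample graph (other
samples stay missing). The free constant is fixed by equating the summed
linear protein intensity with the summed observed precursor intensity. On
noise-free multiplicative data this recovers sample profiles exactly (up
to one global factor), which the tests assert at 1e-9.

Median normalization operates in log2 space: each sample median is shifted
to the median of the original sample medians, making the transform
idempotent. Note that for designs where *every* protein carries the mixing
ratio (same proteome at different loads), median normalization removes the
design signal by construction; channel ratios in such benchmarks are
therefore expressed relative to an anchor channel (d0) instead.

CVs use the sample standard deviation (n-1) over linear intensities,
reported in percent; rows with fewer than two values are excluded.

## QC metrics

* Count-based FDR: `max(identifications in empty channels) /
  min(identifications in filled channels)` at each Channel.Q.Value cutoff
  in a sweep {0.01, 0.05, 0.1, 0.15, 0.2, 0.3, 0.45, 1.0}. Undefined
  (missing) where no filled channel has identifications.
* Completeness by abundance quartile: rows ranked by decreasing mean
  intensity, split 4-ways (remainder to earlier quartiles), fraction of
  observed entries per quartile. The shot-noise expectation for a mean
  abundance x (in detection units) is `1 - exp(-x)`.
* Cell filtering: stage 1 removes cells whose identified-protein count is
  at or below 1% of the experiment-wide distinct protein count; stage 2
  keeps cells within 1.5 standard deviations (inclusive) of the median
  count, both statistics computed on stage-1 survivors. The 1% denominator
  and the post-stage-1 statistics are deliberate choices where the
  procedure admits more than one reading; both are logged per cell.
* Pairwise Pearson correlation on pairwise-complete log2 intensities
  (minimum 3 shared rows), with the median off-diagonal value as summary.

## Synthetic data generator

The generator emulates the long-report dialect and the evaluation designs:
scBenchmark (10 ng reference, 250 pg targets), scQuant (graded targets
62.5-2000 pg), scDecoy (deliberately empty targets), scReference
(reference graded 250 pg-10 ng), the three-plex 17:2:1 bulk mix, the
five-plex 1:2:4:2:1 accuracy mix, and a mixed-species design with
opposing per-species gradients.

Per ion (fragment f of precursor of protein p, run r, channel c):

```
I = A_p * w_f * (amount_c / 250 pg) * exp(N(0, sigma_ion)) + background
```

* `A_p` — protein abundance, log-normal with sigma of one decade
  (about four orders of magnitude across +/-2 sigma), median 100
  intensity units at one single-cell equivalent (250 pg).
* `w_f` — per-fragment response, log-normal (median exp(-0.5), sigma 0.8);
  6-13 fragments per precursor plus one MS1 ion with response 2.0, so a
  fully observed precursor yields 7-14 ratios.
* `sigma_ion` — combines a constant multiplicative CV (0.25 single-cell
  presets, 0.10 bulk presets) with a shot-noise term `CV^2 = 5 / I`
  (one elementary ion count = 5 intensity units): faint ions are
  relatively noisier, which is the mechanism by which a high reference
  load stabilizes ratio estimates.
* `background` — with probability 0.10 an ion receives additive
  exponential interference whose scale is 5x the median single-cell ion
  at a 10 ng total run load, scaling proportionally with the total
  material loaded in the run; MS1 areas additionally sit on a
  load-independent chemical-noise floor (1x the median single-cell ion)
  because MS1 spectra are not isolation- or mobility-filtered. Empty
  channels have no envelope to integrate and only acquire signal through
  the per-ion interference events.
* Dropout — an ion is missing with probability `exp(-flux / 20)` where
  flux is the expected signal plus any realized interference; gating on
  expected flux rather than the noisy recorded area keeps the missingness
  law exactly `1 - exp(-x/lambda)` and avoids conditional-on-detection
  truncation bias. Base-driven and background-driven detections are drawn
  separately; a row whose every detected ion is background-driven is a
  false channel assignment.
* Channel q-values are a deliberate caricature sufficient to exercise the
  filtering and count-based-FDR plumbing: rows with at least one
  base-driven detection draw `U(0, 0.01)`, background-only rows draw
  `U(0, 1)`. Other q-value columns draw uniformly below their preset
  thresholds.

Generation is fully driven by one `numpy` generator seeded from the
config; identical config and seed give byte-identical files.

What the generator does **not** model: spectra (no m/z, ion mobility or
co-elution), retention-time structure, correlated noise between fragments
of one precursor, label-incorporation chemistry, cross-run normalization
drift, and any realistic q-value score distribution. Passing tests
therefore demonstrate correctness of the algorithms under a controlled
noise model with the stated mechanisms, not end-to-end performance on
instrument data.

## Problem sizes and numerical choices

The recovery experiments use 100-320 proteins (about 500-1800 precursors)
over 3-5 runs, chosen so each check resolves a 10% deviation from truth
comfortably while the whole suite runs in well under a minute per
experiment. Ties in the ratio sort are broken by fragment-index order
(stable sort) for determinism. Median-of-even-count values follow the
usual midpoint convention. The MaxLFQ least-squares system is pinned by a
zero-mean row before anchoring; connected components come from
`scipy.sparse.csgraph`. Degenerate inputs (empty ratio lists, all-missing
samples, runs without a reference) raise informative errors rather than
propagating NaNs.

## Known limitations

* The 40% retention fraction is treated as a fixed calibration of the
  workflow, not re-estimated from data.
* One MS1 ratio per precursor; isotopologue-resolved MS1 peaks are not
  separately represented in the consumed report dialect (extra columns
  are accepted but not synthesized).
* No imputation and no differential-expression layer; the output is the
  quantification matrix plus QC.
* The count-based FDR is a bound built from run-level counts; it does not
  model precursor-level dependence between channels.
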