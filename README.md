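# mdiaquant

Reference-channel quantification for dimethyl-labeled multiplexed DIA
(mDIA) proteomics.

In an mDIA experiment several isotopically labeled samples are acquired in
one DIA run and distinguished by their dimethyl mass offsets (channels
d0-d8). Loading one channel with a constant, high-input *reference*
proteome anchors identification and quantification of the low-input
*target* channels — down to single cells (~250 pg of peptide). This
package implements the quantification stack for such data:

* **Report I/O** — parse, validate and q-value-filter DIA-NN-style long
  report tables (bulk and single-cell filter presets), resolve channel
  identities, and map runs/channels to roles via a design table.
* **Label chemistry** — dimethyl tag masses from isotope composition
  (28.0313 / 30.0439 / 32.0564 / 34.0690 / 36.0757 Da), per-channel mass
  deltas, labels-per-peptide rules for trypsin and Lys-N, labeling
  efficiency from evidence tables.
* **RefQuant** — the core estimator. For each precursor, run and target
  channel, every shared fragment ion and the MS1 area contribute one
  target/reference ratio. The ratios are sorted ascending, the lowest 40%
  retained (at least one), and their mean R — robust against the
  interference-inflated upper tail — is scaled by the cross-run median
  reference intensity to give the target-channel intensity:

  `intensity(precursor, run, target) = R * median_runs(reference intensity)`

* **Protein quantification** — MaxLFQ roll-up (pairwise median log-ratios,
  least squares over the connected sample graph), median normalization,
  CV summaries.
* **QC** — count-based empty-channel FDR (`max(empty) / min(filled)`),
  completeness by abundance quartile with the `1 - exp(-x)` shot-noise
  expectation, two-stage cell filtering, summed signal, pairwise Pearson
  correlations.
* **Synthetic data** — a ground-truth generator for the evaluation designs
  (scBenchmark, scQuant, scDecoy, scReference, 17:2:1 and 1:2:4:2:1
  mixes, mixed species), emitting reports the rest of the package reads
  unchanged. See `docs/methods.md` for the noise model.

## Worked example

Simulate the single-cell benchmark design (10 ng reference in d0, one
250 pg single-cell equivalent in each of d4 and d8, four runs) and run the
full pipeline — filter, RefQuant, protein roll-up, QC:

```sh
mdiaquant simulate --preset scBenchmark --seed 7 --out demo
mdiaquant pipeline demo/report.tsv demo/design.tsv --out demo/out
```

```
... INFO mdiaquant: simulated 8095 report rows -> demo/report.tsv
... INFO mdiaquant: refquant: 676 precursors quantified
... INFO mdiaquant: proteinquant: 120 proteins
... INFO mdiaquant: pipeline done -> demo/out
```

`demo/out/` now holds the filtered report, the precursor matrix with
RefQuant provenance (`n_total`, `n_retained`, `R`, scale and scale
source), the protein matrix, a QC summary and a run manifest. The protein
matrix has one column per target-channel sample:

```
               run1_d4  run1_d8  run2_d4
protein_group
P00000           459.1    379.7    406.2
P00001          1344.7   1358.0   1070.3
P00002           500.5    478.4    632.9
```

All eight samples contain the same 250 pg proteome, so protein intensities
agree across columns up to measurement noise: the median protein CV across
the eight samples is 9.5% and the median pairwise Pearson correlation of
log2 intensities is 0.96 (from `demo/out/qc_summary.json`). Completeness
is near 1.0 in all abundance quartiles at this load and becomes strongly
abundance-dependent at lower target loads.

The label-scheme tables print the per-channel chemistry:

```sh
$ mdiaquant labels 3plex-trypsin
channel  label_mass_da  delta_vs_d0_da  example_peptide  example_shift_da
0        28.0313        0.0             PEPTIDEK         56.0626
4        32.0564        4.0251          PEPTIDEK         64.1128
8        36.0757        8.0444          PEPTIDEK         72.1513
```

## Layout

```
src/mdiaquant/
  report_io.py   report parsing, filters, designs
  chemistry.py   dimethyl label masses and efficiency
  refquant.py    reference-channel ratio estimation
  proteins.py    MaxLFQ, normalization, CVs
  qc.py          FDR, completeness, cell filters, correlation
  simulate.py    ground-truth synthetic reports
  cli.py         command-line entry points
docs/methods.md  model, parameters, noise model, limitations
tests/           unit, property and end-to-end tests
```
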