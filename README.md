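# ampcyto

Quantification pipeline for **signal-amplified single-cell mass cytometry
(CyTOF)**.  Cyclic-extension amplification chemistry multiplies the number of
metal-ion detectors bound per antibody, pushing low-abundance epitopes
(transcription factors, phosphorylation sites) above the instrument's
detection floor.  This package implements the downstream *analysis* such an
experiment needs, for cytometrists and computational biologists working with
event-level dual-count data:

- **Preprocessing & I/O** — event tables (FCS 3.0/3.1 or CSV) of nonnegative
  ion counts with per-event condition/timepoint/thermal-cycle metadata, and
  the standard variance-stabilizing transform `data = asinh(dataraw / 5)`.
- **Amplification & linearity quantification** — cells are divided into ten
  equal-width bins of reference-channel (e.g. secondary-antibody) expression
  pooled over all cycle conditions; per-bin medians of the amplified channel
  yield the fold amplification `median(bin 10, condition) / median(bin 10,
  baseline)`, the signal-to-noise ratio `median(bin 10) / median(bins 1–3)`,
  the ratio-to-bin-10 linearity profiles, and the Pearson concordance between
  amplified and reference channels.
- **Crosstalk matrices** — from a K-condition single-stain panel: column-wise
  min-max-normalized signal `N`, crosstalk ratio `N[i, j] / N[i, i]` per
  unmatched initiator–detector pair, off-diagonal average, >10% flags, and a
  ±1-mass-spillover adjacency breakdown.
- **BP-R² signaling networks** — the binned pseudo-R²
  `max(0, 1 − Σ(y − ŷ_bin)² / Σ(y − ȳ)²)` over equal-frequency bins of x,
  scored per marker pair per stimulation timepoint; pairs whose cumulative
  score over eight timepoints reaches 6.2 (mean 0.775) become edges of an
  undirected signaling network.
- **Trajectory statistics** — per-timepoint coefficients of variation,
  min-max-normalized mean trajectories, the shared half-maximal point
  (HMP = global max of the mean trajectory / 2), the trapezoid area of the
  trajectory above the HMP (total signaling response, signal·minutes), and
  the peak time; plus the signed-pseudotime rule for two-phase timecourses.
- **IMC summarization** — label mask + channel images → per-cell table:
  objects with fewer than 30 pixels removed, per-cell ion counts averaged
  over pixels.
- **Synthetic generator** — Poisson ion-count simulations of all four
  experiment designs with known ground truth (gains, leakage matrices,
  latent couplings, object means), used throughout the tests.

Each stage is an sklearn-style estimator (`fit`, fitted attributes with a
trailing underscore, `get_params`/`set_params`) with thin functional
wrappers, so stages compose with sklearn tooling.

## Worked example

Simulate an amplification-gradient experiment with a known 13× gain at 500
thermal cycles and recover it by the binning procedure:

```python
from ampcyto import (SimulationTruth, simulate_amplification_experiment,
                     AmplificationQuantifier)

truth = SimulationTruth(seed=7, n_cells=10_000,
                        cycle_gain={1: 1.0, 100: 11.0, 500: 13.0})
table = simulate_amplification_experiment(truth)
quant = AmplificationQuantifier(baseline_condition="cycle_1").fit(table)
print(quant.report_.round(3).to_string(index=False))
```

```text
condition_id  fold_vs_baseline   snr  snr_enhancement  pearson_r
     cycle_1             1.000 200.5            1.000      0.981
   cycle_100            10.838 434.6            2.168      0.956
   cycle_500            12.918 518.0            2.584      0.954
```

`fold_vs_baseline` recovers the configured gains (10.838 ≈ 11, 12.918 ≈ 13);
`snr` is the bin-10 median over the pooled negative-bin (untransfected-cell)
median, whose enhancement grows because amplification multiplies signal but
not background; and `pearson_r` is the transformed-scale concordance between
the amplified and reference channels.

A command-line entry point `ampcyto` exposes the same stages as subcommands
(`simulate`, `transform`, `ampquant`, `crosstalk`, `bpr2`, `integrals`,
`sign-pseudotime`, `imc-summarize`); run `ampcyto --help`.

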