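# Methods

This note documents the models and procedures `ampcyto` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Data model and preprocessing

An `EventTable` holds a cells × channels matrix of nonnegative, finite ion
("dual") counts with per-event metadata: `condition_id`, `timepoint_min`
(minutes), `cycle_count` (thermal cycles), optional `phase_label`.  Channel
identities resolve through `ChannelInfo` records (marker, metal, integer mass
number in Da, role, initiator/detector barcode indices).  Counts are
variance-stabilized as `asinh(x / cofactor)` with cofactor 5, the standard
CyTOF choice; the transform is strictly monotone, maps 0 → 0 and inverts
exactly as `cofactor · sinh(y)`.  Analyses default to the scale that matches
how each statistic is conventionally reported: binning and concordance on
the transformed scale, medians/fold/SNR/CV/trajectory means on raw counts
(every stage takes a `transformed` flag to switch).

FCS support is a purpose-built reader/writer for list-mode floating-point
FCS 3.0/3.1 (single data segment; ANALYSIS segments and compensation
keywords are ignored with a logged warning).  The writer emits 64-bit floats
so write→read round-trips are exact.  FCS has no standard per-event
metadata slot, so metadata travels in a companion `<stem>.meta.csv` keyed by
0-based event index.

## Amplification quantification by equal-width binning

Cells from all cycle conditions are pooled and the reference channel's range
(transformed scale by default) is split into `n_bins` = 10 equal-width bins;
interior bins are left-closed/right-open and the last bin right-closed so
the maximum falls in bin 10.  Pooled edges are what make bins comparable
across conditions.  Bins with fewer than 10 events (configurable floor) are
flagged and excluded from ratios.  From per-(condition, bin) medians of the
amplified channel:

- **linearity ratio** `median(bin b) / median(bin 10)` per condition; under
  unbiased gain this profile is scale-invariant, so its drift across cycle
  conditions measures amplification bias (raw-count medians are used by
  default — on the transformed scale the ratio is not gain-invariant);
- **fold amplification** = bin-10 median relative to the baseline condition
  (raw counts);
- **SNR** = bin-10 median over the pooled median of events in the negative
  bins (default bins 1–3, the untransfected population).  The SNR
  numerator/denominator choice is this package's definition — "signal-to-
  noise" has no universal formula for this assay — and is declared here
  rather than asserted as canonical;
- **concordance** = Pearson r between amplified and reference channels on
  transformed values, per condition.

## Crosstalk matrices

For a K-initiator single-stain panel, `S[i, j]` summarizes the raw counts of
detector j in condition i (median by default; mean available).  Each
detector column is min-max normalized across conditions,
`N = (S − min) / (max − min)`, and the crosstalk ratio of an unmatched pair
is `N[i, j] / N[i, i]` with the diagonal forced to 1.  Pairs above a 10%
flag threshold are reported, annotated as mass-adjacent when |Δmass| = 1,
with off-diagonal mean ratios stratified by mass distance to separate
instrument ±1-Da spillover from sequence crosstalk.  The matched condition
is identified from the panel (initiator_id = detector_id), never by column
argmax, so a mislabeled panel raises (zero matched signal) instead of being
silently renormalized.  Min-max normalization assumes every detector column
contains at least one non-leaking condition; if leakage into a detector is
dense across all conditions, the column minimum absorbs part of it and
ratios are biased low by that minimum — a property of the statistic itself,
acceptable because real panel crosstalk is sparse.

## BP-R² and network construction

`bp_r2(x, y)` ranks events into 10 equal-frequency bins of x (ties broken by
stable event order, making scores deterministic), drops bins below
`min_bin_count` = 20, fits the piecewise-constant predictor ŷ = bin mean of
y, and returns `max(0, 1 − SS_res / SS_tot)` over retained events.  The
score is invariant under strictly monotone transforms of x and affine
transforms of y; negative raw values (possible after bin dropping) clip
to 0.  Scores are computed per ordered marker pair per timepoint on
transformed values, then summed and averaged per pair.  An undirected edge
joins a pair when the larger of its two ordered summaries reaches the
threshold: cumulative 6.2 over eight stimulation timepoints, equivalently a
mean of 0.775 (the two rules give identical edge sets by construction).
Edge strength is that maximum; the max-over-directions rule is this
package's choice for an undirected network built from an asymmetric score.

Trajectory statistics report, per marker × condition × timepoint, the mean
signal, the population-sd coefficient of variation (divisor n, raw counts;
undefined and flagged when the mean is 0), the event count, and a min-max
normalized mean within each series.  `sign_pseudotime` negates the [0, 1]
pseudotime of cells in a designated phase so two consecutive transitions
(e.g. EMT then MET) share one signed axis; when no cell carries the phase it
warns and returns the input unchanged.

## Signaling integrals

The half-maximal point of a marker is half the maximum of its mean
trajectory over *all* conditions and timepoints — shared across conditions,
which is what makes the integrals comparable between treatments.  The total
signaling response is the area between the piecewise-linear trajectory and
the HMP where the trajectory exceeds it, by trapezoid integration with
linearly interpolated threshold crossings; segments below the HMP contribute
0 (no negative contributions), and the fraction of unsigned area clipped
away is reported (`clipped_fraction_`) so heavily sub-HMP trajectories are
visible.  Timepoints are used exactly as recorded, in minutes, never
resampled; there is no extrapolation outside the observed window.  Peak time
is the observed timepoint of maximal mean, earliest on ties.

## IMC per-cell summarization

A label mask (0 = background) plus channel images become one event per
object: objects with *fewer than* `min_pixels` = 30 pixels are removed (a
30-pixel object survives — removal is a strict inequality), each retained
object's channel value is the arithmetic mean of its pixels, rows are
ordered by ascending object id.  Ids need not be contiguous; disconnected
pixels sharing an id are pooled (label semantics, no re-segmentation).
Border-touching objects are kept by default (`exclude_border` available).

## Synthetic generator

Counts are Poisson (gamma-Poisson optional via `overdispersion`) around
`detection_efficiency · epitope · gain + background_rate`.  Defaults:
`detection_efficiency` 0.1 and log-scale epitope location log(300), i.e.
~30 dual counts unamplified for a median positive cell — a low-abundance
epitope near the practical CyTOF floor, the regime amplification targets;
background 0.5 counts/channel.

- **Amplification design**: per cycle condition, a positive/negative cell
  mixture measured on a cycle-independent reference channel and an amplified
  channel.  Positives draw epitope from a *log-uniform* gradient spanning
  `expr_log_mean ± √3·expr_log_sd` (sd 1.2 → ~2 decades), emulating the
  broad expression gradient of transient transfection and populating all ten
  equal-width bins; a log-normal option exists but leaves the top bin nearly
  empty at these sample sizes.  Negatives are log-normal shifted 4 log-sd
  down.  The default gain schedule `gain(c) = 1 + (F_max − 1)(1 − e^{−c/τ})`
  with F_max = 13, τ = 120 cycles is an invented saturating form — gains are
  empirical outcomes, no mechanistic claim is made — and any explicit
  `cycle_gain` map overrides it.
- **Crosstalk design**: K single-stain conditions of expressing cells, mean
  counts `efficiency · gain · epitope · leakage[i, j] + background`, with
  the full amplification gain applied (orthogonality is assessed on
  amplified signal; unamplified leaked medians would quantize to zero
  counts).  ±1-mass spillover is parameterized separately (`mass_spillover`)
  from the sequence-leakage matrix so the two mechanisms can be disentangled.
- **Signaling design**: per marker a transient activation pulse
  `baseline + amplitude·(t/p)·e^{1−t/p}`; each cell draws a latent around
  the pulse mean with sd shrinking with normalized activation
  (`sd_tightening` 0.5), which produces the post-stimulation CV drop of
  synchronized signaling; coupled markers are monotone link functions
  (linear or saturating) of the driver's latent plus Gaussian noise; counts
  are Poisson around `count_scale · softplus(latent)`.  Planted couplings
  with noise sd 0.05 at count scale 100 give true BP-R² ≈ 0.83 — above the
  0.775 edge threshold by design, since a planted edge is meant to be
  detectable.
- **Images**: exact-size 4-connected blobs grown pixel-by-pixel without
  overlap; channel values constant per object plus optional truncated
  Gaussian noise; the truth table records exact pixel counts and means
  recomputed from the final images.

All generators are deterministic given the truth seed (independent fixed
stream tags per design).  What the generator does **not** emulate: doublets,
debris and bead events, mass-tag barcoding, acquisition drift,
non-Poisson instrument noise beyond the optional gamma mixing, spatial
structure or segmentation errors in images.  Passing recovery tests
therefore demonstrates correctness of the quantification procedures under
the stated count model, not robustness to those real-data artifacts.

## Numerical choices and problem sizes

Equal-width bin assignment uses `searchsorted` on exact edges; the
reference-bin ratio is forced to exactly 1 to guard round-off.  Equal-
frequency binning splits the stable argsort into near-equal chunks.
Degenerate inputs fail fast with named errors: constant bin channel,
constant y in BP-R², zero matched crosstalk signal, zero reference-bin
median, missing metadata fields.  Recovery checks run at the sizes a
desk-scale study of these procedures warrants — 10,000 cells/condition for
fold recovery, 5,000 for crosstalk and signaling, 1,000 null pairs — chosen
so Monte-Carlo error sits well inside the tolerances being verified.

## Known limitations

- Crosstalk ratios inherit the min-max normalization bias under dense
  leakage (above) and, at very low leaked counts, integer quantization of
  the median.
- BP-R² depends on bin count and the minimum-bin-count filter; defaults
  (10 bins, 20 events) are declared in the result metadata rather than
  asserted as the field's single convention.
- The CV drop at stimulated timepoints conflates the generator's sd
  tightening with the mean increase; the package reports CV, it does not
  decompose the two.
- No spillover *correction* is implemented — the crosstalk stage
  quantifies leakage so panels can be designed around it.
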