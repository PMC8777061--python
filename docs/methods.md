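# Methods

## The problem

Most public HumanMethylation BeadChip (450k/EPIC) records are deposited as
processed methylated/unmethylated signal tables without the raw IDAT files,
so the control-probe and out-of-band signals that most normalization
methods rely on are unavailable.  What remains in such tables still carries
four technical distortions: Infinium I/II probe-design bias, red/green dye
bias, background noise, and between-array batch effects.  This package
implements a reference-based normalization that needs nothing beyond the
signal table itself, plus the benchmark machinery to measure how much
technical variation it removes.

## Model

### Two-state structure of Infinium I channel intensities

An Infinium I locus is measured by two beads (methylated and unmethylated)
read in a single color channel.  Because the human methylome is strongly
bimodal — most CpGs are nearly fully methylated or nearly fully
unmethylated — one of the two beads at most loci emits almost no signal.
Pooling all Infinium I intensities of one channel therefore produces a
two-component structure: a narrow low-mean "dark" peak (the silent beads)
and a broad high-mean "lit" peak.  We model the pooled intensities of each
channel as a two-component Gaussian mixture

    x ~ w1 N(mu1, sigma1^2) + w2 N(mu2, sigma2^2),   mu1 < mu2,

with state 1 defined as the component with the smaller mean.  The fitted
(mu, sigma) pairs are sensitive fingerprints of batch: arrays processed
together fit nearly identical parameters, arrays from different batches do
not.

### Between-array normalization (the core quantile map)

A reference distribution — one fitted mixture per channel — is the mapping
target.  To normalize a sample, its own per-channel mixtures are fitted,
every intensity is hard-assigned to the state with the larger posterior,
and each value is pushed through

    rho = F(x  | mu_state,  sigma_state)       (sample fit)
    q   = F^-1(rho | mu_ref,state, sigma_ref,state)   (reference)

Because both F and its inverse are Gaussian, this composite is exactly the
affine map `q = mu_ref + sigma_ref (x - mu_state) / sigma_state` per state.
The decisive consequence: any affine distortion `x -> a x + b` (a > 0) of a
channel's intensities — dye bias, scanner gain, additive offsets — is
absorbed by the sample fit and cancels exactly.  This is verified to
1e-6 relative tolerance in the tests and holds to ~1e-13 in practice.

The reference can be fitted from any user cohort: for every Infinium I
probe the median across samples of M and of U is taken, the per-probe
medians of each channel are pooled, and the mixture is fitted to the
pooled vector.  Medians rather than means are used for robustness to
outlier arrays.  Both signals of a type I probe are pooled into a single
per-channel vector because both beads are read in the same channel and the
model describes that channel's overall intensity distribution.

### Within-array correction (Infinium II bias)

The between-array step deliberately leaves Infinium II probes untouched:
their two signals come from a different chemistry and do not obey the
two-state single-channel model.  They are corrected afterwards against the
now-stable Infinium I probes by one of two adapted standard methods:

* **BMIQ** (on beta-values).  Three-component beta mixtures (states U/H/M,
  ordered by mean) are fitted separately to type I and type II beta.  Type
  II probes are classified by the posterior-crossing boundaries of their
  own fit; U- and M-state probes are beta-quantile-mapped onto the
  corresponding type I component, H-state probes are stretched affinely so
  the type II U-H and H-M boundaries land on the type I boundaries.
  Class images are clipped to the type I boundary intervals, making the
  composite map monotone on [0,1] despite the piecewise construction.
  Unlike original BMIQ, type I probes are never moved — they are the
  anchor.
* **SWAN** (on intensities).  Probes are stratified by the CpG count in
  the probe body, capped at {1, 2, 3+}.  Within each stratum, and for M
  and U separately, each type II intensity is replaced by the type I
  empirical quantile (linear interpolation between order statistics) at
  that probe's own within-stratum quantile.  Only type II moves; ranks
  within a stratum are preserved exactly.  A stratum without type I probes
  falls back to the all-probes type I quantile map.

A within-array fit failure falls back to returning the input with a logged
warning rather than failing the sample: the between-array output is
already usable.

## EM fitters: numerical choices

Both fitters are fully deterministic — quantile-based initialization, no
random restarts — so identical inputs give bit-identical outputs.

* **Gaussian (2 components).**  Initialized from the data halves below and
  above the median (means at the 25th/75th percentiles, within-half
  standard deviations, weights 1/2).  Convergence is declared when the
  *mean per-observation* log-likelihood change falls below `tol` (default
  1e-6).  A per-observation criterion is used rather than a relative
  change of the total log-likelihood because the total shifts by
  `-n log a` under a rescaling of the data, which would make the stopping
  iteration — and hence the output — scale-dependent and break the exact
  affine-invariance property above.  A component standard deviation
  falling below 1e-8 times the data range raises a collapse error; it is
  never silently repaired.
* **Beta (3 components).**  Values are clamped to [1e-6, 1-1e-6] and cut
  at beta = 0.2 and 0.8 (the canonical hypo/hyper boundaries of the
  bimodal methylome) for initial method-of-moments shapes; an initial
  group with fewer than 10 members falls back to fixed prior shapes
  (U: Beta(2,18), H: Beta(5,5), M: Beta(18,2)) and is held fixed during
  fitting.  The M-step maximizes the exact weighted beta log-likelihood
  through its sufficient statistics (sum r log x, sum r log(1-x)) with
  L-BFGS-B and analytic digamma gradients, warm-started at the previous
  parameters and rejected if it fails to improve — so the EM objective is
  non-decreasing at every iteration, which the tests assert.  Fits are run
  on a deterministic thinning of the sorted vector capped at 50,000 values
  for speed; the transform is applied to all probes.

Other numerical choices: mapped intensities are floored at 1.0 so beta
stays defined; the quantile map is evaluated in the nearer Gaussian tail
(via the complement for the upper half) so it retains full double
precision instead of saturating around six sigma; posterior ties in state
assignment go to state 1; missing values propagate and are never imputed.
Hard state assignment can produce a small discontinuity for values that
sit exactly at the posterior boundary between states; a soft blend was
rejected to keep the map exactly testable against its closed form.

## Synthetic data generator

The generator is phenomenological: it reproduces the data features the
method reasons about without modelling scanner physics.

* Per probe, a population methylation level beta is drawn from a
  three-component beta mixture (defaults 0.4 Beta(2,20) + 0.2 Beta(5,5) +
  0.4 Beta(20,2)); subjects scatter around it with `biological_sd` = 0.015
  (typical inter-individual variation at a CpG), clipped to [0.01, 0.99].
* Per probe, a total intensity T is drawn once from a log-normal
  (median 6,000 a.u., sdlog 0.25 by default) and shared across samples —
  probe chemistry, not the sample, drives overall brightness.
* A measurement is `M = beta T + e`, `U = (1-beta) T + e` with Gaussian
  background noise (sd 40 a.u., about 0.7% of the modal intensity, giving
  technical-replicate beta noise of roughly 0.007 — the reproducibility of
  well-run arrays), floored at 0.  For extreme-beta loci one of the two
  signals is near zero, which is exactly what creates the two-peak channel
  structure the mixture model fits.
* Infinium II probes first compress beta toward 0.5 by a monotone factor
  (default 0.2) — the probe-design bias.  Optionally
  (`type2_channel_split`) their M signal is placed in the green channel
  and U in the red channel, the real Infinium II layout, so per-batch dye
  imbalance distorts type II beta directly.
* Each batch applies an affine scale/shift per channel — precisely the
  distortion class the between-array step removes exactly.  Nonlinear
  distortions are deliberately out of scope.
* Designated probes carry case/control shifts, a linear covariate (age)
  relationship with slope 0.08 per covariate SD and residual sd 0.06
  (population correlation 0.8), or membership in an adjacent-CpG pair
  that shares one true beta and sits < 10 bp away.

What the generator does **not** emulate: detection p-values, control and
out-of-band probes, probe cross-hybridization, SNP-affected probes,
beta-dependent (heteroscedastic) measurement noise, and nonlinear batch
distortions.  Passing tests therefore demonstrate correct behaviour under
the stated distortion model, not performance on any real cohort.

## Benchmark study designs

Four frozen desk-scale designs (`gmqn.scenarios`) mirror the standard
evaluation procedures; all are driven by one seed.

1. **Technical replicates** — 1 subject assayed 56 times (or 9 subjects
   x 3), spread round-robin over 3 batches with fixed strong distortions;
   the metric is the probe-level beta variance within replicate groups,
   averaged across groups and probes.
2. **Case-control consistency** — 30 cases and 30 controls; the training
   two-thirds sit on a clean batch, the test third has cases and controls
   on two *different* distorted batches (batch confounded with group
   inside the test split — the failure mode batch effects actually cause);
   1% of probes are differential at delta beta = 0.1.  Welch t-tests with
   Benjamini-Hochberg (0.05) on the training split define the gold
   standard; the test-split p-value ranking is scored as an ROC/AUC.  The
   null calibration scores permuted-label statistics from a matched
   zero-effect dataset against the same gold standard; permuting labels
   within signal-bearing test samples instead produces heavy-tailed AUCs,
   because every truly differential probe co-moves with the realized
   label imbalance of the shuffle.
3. **Covariate regression** — 45 samples pooled from three "projects"
   with fixed, channel-asymmetric (dye-bias) distortions and a wider
   intensity spread (sdlog 0.6); 100 probes track age (population r =
   0.8) independent of project membership.  The metric is the count of
   probes with |Pearson r| above 0.5/0.6/0.7.
4. **Adjacent CpG pairs** — 150 probe pairs < 10 bp apart sharing one
   true beta, against an equal number of random control pairs; the metric
   is the ratio of mean |delta beta| between the two sets.

Problem sizes (4,800 probes, tens of samples) were chosen so the whole
suite and the acceptance script each run in well under a minute per
design while every comparison retains a comfortable margin.

## Known limitations

* The package reads delimited signal tables only; IDAT parsing is out of
  scope by design (the motivating use case is data where IDATs were never
  deposited).
* The affine-removal guarantee applies to Infinium I probes; Infinium II
  correction is distributional (BMIQ/SWAN) and cannot undo probe-level
  distortions that depend on a probe's intensity, only their
  distribution-level component.
* With a reference whose methylation distribution differs grossly from
  the sample (e.g. methyltransferase-knockout material), the two-state
  model assumptions weaken and normalization quality degrades.
* Hard state assignment implies a possible discontinuity at the state
  boundary (documented above).
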