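# Methods

## Model structure

The simulator is a discrete event model of one clinical microbiology
laboratory processing blood cultures. State changes only at event
instants, driven by a binary-heap scheduler; ties are broken by
insertion order, so a specimen finishing a task at time *t* is visible
to an agent waking at the same *t*.

**Arrivals.** Specimen collections form a homogeneous Poisson process:
inter-arrival times are exponential with rate λ (default 35,000 per year
= 0.0666 min⁻¹, mean gap ≈ 15.02 min). Each specimen is independently
growth-positive with probability p = 0.111. Diurnal and weekly arrival
structure is deliberately not modelled; the only clock-of-day effect in
the system is the reception shift (below).

**Pathway.** Collection is followed by a gamma-distributed transport
delay to laboratory receipt; six reception tasks (labelling, LIMS
registration, combining labels, scanning the request form, moving
location, loading the incubator); incubation; then, for flagged
positives, six bench tasks (unload, hazard check, venting, culture/smear
preparation, Gram staining, drying), the scientist's Gram read, and
three lognormal reporting delays (Gram→24 h, 24→48 h, 48 h→final; the
final report doubles as the susceptibility report). No-growth bottles
wait exactly 7,200 min (5 days) in the incubator, are unloaded by the
bench technician, and are complete at that point with no further delay.
Incubator capacity is unbounded. Directly observed task durations are
parameterized in seconds and converted to the canonical internal unit
(minutes since simulation start, t = 0 at midnight) at sampling time.

**Staff and the OnHold wait.** Three agents — reception technician,
bench technician, scientist — perform the staff tasks; one agent per
role. The reception technician is off shift 20:00–08:00: off-shift
agents claim no work (queues simply grow), a task in progress at 20:00
runs to completion, and no task *starts* during the off window. Staff
behaviour is a wake/claim/work/wait loop:

1. at a wake instant, the agent claims **all** specimens queued for its
   deepest pending pathway step (one atomic batch);
2. per-batch steps (the six reception tasks, observed batch sizes ~4–6)
   consume a single duration draw for the whole batch; per-specimen
   steps (bench and scientist tasks, observed batch sizes ~1) draw one
   duration per specimen, worked concurrently, the agent busy until the
   last finishes;
3. the agent then re-enters the OnHold dormancy for exactly its
   configured wait before the next wake; a wake that finds no queued
   work likewise starts a fresh OnHold period.

The OnHold wait abstracts everything the study did not observe — other
specimen types, administrative work, breaks — and is the model's
surrogate for staff availability. It is deliberately a fixed constant
per role (default 23 min for all three), not a random variable: the
point of the calibration exercise is to identify this single scalar.

*Claim priority.* With an unconditional OnHold after every batch, the
claim order among a role's steps matters. Serving the **earliest**
pathway step first starves downstream steps whenever arrivals are
steady (the reception queue at the first task almost never empties, so
later tasks wait indefinitely and throughput collapses). The engine
therefore serves the **deepest** pending step first, which is
equivalent to processing specimens in arrival order (the pipeline
preserves order) and keeps the system stable across the whole 1–100 min
OnHold range.

**Event log.** Each specimen records a completion timestamp per event
(collection, receipt, each staff task, growth flag or incubation
completion, final report) plus task start times for shift diagnostics.
Specimens still in flight at the horizon are retained and flagged
uncompleted.

**Randomness.** One master seed feeds independent named streams
(arrivals, positivity flags, time-to-positivity, one per pathway step)
via `SeedSequence`; stream identity is a CRC of the purpose name. This
is a common-random-numbers design: perturbing one staff parameter does
not reshuffle arrival times, positivity flags or unrelated duration
draws, so calibration and sensitivity contrasts reflect the parameter,
not resampling noise.

## Service-time distributions

Five families cover the observed and retrospectively fitted durations:
exponential (rate), gamma (shape, rate), lognormal (log-scale μ, σ),
Weibull (shape, scale) and uniform (a ≤ b, a ≥ 0). The lognormal
tabulated "Mean"/"SD" values are the log-scale parameters — exp(μ)
reproduces the corresponding observed medians, which a natural-scale
reading does not.

Fitting is maximum likelihood: closed form for exponential (1/mean),
lognormal (moments of log data, ddof = 0) and uniform (sample min/max);
numerical (scipy, location fixed at 0) for gamma and Weibull. Each fit
reports the log-likelihood, a one-sample two-sided KS statistic and
asymptotic p-value against the fitted CDF, and an SSE computed against
a density-normalized histogram with 30 equal-width bins spanning the
data range (bin count configurable; the density-normalization makes the
SSE comparable across families but not across bin counts).

Ranking is by ascending SSE with the KS statistic as tie-break, plus
one parsimony rule: the exponential is nested in both gamma and
Weibull, so on truly exponential data the two-parameter superfamilies
match or marginally beat it in-sample by fitting noise. The exponential
is therefore promoted to first place when its SSE is within a factor 2
of the best competitor. The factor is safe by a wide margin: measured
at n = 5,000, the exponential/best-other SSE ratio is ≤ 1.74 on
exponential data and ≥ 23 on data from any other of the families.
KS p-values are reported but never used for automatic selection.

Cullen–Frey diagnostics report sample skewness and non-excess (Pearson)
kurtosis with a bootstrap cloud (resampling with replacement at the
original n, default 100 replicates). Pearson correlation matrices use
pairwise-complete observations; zero-variance columns yield NaN entries
rather than silent zeros.

## Calibration of the OnHold wait

The OnHold wait is estimated by grid search over k equally spaced
values (default 1, 12, 23, …, 100 min; the 23-min default sits on this
grid), varying all three roles together. For each candidate:

1. the simulator runs for 28 days (2-day warmup excluded from metrics);
   if fewer specimens complete than the reference set holds, the run
   length is doubled, up to three times, before giving up;
2. completed specimens are subsampled without replacement to the
   reference count;
3. the objective is the sum over the four key nodes (receipt→load,
   receipt→flag, receipt→unload, receipt→Gram-report) of the two-sample
   KS statistic between the subsample's and the reference's interval
   distributions — a bounded [0, 4] pseudometric that is zero iff the
   densities match. A Gaussian-KDE negative log-likelihood objective is
   available behind a flag.

The argmin wins; exact ties break toward the smaller wait (the
less-constrained hypothesis). One simulation seed is shared across all
grid values within a calibration (common random numbers), and the
subsample stream is separate from the simulation streams.

Because no retrospective laboratory extract ships with the package, the
reference data set is synthesized by `generate_pseudo_real`: either
`from_table` (independent draws from the retrospectively fitted
interval distributions, cumulated to the receipt-anchored nodes) or
`from_simulator` (emergent intervals from a simulator run at a known
OnHold value, with the generating config and seed as provenance). The
`from_simulator` mode makes calibration *self-recovery* testable: data
generated at 23 min is calibrated back to exactly 23 in 10/10 seeded
trials (12 min: 10/10; 89 min: 9/10).

## Sensitivity analysis

One role's OnHold wait sweeps the same grid while the other roles stay
at their configured values. Each grid value is simulated with 10
stochastic replicates; replicate i uses seed base + i at every grid
value (common random numbers again). Per replicate, the mean of each
key-node interval over completed post-warmup specimens is recorded;
the per-value aggregate is the mean of replicate means. Technician
sweeps produce monotone increases in all downstream node means;
scientist sweeps leave receipt→load flat (slope indistinguishable from
zero) and only shift the Gram-report node.

## What the synthetic data does and does not show

The pseudo-real fixtures emulate the *marginal* distributions of the
four key intervals (from_table mode) or the full dependence structure
of the simulator's own output (from_simulator mode). They do not carry
the messiness of real LIMS extracts — clock skew between instruments
(which produced load-before-receipt records in real data), missing
fields, site effects, diurnal arrival structure, or correlated event
times. Passing the calibration and sensitivity suites therefore shows
that the estimation machinery is consistent (it recovers known
parameters from data the model itself could have produced), not that
the model is a validated description of any particular laboratory. The
record-filtering and waste-accounting routines are exercised on
synthetic tables constructed to the documented exclusion counts, since
the underlying observation sessions are not distributable.

## Problem sizes and numerical choices

Default run length is 28 simulated days with a 2-day warmup — long
enough for ~2,700 specimens and stable interval distributions, small
enough that a full 10-point calibration (10 runs plus extensions) takes
seconds. Trend tests in the test suite use 14-day runs with 10
replicates. Percentages in the record-filtering accounting are rounded
half-up to one decimal, as printed in laboratory reports. Histogram SSE
uses 30 bins. Durations are floats in minutes; shift boundaries are
half-open ([20:00, 08:00) off), so a task may start at exactly 08:00
but not at exactly 20:00. Degenerate uniform distributions (a = b) are
allowed and sample the constant. The bisection-free quantile uses the
underlying scipy `ppf`; CDF/quantile round-trips hold to 10⁻⁶.

## Known limitations

* One agent per role; no weekend/holiday calendars; no multi-site
  (hub/satellite) routing.
* The OnHold wait is a fixed constant — a single scalar standing in for
  a complex mixture of interruptions; exponential or per-role waits are
  natural extensions.
* Incubator capacity is unbounded.
* The calibration objective treats the four nodes as independent
  samples and weighs them equally; nodes dominated by the
  time-to-positivity carry little information about staff parameters.
* Reported wall-clock (ISO) timestamps assume day 0 is a Monday; no
  weekday semantics are attached.
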