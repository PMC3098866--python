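# Methods

## Data model and units

An event log is a time-sorted sequence of pairwise contacts (initiator,
target, time in seconds, optionally the x/y position of the target's head)
plus colony metadata: roster, nest rectangle, recording duration, body
length, interaction radius `D` and mean speed `v`.  All distances are in
units of mean worker body length (about 3 mm for the small myrmicine
workers this was designed around) and all times in seconds; conversions
from millimetres or pixels belong at ingest.  Timestamp ties are preserved
in input order (stable sort): digitised videos genuinely produce
simultaneous events and no disambiguation is defensible.

Only the target's head position is digitised per event.  For displacement
series and spatial analyses both participants are assigned that position
(the error is bounded by the contact distance `D`, small relative to the
distances involved).  For speed estimation the bound is not enough: a
position offset of up to `D` divided by a short inter-fix gap produces
arbitrarily large chord speeds, and on simulated data the both-roles
estimator overshoots the true speed by ~50%.  `mean_speed` therefore uses
only target-role fixes by default (`roles="both"` restores the permissive
behaviour).  Chord speeds are necessarily underestimates of the true path
speed (straight chords between interaction fixes skip wall bounces and
intermediate direction changes); on simulated gas logs the estimator
returns ~0.7 v.

## Time-ordered networks and causal flow

The time-ordered network places a node at every (individual, event time),
virtual start/end nodes at t = 0 and t = duration, directed temporal links
along each individual's timeline, and one undirected interaction link per
event.  Forward paths in this graph are exactly the causally permitted
information routes.  The implementation sweeps the sorted event sequence
directly and only materialises the explicit graph on request.

Two conventions fix the semantics of simultaneity and direction:

* Interaction links are undirected for flow purposes (either participant
  may pass a message); initiator/target direction is kept only for degree
  statistics on aggregated networks, where out-degree counts unique
  individuals touched and in-degree unique individuals touched by.
* A message traverses at most one interaction link per distinct timestamp:
  causal paths must use strictly increasing event times.  Both the
  reachability sweep and the vector clocks process equal-timestamp events
  against the state snapshot taken before that timestamp.  This is the
  conservative choice; chaining through simultaneous events would
  manufacture causality the data cannot support.

Reachability tracing seeds a message at a focal (individual, time) and
reports the informed count at checkpoint lags.  Focal seeds are sampled in
two modes: `event` mode draws (event, participant) pairs uniformly — the
empirical convention, which weights individuals by activity and lets the
focal event itself transmit, so counts start at 2 — and `time` mode draws
a uniform individual at a uniform start time, matching the model's
n(0) = 1 boundary condition.  Model comparisons should use `time` mode;
descriptive analyses of recordings use `event` mode.

Vector clocks maintain, for each individual i, the latest departure time
phi_i(j) of information from every j that could have reached i; an
interaction (a, b) at time s sets phi_a(b) = phi_b(a) = s and merges the
two clocks component-wise.  Latency(i, j) = eval_time - phi_i(j), infinite
when no causal path exists.  The evaluation time is a free parameter; the
summary `grand_mean_latency` evaluates at the end of each recording by
default (averaging per-individual receiver means within recordings, then
across recordings) and can instead average over a grid of evaluation
times.  Infinite entries are excluded from receiver means.

Aggregation windows are half-open [t0, t1), so disjoint windows partition
the event sequence additively; the single exception is the full-recording
window, which also includes events at exactly t = duration.  Betweenness
and diameter are computed on the unweighted skeleton (edge wherever at
least one contact occurred); the classical definitions need a choice here
and unweighted is the defensible default for count-weighted contact data.
Betweenness is normalised by (m-1)(m-2)/2.

Individual roles (e.g. whether the queen is special) are summarised as
mid-rank quantiles: (average rank - 0.5) / m, so ties average and an
all-tied statistic yields 0.5 for everyone.

## The kinetic-gas model

Parameters, with the defaults used throughout the package's own studies:

| parameter | meaning | default | rationale |
|---|---|---|---|
| m | group size | 30 | mid-range colony |
| width x height | nest, body lengths | 20 x 20 | ~0.07 disks/BL^2, the social density of a real nest |
| D | interaction radius | 1 BL | contact = antenna reaching a body length |
| v | speed | 1 BL/s | order of walking speed; all rates scale with it |
| duration | recording | 600 s | ~100 contacts per individual |

For equal speeds and independent uniform headings in 2-D the mean relative
speed is 4v/pi, giving per-pair contact rate `lambda_pair = 8vD/(A pi)`
and per-individual rate `lambda = m * lambda_pair` (the printed form
absorbs m ~ m-1).  The closed-form suite then follows: Poisson(lambda t)
interaction counts; group total m lambda t / 2; exponential waiting-time
survival exp(-lambda t); expected displacement v sqrt(t / lambda), valid
between the mean free time 1/lambda (below which motion is ballistic) and
the boundary-limited time (lambda (min(w,h)/2v)^2); out-degree
Binomial(m-1, 1 - e^(-lambda_pair t)) — m-1, not m, since an individual
cannot touch itself; and the logistic SI solution
n(t) = m / (1 + (m-1) e^(-lambda t)) of dn/dt = lambda n (m-n)/m.  The
`rescale_flow` linearisation y = ln(n(m-1)/(m-n)) against x = lambda t
maps the logistic exactly onto the 1:1 line, so model-faithful flow has
SMA slope 1 and mobility-limited flow slope < 1.

### Simulator

The simulator realises exactly this physics: uniform non-overlapping
initial positions, uniform headings, constant speed v per disk.  Time is
integrated with step h = min(D/(10 v), 0.05) s, small enough that a
crossing of the contact shell cannot be stepped over.  Walls reflect
specularly and record nothing.  A contact onset (centre separation first
<= D) records one event; both participants then take fresh independent
uniform headings at unchanged speed, and the pair must separate beyond D
before it can produce another event.  Random redirection (rather than
momentum-exchange collisions) keeps every speed exactly v, which is the
regime in which the 4v/pi relative-speed constant holds.  Initiator and
target are assigned by a fair seeded coin, since the physics does not
distinguish them.  Identical seeds give byte-identical logs.

The structured variant adds a personal home-range disk (random centre,
radius `fidelity_radius`, reflecting boundary) per individual and a speed
multiplier.  The frozen negative-control conditions —
fidelity_radius = 1.5 BL, speed_factor = 0.25, m = 30 in 20x20 for
1800 s — produce both signatures of constrained colonies: rescaled-flow
SMA slope far below 1 and a pooled waiting-time tail that AIC prefers to
fit as a power law rather than an exponential.

### What the generator does and does not emulate

It emulates the statistical structure the closed forms describe — Poisson
counts, exponential gaps, binomial degree growth, sqrt(t) displacement,
logistic spread — plus the geometry (walls, finite size, disk exclusion at
contact) that real nests impose.  It does not emulate behavioural
heterogeneity, task structure, pauses, pheromone fields, or any feedback
between interactions; passing tests on generated data therefore validate
the *pipeline and the model's internal consistency*, not any claim about
real colonies.

Four systematic gaps between the simulator and the idealised closed forms
are worth knowing, because desk-scale replication has the power to see
them all:

1. A focal disk meets m-1 others, so its true contact rate is
   (m-1) lambda_pair, 3-10% below the printed 8mvD/(A pi) at colony sizes;
   contact dwell and grazing-pass discretisation shave another ~1-2%.
2. Near-contact correlations: gaps shorter than ~0.1 s are suppressed
   (pair dwell) and gaps of 0.25-1 s enhanced (recontact after
   separation).  With thousands of pooled gaps per recording a KS test
   resolves this even though the distribution is exponential to the eye.
3. The same recontact clustering lowers unique-partner conversion slightly
   below the molecular-chaos binomial, and initially-nearby pairs meet
   ballistically fast, inflating the earliest window of degree growth.
4. The logistic is the mean-field solution of the SI process; the mean of
   the stochastic process lies below it near saturation (Jensen gap).  An
   independent Gillespie simulation of the well-mixed Markov SI process
   with the same per-pair rate reproduces the collision simulator's mean
   curve, attributing the deviation to the mean-field idealisation rather
   than the spatial dynamics.  At colony-realistic density there is a
   further, larger slowdown: information spreads faster than the arena
   mixes, so informed individuals cluster spatially and waste contacts on
   each other.  Flow-model comparisons in the tests therefore run at
   dilute density (m = 30 in 50x50), where mixing outpaces spread.

## Statistical layer

SMA regression: slope = sign(r) sd(y)/sd(x), intercept through the means.
The slope = b0 test uses the correlation between (y - b0 x) and
(y + b0 x), which vanishes exactly at the true SMA slope; the CI is the
F-based interval slope (sqrt(B+1) +/- sqrt(B)),
B = F(0.95; 1, n-2)(1-r^2)/(n-2).  Because an SMA slope magnitude is never
0, "slope = 0" hypotheses are operationalised as tests of r = 0 — the
standard model-II convention.  Type-I error and CI coverage are verified
by simulation in the test suite.

ML fits (all with one free parameter, AIC = 2 - 2 logL): exponential rate
1/mean; continuous Pareto alpha = 1 + n / sum ln(x/xmin) with xmin fixed —
by default the smallest observation, and for tail comparisons the pooled
median, with the exponential fitted to the shifted tail (x - xmin) so both
families compete on the same support; binomial p = mean/trials.  AIC ties
prefer the exponential.  Waiting times pool each individual's
consecutive-event gaps across the recording; zero gaps are dropped
(continuous support).

Complete spatial randomness is tested per axis by one-sample KS against
the uniform distribution on the nest side.  Note that even gas-model
contact positions have a ~D-wide depletion layer at the walls, so at
full-recording sample sizes the KS *p-value* rejects while the KS
statistic stays small (< 0.08 in tests); effect size, not significance, is
the meaningful summary at large n.

Spike-train analysis bins each individual's initiator events and target
events into binary 1-s trains (widths configurable), correlates them at
lags up to +/-60 bins, and compares negative- against positive-lag mean
correlations with a Wilcoxon rank-sum test — a positive-lag excess would
indicate being-touched feeding back into touching.

Specialization: across two recordings of the same colony, out-degree is
tested for coupling via r = 0 on the shared roster; within recordings,
in- vs out-degree is fitted by SMA against slope 1.  One caveat
established during development: in a *homogeneous* simulated gas with
coin-flip roles, in- and out-event streams are independent Poisson
thinnings, so the positive in-out coupling expected of real colonies
appears only when individuals differ in activity (e.g. the structured
variant); for the pure gas only the slope magnitude (~1) is informative.

## Numerical and testing choices

* All randomness flows through numpy Generators from explicit integer
  seeds; analysis drivers split one seed via `SeedSequence.spawn`.
* Chi-square goodness-of-fit tests pool pmf classes to expected counts
  >= 5; KS tests against fitted exponentials use the MLE rate (slightly
  conservative).
* The exhaustive oracles in the test suite (fixed-point relaxation for
  reachability, path enumeration for latencies and betweenness, Gillespie
  for SI spread) are deliberately independent re-derivations, feasible
  only at the small sizes they are run at (m <= 8, E <= 40).
* Simulation sizes in the tests (50 replicates of 600-s colonies at two
  colony sizes; 25 dilute replicates for flow) keep the whole suite at a
  few minutes on one CPU while leaving Monte-Carlo error well below the
  effects tested.

## Known limitations

* The simulator is 2-D, monodisperse and memoryless; no pheromones, no
  pauses, no task structure.
* Eq.-level predictions using the per-individual rate inherit the m ~ m-1
  approximation; comparisons at small m should use the per-pair rate.
* Pareto fitting uses a fixed xmin (no automated xmin selection or
  likelihood-ratio machinery); AIC with k = 1 per family is the only model
  comparison offered.
* Latency-vs-distance uses ordinary least squares on per-individual means
  and ignores the spatial autocorrelation between individuals.
* The perfect-transmission assumption makes every flow measure an upper
  bound; per-contact transmission probabilities below 1 are out of scope.
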