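# antflow

Tools for analysing **dynamic interaction networks** in animal groups —
built around complete time-stamped records of antennal contacts in ant
colonies, but applicable to any log of who-touched-whom-when.

Social-insect colonies coordinate through brief pairwise contacts.  A
static ("time-aggregated") contact network hides the property that matters
for function: *when* interactions happen, and therefore which chains of
contacts could actually carry information forward in time.  `antflow`
provides:

* **Time-ordered networks** — a node for every (individual, event time),
  directed temporal links along each individual's timeline and undirected
  links at interactions.  Paths in this graph are exactly the causally
  permitted routes for information flow (no back-propagation in time).
* **Causal flow measures** — reachability tracing (how many unique
  individuals a message seeded at a focal event/time could reach after a
  lag, assuming perfect transmission) and **vector-clock latencies** (for
  each ordered pair *(i, j)*, how stale the freshest information from *j*
  that could have reached *i* is).
* **A kinetic-gas null model** — individuals as identical disks of
  interaction radius *D* moving at speed *v* in straight lines inside a
  nest of area *A*, bouncing off walls and each other.  With *m*
  individuals, kinetic theory gives the per-individual contact rate

      lambda = 8 m v D / (A pi)

  from which the model predicts Poisson interaction counts, exponential
  waiting times *T(t) = exp(-lambda t)*, binomial-exponential out-degree
  *N(n) ~ Binomial(m-1, 1 - e^(-lambda t / m))*, sqrt(t) spatial
  displacement, and logistic SI information spread

      n(t) = m / (1 + (m - 1) e^(-lambda t)).

  The same module contains an explicit 2-D event-recording simulator of
  this gas (the package's synthetic-data generator) and a "structured"
  variant with personal home ranges and reduced speed that reproduces the
  signatures of real colonies: slower-than-predicted flow and heavy-tailed
  waiting times.
* **The statistical layer** — standardised-major-axis (model-II)
  regression with slope tests and CIs, maximum-likelihood
  exponential/Pareto/binomial fits with AIC model selection, per-axis KS
  tests of complete spatial randomness, spike-train cross-correlation with
  a rank-sum lag test, and specialization tests across repeated recordings.

## Worked example

```python
import numpy as np
from antflow import (
    GasModelParams, simulate_gas, build_time_ordered, sample_flow_curves,
    vector_clock_latencies, receiver_mean_latencies, si_flow,
    waiting_times, compare_models,
)

params = GasModelParams(m=30, width=20.0, height=20.0, v=1.0)
print(f"per-individual contact rate 8mvD/(A pi) = {params.lambda_ind:.4f} /s")

log = simulate_gas(params, duration=600.0, rng_seed=1)
print(f"simulated {len(log)} contacts among {log.metadata.m} ants in 600 s")

net = build_time_ordered(log)
lat = vector_clock_latencies(net, eval_time=600.0)
per_receiver = receiver_mean_latencies(lat)
print(f"mean vector-clock latency: {np.mean(list(per_receiver.values())):.1f} s")

lags = np.linspace(5.0, 120.0, 8)
curves = sample_flow_curves(net, n_samples=200, rng_seed=2, checkpoints=lags)
for lag, n_obs in zip(curves.checkpoints, curves.mean):
    print(f"{lag:7.1f}  {n_obs:15.1f}  {si_flow(params, lag):19.1f}")

gaps = waiting_times(log)
comparison = compare_models(gaps, ("exponential", "pareto"))
print(f"waiting times: {comparison.preferred} preferred "
      f"(delta AIC {comparison.delta_aic:.0f})")
```

prints

```
per-individual contact rate 8mvD/(A pi) = 0.1910 /s
simulated 1645 contacts among 30 ants in 600 s
mean vector-clock latency: 26.6 s
    5.0              4.0                  2.5
   21.4             16.1                 20.2
   37.9             25.9                 29.4
   54.3             28.0                 30.0
  120.0             28.2                 30.0
waiting times: exponential preferred (delta AIC 5178)
```

Reading the numbers: 30 disk-ants in a 20x20 body-length nest at speed
1 BL/s meet ~0.19 partners per second each.  A message seeded at a random
focal event reaches most of the colony within ~1 minute; the mean curve
runs ahead of the logistic at short lags (the focal event itself transmits
immediately, and focal events over-sample active individuals) and lags it
near saturation, where the deterministic mean-field solution overestimates
the stochastic mean.  Waiting times between a gas ant's contacts are
exponential, not heavy-tailed — the structured variant
(`simulate_structured`, small home ranges, reduced speed) flips both
findings, which is how the pipeline detects mobility-limited colonies.

## Command line

```
antflow simulate sim.yaml --out-dir data/      # gas or fidelity variant
antflow analyze data/gas-m30-seed1.events.csv data/gas-m30-seed1.meta.yaml \
    --out-dir report --seed 1                  # full per-recording report
antflow flow / latency / fit / compare ...     # individual analyses
```

Event logs are plain CSV (`time_s,initiator,target[,x,y]`, body-length
units); colony metadata is YAML/JSON.  Every artifact records the seed
that produced it.

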