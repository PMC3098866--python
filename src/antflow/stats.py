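"""Statistical layer: model-II (SMA) regression, MLE fits with AIC model
selection, spatial-randomness tests, and spike-train cross-correlation.

SMA (standardised major axis) regression is the model-II line fit that is
symmetric in x and y: |slope| = sd(y)/sd(x) with the sign of the
correlation.  The slope = b0 hypothesis is tested through the correlation
between the rotated residual and fitted axes (y - b0 x vs y + b0 x), and
the 95% CI uses the standard F-based construction.  Because an SMA slope
can never be 0, "slope = 0" tests are operationalised as tests of r = 0,
matching the convention of the model-II regression literature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .event_io import EventLog

__all__ = [
    "SMAFit",
    "sma_fit",
    "correlation_test",
    "ExponentialFit",
    "ParetoFit",
    "BinomialFit",
    "fit_exponential",
    "fit_pareto",
    "fit_binomial",
    "FitComparison",
    "compare_models",
    "waiting_times",
    "csr_test",
    "CSRResult",
    "spike_cross_correlation",
    "SpikeCrossCorrelation",
    "specialization_tests",
    "SpecializationResult",
    "degree_window_transform",
]


# ---------------------------------------------------------------------------
# SMA regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SMAFit:
    """Standardised-major-axis line fit with a slope hypothesis test."""

    slope: float
    intercept: float
    ci: tuple[float, float]
    p_value: float
    hypothesized_slope: float
    n: int
    r: float


def sma_fit(
    x: Sequence[float],
    y: Sequence[float],
    hypothesized_slope: float = 1.0,
    alpha: float = 0.05,
) -> SMAFit:
    """Fit an SMA line and test slope = ``hypothesized_slope``.

    slope = sign(r) * sd(y)/sd(x); intercept = mean(y) - slope * mean(x).
    The two-sided test of slope = b0 uses the correlation between the
    rotated axes (y - b0 x) and (y + b0 x), which is 0 exactly when the
    population SMA slope equals b0; the CI is the F-based interval
    slope * (sqrt(B + 1) +/- sqrt(B)) with B = F(1-alpha; 1, n-2)
    (1 - r^2)/(n - 2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0:
        raise ValueError("zero variance on the x axis")
    if sy == 0:
        raise ValueError("zero variance on the y axis")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = math.copysign(sy / sx, r if r != 0 else 1.0)
    intercept = float(np.mean(y) - slope * np.mean(x))

    b0 = hypothesized_slope
    u = y - b0 * x
    w = y + b0 * x
    su, sw = np.std(u, ddof=1), np.std(w, ddof=1)
    # guard against floating-point residue when data sit exactly on the line
    if su <= 1e-12 * max(sw, 1.0) or sw <= 1e-12 * max(su, 1.0):
        # degenerate: data fall exactly on the hypothesised line (or its
        # reflection); the test statistic is 0
        p_value = 1.0
    else:
        r_uw = float(np.corrcoef(u, w)[0, 1])
        r_uw = max(min(r_uw, 1.0), -1.0)
        if abs(r_uw) == 1.0:
            p_value = 0.0
        else:
            t_stat = r_uw * math.sqrt((n - 2) / (1.0 - r_uw**2))
            p_value = 2.0 * float(sps.t.sf(abs(t_stat), n - 2))

    f_crit = float(sps.f.ppf(1.0 - alpha, 1, n - 2))
    big_b = f_crit * (1.0 - r**2) / (n - 2)
    lo = slope * (math.sqrt(big_b + 1.0) - math.sqrt(big_b))
    hi = slope * (math.sqrt(big_b + 1.0) + math.sqrt(big_b))
    ci = (min(lo, hi), max(lo, hi))
    return SMAFit(
        slope=float(slope),
        intercept=intercept,
        ci=ci,
        p_value=float(p_value),
        hypothesized_slope=b0,
        n=n,
        r=r,
    )


def correlation_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and its two-sided p-value (the SMA 'slope = 0' test)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Maximum-likelihood fits and AIC comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExponentialFit:
    rate: float
    loglik: float
    n: int
    k: int = 1


@dataclass(frozen=True)
class ParetoFit:
    alpha: float
    xmin: float
    loglik: float
    n: int
    k: int = 1


@dataclass(frozen=True)
class BinomialFit:
    p: float
    trials: int
    loglik: float
    n: int
    k: int = 1


def fit_exponential(samples: Sequence[float]) -> ExponentialFit:
    """MLE of an exponential rate: 1/mean, with exact log-likelihood."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("samples must be non-empty")
    if np.any(x <= 0):
        raise ValueError("exponential samples must be positive")
    rate = 1.0 / float(x.mean())
    loglik = x.size * math.log(rate) - rate * float(x.sum())
    return ExponentialFit(rate=rate, loglik=loglik, n=x.size)


def fit_pareto(samples: Sequence[float], xmin: float | None = None) -> ParetoFit:
    """Continuous power-law (Pareto) MLE: alpha = 1 + n / sum(ln(x/xmin)).

    Density (alpha-1)/xmin * (x/xmin)^(-alpha) on [xmin, inf).  ``xmin``
    defaults to the smallest observed value.  All samples at exactly xmin
    make the exponent estimate divergent and raise.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("samples must be non-empty")
    if xmin is None:
        xmin = float(x.min())
    if xmin <= 0:
        raise ValueError("xmin must be positive")
    if np.any(x < xmin):
        raise ValueError("all samples must be >= xmin")
    log_ratio = float(np.sum(np.log(x / xmin)))
    if log_ratio == 0.0:
        raise ValueError("all samples equal xmin; Pareto exponent diverges")
    alpha = 1.0 + x.size / log_ratio
    loglik = x.size * math.log((alpha - 1.0) / xmin) - alpha * log_ratio
    return ParetoFit(alpha=alpha, xmin=xmin, loglik=loglik, n=x.size)


def fit_binomial(degrees: Sequence[int], trials: int) -> BinomialFit:
    """Binomial success-probability MLE for degree counts with fixed trials."""
    k_arr = np.asarray(degrees, dtype=int)
    if k_arr.size == 0:
        raise ValueError("degrees must be non-empty")
    if trials < 1 or np.any(k_arr < 0) or np.any(k_arr > trials):
        raise ValueError("degrees must lie in [0, trials]")
    p = float(k_arr.mean()) / trials
    loglik = float(np.sum(sps.binom.logpmf(k_arr, trials, p)))
    return BinomialFit(p=p, trials=trials, loglik=loglik, n=k_arr.size)


@dataclass(frozen=True)
class FitComparison:
    """AIC comparison across candidate distributions.

    ``fits`` maps model name to its fit record; ``aic`` to 2k - 2 logL.
    ``preferred`` is the minimum-AIC model (ties resolved toward the
    conventional exponential); ``delta_aic`` is the AIC gap between the best
    competitor and the preferred model (>= 0).
    """

    fits: Mapping[str, object]
    aic: Mapping[str, float]
    preferred: str
    delta_aic: float


def compare_models(
    samples: Sequence[float],
    candidates: Sequence[str] = ("exponential", "pareto"),
    *,
    xmin: float | None = None,
    trials: int | None = None,
) -> FitComparison:
    """Fit candidate families by ML and rank them by AIC (k = 1 each).

    Supported candidates: ``exponential``, ``pareto`` (optionally with a
    fixed ``xmin``), ``binomial`` (requires ``trials``).  A candidate whose
    support excludes the sample is dropped with a warning; at least two must
    survive.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    fits: dict[str, object] = {}
    for name in candidates:
        try:
            if name == "exponential":
                fits[name] = fit_exponential(samples)
            elif name == "pareto":
                fits[name] = fit_pareto(samples, xmin=xmin)
            elif name == "binomial":
                if trials is None:
                    raise ValueError("binomial candidate requires trials")
                fits[name] = fit_binomial(np.asarray(samples, dtype=int), trials)
            else:
                raise ValueError(f"unknown candidate model {name!r}")
        except ValueError as exc:
            warnings.warn(f"candidate {name!r} excluded: {exc}", stacklevel=2)
    if len(fits) < 2:
        raise ValueError("fewer than two candidate models applicable to the sample")
    aic = {name: 2.0 * fit.k - 2.0 * fit.loglik for name, fit in fits.items()}
    best_aic = min(aic.values())
    tied = sorted(name for name, a in aic.items() if a == best_aic)
    preferred = "exponential" if "exponential" in tied else tied[0]
    others = [a for name, a in aic.items() if name != preferred]
    delta_aic = min(others) - aic[preferred]
    return FitComparison(fits=fits, aic=aic, preferred=preferred, delta_aic=delta_aic)


def waiting_times(log: EventLog) -> np.ndarray:
    """Pooled waiting times: gaps between each individual's consecutive events.

    Gaps are measured per individual (in either role) and pooled across the
    recording; zero gaps (simultaneous events of one individual) are
    dropped, since the fitted families have continuous positive support.
    """
    by_individual: dict[str, list[float]] = {}
    for e in log.events:
        for who in (e.initiator, e.target):
            by_individual.setdefault(who, []).append(e.time)
    gaps: list[float] = []
    for times in by_individual.values():
        gaps.extend(t1 - t0 for t0, t1 in zip(times, times[1:]) if t1 > t0)
    return np.array(gaps, dtype=float)


# ---------------------------------------------------------------------------
# Spatial randomness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CSRResult:
    """Per-axis KS test of complete spatial randomness."""

    ks_x: float
    p_x: float
    ks_y: float
    p_y: float
    n: int


def csr_test(log: EventLog) -> CSRResult:
    """KS test of event positions against uniform scatter over the nest.

    Under complete spatial randomness each coordinate is uniform on its
    side of the nest rectangle; both axes are tested with one-sample KS
    tests.  Requires at least 10 positioned events.
    """
    xs = [e.position[0] for e in log.events if e.position is not None]
    ys = [e.position[1] for e in log.events if e.position is not None]
    if len(xs) < 10:
        raise ValueError("need at least 10 positioned events for the CSR test")
    w, h = log.metadata.nest_width, log.metadata.nest_height
    res_x = sps.kstest(xs, sps.uniform(loc=0.0, scale=w).cdf)
    res_y = sps.kstest(ys, sps.uniform(loc=0.0, scale=h).cdf)
    return CSRResult(
        ks_x=float(res_x.statistic),
        p_x=float(res_x.pvalue),
        ks_y=float(res_y.statistic),
        p_y=float(res_y.pvalue),
        n=len(xs),
    )


# ---------------------------------------------------------------------------
# Spike-train cross-correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeCrossCorrelation:
    """Initiator-vs-target spike-train cross-correlations and the lag test.

    ``lags`` excludes 0; ``mean_correlation[k]`` is the across-individual
    mean of corr(initiator train at t, target train at t + lags[k]).  A
    positive-lag excess would indicate that being touched activates later
    initiating (feedback); the rank-sum test compares negative- and
    positive-lag correlation sets.
    """

    lags: np.ndarray
    mean_correlation: np.ndarray
    per_individual: Mapping[str, np.ndarray]
    statistic: float
    p_value: float
    skipped: tuple[str, ...]


def spike_cross_correlation(
    log: EventLog, bin_width: float = 1.0, max_lag: int = 60
) -> SpikeCrossCorrelation:
    """Cross-correlate each individual's initiator and target spike trains.

    Events are binned into binary trains of width ``bin_width`` seconds.
    For lags -max_lag..+max_lag (excluding 0, in bins) the Pearson
    correlation between the initiator train and the lag-shifted target
    train is computed per individual (individuals lacking events in either
    role, or with degenerate trains, are skipped with a warning).  Mean
    correlations at negative lags are compared with positive lags by a
    Wilcoxon rank-sum test.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    n_bins = max(int(math.ceil(log.metadata.duration / bin_width)), 2 * max_lag + 2)
    trains: dict[str, tuple[np.ndarray, np.ndarray]] = {
        who: (np.zeros(n_bins), np.zeros(n_bins)) for who in log.metadata.individuals
    }
    for e in log.events:
        b = min(int(e.time / bin_width), n_bins - 1)
        trains[e.initiator][0][b] = 1.0
        trains[e.target][1][b] = 1.0

    lags = np.array([k for k in range(-max_lag, max_lag + 1) if k != 0])
    per_individual: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for who, (init, targ) in trains.items():
        if init.sum() == 0 or targ.sum() == 0:
            skipped.append(who)
            continue
        cc = np.empty(lags.size)
        degenerate = False
        for k, lag in enumerate(lags):
            if lag >= 0:
                a, b = init[: n_bins - lag], targ[lag:]
            else:
                a, b = init[-lag:], targ[: n_bins + lag]
            if a.std() == 0 or b.std() == 0:
                degenerate = True
                break
            cc[k] = np.corrcoef(a, b)[0, 1]
        if degenerate:
            skipped.append(who)
            continue
        per_individual[who] = cc
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} individual(s) with degenerate spike trains",
            stacklevel=2,
        )
    if not per_individual:
        raise ValueError("no individual has usable initiator and target trains")
    mean_cc = np.mean(np.vstack(list(per_individual.values())), axis=0)
    neg = mean_cc[lags < 0]
    pos = mean_cc[lags > 0]
    stat, p = sps.ranksums(neg, pos)
    return SpikeCrossCorrelation(
        lags=lags,
        mean_correlation=mean_cc,
        per_individual=per_individual,
        statistic=float(stat),
        p_value=float(p),
        skipped=tuple(skipped),
    )


# ---------------------------------------------------------------------------
# Specialization tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecializationResult:
    """Cross-recording and within-recording degree relationships.

    ``across``: r and p of out-degree in recording 1 vs recording 2 over the
    shared roster (the model predicts no relationship over long separations,
    because interaction counts are memoryless Poisson draws).
    ``within``: per-recording SMA fits of in-degree vs out-degree (the model
    predicts slope 1: touches given equal touches received).
    """

    across_r: float
    across_p: float
    across_sma: SMAFit
    within: tuple[SMAFit, SMAFit]
    shared: tuple[str, ...]
    dropped: tuple[str, ...]


def specialization_tests(log1: EventLog, log2: EventLog) -> SpecializationResult:
    """Test for persistent interaction specialists across two recordings."""
    roster1, roster2 = set(log1.metadata.individuals), set(log2.metadata.individuals)
    shared = sorted(roster1 & roster2)
    dropped = sorted(roster1 ^ roster2)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared individuals")

    from .time_ordered_network import TimeOrderedNetwork, aggregate

    aggs = []
    for log in (log1, log2):
        net = TimeOrderedNetwork(log)
        aggs.append(aggregate(net, 0.0, log.metadata.duration))
    out1 = np.array([aggs[0].out_degrees()[w] for w in shared], dtype=float)
    out2 = np.array([aggs[1].out_degrees()[w] for w in shared], dtype=float)
    across_r, across_p = correlation_test(out1, out2)
    across_sma = sma_fit(out1, out2, hypothesized_slope=1.0)

    within = []
    for agg in aggs:
        outs = np.array([agg.out_degrees()[w] for w in shared], dtype=float)
        ins = np.array([agg.in_degrees()[w] for w in shared], dtype=float)
        within.append(sma_fit(outs, ins, hypothesized_slope=1.0))
    return SpecializationResult(
        across_r=across_r,
        across_p=across_p,
        across_sma=across_sma,
        within=(within[0], within[1]),
        shared=tuple(shared),
        dropped=tuple(dropped),
    )


def degree_window_transform(mean_degrees: Sequence[float], m: int) -> np.ndarray:
    """Linearise mean-degree growth for the slope test against the model.

    Under binomial-exponential degree growth, ln(1 - mean/(m-1)) equals
    -lambda_pair * t, so observed and predicted transforms compared by SMA
    have slope 1 when the data follow the model.  Saturated entries
    (mean = m-1) are dropped with a warning.
    """
    arr = np.asarray(mean_degrees, dtype=float)
    if np.any(arr < 0) or np.any(arr > m - 1):
        raise ValueError("mean degrees must lie in [0, m-1]")
    saturated = arr >= (m - 1)
    if saturated.any():
        warnings.warn(
            f"dropping {int(saturated.sum())} saturated mean-degree value(s)",
            stacklevel=2,
        )
    return np.log(1.0 - arr[~saturated] / (m - 1))
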