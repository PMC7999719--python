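"""Deconvolved calcium event trains and temporal-aggregation statistics.

Adult-born granule neurons in the dentate gyrus fire sparse calcium
transients (on the order of one per minute), and each transient is
polyphasic: deconvolution decomposes it into several unitary events with
individual times and amplitudes that aggregate within roughly ten
seconds.  This module provides the per-neuron event-train container plus
the statistics that calibrate everything downstream:

* amplitude-weighted binning of a train onto a fixed grid,
* mean unitary-event activity of a window (amplitude units / minute),
* the circular autocorrelation of a binned series, whose exponential
  decay sets the block length of the moving block bootstrap,
* a uniform temporal shuffle used as the de-aggregated null.

Bins are half-open ``[t, t + width)`` with the origin at session start;
an event landing exactly on the session end is assigned to the final
bin.  "Activity" is amplitude-weighted by default (the sum of
unitary-event amplitudes, not the event count); pass ``weighted=False``
for counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

#: Canonical session labels, in protocol order.
SESSIONS = ("preC", "preS", "postS", "consolidation", "test")


@dataclass(frozen=True)
class EventTrain:
    """One neuron's unitary calcium events within one session.

    ``times`` are seconds from session start and must be nondecreasing;
    ``amplitudes`` are strictly positive fluorescence units, one per
    event.  Both may be empty.
    """

    neuron_id: str
    mouse_id: str
    session: str
    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if t.ndim != 1 or a.ndim != 1 or t.shape != a.shape:
            raise ValueError("times and amplitudes must be 1-D and the same length")
        if self.session not in SESSIONS:
            raise ValueError(f"unknown session label {self.session!r}")
        if t.size:
            if t[0] < 0:
                raise ValueError("event times must be >= 0")
            if np.any(np.diff(t) < 0):
                raise ValueError("event times must be nondecreasing")
        if np.any(a <= 0):
            raise ValueError("event amplitudes must be > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", a)

    @property
    def n_events(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class BinnedActivity:
    """Amplitude-summed activity on a half-open bin grid."""

    bin_width: float
    values: np.ndarray
    origin: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if np.any(v < 0):
            raise ValueError("binned activity must be >= 0")
        object.__setattr__(self, "values", v)

    @property
    def n_bins(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width


@dataclass(frozen=True)
class AutocorrelationResult:
    """Circular autocorrelation with an optional exponential-decay fit.

    ``fit_tau`` is the decay constant of ``a + b*exp(-lag/tau)`` fitted
    to positive lags; ``block_length`` is the whole-second lag at which
    the fitted decay has fallen to within ``decay_tol`` of its
    asymptote, used as the moving-block-bootstrap block length.
    ``degenerate`` marks a constant input series, for which the
    correlation is undefined and the acf is reported as all zeros.
    """

    lags: np.ndarray
    acf: np.ndarray
    fit_tau: float | None = None
    block_length: float | None = None
    degenerate: bool = False


def bin_events(train: EventTrain, bin_width: float, duration: float) -> BinnedActivity:
    """Sum event amplitudes onto half-open bins covering ``[0, duration]``.

    An empty train yields all-zero bins; an event beyond ``duration`` is
    rejected.  The number of bins is ``ceil(duration / bin_width)``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if train.n_events and train.times[-1] > duration:
        raise ValueError(
            f"event at t={train.times[-1]:g}s lies beyond the session duration {duration:g}s"
        )
    n_bins = math.ceil(duration / bin_width)
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    values, _ = np.histogram(train.times, bins=edges, weights=train.amplitudes)
    return BinnedActivity(bin_width=float(bin_width), values=values)


def mean_event_activity(
    train: EventTrain, t0: float, t1: float, *, weighted: bool = True
) -> float:
    """Mean unitary-event activity over ``[t0, t1)`` in units / minute.

    Amplitude-weighted by default; with ``weighted=False`` the event
    count rate is returned instead.
    """
    if not t1 > t0:
        raise ValueError("window must have positive length (t1 > t0)")
    mask = (train.times >= t0) & (train.times < t1)
    total = float(train.amplitudes[mask].sum()) if weighted else float(mask.sum())
    return total / ((t1 - t0) / 60.0)


def mean_activity_in_intervals(
    train: EventTrain,
    intervals: list[tuple[float, float]],
    *,
    weighted: bool = True,
) -> tuple[float, float]:
    """Activity rate over a union of half-open intervals.

    Returns ``(rate_per_minute, dwell_seconds)``.  A zero total dwell
    yields rate 0.
    """
    dwell = float(sum(e - s for s, e in intervals))
    if dwell <= 0:
        return 0.0, 0.0
    total = 0.0
    for s, e in intervals:
        mask = (train.times >= s) & (train.times < e)
        total += float(train.amplitudes[mask].sum()) if weighted else float(mask.sum())
    return total / (dwell / 60.0), dwell


def circular_autocorrelation(
    binned: BinnedActivity, max_lag: float
) -> AutocorrelationResult:
    """Pearson correlation of a binned series with its circular rotations.

    The lag-``k`` value is the Pearson correlation between the series
    and itself rotated by ``k`` bins (circular shift), so lag 0 is 1 for
    any non-constant series.  A constant series has no defined
    correlation and is returned as an all-zero acf flagged degenerate.
    """
    x = np.asarray(binned.values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 bins")
    n_lags = int(math.floor(max_lag / binned.bin_width))
    if n_lags >= n:
        raise ValueError("max_lag must be shorter than the series' circular period")
    lags = np.arange(n_lags + 1, dtype=float) * binned.bin_width
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        return AutocorrelationResult(lags=lags, acf=np.zeros(n_lags + 1), degenerate=True)
    acf = np.array([np.dot(xc, np.roll(xc, k)) / denom for k in range(n_lags + 1)])
    return AutocorrelationResult(lags=lags, acf=acf)


def temporal_shuffle(train: EventTrain, duration: float, seed) -> EventTrain:
    """Redraw event times i.i.d. uniform over ``[0, duration)``.

    Amplitudes travel with their events, so the amplitude multiset is
    conserved; only temporal structure (aggregation) is destroyed.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    new_times = rng.uniform(0.0, duration, size=train.n_events)
    order = np.argsort(new_times, kind="stable")
    return replace(
        train, times=new_times[order], amplitudes=train.amplitudes[order]
    )


def estimate_block_length(
    result: AutocorrelationResult,
    *,
    default_block: float = 10.0,
    decay_tol: float = 0.05,
) -> AutocorrelationResult:
    """Fit an exponential decay to the acf and derive the block length.

    ``a + b*exp(-lag/tau)`` is fitted by least squares to the positive
    lags (lag 0 is excluded: it is 1 by construction and would dominate
    the fit).  The block length is the smallest whole second at which
    the fitted decay term has fallen to ``decay_tol`` of its initial
    amplitude, i.e. ``ceil(tau * ln(1/decay_tol))``.  A non-decaying fit
    (``b <= 0``, non-positive ``tau``, or a failed fit) falls back to
    ``default_block`` with a warning.
    """
    lags = np.asarray(result.lags, dtype=float)
    acf = np.asarray(result.acf, dtype=float)
    pos = lags > 0
    if result.degenerate or int(pos.sum()) < 3:
        warnings.warn(
            "autocorrelation unusable for block-length estimation; "
            f"falling back to default block of {default_block:g}s",
            stacklevel=2,
        )
        return replace(result, fit_tau=None, block_length=float(default_block))

    lag_pos, y = lags[pos], acf[pos]
    tail = max(1, y.size // 4)
    a0 = float(np.mean(y[-tail:]))
    b0 = float(y[0] - a0)
    below = np.nonzero(y < a0 + b0 / math.e)[0]
    tau0 = float(lag_pos[below[0]]) if (b0 > 0 and below.size) else float(lag_pos[-1] / 3)
    tau0 = max(tau0, float(lag_pos[0]))

    fitted = None
    if b0 > 1e-6:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # flat tails upset the covariance
                popt, _ = curve_fit(
                    lambda l, a, b, tau: a + b * np.exp(-l / tau),
                    lag_pos,
                    y,
                    p0=(a0, b0, tau0),
                    maxfev=20000,
                )
            fitted = popt
        except (RuntimeError, ValueError):
            fitted = None

    if fitted is None or fitted[1] <= 1e-6 or fitted[2] <= 0:
        warnings.warn(
            "autocorrelation does not decay; "
            f"falling back to default block of {default_block:g}s",
            stacklevel=2,
        )
        return replace(result, fit_tau=None, block_length=float(default_block))

    _, _, tau = (float(v) for v in fitted)
    block = max(1, math.ceil(tau * math.log(1.0 / decay_tol)))
    return replace(result, fit_tau=tau, block_length=float(block))
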