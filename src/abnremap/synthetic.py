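"""Synthetic experiment generator.

Emulates the statistical structure the pipeline assumes, so every stage
is testable without real recordings:

* sparse transients (~1/min per neuron) whose polyphasic structure is
  modelled as a compound Poisson cluster process: each transient onset
  spawns a burst of unitary events with exponentially distributed
  offsets (mean a few seconds), so the population autocorrelation
  decays within ~10 s;
* lognormal unitary-event amplitudes;
* per-neuron lognormal rate-heterogeneity profile shared by the preC,
  preS, postS and consolidation recordings — the persistent population
  identity that makes the learning-side sessions cluster together —
  with an independent profile drawn for the test session (retrieval
  recruits a different population);
* planted subpopulations: context-responsive neurons (elevated preS
  rate), a shock-suppressed subset (returning to baseline after the
  shock), and remapping neurons whose consolidation rate crossfades
  linearly (decreasing: sqrt(E) -> 1/sqrt(E) times baseline for effect
  size E; increasing: the mirror image).  Decreasing neurons belong to
  the context-responsive (learning) population; increasing neurons
  drive the test session;
* an alternating wake/NREM/REM hypnogram with deliberately sparse REM
  (so the pipeline's refusal to compute REM-only traces is exercised).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .events import EventTrain
from .experiment import DEFAULT_SESSION_DURATIONS, Experiment, Hypnogram


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic experiment.

    Durations and rates follow the recording protocol: preC and preS
    10 min, postS 5 min, consolidation recording 150 min, test 10 min;
    baseline ~1 transient/min per neuron.  Fractions plant the
    subpopulations (28% context-responsive, 10% shock-suppressed, 16%
    decreasing and 10% increasing during consolidation).
    """

    n_mice: int = 4
    neurons_per_mouse: int = 25
    session_durations: dict = field(
        default_factory=lambda: dict(DEFAULT_SESSION_DURATIONS)
    )
    base_rate_per_min: float = 1.0
    burst_size_mean: float = 3.0  # unitary events per transient
    burst_spread_s: float = 3.0  # exponential within-burst offsets
    amp_sigma: float = 0.5  # lognormal amplitude shape
    frac_context: float = 0.28
    frac_shock_suppressed: float = 0.10
    frac_decreasing: float = 0.16
    frac_increasing: float = 0.10
    crossfade_effect: float = 4.0  # start/end rate ratio over consolidation
    session_boost: float = 4.0  # drive multiplier of a session's planted population
    rate_heterogeneity_sigma: float = 0.5
    retrieval_remap: bool = True  # independent rate profile in the test session
    wake_dwell_s: float = 200.0
    nrem_dwell_s: float = 400.0
    rem_dwell_s: float = 50.0
    rem_prob: float = 0.3  # probability a NREM bout is followed by REM
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_context,
            self.frac_shock_suppressed,
            self.frac_decreasing,
            self.frac_increasing,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_decreasing + self.frac_increasing > 1.0:
            raise ValueError("remapping fractions exceed the population")
        if self.frac_context < self.frac_decreasing:
            raise ValueError(
                "context-responsive fraction must include the decreasing neurons"
            )
        if self.frac_shock_suppressed > self.frac_context - self.frac_decreasing:
            raise ValueError(
                "shock-suppressed neurons are drawn from the non-remapping part "
                "of the context-responsive population; fraction too large"
            )
        if self.frac_context + self.frac_increasing > 1.0:
            raise ValueError("context and increasing fractions are incompatible")
        if any(d <= 0 for d in self.session_durations.values()):
            raise ValueError("durations must be > 0")
        if self.base_rate_per_min <= 0 or self.crossfade_effect <= 0:
            raise ValueError("rates and effect sizes must be > 0")
        if self.burst_size_mean < 1.0:
            raise ValueError("burst size mean must be >= 1 event per transient")


def _assign_groups(config: GeneratorConfig, rng) -> pd.DataFrame:
    n = config.n_mice * config.neurons_per_mouse
    n_dec = round(config.frac_decreasing * n)
    n_inc = round(config.frac_increasing * n)
    n_ctx = round(config.frac_context * n)
    n_sup = round(config.frac_shock_suppressed * n)
    order = rng.permutation(n)
    dec = set(order[:n_dec])
    inc = set(order[n_dec : n_dec + n_inc])
    ctx_extra = order[n_dec + n_inc : n_dec + n_inc + (n_ctx - n_dec)]
    context = dec | set(ctx_extra)
    suppressed = set(ctx_extra[:n_sup])
    rows = []
    for i in range(n):
        mouse = f"m{i // config.neurons_per_mouse + 1}"
        neuron = f"n{i % config.neurons_per_mouse + 1:03d}"
        group = (
            "decreasing" if i in dec else "increasing" if i in inc else "stationary"
        )
        rows.append(
            {
                "mouse_id": mouse,
                "neuron_id": neuron,
                "remap_group": group,
                "context_responsive": i in context,
                "shock_suppressed": i in suppressed,
            }
        )
    return pd.DataFrame(rows)


def _session_rate_endpoints(
    row: pd.Series, config: GeneratorConfig, h: float, h_test: float
) -> dict[str, tuple[float, float]]:
    """Per-session (start, end) transient rates in events/second."""
    base = config.base_rate_per_min / 60.0
    boost = config.session_boost
    root = math.sqrt(config.crossfade_effect)
    ctx, sup = row.context_responsive, row.shock_suppressed
    group = row.remap_group
    rates = {
        "preC": base * h,
        "preS": base * h * (boost if ctx else 1.0),
        "postS": base * h * (boost if (ctx and not sup) else 1.0),
        "test": base
        * h_test
        * (boost if group == "increasing" else (1.0 / boost if group == "decreasing" else 1.0)),
    }
    out = {s: (r, r) for s, r in rates.items()}
    if group == "decreasing":
        out["consolidation"] = (base * h * root, base * h / root)
    elif group == "increasing":
        out["consolidation"] = (base * h / root, base * h * root)
    else:
        out["consolidation"] = (base * h, base * h)
    return out


def _draw_train(
    rng, rate0: float, rate1: float, duration: float, config: GeneratorConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Events of one session: thinned Poisson onsets expanded into bursts."""
    rate_max = max(rate0, rate1)
    n_onsets = rng.poisson(rate_max * duration)
    onsets = np.sort(rng.uniform(0.0, duration, size=n_onsets))
    if rate1 != rate0 and n_onsets:
        accept = rng.random(n_onsets) < (
            (rate0 + (rate1 - rate0) * onsets / duration) / rate_max
        )
        onsets = onsets[accept]
    sizes = 1 + rng.poisson(config.burst_size_mean - 1.0, size=onsets.size)
    total = int(sizes.sum())
    if total == 0:
        return np.empty(0), np.empty(0)
    rep_onsets = np.repeat(onsets, sizes)
    offsets = rng.exponential(config.burst_spread_s, size=total)
    first_of_burst = np.cumsum(sizes) - sizes
    offsets[first_of_burst] = 0.0
    times = rep_onsets + offsets
    amps = rng.lognormal(0.0, config.amp_sigma, size=total)
    keep = times <= duration
    times, amps = times[keep], amps[keep]
    order = np.argsort(times, kind="stable")
    return times[order], amps[order]


def _generate_hypnogram(config: GeneratorConfig, rng, duration: float) -> Hypnogram:
    intervals = []
    t, state = 0.0, "wake"
    while t < duration:
        if state == "wake":
            dwell, nxt = rng.exponential(config.wake_dwell_s), "NREM"
        elif state == "NREM":
            dwell = rng.exponential(config.nrem_dwell_s)
            nxt = "REM" if rng.random() < config.rem_prob else "wake"
        else:
            dwell, nxt = rng.exponential(config.rem_dwell_s), "wake"
        dwell = max(dwell, 10.0)  # no micro-bouts
        end = min(t + dwell, duration)
        intervals.append((t, end, state))
        t, state = end, nxt
    return Hypnogram(tuple(intervals))


def generate_experiment(
    config: GeneratorConfig,
) -> tuple[Experiment, pd.DataFrame]:
    """Draw a full synthetic experiment and its ground-truth label table."""
    ss = np.random.SeedSequence(config.seed)
    n = config.n_mice * config.neurons_per_mouse
    children = ss.spawn(2 + n)
    hyp_rng = np.random.default_rng(children[0])
    assign_rng = np.random.default_rng(children[1])
    truth = _assign_groups(config, assign_rng)

    sigma = config.rate_heterogeneity_sigma
    mu = -0.5 * sigma**2  # unit-mean lognormal profile
    h = np.exp(assign_rng.normal(mu, sigma, size=n)) if sigma > 0 else np.ones(n)
    if config.retrieval_remap and sigma > 0:
        h_test = np.exp(assign_rng.normal(mu, sigma, size=n))
    else:
        h_test = h

    trains = {}
    for i, row in truth.iterrows():
        rng = np.random.default_rng(children[2 + i])
        endpoints = _session_rate_endpoints(row, config, h[i], h_test[i])
        for session, (r0, r1) in endpoints.items():
            duration = config.session_durations[session]
            times, amps = _draw_train(rng, r0, r1, duration, config)
            trains[(row.mouse_id, row.neuron_id, session)] = EventTrain(
                neuron_id=row.neuron_id,
                mouse_id=row.mouse_id,
                session=session,
                times=times,
                amplitudes=amps,
            )
    hypnogram = _generate_hypnogram(
        config, hyp_rng, config.session_durations["consolidation"]
    )
    experiment = Experiment(
        trains=trains,
        session_durations=dict(config.session_durations),
        hypnogram=hypnogram,
        neuron_index=[(m, nrn) for m, nrn in zip(truth.mouse_id, truth.neuron_id)],
    )
    return experiment, truth


def generate_null_experiment(
    config: GeneratorConfig,
) -> tuple[Experiment, pd.DataFrame]:
    """A fully null experiment: no planted fractions, unit effect sizes,
    no persistent rate heterogeneity, no retrieval remap.

    Every neuron is a stationary compound-Poisson burst process with the
    same rate in every session, so all downstream detections are false
    positives by construction.
    """
    null_config = replace(
        config,
        frac_context=0.0,
        frac_shock_suppressed=0.0,
        frac_decreasing=0.0,
        frac_increasing=0.0,
        crossfade_effect=1.0,
        session_boost=1.0,
        rate_heterogeneity_sigma=0.0,
        retrieval_remap=False,
    )
    return generate_experiment(null_config)
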