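"""Per-neuron responsiveness between sessions and the active/inactive classifier.

A neuron's activity change between two sessions is tested with the
moving block bootstrap on its binned traces (block length from the
population autocorrelation), yielding an increase / decrease /
no_change label.  A separate bootstrap-over-bins criterion classifies
neurons as active within a period, and active sets are compared with
Jaccard / conditional fractions / hypergeometric enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .bootstrap import moving_block_bootstrap_diff
from .events import SESSIONS, BinnedActivity, bin_events
from .experiment import Experiment

RESPONSE_LABELS = ("increase", "decrease", "no_change")


@dataclass(frozen=True)
class ResponseLabel:
    """Activity-change label for one neuron over one session transition."""

    neuron_id: str
    mouse_id: str
    transition: tuple[str, str]
    label: str
    estimate: float = 0.0
    ci_low: float = 0.0
    ci_high: float = 0.0
    missing: bool = False


@dataclass(frozen=True)
class ActiveSet:
    """Neurons classified as active within one period."""

    label: str
    members: frozenset


@dataclass(frozen=True)
class OverlapStats:
    jaccard: float
    p_b_given_a: float
    p_a_given_b: float
    hypergeom_p: float
    n_a: int
    n_b: int
    n_intersection: int
    n_universe: int


def classify_period_response(
    experiment: Experiment,
    transition: tuple[str, str],
    block_length: float,
    *,
    bin_width: float = 1.0,
    n_replicates: int = 10000,
    alpha: float = 0.05,
    n_comparisons: int = 1,
    seed=0,
) -> list[ResponseLabel]:
    """Label every neuron's change from session A to session B.

    The moving block bootstrap tests mean(B) - mean(A) of the two
    binned traces; ``increase`` requires the CI entirely above 0,
    ``decrease`` entirely below.  A neuron absent from either session is
    labelled ``no_change`` with the ``missing`` flag.

    The bootstrap always runs on the pair sorted into protocol session
    order and the sign is flipped for a reversed transition, so swapping
    the transition maps increase <-> decrease exactly.
    """
    session_a, session_b = transition
    if session_a == session_b:
        raise ValueError("transition must involve two distinct sessions")
    for s in transition:
        if s not in experiment.session_durations:
            raise ValueError(f"session {s!r} has no duration in this experiment")
    reversed_order = SESSIONS.index(session_a) > SESSIONS.index(session_b)
    lo_sess, hi_sess = (
        (session_b, session_a) if reversed_order else (session_a, session_b)
    )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(experiment.neuron_index))

    labels: list[ResponseLabel] = []
    for (mouse, neuron), child in zip(experiment.neuron_index, children):
        train_a = experiment.get(mouse, neuron, session_a)
        train_b = experiment.get(mouse, neuron, session_b)
        if train_a is None or train_b is None:
            labels.append(
                ResponseLabel(neuron, mouse, transition, "no_change", missing=True)
            )
            continue
        binned = {
            s: bin_events(
                experiment.get(mouse, neuron, s),
                bin_width,
                experiment.session_durations[s],
            ).values
            for s in (lo_sess, hi_sess)
        }
        # statistic: later-session minus earlier-session mean
        res = moving_block_bootstrap_diff(
            binned[hi_sess],
            binned[lo_sess],
            block_length / bin_width,
            n_replicates=n_replicates,
            alpha=alpha,
            n_comparisons=n_comparisons,
            seed=child,
        )
        if reversed_order:
            res = res.flipped()
        if res.significant and res.ci_low > 0:
            label = "increase"
        elif res.significant and res.ci_high < 0:
            label = "decrease"
        else:
            label = "no_change"
        labels.append(
            ResponseLabel(
                neuron,
                mouse,
                transition,
                label,
                estimate=res.estimate,
                ci_low=res.ci_low,
                ci_high=res.ci_high,
            )
        )
    return labels


def response_fractions(labels: list[ResponseLabel]) -> dict[str, float]:
    """Proportion of neurons per label; the three proportions sum to 1."""
    if not labels:
        raise ValueError("no labels")
    n = len(labels)
    return {
        name: sum(1 for lab in labels if lab.label == name) / n
        for name in RESPONSE_LABELS
    }


def classify_active(
    binned: BinnedActivity,
    *,
    n_replicates: int = 10000,
    quorum: float = 0.95,
    seed=0,
) -> bool:
    """Bootstrap-over-bins active/inactive criterion.

    The period's bins are resampled with replacement at the original
    length; the neuron is active when the fraction of replicates that
    contain at least one event-bearing bin reaches ``quorum``.
    """
    hit = np.asarray(binned.values) > 0
    n = hit.size
    if not hit.any():
        return False
    if hit.all():
        return True
    rng = np.random.default_rng(seed)
    n_with_hit = 0
    chunk = max(1, int(2_000_000 // max(n, 1)))
    remaining = n_replicates
    while remaining > 0:
        m = min(chunk, remaining)
        idx = rng.integers(0, n, size=(m, n))
        n_with_hit += int(hit[idx].any(axis=1).sum())
        remaining -= m
    return bool(n_with_hit / n_replicates >= quorum)


def active_set(
    experiment: Experiment,
    label: str,
    session: str,
    *,
    states=None,
    bin_width: float = 1.0,
    n_replicates: int = 10000,
    quorum: float = 0.95,
    seed=0,
) -> ActiveSet:
    """Active neurons of one session, optionally restricted to hypnogram states.

    For a state restriction the events are mapped onto the cumulative
    dwell time of the matching intervals, so the resampled trace covers
    state time only.
    """
    from .experiment import to_state_time  # local to avoid import noise

    duration = experiment.session_durations[session]
    if states is not None:
        if experiment.hypnogram is None:
            raise ValueError("state restriction requires a hypnogram")
        intervals = experiment.hypnogram.restrict(states, 0.0, duration)
        dwell = sum(e - s for s, e in intervals)
        if dwell <= 0:
            raise ValueError(f"no dwell time in states {states!r}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    members = []
    for (mouse, neuron), child in zip(
        experiment.neuron_index, ss.spawn(len(experiment.neuron_index))
    ):
        train = experiment.train_or_empty(mouse, neuron, session)
        if states is None:
            binned = bin_events(train, bin_width, duration)
        else:
            mapped = to_state_time(train.times, intervals)
            edges = np.arange(int(np.ceil(dwell / bin_width)) + 1) * bin_width
            values, _ = np.histogram(mapped, bins=edges)
            binned = BinnedActivity(bin_width=bin_width, values=values.astype(float))
        if classify_active(
            binned, n_replicates=n_replicates, quorum=quorum, seed=child
        ):
            members.append((mouse, neuron))
    return ActiveSet(label=label, members=frozenset(members))


def population_overlap(set_a: ActiveSet, set_b: ActiveSet, universe) -> OverlapStats:
    """Overlap statistics between two active sets within a neuron universe."""
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set_a.members & universe, set_b.members & universe
    if not (set_a.members <= universe and set_b.members <= universe):
        raise ValueError("active sets must lie within the universe")
    inter = a & b
    union = a | b
    jaccard = len(inter) / len(union) if union else 0.0
    p_b_given_a = len(inter) / len(a) if a else float("nan")
    p_a_given_b = len(inter) / len(b) if b else float("nan")
    p = float(hypergeom.sf(len(inter) - 1, len(universe), len(a), len(b)))
    return OverlapStats(
        jaccard=jaccard,
        p_b_given_a=p_b_given_a,
        p_a_given_b=p_a_given_b,
        hypergeom_p=p,
        n_a=len(a),
        n_b=len(b),
        n_intersection=len(inter),
        n_universe=len(universe),
    )
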