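"""Time-resolved remapping of population activity during consolidation.

The consolidation recording is cut into 15-minute bins and each bin's
population activity vector is located between the first (A) and last
(C) bins by the remapping index

    RI(t) = (AD(C, Bt) - AD(A, Bt)) / (AD(A, Bt) + AD(C, Bt)),

where AD(X, Y) = 1 - cos(X, Y) is the angular distance.  RI is bounded
in [-1, 1]: +1 is a perfect match to the first bin, -1 a perfect match
to the last, 0 equidistance.  This sign convention follows the verbal
definition of the statistic; the originally printed formula has the
numerator reversed and is available via ``convention="printed"``.

On top of the index the module provides the per-state (wake / sleep)
trend of RI against time, the per-neuron classification of activity
trends (Pearson correlation with time, BH-FDR adjusted), group activity
profiles of decreasing / increasing / non-remapping neurons across the
learning, consolidation and test periods, and the similarity-clustering
analysis restricted to remapping vs non-remapping subpopulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .bootstrap import BootstrapResult, bh_fdr, bootstrap_mean_diff
from .experiment import Experiment
from .similarity import (
    ClusterResult,
    SimilarityMatrix,
    Window,
    cluster_significance,
    cosine_similarity,
    raw_activity,
    session_vectors,
    similarity_matrix,
    truncate_percentile,
)

STATE_FILTERS = {"all": None, "sleep": ("NREM", "REM"), "wake": ("wake",)}

REMAP_LABELS = ("decreasing", "increasing", "non_remapping")


@dataclass(frozen=True)
class ConsolidationMatrix:
    """Per-bin, per-neuron activity during the consolidation recording.

    ``raw`` holds outlier-truncated rates (units/min), one row per kept
    bin; ``scaled`` divides each neuron by ``scale`` (its maximum across
    the kept all-state bins), so each neuron's peak bin is exactly 1.
    """

    bin_centers_min: np.ndarray
    raw: np.ndarray
    scaled: np.ndarray
    scale: np.ndarray
    state_filter: str
    neuron_index: tuple


@dataclass(frozen=True)
class RemappingTrace:
    """Remapping index per consolidation bin with its trend against time."""

    bin_centers_min: np.ndarray
    ri: np.ndarray
    state_filter: str
    pearson_r: float
    pearson_p: float
    slope: float  # RI units per minute
    degenerate_bins: np.ndarray


@dataclass(frozen=True)
class RemapLabel:
    neuron_id: str
    mouse_id: str
    label: str
    pearson_r: float
    p: float
    q: float


@dataclass(frozen=True)
class GroupActivityProfile:
    """Mean scaled activity per remapping group and period, with the
    decreasing-vs-increasing bootstrap contrast per period."""

    periods: tuple[str, ...]
    means: dict
    comparisons: dict
    group_sizes: dict


def _consolidation_bins(duration: float, bin_minutes: float) -> int:
    n = int(np.floor(duration / (bin_minutes * 60.0)))
    if n < 2:
        raise ValueError("consolidation recording shorter than two bins")
    return n


def consolidation_activity_matrix(
    experiment: Experiment,
    bin_minutes: float = 15.0,
    state_filter: str = "all",
    *,
    min_dwell_s: float = 60.0,
    truncate_q: float = 95.0,
    scale: np.ndarray | None = None,
    allow_rem: bool = False,
) -> ConsolidationMatrix:
    """Activity vectors of consecutive consolidation bins.

    For ``sleep`` / ``wake`` filters the per-bin activity is computed
    over the hypnogram intervals of the matching states only, and bins
    with less than ``min_dwell_s`` of state dwell time are dropped.  A
    REM-only filter is refused by default: REM occupies too little of
    the recording for a meaningful trace.  ``scale`` may supply external
    per-neuron maxima (used to place state-filtered traces on the
    all-state scale).
    """
    if state_filter == "REM" and not allow_rem:
        raise ValueError(
            "REM-only traces are refused by default (insufficient dwell time); "
            "pass allow_rem=True to override"
        )
    states = STATE_FILTERS.get(state_filter, (state_filter,) if allow_rem else None)
    if state_filter not in STATE_FILTERS and not allow_rem:
        raise ValueError(f"unknown state filter {state_filter!r}")
    duration = experiment.session_durations["consolidation"]
    width = bin_minutes * 60.0
    n_bins = _consolidation_bins(duration, bin_minutes)
    if states is not None and experiment.hypnogram is None:
        raise ValueError("state-filtered matrix requires a hypnogram")
    if states is not None and not experiment.hypnogram.covers(0.0, n_bins * width):
        raise ValueError("hypnogram does not cover the consolidation recording")

    mouse_ids = [m for m, _ in experiment.neuron_index]
    rows, centers = [], []
    for i in range(n_bins):
        t0, t1 = i * width, (i + 1) * width
        window = Window(
            label=f"bin{i}", session="consolidation", t0=t0, t1=t1, states=states
        )
        if states is not None:
            dwell = experiment.hypnogram.state_seconds(states, t0, t1)
            if dwell < min_dwell_s:
                continue
        values = raw_activity(experiment, window)
        rows.append(truncate_percentile(values, mouse_ids, q=truncate_q))
        centers.append((t0 + t1) / 2.0 / 60.0)
    if not rows:
        raise ValueError(f"no qualifying bins for state filter {state_filter!r}")
    raw = np.vstack(rows)
    if scale is None:
        col_max = raw.max(axis=0)
        scale = np.where(col_max > 0, col_max, 1.0)
    scaled = raw / scale
    return ConsolidationMatrix(
        bin_centers_min=np.asarray(centers),
        raw=raw,
        scaled=scaled,
        scale=np.asarray(scale, dtype=float),
        state_filter=state_filter,
        neuron_index=tuple(experiment.neuron_index),
    )


def remapping_index(first, last, current, convention: str = "text") -> float:
    """Locate ``current`` between the first- and last-bin vectors.

    With the default text convention the index is +1 when ``current``
    matches ``first`` (up to positive scale), -1 when it matches
    ``last`` and 0 at equidistance.  ``convention="printed"`` negates
    the value.  A zero denominator (first and last collinear with
    current) is defined as 0.
    """
    value, _ = _remapping_index_flagged(first, last, current, convention)
    return value


def _remapping_index_flagged(first, last, current, convention: str) -> tuple[float, bool]:
    if convention not in ("text", "printed"):
        raise ValueError(f"unknown RI convention {convention!r}")
    ad_a = 1.0 - cosine_similarity(first, current)
    ad_c = 1.0 - cosine_similarity(last, current)
    denom = ad_a + ad_c
    if denom == 0.0:
        return 0.0, True
    value = (ad_c - ad_a) / denom
    if convention == "printed":
        value = -value
    return float(np.clip(value, -1.0, 1.0)), False


def ri_trend(bin_centers_min: np.ndarray, ri: np.ndarray) -> tuple[float, float, float]:
    """Pearson r, two-sided p, and least-squares slope of RI vs time."""
    t = np.asarray(bin_centers_min, dtype=float)
    y = np.asarray(ri, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 bins for a trend")
    if np.std(y) == 0.0 or np.std(t) == 0.0:
        return 0.0, 1.0, 0.0
    r, p = stats.pearsonr(t, y)
    slope = float(np.polyfit(t, y, 1)[0])
    return float(r), float(p), slope


def remapping_trace(
    experiment: Experiment,
    state_filter: str = "all",
    *,
    bin_minutes: float = 15.0,
    min_dwell_s: float = 60.0,
    convention: str = "text",
) -> RemappingTrace:
    """RI per consolidation bin against the first and last all-state bins.

    The anchors A and C are always the first and last bins of the
    all-state matrix, and state-filtered bins are scaled by the
    all-state per-neuron maxima, so wake and sleep traces are
    comparable on one scale.  By construction the all-state trace
    starts at +1 and ends at -1 (text convention).
    """
    all_mat = consolidation_activity_matrix(
        experiment, bin_minutes=bin_minutes, state_filter="all"
    )
    first, last = all_mat.scaled[0], all_mat.scaled[-1]
    if state_filter == "all":
        mat = all_mat
    else:
        mat = consolidation_activity_matrix(
            experiment,
            bin_minutes=bin_minutes,
            state_filter=state_filter,
            min_dwell_s=min_dwell_s,
            scale=all_mat.scale,
        )
    keep, ri, flags = [], [], []
    for i, row in enumerate(mat.scaled):
        if row.max() == 0.0:
            continue  # no activity in this (state-restricted) bin
        value, degenerate = _remapping_index_flagged(first, last, row, convention)
        keep.append(i)
        ri.append(value)
        flags.append(degenerate)
    if len(keep) < 3:
        raise ValueError("fewer than 3 qualifying bins for the remapping trace")
    centers = mat.bin_centers_min[keep]
    r, p, slope = ri_trend(centers, np.asarray(ri))
    return RemappingTrace(
        bin_centers_min=centers,
        ri=np.asarray(ri),
        state_filter=state_filter,
        pearson_r=r,
        pearson_p=p,
        slope=slope,
        degenerate_bins=np.asarray(flags, dtype=bool),
    )


def classify_remapping_neurons(
    experiment: Experiment,
    bin_minutes: float = 15.0,
    alpha: float = 0.05,
    q_threshold: float = 0.05,
) -> list[RemapLabel]:
    """Label each neuron's activity trend across the consolidation bins.

    Pearson correlation of the neuron's per-bin mean activity against
    bin-center time, BH-FDR adjusted across neurons.  ``decreasing`` /
    ``increasing`` require p < alpha and q < q_threshold with a
    matching sign; a constant-activity neuron is non_remapping (its
    correlation is undefined, p = 1).
    """
    mat = consolidation_activity_matrix(
        experiment, bin_minutes=bin_minutes, state_filter="all", truncate_q=100.0
    )
    t = mat.bin_centers_min
    if t.size < 3:
        raise ValueError("need at least 3 bins")
    rs, ps = [], []
    for values in mat.raw.T:
        if np.std(values) == 0.0:
            rs.append(0.0)
            ps.append(1.0)
        else:
            r, p = stats.pearsonr(t, values)
            rs.append(float(r))
            ps.append(float(p))
    qs = bh_fdr(ps)
    labels = []
    for (mouse, neuron), r, p, q in zip(mat.neuron_index, rs, ps, qs):
        if p < alpha and q < q_threshold:
            label = "decreasing" if r < 0 else "increasing"
        else:
            label = "non_remapping"
        labels.append(RemapLabel(neuron, mouse, label, r, p, float(q)))
    return labels


def remap_fractions(labels: list[RemapLabel]) -> dict[str, float]:
    if not labels:
        raise ValueError("no labels")
    n = len(labels)
    return {
        name: sum(1 for lab in labels if lab.label == name) / n
        for name in REMAP_LABELS
    }


#: Windows whose scaled activities make up the group profiles.
_PROFILE_WINDOWS = ("preS", "postS", "consolidation", "test")


def group_activity_profile(
    experiment: Experiment,
    labels: list[RemapLabel],
    *,
    n_replicates: int = 10000,
    alpha: float = 0.05,
    seed=0,
) -> GroupActivityProfile:
    """Mean scaled activity per remapping group across the paradigm.

    Per neuron, mean activity is computed in the preS, postS,
    consolidation and test windows, truncated per mouse, and divided by
    the neuron's maximum across those windows; the learning period is
    the average of preS and postS.  Per period, the decreasing and
    increasing groups are contrasted with the percentile bootstrap,
    Bonferroni-corrected over the three periods.
    """
    index = list(experiment.neuron_index)
    by_key = {(lab.mouse_id, lab.neuron_id): lab.label for lab in labels}
    if set(by_key) != set(index):
        raise ValueError("labels must cover exactly the experiment's neurons")
    mouse_ids = [m for m, _ in index]
    raw = np.vstack(
        [
            truncate_percentile(
                raw_activity(experiment, Window(w, w)), mouse_ids
            )
            for w in _PROFILE_WINDOWS
        ]
    )
    col_max = raw.max(axis=0)
    scaled = raw / np.where(col_max > 0, col_max, 1.0)
    by_window = dict(zip(_PROFILE_WINDOWS, scaled))
    period_values = {
        "learning": (by_window["preS"] + by_window["postS"]) / 2.0,
        "consolidation": by_window["consolidation"],
        "test": by_window["test"],
    }
    groups = {
        name: np.array([by_key[key] == name for key in index])
        for name in REMAP_LABELS
    }
    means = {
        name: {
            period: float(values[sel].mean()) if sel.any() else float("nan")
            for period, values in period_values.items()
        }
        for name, sel in groups.items()
    }
    for name, sel in groups.items():
        if not sel.any():
            warnings.warn(f"empty remapping group {name!r}; omitted from contrasts",
                          stacklevel=2)
    comparisons: dict[str, BootstrapResult] = {}
    dec, inc = groups["decreasing"], groups["increasing"]
    if dec.any() and inc.any():
        ss = (
            seed
            if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed)
        )
        for child, (period, values) in zip(ss.spawn(3), period_values.items()):
            comparisons[period] = bootstrap_mean_diff(
                values[dec],
                values[inc],
                n_replicates=n_replicates,
                alpha=alpha,
                n_comparisons=3,
                seed=child,
            )
    return GroupActivityProfile(
        periods=tuple(period_values),
        means=means,
        comparisons=comparisons,
        group_sizes={name: int(sel.sum()) for name, sel in groups.items()},
    )


def subgroup_similarity(
    experiment: Experiment,
    labels: list[RemapLabel],
    *,
    n_replicates: int = 10000,
    alpha: float = 0.05,
    seed=0,
    scheme: str = "permute_within",
    min_neurons: int = 3,
) -> dict[str, tuple[SimilarityMatrix, ClusterResult]]:
    """The session-similarity analysis restricted to remapping subgroups.

    Subgroups are the remapping neurons (decreasing + increasing) and
    the non-remapping neurons; a subgroup smaller than ``min_neurons``
    is skipped with a warning.
    """
    by_key = {(lab.mouse_id, lab.neuron_id): lab.label for lab in labels}
    subsets = {
        "remapping": [
            key
            for key in experiment.neuron_index
            if by_key.get(key) in ("decreasing", "increasing")
        ],
        "non_remapping": [
            key for key in experiment.neuron_index if by_key.get(key) == "non_remapping"
        ],
    }
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out = {}
    for child, (name, subset) in zip(ss.spawn(len(subsets)), subsets.items()):
        if len(subset) < min_neurons:
            warnings.warn(
                f"subgroup {name!r} has only {len(subset)} neurons; skipped",
                stacklevel=2,
            )
            continue
        vectors = session_vectors(experiment, neurons=subset)
        sim = similarity_matrix(vectors)
        clusters = cluster_significance(
            vectors, n_replicates=n_replicates, alpha=alpha, seed=child, scheme=scheme
        )
        out[name] = (sim, clusters)
    return out
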