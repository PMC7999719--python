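"""Population activity vectors, cosine similarity, and significant clustering.

An activity vector holds every neuron's mean event activity over one
window, outlier-truncated at the 95th percentile per mouse (linear
interpolation between order statistics) and rescaled.  Two rescaling
modes exist because both are used downstream: min-max over the whole
concatenated vector (``vector_01``) and per-neuron division by the
maximum across a set of windows (``neuron_max``).

Similarity is the normalized dot product; clustering is agglomerative
with Ward's linkage on the angular distance ``1 - cos``.  Ward on a
non-Euclidean distance is mathematically improper but is applied as
such deliberately (it is the procedure being reproduced); the caveat is
documented in the methods note.  Significance of dendrogram merges is
assessed against a resampling null that destroys inter-vector alignment
while preserving marginals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .events import mean_activity_in_intervals, mean_event_activity
from .experiment import Experiment

#: Sessions entering the learning-vs-retrieval similarity analysis.
FIG_SESSIONS = ("preC", "preS", "postS", "test")


@dataclass(frozen=True)
class Window:
    """A labelled analysis window: a session, optionally a sub-interval
    and a hypnogram-state restriction."""

    label: str
    session: str
    t0: float | None = None
    t1: float | None = None
    states: tuple[str, ...] | None = None


@dataclass(frozen=True)
class ActivityVector:
    label: str
    values: np.ndarray
    neuron_index: tuple = ()
    degenerate: bool = False


@dataclass(frozen=True)
class SimilarityMatrix:
    labels: tuple[str, ...]
    values: np.ndarray


@dataclass(frozen=True)
class ClusterResult:
    """Dendrogram with its resampling-derived significance threshold.

    ``significant_merges[i]`` is True when merge ``i`` of ``linkage`` is
    tighter than the alpha-quantile of the null distribution of minimum
    merge heights.  ``memberships`` assigns each label the flat cluster
    formed by the significant merges; ``n_significant_clusters`` counts
    clusters with at least two members.
    """

    linkage: np.ndarray
    threshold: float
    labels: tuple[str, ...]
    memberships: np.ndarray
    significant_merges: np.ndarray

    @property
    def n_significant_clusters(self) -> int:
        _, counts = np.unique(self.memberships, return_counts=True)
        return int((counts >= 2).sum())

    def cluster_members(self) -> list[frozenset]:
        out = []
        for cid in np.unique(self.memberships):
            members = frozenset(
                lab for lab, m in zip(self.labels, self.memberships) if m == cid
            )
            if len(members) >= 2:
                out.append(members)
        return out


def truncate_percentile(
    values: np.ndarray, mouse_ids, q: float = 95.0, thresholds: dict | None = None
) -> np.ndarray:
    """Clip each mouse's values at that mouse's ``q``-th percentile.

    Percentiles use linear interpolation between order statistics.  A
    precomputed ``thresholds`` mapping (mouse -> clip value) may be
    passed, under which clipping is idempotent.
    """
    values = np.asarray(values, dtype=float).copy()
    mouse_ids = np.asarray(mouse_ids)
    for mouse in np.unique(mouse_ids):
        sel = mouse_ids == mouse
        t = (
            thresholds[mouse]
            if thresholds is not None
            else float(np.percentile(values[sel], q))
        )
        values[sel] = np.minimum(values[sel], t)
    return values


def raw_activity(
    experiment: Experiment, window: Window, *, neurons=None, weighted: bool = True
) -> np.ndarray:
    """Per-neuron mean activity (units/min) over a window, in neuron order."""
    index = experiment.neuron_index if neurons is None else list(neurons)
    duration = experiment.session_durations[window.session]
    t0 = 0.0 if window.t0 is None else window.t0
    t1 = duration if window.t1 is None else window.t1
    intervals = None
    if window.states is not None:
        if experiment.hypnogram is None:
            raise ValueError("state-restricted window requires a hypnogram")
        intervals = experiment.hypnogram.restrict(window.states, t0, t1)
    out = np.empty(len(index))
    for i, (mouse, neuron) in enumerate(index):
        train = experiment.train_or_empty(mouse, neuron, window.session)
        if intervals is None:
            out[i] = mean_event_activity(train, t0, t1, weighted=weighted)
        else:
            out[i], _ = mean_activity_in_intervals(train, intervals, weighted=weighted)
    return out


def _minmax_01(values: np.ndarray) -> tuple[np.ndarray, bool]:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.zeros_like(values), True
    return (values - lo) / (hi - lo), False


def build_activity_vector(
    experiment: Experiment,
    window,
    scaling: str = "vector_01",
    *,
    neurons=None,
    truncate_q: float = 95.0,
) -> ActivityVector:
    """One window's activity vector: truncated per mouse, min-max rescaled.

    ``window`` may be a session label or a :class:`Window`.  Only the
    ``vector_01`` scaling applies to a single window; the per-neuron-max
    mode needs the whole set of windows (see
    :func:`build_activity_vectors`).  A constant vector cannot be
    rescaled and is returned all-zero with the degenerate flag.
    """
    if scaling != "vector_01":
        raise ValueError("single-window vectors support only vector_01 scaling")
    if isinstance(window, str):
        window = Window(label=window, session=window)
    index = experiment.neuron_index if neurons is None else list(neurons)
    values = raw_activity(experiment, window, neurons=index)
    mouse_ids = [m for m, _ in index]
    values = truncate_percentile(values, mouse_ids, q=truncate_q)
    scaled, degenerate = _minmax_01(values)
    return ActivityVector(
        label=window.label,
        values=scaled,
        neuron_index=tuple(index),
        degenerate=degenerate,
    )


def build_activity_vectors(
    experiment: Experiment,
    windows,
    scaling: str = "neuron_max",
    *,
    neurons=None,
    truncate_q: float = 95.0,
) -> list[ActivityVector]:
    """Activity vectors for a set of windows under a common scaling.

    ``neuron_max`` divides each neuron by its maximum across the
    windows (a neuron silent everywhere stays 0); ``vector_01`` min-max
    rescales each vector independently.
    """
    windows = [Window(label=w, session=w) if isinstance(w, str) else w for w in windows]
    index = experiment.neuron_index if neurons is None else list(neurons)
    mouse_ids = [m for m, _ in index]
    raw = np.vstack(
        [
            truncate_percentile(
                raw_activity(experiment, w, neurons=index), mouse_ids, q=truncate_q
            )
            for w in windows
        ]
    )
    if scaling == "vector_01":
        out = []
        for w, row in zip(windows, raw):
            scaled, degenerate = _minmax_01(row)
            out.append(
                ActivityVector(w.label, scaled, tuple(index), degenerate=degenerate)
            )
        return out
    if scaling != "neuron_max":
        raise ValueError(f"unknown scaling {scaling!r}")
    col_max = raw.max(axis=0)
    scale = np.where(col_max > 0, col_max, 1.0)
    scaled = raw / scale
    return [
        ActivityVector(
            w.label, row, tuple(index), degenerate=bool(row.max() == row.min())
        )
        for w, row in zip(windows, scaled)
    ]


def _values(v) -> np.ndarray:
    return np.asarray(v.values if isinstance(v, ActivityVector) else v, dtype=float)


def cosine_similarity(a, b) -> float:
    """Normalized dot product of two activity vectors."""
    x, y = _values(a), _values(b)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    nx, ny = float(np.linalg.norm(x)), float(np.linalg.norm(y))
    if nx == 0.0 or ny == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(x, y) / (nx * ny))


def similarity_matrix(vectors) -> SimilarityMatrix:
    """All pairwise cosine similarities; symmetric with unit diagonal."""
    if len(vectors) < 2:
        raise ValueError("need at least 2 vectors")
    labels = tuple(
        v.label if isinstance(v, ActivityVector) else f"v{i}"
        for i, v in enumerate(vectors)
    )
    mat = np.vstack([_values(v) for v in vectors])
    norms = np.linalg.norm(mat, axis=1)
    if np.any(norms == 0):
        bad = labels[int(np.argmax(norms == 0))]
        raise ValueError(f"zero activity vector {bad!r}")
    sims = (mat @ mat.T) / np.outer(norms, norms)
    sims = np.clip(sims, -1.0, 1.0)
    np.fill_diagonal(sims, 1.0)
    return SimilarityMatrix(labels=labels, values=sims)


def hierarchical_clustering(matrix: SimilarityMatrix) -> np.ndarray:
    """Ward-linkage dendrogram on the angular distance ``1 - similarity``."""
    dist = 1.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(np.maximum(dist, 0.0), checks=False)
    return linkage(condensed, method="ward")


def _null_linkage_minima(
    mat: np.ndarray, n_replicates: int, rng, scheme: str
) -> np.ndarray:
    n_vec, n = mat.shape
    mins = np.empty(n_replicates)
    for i in range(n_replicates):
        if scheme == "permute_within":
            idx = np.argsort(rng.random((n_vec, n)), axis=1)
        elif scheme == "bootstrap_within":
            idx = rng.integers(0, n, size=(n_vec, n))
        else:
            raise ValueError(f"unknown null scheme {scheme!r}")
        resampled = np.take_along_axis(mat, idx, axis=1)
        norms = np.linalg.norm(resampled, axis=1)
        norms = np.where(norms > 0, norms, 1.0)
        sims = np.clip((resampled @ resampled.T) / np.outer(norms, norms), -1.0, 1.0)
        dist = 1.0 - sims
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(np.maximum(dist, 0.0), checks=False), method="ward")
        mins[i] = z[:, 2].min()
    return mins


def cluster_significance(
    vectors,
    n_replicates: int = 10000,
    alpha: float = 0.05,
    seed=0,
    scheme: str = "permute_within",
) -> ClusterResult:
    """Dendrogram cut-off from a resampling reference distribution.

    Per replicate each vector's entries are independently permuted
    across neuron positions (default scheme; ``bootstrap_within``
    resamples entries with replacement instead), destroying inter-vector
    correlation while preserving marginals, and the linkage is
    recomputed.  The threshold is the ``alpha``-quantile of the null
    minimum merge heights, so under the null the probability that any
    observed merge falls below it is ``alpha``.  Observed merges below
    the threshold are significant; the flat clusters they form are the
    significant clusters.
    """
    if len(vectors) < 3:
        raise ValueError("need at least 3 vectors")
    sim = similarity_matrix(vectors)
    z = hierarchical_clustering(sim)
    mat = np.vstack([_values(v) for v in vectors])
    rng = np.random.default_rng(seed)
    mins = _null_linkage_minima(mat, n_replicates, rng, scheme)
    threshold = float(np.quantile(mins, alpha))
    significant = z[:, 2] < threshold
    memberships = fcluster(z, t=threshold * (1 - 1e-12), criterion="distance")
    return ClusterResult(
        linkage=z,
        threshold=threshold,
        labels=sim.labels,
        memberships=memberships,
        significant_merges=significant,
    )


def session_vectors(
    experiment: Experiment,
    sessions=FIG_SESSIONS,
    scaling: str = "vector_01",
    *,
    neurons=None,
) -> list[ActivityVector]:
    """The session-wise activity vectors of the learning-vs-retrieval analysis."""
    vectors = build_activity_vectors(
        experiment, list(sessions), scaling=scaling, neurons=neurons
    )
    for v in vectors:
        if v.degenerate:
            warnings.warn(f"degenerate (constant) activity vector {v.label!r}",
                          stacklevel=2)
    return vectors
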