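"""End-to-end analysis pipeline.

Runs, in order: population autocorrelation and block-length estimation;
per-neuron responsiveness between sessions; active-set overlap
statistics; session-vector similarity and significant clustering;
consolidation remapping traces, per-neuron remapping classification,
group activity profiles and subgroup clustering.  Writes result tables
and a JSON run report that echoes every seed, threshold and convention
flag used, so a run is reproducible bit-for-bit from its report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import RunConfig
from .events import circular_autocorrelation, estimate_block_length
from .experiment import Experiment
from .remapping import (
    classify_remapping_neurons,
    group_activity_profile,
    remap_fractions,
    remapping_trace,
    subgroup_similarity,
)
from .responsiveness import (
    active_set,
    classify_period_response,
    population_overlap,
    response_fractions,
)
from .similarity import cluster_significance, session_vectors, similarity_matrix

RESPONSE_TRANSITIONS = (("preC", "preS"), ("preS", "postS"))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _trace_summary(trace) -> dict:
    return {
        "state_filter": trace.state_filter,
        "bin_centers_min": trace.bin_centers_min,
        "ri": trace.ri,
        "pearson_r": trace.pearson_r,
        "pearson_p": trace.pearson_p,
        "slope_per_min": trace.slope,
    }


def run_pipeline(
    config: RunConfig,
    experiment: Experiment | None = None,
) -> dict:
    """Run the full analysis; returns the run report as a dict.

    ``experiment`` may be supplied directly (e.g. fresh from the
    generator); otherwise it is loaded from ``config.data_dir``.
    Tables and the JSON report are written under ``config.output_dir``.
    """
    if experiment is None:
        if config.data_dir is None:
            raise ValueError("either an experiment or config.data_dir is required")
        experiment = io.load_experiment(config.data_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: child
        for name, child in zip(
            ("responsiveness", "active_sets", "clustering", "profile", "subgroups"),
            ss.spawn(5),
        )
    }
    report: dict = {"config": _jsonable(asdict(config)), "stages": {}}

    # --- block length from the population autocorrelation -------------
    binned = experiment.population_binned("consolidation", config.acf_bin_s)
    acf = estimate_block_length(
        circular_autocorrelation(binned, config.acf_max_lag_s),
        default_block=config.default_block_s,
    )
    block = (
        config.block_length_s
        if config.block_length_s is not None
        else float(acf.block_length)
    )
    report["stages"]["autocorrelation"] = {
        "fit_tau_s": acf.fit_tau,
        "estimated_block_s": acf.block_length,
        "block_used_s": block,
    }

    # --- per-neuron responsiveness -------------------------------------
    resp = {}
    rows = []
    for transition, child in zip(
        RESPONSE_TRANSITIONS, seeds["responsiveness"].spawn(len(RESPONSE_TRANSITIONS))
    ):
        labels = classify_period_response(
            experiment,
            transition,
            block,
            bin_width=config.acf_bin_s,
            n_replicates=config.n_replicates,
            alpha=config.alpha,
            n_comparisons=config.bonferroni_comparisons,
            seed=child,
        )
        resp["->".join(transition)] = response_fractions(labels)
        rows.extend(
            {
                "mouse_id": lab.mouse_id,
                "neuron_id": lab.neuron_id,
                "transition": "->".join(lab.transition),
                "label": lab.label,
                "estimate": lab.estimate,
                "ci_low": lab.ci_low,
                "ci_high": lab.ci_high,
            }
            for lab in labels
        )
    pd.DataFrame(rows).to_csv(out / "responsiveness.csv", index=False)
    report["stages"]["responsiveness"] = resp

    # --- active sets and overlaps --------------------------------------
    overlaps = {}
    if experiment.hypnogram is not None:
        set_children = seeds["active_sets"].spawn(3)
        sets = {
            "postS": active_set(
                experiment, "postS", "postS",
                n_replicates=config.n_replicates, seed=set_children[0],
            ),
            "test": active_set(
                experiment, "test", "test",
                n_replicates=config.n_replicates, seed=set_children[1],
            ),
            "REM": active_set(
                experiment, "REM", "consolidation", states=("REM",),
                n_replicates=config.n_replicates, seed=set_children[2],
            ),
        }
        universe = frozenset(experiment.neuron_index)
        for a, b in (("REM", "postS"), ("REM", "test")):
            overlaps["|".join((a, b))] = asdict(
                population_overlap(sets[a], sets[b], universe)
            )
        pd.DataFrame(
            [
                {"set": name, "mouse_id": m, "neuron_id": n}
                for name, s in sets.items()
                for m, n in sorted(s.members)
            ]
        ).to_csv(out / "active_sets.csv", index=False)
    report["stages"]["active_set_overlaps"] = overlaps

    # --- session similarity and clustering -----------------------------
    vectors = session_vectors(experiment)
    sim = similarity_matrix(vectors)
    clusters = cluster_significance(
        vectors,
        n_replicates=config.n_replicates,
        alpha=config.alpha,
        seed=seeds["clustering"],
        scheme=config.cluster_null_scheme,
    )
    pd.DataFrame(sim.values, index=sim.labels, columns=sim.labels).to_csv(
        out / "session_similarity.csv"
    )
    (out / "session_dendrogram.nwk").write_text(
        io.linkage_to_newick(clusters.linkage, clusters.labels) + "\n"
    )
    report["stages"]["session_clustering"] = {
        "labels": list(sim.labels),
        "similarity": sim.values,
        "threshold": clusters.threshold,
        "memberships": clusters.memberships,
        "n_significant_clusters": clusters.n_significant_clusters,
        "significant_clusters": [sorted(c) for c in clusters.cluster_members()],
    }

    # --- consolidation remapping ---------------------------------------
    traces = {}
    state_filters = ["all"] + (
        ["sleep", "wake"] if experiment.hypnogram is not None else []
    )
    for state in state_filters:
        trace = remapping_trace(
            experiment,
            state,
            bin_minutes=config.consolidation_bin_min,
            min_dwell_s=config.min_state_dwell_s,
            convention=config.ri_convention,
        )
        traces[state] = _trace_summary(trace)
    pd.concat(
        [
            pd.DataFrame(
                {
                    "state_filter": s,
                    "bin_center_min": t["bin_centers_min"],
                    "ri": t["ri"],
                }
            )
            for s, t in traces.items()
        ]
    ).to_csv(out / "remapping_traces.csv", index=False)
    report["stages"]["remapping_traces"] = traces

    remap_labels = classify_remapping_neurons(
        experiment,
        bin_minutes=config.consolidation_bin_min,
        alpha=config.alpha,
        q_threshold=config.q_threshold,
    )
    pd.DataFrame(
        [
            {
                "mouse_id": lab.mouse_id,
                "neuron_id": lab.neuron_id,
                "label": lab.label,
                "pearson_r": lab.pearson_r,
                "p": lab.p,
                "q": lab.q,
            }
            for lab in remap_labels
        ]
    ).to_csv(out / "remap_labels.csv", index=False)
    report["stages"]["remapping_classification"] = {
        "fractions": remap_fractions(remap_labels),
        "counts": {
            name: sum(1 for lab in remap_labels if lab.label == name)
            for name in ("decreasing", "increasing", "non_remapping")
        },
    }

    profile = group_activity_profile(
        experiment,
        remap_labels,
        n_replicates=config.n_replicates,
        alpha=config.alpha,
        seed=seeds["profile"],
    )
    report["stages"]["group_profile"] = {
        "means": profile.means,
        "group_sizes": profile.group_sizes,
        "comparisons": {p: asdict(r) for p, r in profile.comparisons.items()},
    }

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small subgroups are expected sometimes
        subgroups = subgroup_similarity(
            experiment,
            remap_labels,
            n_replicates=config.n_replicates,
            alpha=config.alpha,
            seed=seeds["subgroups"],
            scheme=config.cluster_null_scheme,
        )
    report["stages"]["subgroup_clustering"] = {
        name: {
            "labels": list(sim_m.labels),
            "n_significant_clusters": clu.n_significant_clusters,
            "significant_clusters": [sorted(c) for c in clu.cluster_members()],
        }
        for name, (sim_m, clu) in subgroups.items()
    }

    report = _jsonable(report)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
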