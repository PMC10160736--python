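"""FDR/power benchmark harness over simulation replicates.

For each replicate: simulate single-cell counts, aggregate to pseudo-bulk,
filter (<30 reads per gene), TMM-normalize; then for every pairwise group
comparison fit each voom-family method on the full multi-group design with
the pair's contrast, call DE at each BH-adjusted p cutoff, and score
against the simulation truth. FDR = FP / max(#called, 1) (a comparison
with zero calls contributes FDR 0), TPR = TP / #truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .ebayes_dea import de_table, decide_de
from .pseudobulk import aggregate_cells, filter_genes, tmm_norm_factors
from .simulator import SimConfig, scenario_preset, simulate_dataset
from .voom_by_group import voom_by_group
from .voom_core import DesignMatrix, voom
from .voom_qwb import voom_qwb

__all__ = ["METHODS", "run_benchmark", "summarize", "score_calls"]

_VARIABILITY_CLASS = {
    # scenario terminology: groups 1-2 low variation, 3-4 high
    ("group1", "group2"): "Low vs Low",
    ("group1", "group3"): "Low vs High",
    ("group1", "group4"): "Low vs High",
    ("group2", "group3"): "Low vs High",
    ("group2", "group4"): "Low vs High",
    ("group3", "group4"): "High vs High",
}


def _fit_method(method: str, pb, design: DesignMatrix, group: np.ndarray):
    if method == "voom":
        return voom(pb, design)
    if method == "voomqwb":
        return voom_qwb(pb, design, group=group)
    if method == "voombygroup":
        return voom_by_group(pb, design, group=group)
    raise ValueError(f"unknown method {method!r}")


METHODS = ("voom", "voomqwb", "voombygroup")


def score_calls(called: set, truth: set, cutoff: float) -> dict:
    """TP/FP/FDR/TPR bookkeeping for one comparison at one cutoff."""
    tp = len(called & truth)
    fp = len(called - truth)
    n_called = len(called)
    assert tp + fp == n_called
    fdr = fp / max(n_called, 1)
    tpr = tp / max(len(truth), 1)
    assert 0.0 <= fdr <= 1.0 and 0.0 <= tpr <= 1.0
    return {"n_called": n_called, "tp": tp, "fp": fp, "fdr": fdr, "tpr": tpr}


def run_benchmark(
    presets: Sequence[str | SimConfig],
    methods: Sequence[str] = METHODS,
    reps: int = 10,
    cutoffs: Sequence[float] = (0.01, 0.05, 0.10),
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full simulate-aggregate-test-score loop.

    One row per (scenario, method, comparison, rep, cutoff). Replicate r of
    a preset uses seed = seed + r, so results are deterministic given
    (seed, reps). A replicate that fails is excluded and counted in the
    frame's ``attrs['failed_reps']``.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    rows = []
    failed = 0
    for preset in presets:
        name = preset if isinstance(preset, str) else "custom"
        for rep in range(1, reps + 1):
            if isinstance(preset, str):
                cfg = scenario_preset(preset, seed=seed + rep)
            else:
                from dataclasses import replace

                cfg = replace(preset, seed=seed + rep)
            try:
                rows.extend(
                    _one_rep(name, cfg, methods, cutoffs, rep)
                )
            except Exception as exc:  # noqa: BLE001 - harness logs and moves on
                failed += 1
                print(f"[run_benchmark] rep {rep} of {name} failed: {exc}")
    out = pd.DataFrame(rows)
    out.attrs["failed_reps"] = failed
    return out


def _one_rep(
    name: str,
    cfg: SimConfig,
    methods: Sequence[str],
    cutoffs: Sequence[float],
    rep: int,
) -> list:
    cc, truth = simulate_dataset(cfg)
    pb = tmm_norm_factors(filter_genes(aggregate_cells(cc), min_total=30))
    group = pb.group_labels
    levels = list(pd.unique(group))
    design = DesignMatrix.from_groups(group, coding="means")
    rows = []
    for method in methods:
        wle = _fit_method(method, pb, design, group)
        for ga, gb in combinations(levels, 2):
            contrast = np.zeros(len(levels))
            contrast[levels.index(gb)] = 1.0
            contrast[levels.index(ga)] = -1.0
            tab = de_table(wle, contrast)
            truth_set = truth.de_for_comparison(ga, gb)
            for cutoff in cutoffs:
                called = decide_de(tab, cutoff)
                rows.append(
                    {
                        "scenario": name,
                        "method": method,
                        "comparison": f"{ga}-{gb}",
                        "class": _VARIABILITY_CLASS.get((ga, gb), "unknown"),
                        "rep": rep,
                        "cutoff": cutoff,
                        "n_truth": len(truth_set),
                        **score_calls(called, truth_set, cutoff),
                    }
                )
    return rows


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Replicate means of FDR and TPR with Monte-Carlo standard errors,
    per (scenario, method, comparison, cutoff)."""
    if len(results) == 0:
        raise ValueError("empty results")
    grp = results.groupby(
        ["scenario", "method", "comparison", "class", "cutoff"], sort=False
    )
    out = grp.agg(
        n_reps=("rep", "size"),
        mean_fdr=("fdr", "mean"),
        se_fdr=("fdr", "sem"),
        mean_tpr=("tpr", "mean"),
        se_tpr=("tpr", "sem"),
        mean_called=("n_called", "mean"),
    ).reset_index()
    out["se_fdr"] = out["se_fdr"].fillna(0.0)
    out["se_tpr"] = out["se_tpr"].fillna(0.0)
    return out
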