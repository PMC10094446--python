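"""Cohort-level orchestration helpers shared by the CLI and scripted use.

These functions tie the stages together at DataFrame granularity: per-neuron
morphometric tables, percent-change-from-control summaries per genotype
(per-neuron values first, then group means), and cohort signal profiling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .morphometry import build_tree, morpho_metrics, percent_change
from .signal_quant import (
    PathProfile,
    compartment_signals,
    path_profile,
    percent_change_profile,
)
from .swc_io import Reconstruction

__all__ = [
    "metrics_table",
    "percent_change_report",
    "cohort_profiles",
    "cohort_percent_change_profile",
]

METRIC_COLUMNS = ["tdl", "tdb", "dbd", "n_tips", "n_branch_nodes", "max_path_distance"]


def metrics_table(recons: list[Reconstruction]) -> pd.DataFrame:
    """Per-neuron morphometrics for a list of reconstructions."""
    rows = []
    for r in recons:
        mm = morpho_metrics(build_tree(r))
        rows.append(
            {
                "neuron_id": r.neuron_id,
                "genotype": r.condition,
                "class": r.neuron_class,
                "subtype": r.subtype,
                "tdl": mm.tdl,
                "tdb": mm.tdb,
                "dbd": mm.dbd if mm.dbd is not None else np.nan,
                "n_tips": mm.n_tips,
                "n_branch_nodes": mm.n_branch_nodes,
                "max_path_distance": mm.max_path_distance,
                "degenerate": mm.degenerate,
            }
        )
    return pd.DataFrame(rows)


def percent_change_report(
    metrics: pd.DataFrame,
    control: str = "control",
    group: str = "genotype",
    metrics_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Percent change of each case group's mean from the control group's
    mean, per metric (long format: genotype, metric, percent_change,
    case_mean, control_mean, n_case, n_control)."""
    cols = metrics_cols or ["tdl", "tdb", "dbd"]
    if control not in set(metrics[group]):
        raise ValueError(f"control group {control!r} not in table")
    ctrl = metrics[metrics[group] == control]
    rows = []
    for label, sub in metrics.groupby(group, sort=False):
        if label == control:
            continue
        for col in cols:
            rows.append(
                {
                    "genotype": label,
                    "metric": col,
                    "percent_change": percent_change(sub[col], ctrl[col]),
                    "case_mean": float(sub[col].mean()),
                    "control_mean": float(ctrl[col].mean()),
                    "n_case": len(sub),
                    "n_control": len(ctrl),
                }
            )
    return pd.DataFrame(rows)


def cohort_profiles(
    recons: list[Reconstruction],
    channel: str,
    bin_width: float = 20.0,
    statistic: str = "asi",
    length_weighted: bool = True,
) -> list[PathProfile]:
    """One path-distance profile per neuron."""
    out = []
    for r in recons:
        tree = build_tree(r)
        sigs = compartment_signals(r, tree, channel)
        out.append(
            path_profile(
                tree, sigs, channel, bin_width=bin_width, statistic=statistic,
                length_weighted=length_weighted,
            )
        )
    return out


def cohort_percent_change_profile(
    case: list[Reconstruction],
    control: list[Reconstruction],
    channel: str,
    bin_width: float = 20.0,
    statistic: str = "asi",
) -> pd.DataFrame:
    """Binned percent-change table of a case cohort against control."""
    return percent_change_profile(
        cohort_profiles(case, channel, bin_width, statistic),
        cohort_profiles(control, channel, bin_width, statistic),
    )
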