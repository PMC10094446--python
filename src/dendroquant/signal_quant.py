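"""Per-compartment signal quantification and path-distance profiling.

Multi-signal reconstructions attach, to every compartment, the fraction F of
the compartment volume occupied by a fluorescence signal and the average
signal intensity ASI over the compartment.  The local signal quantity is

    RQ = F x ASI x D

where D is the local dendrite thickness, approximated by the local diameter
(µm).  RQ is therefore zero whenever the signal is absent (F = 0 or
ASI = 0) and is linear in each factor separately.

Arbor-level summaries follow the per-micrometre convention: the total RQ of
a neuron divided by its total dendritic length, a branch-point-restricted
mean, and a fraction-of-max normalization across the neurons of an analysis
set.  Signal distributions along the arbor are profiled by binning
compartments by the path distance of their midpoint from the soma and
comparing case to control bin-by-bin as a percent-change table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphometry import NeuronTree, path_distance
from .swc_io import Reconstruction

__all__ = [
    "CompartmentSignal",
    "NeuronSignalSummary",
    "PathProfile",
    "local_quantity",
    "compartment_signals",
    "neuron_signal_summary",
    "normalize_across_neurons",
    "path_profile",
    "percent_change_profile",
]

#: default path-distance bin width, µm
DEFAULT_BIN_WIDTH = 20.0

#: default branch-point positivity threshold, as a fraction of the neuron's
#: maximum compartment RQ
DEFAULT_POSITIVITY_FRACTION = 0.10


@dataclass(frozen=True)
class CompartmentSignal:
    """Signal attributes of one compartment for one channel."""

    parent: int
    child: int
    length: float  # µm
    F: float  # occupied volume fraction, [0, 1]
    ASI: float  # average signal intensity, a.u.
    D: float  # local thickness (diameter), µm

    @property
    def RQ(self) -> float:
        return local_quantity(self.F, self.ASI, self.D)


@dataclass(frozen=True)
class NeuronSignalSummary:
    """Arbor-level signal summary for one neuron and one channel."""

    total_rq: float
    per_micrometer: float  # total_rq / tdl
    branchpoint_mean_rq: float
    positive_branchpoint_count: int
    n_branch_nodes: int


def local_quantity(F: float, ASI: float, D: float) -> float:
    """Local signal quantity RQ = F x ASI x D (intensity·µm).

    Raises on domain violations (F outside [0, 1], negative ASI,
    non-positive D).
    """
    if not 0.0 <= F <= 1.0:
        raise ValueError(f"F must be in [0, 1], got {F}")
    if ASI < 0:
        raise ValueError(f"ASI must be >= 0, got {ASI}")
    if D <= 0:
        raise ValueError(f"D must be > 0, got {D}")
    return F * ASI * D


def compartment_signals(
    recon: Reconstruction, tree: NeuronTree, channel: str | int
) -> list[CompartmentSignal]:
    """Attach one channel's (F, ASI) node values to the tree's dendritic
    compartments.

    Node signal values describe the compartment ending at that node, so the
    compartment takes F and ASI from its child node and D as the mean of the
    endpoint diameters.
    """
    ch = recon.channel_index(channel)
    by_id = {r.node_id: r for r in recon.records}
    out = []
    for c in tree.dendritic_compartments:
        rec = by_id[c.child]
        if len(rec.signal) <= ch:
            raise ValueError(f"node {c.child} carries no signal for channel {ch}")
        frac, asi = rec.signal[ch]
        out.append(
            CompartmentSignal(
                parent=c.parent,
                child=c.child,
                length=c.length,
                F=frac,
                ASI=asi,
                D=c.diameter,
            )
        )
    return out


def neuron_signal_summary(
    tree: NeuronTree,
    signals: list[CompartmentSignal],
    positivity_threshold: float | None = None,
) -> NeuronSignalSummary:
    """Summarize one channel over one arbor.

    ``total_rq`` is the unweighted sum of per-compartment RQ (RQ already
    carries the local geometry through D); ``per_micrometer`` divides by
    TDL.  Branch-point expression averages RQ over the compartments incident
    to each branch node (its parent edge and all child edges); a branch
    point counts as signal-positive when that local mean exceeds the
    threshold, which defaults to 10% of the neuron's maximum compartment RQ.
    """
    if not signals:
        raise ValueError("no compartment signals supplied")
    covered = {(s.parent, s.child) for s in signals}
    for c in tree.dendritic_compartments:
        if (c.parent, c.child) not in covered:
            raise ValueError(f"missing signal on compartment {c.parent}->{c.child}")
    rq = np.array([s.RQ for s in signals])
    lengths = np.array([s.length for s in signals])
    tdl = float(lengths.sum())
    if tdl <= 0:
        raise ValueError("total dendritic length must be positive")
    total = float(rq.sum())

    by_node: dict[int, list[float]] = {}
    for s, q in zip(signals, rq):
        by_node.setdefault(s.parent, []).append(q)
        by_node.setdefault(s.child, []).append(q)
    branch_nodes = [n for n in tree.nodes if tree.is_branch_node(n)]
    local_means = [float(np.mean(by_node.get(n, [0.0]))) for n in branch_nodes]

    if positivity_threshold is None:
        positivity_threshold = DEFAULT_POSITIVITY_FRACTION * float(rq.max())
    positive = sum(1 for m in local_means if m > positivity_threshold)
    return NeuronSignalSummary(
        total_rq=total,
        per_micrometer=total / tdl,
        branchpoint_mean_rq=float(np.mean(local_means)) if local_means else 0.0,
        positive_branchpoint_count=positive,
        n_branch_nodes=len(branch_nodes),
    )


def normalize_across_neurons(values) -> np.ndarray:
    """Express each neuron's value as a fraction of the maximum over the
    analysis set; the maximum maps to exactly 1."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    vmax = v.max()
    if vmax <= 0:
        raise ValueError("all values are zero; fraction-of-max undefined")
    return v / vmax


@dataclass
class PathProfile:
    """Binned signal along path distance from the soma for one neuron.

    Bins are contiguous, left-closed intervals ``[k*w, (k+1)*w)`` labeled by
    their distal edge.  Empty bins are absent from the table (missing, not
    zero).  ``table`` columns: bin_end, mean_signal, n_compartments,
    total_length.
    """

    channel: str
    bin_width: float
    statistic: str  # "asi" or "rq"
    table: pd.DataFrame

    @property
    def bin_ends(self) -> np.ndarray:
        return self.table["bin_end"].to_numpy()


def path_profile(
    tree: NeuronTree,
    signals: list[CompartmentSignal],
    channel: str,
    bin_width: float = DEFAULT_BIN_WIDTH,
    statistic: str = "asi",
    length_weighted: bool = True,
) -> PathProfile:
    """Profile one channel against path distance from the soma.

    Each compartment is assigned to the bin containing the path distance of
    its midpoint; the per-bin statistic is the (length-weighted, by default)
    mean of ASI or RQ over the bin's compartments.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if statistic not in ("asi", "rq"):
        raise ValueError(f"statistic must be 'asi' or 'rq', got {statistic!r}")
    rows = []
    for s in signals:
        mid = path_distance(tree, s.parent) + 0.5 * s.length
        k = int(math.floor(mid / bin_width))
        val = s.ASI if statistic == "asi" else s.RQ
        rows.append((k, val, s.length))
    df = pd.DataFrame(rows, columns=["bin", "value", "length"])
    if length_weighted:
        agg = df.groupby("bin").apply(
            lambda g: pd.Series(
                {
                    "mean_signal": np.average(g["value"], weights=g["length"]),
                    "n_compartments": len(g),
                    "total_length": g["length"].sum(),
                }
            ),
            include_groups=False,
        )
    else:
        agg = df.groupby("bin").agg(
            mean_signal=("value", "mean"),
            n_compartments=("value", "size"),
            total_length=("length", "sum"),
        )
    agg = agg.reset_index()
    agg["bin_end"] = (agg["bin"] + 1) * bin_width
    agg["n_compartments"] = agg["n_compartments"].astype(int)
    table = agg[["bin_end", "mean_signal", "n_compartments", "total_length"]]
    return PathProfile(
        channel=channel, bin_width=bin_width, statistic=statistic, table=table
    )


def percent_change_profile(
    case_profiles: list[PathProfile], control_profiles: list[PathProfile]
) -> pd.DataFrame:
    """Bin-by-bin percent change of a case cohort from a control cohort.

    For each bin, the cohort value is the mean over neurons of that neuron's
    bin mean; the cell is ``100 * (case - control) / control``.  Bins with
    no control coverage are reported with a NaN cell and flagged, never as a
    division by zero.

    Returns a tidy frame: bin_end, case_mean, control_mean, percent_change,
    n_case, n_control, control_empty.
    """
    if not case_profiles or not control_profiles:
        raise ValueError("both cohorts must be non-empty")
    ref = control_profiles[0]
    for p in case_profiles + control_profiles:
        if p.bin_width != ref.bin_width or p.statistic != ref.statistic:
            raise ValueError("profiles binned on different edges or statistics")

    def cohort(profiles: list[PathProfile]) -> pd.DataFrame:
        frames = [
            p.table[["bin_end", "mean_signal"]].assign(neuron=i)
            for i, p in enumerate(profiles)
        ]
        long = pd.concat(frames, ignore_index=True)
        return long.groupby("bin_end")["mean_signal"].agg(["mean", "size"])

    case = cohort(case_profiles)
    ctrl = cohort(control_profiles)
    merged = case.join(ctrl, how="outer", lsuffix="_case", rsuffix="_ctrl")
    out = pd.DataFrame(
        {
            "bin_end": merged.index,
            "case_mean": merged["mean_case"].to_numpy(),
            "control_mean": merged["mean_ctrl"].to_numpy(),
            "n_case": merged["size_case"].fillna(0).astype(int).to_numpy(),
            "n_control": merged["size_ctrl"].fillna(0).astype(int).to_numpy(),
        }
    ).reset_index(drop=True)
    empty = out["control_mean"].isna() | (out["control_mean"] == 0)
    pct = np.full(len(out), np.nan)
    ok = ~empty & out["case_mean"].notna()
    pct[ok] = (
        100.0
        * (out.loc[ok, "case_mean"] - out.loc[ok, "control_mean"])
        / out.loc[ok, "control_mean"]
    )
    out["percent_change"] = pct
    out["control_empty"] = empty.to_numpy()
    return out
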