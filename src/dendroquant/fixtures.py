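"""Packaged effect-size fixtures and their translation into condition effects.

The YAML files under ``dendroquant/data/`` transcribe published cohort-level
effect sizes (morphometric percent changes, branch-density changes,
overexpression fold changes, qPCR folds, and distance-dependent
microtubule-signal suppression curves).  The loaders here turn fixture
entries into :class:`~dendroquant.synthetic.ConditionEffect` objects with
the scale semantics of the generator:

* ``length_scale = 1 + tdl_pct/100`` (multiplies expected TDL),
* ``branch_scale = 1 + tdb_pct/100`` (multiplies expected TDB),
* a branch-density change combines with the size change as
  ``branch_scale = (1 + dbd_pct/100) * length_scale``.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .synthetic import CONTROL, ConditionEffect

__all__ = [
    "FIXTURE_NAMES",
    "load_fixture",
    "control_effect",
    "effect_from_fig1q",
    "effect_from_fig2g",
    "effect_from_fig5",
    "effect_from_fig7h",
    "qpcr_folds",
]

FIXTURE_NAMES = (
    "fig1q_effects",
    "fig2g_effects",
    "fig5_cutOE",
    "fig7h_mt_suppression",
    "fig4a_folds",
)


def load_fixture(name: str) -> dict:
    """Load a packaged fixture by name (without the .yaml suffix)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; have {FIXTURE_NAMES}")
    text = resources.files("dendroquant.data").joinpath(f"{name}.yaml").read_text()
    return yaml.safe_load(text)


def control_effect() -> ConditionEffect:
    return CONTROL


def effect_from_fig1q(neuron_class: str, condition: str) -> ConditionEffect:
    """Length/branch effect for a class x condition cell of the fig1q fixture."""
    fx = load_fixture("fig1q_effects")
    try:
        entry = fx[neuron_class][condition]
    except KeyError:
        raise KeyError(
            f"no fig1q entry for class {neuron_class!r}, condition {condition!r}"
        ) from None
    return ConditionEffect(
        label=condition,
        length_scale=1.0 + entry["tdl_pct"] / 100.0,
        branch_scale=1.0 + entry["tdb_pct"] / 100.0,
        provenance=f"fig1q_effects[{neuron_class}][{condition}]",
    )


def effect_from_fig2g(condition: str, subtype_or_class: str) -> ConditionEffect:
    """Branch-density effect for a condition x subtype (or class) entry."""
    fx = load_fixture("fig2g_effects")
    try:
        entry = fx[condition][subtype_or_class]
    except KeyError:
        raise KeyError(
            f"no fig2g entry for condition {condition!r}, group {subtype_or_class!r}"
        ) from None
    ls = 1.0 + entry["tdl_pct"] / 100.0
    bs = (1.0 + entry["dbd_pct"] / 100.0) * ls
    return ConditionEffect(
        label=condition,
        length_scale=ls,
        branch_scale=bs,
        provenance=f"fig2g_effects[{condition}][{subtype_or_class}]",
    )


def effect_from_fig5(condition: str = "ct-OE") -> ConditionEffect:
    """Overexpression hypertrophy effect (fold changes of TDL and TDB)."""
    fx = load_fixture("fig5_cutOE")
    entry = fx[condition]
    return ConditionEffect(
        label=condition,
        length_scale=float(entry["tdl_fold"]),
        branch_scale=float(entry["tdb_fold"]),
        provenance=f"fig5_cutOE[{condition}]",
    )


def effect_from_fig7h(condition: str) -> ConditionEffect:
    """Distance-dependent microtubule-signal suppression (morphology intact)."""
    fx = load_fixture("fig7h_mt_suppression")
    try:
        entry = fx[condition]
    except KeyError:
        raise KeyError(f"no fig7h entry for condition {condition!r}") from None
    anchors = [(float(d), float(loss)) for d, loss in entry["anchors"]]
    return ConditionEffect(
        label=condition,
        suppression={"mt": anchors},
        provenance=f"fig7h_mt_suppression[{condition}]",
    )


def qpcr_folds() -> dict:
    """The qPCR fold-change fixture (folds, reference gene, condition names)."""
    return load_fixture("fig4a_folds")
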