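"""Seeded synthetic cohorts of da-neuron arbors with attached signal channels.

Confocal-derived reconstructions of larval *Drosophila* multidendritic
neurons are archive-bound and not redistributable with this package, so
every pipeline stage is exercised against a generator that emulates the
relevant statistical structure of such data: class-specific arbor size and
branching regimes (Class I simplest, Class III dominated by short terminal
filopodia, Class IV largest and space-filling), genotype effects that scale
growth and branching independently, and per-compartment fluorescence
channels (a microtubule signal with optional distance-dependent
suppression, a distally weighted F-actin signal, a punctate ribosome signal
enriched at branch points, and a flat translation-reporter signal).

Growth model
------------
Each arbor is a trunk-and-side-branch construction: ``n_primary`` trunks
radiate from the soma out to the class's radial extent; branch points are
spread along each trunk and each sprouts a short side subtree (a terminal,
or a stem that bifurcates into two terminals).  Per-neuron total length and
branch count are drawn around their class targets with small, controlled
dispersion and then realized *exactly* by the construction, which makes the
first moments closed-form:

    E[TDL] = total_length_um x length_scale
    E[TDB] = branch_rate_per_um x total_length_um x branch_scale
    E[DBD] = branch_rate_per_um x branch_scale / length_scale

A condition therefore multiplies expected TDL by ``length_scale`` and
expected TDB by ``branch_scale``; a proportional effect
(``length_scale == branch_scale``) leaves branch density unchanged.  This
construction trades biophysical realism of the growth *process* for exact
moment control; see the methods note for what that does and does not buy.

Every operation is a pure function of its arguments and the integer seed:
identical inputs give bit-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .swc_io import DENDRITE, SOMA, Reconstruction, SwcRecord

__all__ = [
    "ArborArchetype",
    "ConditionEffect",
    "SignalModel",
    "CONTROL",
    "ARCHETYPES",
    "SUBTYPES",
    "CHANNELS",
    "generate_arbor",
    "generate_cohort",
    "generate_qpcr",
    "generate_roi_table",
    "closed_form_moments",
]

#: channel order of generated multi-signal reconstructions
CHANNELS = ("mt", "factin", "ribosome", "translation")


@dataclass(frozen=True)
class ArborArchetype:
    """Class-level growth parameters of a da-neuron archetype.

    Absolute sizes are package defaults calibrated only ordinally to the
    class descriptions (CI simplest, CIII filopodia-rich, CIV most complex
    and most extended); they are not measured values.
    """

    label: str  # "CI" | "CIII" | "CIV"
    n_primary: int  # primary dendrites leaving the soma
    total_length_um: float  # expected TDL, µm
    branch_rate_per_um: float  # expected branches per µm of dendrite (= DBD)
    extent_cap_um: float  # radial extent of the primary trunks, µm
    side_bifurcation_fraction: float  # fraction of side subtrees that bifurcate
    size_cv: float = 0.04  # per-neuron CV of total length
    dbd_cv: float = 0.008  # per-neuron CV of branch density
    extent_jitter_cv: float = 0.01  # per-trunk extent jitter
    side_length_shape: float = 3.0  # gamma shape of side segment lengths
    step_um: float = 4.0  # compartment subdivision step
    soma_radius_um: float = 3.0
    base_radius_um: float = 1.0  # dendrite radius at the soma
    tip_radius_um: float = 0.25  # radius floor at the distal extent


@dataclass(frozen=True)
class ConditionEffect:
    """A genotype/condition modifier, purely configurational.

    ``length_scale`` multiplies expected total dendritic length and
    ``branch_scale`` multiplies expected total branch count; equality of the
    two is a proportional (density-preserving) effect.  ``signal_scale``
    multiplies a channel's baseline intensity, and ``suppression`` maps a
    channel to ``[(path_distance_um, fraction_lost), ...]`` anchors of a
    distance-dependent suppression curve s(d) = 1 - loss(d), interpolated
    linearly and flat beyond the anchors.
    """

    label: str = "control"
    length_scale: float = 1.0
    branch_scale: float = 1.0
    signal_scale: dict = field(default_factory=dict)
    suppression: dict = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self):
        if self.length_scale <= 0 or self.branch_scale <= 0:
            raise ValueError("condition scales must be positive")

    def survival(self, channel: str, d: float) -> float:
        """s(d) in [0, 1]: the fraction of the channel signal surviving at
        path distance ``d``."""
        anchors = self.suppression.get(channel)
        if not anchors:
            return 1.0
        ds = [a[0] for a in anchors]
        losses = [a[1] for a in anchors]
        loss = float(np.interp(d, ds, losses))
        return float(min(1.0, max(0.0, 1.0 - loss)))


CONTROL = ConditionEffect()


@dataclass(frozen=True)
class SignalModel:
    """Per-channel generative parameters for compartment signals."""

    mt_intensity: float = 200.0  # a.u. at the soma
    mt_decay_um: float = 2000.0  # gentle baseline decline with distance
    mt_fraction: float = 0.6
    factin_intensity: float = 150.0
    factin_distal_weight: float = 0.5  # 0 flat .. 1 fully distal-weighted
    factin_fraction: float = 0.5
    ribosome_rate_per_um: float = 0.8  # puncta per µm of dendrite
    ribosome_branch_enrichment: float = 3.0  # puncta rate multiplier at branch points
    ribosome_intensity: float = 120.0  # a.u. per punctum per µm
    ribosome_fraction_per_punctum: float = 0.15
    translation_intensity: float = 100.0
    translation_fraction: float = 0.4
    intensity_noise_cv: float = 0.05  # per-compartment multiplicative noise
    neuron_gain_cv: float = 0.03  # per-neuron multiplicative gain
    fraction_noise_sd: float = 0.02


DEFAULT_SIGNAL_MODEL = SignalModel()

#: package archetypes; ordinal calibration only (see module docstring)
ARCHETYPES: dict[str, ArborArchetype] = {
    "CI": ArborArchetype(
        label="CI",
        n_primary=2,
        total_length_um=600.0,
        branch_rate_per_um=40.0 / 600.0,
        extent_cap_um=200.0,
        side_bifurcation_fraction=0.20,
    ),
    "CIII": ArborArchetype(
        label="CIII",
        n_primary=3,
        total_length_um=2200.0,
        branch_rate_per_um=800.0 / 2200.0,
        extent_cap_um=300.0,
        side_bifurcation_fraction=0.15,
    ),
    "CIV": ArborArchetype(
        label="CIV",
        n_primary=4,
        total_length_um=3200.0,
        branch_rate_per_um=560.0 / 3200.0,
        extent_cap_um=560.0,
        side_bifurcation_fraction=0.25,
    ),
}

#: subtype labels are manifest metadata only; geometry follows the class
SUBTYPES: dict[str, list[str]] = {
    "CI": ["ddaE", "vpda"],
    "CIII": ["ddaF"],
    "CIV": ["ddaC", "v'ada", "vdaB"],
}


def closed_form_moments(
    archetype: ArborArchetype, effect: ConditionEffect = CONTROL
) -> dict[str, float]:
    """First moments of the generated cohort metrics, exact by construction."""
    tdl = archetype.total_length_um * effect.length_scale
    tdb = archetype.branch_rate_per_um * archetype.total_length_um * effect.branch_scale
    return {
        "tdl_mean": tdl,
        "tdl_sd": tdl * archetype.size_cv,
        "tdb_mean": tdb,
        "dbd_mean": archetype.branch_rate_per_um
        * effect.branch_scale
        / effect.length_scale,
    }


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


class _Builder:
    """Accumulates SWC records while tracking path distance per node."""

    def __init__(self, soma_radius: float):
        self.records: list[SwcRecord] = [
            SwcRecord(1, SOMA, 0.0, 0.0, 0.0, soma_radius, -1)
        ]
        self.pos: dict[int, np.ndarray] = {1: np.zeros(3)}
        self.pathd: dict[int, float] = {1: 0.0}
        self.next_id = 2

    def add(self, parent: int, pos: np.ndarray, radius: float, length: float) -> int:
        nid = self.next_id
        self.next_id += 1
        self.records.append(
            SwcRecord(
                nid, DENDRITE, float(pos[0]), float(pos[1]), float(pos[2]),
                radius, parent,
            )
        )
        self.pos[nid] = pos
        self.pathd[nid] = self.pathd[parent] + length
        return nid


def _radius_at(archetype: ArborArchetype, d: float, extent: float, side: bool) -> float:
    frac = min(1.0, d / max(extent, 1e-9))
    r = archetype.tip_radius_um + (archetype.base_radius_um - archetype.tip_radius_um) * (
        1.0 - frac
    )
    if side:
        r *= 0.7
    return max(archetype.tip_radius_um * 0.5, r)


def _grow_polyline(
    b: _Builder,
    rng: np.random.Generator,
    archetype: ArborArchetype,
    parent: int,
    direction: np.ndarray,
    length: float,
    extent: float,
    side: bool,
    wobble: float = 0.15,
) -> int:
    """Extend a straight-ish polyline of exactly ``length`` µm from
    ``parent``; returns the distal node id.  Each sub-compartment is a
    straight step, so the Euclidean compartment lengths sum to ``length``."""
    n_steps = max(1, int(math.ceil(length / archetype.step_um)))
    step = length / n_steps
    cur = parent
    d = direction
    for _ in range(n_steps):
        d = _unit(d + wobble * rng.normal(size=3) * np.array([1.0, 1.0, 0.25]))
        pos = b.pos[cur] + d * step
        pd = b.pathd[cur] + step
        cur = b.add(cur, pos, _radius_at(archetype, pd, extent, side), step)
    return cur


def generate_arbor(
    archetype: ArborArchetype,
    effect: ConditionEffect = CONTROL,
    seed: int = 0,
    signal_model: SignalModel = DEFAULT_SIGNAL_MODEL,
    channels: tuple[str, ...] = CHANNELS,
    neuron_id: str = "",
    subtype: str = "",
) -> Reconstruction:
    """Generate one multi-signal reconstruction.

    The output passes ``swc_io.validate`` and has, in expectation, the
    morphometric moments of :func:`closed_form_moments`; identical
    arguments and seed give identical output.
    """
    for ch in channels:
        if ch not in CHANNELS:
            raise ValueError(f"unknown channel {ch!r}; choose from {CHANNELS}")
    rng = np.random.default_rng(seed)
    ls, bs = effect.length_scale, effect.branch_scale
    P = archetype.n_primary

    # per-neuron size and density draws; the construction realizes them exactly
    shape = 1.0 / archetype.size_cv**2
    L = float(rng.gamma(shape, archetype.total_length_um * ls / shape))
    dbd_target = (
        archetype.branch_rate_per_um
        * (bs / ls)
        * (1.0 + rng.normal(0.0, archetype.dbd_cv))
    )
    K = max(0, round((dbd_target * L - P) / 2.0))
    B = P + 2 * K  # realized TDB
    q = archetype.side_bifurcation_fraction
    m = min(K, max(math.ceil(K / 2), round(K / (1.0 + q)))) if K else 0
    s = K - m  # side subtrees that bifurcate

    extent = min(archetype.extent_cap_um * ls, 0.75 * L / P)
    trunk_lengths = extent * (
        1.0 + rng.normal(0.0, archetype.extent_jitter_cv, size=P)
    )
    if trunk_lengths.sum() > 0.9 * L:
        trunk_lengths *= 0.9 * L / trunk_lengths.sum()
    side_budget = L - float(trunk_lengths.sum())
    n_side_segments = m + 2 * s
    if n_side_segments == 0:
        # degenerate (branch rate 0): bare trunks carry the whole length
        trunk_lengths *= L / trunk_lengths.sum()
        side_budget = 0.0
        side_lengths = np.empty(0)
    else:
        w = rng.gamma(archetype.side_length_shape, 1.0, size=n_side_segments)
        side_lengths = w / w.sum() * side_budget

    m_per_trunk = rng.multinomial(m, np.full(P, 1.0 / P)) if m else np.zeros(P, int)
    bifurcating = np.zeros(m, dtype=bool)
    if s:
        bifurcating[rng.choice(m, size=s, replace=False)] = True

    b = _Builder(archetype.soma_radius_um)
    # primary directions: quasi-planar, evenly spread with angular jitter
    base_angles = 2.0 * np.pi * (np.arange(P) + rng.uniform(0.0, 1.0)) / P
    side_iter = iter(side_lengths)
    side_idx = 0
    for p in range(P):
        ang = base_angles[p] + rng.normal(0.0, 0.2)
        direction = np.array([np.cos(ang), np.sin(ang), rng.normal(0.0, 0.05)])
        direction = _unit(direction)
        n_bp = int(m_per_trunk[p])
        tl = float(trunk_lengths[p])
        # jittered-regular branch point positions along the trunk
        u = rng.uniform(0.3, 0.7, size=n_bp)
        positions = (np.arange(n_bp) + u) / (n_bp + 1) * tl
        cur = 1
        prev = 0.0
        for pos_d in positions:
            cur = _grow_polyline(
                b, rng, archetype, cur, direction, float(pos_d - prev), extent, False
            )
            prev = float(pos_d)
            # sprout a side subtree at this branch point
            normal = _unit(np.cross(direction, np.array([0.0, 0.0, 1.0])))
            sgn = 1.0 if rng.random() < 0.5 else -1.0
            side_dir = _unit(
                sgn * normal + 0.3 * rng.normal(size=3) * np.array([1, 1, 0.3])
            )
            stem_len = float(next(side_iter))
            stem_end = _grow_polyline(
                b, rng, archetype, cur, side_dir, stem_len, extent, True, wobble=0.3
            )
            if bifurcating[side_idx]:
                for _ in range(2):
                    term_dir = _unit(side_dir + 0.6 * rng.normal(size=3))
                    _grow_polyline(
                        b, rng, archetype, stem_end, term_dir,
                        float(next(side_iter)), extent, True, wobble=0.3,
                    )
            side_idx += 1
        _grow_polyline(
            b, rng, archetype, cur, direction, tl - prev, extent, False
        )

    records = _attach_signals(
        b, rng, archetype, effect, signal_model, channels, extent
    )
    return Reconstruction(
        records=records,
        channel_names=list(channels),
        neuron_id=neuron_id,
        condition=effect.label,
        neuron_class=archetype.label,
        subtype=subtype,
    )


def _attach_signals(
    b: _Builder,
    rng: np.random.Generator,
    archetype: ArborArchetype,
    effect: ConditionEffect,
    sm: SignalModel,
    channels: tuple[str, ...],
    extent: float,
) -> list[SwcRecord]:
    """Sample (F, ASI) per channel for every node's parent compartment."""
    children: dict[int, int] = {}
    for r in b.records:
        if r.parent_id != -1:
            children[r.parent_id] = children.get(r.parent_id, 0) + 1
    branchy = {nid for nid, c in children.items() if c >= 2 and nid != 1}
    gain = float(np.exp(rng.normal(0.0, sm.neuron_gain_cv)))

    def noisy(base: float) -> float:
        return max(0.0, base * (1.0 + rng.normal(0.0, sm.intensity_noise_cv)))

    def frac(base: float) -> float:
        return float(np.clip(base + rng.normal(0.0, sm.fraction_noise_sd), 0.0, 1.0))

    out: list[SwcRecord] = []
    for r in b.records:
        if r.parent_id == -1:
            out.append(replace(r, signal=tuple((0.0, 0.0) for _ in channels)))
            continue
        length = b.pathd[r.node_id] - b.pathd[r.parent_id]
        d = 0.5 * (b.pathd[r.node_id] + b.pathd[r.parent_id])  # midpoint distance
        incident = r.node_id in branchy or r.parent_id in branchy
        sig: list[tuple[float, float]] = []
        for ch in channels:
            scale = effect.signal_scale.get(ch, 1.0) * effect.survival(ch, d) * gain
            if ch == "mt":
                asi = noisy(sm.mt_intensity * math.exp(-d / sm.mt_decay_um) * scale)
                f = frac(sm.mt_fraction)
            elif ch == "factin":
                w = sm.factin_distal_weight
                profile = (1.0 - w) + w * min(1.0, d / max(extent, 1e-9))
                asi = noisy(sm.factin_intensity * profile * scale)
                f = frac(sm.factin_fraction)
            elif ch == "ribosome":
                rate = sm.ribosome_rate_per_um * (
                    sm.ribosome_branch_enrichment if incident else 1.0
                )
                count = rng.poisson(rate * length * scale / gain)
                if count == 0:
                    f, asi = 0.0, 0.0
                else:
                    f = float(
                        np.clip(
                            1.0 - math.exp(-sm.ribosome_fraction_per_punctum * count),
                            0.0,
                            1.0,
                        )
                    )
                    asi = noisy(
                        sm.ribosome_intensity * count / max(length, 1e-9) * gain
                    )
            else:  # translation
                asi = noisy(sm.translation_intensity * scale)
                f = frac(sm.translation_fraction)
            sig.append((f, asi))
        out.append(replace(r, signal=tuple(sig)))
    return out


def generate_cohort(
    archetype: ArborArchetype,
    effects: dict[str, ConditionEffect],
    n_per_group: int | dict[str, int],
    seed: int = 0,
    outdir=None,
    subtype: str = "",
    signal_model: SignalModel = DEFAULT_SIGNAL_MODEL,
    channels: tuple[str, ...] = CHANNELS,
) -> tuple[dict[str, list[Reconstruction]], pd.DataFrame]:
    """Generate one cohort per condition plus a manifest.

    ``n_per_group`` is a single count or a per-condition mapping.  When
    ``outdir`` is given, each neuron is written as ``<neuron_id>.swc`` and
    the manifest records the file names.  Per-neuron seeds are derived
    deterministically from ``seed`` and shared across conditions (common
    random numbers): the i-th neuron of every group is generated from the
    same seed, so condition effects are applied to matched draws and
    between-group comparisons are paired rather than fully independent.
    Marginal cohort distributions are unaffected.
    """
    if isinstance(n_per_group, int):
        if n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        n_map = {label: n_per_group for label in effects}
    else:
        n_map = dict(n_per_group)
    master = np.random.default_rng(seed)
    shared_seeds = master.integers(0, 2**31 - 1, size=max(n_map.values()))
    rows = []
    cohorts: dict[str, list[Reconstruction]] = {}
    sub = subtype or SUBTYPES.get(archetype.label, [""])[0]
    for label, effect in effects.items():
        neuron_seeds = shared_seeds[: n_map[label]]
        group = []
        for i, s in enumerate(neuron_seeds):
            nid = f"{archetype.label}_{sub}_{label}_{i:03d}".replace("'", "p")
            recon = generate_arbor(
                archetype,
                effect,
                seed=int(s),
                signal_model=signal_model,
                channels=channels,
                neuron_id=nid,
                subtype=sub,
            )
            group.append(recon)
            fname = ""
            if outdir is not None:
                from pathlib import Path

                from .swc_io import write_swc

                path = Path(outdir) / f"{nid}.swc"
                path.parent.mkdir(parents=True, exist_ok=True)
                with open(path, "w") as fh:
                    write_swc(recon, fh)
                fname = path.name
            rows.append(
                {
                    "neuron_id": nid,
                    "genotype": label,
                    "class": archetype.label,
                    "subtype": sub,
                    "seed": int(s),
                    "file": fname,
                }
            )
        cohorts[label] = group
    return cohorts, pd.DataFrame(rows)


def generate_qpcr(
    fold_map: dict[str, float],
    reference_gene: str = "RpL32",
    noise_sd: float = 0.0,
    seed: int = 0,
    replicates: int = 3,
    case_condition: str = "case",
    control_condition: str = "control",
    base_ct: float = 22.0,
    reference_ct: float = 16.0,
) -> pd.DataFrame:
    """Construct a long-format Ct table whose noiseless ddCt fold change
    equals ``fold_map`` per gene.

    A fold f is encoded as a case Ct shift of -log2(f) cycles on the target
    gene with the reference gene held constant across conditions, so the
    ddCt estimator inverts the construction exactly when ``noise_sd`` is 0.
    """
    for g, f in fold_map.items():
        if f <= 0:
            raise ValueError(f"fold for {g!r} must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for cond in (control_condition, case_condition):
        for gene in list(fold_map) + [reference_gene]:
            if gene == reference_gene:
                ct = reference_ct
            elif cond == control_condition:
                ct = base_ct
            else:
                ct = base_ct - math.log2(fold_map[gene])
            for rep in range(replicates):
                rows.append(
                    {
                        "gene": gene,
                        "condition": cond,
                        "replicate": rep + 1,
                        "ct": ct + rng.normal(0.0, noise_sd) if noise_sd else ct,
                    }
                )
    return pd.DataFrame(rows)


def generate_roi_table(
    enrichment_factors: dict[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    n_animals: int = 10,
    base_intensity: float = 100.0,
) -> pd.DataFrame:
    """Construct a per-animal two-region intensity table.

    For each condition with enrichment factor e, region_a = e x region_b up
    to multiplicative log-normal noise, so the mean per-animal a/b ratio
    recovers e (exactly at ``noise_sd`` 0).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cond, e in enrichment_factors.items():
        if e <= 0:
            raise ValueError(f"enrichment factor for {cond!r} must be positive")
        for i in range(n_animals):
            rb = base_intensity * float(np.exp(rng.normal(0.0, 0.1)))
            # noise has mean exactly 1 so the mean per-animal ratio is unbiased
            noise = (
                float(np.exp(rng.normal(-0.5 * noise_sd**2, noise_sd)))
                if noise_sd
                else 1.0
            )
            ra = e * rb * noise
            rows.append(
                {
                    "condition": cond,
                    "animal": i + 1,
                    "region_a_mean": ra,
                    "region_b_mean": rb,
                }
            )
    return pd.DataFrame(rows)
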