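"""Cohort-level derived statistics.

Three families of quantities:

* relative qPCR expression by the ddCt method — fold change
  ``2**(-ddCt)`` after normalizing the target gene's Ct to a reference gene
  (e.g. RpL32) and a control condition;
* region-intensity ratios (nuclear/soma, target-neuron/reference-neuron)
  used for protein-level quantification from immunostaining;
* annotation-category enrichment with the conservative EASE variant of
  Fisher's exact statistic, in which one member is removed from the observed
  category overlap before computing the right tail.

Hypothesis testing (ANOVA with Dunnett's post hoc, t-test, Mann-Whitney,
Kruskal-Wallis with Dunn's post hoc) is delegated to scipy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FoldChange",
    "EnrichmentResult",
    "ddct_fold_change",
    "intensity_ratio",
    "normalized_intensity",
    "fisher_right_tail_p",
    "ease_p",
    "ease_enrichment",
    "group_tests",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class FoldChange:
    """Relative expression of one gene in a case condition vs control."""

    gene: str
    delta_delta_ct: float  # cycles
    fold: float  # 2**(-ddCt)


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment of a hit list in one annotation category."""

    category: str
    hits_in_category: int  # k
    hit_list_size: int  # n
    category_size: int  # K
    background_size: int  # N
    fold_enrichment: float  # (k/n) / (K/N)
    fisher_p: float  # classical right-tail Fisher p
    ease_p: float  # one-removed right-tail p (>= fisher_p)


def ddct_fold_change(
    table: pd.DataFrame,
    gene: str,
    case_condition: str,
    control_condition: str,
    reference_gene: str,
) -> FoldChange:
    """ddCt relative quantification.

    ``table`` is long-format with columns gene, condition, ct (one row per
    replicate).  Per condition, dCt = mean Ct(gene) - mean Ct(reference);
    ddCt = dCt(case) - dCt(control); fold = 2**(-ddCt).  The point estimate
    averages replicate Ct values before differencing, so it is invariant to
    any constant added to every Ct on a plate.
    """
    if gene == reference_gene:
        raise ValueError("reference gene must differ from the target gene")
    need = {"gene", "condition", "ct"}
    if not need.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(need)}")

    def mean_ct(g: str, cond: str) -> float:
        sel = table[(table["gene"] == g) & (table["condition"] == cond)]["ct"]
        if sel.empty:
            raise ValueError(f"no Ct rows for gene {g!r} in condition {cond!r}")
        if not np.isfinite(sel).all():
            raise ValueError(f"non-finite Ct for gene {g!r} in condition {cond!r}")
        return float(sel.mean())

    dct_case = mean_ct(gene, case_condition) - mean_ct(reference_gene, case_condition)
    dct_ctrl = mean_ct(gene, control_condition) - mean_ct(
        reference_gene, control_condition
    )
    ddct = dct_case - dct_ctrl
    return FoldChange(gene=gene, delta_delta_ct=ddct, fold=float(2.0 ** (-ddct)))


def intensity_ratio(region_mean_a: float, region_mean_b: float) -> float:
    """Ratio of two region mean intensities (e.g. nuclear / whole-soma)."""
    if region_mean_b <= 0:
        raise ValueError("denominator region mean must be positive")
    return region_mean_a / region_mean_b


def normalized_intensity(
    target_neuron_mean: float, reference_neuron_mean: float
) -> float:
    """Target-neuron mean intensity normalized to a reference neuron imaged
    in the same animal (cohort summaries are then taken over per-animal
    ratios)."""
    return intensity_ratio(target_neuron_mean, reference_neuron_mean)


def fisher_right_tail_p(k: int, N: int, K: int, n: int) -> float:
    """Right-tail Fisher p of a 2x2 overlap table: P(X >= k) for
    X ~ Hypergeom(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def ease_p(k: int, N: int, K: int, n: int) -> float:
    """EASE score: the right-tail p recomputed with the observed overlap
    reduced by one, floored at zero (so k <= 1 gives p = 1)."""
    return fisher_right_tail_p(k - 1, N, K, n)


def ease_enrichment(
    hit_set,
    category_map: dict[str, set],
    background,
) -> list[EnrichmentResult]:
    """Per-category fold enrichment with classical Fisher and EASE p-values.

    The right-tail Fisher p of a 2x2 overlap table is the hypergeometric
    survival ``P(X >= k)``; the EASE score recomputes it with the observed
    overlap reduced by one (floored at zero), which penalizes categories
    supported by a single hit (k = 1 gives p = 1).
    """
    hits = set(hit_set)
    bg = set(background)
    if not hits:
        raise ValueError("empty hit set")
    if not bg:
        raise ValueError("empty background")
    if not hits <= bg:
        raise ValueError("hit set must be a subset of the background")
    n = len(hits)
    N = len(bg)
    results = []
    for name, members in category_map.items():
        cat = set(members) & bg
        K = len(cat)
        if K == 0:
            continue
        k = len(hits & cat)
        fold = (k / n) / (K / N)
        results.append(
            EnrichmentResult(
                category=name,
                hits_in_category=k,
                hit_list_size=n,
                category_size=K,
                background_size=N,
                fold_enrichment=fold,
                fisher_p=fisher_right_tail_p(k, N, K, n),
                ease_p=ease_p(k, N, K, n),
            )
        )
    return results


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _dunn_posthoc(groups: dict[str, np.ndarray], control: str) -> list[dict]:
    """Dunn's rank-based z comparisons of each group against the control,
    with tie correction, on the pooled ranks of a Kruskal-Wallis layout."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n_total**3 - n_total)
    mean_ranks = {}
    i = 0
    for g in labels:
        n_g = groups[g].size
        mean_ranks[g] = ranks[i : i + n_g].mean()
        i += n_g
    rows = []
    for g in labels:
        if g == control:
            continue
        se = np.sqrt(
            (n_total * (n_total + 1) / 12.0)
            * tie
            * (1.0 / groups[g].size + 1.0 / groups[control].size)
        )
        z = (mean_ranks[g] - mean_ranks[control]) / se
        rows.append(
            {
                "test": "dunn",
                "comparison": f"{g} vs {control}",
                "statistic": float(z),
                "p": float(2.0 * stats.norm.sf(abs(z))),
            }
        )
    return rows


def group_tests(
    table: pd.DataFrame,
    value: str,
    group: str,
    control: str,
    method: str = "anova_dunnett",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare each case group to the control on one metric.

    ``method`` is one of ``anova_dunnett``, ``ttest``, ``mannwhitney``,
    ``kruskal_dunn``.  Returns a tidy frame (test, comparison, statistic, p,
    significant, note); constant-variance degenerate inputs are flagged in
    ``note`` rather than raising.
    """
    groups = {
        str(g): np.asarray(sub[value], dtype=float)
        for g, sub in table.groupby(group, sort=False)
    }
    if control not in groups:
        raise ValueError(f"control group {control!r} not present")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    cases = [g for g in groups if g != control]
    rows: list[dict] = []

    pooled = np.concatenate(list(groups.values()))
    degenerate = np.ptp(pooled) == 0

    if method == "anova_dunnett":
        for g, v in groups.items():
            if v.size < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")
        if degenerate:
            rows = [
                {
                    "test": "dunnett",
                    "comparison": f"{g} vs {control}",
                    "statistic": np.nan,
                    "p": np.nan,
                    "note": "degenerate: zero variance in all groups",
                }
                for g in cases
            ]
        else:
            f_stat, f_p = stats.f_oneway(*groups.values())
            res = stats.dunnett(
                *[groups[g] for g in cases], control=groups[control]
            )
            rows.append(
                {
                    "test": "anova",
                    "comparison": "omnibus",
                    "statistic": float(f_stat),
                    "p": float(f_p),
                    "note": "",
                }
            )
            for g, t, p in zip(cases, res.statistic, res.pvalue):
                rows.append(
                    {
                        "test": "dunnett",
                        "comparison": f"{g} vs {control}",
                        "statistic": float(t),
                        "p": float(p),
                        "note": "",
                    }
                )
    elif method in ("ttest", "mannwhitney"):
        for g in cases:
            a, b = groups[g], groups[control]
            if np.ptp(np.concatenate([a, b])) == 0:
                rows.append(
                    {
                        "test": method,
                        "comparison": f"{g} vs {control}",
                        "statistic": np.nan,
                        "p": 1.0,
                        "note": "degenerate: identical constant groups",
                    }
                )
                continue
            if method == "ttest":
                if min(a.size, b.size) < 2:
                    raise ValueError("t-test needs >= 2 samples per group")
                s, p = stats.ttest_ind(a, b)
            else:
                s, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append(
                {
                    "test": method,
                    "comparison": f"{g} vs {control}",
                    "statistic": float(s),
                    "p": float(p),
                    "note": "",
                }
            )
    elif method == "kruskal_dunn":
        if degenerate:
            rows = [
                {
                    "test": "dunn",
                    "comparison": f"{g} vs {control}",
                    "statistic": np.nan,
                    "p": np.nan,
                    "note": "degenerate: zero variance in all groups",
                }
                for g in cases
            ]
        else:
            h, p = stats.kruskal(*groups.values())
            rows.append(
                {
                    "test": "kruskal",
                    "comparison": "omnibus",
                    "statistic": float(h),
                    "p": float(p),
                    "note": "",
                }
            )
            for r in _dunn_posthoc(groups, control):
                r["note"] = ""
                rows.append(r)
    else:
        raise ValueError(f"unknown method {method!r}")

    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < alpha
    return out
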