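"""Site-level water-partitioning statistics.

The central quantity is the herb-to-shrub ratio

    R_h/s = C_h / C_s,

where C_h is the mean contribution (%) of shallow soil water (0-20 cm) to
herbaceous species and C_s the mean contribution of deep soil water
(40-100 cm) to shrubs, each averaged over the species present at a site.
Low ratios indicate a system anchored on stable deep water (shrub
dominance); high ratios indicate reliance on shallow, precipitation-driven
moisture and intensifying herb-shrub competition. The classifier uses the
established thresholds: stable below 0.9, semi-stable on the closed
interval [0.9, 1.4], unstable above 1.4.

Also provided: the restoration-age trend (Pearson), proportional-
similarity niche overlap between source-proportion vectors, and standard
one-way ANOVA with Tukey HSD post-hoc comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    MappingError,
    MissingGroupError,
    UndefinedRatioError,
)

__all__ = [
    "STABLE_MAX",
    "UNSTABLE_MIN",
    "SiteContribution",
    "mean_contribution",
    "herb_shrub_ratio",
    "classify_stability",
    "age_trend",
    "niche_overlap",
    "anova_tukey",
]

#: Classifier boundaries: stable strictly below, unstable strictly above;
#: the closed interval between is semi-stable (the upper boundary is the
#: bifurcation point of the companion dynamical model).
STABLE_MAX = 0.9
UNSTABLE_MIN = 1.4


@dataclass(frozen=True)
class SiteContribution:
    """Per-site summary feeding the stability table."""

    site_id: str
    C_h: float  # mean herbaceous 0-20 cm contribution, %
    C_s: float  # mean shrub 40-100 cm contribution, %
    n_herb: int
    m_shrub: int
    R_hs: float
    stability_class: str
    restoration_age: int | None = None  # None for the natural control


def mean_contribution(per_species_props: Sequence[float], role: str = "") -> float:
    """Arithmetic mean contribution (%) over the species of one group.

    Raises
    ------
    MissingGroupError
        Empty list: the site lacks that functional group (common for
        semi-shrubs, which drop out during succession).
    """
    vals = list(per_species_props)
    if not vals:
        raise MissingGroupError(f"no {role or 'group'} species at this site")
    if any(not (0 < v <= 100) for v in vals):
        raise DegenerateInputError(
            f"contributions must be in (0, 100] %, got {vals}"
        )
    return float(np.mean(vals))


def herb_shrub_ratio(C_h: float, C_s: float) -> float:
    """R_h/s = C_h / C_s (scale-invariant in the common units)."""
    if C_s <= 0:
        raise UndefinedRatioError(f"C_s must be > 0, got {C_s}")
    return C_h / C_s


def classify_stability(
    R_hs: float, stable_max: float = STABLE_MAX, unstable_min: float = UNSTABLE_MIN
) -> str:
    """Classify a herb-to-shrub ratio as stable / semi-stable / unstable.

    Both boundaries belong to the semi-stable class (closed interval),
    matching the treatment of the upper threshold as a critical,
    not-yet-unstable state.
    """
    if not np.isfinite(R_hs) or R_hs <= 0:
        raise DegenerateInputError(f"R_h/s must be positive and finite, got {R_hs}")
    if R_hs < stable_max:
        return "stable"
    if R_hs <= unstable_min:
        return "semi-stable"
    return "unstable"


def site_contribution(
    site_id: str,
    herb_props: Sequence[float],
    shrub_props: Sequence[float],
    restoration_age: int | None = None,
) -> SiteContribution:
    """Assemble a site's C_h, C_s, ratio and class from per-species values."""
    C_h = mean_contribution(herb_props, "herb")
    C_s = mean_contribution(shrub_props, "shrub")
    r = herb_shrub_ratio(C_h, C_s)
    return SiteContribution(
        site_id=site_id,
        C_h=C_h,
        C_s=C_s,
        n_herb=len(list(herb_props)),
        m_shrub=len(list(shrub_props)),
        R_hs=r,
        stability_class=classify_stability(r),
        restoration_age=restoration_age,
    )


def age_trend(site_values: Sequence[tuple[float, float]]) -> tuple[float, float, int]:
    """Pearson correlation of a site statistic with restoration age.

    Parameters
    ----------
    site_values
        ``(age, value)`` pairs for dated sites only (the natural control
        has no restoration age and must be excluded by the caller).

    Returns
    -------
    (r, p, n) with a two-sided t-test p-value.
    """
    pairs = list(site_values)
    n = len(pairs)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 dated sites, got {n}")
    ages = np.array([a for a, _ in pairs], dtype=float)
    vals = np.array([v for _, v in pairs], dtype=float)
    if np.ptp(ages) == 0 or np.ptp(vals) == 0:
        raise DegenerateInputError("zero variance in ages or values")
    res = stats.pearsonr(ages, vals)
    return float(res.statistic), float(res.pvalue), n


def niche_overlap(p, q, labels_p=None, labels_q=None, atol: float = 1e-6) -> float:
    """Proportional similarity index PSI = Σ_k min(p_k, q_k), in %.

    Accepts proportion vectors either as fractions summing to 1 or as
    percentages summing to 100 (both on the same convention). If layer
    labels are given for both vectors they must match element-wise.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if labels_p is not None or labels_q is not None:
        if list(labels_p or []) != list(labels_q or []):
            raise MappingError(
                f"layer sets differ: {list(labels_p or [])} vs {list(labels_q or [])}"
            )
    if p.shape != q.shape:
        raise MappingError(f"vector lengths differ: {p.shape} vs {q.shape}")
    for name, v in (("p", p), ("q", q)):
        if (v < -atol).any():
            raise DegenerateInputError(f"{name} has negative entries")
    sp, sq = p.sum(), q.sum()
    for s in (sp, sq):
        if not (abs(s - 1.0) <= atol or abs(s - 100.0) <= 100 * atol):
            raise DegenerateInputError(
                f"vectors must sum to 1 (fractions) or 100 (percent); got {s}"
            )
    if abs(sp - sq) > max(atol, 100 * atol) and (abs(sp - 1) <= atol) != (
        abs(sq - 1) <= atol
    ):
        raise DegenerateInputError("p and q use different conventions (1 vs 100)")
    overlap = np.minimum(p, q).sum()
    return float(overlap * 100.0) if abs(sp - 1.0) <= atol else float(overlap)


def anova_tukey(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA plus Tukey HSD pairwise comparisons.

    Returns ``(F, p, tukey_table)`` where the table has one row per pair
    with the mean difference, adjusted p-value and significance flag at
    ``alpha``.

    Raises
    ------
    InsufficientDataError
        Fewer than two groups, or any group with fewer than two values.
    """
    keys = list(groups)
    if len(keys) < 2:
        raise InsufficientDataError("need >= 2 groups for ANOVA")
    arrays = [np.asarray(groups[k], dtype=float) for k in keys]
    if any(len(a) < 2 for a in arrays):
        small = [k for k, a in zip(keys, arrays) if len(a) < 2]
        raise InsufficientDataError(f"groups with < 2 values: {small}")

    if np.ptp(np.concatenate(arrays)) == 0:
        # all observations identical: F is 0/0 in scipy; report 0, p = 1
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*arrays)
        if not np.isfinite(f_stat):
            f_stat, p_val = 0.0, 1.0

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(arrays)
    labels = np.concatenate([[k] * len(a) for k, a in zip(keys, arrays)])
    if np.ptp(values) == 0:
        pairs = [
            (keys[i], keys[j])
            for i in range(len(keys))
            for j in range(i + 1, len(keys))
        ]
        table = pd.DataFrame(
            {
                "group1": [a for a, _ in pairs],
                "group2": [b for _, b in pairs],
                "meandiff": 0.0,
                "p_adj": 1.0,
                "reject": False,
            }
        )
        return float(f_stat), float(p_val), table

    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    table = pd.DataFrame(
        tk.summary().data[1:], columns=[c.replace("-", "_") for c in tk.summary().data[0]]
    ).rename(columns={"p_adj": "p_adj"})
    table = table.rename(columns=str.lower)
    return float(f_stat), float(p_val), table
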