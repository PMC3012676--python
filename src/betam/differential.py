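"""Two-group differential methylation: Welch's t-test, range groups, ranking.

The workflow mirrors the classic "fold-change ranking with a non-stringent
p-value cutoff" paradigm of expression arrays: sites pass an unequal-variance
two-sample t-test gate (p < 0.05, no multiple-testing correction), are ranked
by absolute mean methylation difference |mean_A - mean_B|, and can additionally
be required to exceed a minimum-difference threshold. Because the logit link
between the two scales is only approximately linear in the middle, sites are
also assigned to low / middle / high methylation range groups — Beta: low
(0, 0.2), middle [0.2, 0.8], high (0.8, 1); M: low (-inf, -2), middle [-2, 2],
high (2, inf) — and method comparisons are made within groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from betam.core_metrics import MethylationMatrix

__all__ = [
    "DifferentialResult",
    "welch_test",
    "assign_range_group",
    "select_candidates",
    "differential_analysis",
]

RANGE_BOUNDS = {"beta": (0.2, 0.8), "m": (-2.0, 2.0)}


@dataclass
class DifferentialResult:
    """Per-site differential statistics on one methylation scale.

    ``table`` is indexed by site id with columns mean_A, mean_B, abs_diff,
    t_statistic, p_value, range_group. ``scale`` tags which metric the values
    were computed on; the group ids used are recorded for provenance.
    """

    table: pd.DataFrame
    scale: str
    group_A: list[str] = field(default_factory=list)
    group_B: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.9g")


def _group_columns(values: MethylationMatrix, group: list[str], name: str) -> np.ndarray:
    col = {a: j for j, a in enumerate(values.array_ids)}
    missing = [a for a in group if a not in col]
    if missing:
        raise KeyError(f"{name} references unknown arrays {missing}")
    if len(group) < 2:
        raise ValueError(f"{name} must contain at least 2 arrays")
    return values.values[:, [col[a] for a in group]]


def welch_test(
    values: MethylationMatrix,
    group_A: list[str],
    group_B: list[str],
) -> pd.DataFrame:
    """Welch's unequal-variance two-sample t-test, per site.

    Returns a DataFrame indexed by site id with columns ``t`` and ``p``
    (two-sided, Welch-Satterthwaite degrees of freedom). Sites with fewer than
    two non-missing values in either group get NaN. Degenerate sites where
    both groups have zero variance are defined to have p = 1 when the means
    are equal; when the means differ the zero-variance limit (t infinite,
    p = 0) is used and a warning is emitted, since Welch's statistic itself is
    undefined there.
    """
    a = _group_columns(values, group_A, "group_A")
    b = _group_columns(values, group_B, "group_B")

    def moments(x: np.ndarray):
        ok = np.isfinite(x)
        n = ok.sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(x, axis=1)
            v = np.nanvar(x, axis=1, ddof=1)
        return n, m, v

    n1, m1, v1 = moments(a)
    n2, m2, v2 = moments(b)
    valid = (n1 >= 2) & (n2 >= 2)

    with np.errstate(invalid="ignore", divide="ignore"):
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)

    degenerate = valid & (se2 == 0)
    if np.any(degenerate):
        equal = degenerate & (m1 == m2)
        t[equal], p[equal] = 0.0, 1.0
        unequal = degenerate & (m1 != m2)
        if np.any(unequal):
            warnings.warn(
                f"{int(unequal.sum())} site(s) have zero variance in both groups "
                "but unequal means; reporting the zero-variance limit p=0",
                RuntimeWarning,
                stacklevel=2,
            )
            t[unequal] = np.sign(m1[unequal] - m2[unequal]) * np.inf
            p[unequal] = 0.0
    t[~valid] = np.nan
    p[~valid] = np.nan
    return pd.DataFrame({"t": t, "p": p},
                        index=pd.Index(values.site_ids, name="TargetID"))


def assign_range_group(
    values: MethylationMatrix,
    array_ids: list[str] | None = None,
) -> pd.Series:
    """Assign each site to the low / middle / high methylation range.

    The locating summary is the per-site mean over ``array_ids`` (all arrays
    if None). Boundaries are closed on the middle interval: a Beta mean of
    exactly 0.2 or 0.8 (M mean of exactly -2 or 2) is middle.
    """
    if values.scale not in RANGE_BOUNDS:
        raise ValueError(f"unknown scale {values.scale!r}")
    lo, hi = RANGE_BOUNDS[values.scale]
    if array_ids is None:
        sub = values.values
    else:
        sub = _group_columns(values, list(array_ids), "array_ids")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(sub, axis=1)
    group = np.where(m < lo, "low", np.where(m > hi, "high", "middle"))
    out = pd.Series(group, index=pd.Index(values.site_ids, name="TargetID"),
                    name="range_group")
    out[~np.isfinite(m)] = pd.NA
    return out


def differential_analysis(
    values: MethylationMatrix,
    group_A: list[str],
    group_B: list[str],
) -> DifferentialResult:
    """Full per-site differential table between two replicate groups.

    Combines group means, absolute difference, Welch's test and range-group
    assignment (located by the mean over the compared arrays).
    """
    a = _group_columns(values, group_A, "group_A")
    b = _group_columns(values, group_B, "group_B")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
    tp = welch_test(values, group_A, group_B)
    groups = assign_range_group(values, list(group_A) + list(group_B))
    table = pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "abs_diff": np.abs(mean_a - mean_b),
            "t_statistic": tp["t"],
            "p_value": tp["p"],
            "range_group": groups,
        },
        index=pd.Index(values.site_ids, name="TargetID"),
    )
    return DifferentialResult(table=table, scale=values.scale,
                              group_A=list(group_A), group_B=list(group_B))


def select_candidates(
    result: DifferentialResult,
    p_cutoff: float = 0.05,
    diff_threshold: float = 0.0,
    range_group: str | None = None,
) -> list[str]:
    """Gated, ranked candidate list of differentially methylated sites.

    Keeps sites with p-value strictly below ``p_cutoff`` and absolute mean
    difference strictly above ``diff_threshold`` (optionally restricted to one
    range group), sorted by decreasing absolute difference with ties broken by
    site id for determinism.
    """
    t = result.table
    mask = (t["p_value"] < p_cutoff) & (t["abs_diff"] > diff_threshold)
    if range_group is not None:
        mask &= t["range_group"] == range_group
    sel = t.loc[mask.fillna(False)]
    order = np.lexsort((sel.index.to_numpy(), -sel["abs_diff"].to_numpy()))
    return list(sel.index.to_numpy()[order])
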