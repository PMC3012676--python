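"""Correlation-defined true positives and TPR/DR evaluation curves.

In a titration experiment the arrays carry known mixing fractions of two base
samples, so a site that is truly differentially methylated between the samples
must track that mixing profile: its methylation values across arrays correlate
with the per-array fraction of sample A. True positives (TP) are therefore
defined as sites whose absolute Pearson correlation with the titration profile
exceeds a threshold (default 0.8) on BOTH the Beta and M scales.

Candidate lists from a differential analysis are scored by

    TPR = |TP ∩ detected| / |detected|   (precision against the TP set)
    DR  = |TP ∩ detected| / |TP|         (recall of the TP set)

either along a top-N ranking curve (N in steps of 50, ROC-like when plotted as
1-DR versus TPR) or along a minimum-difference threshold sweep, from which
plateau turning points yield practical lower/upper difference thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from betam.core_metrics import MethylationMatrix
from betam.differential import DifferentialResult, select_candidates
from betam.synthetic_titration import TitrationDesign

__all__ = [
    "TruePositiveSet",
    "EvaluationCurve",
    "ThresholdSuggestion",
    "titration_profile",
    "define_true_positives",
    "tpr",
    "dr",
    "top_n_curve",
    "threshold_sweep",
    "suggest_thresholds",
]


@dataclass
class TruePositiveSet:
    """Sites whose methylation tracks the titration profile on both scales."""

    site_ids: list[str]
    r_threshold: float
    correlations: pd.DataFrame  # per-site columns r_beta, r_m

    def __post_init__(self) -> None:
        self._set = set(self.site_ids)

    def __len__(self) -> int:
        return len(self.site_ids)

    def __contains__(self, site_id: str) -> bool:
        return site_id in self._set

    @property
    def as_set(self) -> set[str]:
        return self._set

    def to_tsv(self, path) -> None:
        self.correlations.loc[self.site_ids].to_csv(
            path, sep="\t", float_format="%.9g"
        )


@dataclass
class EvaluationCurve:
    """Ordered (x, n_detected, TPR, DR) records along a ranking or sweep."""

    table: pd.DataFrame
    axis: str  # "top_n" or "threshold"
    scale: str | None = None
    range_group: str | None = None

    @property
    def roc_points(self) -> pd.DataFrame:
        """(1 - DR, TPR) pairs for ROC-like plotting."""
        return pd.DataFrame(
            {"one_minus_dr": 1.0 - self.table["dr"], "tpr": self.table["tpr"]}
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.9g")


@dataclass
class ThresholdSuggestion:
    """Lower/upper difference thresholds read off the sweep plateaus."""

    lower: float
    upper: float
    plateau_tolerance: float
    inconsistent: bool = False


def titration_profile(design: TitrationDesign) -> np.ndarray:
    """Per-array fraction of sample A; replicates repeat their mix's fraction."""
    return design.fractions


def _rowwise_pearson(values: np.ndarray, profile: np.ndarray) -> np.ndarray:
    ok = np.all(np.isfinite(values), axis=1)
    x = values - values.mean(axis=1, keepdims=True)
    f = profile - profile.mean()
    denom = np.sqrt((x**2).sum(axis=1) * (f**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ f) / denom
    constant = np.ptp(values, axis=1) == 0  # robust to 1-ulp centering noise
    r[~ok | (denom == 0) | constant] = np.nan
    return r


def _aligned(values: MethylationMatrix, design: TitrationDesign) -> np.ndarray:
    col = {a: j for j, a in enumerate(values.array_ids)}
    missing = [a for a in design.array_ids if a not in col]
    if missing:
        raise ValueError(f"matrix is missing design arrays {missing}")
    return values.values[:, [col[a] for a in design.array_ids]]


def define_true_positives(
    beta: MethylationMatrix,
    m: MethylationMatrix,
    design: TitrationDesign,
    r_threshold: float = 0.8,
    require_both_scales: bool = True,
) -> TruePositiveSet:
    """Correlation-defined TP set against the titration profile.

    A site enters the set iff |Pearson r| with the per-array fraction of
    sample A exceeds ``r_threshold`` on both scales (set
    ``require_both_scales=False`` for a single-scale sensitivity mode, which
    then requires the criterion on the beta scale only for ordering and on m
    if beta is undefined). Sites with zero variance on either scale have
    undefined r and are excluded.
    """
    if beta.site_ids != m.site_ids:
        raise ValueError("beta and m matrices must share site ids in order")
    if beta.scale != "beta" or m.scale != "m":
        raise ValueError("expected one beta-scale and one m-scale matrix")
    profile = titration_profile(design)
    if np.ptp(profile) == 0:
        raise ValueError("titration profile is constant; correlations undefined")
    r_beta = _rowwise_pearson(_aligned(beta, design), profile)
    r_m = _rowwise_pearson(_aligned(m, design), profile)
    with np.errstate(invalid="ignore"):
        if require_both_scales:
            included = (np.abs(r_beta) > r_threshold) & (np.abs(r_m) > r_threshold)
        else:
            included = np.where(
                np.isfinite(r_beta), np.abs(r_beta) > r_threshold,
                np.abs(r_m) > r_threshold,
            )
    included &= np.isfinite(r_beta) & np.isfinite(r_m)
    correlations = pd.DataFrame(
        {"r_beta": r_beta, "r_m": r_m},
        index=pd.Index(beta.site_ids, name="TargetID"),
    )
    site_ids = [s for s, inc in zip(beta.site_ids, included) if inc]
    return TruePositiveSet(site_ids=site_ids, r_threshold=r_threshold,
                           correlations=correlations)


def tpr(detected, tp: TruePositiveSet) -> float:
    """True Positive Rate |TP ∩ detected| / |detected|; undefined when empty."""
    detected = set(detected)
    if not detected:
        raise ValueError("TPR is undefined for an empty detected set")
    return len(detected & tp.as_set) / len(detected)


def dr(detected, tp: TruePositiveSet) -> float:
    """Detection Rate |TP ∩ detected| / |TP|; requires a non-empty TP set."""
    if len(tp) == 0:
        raise ValueError("DR is undefined for an empty TP set")
    return len(set(detected) & tp.as_set) / len(tp)


def top_n_curve(
    ranked_candidates: list[str],
    tp: TruePositiveSet,
    step: int = 50,
    scale: str | None = None,
    range_group: str | None = None,
) -> EvaluationCurve:
    """TPR/DR along nested top-N prefixes of a ranked candidate list.

    N runs in increments of ``step`` and always ends with the full list
    length, so every candidate is eventually included.
    """
    if not ranked_candidates:
        raise ValueError("ranked candidate list is empty")
    if step < 1:
        raise ValueError("step must be >= 1")
    total = len(ranked_candidates)
    grid = list(range(step, total + 1, step))
    if not grid or grid[-1] != total:
        grid.append(total)
    tp_set = tp.as_set
    rows = []
    n_hit = 0
    prev = 0
    for n in grid:
        n_hit += sum(1 for s in ranked_candidates[prev:n] if s in tp_set)
        prev = n
        rows.append({"x": n, "n_detected": n, "tpr": n_hit / n,
                     "dr": n_hit / len(tp) if len(tp) else np.nan})
    return EvaluationCurve(table=pd.DataFrame(rows), axis="top_n",
                           scale=scale, range_group=range_group)


def threshold_sweep(
    result: DifferentialResult,
    tp: TruePositiveSet,
    thresholds,
    p_cutoff: float = 0.05,
    range_group: str | None = None,
) -> EvaluationCurve:
    """TPR/DR as the minimum-difference threshold grows.

    Each record applies the p-value gate plus one difference threshold; TPR is
    reported as missing (NaN), not zero, when nothing is detected.
    """
    thresholds = list(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be non-decreasing")
    rows = []
    for th in thresholds:
        detected = select_candidates(result, p_cutoff=p_cutoff,
                                     diff_threshold=th, range_group=range_group)
        rows.append(
            {
                "x": th,
                "n_detected": len(detected),
                "tpr": tpr(detected, tp) if detected else np.nan,
                "dr": dr(detected, tp),
            }
        )
    return EvaluationCurve(table=pd.DataFrame(rows), axis="threshold",
                           scale=result.scale, range_group=range_group)


def suggest_thresholds(
    curve: EvaluationCurve,
    plateau_tolerance: float = 0.02,
) -> ThresholdSuggestion:
    """Read lower/upper difference thresholds off the sweep's plateaus.

    The lower (down-limit) threshold is the largest threshold at which DR is
    still within ``plateau_tolerance`` (relative) of its value at threshold 0
    — the last point before DR leaves its initial plateau. The upper
    (up-limit) threshold is the smallest threshold at which TPR is within the
    tolerance of its maximum — the first point of the TPR plateau. If the two
    cross (upper < lower) both are returned with ``inconsistent=True``.
    """
    if curve.axis != "threshold":
        raise ValueError("threshold suggestion needs a threshold-axis curve")
    t = curve.table
    if len(t) < 3:
        raise ValueError("need at least 3 sweep records")
    x = t["x"].to_numpy(float)
    dr_vals = t["dr"].to_numpy(float)
    tpr_vals = t["tpr"].to_numpy(float)

    dr0 = dr_vals[0]
    ok_dr = dr_vals >= (1.0 - plateau_tolerance) * dr0
    lower = float(x[np.flatnonzero(ok_dr)[-1]]) if np.any(ok_dr) else float(x[0])

    finite = np.isfinite(tpr_vals)
    tpr_max = np.nanmax(tpr_vals) if np.any(finite) else np.nan
    ok_tpr = finite & (tpr_vals >= (1.0 - plateau_tolerance) * tpr_max)
    upper = float(x[np.flatnonzero(ok_tpr)[0]]) if np.any(ok_tpr) else float(x[-1])

    if upper < lower:
        warnings.warn(
            "threshold suggestion inconsistent: TPR plateau starts before the "
            "DR plateau ends (upper < lower)",
            RuntimeWarning,
            stacklevel=2,
        )
    return ThresholdSuggestion(lower=lower, upper=upper,
                               plateau_tolerance=plateau_tolerance,
                               inconsistent=upper < lower)
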