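"""Core methylation metrics: Beta-value, M-value and their logit inter-conversion.

The Beta-value of a CpG site is the methylated-probe intensity divided by the
total intensity,

    Beta = max(meth, 0) / (max(unmeth, 0) + max(meth, 0) + alpha),

with a small offset ``alpha`` (default 100) that regularizes the ratio when both
channels are dim. It lies in [0, 1) and approximates the fraction of methylated
molecules at the site. The M-value is the offset-adjusted log-ratio of the two
channels,

    M = log2((max(meth, 0) + alpha) / (max(unmeth, 0) + alpha)),

with default offset 1; it is unbounded and approximately homoscedastic. When
total intensity is high the two metrics are linked by a base-2 logistic (logit)
relationship:

    M = log2(Beta / (1 - Beta)),    Beta = 2**M / (2**M + 1),

so Beta-values of 0.2, 0.5 and 0.8 correspond to M-values of -2, 0 and 2.

All operations are elementwise and preserve site/array ordering; missing cells
(NaN) propagate unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "IntensityMatrix",
    "MethylationMatrix",
    "compute_beta",
    "compute_m",
    "beta_to_m",
    "m_to_beta",
]


def _as_2d_float(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D site x array matrix, got ndim={arr.ndim}")
    return arr


def _check_unique(ids: Sequence[str], name: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{name} must be unique")
    return ids


@dataclass
class IntensityMatrix:
    """Per-site, per-array channel intensities with detection p-values.

    ``meth`` and ``unmeth`` hold the fluorescence intensities of the methylated
    and unmethylated probes (they may be negative after background adjustment;
    metric computations clamp them at 0). ``detection_p`` holds the per-probe
    detection p-values in [0, 1]; large values mean the signal is
    indistinguishable from background.
    """

    site_ids: list[str]
    array_ids: list[str]
    meth: np.ndarray
    unmeth: np.ndarray
    detection_p: np.ndarray

    def __post_init__(self) -> None:
        self.site_ids = _check_unique(self.site_ids, "site_ids")
        self.array_ids = _check_unique(self.array_ids, "array_ids")
        self.meth = _as_2d_float(self.meth, "meth")
        self.unmeth = _as_2d_float(self.unmeth, "unmeth")
        self.detection_p = _as_2d_float(self.detection_p, "detection_p")
        shape = (len(self.site_ids), len(self.array_ids))
        for name in ("meth", "unmeth", "detection_p"):
            if getattr(self, name).shape != shape:
                raise ValueError(
                    f"{name} has shape {getattr(self, name).shape}, expected {shape} "
                    "from site_ids x array_ids"
                )
        p = self.detection_p
        finite = np.isfinite(p)
        if np.any((p[finite] < 0) | (p[finite] > 1)):
            raise ValueError("detection_p values must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_arrays(self) -> int:
        return len(self.array_ids)

    @property
    def total(self) -> np.ndarray:
        """Per-cell total intensity meth + unmeth (no clamping)."""
        return self.meth + self.unmeth


@dataclass
class MethylationMatrix:
    """Site x array methylation levels on one of the two scales.

    ``scale`` is ``"beta"`` (values in [0, 1)) or ``"m"`` (finite reals);
    ``alpha_used`` records the offset applied when the values were computed
    from intensities so downstream reports are self-describing.
    """

    site_ids: list[str]
    array_ids: list[str]
    values: np.ndarray
    scale: str
    alpha_used: float = 0.0

    def __post_init__(self) -> None:
        self.site_ids = _check_unique(self.site_ids, "site_ids")
        self.array_ids = _check_unique(self.array_ids, "array_ids")
        self.values = _as_2d_float(self.values, "values")
        if self.values.shape != (len(self.site_ids), len(self.array_ids)):
            raise ValueError("values shape does not match site_ids x array_ids")
        if self.scale not in ("beta", "m"):
            raise ValueError(f"scale must be 'beta' or 'm', got {self.scale!r}")
        if self.alpha_used < 0:
            raise ValueError("alpha_used must be nonnegative")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_arrays(self) -> int:
        return len(self.array_ids)


def compute_beta(x: IntensityMatrix, alpha: float = 100.0) -> MethylationMatrix:
    """Compute Beta-values from channel intensities.

    Negative intensities are clamped to 0 before forming the ratio
    ``meth / (unmeth + meth + alpha)``. With ``alpha > 0`` every value is
    strictly below 1. With ``alpha = 0`` a cell whose clamped channels are both
    zero has no defined Beta-value and raises, naming the offending cell.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    meth = np.maximum(x.meth, 0.0)
    unmeth = np.maximum(x.unmeth, 0.0)
    denom = meth + unmeth + alpha
    if alpha == 0:
        bad = (denom == 0) & np.isfinite(denom)
        if np.any(bad):
            i, j = map(int, np.argwhere(bad)[0])
            raise ZeroDivisionError(
                "Beta-value undefined with alpha=0: both channels are zero at "
                f"site {x.site_ids[i]!r}, array {x.array_ids[j]!r}"
            )
    values = meth / denom
    return MethylationMatrix(
        site_ids=list(x.site_ids),
        array_ids=list(x.array_ids),
        values=values,
        scale="beta",
        alpha_used=float(alpha),
    )


def compute_m(x: IntensityMatrix, alpha: float = 1.0) -> MethylationMatrix:
    """Compute M-values, the offset-adjusted log2 channel ratio.

    ``alpha`` must be strictly positive: the offset is what keeps both the
    numerator and denominator positive after negative intensities are clamped
    to 0, and hence what guarantees finite M-values.
    """
    if alpha <= 0:
        raise ValueError("alpha must be strictly positive for M-values")
    meth = np.maximum(x.meth, 0.0)
    unmeth = np.maximum(x.unmeth, 0.0)
    values = np.log2(meth + alpha) - np.log2(unmeth + alpha)
    return MethylationMatrix(
        site_ids=list(x.site_ids),
        array_ids=list(x.array_ids),
        values=values,
        scale="m",
        alpha_used=float(alpha),
    )


def _beta_to_m_array(beta: np.ndarray, clip: float | None) -> np.ndarray:
    beta = np.asarray(beta, dtype=float)
    finite = np.isfinite(beta)
    if np.any((beta[finite] < 0) | (beta[finite] > 1)):
        raise ValueError("Beta-values must lie in [0, 1]")
    if clip is None:
        if np.any((beta[finite] <= 0) | (beta[finite] >= 1)):
            raise ValueError(
                "Beta-value of exactly 0 or 1 has no finite logit; "
                "pass a clip epsilon to map boundary values inside (0, 1)"
            )
        clipped = beta
    else:
        if not 0 < clip < 0.5:
            raise ValueError("clip epsilon must lie in (0, 0.5)")
        clipped = np.clip(beta, clip, 1.0 - clip)
    return np.log2(clipped) - np.log2(1.0 - clipped)


def beta_to_m(beta, clip: float | None = 1e-6):
    """Map Beta-values to M-values through the base-2 logit.

    Accepts a scalar, an array, or a :class:`MethylationMatrix` with
    ``scale="beta"``. Boundary values (exactly 0 or 1) are first clipped into
    ``[clip, 1 - clip]``; with ``clip=None`` they raise instead, since the
    logit is undefined there.
    """
    if isinstance(beta, MethylationMatrix):
        if beta.scale != "beta":
            raise ValueError(f"expected a beta-scale matrix, got scale={beta.scale!r}")
        return MethylationMatrix(
            site_ids=list(beta.site_ids),
            array_ids=list(beta.array_ids),
            values=_beta_to_m_array(beta.values, clip),
            scale="m",
            alpha_used=beta.alpha_used,
        )
    out = _beta_to_m_array(np.asarray(beta, dtype=float), clip)
    return float(out) if out.ndim == 0 else out


def _m_to_beta_array(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if np.any(np.isinf(m)):
        raise ValueError("M-values must be finite")
    # 1/(1 + 2**-M) for M >= 0 and 2**M/(2**M + 1) for M < 0: the exponent is
    # always <= 0, so neither branch can overflow.
    out = np.empty_like(m)
    pos = m >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-m[pos]))
    e = np.exp2(m[~pos])
    out[~pos] = e / (e + 1.0)
    out[np.isnan(m)] = np.nan
    return out


def m_to_beta(m):
    """Map M-values back to Beta-values, ``2**M / (2**M + 1)``, always in (0, 1).

    Accepts a scalar, an array, or a :class:`MethylationMatrix` with
    ``scale="m"``. Evaluated in a symmetric form that cannot overflow for
    large ``|M|``. Infinite input raises; NaN propagates.
    """
    if isinstance(m, MethylationMatrix):
        if m.scale != "m":
            raise ValueError(f"expected an m-scale matrix, got scale={m.scale!r}")
        return MethylationMatrix(
            site_ids=list(m.site_ids),
            array_ids=list(m.array_ids),
            values=_m_to_beta_array(m.values),
            scale="beta",
            alpha_used=m.alpha_used,
        )
    out = _m_to_beta_array(np.asarray(m, dtype=float))
    return float(out) if out.ndim == 0 else out
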