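"""Synthetic Infinium-like titration experiments with known ground truth.

The simulator emulates a two-sample titration design on a HumanMethylation27-like
array: two base samples A and B are mixed at known fractions and each mixture is
hybridized to one or more arrays. Per site, true methylation fractions ``p_A``
and ``p_B`` are drawn from a bimodal prior (most CpG sites are nearly
unmethylated or nearly fully methylated, a minority intermediate); a chosen
fraction of sites is truly differential (``p_B`` redrawn independently of
``p_A``), the rest have ``p_B == p_A``. On an array carrying a fraction ``f`` of
sample A, the site-level methylation fraction is the mixture ``f*p_A +
(1-f)*p_B``. Channel intensities are Gamma distributed — under which the
Beta-value is Beta-distributed — with means ``T_i * p * s_a`` (methylated) and
``T_i * (1-p) * s_a`` (unmethylated), where ``T_i`` is a per-site log-normal
total-intensity level and ``s_a`` a per-array log-normal technical scale factor.

Defaults are tuned to the platform's gross statistics: ~27,578 sites, nearly
all total intensities above 1000, and a clearly bimodal M-value histogram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from betam.core_metrics import IntensityMatrix

__all__ = [
    "TitrationDesign",
    "SimulationTruth",
    "default_design",
    "sample_channel_intensities",
    "simulate_titration",
    "write_truth_table",
    "read_truth_table",
]


def sample_channel_intensities(
    p: np.ndarray,
    total: np.ndarray,
    gamma_shape: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw methylated/unmethylated intensities for methylation fractions ``p``.

    Channels are independent Gamma variates with the given shape and means
    ``total * p`` and ``total * (1 - p)``, so the per-channel coefficient of
    variation is ``1/sqrt(gamma_shape)`` and the noise-free Beta-value (offset
    0) is exactly ``p`` in expectation of the channel means.
    """
    p = np.asarray(p, dtype=float)
    total = np.broadcast_to(np.asarray(total, dtype=float), p.shape)
    meth = rng.gamma(gamma_shape, total * p / gamma_shape)
    unmeth = rng.gamma(gamma_shape, total * (1.0 - p) / gamma_shape)
    return meth, unmeth


@dataclass
class TitrationDesign:
    """Mixing design: one (array_id, fraction of sample A, mix label) per array."""

    arrays: list[tuple[str, float, str]]

    def __post_init__(self) -> None:
        ids = [a[0] for a in self.arrays]
        if len(set(ids)) != len(ids):
            raise ValueError("array ids in a design must be unique")
        for _, f, _ in self.arrays:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"mixing fraction {f} outside [0, 1]")

    @property
    def array_ids(self) -> list[str]:
        return [a[0] for a in self.arrays]

    @property
    def fractions(self) -> np.ndarray:
        return np.array([a[1] for a in self.arrays], dtype=float)

    @property
    def mix_labels(self) -> list[str]:
        return [a[2] for a in self.arrays]

    @property
    def n_arrays(self) -> int:
        return len(self.arrays)


def default_design() -> TitrationDesign:
    """The standard 5-mix titration design expanded to 8 physical arrays.

    Mixing ratios of A:B are 100:0, 90:10, 75:25, 50:50 and 0:100 with
    2, 2, 1, 1 and 2 technical replicates respectively.
    """
    mixes = [("Mix1", 1.0, 2), ("Mix2", 0.9, 2), ("Mix3", 0.75, 1),
             ("Mix4", 0.5, 1), ("Mix5", 0.0, 2)]
    arrays = [(f"{label}_r{r + 1}", frac, label)
              for label, frac, n_rep in mixes for r in range(n_rep)]
    return TitrationDesign(arrays=arrays)


@dataclass
class SimulationTruth:
    """Ground truth for one simulated titration experiment."""

    site_ids: list[str]
    p_A: np.ndarray
    p_B: np.ndarray
    is_differential: np.ndarray
    params_used: dict

    def __post_init__(self) -> None:
        n = len(self.site_ids)
        self.p_A = np.asarray(self.p_A, dtype=float)
        self.p_B = np.asarray(self.p_B, dtype=float)
        self.is_differential = np.asarray(self.is_differential, dtype=bool)
        if not (len(self.p_A) == len(self.p_B) == len(self.is_differential) == n):
            raise ValueError("truth vectors must all have one entry per site")


def simulate_titration(
    n_sites: int = 27578,
    design: TitrationDesign | None = None,
    diff_fraction: float = 0.3,
    gamma_shape: float = 50.0,
    mean_total_intensity: float = 5000.0,
    replicate_cv: float = 0.1,
    seed: int = 0,
    *,
    total_intensity_log_sd: float = 0.5,
    bimodal_weights: tuple[float, float, float] = (0.4, 0.4, 0.2),
    unmeth_mode_ab: tuple[float, float] = (2.0, 20.0),
    meth_mode_ab: tuple[float, float] = (20.0, 2.0),
    detection_p_value: float = 1e-6,
    failed_site_fraction: float = 0.0,
) -> tuple[IntensityMatrix, SimulationTruth]:
    """Simulate one titration experiment; fully reproducible from ``seed``.

    Parameters
    ----------
    n_sites:
        Number of CpG sites (default matches the HumanMethylation27 platform).
    design:
        Titration design; defaults to :func:`default_design`.
    diff_fraction:
        Fraction of sites that are truly differential between A and B. The
        count is exact (``round(diff_fraction * n_sites)`` sites chosen without
        replacement), not per-site Bernoulli, so truth denominators are
        deterministic.
    gamma_shape:
        Shape of the Gamma intensity noise for both channels; the per-channel
        coefficient of variation is ``1/sqrt(gamma_shape)``.
    mean_total_intensity:
        Mean of the per-site log-normal total-intensity level ``T_i``.
    replicate_cv:
        Coefficient of variation of the per-array log-normal technical factor.
    total_intensity_log_sd:
        Log-scale SD of ``T_i``.
    bimodal_weights, unmeth_mode_ab, meth_mode_ab:
        Methylation-fraction prior: mixture of Beta(*unmeth_mode_ab*) near 0,
        Beta(*meth_mode_ab*) near 1, and a uniform middle component, with the
        given weights.
    detection_p_value:
        Detection p-value assigned to all well-behaved probes (everything
        simulated is real signal).
    failed_site_fraction:
        Optional fraction of sites marked as failed (detection p 0.5 on every
        array), for exercising detection filtering end to end.
    """
    if design is None:
        design = default_design()
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not 0.0 <= diff_fraction <= 1.0:
        raise ValueError("diff_fraction must lie in [0, 1]")
    if gamma_shape <= 0 or mean_total_intensity <= 0:
        raise ValueError("gamma_shape and mean_total_intensity must be positive")
    if replicate_cv < 0 or total_intensity_log_sd < 0:
        raise ValueError("replicate_cv and total_intensity_log_sd must be >= 0")
    w = np.asarray(bimodal_weights, dtype=float)
    if w.shape != (3,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("bimodal_weights must be three nonnegative values summing to 1")
    if not 0.0 <= failed_site_fraction <= 1.0:
        raise ValueError("failed_site_fraction must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    site_ids = [f"cg{i:08d}" for i in range(n_sites)]

    def draw_fractions(n: int) -> np.ndarray:
        comp = rng.choice(3, size=n, p=w)
        out = np.empty(n)
        for c, sampler in enumerate((
            lambda k: rng.beta(*unmeth_mode_ab, size=k),
            lambda k: rng.beta(*meth_mode_ab, size=k),
            lambda k: rng.uniform(0.0, 1.0, size=k),
        )):
            mask = comp == c
            out[mask] = sampler(int(mask.sum()))
        return out

    p_A = draw_fractions(n_sites)
    n_diff = int(round(diff_fraction * n_sites))
    diff_idx = rng.choice(n_sites, size=n_diff, replace=False)
    is_differential = np.zeros(n_sites, dtype=bool)
    is_differential[diff_idx] = True
    p_B = p_A.copy()
    p_B[diff_idx] = draw_fractions(n_diff)

    # per-site total intensity T_i (log-normal with mean mean_total_intensity)
    sig_t = total_intensity_log_sd
    T = rng.lognormal(np.log(mean_total_intensity) - sig_t**2 / 2.0, sig_t, n_sites)
    # per-array technical factor with CV replicate_cv, mean 1
    sig_a = np.sqrt(np.log1p(replicate_cv**2))
    s = rng.lognormal(-sig_a**2 / 2.0, sig_a, design.n_arrays)

    f = design.fractions
    p = f[None, :] * p_A[:, None] + (1.0 - f[None, :]) * p_B[:, None]
    total = T[:, None] * s[None, :]
    meth, unmeth = sample_channel_intensities(p, total, gamma_shape, rng)

    detection_p = np.full((n_sites, design.n_arrays), detection_p_value)
    if failed_site_fraction > 0:
        n_fail = int(round(failed_site_fraction * n_sites))
        fail_idx = rng.choice(n_sites, size=n_fail, replace=False)
        detection_p[fail_idx, :] = 0.5

    params = {
        "n_sites": n_sites,
        "diff_fraction": diff_fraction,
        "gamma_shape": gamma_shape,
        "mean_total_intensity": mean_total_intensity,
        "replicate_cv": replicate_cv,
        "total_intensity_log_sd": total_intensity_log_sd,
        "bimodal_weights": list(map(float, w)),
        "unmeth_mode_ab": list(unmeth_mode_ab),
        "meth_mode_ab": list(meth_mode_ab),
        "detection_p_value": detection_p_value,
        "failed_site_fraction": failed_site_fraction,
        "seed": seed,
        "design": [list(a) for a in design.arrays],
    }
    intensities = IntensityMatrix(
        site_ids=site_ids,
        array_ids=design.array_ids,
        meth=meth,
        unmeth=unmeth,
        detection_p=detection_p,
    )
    truth = SimulationTruth(
        site_ids=site_ids,
        p_A=p_A,
        p_B=p_B,
        is_differential=is_differential,
        params_used=params,
    )
    return intensities, truth


def write_truth_table(truth: SimulationTruth, path: str | Path,
                      params_path: str | Path | None = None) -> None:
    """Write ground truth as TSV; optionally dump the parameter record as JSON."""
    pd.DataFrame(
        {
            "TargetID": truth.site_ids,
            "p_A": truth.p_A,
            "p_B": truth.p_B,
            "is_differential": truth.is_differential.astype(int),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.9g")
    if params_path is not None:
        Path(params_path).write_text(json.dumps(truth.params_used, indent=2) + "\n")


def read_truth_table(path: str | Path) -> SimulationTruth:
    df = pd.read_csv(path, sep="\t")
    return SimulationTruth(
        site_ids=df["TargetID"].astype(str).tolist(),
        p_A=df["p_A"].to_numpy(float),
        p_B=df["p_B"].to_numpy(float),
        is_differential=df["is_differential"].to_numpy(bool),
        params_used={},
    )
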