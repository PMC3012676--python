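"""Intensity-table I/O, detection-p prefiltering and simple scaling normalization.

The on-disk format is a GenomeStudio-flavoured tab-separated table: UTF-8, one
header row, first column ``TargetID``, then one column triplet per array named
``<array>.Methylated``, ``<array>.Unmethylated`` and ``<array>.Detection_Pval``.
Missing cells are empty.

Preprocessing follows the standard Infinium workflow: sites whose detection
p-values are worse than a threshold in more than a given fraction of arrays are
removed (defaults: p > 1e-4 in more than 50% of arrays), and arrays are put on
a common intensity scale by simple scaling normalization (SSN) — one scale
factor per array, shared by both channels so within-array meth/unmeth ratios
(and hence M-values) are untouched, bringing each array's pooled mean probe
intensity to the across-array grand mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from betam.core_metrics import IntensityMatrix, MethylationMatrix

__all__ = [
    "FilterReport",
    "read_intensity_table",
    "write_intensity_table",
    "read_methylation_table",
    "write_methylation_table",
    "detection_filter",
    "scaling_normalize",
]

_SUFFIXES = ("Methylated", "Unmethylated", "Detection_Pval")
FLOAT_FORMAT = "%.9g"


@dataclass
class FilterReport:
    """Bookkeeping for a site-filtering step."""

    n_sites_in: int
    removed_site_ids: list[str]
    rule: str

    @property
    def n_sites_removed(self) -> int:
        return len(self.removed_site_ids)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_sites_in": self.n_sites_in,
                    "n_sites_removed": self.n_sites_removed,
                    "rule": self.rule,
                    "removed_site_ids": self.removed_site_ids,
                },
                indent=2,
            )
            + "\n"
        )

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text("".join(f"{s}\n" for s in self.removed_site_ids))


class IntensityTableError(ValueError):
    """Raised when an intensity table does not conform to the TSV dialect."""


def _numeric_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    raw = df[col]
    converted = pd.to_numeric(raw, errors="coerce")
    # empty cells are legitimate missing values; anything else non-numeric is a
    # parse error reported with its 1-based file line (header is line 1)
    bad = converted.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise IntensityTableError(
            f"{path}: non-numeric value {raw.iloc[row]!r} in column {col!r} "
            f"at line {row + 2}"
        )
    return converted.to_numpy(dtype=float)


def read_intensity_table(path: str | Path) -> IntensityMatrix:
    """Read an intensity TSV into an :class:`IntensityMatrix`.

    Array identifiers and their order are recovered from the
    ``<array>.Methylated`` header columns; every array must supply the full
    triplet of columns. Row and column order is preserved from the file.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=True,
                         na_values=[""], engine="c")
    except pd.errors.ParserError as exc:
        raise IntensityTableError(f"{path}: malformed table: {exc}") from exc
    if df.columns.empty or df.columns[0] != "TargetID":
        raise IntensityTableError(f"{path}: first column must be 'TargetID'")
    array_ids = [c[: -len(".Methylated")] for c in df.columns[1:]
                 if c.endswith(".Methylated")]
    if not array_ids:
        raise IntensityTableError(f"{path}: no '<array>.Methylated' columns found")
    expected = ["TargetID"] + [f"{a}.{s}" for a in array_ids for s in _SUFFIXES]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise IntensityTableError(f"{path}: missing required columns: {missing}")
    extra = [c for c in df.columns if c not in expected]
    if extra:
        raise IntensityTableError(f"{path}: unrecognized columns: {extra}")

    site_ids = df["TargetID"].astype(str).tolist()
    cols = {c: _numeric_column(df, c, path) for c in expected[1:]}
    stack = lambda suffix: np.column_stack(
        [cols[f"{a}.{suffix}"] for a in array_ids]
    ) if site_ids else np.empty((0, len(array_ids)))
    return IntensityMatrix(
        site_ids=site_ids,
        array_ids=array_ids,
        meth=stack("Methylated"),
        unmeth=stack("Unmethylated"),
        detection_p=stack("Detection_Pval"),
    )


def write_intensity_table(x: IntensityMatrix, path: str | Path) -> None:
    """Write an :class:`IntensityMatrix` as the intensity TSV dialect."""
    data: dict[str, object] = {"TargetID": x.site_ids}
    for j, a in enumerate(x.array_ids):
        data[f"{a}.Methylated"] = x.meth[:, j]
        data[f"{a}.Unmethylated"] = x.unmeth[:, j]
        data[f"{a}.Detection_Pval"] = x.detection_p[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False,
                              float_format=FLOAT_FORMAT, na_rep="")


def write_methylation_table(x: MethylationMatrix, path: str | Path) -> None:
    """Write a methylation matrix as TSV: TargetID plus one column per array.

    Values only; the scale tag and offset are the caller's to record (the CLI
    puts them in the run's config sidecar).
    """
    data: dict[str, object] = {"TargetID": x.site_ids}
    for j, a in enumerate(x.array_ids):
        data[a] = x.values[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False,
                              float_format=FLOAT_FORMAT, na_rep="")


def read_methylation_table(path: str | Path, scale: str,
                           alpha_used: float = 0.0) -> MethylationMatrix:
    """Read a TargetID-plus-arrays TSV back into a :class:`MethylationMatrix`."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[""])
    if df.columns.empty or df.columns[0] != "TargetID":
        raise IntensityTableError(f"{path}: first column must be 'TargetID'")
    array_ids = list(df.columns[1:])
    if not array_ids:
        raise IntensityTableError(f"{path}: no array columns found")
    values = np.column_stack([_numeric_column(df, c, path) for c in array_ids]) \
        if len(df) else np.empty((0, len(array_ids)))
    return MethylationMatrix(
        site_ids=df["TargetID"].astype(str).tolist(),
        array_ids=array_ids,
        values=values,
        scale=scale,
        alpha_used=alpha_used,
    )


def detection_filter(
    x: IntensityMatrix,
    p_threshold: float = 1e-4,
    sample_fraction: float = 0.5,
) -> tuple[IntensityMatrix, FilterReport]:
    """Remove sites that fail detection in too many arrays.

    A site is removed when the fraction of arrays with detection p-value
    strictly greater than ``p_threshold`` ("worse than", since small detection
    p-values are good) is strictly greater than ``sample_fraction``.
    """
    if not 0 < p_threshold < 1 or not 0 < sample_fraction < 1:
        raise ValueError("p_threshold and sample_fraction must lie in (0, 1)")
    bad_frac = np.mean(x.detection_p > p_threshold, axis=1)
    remove = bad_frac > sample_fraction
    keep = ~remove
    report = FilterReport(
        n_sites_in=x.n_sites,
        removed_site_ids=[s for s, r in zip(x.site_ids, remove) if r],
        rule=(f"removed sites with detection p > {p_threshold:g} in more than "
              f"{sample_fraction:.0%} of arrays"),
    )
    filtered = IntensityMatrix(
        site_ids=[s for s, k in zip(x.site_ids, keep) if k],
        array_ids=list(x.array_ids),
        meth=x.meth[keep],
        unmeth=x.unmeth[keep],
        detection_p=x.detection_p[keep],
    )
    return filtered, report


def scaling_normalize(x: IntensityMatrix) -> IntensityMatrix:
    """Simple scaling normalization: rescale arrays to a common mean intensity.

    For each array the two channels are pooled (negative intensities clamped to
    0 for the mean computation) and the array is multiplied by one factor so
    every pooled per-array mean equals the grand mean of those means. Both
    channels share the factor, so M-values are unaffected up to the offset term.
    """
    if x.n_arrays < 1:
        raise ValueError("need at least one array")
    pooled = np.concatenate([np.maximum(x.meth, 0.0), np.maximum(x.unmeth, 0.0)])
    means = np.nanmean(pooled, axis=0)
    if np.any(means == 0):
        j = int(np.flatnonzero(means == 0)[0])
        raise ValueError(f"array {x.array_ids[j]!r} has zero pooled mean intensity")
    factors = means.mean() / means
    return IntensityMatrix(
        site_ids=list(x.site_ids),
        array_ids=list(x.array_ids),
        meth=x.meth * factors,
        unmeth=x.unmeth * factors,
        detection_p=x.detection_p.copy(),
    )
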