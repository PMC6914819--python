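"""Analysis-scale transforms: log10, unit-variance scaling, normality.

Metabolite abundances are approximately log-normal, so the analysis scale
is log10; mean-centering and unit-variance (UV, auto-) scaling then give
every metabolite equal weight in the PCA regardless of its dynamic range.
Shapiro-Wilk W per metabolite, before and after the log transform,
documents how much the transform improves normality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model_io import MetaboliteMatrix

__all__ = ["ScalingParameters", "log_transform", "uv_scale", "normality_report"]


class PreprocessingError(ValueError):
    pass


@dataclass(frozen=True)
class ScalingParameters:
    """Per-metabolite mean and s.d. on the log10 scale (ddof=1)."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if (self.sd <= 0).any():
            bad = self.sd.index[self.sd <= 0].tolist()
            raise PreprocessingError(f"non-positive scaling s.d. for {bad}")


def log_transform(matrix: MetaboliteMatrix, zero_policy: str = "error") -> MetaboliteMatrix:
    """Element-wise log10 with an explicit zero policy.

    ``zero_policy="error"`` (default) rejects zeros; ``"half_minimum"``
    substitutes half the metabolite's smallest positive value before the
    log.  Negative values are always a hard error and missing entries stay
    missing.
    """
    if zero_policy not in ("error", "half_minimum"):
        raise PreprocessingError(f"unknown zero_policy {zero_policy!r}")
    vals = matrix.values.to_numpy(dtype=float).copy()
    finite = np.isfinite(vals)
    if np.any(vals[finite] < 0):
        i, j = np.argwhere(finite & (vals < 0))[0]
        raise PreprocessingError(
            f"negative value at sample {matrix.values.index[i]!r}, "
            f"metabolite {matrix.values.columns[j]!r}"
        )
    zeros = finite & (vals == 0)
    if zeros.any():
        if zero_policy == "error":
            i, j = np.argwhere(zeros)[0]
            raise PreprocessingError(
                f"zero value at sample {matrix.values.index[i]!r}, metabolite "
                f"{matrix.values.columns[j]!r}; use zero_policy='half_minimum' "
                "to substitute half the smallest positive value"
            )
        for j in np.unique(np.argwhere(zeros)[:, 1]):
            col = vals[:, j]
            pos = col[np.isfinite(col) & (col > 0)]
            if len(pos) == 0:
                raise PreprocessingError(
                    f"metabolite {matrix.values.columns[j]!r} has no positive "
                    "values; cannot apply half-minimum substitution"
                )
            col[np.isfinite(col) & (col == 0)] = pos.min() / 2.0
    with np.errstate(invalid="ignore"):
        out = np.log10(vals)  # all entries now positive or NaN
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(frame, "log10")


def uv_scale(matrix: MetaboliteMatrix) -> tuple[MetaboliteMatrix, ScalingParameters]:
    """Center each metabolite to mean 0 and scale to s.d. 1 (ddof=1).

    Statistics are computed over non-missing entries only.  A metabolite
    with fewer than two values or zero variance is an error naming it;
    the caller may drop it first.
    """
    if matrix.stage_tag != "log10":
        raise PreprocessingError(
            f"uv_scale expects a log10 matrix, got {matrix.stage_tag!r}"
        )
    vals = matrix.values
    n_ok = vals.notna().sum(axis=0)
    if (n_ok < 2).any():
        raise PreprocessingError(
            f"metabolite(s) with < 2 non-missing values: "
            f"{n_ok.index[n_ok < 2].tolist()}"
        )
    mean = vals.mean(axis=0, skipna=True)
    sd = vals.std(axis=0, ddof=1, skipna=True)
    if (sd == 0).any():
        raise PreprocessingError(
            f"zero-variance metabolite(s): {sd.index[sd == 0].tolist()}; "
            "drop them before scaling"
        )
    scaled = (vals - mean) / sd
    return (
        matrix.with_values(scaled, "scaled"),
        ScalingParameters(mean=mean, sd=sd),
    )


def normality_report(
    before: MetaboliteMatrix, after: MetaboliteMatrix
) -> pd.DataFrame:
    """Shapiro-Wilk W and p per metabolite, pre- and post-log10.

    Metabolites with fewer than three non-missing values or zero range are
    reported as missing rather than erroring.
    """
    if list(before.metabolite_ids) != list(after.metabolite_ids):
        raise PreprocessingError("before/after matrices list different metabolites")

    def _shapiro(col: np.ndarray) -> tuple[float, float]:
        v = col[np.isfinite(col)]
        if len(v) < 3 or np.ptp(v) == 0:
            return (np.nan, np.nan)
        w, p = stats.shapiro(v)
        return (float(w), float(p))

    rows = []
    for met in before.metabolite_ids:
        wb, pb = _shapiro(before.values[met].to_numpy(dtype=float))
        wa, pa = _shapiro(after.values[met].to_numpy(dtype=float))
        rows.append(
            {"metabolite": met, "W_before": wb, "p_before": pb,
             "W_after": wa, "p_after": pa}
        )
    return pd.DataFrame(rows).set_index("metabolite")
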