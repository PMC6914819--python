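"""Injection-order signal-drift correction from repeat-injected pooled QCs.

GC-MS signal intensity drifts smoothly over a run (source fouling,
detector response).  Because every pooled QC injection is the same
material, its trend over injection order estimates that drift.  Per batch
and per metabolite a cubic smoothing spline is fitted to QC log10
intensity versus injection order; every sample is then rescaled by
``reference_level / fitted_drift(order)`` on the raw intensity scale, so
the correction is multiplicative and positivity-preserving.  Batches
(here: spinal-cord segments, run separately) are normalized fully
independently.

The smoothing parameter is chosen by leave-one-out cross-validation over
a fixed grid spanning near-interpolating to near-linear fits, ties broken
toward the smoother fit.  Outside the QC-covered order range the fitted
drift is held constant at its terminal value.  Metabolites with fewer
usable QC points than ``min_qc`` fall back to a constant drift at the QC
median (with a warning); with fewer than six points a straight-line fit
replaces the spline, which needs five points and would be unstable there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .data_model_io import MetaboliteMatrix, StudyDesign

__all__ = ["DriftModel", "fit_drift", "correct_drift", "qc_report"]

#: LOO-CV grid for the spline penalty; large values approach a straight line.
DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(np.logspace(-3.0, 7.0, 11))
DEFAULT_MIN_QC = 4


class DriftFitError(ValueError):
    pass


@dataclass(frozen=True)
class _MetDrift:
    """Fitted log10 drift for one (batch, metabolite)."""

    kind: str                      # "spline" | "line" | "constant"
    order_lo: float                # QC-covered injection-order range
    order_hi: float
    spline: object | None = None   # scipy BSpline when kind == "spline"
    coef: tuple[float, float] = (0.0, 0.0)  # (intercept, slope) otherwise
    lam: float | None = None

    def log10_at(self, orders: np.ndarray) -> np.ndarray:
        o = np.clip(np.asarray(orders, dtype=float), self.order_lo, self.order_hi)
        if self.kind == "spline":
            return np.asarray(self.spline(o), dtype=float)
        a, b = self.coef
        return a + b * o


@dataclass(frozen=True)
class DriftModel:
    """Per-(batch, metabolite) drift fits plus batch-wise reference levels.

    ``reference_level[(batch, met)]`` is the batch-wise median of the QC
    fitted values on the raw intensity scale; correction restores every
    sample to this common level.
    """

    fits: Mapping[tuple[str, str], _MetDrift]
    reference_level: Mapping[tuple[str, str], float]
    n_qc_points: Mapping[str, int]
    min_qc: int

    def fitted_raw(self, batch: str, metabolite: str, orders: np.ndarray) -> np.ndarray:
        return 10.0 ** self.fits[(batch, metabolite)].log10_at(orders)


def _loo_cv_lambda(x: np.ndarray, y: np.ndarray, grid) -> float:
    """Leave-one-out CV for the spline penalty; ties go to the smoother fit."""
    grid = np.sort(np.asarray(grid, dtype=float))
    if len(x) - 1 < 5:  # leave-one-out subsets too small for a cubic spline
        return float(grid[-1])
    errs = np.zeros(len(grid))
    for k, lam in enumerate(grid):
        for i in range(len(x)):
            xi = np.delete(x, i)
            yi = np.delete(y, i)
            spl = make_smoothing_spline(xi, yi, lam=lam)
            pred = float(spl(np.clip(x[i], xi[0], xi[-1])))
            errs[k] += (y[i] - pred) ** 2
    best = errs.min()
    tol = 1e-9 * max(best, np.var(y) * len(y), 1e-30)
    return float(grid[np.flatnonzero(errs <= best + tol)[-1]])


def fit_drift(
    matrix: MetaboliteMatrix,
    design: StudyDesign | None = None,
    *,
    min_qc: int = DEFAULT_MIN_QC,
    smoothing: str | float = "cv",
    lambda_grid=DEFAULT_LAMBDA_GRID,
) -> DriftModel:
    """Fit per-(batch, metabolite) smoothing-spline drift models to QCs.

    ``smoothing`` is ``"cv"`` (leave-one-out over ``lambda_grid``) or a
    fixed penalty value.  Raises if the matrix is not raw-scale or any
    batch has no QC samples.
    """
    if matrix.stage_tag != "raw":
        raise DriftFitError(f"expected raw matrix, got stage_tag={matrix.stage_tag!r}")
    design = design if design is not None else matrix.design
    table = design.table
    fits: dict[tuple[str, str], _MetDrift] = {}
    refs: dict[tuple[str, str], float] = {}
    n_qc: dict[str, int] = {}

    for batch in design.batches:
        in_batch = (table["segment"] == batch).to_numpy()
        qc = in_batch & design.is_qc()
        if not qc.any():
            raise DriftFitError(f"batch {batch!r} has no QC samples")
        n_qc[batch] = int(qc.sum())
        qc_orders_all = table.loc[qc, "injection_order"].to_numpy(dtype=float)
        qc_vals = matrix.values.loc[qc]
        for met in matrix.metabolite_ids:
            y_raw = qc_vals[met].to_numpy(dtype=float)
            ok = np.isfinite(y_raw)
            x, y = qc_orders_all[ok], np.log10(y_raw[ok])
            srt = np.argsort(x)
            x, y = x[srt], y[srt]
            if len(x) < min_qc:
                warnings.warn(
                    f"metabolite {met!r} in batch {batch!r} has only {len(x)} "
                    f"usable QC points (< min_qc={min_qc}); using constant drift "
                    "at the QC median",
                    stacklevel=2,
                )
                level = float(np.median(y)) if len(y) else np.nan
                fit = _MetDrift("constant", x.min(initial=0), x.max(initial=0),
                                coef=(level, 0.0))
            elif len(x) < 6:
                b, a = np.polyfit(x, y, 1)
                fit = _MetDrift("line", x[0], x[-1], coef=(float(a), float(b)))
            else:
                lam = (
                    _loo_cv_lambda(x, y, lambda_grid)
                    if smoothing == "cv"
                    else float(smoothing)
                )
                spl = make_smoothing_spline(x, y, lam=lam)
                fit = _MetDrift("spline", x[0], x[-1], spline=spl, lam=lam)
            fits[(batch, met)] = fit
            fitted_qc = 10.0 ** fit.log10_at(x if len(x) else qc_orders_all)
            refs[(batch, met)] = float(np.median(fitted_qc))
    return DriftModel(fits=fits, reference_level=refs, n_qc_points=n_qc, min_qc=min_qc)


def correct_drift(matrix: MetaboliteMatrix, model: DriftModel) -> MetaboliteMatrix:
    """Rescale every sample by reference_level / fitted drift at its order.

    Preserves positivity, labels and the missingness mask; raises if any
    needed fitted drift value is non-positive (a pathological fit).
    """
    if matrix.stage_tag != "raw":
        raise DriftFitError(f"expected raw matrix, got stage_tag={matrix.stage_tag!r}")
    table = matrix.design.table
    corrected = matrix.values.to_numpy(dtype=float).copy()
    for batch in matrix.design.batches:
        rows = (table["segment"] == batch).to_numpy()
        orders = table.loc[rows, "injection_order"].to_numpy(dtype=float)
        for j, met in enumerate(matrix.metabolite_ids):
            key = (batch, met)
            if key not in model.fits:
                raise DriftFitError(f"drift model has no fit for {key}")
            fitted = model.fitted_raw(batch, met, orders)
            if np.any(fitted <= 0) or not np.all(np.isfinite(fitted)):
                raise DriftFitError(
                    f"non-positive fitted drift for metabolite {met!r} in "
                    f"batch {batch!r}"
                )
            corrected[rows, j] *= model.reference_level[key] / fitted
    out = pd.DataFrame(corrected, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(out, "normalized")


def qc_report(
    before: MetaboliteMatrix,
    after: MetaboliteMatrix,
    design: StudyDesign | None = None,
) -> pd.DataFrame:
    """Per-metabolite, per-batch QC relative s.d. before/after correction.

    RSD = s.d. / mean over the batch's QC injections on the raw intensity
    scale; reported missing with fewer than two usable QC values.
    """
    design = design if design is not None else before.design
    if before.values.shape != after.values.shape:
        raise ValueError("before/after matrices have different shapes")
    table = design.table
    rows = []
    for batch in design.batches:
        qc = ((table["segment"] == batch).to_numpy()) & design.is_qc()
        for met in before.metabolite_ids:
            rec = {"segment": batch, "metabolite": met}
            for label, mat in (("rsd_before", before), ("rsd_after", after)):
                v = mat.values.loc[qc, met].to_numpy(dtype=float)
                v = v[np.isfinite(v)]
                rec[label] = (
                    float(np.std(v, ddof=1) / np.mean(v)) if len(v) >= 2 else np.nan
                )
            rows.append(rec)
    return pd.DataFrame(rows)
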