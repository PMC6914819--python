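"""Synthetic factorial GC-MS study generator with known ground truth.

Emulates the mouse spinal-cord study design: 2 genetic backgrounds
(C57, 129S) x 2 SOD1 genotypes (NTG, G93A) x 3 disease stages
(PRE, ONS, LATE), n mice per cell, measured in two analytical batches
(one per spinal-cord segment) with repeat-injected pooled QC samples and
smooth injection-order drift.

Effects are injected on the log10 scale so the downstream log transform
linearizes them and every term's variance contribution has a closed form.
A term with effect size ``e`` contributes ``+/- e/2`` cell offsets along a
fixed sign pattern (C57/NTG/PRE negative), giving a between-cell variance
of ``e**2/4`` for terms built from the two-level factors only and
``e**2/6`` for terms involving stage (whose pattern is -1, 0, +1 across
PRE, ONS, LATE).  A pure background effect ``e`` therefore shifts the
C57 - 129S mean difference by ``-e`` on the log10 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .data_model_io import (
    FACTOR_LEVELS,
    MetaboliteMatrix,
    StudyDesign,
)

__all__ = [
    "TERMS",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_study",
    "truth_variance_fractions",
    "default_study_effects",
]

#: Canonical factorial term order used everywhere downstream.
TERMS: tuple[str, ...] = (
    "genotype",
    "background",
    "stage",
    "genotype:background",
    "genotype:stage",
    "background:stage",
    "genotype:background:stage",
)

_TERM_DF = {
    "genotype": 1,
    "background": 1,
    "stage": 2,
    "genotype:background": 1,
    "genotype:stage": 2,
    "background:stage": 2,
    "genotype:background:stage": 2,
}

# Sign patterns over factor levels; first level negative by convention.
_SIGNS = {
    "background": {"C57": -1.0, "129S": 1.0},
    "genotype": {"NTG": -1.0, "G93A": 1.0},
    "stage": {"PRE": -1.0, "ONS": 0.0, "LATE": 1.0},
}

_DRIFT_FAMILIES = ("none", "linear", "cubic", "sinusoidal")


def canonical_term(term: str) -> str:
    """Normalize e.g. ``"background:genotype"`` to the canonical order."""
    parts = term.split(":")
    order = {"genotype": 0, "background": 1, "stage": 2}
    try:
        parts = sorted(set(parts), key=lambda p: order[p])
    except KeyError as exc:
        raise ValueError(f"unknown factor in term {term!r}") from exc
    return ":".join(parts)


def term_pattern(term: str, cell: Mapping[str, str]) -> float:
    """Product of sign patterns for a term at one design cell."""
    return math.prod(_SIGNS[f][cell[f]] for f in canonical_term(term).split(":"))


def term_pattern_variance(term: str) -> float:
    """Mean squared pattern value over the 12 balanced cells.

    1 for terms of two-level factors only, 2/3 for terms involving stage.
    """
    return math.prod(
        np.mean([v**2 for v in _SIGNS[f].values()])
        for f in canonical_term(term).split(":")
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated study; identical config + seed is
    bit-reproducible.

    ``effect_spec`` maps metabolite id -> {term -> effect size on the log10
    scale}; ``drift_spec`` maps segment -> (family, amplitude) where
    amplitude is the max |log10 fold change| over a batch and family is
    one of none/linear/cubic/sinusoidal.  ``qc_every`` inserts one pooled
    QC after every k study injections (plus one leading and one trailing
    QC); the pooled QC level is the grand mean of the configured cell
    means, mimicking an aliquot pooled from all study samples.
    """

    n_metabolites: int = 40
    n_per_cell: int = 5
    backgrounds: tuple[str, ...] = FACTOR_LEVELS["background"]
    genotypes: tuple[str, ...] = FACTOR_LEVELS["genotype"]
    stages: tuple[str, ...] = FACTOR_LEVELS["stage"]
    segments: tuple[str, ...] = ("lumbar", "thoracic")
    effect_spec: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    drift_spec: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: {"lumbar": ("linear", 0.05), "thoracic": ("sinusoidal", 0.05)}
    )
    qc_every: int = 5
    noise_sd: float = 0.1
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 0.5
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_metabolites <= 0 or self.n_per_cell <= 0 or self.qc_every <= 0:
            raise ValueError("n_metabolites, n_per_cell and qc_every must be positive")
        if self.noise_sd < 0 or not (0 <= self.dropout_rate < 1):
            raise ValueError("noise_sd must be >= 0 and dropout_rate in [0, 1)")
        for factor, levels in (
            ("background", self.backgrounds),
            ("genotype", self.genotypes),
            ("stage", self.stages),
        ):
            unknown = set(levels) - set(FACTOR_LEVELS[factor])
            if unknown:
                raise ValueError(f"unknown {factor} level(s) {sorted(unknown)}")
        for seg, (family, amp) in self.drift_spec.items():
            if family not in _DRIFT_FAMILIES:
                raise ValueError(f"unknown drift family {family!r} for segment {seg!r}")
            if not np.isfinite(amp):
                raise ValueError(f"non-finite drift amplitude for segment {seg!r}")
        for met, spec in self.effect_spec.items():
            for term in spec:
                canonical_term(term)  # raises on unknown factor

    @property
    def metabolite_ids(self) -> list[str]:
        return [f"m{i + 1:03d}" for i in range(self.n_metabolites)]

    def cells(self) -> list[dict[str, str]]:
        return [
            {"background": b, "genotype": g, "stage": s}
            for b in self.backgrounds
            for g in self.genotypes
            for s in self.stages
        ]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth registry for recovery tests.

    ``cell_means``: cells x metabolites log10 means (index is
    "background/genotype/stage").  ``variance_fractions``: metabolites x
    terms population fractions of total (between-cell + residual)
    variance.  ``drift_log10``: per segment, the drift offset at every
    injection order.  ``qc_log_level``: drift-free pooled-QC log10 level
    per metabolite.
    """

    cell_means: pd.DataFrame
    variance_fractions: pd.DataFrame
    drift_log10: dict[str, np.ndarray]
    qc_log_level: pd.Series
    noise_sd: float

    def expected_r2(self, n_per_cell: int) -> pd.DataFrame:
        """Finite-sample expectation of each term's ANOVA R^2 (in %).

        For a balanced design with N samples, E[SS_term] =
        df_term * sigma^2 + N * v_term and E[SS_total] =
        (N-1) * sigma^2 + N * sum(v); the ratio of expectations is the
        natural target for the mean recovered R^2 over many replicates
        (at small n the df term inflates every null R^2 above zero).
        """
        n_cells = self.cell_means.shape[0]
        n_total = n_per_cell * n_cells
        sig2 = self.noise_sd**2
        frac = self.variance_fractions
        # invert fractions back to absolute between-cell variances
        denom = (1.0 - frac.sum(axis=1)).clip(lower=1e-300)
        v = frac.mul(sig2 / denom, axis=0) if sig2 > 0 else frac * np.nan
        num = v * n_total + pd.DataFrame(
            {t: _TERM_DF[t] * sig2 for t in frac.columns}, index=frac.index
        )
        total = (n_total - 1) * sig2 + n_total * v.sum(axis=1)
        return num.div(total, axis=0) * 100.0


def _drift_function(family: str, amplitude: float) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth log10 drift over normalized run position u in [0, 1]."""
    if family == "none" or amplitude == 0:
        return lambda u: np.zeros_like(u, dtype=float)
    if family == "linear":
        return lambda u: amplitude * (2 * u - 1)
    if family == "cubic":
        # Chebyshev T3: two interior extrema, range +/- amplitude
        return lambda u: amplitude * (4 * (2 * u - 1) ** 3 - 3 * (2 * u - 1))
    if family == "sinusoidal":
        return lambda u: amplitude * np.sin(2 * np.pi * 1.5 * u)
    raise ValueError(f"unknown drift family {family!r}")


def _true_cell_means(config: SimulationConfig, baselines: np.ndarray) -> pd.DataFrame:
    cells = config.cells()
    index = pd.Index(
        ["/".join(c[f] for f in ("background", "genotype", "stage")) for c in cells],
        name="cell",
    )
    means = np.tile(baselines, (len(cells), 1))
    for j, met in enumerate(config.metabolite_ids):
        spec = config.effect_spec.get(met, {})
        for term, e in spec.items():
            for i, cell in enumerate(cells):
                means[i, j] += 0.5 * e * term_pattern(term, cell)
    return pd.DataFrame(means, index=index, columns=config.metabolite_ids)


def truth_variance_fractions(config: SimulationConfig) -> pd.DataFrame:
    """Analytic per-metabolite, per-term fraction of total variance.

    Balanced-design closed form: a term with effect size ``e`` contributes
    between-cell variance ``(e/2)**2 * m2(term)`` where ``m2`` is the mean
    squared sign pattern (1 without stage, 2/3 with); the fraction is that
    variance over the sum of all term variances plus ``noise_sd**2``.
    """
    rows = []
    for met in config.metabolite_ids:
        spec = {canonical_term(t): e for t, e in config.effect_spec.get(met, {}).items()}
        v = {t: (spec.get(t, 0.0) / 2.0) ** 2 * term_pattern_variance(t) for t in TERMS}
        total = sum(v.values()) + config.noise_sd**2
        if total == 0:
            rows.append({t: 0.0 for t in TERMS})
        else:
            rows.append({t: v[t] / total for t in TERMS})
    return pd.DataFrame(rows, index=pd.Index(config.metabolite_ids, name="metabolite"))


def simulate_study(
    config: SimulationConfig,
) -> tuple[MetaboliteMatrix, StudyDesign, SyntheticTruth]:
    """Generate one study: intensities, design and ground truth.

    Study samples are randomized to injection order within each batch;
    pooled QCs are injected first, after every ``qc_every`` study samples,
    and last, and are subject to the same drift and measurement noise.
    Intensities are ``10**(cell_mean + drift + noise)`` and strictly
    positive (before optional uniform dropout to NaN).
    """
    rng = np.random.default_rng(config.seed)
    mets = config.metabolite_ids
    baselines = rng.normal(config.baseline_log_mean, config.baseline_log_sd, len(mets))
    cell_means = _true_cell_means(config, baselines)
    qc_level = cell_means.mean(axis=0)  # pooled aliquot = grand mean
    cells = config.cells()

    design_rows: list[dict] = []
    value_rows: list[np.ndarray] = []
    drift_curves: dict[str, np.ndarray] = {}

    for seg in config.segments:
        study_cells = np.repeat(np.arange(len(cells)), config.n_per_cell)
        study_cells = rng.permutation(study_cells)
        n_study = len(study_cells)
        # interleave: QC, k study, QC, k study, ..., QC
        sequence: list[int | None] = [None]
        for i, c in enumerate(study_cells):
            sequence.append(int(c))
            if (i + 1) % config.qc_every == 0 and i + 1 < n_study:
                sequence.append(None)
        sequence.append(None)
        n_inj = len(sequence)
        u = (np.arange(n_inj, dtype=float)) / max(n_inj - 1, 1)
        family, amp = config.drift_spec.get(seg, ("none", 0.0))
        drift = _drift_function(family, amp)(u)
        drift_curves[seg] = drift

        qc_counter = 0
        study_counter = 0
        for order0, cell_idx in enumerate(sequence):
            order = order0 + 1
            if cell_idx is None:
                qc_counter += 1
                sid = f"{seg}_QC{qc_counter:02d}"
                design_rows.append(
                    dict(sample_id=sid, background="", genotype="", stage="",
                         segment=seg, injection_order=order, sample_type="QC")
                )
                log_mu = qc_level.to_numpy()
            else:
                study_counter += 1
                cell = cells[cell_idx]
                sid = f"{seg}_S{study_counter:03d}"
                design_rows.append(
                    dict(sample_id=sid, segment=seg, injection_order=order,
                         sample_type="study", **cell)
                )
                log_mu = cell_means.iloc[cell_idx].to_numpy()
            noise = rng.normal(0.0, config.noise_sd, len(mets))
            with np.errstate(over="ignore"):
                value_rows.append(10.0 ** (log_mu + drift[order0] + noise))

    values = np.asarray(value_rows)
    if not np.all(np.isfinite(values)):
        raise ValueError(
            "simulated intensities are non-finite; reduce drift amplitude, "
            "baseline or effect sizes"
        )
    if config.dropout_rate > 0:
        drop = rng.random(values.shape) < config.dropout_rate
        values = np.where(drop, np.nan, values)

    design = StudyDesign(pd.DataFrame(design_rows))
    frame = pd.DataFrame(values, index=pd.Index(design.sample_ids, name="sample_id"),
                         columns=mets)
    matrix = MetaboliteMatrix(values=frame, design=design, stage_tag="raw")
    truth = SyntheticTruth(
        cell_means=cell_means,
        variance_fractions=truth_variance_fractions(config),
        drift_log10=drift_curves,
        qc_log_level=qc_level,
        noise_sd=config.noise_sd,
    )
    return matrix, design, truth


def default_study_effects(
    n_metabolites: int = 40, seed: int = 0
) -> dict[str, dict[str, float]]:
    """Effect layout echoing the study's findings: background effects
    dominate (a handful of metabolites, moderate sizes), disease stage
    affects a few, genotype acts mostly through its interaction with
    stage, and most metabolites are null.

    Effect sizes are on the log10 scale relative to the default residual
    noise of 0.1 (so e.g. 0.2 is a 2-s.d. shift between extreme cells).
    """
    rng = np.random.default_rng(seed)
    mets = [f"m{i + 1:03d}" for i in range(n_metabolites)]
    spec: dict[str, dict[str, float]] = {}
    picks = rng.permutation(n_metabolites)
    n_bg = max(1, round(0.15 * n_metabolites))
    n_stage = max(1, round(0.10 * n_metabolites))
    n_gs = max(1, round(0.05 * n_metabolites))
    for i in picks[:n_bg]:
        spec.setdefault(mets[i], {})["background"] = float(rng.uniform(0.1, 0.3)) * float(rng.choice([-1, 1]))
    for i in picks[n_bg : n_bg + n_stage]:
        spec.setdefault(mets[i], {})["stage"] = float(rng.uniform(0.1, 0.25)) * float(rng.choice([-1, 1]))
    for i in picks[n_bg + n_stage : n_bg + n_stage + n_gs]:
        spec.setdefault(mets[i], {})["genotype:stage"] = float(rng.uniform(0.15, 0.3)) * float(rng.choice([-1, 1]))
    return spec
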