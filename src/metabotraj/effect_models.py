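"""Factorial linear models, variance partitioning, FDR and t-test tiers.

Every feature (a metabolite's log10 level, or a principal-component score
vector) is related to the three experimental factors -- SOD1 genotype,
genetic background and disease stage -- and their two- and three-way
interactions by a fixed-effects linear model with sum-to-zero (effect)
coding.  For the study's balanced 2 x 2 x 3 design with equal cell sizes
the seven term subspaces are mutually orthogonal, so each term's ANOVA
sum of squares is the squared norm of the response projected onto that
subspace and the decomposition is unique; percent variance explained is
R^2_term = SS_term / SS_total * 100.  Unbalanced data fall back to
Type-II sums of squares via statsmodels with a warning.

Multiple testing uses Benjamini-Hochberg step-up FDR.  Families are one
model term (for the per-metabolite ANOVA table) or one contrast
definition (for the t-test tables), each across metabolites.  The
two-tier significance scheme flags p <= 0.05 & FDR < 20% as significant
and p <= 0.05 & FDR < 5% as highlighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model_io import FACTOR_LEVELS, FACTORS, MetaboliteMatrix, StudyDesign
from .synthetic import TERMS, canonical_term

__all__ = [
    "TERMS",
    "EffectTable",
    "TestTable",
    "fit_factorial",
    "anova_matrix",
    "effect_table",
    "two_group_tests",
    "per_cell_scheme",
    "bh_adjust",
]


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# factorial ANOVA engine
# ---------------------------------------------------------------------------


def _sum_coded(labels: pd.Series, factor: str) -> np.ndarray:
    """Sum-to-zero coding columns (n x (L-1)) with the last level as -1."""
    levels = FACTOR_LEVELS[factor]
    idx = pd.Categorical(labels, categories=levels).codes
    if (idx < 0).any():
        raise ModelError(f"unknown {factor} level in design")
    code = np.eye(len(levels))[:, :-1]
    code[-1, :] = -1.0
    return code[idx]


def _check_cells(table: pd.DataFrame) -> np.ndarray:
    """Return per-row cell index; error on an empty design cell."""
    counts = table.groupby(list(FACTORS), observed=False).size()
    full = [
        (b, g, s)
        for b in FACTOR_LEVELS["background"]
        for g in FACTOR_LEVELS["genotype"]
        for s in FACTOR_LEVELS["stage"]
    ]
    empty = [c for c in full if counts.get(c, 0) == 0]
    if empty:
        raise ModelError(f"empty design cell(s): {empty}")
    return counts.loc[full].to_numpy()


def _term_bases(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Orthonormal basis (n x df) per factorial term, balanced designs.

    Main-effect blocks are the sum-coded columns; interaction blocks are
    elementwise products of their parents' columns.  In a balanced design
    all blocks have zero column means and are mutually orthogonal, so a
    per-block QR gives projectors whose squared projections are the
    classical ANOVA sums of squares.
    """
    mains = {f: _sum_coded(table[f], f) for f in FACTORS}
    bases: dict[str, np.ndarray] = {}
    for term in TERMS:
        parts = term.split(":")
        block = mains[parts[0]]
        for p in parts[1:]:
            block = np.concatenate(
                [block[:, [i]] * mains[p] for i in range(block.shape[1])], axis=1
            )
        q, r = np.linalg.qr(block)
        keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1.0)
        bases[term] = q[:, keep]
    return bases


def _is_balanced(cell_counts: np.ndarray) -> bool:
    return bool(np.all(cell_counts == cell_counts[0]))


def anova_matrix(Y: np.ndarray, design_table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Vectorized balanced factorial ANOVA over feature columns.

    ``Y`` is samples x features (complete); returns arrays of shape
    (n_terms + 1, n_features) for ``ss`` (residual last), plus per-term
    ``F`` and ``p`` and the scalar ``df`` vector.  Exact for balanced
    designs (orthogonal term subspaces).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    cell_counts = _check_cells(design_table)
    if not _is_balanced(cell_counts):
        raise ModelError("anova_matrix requires a balanced design")
    bases = _term_bases(design_table)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    ss_total = np.sum(Yc**2, axis=0)
    ss_terms = np.array([np.sum((bases[t].T @ Yc) ** 2, axis=0) for t in TERMS])
    df_terms = np.array([bases[t].shape[1] for t in TERMS])
    ss_res = np.clip(ss_total - ss_terms.sum(axis=0), 0.0, None)
    df_res = n - 1 - int(df_terms.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_res = ss_res / df_res
        F = (ss_terms / df_terms[:, None]) / ms_res
        p = stats.f.sf(F, df_terms[:, None], df_res)
    return {
        "ss": np.vstack([ss_terms, ss_res]),
        "ss_total": ss_total,
        "df": np.append(df_terms, df_res),
        "F": F,
        "p": p,
    }


def _fit_unbalanced(y: np.ndarray, table: pd.DataFrame) -> pd.DataFrame:
    """Type-II ANOVA via statsmodels for unbalanced designs."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    warnings.warn(
        "unbalanced design: reporting Type-II sums of squares "
        "(terms no longer partition the total variance exactly)",
        stacklevel=3,
    )
    df = table[list(FACTORS)].copy()
    df["y"] = y
    formula = (
        "y ~ C(genotype, Sum) * C(background, Sum) * C(stage, Sum)"
    )
    fit = smf.ols(formula, data=df).fit()
    tab = anova_lm(fit, typ=2)
    rename = {}
    for name in tab.index:
        inner = [p.split(",")[0].replace("C(", "").strip() for p in name.split(":")]
        if all(i in FACTORS for i in inner):
            rename[name] = canonical_term(":".join(inner))
    tab = tab.rename(index=rename)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    rows = []
    for term in TERMS:
        r = tab.loc[term]
        rows.append(
            dict(term=term, sum_sq=float(r["sum_sq"]), df=int(r["df"]),
                 F=float(r["F"]), p=float(r["PR(>F)"]),
                 percent_variance=100.0 * float(r["sum_sq"]) / ss_total)
        )
    res = tab.loc["Residual"]
    rows.append(
        dict(term="residual", sum_sq=float(res["sum_sq"]), df=int(res["df"]),
             F=np.nan, p=np.nan,
             percent_variance=100.0 * float(res["sum_sq"]) / ss_total)
    )
    return pd.DataFrame(rows).set_index("term")


def fit_factorial(y: np.ndarray | pd.Series, design: StudyDesign) -> pd.DataFrame:
    """Factorial ANOVA of one response against the 7-term model.

    Returns a frame indexed by term (plus ``residual``) with columns
    ``sum_sq, df, percent_variance, F, p``.  The same engine serves
    metabolite levels and PC scores.  Zero total variance yields all-zero
    terms with residual 100%.
    """
    table = design.table
    study = design.is_study()
    if not study.all():
        table = table.loc[study]
        y = np.asarray(y, dtype=float)[study]
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != len(table):
        raise ModelError(f"response length {len(y)} != design rows {len(table)}")
    if not np.all(np.isfinite(y)):
        raise ModelError("response contains missing values; complete data required")
    cell_counts = _check_cells(table)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total == 0.0:
        df_t = {
            t: int(np.prod([len(FACTOR_LEVELS[f]) - 1 for f in t.split(":")]))
            for t in TERMS
        }
        rows = [dict(term=t, sum_sq=0.0, df=df_t[t], percent_variance=0.0,
                     F=np.nan, p=np.nan) for t in TERMS]
        rows.append(dict(term="residual", sum_sq=0.0,
                         df=len(y) - 1 - sum(df_t.values()),
                         percent_variance=100.0, F=np.nan, p=np.nan))
        return pd.DataFrame(rows).set_index("term")
    if not _is_balanced(cell_counts):
        return _fit_unbalanced(y, table)
    res = anova_matrix(y, table)
    rows = []
    for i, term in enumerate(TERMS):
        rows.append(
            dict(term=term, sum_sq=float(res["ss"][i, 0]), df=int(res["df"][i]),
                 percent_variance=100.0 * float(res["ss"][i, 0]) / ss_total,
                 F=float(res["F"][i, 0]), p=float(res["p"][i, 0]))
        )
    rows.append(
        dict(term="residual", sum_sq=float(res["ss"][-1, 0]), df=int(res["df"][-1]),
             percent_variance=100.0 * float(res["ss"][-1, 0]) / ss_total,
             F=np.nan, p=np.nan)
    )
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    Missing entries are excluded from the family and reinserted as NaN;
    values outside [0, 1] are an error.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ModelError("p-values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# per-metabolite effect table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectTable:
    """Long-format per-(feature, term) ANOVA results with FDR.

    Columns: ``sum_sq, df, percent_variance, F, p, p_fdr, significant,
    ok``; BH is applied separately within each model term across
    features, and ``significant`` marks p_fdr <= 0.05.
    """

    table: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def wide_r2(self, significant_only: bool = False) -> pd.DataFrame:
        """Features x terms percent-variance matrix (heatmap-ready)."""
        t = self.table[self.table["term"] != "residual"]
        if significant_only:
            keep = t.groupby("feature")["significant"].any()
            t = t[t["feature"].isin(keep.index[keep])]
        return t.pivot(index="feature", columns="term", values="percent_variance")[
            list(TERMS)
        ]


def effect_table(matrix: MetaboliteMatrix, design: StudyDesign | None = None) -> EffectTable:
    """Fit the factorial model to every metabolite and BH-adjust per term.

    Metabolites whose fit fails (missing values, degenerate data) are kept
    as flagged rows (``ok=False``) rather than aborting the table.
    """
    design = design if design is not None else matrix.design
    study = design.is_study()
    table = design.table.loc[study]
    Y = matrix.values.loc[study].to_numpy(dtype=float)
    complete = np.all(np.isfinite(Y), axis=0)
    try:
        counts = _check_cells(table)
        balanced = _is_balanced(counts)
    except ModelError:
        raise  # empty cell invalidates every fit identically
    rows: list[dict] = []
    if balanced and complete.any():
        # one projection per term for all complete metabolites at once
        res = anova_matrix(Y[:, complete], table)
        mets = [m for m, c in zip(matrix.metabolite_ids, complete) if c]
        ss_total = np.where(res["ss_total"] > 0, res["ss_total"], np.nan)
        for i, term in enumerate((*TERMS, "residual")):
            is_res = term == "residual"
            ss = res["ss"][i]
            pct = np.where(
                np.isnan(ss_total), 100.0 if is_res else 0.0, 100.0 * ss / ss_total
            )
            for j, met in enumerate(mets):
                rows.append(
                    dict(feature=met, term=term, sum_sq=ss[j],
                         df=int(res["df"][i]), percent_variance=float(pct[j]),
                         F=np.nan if is_res else float(res["F"][i, j]),
                         p=np.nan if is_res else float(res["p"][i, j]), ok=True)
                )
    for j, met in enumerate(matrix.metabolite_ids):
        if balanced and complete[j]:
            continue
        try:
            fit = fit_factorial(Y[:, j], design.subset(study))
            for term, r in fit.iterrows():
                rows.append(
                    dict(feature=met, term=term, sum_sq=r["sum_sq"], df=r["df"],
                         percent_variance=r["percent_variance"], F=r["F"],
                         p=r["p"], ok=True)
                )
        except ModelError:
            for term in (*TERMS, "residual"):
                rows.append(
                    dict(feature=met, term=term, sum_sq=np.nan, df=np.nan,
                         percent_variance=np.nan, F=np.nan, p=np.nan, ok=False)
                )
    tab = pd.DataFrame(rows)
    order = {m: i for i, m in enumerate(matrix.metabolite_ids)}
    term_order = {t: i for i, t in enumerate((*TERMS, "residual"))}
    tab = tab.sort_values(
        ["feature", "term"],
        key=lambda s: s.map(order) if s.name == "feature" else s.map(term_order),
        kind="stable",
    ).reset_index(drop=True)
    tab["p_fdr"] = np.nan
    for term in TERMS:
        sel = tab["term"] == term
        tab.loc[sel, "p_fdr"] = bh_adjust(tab.loc[sel, "p"].to_numpy())
    tab["significant"] = tab["p_fdr"] <= 0.05
    return EffectTable(tab)


# ---------------------------------------------------------------------------
# two-group t-test tiers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TestTable:
    """Per-(feature, contrast) two-group t-test results with FDR tiers.

    ``sig_fdr20`` is the study's significance tier (p <= 0.05 and
    FDR < 20%); ``sig_fdr5`` the highlighted tier (p <= 0.05, FDR < 5%).
    """

    table: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.table


def per_cell_scheme() -> dict[str, tuple[dict, dict]]:
    """NTG vs G93A within each (background, stage): 2 x 3 = 6 contrasts."""
    scheme = {}
    for b in FACTOR_LEVELS["background"]:
        for s in FACTOR_LEVELS["stage"]:
            scheme[f"{b}-{s}:NTG_vs_G93A"] = (
                {"background": b, "stage": s, "genotype": "NTG"},
                {"background": b, "stage": s, "genotype": "G93A"},
            )
    return scheme


def _select(table: pd.DataFrame, selector: Mapping[str, str | Sequence[str]]) -> np.ndarray:
    mask = (table["sample_type"] == "study").to_numpy()
    for factor, levels in selector.items():
        if factor not in table.columns:
            raise ModelError(f"unknown design column {factor!r} in contrast selector")
        levels = [levels] if isinstance(levels, str) else list(levels)
        mask &= table[factor].isin(levels).to_numpy()
    return mask


def two_group_tests(
    matrix: MetaboliteMatrix,
    design: StudyDesign | None = None,
    scheme: str | Mapping[str, tuple[Mapping, Mapping]] = "per_cell",
    welch: bool = False,
) -> TestTable:
    """Student's t-tests for a family of two-group contrasts.

    ``scheme`` is ``"per_cell"`` (NTG vs G93A within each background x
    stage cell) or a mapping of contrast name -> (selector_a, selector_b),
    each selector a dict of design columns to level(s) -- e.g. all C57 vs
    all 129S mice.  Classical pooled-variance t by default; ``welch=True``
    drops the equal-variance assumption.  BH runs within each contrast
    across metabolites; groups with n < 2 are flagged untestable.
    """
    design = design if design is not None else matrix.design
    table = design.table
    if scheme == "per_cell":
        scheme = per_cell_scheme()
    elif isinstance(scheme, str):
        raise ModelError(f"unknown scheme {scheme!r}")
    rows = []
    for name, (sel_a, sel_b) in scheme.items():
        mask_a, mask_b = _select(table, sel_a), _select(table, sel_b)
        if (mask_a & mask_b).any():
            raise ModelError(f"contrast {name!r}: overlapping groups")
        for met in matrix.metabolite_ids:
            v = matrix.values[met].to_numpy(dtype=float)
            a = v[mask_a]
            b = v[mask_b]
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            rec = dict(feature=met, contrast=name,
                       mean_a=float(np.mean(a)) if len(a) else np.nan,
                       mean_b=float(np.mean(b)) if len(b) else np.nan,
                       n_a=len(a), n_b=len(b))
            if len(a) < 2 or len(b) < 2:
                rec.update(t=np.nan, p=np.nan, testable=False)
            else:
                t, p = stats.ttest_ind(a, b, equal_var=not welch)
                rec.update(t=float(t), p=float(p), testable=True)
            rows.append(rec)
    tab = pd.DataFrame(rows)
    tab["p_fdr"] = np.nan
    for name in scheme:
        sel = tab["contrast"] == name
        tab.loc[sel, "p_fdr"] = bh_adjust(tab.loc[sel, "p"].to_numpy())
    tab["sig_fdr20"] = (tab["p"] <= 0.05) & (tab["p_fdr"] < 0.20)
    tab["sig_fdr5"] = (tab["p"] <= 0.05) & (tab["p_fdr"] < 0.05)
    return TestTable(tab)
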