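"""Independent reference implementations used only by the tests.

Each oracle computes its quantity from first principles (group means,
step-up definition, covariance eigendecomposition) so the package code
paths are checked against something they do not share.
"""

from __future__ import annotations


import numpy as np
import pandas as pd
from scipy import stats

from metabotraj.data_model_io import FACTOR_LEVELS, StudyDesign
from metabotraj.synthetic import TERMS

FACTORS = ("genotype", "background", "stage")


def make_balanced_design(n_per_cell: int, segment: str = "lumbar") -> StudyDesign:
    """Study-only balanced 2x2x3 design with sequential injection order."""
    rows = []
    order = 1
    for b in FACTOR_LEVELS["background"]:
        for g in FACTOR_LEVELS["genotype"]:
            for s in FACTOR_LEVELS["stage"]:
                for _ in range(n_per_cell):
                    rows.append(
                        dict(sample_id=f"s{order:03d}", background=b, genotype=g,
                             stage=s, segment=segment, injection_order=order,
                             sample_type="study")
                    )
                    order += 1
    return StudyDesign(pd.DataFrame(rows))


def anova_oracle(y: np.ndarray, table: pd.DataFrame) -> pd.DataFrame:
    """Factorial ANOVA sums of squares from cell and marginal means.

    Brute force for balanced designs: each term's SS is the count-weighted
    sum of squared effects obtained by subtracting all lower-order means
    (the classical decomposition), residual SS from within-cell scatter.
    """
    y = np.asarray(y, dtype=float)
    df = table[list(FACTORS)].copy()
    df["y"] = y
    grand = y.mean()

    def means(by):
        return df.groupby(list(by), observed=False)["y"].mean()

    def counts(by):
        return df.groupby(list(by), observed=False)["y"].size()

    effects: dict[tuple, pd.Series] = {}
    for k in (1, 2, 3):
        for combo in [c for c in _combos(k)]:
            m = means(combo)
            eff = m - grand
            # subtract every strictly contained lower-order effect
            for sub_k in range(1, k):
                for sub in _combos(sub_k):
                    if set(sub) <= set(combo):
                        sub_eff = effects[sub]
                        aligned = _broadcast(sub_eff, m.index, combo, sub)
                        eff = eff - aligned
            effects[combo] = eff

    rows = {}
    for combo, eff in effects.items():
        n = counts(combo)
        term = ":".join([f for f in FACTORS if f in combo])
        rows[term] = float((n * eff**2).sum())
    cell_mean = means(FACTORS)
    keyed = df.set_index(list(FACTORS))
    resid = keyed["y"] - cell_mean.reindex(keyed.index)
    ss_res = float((resid**2).sum())
    out = pd.DataFrame(
        {"sum_sq": [rows[t] for t in TERMS] + [ss_res]},
        index=[*TERMS, "residual"],
    )
    df_terms = [
        int(np.prod([len(FACTOR_LEVELS[f]) - 1 for f in t.split(":")])) for t in TERMS
    ]
    n_total = len(y)
    out["df"] = df_terms + [n_total - 1 - sum(df_terms)]
    ms_res = ss_res / out.loc["residual", "df"]
    out["F"] = out["sum_sq"] / out["df"] / ms_res
    out.loc["residual", "F"] = np.nan
    out["p"] = stats.f.sf(out["F"], out["df"], out.loc["residual", "df"])
    return out


def _combos(k: int):
    from itertools import combinations

    return list(combinations(FACTORS, k))


def _broadcast(sub_eff: pd.Series, index: pd.Index, combo, sub) -> np.ndarray:
    pos = [combo.index(f) for f in sub]
    keys = [
        (tuple(ix[p] for p in pos) if len(pos) > 1 else ix[pos[0]])
        for ix in index
    ]
    return np.asarray([sub_eff.loc[k] for k in keys])


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def pooled_t_oracle(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Classical pooled-variance two-sided Student's t from the formula."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return float(t), float(p)


def pca_eigen_oracle(X: np.ndarray):
    """Explained fractions and loadings from the covariance eigendecomposition."""
    Xc = X - X.mean(axis=0, keepdims=True)
    C = Xc.T @ Xc / (len(X) - 1)
    w, V = np.linalg.eigh(C)
    idx = np.argsort(w)[::-1]
    w, V = np.clip(w[idx], 0, None), V[:, idx]
    frac = w / w.sum()
    return frac, V
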