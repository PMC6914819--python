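"""PCA, per-PC factor attribution, and disease-stage trajectories.

PCA on the scaled matrix summarizes the metabolome in orthogonal
components.  Each PC's score vector is decomposed against the factorial
model (shared engine with the per-metabolite ANOVA) to show which
experimental factors drive it -- in the study this is what exposes PC1 as
residual-dominated and directs attention to later components.  Group mean
scores (one group per background x genotype combination) across the three
disease stages trace a metabolic trajectory; translating each group's
presymptomatic mean to the origin ("alignment") isolates the direction
and magnitude of the disease response from baseline differences, and the
segment-angle / path-length-ratio summary quantifies how similar two
groups' responses are.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model_io import FACTOR_LEVELS, MetaboliteMatrix, StudyDesign
from .effect_models import fit_factorial
from .synthetic import TERMS

__all__ = [
    "PCAModel",
    "TrajectorySet",
    "GeometrySummary",
    "fit_pca",
    "pc_variance_attribution",
    "build_trajectories",
    "align_trajectories",
    "trajectory_geometry",
]

_STAGES = FACTOR_LEVELS["stage"]


class PCAError(ValueError):
    pass


@dataclass(frozen=True)
class PCAModel:
    """SVD-based PCA fit.

    ``loadings``: metabolites x K orthonormal; ``scores``: samples x K
    with ``scores = X @ loadings``; ``explained_fraction``: each PC's
    share of the total variance (Frobenius norm) of the scaled matrix.
    Sign convention: each loading vector's largest-magnitude element is
    positive, making component signs reproducible.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_fraction: np.ndarray

    @property
    def K(self) -> int:
        return self.loadings.shape[1]


def fit_pca(matrix: MetaboliteMatrix, K: int | None = None) -> PCAModel:
    """Fit PCA to a complete scaled matrix via SVD.

    ``K`` defaults to min(n - 1, p).  Missing values are an error: impute
    or drop in preprocessing first.
    """
    if matrix.stage_tag != "scaled":
        raise PCAError(f"fit_pca expects a scaled matrix, got {matrix.stage_tag!r}")
    X = matrix.values.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise PCAError(
            "matrix contains missing values; resolve them in preprocessing "
            "before PCA"
        )
    n, p = X.shape
    kmax = min(n - 1, p)
    K = kmax if K is None else int(K)
    if not (1 <= K <= kmax):
        raise PCAError(f"K must be in [1, {kmax}], got {K}")
    Xc = X - X.mean(axis=0, keepdims=True)  # scaled data is centered already
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt[:K].T
    # deterministic signs: largest-|loading| element positive per component
    for k in range(K):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    scores = Xc @ V
    total = float(np.sum(Xc**2))
    frac = (s[:K] ** 2) / total if total > 0 else np.zeros(K)
    pcs = [f"PC{k + 1}" for k in range(K)]
    return PCAModel(
        loadings=pd.DataFrame(V, index=matrix.values.columns, columns=pcs),
        scores=pd.DataFrame(scores, index=matrix.values.index, columns=pcs),
        explained_fraction=frac,
    )


def pc_variance_attribution(model: PCAModel, design: StudyDesign) -> pd.DataFrame:
    """Percent of each PC's score variance attributed to each model term.

    Fits the 7-term factorial model to every PC's scores (study samples
    only) with the same engine used for metabolite levels; rows per PC
    sum to 100% including the residual.  The table guides PC selection
    for trajectory plots (components dominated by the residual carry no
    design signal).
    """
    rows = []
    for pc in model.scores.columns:
        fit = fit_factorial(model.scores[pc].to_numpy(), design)
        rec = {"pc": pc}
        rec.update(fit["percent_variance"].to_dict())
        rec["p_" + "min"] = float(np.nanmin(fit["p"].to_numpy()))
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("pc")
    return out[[*TERMS, "residual", "p_min"]]


@dataclass(frozen=True)
class TrajectorySet:
    """Per-group, per-stage mean +/- s.e.m. scores on selected PCs.

    ``table`` is indexed by (group, stage) with one ``mean_<pc>`` and
    ``sem_<pc>`` column per selected PC plus ``n``; groups are
    "background-genotype" labels.  ``aligned`` marks trajectories
    translated so each group's PRE mean sits at the origin.
    """

    table: pd.DataFrame
    pcs: tuple[str, ...]
    aligned: bool = False

    def to_frame(self) -> pd.DataFrame:
        out = self.table.reset_index()
        out["aligned"] = self.aligned
        return out.set_index(["group", "stage"])

    def group_means(self, group: str) -> np.ndarray:
        """Stage-ordered (n_stages x n_pcs) mean matrix for one group."""
        sub = self.table.xs(group, level="group")
        return sub.loc[list(_STAGES), [f"mean_{pc}" for pc in self.pcs]].to_numpy()

    @property
    def groups(self) -> list[str]:
        return sorted(self.table.index.get_level_values("group").unique())


def build_trajectories(
    model: PCAModel, design: StudyDesign, pcs: Sequence[int | str]
) -> TrajectorySet:
    """Group-mean stage trajectories on the selected PCs.

    ``pcs`` are 1-based component indices or "PC<k>" labels.  Every
    (background-genotype group, stage) cell must be non-empty; s.e.m. is
    s.d./sqrt(n) with the per-cell n.
    """
    pc_labels = tuple(p if isinstance(p, str) else f"PC{p}" for p in pcs)
    missing = [p for p in pc_labels if p not in model.scores.columns]
    if missing:
        raise PCAError(f"PC(s) {missing} not in fitted model (K={model.K})")
    table = design.table
    study = design.is_study()
    scores = model.scores.loc[study, list(pc_labels)]
    meta = table.loc[study]
    rows = []
    for b in FACTOR_LEVELS["background"]:
        for g in FACTOR_LEVELS["genotype"]:
            group = f"{b}-{g}"
            for s in _STAGES:
                sel = (
                    (meta["background"] == b)
                    & (meta["genotype"] == g)
                    & (meta["stage"] == s)
                ).to_numpy()
                if not sel.any():
                    raise PCAError(f"empty trajectory cell: group {group}, stage {s}")
                sub = scores.loc[sel]
                n = len(sub)
                rec = {"group": group, "stage": s, "n": n}
                for pc in pc_labels:
                    rec[f"mean_{pc}"] = float(sub[pc].mean())
                    rec[f"sem_{pc}"] = (
                        float(sub[pc].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
                    )
                rows.append(rec)
    tab = pd.DataFrame(rows).set_index(["group", "stage"])
    return TrajectorySet(table=tab, pcs=pc_labels, aligned=False)


def align_trajectories(t: TrajectorySet) -> TrajectorySet:
    """Translate each group so its PRE mean sits exactly at the origin.

    A per-group translation: s.e.m. and all within-group segment vectors
    are unchanged; no rescaling is applied.  Idempotent.
    """
    if "PRE" not in t.table.index.get_level_values("stage"):
        raise PCAError("alignment requires the PRE stage")
    tab = t.table.copy()
    mean_cols = [f"mean_{pc}" for pc in t.pcs]
    for group in t.groups:
        pre = tab.loc[(group, "PRE"), mean_cols].to_numpy(dtype=float)
        tab.loc[group, mean_cols] = tab.loc[group, mean_cols].to_numpy() - pre
    return replace(t, table=tab, aligned=True)


@dataclass(frozen=True)
class GeometrySummary:
    """Descriptive geometry of stage trajectories.

    ``segments``: per group, the stage-to-stage displacement vectors and
    their Euclidean lengths plus the total path length.  ``pairs``: per
    requested group pair, the angle (degrees) between corresponding
    segments and the path-length ratio (first/second), the scalar
    enlargement diagnostic.
    """

    segments: pd.DataFrame
    pairs: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.pairs


def _segments(t: TrajectorySet, group: str) -> np.ndarray:
    m = t.group_means(group)
    return np.diff(m, axis=0)  # (ONS-PRE, LATE-ONS)


def trajectory_geometry(
    t: TrajectorySet, group_pairs: Sequence[tuple[str, str]] | None = None
) -> GeometrySummary:
    """Segment vectors, lengths, inter-group angles and length ratios.

    Angles come from the arccos of the normalized dot product of
    corresponding segments in the selected-PC subspace; a zero-length
    segment yields a missing angle for that pair.
    """
    seg_names = [f"{a}->{b}" for a, b in zip(_STAGES[:-1], _STAGES[1:])]
    seg_rows = []
    segs: dict[str, np.ndarray] = {}
    for group in t.groups:
        v = _segments(t, group)
        segs[group] = v
        lengths = np.linalg.norm(v, axis=1)
        for name, vec, ln in zip(seg_names, v, lengths):
            seg_rows.append(
                {"group": group, "segment": name, "length": float(ln),
                 **{f"d_{pc}": float(x) for pc, x in zip(t.pcs, vec)}}
            )
        seg_rows.append(
            {"group": group, "segment": "total_path", "length": float(lengths.sum()),
             **{f"d_{pc}": np.nan for pc in t.pcs}}
        )
    if group_pairs is None:
        groups = t.groups
        group_pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    pair_rows = []
    for a, b in group_pairs:
        if a not in segs or b not in segs:
            raise PCAError(f"unknown group in pair ({a!r}, {b!r})")
        va, vb = segs[a], segs[b]
        len_a = np.linalg.norm(va, axis=1)
        len_b = np.linalg.norm(vb, axis=1)
        path_a, path_b = float(len_a.sum()), float(len_b.sum())
        for name, u, v, lu, lv in zip(seg_names, va, vb, len_a, len_b):
            if lu == 0 or lv == 0:
                angle = np.nan
            else:
                # atan2 form of arccos(u.v / |u||v|): stable near 0 and 180
                dot = float(np.dot(u, v))
                sin2 = max(float(np.dot(u, u)) * float(np.dot(v, v)) - dot * dot, 0.0)
                angle = float(np.degrees(np.arctan2(np.sqrt(sin2), dot)))
            pair_rows.append(
                {"group_a": a, "group_b": b, "segment": name,
                 "angle_deg": angle,
                 "path_length_ratio": path_a / path_b if path_b > 0 else np.nan}
            )
    return GeometrySummary(
        segments=pd.DataFrame(seg_rows), pairs=pd.DataFrame(pair_rows)
    )
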