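"""Core data model and tabular I/O for the spinal-cord metabolomics pipeline.

Two containers travel through every stage: :class:`StudyDesign`, the
per-sample factor labels of the 2 background x 2 genotype x 3 stage mouse
study (plus batch/segment, injection order and the study/QC flag), and
:class:`MetaboliteMatrix`, the samples x metabolites relative-abundance
table tied to that design.  Missing values are a first-class NaN mask that
is carried, never silently zero-filled, through the whole pipeline.

Readers validate hard: duplicate ids, unknown factor levels and non-numeric
cells are errors, not coercions.  Writers emit plain CSV that round-trips
to 12 significant digits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FACTOR_LEVELS",
    "FACTORS",
    "STAGE_ORDER",
    "StudyDesign",
    "MetaboliteMatrix",
    "read_metabolite_table",
    "read_design",
    "write_table",
    "read_table",
]

#: Fixed factor level order; determines contrast signs and label order
#: everywhere downstream (C57 < 129S, NTG < G93A, PRE < ONS < LATE).
FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "background": ("C57", "129S"),
    "genotype": ("NTG", "G93A"),
    "stage": ("PRE", "ONS", "LATE"),
}
FACTORS: tuple[str, ...] = ("background", "genotype", "stage")
STAGE_ORDER: tuple[str, ...] = FACTOR_LEVELS["stage"]

_DESIGN_COLUMNS = (
    "sample_id",
    "background",
    "genotype",
    "stage",
    "segment",
    "injection_order",
    "sample_type",
)
_SAMPLE_TYPES = ("study", "QC")

#: Processing states a matrix moves through, in pipeline order.
_STAGE_TAGS = ("raw", "normalized", "log10", "scaled")


class DataModelError(ValueError):
    """Malformed input table or violated data-model invariant."""


@dataclass(frozen=True)
class StudyDesign:
    """Per-sample metadata of a factorial GC-MS study.

    ``table`` has one row per sample with the columns
    ``sample_id, background, genotype, stage, segment, injection_order,
    sample_type``.  Study samples carry all three factor labels; pooled-QC
    samples carry none (empty string).  ``segment`` doubles as the
    analytical batch id (the study ran one batch per spinal-cord segment),
    and ``injection_order`` is unique within a batch.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _DESIGN_COLUMNS if c not in t.columns]
        if missing:
            raise DataModelError(f"design table missing required columns: {missing}")
        if t["sample_id"].duplicated().any():
            dup = sorted(t.loc[t["sample_id"].duplicated(), "sample_id"].unique())
            raise DataModelError(f"duplicate sample_id values: {dup}")
        bad_type = ~t["sample_type"].isin(_SAMPLE_TYPES)
        if bad_type.any():
            raise DataModelError(
                "unknown sample_type in rows "
                f"{t.index[bad_type].tolist()}: expected one of {_SAMPLE_TYPES}"
            )
        study = t[t["sample_type"] == "study"]
        for factor, levels in FACTOR_LEVELS.items():
            bad = ~study[factor].isin(levels)
            if bad.any():
                offending = study.loc[bad, ["sample_id", factor]]
                raise DataModelError(
                    f"unknown {factor} level(s) "
                    f"{sorted(offending[factor].unique())} in samples "
                    f"{offending['sample_id'].tolist()} (allowed: {levels})"
                )
        order = pd.to_numeric(t["injection_order"], errors="coerce")
        if order.isna().any() or (order <= 0).any() or (order != order.round()).any():
            raise DataModelError("injection_order must be positive integers")
        for batch, grp in t.groupby("segment"):
            if grp["injection_order"].duplicated().any():
                raise DataModelError(
                    f"duplicate injection_order within batch {batch!r}"
                )
        object.__setattr__(self, "table", t.reset_index(drop=True))

    # -- convenience views -------------------------------------------------

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    @property
    def n_samples(self) -> int:
        return len(self.table)

    @property
    def batches(self) -> list[str]:
        return sorted(self.table["segment"].unique())

    def is_study(self) -> np.ndarray:
        return (self.table["sample_type"] == "study").to_numpy()

    def is_qc(self) -> np.ndarray:
        return (self.table["sample_type"] == "QC").to_numpy()

    def study_groups(self) -> pd.DataFrame:
        """Group sizes of the (background, genotype, stage) cells."""
        study = self.table[self.table["sample_type"] == "study"]
        return (
            study.groupby(list(FACTORS), observed=True)
            .size()
            .rename("n")
            .reset_index()
        )

    def subset(self, mask: np.ndarray) -> "StudyDesign":
        return StudyDesign(self.table.loc[np.asarray(mask)].reset_index(drop=True))


@dataclass(frozen=True)
class MetaboliteMatrix:
    """Samples x metabolites relative-abundance matrix with its design.

    ``values`` is indexed by sample_id with metabolite ids as columns;
    NaN marks a missing measurement.  ``stage_tag`` records the processing
    state: raw -> normalized -> log10 -> scaled.
    """

    values: pd.DataFrame
    design: StudyDesign
    stage_tag: str = "raw"

    def __post_init__(self) -> None:
        if self.stage_tag not in _STAGE_TAGS:
            raise DataModelError(
                f"unknown stage_tag {self.stage_tag!r}; expected one of {_STAGE_TAGS}"
            )
        if len(self.values) != self.design.n_samples:
            raise DataModelError(
                f"matrix has {len(self.values)} rows but design has "
                f"{self.design.n_samples} samples"
            )
        if not self.values.index.equals(pd.Index(self.design.sample_ids)):
            raise DataModelError("matrix row index does not match design sample_ids")
        if self.values.columns.duplicated().any():
            raise DataModelError("duplicate metabolite ids")
        vals = self.values.to_numpy(dtype=float)
        if self.stage_tag in ("raw", "normalized"):
            # zeros are tolerated here (an integrated peak can be empty) and
            # resolved explicitly by the log-transform zero policy
            with np.errstate(invalid="ignore"):
                if np.any(vals[~np.isnan(vals)] < 0):
                    raise DataModelError(
                        f"{self.stage_tag} matrix contains negative values; "
                        "mark unusable measurements as missing instead"
                    )

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def with_values(self, values: pd.DataFrame, stage_tag: str) -> "MetaboliteMatrix":
        return MetaboliteMatrix(values=values, design=self.design, stage_tag=stage_tag)

    def subset_samples(self, mask: np.ndarray) -> "MetaboliteMatrix":
        mask = np.asarray(mask)
        return MetaboliteMatrix(
            values=self.values.loc[mask].copy(),
            design=self.design.subset(mask),
            stage_tag=self.stage_tag,
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","


def _to_float_frame(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    """Convert str cells to float; blank -> NaN; anything else -> error."""
    out = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        raw = df[col].astype("string")
        stripped = raw.str.strip()
        blank = stripped.isna() | (stripped == "")
        converted = pd.to_numeric(stripped.mask(blank), errors="coerce")
        bad = converted.isna() & ~blank
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataModelError(
                f"{path}: non-numeric value {raw.iloc[i]!r} at row "
                f"{df.index[i]!r}, column {col!r}"
            )
        out[:, j] = converted.to_numpy(dtype=float)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def read_metabolite_table(
    path: str | Path, orientation: str = "samples_as_rows"
) -> pd.DataFrame:
    """Read a delimited intensity table into a samples x metabolites frame.

    ``orientation`` is ``"samples_as_rows"`` (default) or
    ``"metabolites_as_rows"`` (the file is transposed on read so both
    orientations yield identical frames).  Blank cells become NaN; any
    other non-numeric cell is a hard error naming its row and column.
    The result carries no design; pair it with :func:`read_design` via
    :class:`MetaboliteMatrix`.
    """
    path = Path(path)
    if orientation not in ("samples_as_rows", "metabolites_as_rows"):
        raise DataModelError(f"unknown orientation {orientation!r}")
    sep = _sniff_delimiter(path)
    with open(path) as fh:
        header = [t.strip() for t in fh.readline().rstrip("\r\n").split(sep)][1:]
    dup_header = pd.Index(header)[pd.Index(header).duplicated()]
    if len(dup_header):  # pandas would silently rename these
        raise DataModelError(
            f"{path}: duplicate column ids {sorted(set(dup_header))}"
        )
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if orientation == "metabolites_as_rows":
        df = df.T
    if df.index.duplicated().any():
        raise DataModelError(
            f"{path}: duplicate sample ids "
            f"{sorted(df.index[df.index.duplicated()].unique())}"
        )
    if df.columns.duplicated().any():
        raise DataModelError(
            f"{path}: duplicate metabolite ids "
            f"{sorted(df.columns[df.columns.duplicated()].unique())}"
        )
    df.index.name = "sample_id"
    return _to_float_frame(df, path)


def read_design(path: str | Path) -> StudyDesign:
    """Read and validate a sample metadata table.

    Required columns: ``sample_id, background, genotype, stage, segment,
    injection_order, sample_type``.  QC rows may leave the three factor
    columns blank; study rows must carry valid levels.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    df.columns = df.columns.str.strip()
    missing = [c for c in _DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise DataModelError(f"{path}: missing required columns {missing}")
    for col in ("sample_id", "background", "genotype", "stage", "segment", "sample_type"):
        df[col] = df[col].fillna("").astype(str).str.strip()
    df["injection_order"] = pd.to_numeric(df["injection_order"], errors="raise").astype(int)
    return StudyDesign(df[list(_DESIGN_COLUMNS)])


def assemble_matrix(
    values: pd.DataFrame, design: StudyDesign, stage_tag: str = "raw"
) -> MetaboliteMatrix:
    """Pair an intensity frame with its design, aligning row order."""
    ids = pd.Index(design.sample_ids)
    missing = ids.difference(values.index)
    if len(missing):
        raise DataModelError(f"intensity table lacks samples {missing.tolist()}")
    extra = values.index.difference(ids)
    if len(extra):
        raise DataModelError(f"intensity table has unknown samples {extra.tolist()}")
    return MetaboliteMatrix(values=values.loc[ids], design=design, stage_tag=stage_tag)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"  # round-trips to 12 significant digits


def write_table(obj, path: str | Path) -> Path:
    """Write a pipeline product to CSV (12 significant digits).

    Accepts any pandas DataFrame or an object exposing ``to_frame()``
    (EffectTable, TestTable, TrajectorySet, GeometrySummary).  An empty
    table produces a header-only file.
    """
    path = Path(path)
    frame = obj.to_frame() if hasattr(obj, "to_frame") and not isinstance(obj, pd.DataFrame) else obj
    if not isinstance(frame, pd.DataFrame):
        raise DataModelError(f"cannot write object of type {type(obj).__name__}")
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, float_format=_FLOAT_FMT, lineterminator="\n")
    return path


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """Re-read a table written by :func:`write_table`."""
    return pd.read_csv(Path(path), index_col=index_col)
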