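"""Delimited-table I/O and the package's core data containers.

Expression (FPKM) and quantification-cycle (Ct) matrices are stored as pandas
DataFrames with genes on the rows and samples on the columns; Ct matrices carry
a per-sample metadata frame (group, condition, biological/technical replicate
indices). Delimiters are always explicit — auto-detection is deliberately not
attempted, because a silently mis-parsed Ct table is a worse failure than a
flag.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DimensionError,
    IdentifierError,
    JoinError,
    TableFormatError,
    TableValueError,
)

CT_MIN = 0.0    # exclusive lower bound for a valid Ct
CT_MAX = 45.0   # inclusive upper bound (a 45-cycle run is the practical limit)

META_COLUMNS = ("group", "condition", "bio_rep", "tech_rep")
CONDITIONS = ("treatment", "control")


@dataclass
class ExpressionMatrix:
    """Nonnegative FPKM values, genes x samples."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        if df.shape[1] < 2:
            raise DimensionError("an expression matrix needs at least 2 samples")
        values = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            bad = _first_bad(df, ~np.isfinite(values))
            raise TableValueError(f"non-finite FPKM at gene {bad[0]!r}, sample {bad[1]!r}")
        if (values < 0).any():
            bad = _first_bad(df, values < 0)
            raise TableValueError(f"negative FPKM at gene {bad[0]!r}, sample {bad[1]!r}")
        self.data = df.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class CtMatrix:
    """Complete Ct matrix (genes x samples) with per-sample metadata.

    ``meta`` is indexed by sample id and has columns group, condition
    ('treatment' or 'control'), bio_rep (>= 1) and tech_rep (>= 1).
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        values = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            bad = _first_bad(df, ~np.isfinite(values))
            raise TableValueError(f"missing or non-finite Ct at gene {bad[0]!r}, sample {bad[1]!r}")
        if (values <= CT_MIN).any() or (values > CT_MAX).any():
            bad = _first_bad(df, (values <= CT_MIN) | (values > CT_MAX))
            raise TableValueError(
                f"Ct outside ({CT_MIN:g}, {CT_MAX:g}] at gene {bad[0]!r}, sample {bad[1]!r}"
            )
        meta = self.meta
        missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
        if missing_cols:
            raise TableFormatError(f"sample metadata lacks columns: {missing_cols}")
        absent = [s for s in df.columns if s not in meta.index]
        if absent:
            raise JoinError(f"samples missing from metadata: {absent}")
        meta = meta.loc[list(df.columns), list(META_COLUMNS)].copy()
        bad_cond = sorted(set(meta["condition"]) - set(CONDITIONS))
        if bad_cond:
            raise TableValueError(f"condition labels must be one of {CONDITIONS}, got {bad_cond}")
        for col in ("bio_rep", "tech_rep"):
            reps = meta[col].to_numpy()
            if not np.issubdtype(np.asarray(reps).dtype, np.integer) or (reps < 1).any():
                raise TableValueError(f"{col} must be integers >= 1")
        self.data = df.astype(float)
        self.meta = meta

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in column order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.meta["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def subset_groups(self, groups: list[str]) -> "CtMatrix":
        """Restrict to the samples whose group label is in ``groups``."""
        unknown = sorted(set(groups) - set(self.meta["group"]))
        if unknown:
            raise JoinError(f"unknown group labels: {unknown}")
        keep = [s for s in self.data.columns if self.meta.at[s, "group"] in set(groups)]
        return CtMatrix(self.data[keep].copy(), self.meta.loc[keep].copy())


@dataclass
class DilutionSeries:
    """(log10 relative template amount, Ct) points for one primer pair."""

    gene_id: str
    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        pts = [(float(x), float(ct)) for x, ct in self.points]
        if len(pts) < 3:
            raise DimensionError("a dilution series needs at least 3 points")
        if len({x for x, _ in pts}) < 3:
            raise DimensionError("a dilution series needs at least 3 distinct dilutions")
        if not all(np.isfinite(x) and np.isfinite(ct) for x, ct in pts):
            raise TableValueError(f"non-finite dilution point for gene {self.gene_id!r}")
        self.points = pts

    @property
    def log10_amounts(self) -> np.ndarray:
        return np.array([x for x, _ in self.points])

    @property
    def cts(self) -> np.ndarray:
        return np.array([ct for _, ct in self.points])


@dataclass
class RunConfig:
    """Thresholds and switches for a full pipeline run."""

    mv_min: float = 30.0
    top_n_sd: int = 500
    cv_max: float = 0.5
    mfc_max: float = 6.3
    efficiency_source: str = "default"  # 'default' (E = 2) or 'curves'
    v_cutoff: float = 0.15
    bestkeeper_variant: str = "plain_sd"
    seed: int = 0
    outdir: str = "refstab_out"
    # optional orchestration knobs
    simulate: bool = True
    subsets: dict = field(default_factory=dict)  # partition name -> list of groups
    targets: list = field(default_factory=list)
    references: list = field(default_factory=list)
    bad_reference: str | None = None
    control_group: str | None = None

    def __post_init__(self) -> None:
        for name in ("mv_min", "top_n_sd", "cv_max", "mfc_max"):
            if getattr(self, name) <= 0:
                raise TableValueError(f"{name} must be strictly positive")
        if not (0.0 < self.v_cutoff < 1.0):
            raise TableValueError("v_cutoff must lie in (0, 1)")
        if self.bestkeeper_variant not in ("plain_sd", "mad_geomean"):
            raise TableValueError("bestkeeper_variant must be 'plain_sd' or 'mad_geomean'")


def load_config(path: str | Path) -> RunConfig:
    """Read a flat YAML key-value file into a :class:`RunConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise TableFormatError(f"config file {path} is not a key-value document")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise TableFormatError(f"unknown config keys: {unknown}")
    return RunConfig(**raw)


def _check_unique(index, what: str) -> None:
    idx = pd.Index(index)
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique())
        raise IdentifierError(f"duplicate {what} identifiers: {dups}")
    if any(str(v).strip() == "" for v in idx):
        raise IdentifierError(f"empty {what} identifier")


def _first_bad(df: pd.DataFrame, mask: np.ndarray) -> tuple[str, str]:
    i, j = np.argwhere(mask)[0]
    return str(df.index[i]), str(df.columns[j])


def _read_matrix(path: str | Path, delimiter: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{path} is empty") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise TableFormatError(f"{path} has no data rows/columns")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise TableValueError(f"non-numeric value at gene {gene!r}, sample {col!r} in {path}")
        df[col] = coerced
    return df


def read_expression_table(path: str | Path, delimiter: str = ",") -> ExpressionMatrix:
    """Read a genes x samples FPKM table (header row = sample ids, first column = gene ids)."""
    return ExpressionMatrix(_read_matrix(path, delimiter))


def read_ct_table(path: str | Path, meta_path: str | Path, delimiter: str = ",") -> CtMatrix:
    """Read a Ct table plus its sample metadata table (columns sample_id, group,
    condition, bio_rep, tech_rep) and join them into a :class:`CtMatrix`."""
    data = _read_matrix(path, delimiter)
    meta = pd.read_csv(meta_path, sep=delimiter)
    if "sample_id" not in meta.columns:
        raise TableFormatError(f"{meta_path} lacks a sample_id column")
    _check_unique(meta["sample_id"], "metadata sample")
    meta = meta.set_index("sample_id")
    meta.index = meta.index.astype(str)
    return CtMatrix(data, meta)


def collapse_technical_replicates(ct: CtMatrix) -> CtMatrix:
    """Average technical replicates on the Ct scale.

    Columns sharing (group, condition, bio_rep) are technical replicates of one
    biological sample; each cell of the collapsed matrix is the arithmetic mean
    of its replicate Ct values. The surviving column keeps the first replicate's
    sample id and its tech_rep index is reset to 1. Idempotent.
    """
    meta = ct.meta
    key_of = {s: (meta.at[s, "group"], meta.at[s, "condition"], meta.at[s, "bio_rep"]) for s in ct.sample_ids}
    order: list[tuple] = []
    members: dict[tuple, list[str]] = {}
    for s in ct.sample_ids:
        k = key_of[s]
        if k not in members:
            members[k] = []
            order.append(k)
        members[k].append(s)
    cols = {}
    meta_rows = {}
    for k in order:
        reps = members[k]
        keep_id = reps[0]
        cols[keep_id] = ct.data[reps].mean(axis=1)
        row = meta.loc[keep_id].copy()
        row["tech_rep"] = 1
        meta_rows[keep_id] = row
    new_data = pd.DataFrame(cols)
    new_meta = pd.DataFrame(meta_rows).T
    new_meta["bio_rep"] = new_meta["bio_rep"].astype(int)
    new_meta["tech_rep"] = new_meta["tech_rep"].astype(int)
    return CtMatrix(new_data, new_meta)


def write_matrix(df: pd.DataFrame, path: str | Path, float_digits: int = 4, index_label: str = "gene_id") -> None:
    """Write a genes x samples matrix as CSV with fixed fractional digits."""
    df.to_csv(path, float_format=f"%.{float_digits}f", index_label=index_label)


def write_table(df: pd.DataFrame, path: str | Path, float_digits: int = 4) -> None:
    """Write a result table (no index) as CSV with fixed fractional digits."""
    df.to_csv(path, float_format=f"%.{float_digits}f", index=False)
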