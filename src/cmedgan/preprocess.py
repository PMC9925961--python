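"""Feature-table I/O and the preprocessing protocol.

Raw patient tables (mixed continuous / categorical / binary columns with
missing cells) are imputed, dummy-coded and min-max normalised into a
:class:`FeatureTable` whose values all lie in [0, 1] — the representation every
model in the pipeline consumes.  Min-max (rather than z-score) scaling is used
because the decoder emits sigmoid-bounded outputs, so generated features live
on the same scale as real ones.

Columns are always matched by name, never by position, and row order is
preserved end to end.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Schema",
    "RawTable",
    "FeatureTable",
    "SplitSpec",
    "SchemaError",
    "TableParseError",
    "read_table",
    "impute",
    "dummy_code",
    "normalize",
    "denormalize",
    "subsample",
    "write_feature_table",
    "read_feature_table",
]

KINDS = ("continuous", "categorical", "binary")


class SchemaError(ValueError):
    """Configuration problem: schema and table disagree."""


class TableParseError(ValueError):
    """A cell could not be parsed under its declared column kind."""


@dataclass
class Schema:
    """Declared column kinds plus the (optional) label column name."""

    kinds: dict[str, str]
    label: str | None = None

    def __post_init__(self) -> None:
        for col, kind in self.kinds.items():
            if kind not in KINDS:
                raise SchemaError(f"column {col!r}: unknown kind {kind!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "Schema":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        return cls(kinds=dict(data["columns"]), label=data.get("label"))

    def to_file(self, path: str | Path) -> None:
        data = {"columns": self.kinds, "label": self.label}
        p = Path(path)
        if p.suffix in (".yaml", ".yml"):
            p.write_text(yaml.safe_dump(data))
        else:
            p.write_text(json.dumps(data, indent=1))


@dataclass
class RawTable:
    """A parsed patient table prior to (or during) preprocessing.

    ``df`` holds feature columns only (label split off at read time);
    missingness is NaN.  Dummy-coded columns record their parent categorical
    in ``parents``.
    """

    df: pd.DataFrame
    kinds: dict[str, str]
    labels: pd.Series | None = None
    parents: dict[str, str] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def copy(self) -> "RawTable":
        return RawTable(
            self.df.copy(),
            dict(self.kinds),
            None if self.labels is None else self.labels.copy(),
            dict(self.parents),
        )


@dataclass
class FeatureTable:
    """Fully numeric feature matrix, all values in [0, 1]."""

    X: np.ndarray
    columns: list[str]
    kinds: list[str]  # per column: "binary" | "continuous"
    parents: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("matrix shape does not match column metadata")
        if len(self.kinds) != len(self.columns):
            raise ValueError("kinds must align with columns")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    @property
    def binary_mask(self) -> np.ndarray:
        return np.array([k == "binary" for k in self.kinds])

    def take(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.X[idx], list(self.columns), list(self.kinds), dict(self.parents))


@dataclass
class SplitSpec:
    """Repeated random-subset specification (the dataset-size protocol)."""

    fraction: float
    n_repeats: int = 5
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def _check_label(values: pd.Series) -> pd.Series:
    vals = pd.to_numeric(values, errors="coerce")
    bad = vals.dropna()[~vals.dropna().isin([0, 1])]
    if len(bad):
        raise TableParseError(
            f"label column contains non-binary value {bad.iloc[0]!r} at row {bad.index[0]}"
        )
    return vals


def read_table(
    path: str | Path,
    schema: Schema,
    *,
    sep: str | None = None,
    allow_extra: bool = False,
) -> RawTable:
    """Read a delimited table under a column-kind schema.

    The delimiter is taken from the file extension (``.tsv`` → tab) unless
    given explicitly.  Declared columns must all be present; undeclared ones
    are rejected unless ``allow_extra`` (then dropped with a warning).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)

    declared = set(schema.kinds) | ({schema.label} if schema.label else set())
    missing = declared - set(df.columns)
    if missing:
        raise SchemaError(f"declared columns absent from file: {sorted(missing)}")
    extra = set(df.columns) - declared
    if extra:
        if not allow_extra:
            raise SchemaError(f"undeclared columns present: {sorted(extra)}")
        warnings.warn(f"dropping undeclared columns: {sorted(extra)}")
        df = df.drop(columns=sorted(extra))

    labels = None
    if schema.label is not None:
        labels = _check_label(df[schema.label])
        df = df.drop(columns=[schema.label])

    out = {}
    for col, kind in schema.kinds.items():
        if kind in ("continuous", "binary"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() & df[col].notna() & (df[col].str.strip() != "")
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise TableParseError(
                    f"non-numeric value {df[col].iloc[row]!r} in numeric column "
                    f"{col!r} at row {row}"
                )
            if kind == "binary":
                obs = vals.dropna()
                if len(obs) and not obs.isin([0, 1]).all():
                    raise TableParseError(f"binary column {col!r} has values outside {{0,1}}")
            out[col] = vals
        else:
            out[col] = df[col].where(df[col].notna() & (df[col].str.strip() != ""))
    return RawTable(pd.DataFrame(out, columns=list(schema.kinds)), dict(schema.kinds), labels)


def impute(t: RawTable, *, continuous: str = "mean") -> RawTable:
    """Fill missing cells: mean (or median) for continuous, mode otherwise.

    Observed cells are never changed, so the operation is idempotent.
    """
    if continuous not in ("mean", "median"):
        raise ValueError("continuous strategy must be 'mean' or 'median'")
    t = t.copy()
    for col in t.df.columns:
        s = t.df[col]
        if not s.isna().any():
            continue
        obs = s.dropna()
        if obs.empty:
            raise ValueError(f"column {col!r} is entirely missing; cannot impute")
        if t.kinds[col] == "continuous":
            fill = obs.mean() if continuous == "mean" else obs.median()
        else:
            fill = obs.mode().iloc[0]
        t.df[col] = s.fillna(fill)
    if t.labels is not None and t.labels.isna().any():
        obs = t.labels.dropna()
        if obs.empty:
            raise ValueError("label column is entirely missing")
        t.labels = t.labels.fillna(obs.mode().iloc[0])
    return t


def dummy_code(t: RawTable) -> RawTable:
    """One-hot expand categorical columns; binary/continuous pass through.

    A categorical with k levels becomes k indicator columns named
    ``parent=level`` (levels sorted for determinism); their parent is recorded
    so dummy groups can be audited (they sum to 1 per row).
    """
    if t.df.isna().any().any():
        raise ValueError("impute before dummy coding")
    cols, kinds, parents = {}, {}, {}
    for col in t.df.columns:
        kind = t.kinds[col]
        if kind != "categorical":
            cols[col] = pd.to_numeric(t.df[col])
            kinds[col] = kind
            continue
        levels = sorted(t.df[col].astype(str).unique())
        if len(levels) == 1:
            warnings.warn(f"categorical column {col!r} has a single level")
        for lev in levels:
            name = f"{col}={lev}"
            cols[name] = (t.df[col].astype(str) == lev).astype(float)
            kinds[name] = "binary"
            parents[name] = col
    return RawTable(pd.DataFrame(cols), kinds, t.labels, parents)


def normalize(
    t: RawTable,
    stats: dict[str, tuple[float, float]] | None = None,
    *,
    clip: bool = True,
) -> tuple[FeatureTable, dict[str, tuple[float, float]]]:
    """Min-max scale continuous columns to [0, 1]; binary columns untouched.

    When ``stats`` (column → (min, max)) is supplied — e.g. training-set
    statistics applied to held-out data — those bounds are reused; out-of-range
    results are clipped to [0, 1] unless ``clip`` is off.  A constant column
    maps to 0.0 with a warning.
    """
    if t.df.isna().any().any():
        raise ValueError("normalize requires a complete (imputed) table")
    fitted = stats is None
    stats = {} if fitted else dict(stats)
    mat = np.empty((len(t.df), len(t.df.columns)), dtype=float)
    kinds = []
    for j, col in enumerate(t.df.columns):
        vals = pd.to_numeric(t.df[col]).to_numpy(dtype=float)
        kind = "continuous" if t.kinds[col] == "continuous" else "binary"
        kinds.append(kind)
        if kind == "binary":
            if not np.isin(vals, [0.0, 1.0]).all():
                raise TableParseError(f"binary column {col!r} has values outside {{0,1}}")
            mat[:, j] = vals
            continue
        if fitted:
            stats[col] = (float(vals.min()), float(vals.max()))
        lo, hi = stats[col]
        if hi == lo:
            warnings.warn(f"constant continuous column {col!r} mapped to 0.0")
            mat[:, j] = 0.0
            continue
        scaled = (vals - lo) / (hi - lo)
        mat[:, j] = np.clip(scaled, 0.0, 1.0) if clip else scaled
    ft = FeatureTable(mat, list(t.df.columns), kinds, dict(t.parents))
    return ft, stats


def denormalize(ft: FeatureTable, stats: dict[str, tuple[float, float]]) -> np.ndarray:
    """Invert :func:`normalize` for continuous columns (round-trip check)."""
    out = ft.X.copy()
    for j, (col, kind) in enumerate(zip(ft.columns, ft.kinds)):
        if kind == "continuous" and col in stats:
            lo, hi = stats[col]
            out[:, j] = out[:, j] * (hi - lo) + lo
    return out


def _stratified_indices(y: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    n_pos = int(round(size * len(pos) / len(y)))
    n_pos = min(max(n_pos, 1 if len(pos) else 0), len(pos), size)
    n_neg = size - n_pos
    idx = np.concatenate(
        [rng.choice(pos, n_pos, replace=False), rng.choice(neg, n_neg, replace=False)]
    )
    return np.sort(idx)


def subsample(
    ft: FeatureTable, y: np.ndarray, spec: SplitSpec
) -> list[tuple[FeatureTable, np.ndarray]]:
    """Draw ``n_repeats`` independent random subsets of the data.

    Each subset has round(fraction × n) rows, drawn without replacement and
    seeded from ``spec.seed`` plus the repeat index.  Stratified mode (default)
    matches the label prevalence of each subset to the full data, which is how
    the dataset-size ablation keeps mortality rates comparable across sizes.
    """
    y = np.asarray(y)
    size = int(round(spec.fraction * ft.n_rows))
    if size < 2:
        raise ValueError(f"subset size {size} too small (fraction={spec.fraction})")
    out = []
    for r in range(spec.n_repeats):
        if spec.fraction == 1.0:
            out.append((ft, y))
            continue
        rng = np.random.default_rng(spec.seed + r)
        if spec.stratified:
            idx = _stratified_indices(y, size, rng)
        else:
            idx = np.sort(rng.choice(ft.n_rows, size, replace=False))
        out.append((ft.take(idx), y[idx]))
    return out


def write_feature_table(
    ft: FeatureTable,
    y: np.ndarray | None,
    out_dir: str | Path,
    stats: dict | None = None,
) -> None:
    """Write features.csv + column_meta.json (+ norm_stats.json) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(ft.X, columns=ft.columns)
    if y is not None:
        df["__label__"] = np.asarray(y, dtype=int)
    df.to_csv(out / "features.csv", index=False)
    meta = {
        "columns": ft.columns,
        "kinds": ft.kinds,
        "parents": ft.parents,
        "label": "__label__" if y is not None else None,
    }
    (out / "column_meta.json").write_text(json.dumps(meta, indent=1))
    if stats is not None:
        (out / "norm_stats.json").write_text(json.dumps(stats, indent=1))


def read_feature_table(in_dir: str | Path) -> tuple[FeatureTable, np.ndarray | None]:
    """Read a directory written by :func:`write_feature_table`."""
    d = Path(in_dir)
    meta = json.loads((d / "column_meta.json").read_text())
    df = pd.read_csv(d / "features.csv")
    y = None
    if meta["label"] and meta["label"] in df.columns:
        y = df.pop(meta["label"]).to_numpy(dtype=int)
    ft = FeatureTable(
        df[meta["columns"]].to_numpy(dtype=float),
        meta["columns"],
        meta["kinds"],
        meta.get("parents", {}),
    )
    return ft, y
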