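"""Feature-table and metadata containers, TSV/BIOM IO, alignment and filtering.

The central container is :class:`FeatureTable`, a samples-in-rows numeric
matrix with a declared *space* tag describing what the values mean:

``counts``
    non-negative (integer-valued) sequencing counts;
``relative``
    compositions, each row summing to 1;
``log``
    log-transformed counts (e.g. log-CPM);
``clr``
    centered log-ratio coordinates, each row summing to 0;
``generic``
    anything else (externally transformed input, percentile scores, ...).

Downstream operations dispatch on the space tag and refuse inputs in the
wrong space, which catches most pipeline-wiring mistakes early.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("mbnoise")

SPACES = ("counts", "relative", "log", "clr", "generic")

#: tolerance for deciding that rows sum to 1 during space inference
RELATIVE_SUM_TOL = 1e-6


class FeatureTableError(ValueError):
    """Raised for malformed tables or invalid operations on them."""


@dataclass
class FeatureTable:
    """Sample x feature numeric matrix with identifiers and a space tag.

    Samples are rows. The per-feature design matrix used by the covariate
    correction (features x samples in the usual regression notation) is the
    transpose of ``values``.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    space: str = "generic"
    transform_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.space not in SPACES:
            raise FeatureTableError(f"unknown space {self.space!r}; expected one of {SPACES}")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise FeatureTableError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.feature_ids)} features)"
            )
        if not np.all(np.isfinite(self.values)):
            raise FeatureTableError("values contain NaN or infinities")
        if self.space == "counts" and np.any(self.values < 0):
            raise FeatureTableError("space='counts' requires non-negative values")
        if self.space == "relative":
            if np.any(self.values < 0):
                raise FeatureTableError("space='relative' requires non-negative values")
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-8):
                bad = np.argmax(np.abs(sums - 1.0))
                raise FeatureTableError(
                    f"space='relative' requires unit row sums; sample "
                    f"{self.sample_ids[bad]!r} sums to {sums[bad]!r}"
                )
        if self.space == "clr":
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 0.0, atol=1e-8):
                bad = np.argmax(np.abs(sums))
                raise FeatureTableError(
                    f"space='clr' requires zero row sums; sample "
                    f"{self.sample_ids[bad]!r} sums to {sums[bad]!r}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def with_values(self, values: np.ndarray, space: str, note: str) -> "FeatureTable":
        """Return a copy with new values/space, appending ``note`` to the log."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            space=space,
            transform_log=self.transform_log + [note],
        )

    def select_samples(self, index: np.ndarray | list[int]) -> "FeatureTable":
        idx = np.asarray(index)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[idx],
            transform_log=list(self.transform_log),
        )

    def select_features(self, index: np.ndarray | list[int]) -> "FeatureTable":
        idx = np.asarray(index)
        return replace(
            self,
            feature_ids=[self.feature_ids[i] for i in idx],
            values=self.values[:, idx],
            transform_log=list(self.transform_log),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, space: str | None = None, transform_log: list[str] | None = None
    ) -> "FeatureTable":
        values = df.to_numpy(dtype=float)
        if space is None:
            space = infer_space(values)
        return cls(
            sample_ids=list(df.index.astype(str)),
            feature_ids=list(df.columns.astype(str)),
            values=values,
            space=space,
            transform_log=list(transform_log or []),
        )


@dataclass
class SampleMetadata:
    """Per-sample covariate table with declared column types.

    ``column_types`` maps each usable column to ``"categorical"`` or
    ``"continuous"``; ``phenotype_col`` and ``batch_col`` designate the
    outcome and the study/batch label respectively.
    """

    data: pd.DataFrame
    column_types: dict[str, str]
    phenotype_col: str | None = None
    batch_col: str | None = None

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        _check_unique(list(self.data.index), "sample")
        for col, kind in self.column_types.items():
            if col not in self.data.columns:
                raise FeatureTableError(f"typed column {col!r} not present in metadata")
            if kind not in ("categorical", "continuous"):
                raise FeatureTableError(f"column {col!r} has unknown type {kind!r}")
        for name, col in (("phenotype_col", self.phenotype_col), ("batch_col", self.batch_col)):
            if col is not None and col not in self.data.columns:
                raise FeatureTableError(f"{name}={col!r} not present in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def column(self, name: str, samples: list[str] | None = None) -> pd.Series:
        """A fully observed column; missing values in a requested column are a hard error."""
        if name not in self.data.columns:
            raise FeatureTableError(f"metadata column {name!r} does not exist")
        series = self.data[name] if samples is None else self.data.loc[samples, name]
        if series.isna().any():
            missing = list(series.index[series.isna()])[:5]
            raise FeatureTableError(
                f"metadata column {name!r} has missing values for samples {missing} "
                "(no imputation is performed; drop these samples first)"
            )
        return series

    def type_of(self, name: str) -> str:
        if name in self.column_types:
            return self.column_types[name]
        # fall back on dtype for undeclared columns
        return "continuous" if pd.api.types.is_numeric_dtype(self.data[name]) else "categorical"

    def select_samples(self, sample_ids: list[str]) -> "SampleMetadata":
        return SampleMetadata(
            data=self.data.loc[sample_ids],
            column_types=dict(self.column_types),
            phenotype_col=self.phenotype_col,
            batch_col=self.batch_col,
        )


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
        raise FeatureTableError(f"duplicate {what} identifiers: {dupes[:10]}")


def infer_space(values: np.ndarray) -> str:
    """counts if non-negative integers, relative if rows sum to 1, else generic."""
    if np.all(values >= 0):
        if np.allclose(values, np.round(values), atol=1e-9):
            return "counts"
        if np.allclose(values.sum(axis=1), 1.0, atol=RELATIVE_SUM_TOL):
            return "relative"
    return "generic"


def read_feature_table(
    path, orientation: str = "samples_in_rows", space: str | None = None
) -> FeatureTable:
    """Read a TSV feature table (header row + one identifier column).

    Parameters
    ----------
    path : path-like
        Tab-delimited file; first column holds sample ids (or feature ids
        when ``orientation="features_in_rows"``).
    orientation : str
        ``samples_in_rows`` or ``features_in_rows``; the returned table is
        always samples-in-rows.
    space : str, optional
        Explicit space tag overriding inference.
    """
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise FeatureTableError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise FeatureTableError(
                f"non-numeric cell at row {row!r}, column {col!r}: {df.loc[row, col]!r}"
            )
        if converted.isna().any():
            row = df.index[converted.isna().to_numpy().argmax()]
            raise FeatureTableError(f"missing cell at row {row!r}, column {col!r}")
        numeric[col] = converted
    if not np.all(np.isfinite(numeric.to_numpy())):
        raise FeatureTableError("table contains non-finite values")
    if orientation == "features_in_rows":
        numeric = numeric.T
    return FeatureTable.from_dataframe(numeric, space=space)


def write_feature_table(table: FeatureTable, path, orientation: str = "samples_in_rows") -> None:
    """Write a TSV with 12 significant digits (round-trips through read)."""
    df = table.to_dataframe()
    id_col = "sample_id"
    if orientation == "features_in_rows":
        df = df.T
        id_col = "feature_id"
    df.index.name = id_col
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_biom_table(path) -> FeatureTable:
    """Read a BIOM 2.1 (HDF5) table into a samples-in-rows FeatureTable.

    BIOM 2.1 stores observations (features) x samples in CSR/CSC sparse
    groups; only the sample-major group is needed here.
    """
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as fh:
        sample_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in fh["sample/ids"][:]]
        feature_ids = [
            s.decode() if isinstance(s, bytes) else str(s) for s in fh["observation/ids"][:]
        ]
        grp = fh["sample/matrix"]
        mat = sparse.csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(sample_ids), len(feature_ids)),
        )
    return FeatureTable.from_dataframe(
        pd.DataFrame(mat.toarray(), index=sample_ids, columns=feature_ids)
    )


def read_metadata(
    path,
    column_types: dict[str, str] | None = None,
    phenotype_col: str | None = None,
    batch_col: str | None = None,
) -> SampleMetadata:
    """Read a sample metadata TSV (must contain a ``sample_id`` column)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FeatureTableError("metadata file must contain a 'sample_id' column")
    df = df.set_index("sample_id")
    if column_types is None:
        column_types = {}
        for col in df.columns:
            converted = pd.to_numeric(df[col], errors="coerce")
            column_types[col] = (
                "continuous" if converted.notna().all() and df[col].notna().all() else "categorical"
            )
    for col, kind in column_types.items():
        if kind == "continuous" and col in df.columns:
            df[col] = pd.to_numeric(df[col])
    return SampleMetadata(
        data=df, column_types=column_types, phenotype_col=phenotype_col, batch_col=batch_col
    )


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def align(table: FeatureTable, meta: SampleMetadata) -> tuple[FeatureTable, SampleMetadata]:
    """Restrict table and metadata to their common samples, in table order."""
    common = [s for s in table.sample_ids if s in set(meta.sample_ids)]
    if not common:
        raise FeatureTableError("no samples shared between feature table and metadata")
    dropped_t = sorted(set(table.sample_ids) - set(common))
    dropped_m = sorted(set(meta.sample_ids) - set(common))
    if dropped_t or dropped_m:
        logger.warning(
            "align dropped %d table-only samples %s and %d metadata-only samples %s",
            len(dropped_t), dropped_t[:5], len(dropped_m), dropped_m[:5],
        )
    pos = {s: i for i, s in enumerate(table.sample_ids)}
    table_out = table.select_samples([pos[s] for s in common])
    meta_out = meta.select_samples(common)
    return table_out, meta_out


def closure(table: FeatureTable) -> FeatureTable:
    """Renormalize each row to sum to 1 (composition / relative abundance)."""
    if table.space not in ("counts", "relative"):
        raise FeatureTableError(f"closure expects counts or relative data, got {table.space!r}")
    sums = table.values.sum(axis=1)
    if np.any(sums <= 0):
        bad = table.sample_ids[int(np.argmax(sums <= 0))]
        raise FeatureTableError(f"sample {bad!r} has no positive values; cannot close")
    return table.with_values(table.values / sums[:, None], "relative", "closure")


def prevalence_filter(table: FeatureTable, min_prevalence: float) -> FeatureTable:
    """Keep features present (value > 0) in at least ``min_prevalence`` of samples."""
    if not 0 <= min_prevalence <= 1:
        raise FeatureTableError("min_prevalence must be in [0, 1]")
    prevalence = (table.values > 0).mean(axis=0)
    keep = np.flatnonzero(prevalence >= min_prevalence)
    if keep.size == 0:
        raise FeatureTableError(
            f"prevalence filter at {min_prevalence} would remove every feature"
        )
    out = table.select_features(keep)
    out.transform_log = table.transform_log + [f"prevalence_filter({min_prevalence})"]
    return out
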